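import pytest

from hybnum.hybridnumber import (
    _sound_to_expand,
    attain_simple,
    enumerate_small_networks,
    hybrid_number,
    min_hybrids_strictly_simple,
    proposition2_upper,
)
from hybnum.netcore import NetworkError
from hybnum.numrep import ceil_log2

from hybnum.cli_io import random_profile
from conftest import profile


class TestSearch:
    @pytest.mark.parametrize("m,h", [(1, 0), (2, 1), (4, 2), (5, 3), (9, 4), (15, 5)])
    def test_known_minima(self, m, h):
        got, net = min_hybrids_strictly_simple(m)
        assert got == h
        assert net.path_count_vector() == {"x1": m}
        assert net.hybrid_number() == h
        assert net.is_binary()

    def test_power_of_two_is_bead_chain_depth(self):
        for k in range(7):
            got, net = min_hybrids_strictly_simple(2**k)
            assert got == k

    def test_budget_below_lower_bound_rejected(self):
        with pytest.raises(ValueError):
            min_hybrids_strictly_simple(5, budget=2)

    def test_infeasible_budget_raises(self):
        with pytest.raises(NetworkError):
            min_hybrids_strictly_simple(7, budget=3)  # h((7)) = 4


class TestPruning:
    """The prune predicate must never cut a feasible state."""

    def test_sum_rule(self):
        # sum of open counts exceeds the target: infeasible
        assert not _sound_to_expand((3, 3), 5, 5)
        assert _sound_to_expand((3, 2), 5, 5)

    def test_size_rule(self):
        # closing k open arcs needs k-1 merges
        assert not _sound_to_expand((1, 1, 1), 1, 3)
        assert _sound_to_expand((1, 1, 1), 2, 3)

    def test_doubling_potential(self):
        # {1,1} with 2 merges can reach at most 4
        assert not _sound_to_expand((1, 1), 2, 5)
        assert _sound_to_expand((1, 1), 3, 5)

    def test_gcd_rule(self):
        assert not _sound_to_expand((2, 4), 5, 7)
        assert _sound_to_expand((2, 4), 5, 8)


class TestEnumerationOracle:
    def test_h1_counts(self):
        nets = enumerate_small_networks(1)
        counts = sorted(next(iter(n.unfold_leaf_multiset().values())) for n in nets)
        assert counts == [1, 2]  # the single-leaf tree and the bead

    def test_h2_max_count_is_4(self):
        nets = enumerate_small_networks(2)
        best = max(
            next(iter(n.unfold_leaf_multiset().values()))
            for n in nets
            if n.hybrid_number() == 2
        )
        assert best == 4

    def test_h3_reaches_5(self):
        nets = enumerate_small_networks(3)
        reachable = {next(iter(n.unfold_leaf_multiset().values())) for n in nets}
        assert 5 in reachable

    def test_rejects_large_hmax(self):
        with pytest.raises(ValueError):
            enumerate_small_networks(4)

    def test_search_matches_enumeration(self):
        """Two independent routes: multiset-quotient IDDFS vs brute-force
        network enumeration, for every m reachable with <= 3 hybrids."""
        best: dict[int, int] = {}
        for net in enumerate_small_networks(3):
            (m,) = net.unfold_leaf_multiset().values()
            h = net.hybrid_number()
            best[m] = min(best.get(m, 99), h)
        assert set(best) == {1, 2, 3, 4, 5, 6, 8}
        for m, h in best.items():
            assert min_hybrids_strictly_simple(m)[0] == h


class TestAttainSimple:
    def test_2111(self):
        net, certified = attain_simple(profile(2, 1, 1, 1))
        assert certified
        assert net.hybrid_number() == 1
        assert net.realizes(profile(2, 1, 1, 1))

    def test_51(self):
        net, certified = attain_simple(profile(5, 1))
        assert certified
        assert net.hybrid_number() == 3

    def test_all_ones_tree(self):
        net, certified = attain_simple(profile(1, 1, 1))
        assert certified
        assert net.hybrid_number() == 0
        assert net.path_count_vector() == {"x1": 1, "x2": 1, "x3": 1}

    def test_above_limit_falls_back_uncertified(self):
        net, certified = attain_simple(profile(47), search_limit=10)
        assert not certified
        assert net.path_count_vector() == {"x1": 47}

    def test_non_simple_rejected(self):
        with pytest.raises(NetworkError):
            attain_simple(profile(5, 2))


class TestHybridNumber:
    def test_12665_exact_5(self):
        res = hybrid_number(profile(12, 6, 6, 5))
        assert res.status == "exact" and res.value == 5
        assert res.certificate.realizes(profile(12, 6, 6, 5))
        assert res.certificate.hybrid_number() == 5

    def test_viola_exact_5(self):
        res = hybrid_number(profile(9, 7, 7, 4, 4, 4, 2, 2, 2, 2, 2, 1))
        assert res.status == "exact" and res.value == 5

    def test_842_exact_3_both_routes(self):
        res = hybrid_number(profile(8, 4, 2))
        assert res.status == "exact" and res.value == 3

    def test_82_power_of_two_exact(self):
        # the simplification route alone is not exact here (its traceback
        # network has 4 hybrids), but the power-of-two attainment is
        res = hybrid_number(profile(8, 2))
        assert res.status == "exact" and res.value == 3
        assert res.certificate.hybrid_number() == 3

    def test_122_returns_bounds(self):
        res = hybrid_number(profile(12, 2))
        assert res.status == "bounds"
        assert res.lower == 4
        assert res.upper == 5
        assert res.certificate.realizes(profile(12, 2))
        assert res.certificate.hybrid_number() == res.upper

    def test_random_profiles_bounds_and_certificates(self):
        for seed in range(200):
            p = random_profile(seed=1000 + seed, n=(seed % 5) + 1, max_entry=32)
            res = hybrid_number(p, search_limit=32)
            assert res.lower <= res.upper
            assert res.certificate.realizes(p)
            assert res.certificate.hybrid_number() == res.upper
            assert res.lower >= ceil_log2(p.head)
            if res.status == "exact":
                assert res.value == res.lower == res.upper

    def test_power_of_two_profiles_agree_with_formula(self):
        for mults in [(8,), (16, 4), (8, 8, 2, 1), (4, 4, 4, 4), (32, 16, 1, 1)]:
            res = hybrid_number(profile(*mults))
            assert res.status == "exact"
            assert res.value == max(mults).bit_length() - 1


class TestProposition2Upper:
    def test_15(self):
        assert proposition2_upper(profile(15)) == 6

    def test_all_ones(self):
        assert proposition2_upper(profile(1, 1)) == 0

    def test_12665(self):
        assert proposition2_upper(profile(12, 6, 6, 5)) == 13
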