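"""Exact attainment search and the top-level hybrid-number computation.

The search operates on a quotient of single-leaf binary network space: a
state is the multiset of root-to-arc path counts of the currently "open"
arcs.  Starting from ``{1, 1}`` (the two root arcs), a tree vertex
duplicates one open count (free) and a hybrid vertex merges two open counts
into their sum (cost one); the goal state is the singleton ``{m}``.  Every
single-leaf binary network induces such a move sequence via a topological
order, and every move sequence rebuilds a valid network, so the minimum
number of merges equals the minimum hybrid number.  A brute-force network
enumerator (:func:`enumerate_small_networks`) guards this quotient argument
for up to three hybrids.

The top-level :func:`hybrid_number` combines the simplification sequence,
the terminal attainment and the traceback into either an exact value (when
no simplification step had ``m_1 > 2 m_2`` and the terminal attainment is
certified) or certified lower/upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import gcd

import networkx as nx

from .constructions import beaded_tree, build_B, build_D, naive_realization
from .netcore import NetworkError, PhyloNetwork, PloidyProfile
from .numrep import binary_representation, ceil_log2
from .simplify import simplification_sequence
from .traceback import build_N

__all__ = [
    "HybridNumberResult",
    "min_hybrids_strictly_simple",
    "enumerate_small_networks",
    "attain_simple",
    "hybrid_number",
    "proposition2_upper",
    "DEFAULT_SEARCH_LIMIT",
    "DEFAULT_BUDGET",
]

#: Heads above this are not searched exhaustively by default.
DEFAULT_SEARCH_LIMIT = 512
#: Hybrid budget cap for the default iterative-deepening search.
DEFAULT_BUDGET = 12


@dataclass
class HybridNumberResult:
    """Outcome of :func:`hybrid_number`.

    ``status`` is "exact" (then ``value == lower == upper``) or "bounds".
    ``certificate`` is a verifying network achieving ``upper``.
    """

    status: str
    lower: int
    upper: int
    certificate: PhyloNetwork
    value: int | None = None
    method_notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.lower <= self.upper
        if self.status == "exact":
            assert self.value == self.lower == self.upper


# ---------------------------------------------------------------------------
# State-space search over open-count multisets
# ---------------------------------------------------------------------------


def _sound_to_expand(state: tuple[int, ...], r: int, m: int) -> bool:
    """Prune predicates.  All are *soundness-preserving*: a pruned state
    cannot reach {m} within r further merges.

    - every open arc has at least one path to the single leaf, so m is a
      positive integer combination of the open counts; hence sum(state) <= m
      and gcd(state) divides m;
    - closing k open arcs into one needs k - 1 merges;
    - only duplicates raise the sum, at most doubling it, and exactly
      r - (k - 1) duplicates remain, so sum * 2^(r - (k - 1)) >= m.
    """
    k = len(state)
    if k - 1 > r:
        return False
    total = sum(state)
    if total > m:
        return False
    if total << (r - (k - 1)) < m:
        return False
    g = 0
    for c in state:
        g = gcd(g, c)
    return m % g == 0


def _dfs(
    state: tuple[int, ...],
    r: int,
    m: int,
    fail: dict[tuple[int, ...], int],
    moves: list[tuple],
) -> bool:
    """Depth-first search for a move sequence from ``state`` to ``(m,)``
    using at most ``r`` merges.  ``fail`` memoizes states that cannot reach
    the goal with a given remaining budget (the predicate is absolute, so
    the memo survives iterative deepening)."""
    if state == (m,):
        return True
    if not _sound_to_expand(state, r, m):
        return False
    if fail.get(state, -1) >= r:
        return False
    k = len(state)
    values = sorted(set(state))
    # duplicates: only if budget allows an extra merge beyond the mandatory k-1
    if r - (k - 1) >= 1:
        total = sum(state)
        for c in values:  # smaller counts first
            if total + c > m:
                break
            child = tuple(sorted(state + (c,)))
            moves.append(("dup", c))
            if _dfs(child, r, m, fail, moves):
                return True
            moves.pop()
    # merges, in sorted order of the value pair
    seen_pairs = set()
    for i, c1 in enumerate(values):
        for c2 in values[i:]:
            if c2 == c1 and state.count(c1) < 2:
                continue
            if c1 + c2 > m:
                break
            if (c1, c2) in seen_pairs:
                continue
            seen_pairs.add((c1, c2))
            lst = list(state)
            lst.remove(c1)
            lst.remove(c2)
            lst.append(c1 + c2)
            child = tuple(sorted(lst))
            moves.append(("merge", c1, c2))
            if _dfs(child, r - 1, m, fail, moves):
                return True
            moves.pop()
    prev = fail.get(state, -1)
    if r > prev:
        fail[state] = r
    return False


def _replay(moves: list[tuple], m: int, leaf_label: str) -> PhyloNetwork:
    """Rebuild the explicit network from a successful move sequence."""
    net = PhyloNetwork()
    root = net.new_vertex()
    open_arcs: list[tuple[str, int]] = [(root, 1), (root, 1)]
    for move in moves:
        if move[0] == "dup":
            c = move[1]
            idx = next(i for i, (_, cc) in enumerate(open_arcs) if cc == c)
            tail, _ = open_arcs.pop(idx)
            t = net.new_vertex()
            net.add_arc(tail, t)
            open_arcs.insert(idx, (t, c))
            open_arcs.insert(idx + 1, (t, c))
        else:
            _, c1, c2 = move
            i1 = next(i for i, (_, cc) in enumerate(open_arcs) if cc == c1)
            i2 = next(i for i, (_, cc) in enumerate(open_arcs) if cc == c2 and i != i1)
            t1, _ = open_arcs[i1]
            t2, _ = open_arcs[i2]
            for i in sorted((i1, i2), reverse=True):
                open_arcs.pop(i)
            w = net.new_vertex()
            net.add_arc(t1, w)
            net.add_arc(t2, w)
            open_arcs.append((w, c1 + c2))
    assert len(open_arcs) == 1 and open_arcs[0][1] == m
    leaf = net.new_vertex(label=leaf_label)
    net.add_arc(open_arcs[0][0], leaf)
    return net


@lru_cache(maxsize=None)
def _search_cached(m: int, budget: int) -> tuple[int, tuple] | None:
    fail: dict[tuple[int, ...], int] = {}
    for h in range(ceil_log2(m), budget + 1):
        moves: list[tuple] = []
        if _dfs((1, 1), h, m, fail, moves):
            return h, tuple(moves)
    return None


def min_hybrids_strictly_simple(
    m: int, budget: int | None = None, leaf_label: str = "x1"
) -> tuple[int, PhyloNetwork]:
    """Minimum hybrid number over single-leaf binary networks realizing (m),
    plus an explicit network achieving it.

    Iterative deepening on the hybrid count, from ``ceil_log2(m)`` up to
    ``budget`` (default: the B-construction count ``i_1 + q - 1``, which is
    always sufficient).  Raises :class:`NetworkError` if no realization
    exists within an explicitly passed budget.
    """
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    if m == 1:
        net = PhyloNetwork()
        net.new_vertex(label=leaf_label)
        return 0, net
    rep = binary_representation(m)
    b_count = rep.msb_exponent + rep.q - 1
    if budget is None:
        budget = b_count
    if budget < ceil_log2(m):
        raise ValueError(
            f"budget {budget} is below the path-count lower bound {ceil_log2(m)}"
        )
    found = _search_cached(m, min(budget, b_count))
    if found is None:
        raise NetworkError(f"no realization of ({m},) within a budget of {budget} hybrids")
    h, moves = found
    net = _replay(list(moves), m, leaf_label)
    # verify the certificate independently
    net.require_valid()
    assert net.is_binary()
    assert net.path_count_vector() == {leaf_label: m}
    assert net.hybrid_number() == h
    return h, net


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle (small instances only)
# ---------------------------------------------------------------------------


def enumerate_small_networks(h_max: int) -> list[PhyloNetwork]:
    """All single-leaf binary networks with at most ``h_max`` hybrid
    vertices, up to isomorphism.  Brute force over construction sequences on
    an *ordered* list of open arcs (no multiset quotient, no pruning beyond
    feasibility), so it is an independent check of the search."""
    if h_max > 3:
        raise ValueError("enumerate_small_networks is a brute-force oracle; h_max <= 3")
    results: list[PhyloNetwork] = []
    degenerate = PhyloNetwork()
    degenerate.new_vertex(label="x1")
    results.append(degenerate)  # the only hybrid-free single-leaf network

    def close(net: PhyloNetwork, open_arcs: list[str]) -> PhyloNetwork:
        closed = net.copy()
        leaf = closed.new_vertex(label="x1")
        closed.add_arc(open_arcs[0], leaf)
        return closed

    def rec(net: PhyloNetwork, open_arcs: list[str], merges: int) -> None:
        if len(open_arcs) == 1:
            results.append(close(net, open_arcs))
        if len(open_arcs) - 1 > h_max - merges:
            return
        # split arc i -> tree vertex
        if merges < h_max:  # a split only pays off if another merge follows
            for i in range(len(open_arcs)):
                child = net.copy()
                t = child.new_vertex()
                child.add_arc(open_arcs[i], t)
                rec(child, open_arcs[:i] + [t, t] + open_arcs[i + 1 :], merges)
        # merge arcs i < j -> hybrid vertex
        if merges < h_max:
            for i in range(len(open_arcs)):
                for j in range(i + 1, len(open_arcs)):
                    child = net.copy()
                    w = child.new_vertex()
                    child.add_arc(open_arcs[i], w)
                    child.add_arc(open_arcs[j], w)
                    rest = [t for k, t in enumerate(open_arcs) if k not in (i, j)]
                    rec(child, rest + [w], merges + 1)

    seed = PhyloNetwork()
    root = seed.new_vertex()
    rec(seed, [root, root], 0)

    # deduplicate up to isomorphism (instances are tiny)
    unique: list[PhyloNetwork] = []
    signatures: list[tuple] = []
    for net in results:
        degs = tuple(sorted((net.indegree(v), net.outdegree(v)) for v in net.vertices))
        sig = (net.num_vertices(), net.num_arcs(), degs)
        dup = False
        for other, other_sig in zip(unique, signatures):
            if sig == other_sig and nx.is_isomorphic(net._g, other._g):
                dup = True
                break
        if not dup:
            unique.append(net)
            signatures.append(sig)
    return unique


# ---------------------------------------------------------------------------
# Attainments of simple profiles
# ---------------------------------------------------------------------------


def attain_simple(
    profile: PloidyProfile,
    search_limit: int = DEFAULT_SEARCH_LIMIT,
    budget: int | None = DEFAULT_BUDGET,
) -> tuple[PhyloNetwork, bool]:
    """A realization of a simple profile, minimal when certifiable.

    The head component is realized by the exact search when it is within
    ``search_limit`` (certified: pendant 1-leaves cannot contribute hybrid
    vertices, so the head search minimum is the profile's hybrid number);
    otherwise by the better of B and D (not certified).  The remaining
    1-components become pendant leaves on a root outgoing arc, where the
    path count is one.
    """
    if not profile.is_simple:
        raise NetworkError(f"attain_simple requires a simple profile, got {profile}")
    m1 = profile.head
    head_label = profile.labels[0]
    if m1 == 1:
        from .constructions import _caterpillar

        return _caterpillar(profile.labels), True

    certified = False
    core: PhyloNetwork | None = None
    if m1 <= search_limit:
        try:
            _, core = min_hybrids_strictly_simple(m1, budget=budget, leaf_label=head_label)
            certified = True
        except NetworkError:
            core = None
    if core is None:
        b = build_B(PloidyProfile.from_multiplicities([m1], [head_label]))
        try:
            d = build_D(
                PloidyProfile.from_multiplicities([m1], [head_label]),
                search_limit=search_limit,
            )
        except (NetworkError, ValueError):
            d = None
        core = b if d is None or b.hybrid_number() <= d.hybrid_number() else d

    if len(profile) > 1:
        from .constructions import _attach_pendant_chain

        root_arcs = sorted(core.out_arcs(core.root), key=lambda a: a[2])
        _attach_pendant_chain(core, root_arcs[0], list(profile.labels[1:]))
    return core, certified


# ---------------------------------------------------------------------------
# Bounds and the closed formula
# ---------------------------------------------------------------------------


def proposition2_upper(profile: PloidyProfile) -> int:
    """Component-wise upper bound: sum over k of (msb exponent + popcount - 1),
    realized by joining the single-leaf B-networks of every component under
    one root."""
    total = 0
    for _, m in profile:
        rep = binary_representation(m)
        total += rep.msb_exponent + rep.q - 1
    return total


def _star_of_B(profile: PloidyProfile) -> PhyloNetwork:
    """The network realizing the :func:`proposition2_upper` bound: one
    single-leaf B-network per component, joined by a caterpillar of roots."""
    blocks = [
        build_B(PloidyProfile.from_multiplicities([m], [lab])) for lab, m in profile
    ]
    if len(blocks) == 1:
        return blocks[0]
    net = PhyloNetwork()
    spine = [net.new_vertex() for _ in range(len(blocks) - 1)]
    for a, b in zip(spine, spine[1:]):
        net.add_arc(a, b)
    roots = []
    for block in blocks:
        vmap = net.absorb(block, carry_labels=True)
        roots.append(vmap[block.root])
    for i, r in enumerate(roots[:-1]):
        net.add_arc(spine[i], r)
    net.add_arc(spine[-1], roots[-1])
    return net


def _power_of_two_chain(profile: PloidyProfile) -> PhyloNetwork:
    """Attainment for profiles whose components are all powers of two: a
    bead chain for the head, with each other component hung as a pendant
    leaf at the depth where the path count matches it."""
    mults = profile.multiplicities
    assert all(m & (m - 1) == 0 for m in mults)
    a1 = mults[0].bit_length() - 1
    if a1 == 0:
        from .constructions import _caterpillar

        return _caterpillar(profile.labels)
    net = beaded_tree(a1, leaf_label=profile.labels[0])
    # attachment arc per depth: depth 0 -> a root arc; depth j -> out-arc of
    # the j-th bead hybrid.  Kept current as subdivisions accumulate.
    hybrids = []
    v = net.root
    while net.outdegree(v) > 0:
        v = net.out_arcs(v)[0][1]
        if net.indegree(v) >= 2:
            hybrids.append(v)
    attach_arc: dict[int, tuple] = {0: sorted(net.out_arcs(net.root), key=lambda a: a[2])[0]}
    for j, h in enumerate(hybrids, start=1):
        attach_arc[j] = net.out_arcs(h)[0]
    for lab, m in profile.entries[1:]:
        depth = m.bit_length() - 1
        arc = attach_arc[depth]
        head = arc[1]
        t, _ = net.add_pendant_leaf(arc, lab)
        (cont,) = [a for a in net.out_arcs(t) if a[1] == head]
        attach_arc[depth] = cont
    return net


def hybrid_number(
    profile: PloidyProfile,
    search_limit: int = DEFAULT_SEARCH_LIMIT,
    budget: int | None = DEFAULT_BUDGET,
) -> HybridNumberResult:
    """Hybrid number of an arbitrary ploidy profile.

    Exact when (a) every component is a power of two (bead-chain attainment
    meets the path-count lower bound), or (b) no simplification step had
    ``alpha > m_2`` and the terminal attainment is certified, in which case
    the value is ``h(terminal) + c`` with the traceback network as
    certificate.  Otherwise certified lower/upper bounds are returned.
    """
    notes: list[str] = []
    mults = profile.multiplicities
    m1 = mults[0]

    if all(m & (m - 1) == 0 for m in mults):
        value = m1.bit_length() - 1
        cert = _power_of_two_chain(profile)
        assert cert.realizes(profile) and cert.hybrid_number() == value
        notes.append(
            "all components are powers of two: bead-chain attainment meets the "
            f"2^h path-count lower bound (h = {value})"
        )
        seq = simplification_sequence(profile)
        if not seq.line8_fired:
            terminal_net, certified = attain_simple(
                seq.terminal, search_limit=search_limit, budget=budget
            )
            if certified:
                general = terminal_net.hybrid_number() + seq.c
                assert general == value, (
                    f"closed formula ({general}) disagrees with the power-of-two "
                    f"shortcut ({value})"
                )
                notes.append("cross-checked against the simplification-sequence formula")
        return HybridNumberResult(
            status="exact",
            lower=value,
            upper=value,
            value=value,
            certificate=cert,
            method_notes=notes,
        )

    seq = simplification_sequence(profile)
    terminal_net, certified = attain_simple(
        seq.terminal, search_limit=search_limit, budget=budget
    )
    network = build_N(seq, terminal_net)

    if not seq.line8_fired and certified:
        value = terminal_net.hybrid_number() + seq.c
        assert network.hybrid_number() == value
        assert network.realizes(profile)
        notes.append(
            f"exact: no simplification step had alpha > m_2; h = h(terminal) + c "
            f"= {terminal_net.hybrid_number()} + {seq.c}"
        )
        return HybridNumberResult(
            status="exact",
            lower=value,
            upper=value,
            value=value,
            certificate=network,
            method_notes=notes,
        )

    # bounds
    lower = ceil_log2(m1)
    notes.append(f"lower bound {lower}: a realization of ({m1},) needs ceil(log2) hybrids")
    if m1 <= search_limit:
        try:
            h1, _ = min_hybrids_strictly_simple(m1, budget=budget)
            if h1 > lower:
                lower = h1
                notes.append(
                    f"lower bound raised to {h1}: deleting all other leaves of a "
                    f"realization leaves a realization of ({m1},)"
                )
        except NetworkError:
            pass

    candidates: list[tuple[int, PhyloNetwork, str]] = [
        (network.hybrid_number(), network, "traceback network"),
        (proposition2_upper(profile), _star_of_B(profile), "per-component B star"),
        (sum(m - 1 for m in mults), naive_realization(profile), "naive ladder realization"),
    ]
    upper, certificate, how = min(candidates, key=lambda t: t[0])
    assert certificate.realizes(profile)
    assert certificate.hybrid_number() == upper
    notes.append(f"upper bound {upper} from the {how}")
    if seq.line8_fired:
        notes.append("a simplification step had alpha > m_2, so the traceback is not certified exact")
    if not certified:
        notes.append("terminal attainment was not certified (head above the search limit)")

    if lower == upper:
        return HybridNumberResult(
            status="exact",
            lower=lower,
            upper=upper,
            value=upper,
            certificate=certificate,
            method_notes=notes + ["bounds met, so the value is exact"],
        )
    return HybridNumberResult(
        status="bounds",
        lower=lower,
        upper=upper,
        certificate=certificate,
        method_notes=notes,
    )
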