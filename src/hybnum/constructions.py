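"""Explicit realizations of simple ploidy profiles.

* :func:`beaded_tree` -- a chain of q beads over a single leaf; path count 2^q.
* :func:`build_B` -- realization driven by the binary representation of the
  head multiplicity; hybrid count ``i_1 + q - 1``.
* :func:`build_D` -- realization driven by the prime factor decomposition of
  the head, stacking single-leaf realizations of each prime.
* :func:`naive_realization` -- works for any profile, with sum(m_i - 1)
  hybrid vertices; establishes that the hybrid number always exists.
"""

from __future__ import annotations

from typing import Mapping

from .netcore import Arc, NetworkError, PhyloNetwork, PloidyProfile
from .numrep import binary_representation, prime_factorization_desc

__all__ = [
    "beaded_tree",
    "build_B",
    "build_D",
    "naive_realization",
    "theorem1_vertex_count",
]


def _require_simple(profile: PloidyProfile, op: str) -> None:
    if not profile.is_simple:
        raise NetworkError(
            f"{op} is only defined for simple profiles "
            f"(every component after the first must be 1); got {profile.multiplicities}"
        )


def _caterpillar(labels: tuple[str, ...]) -> PhyloNetwork:
    """A rooted binary tree with the given leaves (all path counts 1)."""
    net = PhyloNetwork()
    if len(labels) == 1:
        net.new_vertex(label=labels[0])
        return net
    cur = net.new_vertex()  # root
    for lab in labels[:-2]:
        leaf = net.new_vertex(label=lab)
        nxt = net.new_vertex()
        net.add_arc(cur, leaf)
        net.add_arc(cur, nxt)
        cur = nxt
    for lab in labels[-2:]:
        leaf = net.new_vertex(label=lab)
        net.add_arc(cur, leaf)
    return net


def beaded_tree(q: int, leaf_label: str = "x1") -> PhyloNetwork:
    """Chain of ``q`` beads from the root down to a single leaf.

    Each bead doubles the path count, so the leaf count is 2^q and the hybrid
    number is q.  For q = 0 the degenerate single-vertex network is returned
    (a two-vertex rooted tree would violate root out-degree two).
    """
    if q < 0:
        raise ValueError(f"q must be non-negative, got {q}")
    net = PhyloNetwork()
    if q == 0:
        net.new_vertex(label=leaf_label)
        return net
    top = net.new_vertex()  # root, tail of the first bead
    for j in range(q):
        if j > 0:  # tree vertex between consecutive beads
            t = net.new_vertex()
            net.add_arc(top, t)
            top = t
        hyb = net.new_vertex()
        net.add_arc(top, hyb)
        net.add_arc(top, hyb)  # parallel arc: the bead
        top = hyb
    leaf = net.new_vertex(label=leaf_label)
    net.add_arc(top, leaf)
    return net


def _bead_chain_with_handles(q: int, leaf_label: str) -> tuple[PhyloNetwork, list[str]]:
    """beaded_tree(q) plus the hybrid vertices ordered root-to-leaf."""
    net = beaded_tree(q, leaf_label=leaf_label)
    hybrids: list[str] = []
    v = net.root
    while net.outdegree(v) > 0:
        v = net.out_arcs(v)[0][1]
        if net.indegree(v) >= 2:
            hybrids.append(v)
    return net, hybrids


def _attach_pendant_chain(net: PhyloNetwork, arc: Arc, labels: list[str]) -> None:
    """Subdivide ``arc`` into a chain t_2, t_3, ... (nearest the tail first)
    and hang one pendant leaf per label; every pendant's path count equals
    the root-to-tail count of ``arc``."""
    head = arc[1]
    cur = arc
    for lab in labels:
        t, _ = net.add_pendant_leaf(cur, lab)
        # continue subdividing below t, i.e. on the arc (t, head)
        (cont,) = [a for a in net.out_arcs(t) if a[1] == head]
        cur = cont
        head = cur[1]


def build_B(profile: PloidyProfile) -> PhyloNetwork:
    """The binary-representation realization of a simple profile.

    Starting from the bead chain ``B(i_1)``, one chain of subdivision
    vertices s_2..s_q on one root arc feeds an extra arc a_j into a
    subdivision vertex of the outgoing arc of the hybrid with exactly i_j
    bead hybrids strictly below it (for i_j = 0 this is the leaf's incoming
    arc).  Pendant 1-leaves for the non-head taxa go on the other root arc.

    Hybrid count: i_1 + q - 1; vertex count: :func:`theorem1_vertex_count`.
    """
    _require_simple(profile, "build_B")
    head_label = profile.labels[0]
    m1 = profile.head
    if m1 == 1:
        return _caterpillar(profile.labels)

    rep = binary_representation(m1)
    i1, exps, q = rep.msb_exponent, rep.exponents, rep.q
    net, hybrids = _bead_chain_with_handles(i1, head_label)
    root = net.root
    # out-arc of each bead hybrid, recorded before any surgery
    hybrid_out = {h: net.out_arcs(h)[0] for h in hybrids}
    root_arcs = sorted(net.out_arcs(root), key=lambda a: a[2])
    s_arc, t_arc = root_arcs[0], root_arcs[1]

    cur = s_arc
    for j in range(1, q):  # s_{j+1}; exponents i_2..i_q
        i_j = exps[j]
        head = cur[1]
        s = net.subdivide_arc(cur)
        # hybrid with exactly i_j bead hybrids strictly below it
        target = hybrids[i1 - i_j - 1]
        w = net.subdivide_arc(hybrid_out[target])
        net.add_arc(s, w)
        (cur,) = [a for a in net.out_arcs(s) if a[1] == head]

    if len(profile) > 1:
        _attach_pendant_chain(net, t_arc, list(profile.labels[1:]))
    return net


def theorem1_vertex_count(profile: PloidyProfile) -> int:
    """Closed-form vertex count of ``build_B``: 2(i_1 + q - 1 + n - 1) + 1."""
    _require_simple(profile, "theorem1_vertex_count")
    rep = binary_representation(profile.head)
    return 2 * (rep.msb_exponent + rep.q - 1 + len(profile) - 1) + 1


def _stack(lower_onto: PhyloNetwork, block: PhyloNetwork) -> PhyloNetwork:
    """Identify the unique leaf of ``lower_onto`` with the root of ``block``
    (both single-leaf networks); returns ``lower_onto`` mutated in place."""
    (leaf,) = lower_onto.leaves
    lower_onto.drop_label(leaf)
    vmap = lower_onto.absorb(block)
    block_root = vmap[block.root]
    for _, w, _ in lower_onto.out_arcs(block_root):
        lower_onto.add_arc(leaf, w)
    # delete the absorbed root; `leaf` has taken over its role
    lower_onto.remove_vertex(block_root)
    (block_leaf,) = [v for v in lower_onto.leaves]
    lab = block.leaf_labels[block.leaves[0]]
    lower_onto.set_label(block_leaf, lab)
    return lower_onto


def build_D(
    profile: PloidyProfile,
    prime_attainments: Mapping[int, PhyloNetwork] | None = None,
    search_limit: int = 512,
) -> PhyloNetwork:
    """The prime-decomposition realization of a simple profile with head >= 2.

    For ``m_1 = p_1^a_1 * ... * p_k^a_k`` (primes descending), single-leaf
    realizations of each prime are stacked leaf-onto-root, a_i consecutive
    copies per prime.  ``prime_attainments`` may supply a single-leaf binary
    network realizing ``(p)`` for any prime ``p``; otherwise the exact search
    provides one (falling back to ``build_B((p,))`` above ``search_limit``).
    """
    _require_simple(profile, "build_D")
    m1 = profile.head
    if m1 < 2:
        raise NetworkError("build_D requires a head multiplicity of at least 2")
    head_label = profile.labels[0]
    prime_attainments = dict(prime_attainments or {})

    def realization_of(p: int) -> PhyloNetwork:
        if p in prime_attainments:
            cand = prime_attainments[p]
            cand.require_valid()
            counts = list(cand.path_count_vector().values())
            if len(counts) != 1 or counts[0] != p:
                raise NetworkError(
                    f"supplied attainment for prime {p} realizes {counts}, not ({p},)"
                )
            if not cand.is_binary():
                raise NetworkError(f"supplied attainment for prime {p} is not binary")
            return cand
        if p <= search_limit:
            from .hybridnumber import min_hybrids_strictly_simple

            _, net = min_hybrids_strictly_simple(p)
            return net
        return build_B(PloidyProfile.from_multiplicities([p]))

    stacked: PhyloNetwork | None = None
    for p, alpha in prime_factorization_desc(m1):
        block = realization_of(p)
        for _ in range(alpha):
            if stacked is None:
                stacked = PhyloNetwork()
                stacked.absorb(block, carry_labels=True)
            else:
                stacked = _stack(stacked, block)
    assert stacked is not None
    # normalise the single leaf's label to the profile's head label
    (leaf,) = stacked.leaves
    stacked.drop_label(leaf)
    stacked.set_label(leaf, head_label)

    if len(profile) > 1:
        root_arcs = sorted(stacked.out_arcs(stacked.root), key=lambda a: a[2])
        _attach_pendant_chain(stacked, root_arcs[0], list(profile.labels[1:]))
    return stacked


def _count_ladder(net: PhyloNetwork, leaf_vertex: str, m: int) -> None:
    """Replace the leaf's incoming arc (count 1) by a ladder gadget raising
    the leaf's path count to ``m`` with exactly m - 1 binary hybrids."""
    (in_arc,) = net.in_arcs(leaf_vertex)
    p = in_arc[0]
    net.remove_arc(in_arc)
    c = [net.new_vertex() for _ in range(m - 1)]
    d = [net.new_vertex() for _ in range(m - 1)]
    net.add_arc(p, c[0])
    for k in range(m - 2):
        net.add_arc(c[k], c[k + 1])
    net.add_arc(c[-1], d[0])
    for k in range(m - 2):
        net.add_arc(d[k], d[k + 1])
    net.add_arc(d[-1], leaf_vertex)
    for k in range(m - 1):
        net.add_arc(c[k], d[k])


def naive_realization(profile: PloidyProfile) -> PhyloNetwork:
    """A realization of an arbitrary profile with sum(m_i - 1) hybrid vertices.

    A binary tree carries one leaf per taxon (path count 1); each leaf whose
    multiplicity is m >= 2 gets a ladder gadget on its incoming arc in which
    m - 1 rungs each add one extra root-to-leaf path.
    """
    labels, mults = profile.labels, profile.multiplicities
    n = len(profile)
    if n == 1:
        m = mults[0]
        if m == 1:
            return _caterpillar(labels)
        # root doubles as the top rung tail so that its out-degree is two
        net = PhyloNetwork()
        c = [net.new_vertex() for _ in range(m - 1)]
        d = [net.new_vertex() for _ in range(m - 1)]
        leaf = net.new_vertex(label=labels[0])
        for k in range(m - 2):
            net.add_arc(c[k], c[k + 1])
        net.add_arc(c[-1], d[0])
        for k in range(m - 2):
            net.add_arc(d[k], d[k + 1])
        net.add_arc(d[-1], leaf)
        for k in range(m - 1):
            net.add_arc(c[k], d[k])
        return net
    net = _caterpillar(labels)
    for lab, m in profile:
        if m >= 2:
            _count_ladder(net, net.leaf_vertex(lab), m)
    return net
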