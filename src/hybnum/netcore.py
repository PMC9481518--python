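"""Rooted phylogenetic networks with parallel arcs (beads).

A phylogenetic network here is a rooted, connected, acyclic multigraph in
which the root has out-degree two, every other internal vertex is either a
tree vertex (in-degree 1, out-degree 2) or a hybrid vertex (in-degree >= 2,
out-degree 1), and every leaf (in-degree 1, out-degree 0) carries a unique
taxon label.  Parallel arcs are first class: a pair of parallel arcs between
two vertices is a *bead* and models whole-genome doubling.  Loops are
forbidden.

The one intentional degeneracy is the single-vertex network (its vertex is
simultaneously root and leaf), which realizes the profile ``(1)`` and is the
only network whose root has out-degree zero.

This module also defines :class:`PloidyProfile`, the descending multiplicity
vector whose hybrid number the rest of the package computes, and the local
surgeries (arc subdivision, cherry expansion, hybridization, pendant-leaf
attachment) that the network constructions are built from.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "NetworkError",
    "PloidyProfile",
    "PhyloNetwork",
    "Arc",
    "validate",
    "is_binary",
    "path_count_vector",
    "network_hybrid_number",
    "realizes",
    "subdivide_arc",
    "expand_cherry",
    "hybridize",
    "add_pendant_leaf",
    "unfold_leaf_multiset",
]

#: An arc occurrence handle: (tail, head, key).  The key distinguishes
#: parallel arcs, so "subdivide this particular parallel arc" is well defined.
Arc = tuple


class NetworkError(ValueError):
    """Raised when a network violates the model or an operation precondition."""


# ---------------------------------------------------------------------------
# Ploidy profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PloidyProfile:
    """A descending multiplicity vector indexed by taxon labels.

    ``entries`` is a tuple of ``(label, multiplicity)`` pairs with unique
    labels, all multiplicities >= 1 and multiplicities in descending order.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a ploidy profile must have at least one entry")
        labels = [lab for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate taxon labels in profile: {labels}")
        mults = [m for _, m in self.entries]
        for lab, m in self.entries:
            if not isinstance(m, int) or m < 1:
                raise ValueError(f"multiplicity of {lab!r} must be a positive integer, got {m!r}")
        if any(mults[i] < mults[i + 1] for i in range(len(mults) - 1)):
            raise ValueError(f"multiplicities must be in descending order, got {mults}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "PloidyProfile":
        """Build a profile from (label, multiplicity) pairs, sorting them
        into descending order (stable, so ties keep their input order)."""
        ordered = sorted(pairs, key=lambda p: -p[1])
        return cls(tuple((str(lab), int(m)) for lab, m in ordered))

    @classmethod
    def from_multiplicities(
        cls, multiplicities: Sequence[int], labels: Sequence[str] | None = None
    ) -> "PloidyProfile":
        """Build a profile from bare multiplicities; default labels are
        ``x1, x2, ...`` assigned after descending sort."""
        mults = sorted((int(m) for m in multiplicities), reverse=True)
        if labels is None:
            labels = [f"x{i + 1}" for i in range(len(mults))]
        if len(labels) != len(mults):
            raise ValueError("labels and multiplicities differ in length")
        return cls(tuple(zip(labels, mults)))

    # -- accessors ----------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.entries)

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(m for _, m in self.entries)

    @property
    def mapping(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def head(self) -> int:
        """The first (largest) multiplicity."""
        return self.entries[0][1]

    @property
    def is_simple(self) -> bool:
        """True iff every component after the first equals one."""
        return all(m == 1 for _, m in self.entries[1:])

    @property
    def is_strictly_simple(self) -> bool:
        return len(self.entries) == 1

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{lab}:{m}" for lab, m in self.entries)
        return f"PloidyProfile({inner})"


# ---------------------------------------------------------------------------
# Phylogenetic networks
# ---------------------------------------------------------------------------


class PhyloNetwork:
    """Mutable rooted DAG multigraph with labelled leaves.

    Fresh vertices are named ``v0, v1, ...`` in creation order so repeated
    runs produce identical arc lists.
    """

    def __init__(self) -> None:
        self._g: nx.MultiDiGraph = nx.MultiDiGraph()
        self._next_id = 0
        self._labels: dict[str, str] = {}  # vertex -> taxon label

    # -- low-level construction --------------------------------------------

    def new_vertex(self, label: str | None = None) -> str:
        """Create a fresh, deterministically named vertex."""
        while True:
            v = f"v{self._next_id}"
            self._next_id += 1
            if v not in self._g:
                break
        self._g.add_node(v)
        if label is not None:
            self.set_label(v, label)
        return v

    def add_named_vertex(self, name: str) -> str:
        """Add a vertex with a caller-chosen name (used by file readers)."""
        self._g.add_node(name)
        return name

    def add_arc(self, tail: str, head: str) -> Arc:
        if tail == head:
            raise NetworkError(f"loop arc at {tail!r} is not allowed")
        key = self._g.add_edge(tail, head)
        return (tail, head, key)

    def remove_arc(self, arc: Arc) -> None:
        tail, head, key = arc
        if not self._g.has_edge(tail, head, key):
            raise NetworkError(f"arc {arc!r} is not in the network")
        self._g.remove_edge(tail, head, key)

    def remove_vertex(self, vertex: str) -> None:
        self._g.remove_node(vertex)
        self._labels.pop(vertex, None)

    def set_label(self, vertex: str, label: str) -> None:
        if label in self._labels.values():
            raise NetworkError(f"taxon label {label!r} already in use")
        self._labels[vertex] = label

    def drop_label(self, vertex: str) -> None:
        self._labels.pop(vertex, None)

    def copy(self) -> "PhyloNetwork":
        other = PhyloNetwork()
        other._g = self._g.copy()
        other._next_id = self._next_id
        other._labels = dict(self._labels)
        return other

    def absorb(self, other: "PhyloNetwork", carry_labels: bool = False) -> dict[str, str]:
        """Copy ``other``'s vertices and arcs into this network under fresh
        vertex names; returns the old-name -> new-name map."""
        vmap: dict[str, str] = {}
        for v in other.vertices:
            vmap[v] = self.new_vertex()
        for tail, head, _ in other.arcs:
            self.add_arc(vmap[tail], vmap[head])
        if carry_labels:
            for v, lab in other._labels.items():
                self.set_label(vmap[v], lab)
        return vmap

    # -- basic accessors ----------------------------------------------------

    @property
    def vertices(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def arcs(self) -> list[Arc]:
        return [(u, v, k) for u, v, k in self._g.edges(keys=True)]

    def num_vertices(self) -> int:
        return self._g.number_of_nodes()

    def num_arcs(self) -> int:
        return self._g.number_of_edges()

    def indegree(self, v: str) -> int:
        return self._g.in_degree(v)

    def outdegree(self, v: str) -> int:
        return self._g.out_degree(v)

    def in_arcs(self, v: str) -> list[Arc]:
        return [(u, w, k) for u, w, k in self._g.in_edges(v, keys=True)]

    def out_arcs(self, v: str) -> list[Arc]:
        return [(u, w, k) for u, w, k in self._g.out_edges(v, keys=True)]

    def has_arc(self, arc: Arc) -> bool:
        tail, head, key = arc
        return self._g.has_edge(tail, head, key)

    @property
    def root(self) -> str:
        roots = [v for v in self._g.nodes if self._g.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkError(f"network has {len(roots)} in-degree-0 vertices, expected 1")
        return roots[0]

    @property
    def leaves(self) -> list[str]:
        return [v for v in self._g.nodes if self._g.out_degree(v) == 0]

    @property
    def leaf_labels(self) -> dict[str, str]:
        """Mapping leaf vertex -> taxon label."""
        return {v: self._labels[v] for v in self.leaves if v in self._labels}

    def label_of(self, vertex: str) -> str | None:
        return self._labels.get(vertex)

    def leaf_vertex(self, label: str) -> str:
        for v, lab in self._labels.items():
            if lab == label:
                return v
        raise NetworkError(f"no leaf labelled {label!r}")

    def hybrid_vertices(self) -> list[str]:
        return [v for v in self._g.nodes if self._g.in_degree(v) >= 2]

    def leaf_in_arc(self, label: str) -> Arc:
        """The unique incoming arc of the leaf carrying ``label``."""
        v = self.leaf_vertex(label)
        ins = self.in_arcs(v)
        if len(ins) != 1:
            raise NetworkError(f"leaf {label!r} has in-degree {len(ins)}, expected 1")
        return ins[0]

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of human-readable invariant violations (empty iff
        the network is a valid phylogenetic network)."""
        g = self._g
        problems: list[str] = []
        if g.number_of_nodes() == 0:
            return ["network has no vertices"]
        if g.number_of_nodes() == 1:
            v = next(iter(g.nodes))
            if g.number_of_edges() != 0:
                problems.append(f"single-vertex network has arcs (loop at {v!r}?)")
            if v not in self._labels:
                problems.append(f"degenerate leaf {v!r} has no taxon label")
            return problems

        for u, v in g.edges():
            if u == v:
                problems.append(f"loop arc at {u!r}")
        roots = [v for v in g.nodes if g.in_degree(v) == 0]
        if len(roots) == 0:
            problems.append("multiple roots: no in-degree-0 vertex (graph is cyclic?)")
        elif len(roots) > 1:
            problems.append(f"multiple roots: in-degree-0 vertices {sorted(roots)}")
        else:
            root = roots[0]
            if g.out_degree(root) != 2:
                problems.append(
                    f"root {root!r} has out-degree {g.out_degree(root)}, expected 2"
                )
        if not nx.is_directed_acyclic_graph(g):
            problems.append("arc relation contains a directed cycle")
        if not nx.is_weakly_connected(g):
            problems.append("underlying graph is not connected")

        for v in g.nodes:
            indeg, outdeg = g.in_degree(v), g.out_degree(v)
            if indeg == 0:
                continue  # root, handled above
            if outdeg == 0:
                if indeg != 1:
                    problems.append(f"leaf {v!r} has in-degree {indeg}, expected 1")
                if v not in self._labels:
                    problems.append(f"leaf {v!r} has no taxon label")
            elif (indeg, outdeg) == (1, 2):
                pass  # tree vertex
            elif indeg >= 2 and outdeg == 1:
                pass  # hybrid vertex
            else:
                problems.append(
                    f"vertex {v!r} has degree ({indeg},{outdeg}); it is neither a "
                    "tree vertex (1,2), hybrid vertex (>=2,1), nor a leaf (1,0)"
                )
        labelled = [v for v in self._labels if g.out_degree(v) > 0]
        for v in labelled:
            problems.append(f"non-leaf vertex {v!r} carries taxon label {self._labels[v]!r}")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise NetworkError("; ".join(problems))

    def is_binary(self) -> bool:
        """True iff every hybrid vertex has in-degree exactly two."""
        self.require_valid()
        return all(self._g.in_degree(v) == 2 for v in self.hybrid_vertices())

    # -- path counting ------------------------------------------------------

    def path_count_vector(self) -> dict[str, int]:
        """Number of root-to-leaf directed paths per taxon label, computed by
        dynamic programming over a topological order.  Parallel arcs count
        with multiplicity."""
        g = self._g
        root = self.root
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise NetworkError("cannot count paths: network is cyclic") from exc
        counts: dict[str, int] = {v: 0 for v in g.nodes}
        counts[root] = 1
        for v in order:
            if v == root:
                continue
            counts[v] = sum(counts[u] for u, _, _ in g.in_edges(v, keys=True))
        labels = self.leaf_labels
        missing = [v for v in self.leaves if v not in labels]
        if missing:
            raise NetworkError(f"unlabelled leaves: {missing}")
        return {labels[v]: counts[v] for v in self.leaves}

    def vertex_path_counts(self) -> dict[str, int]:
        """Root-to-vertex path counts for every vertex (same DP as above)."""
        g = self._g
        root = self.root
        counts: dict[str, int] = {v: 0 for v in g.nodes}
        counts[root] = 1
        for v in nx.topological_sort(g):
            if v == root:
                continue
            counts[v] = sum(counts[u] for u, _, _ in g.in_edges(v, keys=True))
        return counts

    def unfold_leaf_multiset(self) -> Counter:
        """Leaf multiset of the unfolded multi-labelled tree: every complete
        root-to-leaf walk is enumerated explicitly, one per arc occurrence.

        Deliberately independent of :meth:`path_count_vector` (no dynamic
        programming) so the two can cross-check each other.  Cost is linear
        in the total number of root-to-leaf paths.
        """
        labels = self.leaf_labels
        multiset: Counter = Counter()

        def walk(v: str) -> None:
            if self._g.out_degree(v) == 0:
                multiset[labels[v]] += 1
                return
            for _, w, _ in self._g.out_edges(v, keys=True):
                walk(w)

        walk(self.root)
        return multiset

    def hybrid_number(self) -> int:
        """Sum over hybrid vertices of (in-degree - 1)."""
        return sum(self._g.in_degree(v) - 1 for v in self.hybrid_vertices())

    def realizes(self, profile: PloidyProfile) -> bool:
        """True iff the per-label path counts equal the profile's mapping."""
        counts = self.path_count_vector()
        if set(counts) != set(profile.labels):
            raise NetworkError(
                f"leaf label set {sorted(counts)} differs from profile labels "
                f"{sorted(profile.labels)}"
            )
        return counts == profile.mapping

    def profile(self) -> PloidyProfile:
        """The ploidy profile this network realizes."""
        return PloidyProfile.from_pairs(self.path_count_vector().items())

    # -- surgeries ----------------------------------------------------------

    def subdivide_arc(self, arc: Arc) -> str:
        """Replace arc (u, v) by (u, s), (s, v) with a fresh vertex s.

        Path counts to all pre-existing vertices are unchanged.
        """
        tail, head, key = arc
        if not self._g.has_edge(tail, head, key):
            raise NetworkError(f"arc {arc!r} is not in the network")
        self._g.remove_edge(tail, head, key)
        s = self.new_vertex()
        self.add_arc(tail, s)
        self.add_arc(s, head)
        return s

    def expand_cherry(self, leaf_label: str, new_label: str) -> tuple[str, str]:
        """Turn the leaf carrying ``leaf_label`` into a tree vertex with two
        new leaf children labelled ``leaf_label`` and ``new_label``.

        Both new leaves inherit the old leaf's path count; +2 vertices.
        """
        if new_label in self._labels.values():
            raise NetworkError(f"label {new_label!r} already present")
        v = self.leaf_vertex(leaf_label)
        self.drop_label(v)
        c1 = self.new_vertex(label=leaf_label)
        c2 = self.new_vertex(label=new_label)
        self.add_arc(v, c1)
        self.add_arc(v, c2)
        return c1, c2

    def hybridize(self, donor_label: str, receiver_label: str) -> str:
        """Route one extra bundle of paths from above the donor leaf into the
        receiver leaf.

        The donor's incoming arc is subdivided by a tree vertex ``u``, the
        receiver's incoming arc by a vertex ``v``, and the arc (u, v) is
        added, making ``v`` a binary hybrid.  The receiver's path count grows
        by the donor's; all other counts are unchanged.  +2 vertices, +1 to
        the hybrid number.  Returns the new hybrid vertex ``v``.
        """
        if donor_label == receiver_label:
            raise NetworkError("donor and receiver must be distinct leaves")
        donor_arc = self.leaf_in_arc(donor_label)
        receiver_arc = self.leaf_in_arc(receiver_label)
        u = self.subdivide_arc(donor_arc)
        v = self.subdivide_arc(receiver_arc)
        self.add_arc(u, v)
        return v

    def add_pendant_leaf(self, arc: Arc, label: str) -> tuple[str, str]:
        """Subdivide ``arc`` by a vertex t and hang a new leaf off t.

        The new leaf's path count equals the root-to-t count; all other
        counts are unchanged.  Returns ``(t, leaf_vertex)``.
        """
        if label in self._labels.values():
            raise NetworkError(f"label {label!r} already present")
        t = self.subdivide_arc(arc)
        leaf = self.new_vertex(label=label)
        self.add_arc(t, leaf)
        return t, leaf

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PhyloNetwork |V|={self.num_vertices()} |A|={self.num_arcs()} "
            f"leaves={sorted(self._labels.values())}>"
        )


# ---------------------------------------------------------------------------
# Functional aliases mirroring the operation names used elsewhere
# ---------------------------------------------------------------------------


def validate(network: PhyloNetwork) -> list[str]:
    return network.validate()


def is_binary(network: PhyloNetwork) -> bool:
    return network.is_binary()


def path_count_vector(network: PhyloNetwork) -> dict[str, int]:
    return network.path_count_vector()


def network_hybrid_number(network: PhyloNetwork) -> int:
    return network.hybrid_number()


def realizes(network: PhyloNetwork, profile: PloidyProfile) -> bool:
    return network.realizes(profile)


def subdivide_arc(network: PhyloNetwork, arc: Arc) -> str:
    return network.subdivide_arc(arc)


def expand_cherry(network: PhyloNetwork, leaf_label: str, new_label: str) -> tuple[str, str]:
    return network.expand_cherry(leaf_label, new_label)


def hybridize(network: PhyloNetwork, donor_label: str, receiver_label: str) -> str:
    return network.hybridize(donor_label, receiver_label)


def add_pendant_leaf(network: PhyloNetwork, arc: Arc, label: str) -> tuple[str, str]:
    return network.add_pendant_leaf(arc, label)


def unfold_leaf_multiset(network: PhyloNetwork) -> Counter:
    return network.unfold_leaf_multiset()
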