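"""Core data structures for generic ancestral recombination graphs (ARGs).

An ARG is viewed as the union of ``M`` embedded marginal trees over the same
``K`` extant samples: a directed acyclic multigraph whose edges carry one
*strand* per tree index ("color"), each strand annotated with a set of
mutation labels.  Edges are directed from parent (older) to child (more
recent); leaves sit at time 0 and carry all ``M`` non-mixing segments.

Vertices are classified locally:

* *coalescent*   -- at least two distinct children;
* *exchange*     -- at least two distinct parents (genetic-exchange node);
* *t-coalescent* -- coalescent in at least one embedded tree, i.e. at least
  two outgoing strands of the same color;
* *gapped*       -- the set of incident tree indices ``sg(v)`` is not a
  consecutive integer run.

A vertex may be coalescent and exchange at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional


class ArgError(ValueError):
    """Invalid operation on an ARG (unknown vertex, undefined removal, ...)."""


@dataclass(frozen=True)
class Strand:
    """One colored edge between a parent/child vertex pair.

    ``tree`` is the 1-based index of the embedded marginal tree the strand
    belongs to; ``labels`` is the (possibly empty) set of mutation
    identifiers riding on this strand.
    """

    parent: str
    child: str
    tree: int
    labels: frozenset = frozenset()

    def with_labels(self, labels: Iterable[str]) -> "Strand":
        return Strand(self.parent, self.child, self.tree, frozenset(labels))


def _strand_key(s: Strand):
    return (s.parent, s.child, s.tree)


class Arg:
    """A generic ARG: timed vertices plus colored, labeled strands.

    Parameters
    ----------
    M : int
        Number of non-mixing segments (embedded trees), numbered ``1..M``
        left to right along the chromosome.
    segment_lengths : sequence of float
        Lengths ``s_1..s_M`` of the segments (presentation/rate weighting
        only; intra-segment positions are not modeled).
    vertices : mapping str -> float
        Vertex identifier to time in generations (leaves at 0, increasing
        into the past).
    strands : iterable of Strand
    leaves : sequence of str
        The ``K`` extant samples, in fixed order.
    """

    def __init__(self, M, segment_lengths, vertices, strands, leaves):
        self.M = int(M)
        self.segment_lengths = tuple(float(x) for x in segment_lengths)
        self.vertices: dict = dict(vertices)
        self.strands: tuple = tuple(strands)
        self.leaves: tuple = tuple(leaves)
        self._out = None
        self._in = None

    # -- basic accessors ---------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.leaves)

    def time(self, v: str) -> float:
        try:
            return self.vertices[v]
        except KeyError:
            raise ArgError(f"unknown vertex {v!r}")

    def is_leaf(self, v: str) -> bool:
        return v in self._leafset

    @property
    def _leafset(self):
        return frozenset(self.leaves)

    def _index(self):
        if self._out is None:
            out: dict = {v: [] for v in self.vertices}
            inc: dict = {v: [] for v in self.vertices}
            for s in self.strands:
                out[s.parent].append(s)
                inc[s.child].append(s)
            self._out = out
            self._in = inc
        return self._out, self._in

    def out_strands(self, v: str):
        out, _ = self._index()
        if v not in out:
            raise ArgError(f"unknown vertex {v!r}")
        return out[v]

    def in_strands(self, v: str):
        _, inc = self._index()
        if v not in inc:
            raise ArgError(f"unknown vertex {v!r}")
        return inc[v]

    def children(self, v: str) -> set:
        return {s.child for s in self.out_strands(v)}

    def parents(self, v: str) -> set:
        return {s.parent for s in self.in_strands(v)}

    def out_by_tree(self, v: str) -> dict:
        d: dict = {}
        for s in self.out_strands(v):
            d.setdefault(s.tree, []).append(s)
        return d

    def in_by_tree(self, v: str) -> dict:
        d: dict = {}
        for s in self.in_strands(v):
            d.setdefault(s.tree, []).append(s)
        return d

    def replace(self, vertices=None, strands=None, leaves=None) -> "Arg":
        return Arg(
            self.M,
            self.segment_lengths,
            self.vertices if vertices is None else vertices,
            self.strands if strands is None else strands,
            self.leaves if leaves is None else leaves,
        )

    # -- reachability ------------------------------------------------------

    def descendants(self, v: str, tree: Optional[int] = None) -> set:
        """All vertices reachable from ``v`` (excluding ``v``) along strands,
        optionally restricted to one tree color."""
        seen: set = set()
        stack = [v]
        while stack:
            u = stack.pop()
            for s in self.out_strands(u):
                if tree is not None and s.tree != tree:
                    continue
                if s.child not in seen:
                    seen.add(s.child)
                    stack.append(s.child)
        return seen

    def ancestors(self, v: str, tree: Optional[int] = None) -> set:
        """All vertices from which ``v`` is reachable (excluding ``v``)."""
        seen: set = set()
        stack = [v]
        while stack:
            u = stack.pop()
            for s in self.in_strands(u):
                if tree is not None and s.tree != tree:
                    continue
                if s.parent not in seen:
                    seen.add(s.parent)
                    stack.append(s.parent)
        return seen

    def canonical_strands(self) -> tuple:
        return tuple(sorted(self.strands, key=_strand_key))

    def __eq__(self, other):
        if not isinstance(other, Arg):
            return NotImplemented
        return (
            self.M == other.M
            and self.segment_lengths == other.segment_lengths
            and self.vertices == other.vertices
            and sorted(self.strands, key=_strand_key)
            == sorted(other.strands, key=_strand_key)
            and self.leaves == other.leaves
        )

    def __repr__(self):
        return (
            f"Arg(K={self.K}, M={self.M}, |V|={len(self.vertices)}, "
            f"|strands|={len(self.strands)})"
        )


@dataclass(frozen=True)
class VertexClass:
    """Local classification of one ARG vertex."""

    is_coalescent: bool
    is_exchange: bool
    is_t_coalescent: bool
    is_gapped: bool
    sg: frozenset


@dataclass(frozen=True)
class Violation:
    """One structural-validation failure; violations are data, not exceptions."""

    code: str
    subject: str
    message: str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def sg(arg: Arg, v: str) -> frozenset:
    """The set of embedded-tree indices incident (in or out) on ``v``."""
    if v not in arg.vertices:
        raise ArgError(f"unknown vertex {v!r}")
    return frozenset(
        s.tree for s in list(arg.out_strands(v)) + list(arg.in_strands(v))
    )


def overlap(arg: Arg, v1: str, v2: str) -> bool:
    """Do ``v1`` and ``v2`` carry at least one common segment?"""
    return bool(sg(arg, v1) & sg(arg, v2))


def _is_consecutive(indices: frozenset) -> bool:
    if not indices:
        return True
    return max(indices) - min(indices) + 1 == len(indices)


def classify(arg: Arg, v: str) -> VertexClass:
    if v not in arg.vertices:
        raise ArgError(f"unknown vertex {v!r}")
    out_by_tree = arg.out_by_tree(v)
    s = sg(arg, v)
    return VertexClass(
        is_coalescent=len(arg.children(v)) >= 2,
        is_exchange=len(arg.parents(v)) >= 2,
        is_t_coalescent=any(len(ss) >= 2 for ss in out_by_tree.values()),
        is_gapped=bool(s) and not _is_consecutive(s),
        sg=s,
    )


def is_t_coalescent(arg: Arg, v: str) -> bool:
    """Coalescent in at least one embedded tree: >=2 same-color out-strands."""
    return any(len(ss) >= 2 for ss in arg.out_by_tree(v).values())


def validate(arg: Arg) -> list:
    """Check all structural invariants; returns a (possibly empty) report.

    Checks: parameter sanity, referential integrity, strict time ordering
    along strands (which implies acyclicity), one strand per color per
    vertex pair, the no-chains rule (every non-leaf vertex has multiple
    children or multiple parents), label transmission (every mutation
    label reaches a leaf along its tree), and that every leaf carries all
    ``M`` segments and has no outgoing strands.
    """
    out: list = []

    if arg.K < 2:
        out.append(Violation("params", "K", f"K={arg.K}, need K > 1"))
    if arg.M < 1:
        out.append(Violation("params", "M", f"M={arg.M}, need M >= 1"))
    if len(arg.segment_lengths) != arg.M:
        out.append(
            Violation(
                "params",
                "segment_lengths",
                f"{len(arg.segment_lengths)} lengths for M={arg.M} segments",
            )
        )
    for i, s in enumerate(arg.segment_lengths, 1):
        if not s > 0:
            out.append(Violation("params", f"s_{i}", f"segment length {s} <= 0"))

    for u in arg.leaves:
        if u not in arg.vertices:
            out.append(Violation("referential", u, "leaf not among vertices"))
    known = set(arg.vertices)
    seen_pairs: set = set()
    for s in arg.strands:
        subj = f"{s.parent}->{s.child}[{s.tree}]"
        if s.parent not in known or s.child not in known:
            out.append(Violation("referential", subj, "strand endpoint undeclared"))
            continue
        if not 1 <= s.tree <= arg.M:
            out.append(Violation("tree-index", subj, f"tree {s.tree} not in 1..{arg.M}"))
        key = (s.parent, s.child, s.tree)
        if key in seen_pairs:
            out.append(
                Violation("duplicate-strand", subj, "two strands of the same color")
            )
        seen_pairs.add(key)
        if not arg.vertices[s.parent] > arg.vertices[s.child]:
            out.append(
                Violation(
                    "time-order",
                    subj,
                    f"parent time {arg.vertices[s.parent]} <= child time "
                    f"{arg.vertices[s.child]}",
                )
            )

    if any(v.code == "referential" for v in out):
        return out  # adjacency-based checks would be meaningless

    leafset = set(arg.leaves)
    for u in arg.leaves:
        if arg.out_strands(u):
            out.append(Violation("leaf-outgoing", u, "leaf has outgoing strands"))
        carried = frozenset(s.tree for s in arg.in_strands(u))
        if carried != frozenset(range(1, arg.M + 1)):
            out.append(
                Violation(
                    "leaf-segments",
                    u,
                    f"leaf carries trees {sorted(carried)}, expected 1..{arg.M}",
                )
            )

    for v in arg.vertices:
        if v in leafset:
            continue
        if len(arg.children(v)) < 2 and len(arg.parents(v)) < 2:
            out.append(
                Violation(
                    "chain",
                    v,
                    "non-leaf vertex with <2 children and <2 parents (a chain)",
                )
            )

    # label transmission: a label on a tree-i strand must reach a leaf along
    # tree-i strands below it.
    reaches_leaf: dict = {}  # (tree, vertex) -> bool, memoized
    def _reaches(tree: int, v: str) -> bool:
        if v in leafset:
            return True
        key = (tree, v)
        if key in reaches_leaf:
            return reaches_leaf[key]
        reaches_leaf[key] = False  # cycle guard; cycles flagged via time-order
        res = any(_reaches(tree, s.child) for s in arg.out_by_tree(v).get(tree, []))
        reaches_leaf[key] = res
        return res

    for s in arg.strands:
        if s.labels and not (s.child in leafset or _reaches(s.tree, s.child)):
            out.append(
                Violation(
                    "label-unreachable",
                    f"{s.parent}->{s.child}[{s.tree}]",
                    f"labels {sorted(s.labels)} never reach a leaf on tree {s.tree}",
                )
            )
    return out


def marginal_lca(arg: Arg, tree: int) -> Optional[str]:
    """The LCA of the K leaves within embedded tree ``tree``, or None if the
    tree-restricted subgraph does not connect all leaves (a forest)."""
    common: Optional[set] = None
    for u in arg.leaves:
        anc = arg.ancestors(u, tree=tree)
        anc.add(u)
        common = anc if common is None else (common & anc)
        if not common:
            return None
    assert common is not None
    return min(common, key=lambda v: (arg.vertices[v], v))


def find_gmrca(arg: Arg) -> Optional[str]:
    """The unique vertex ancestral (via strands of any color) to every
    embedded tree's LCA, with no such vertex below it; None when the
    instance is unbounded (no common ancestor) or any tree is a forest."""
    lcas = []
    for i in range(1, arg.M + 1):
        lca = marginal_lca(arg, i)
        if lca is None:
            return None
        lcas.append(lca)
    common: Optional[set] = None
    for l in set(lcas):
        anc = arg.ancestors(l)
        anc.add(l)
        common = anc if common is None else (common & anc)
        if not common:
            return None
    assert common
    minimal = [
        v for v in common if not any(u in common for u in arg.descendants(v))
    ]
    if len(minimal) == 1:
        return minimal[0]
    return None
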