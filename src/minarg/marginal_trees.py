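"""Embedded (marginal) trees: extraction, canonical comparison, newick.

The marginal tree of segment ``i`` is the genealogy of the K leaves induced
by the tree-``i`` strands: the subgraph is climbed from the leaves up to
their common ancestor (the marginal LCA), unary pass-through vertices are
suppressed with branch lengths summed, and vertex times convert to branch
lengths in generations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .arg_model import Arg, ArgError


class ForestError(ArgError):
    """Tree-restricted strands do not connect all K leaves to one LCA."""

    def __init__(self, tree: int, roots):
        self.tree = tree
        self.roots = tuple(sorted(roots))
        super().__init__(
            f"tree {tree} is a forest: leaf lineages top out at {self.roots}"
        )


@dataclass(frozen=True)
class MarginalTree:
    """Rooted, leaf-labeled tree with branch lengths in generations.

    ``children`` maps an internal node (an ARG vertex id) to a tuple of
    ``(child, branch_length)`` pairs; leaves of the tree are exactly the
    ARG's K leaves.  The root is the marginal LCA; unary vertices have been
    suppressed.
    """

    index: int
    root: str
    root_time: float
    children: tuple  # tuple of (node, ((child, length), ...)) pairs
    leaves: tuple

    @property
    def K(self) -> int:
        return len(self.leaves)

    def child_map(self) -> dict:
        return dict(self.children)

    def branch_lengths(self) -> list:
        return [l for _, kids in self.children for _, l in kids]


def extract_marginal_tree(arg: Arg, i: int) -> MarginalTree:
    """Extract embedded tree ``i``; raises :class:`ForestError` if the
    tree-``i`` strands do not join all leaves under a single LCA."""
    if not 1 <= i <= arg.M:
        raise ArgError(f"tree index {i} not in 1..{arg.M}")

    parent_of: dict = {}
    # Climb from every leaf; record the unique tree-i parent of each vertex.
    tops: set = set()
    on_path: set = set(arg.leaves)
    for u in arg.leaves:
        v = u
        while True:
            if v in parent_of:
                break
            ins = [s for s in arg.in_strands(v) if s.tree == i]
            if not ins:
                tops.add(v)
                break
            if len(ins) > 1:
                raise ArgError(
                    f"vertex {v} has {len(ins)} parents in tree {i}; "
                    "embedded structure is not a tree"
                )
            parent_of[v] = ins[0].parent
            v = ins[0].parent
            on_path.add(v)

    # The common ancestors of all leaves within tree i lie on every upward
    # path; the LCA is the earliest (minimum-time) one.
    common = None
    for u in arg.leaves:
        chain = {u}
        v = u
        while v in parent_of:
            v = parent_of[v]
            chain.add(v)
        common = chain if common is None else common & chain
    if not common:
        raise ForestError(i, tops)
    lca = min(common, key=lambda v: (arg.vertices[v], v))

    # Children within the on-path vertex set, restricted to below the LCA.
    kids: dict = {}
    for c, p in parent_of.items():
        kids.setdefault(p, []).append(c)

    leafset = set(arg.leaves)

    def build(v):
        """Return (node_id, children_spec) entries, descending from v and
        suppressing unary vertices; returns the effective node replacing v
        and the accumulated extra length."""
        while v not in leafset and len(kids.get(v, [])) == 1:
            v = kids[v][0]
        return v

    entries = []

    def descend(v):
        v = build(v)
        if v in leafset:
            return v
        row = []
        for c in kids[v]:
            eff = descend(c)
            row.append((eff, arg.vertices[v] - arg.vertices[eff]))
        entries.append((v, tuple(sorted(row))))
        return v

    root = descend(lca)
    if root in leafset:
        raise ForestError(i, tops)
    return MarginalTree(
        index=i,
        root=root,
        root_time=arg.vertices[root],
        children=tuple(entries),
        leaves=arg.leaves,
    )


# ---------------------------------------------------------------------------
# Canonical form and comparison
# ---------------------------------------------------------------------------


def _canonical(t: MarginalTree):
    """Nested-tuple canonical form: leaves as ("leaf", label), internal
    nodes as ("node", ((child_canon, min_leaf, length), ...)) with children
    sorted by minimal descendant leaf label."""
    cmap = t.child_map()
    leafset = set(t.leaves)

    def canon(v):
        if v in leafset:
            return ("leaf", v), v
        rows = []
        for c, length in cmap[v]:
            sub, mn = canon(c)
            rows.append((sub, mn, length))
        rows.sort(key=lambda r: r[1])
        return ("node", tuple(rows)), rows[0][1]

    return canon(t.root)[0]


def _lengths_close(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))


def trees_equal(a: MarginalTree, b: MarginalTree, tol: float = 1e-9) -> bool:
    """Leaf-label and edge-length preserving isomorphism of rooted trees.

    Canonical child ordering (by minimal descendant leaf) makes the
    comparison deterministic; branch lengths match within relative
    tolerance ``tol`` (``tol=0`` demands exact equality, appropriate for
    integer-generation times).
    """
    if set(a.leaves) != set(b.leaves):
        return False

    def cmp(x, y):
        if x[0] == "leaf" or y[0] == "leaf":
            return x == y
        rx, ry = x[1], y[1]
        if len(rx) != len(ry):
            return False
        return all(
            _lengths_close(lx, ly, tol) and cmp(sx, sy)
            for (sx, _, lx), (sy, _, ly) in zip(rx, ry)
        )

    return cmp(_canonical(a), _canonical(b))


def structure_preserving(g1: Arg, g2: Arg, tol: float = 1e-9) -> bool:
    """All M embedded trees identical in topology and branch lengths."""
    if g1.K != g2.K or g1.M != g2.M:
        raise ArgError(
            f"parameter mismatch: (K={g1.K}, M={g1.M}) vs (K={g2.K}, M={g2.M})"
        )
    return all(
        trees_equal(extract_marginal_tree(g1, i), extract_marginal_tree(g2, i), tol)
        for i in range(1, g1.M + 1)
    )


# ---------------------------------------------------------------------------
# Statistics and export
# ---------------------------------------------------------------------------


def tree_stats(t: MarginalTree):
    """TMRCA (root time) and total branch length, both in generations."""
    return {"tmrca": t.root_time, "total_length": sum(t.branch_lengths())}


def _fmt(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(x)


def to_newick(t: MarginalTree) -> str:
    """Standard newick with branch lengths, in canonical child order."""
    cmap = t.child_map()
    leafset = set(t.leaves)

    def min_leaf(v):
        if v in leafset:
            return v
        return min(min_leaf(c) for c, _ in cmap[v])

    def render(v):
        if v in leafset:
            return v
        rows = sorted(cmap[v], key=lambda cl: min_leaf(cl[0]))
        return "(" + ",".join(f"{render(c)}:{_fmt(l)}" for c, l in rows) + ")"

    return render(t.root) + ";"
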