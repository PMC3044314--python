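"""The ARG transform algebra.

Vertex removal (the "missing node" operation), resolvability, reduction to
canonical form, 1-vertex compactification of truncated/unbounded instances,
node-merge, minimal-descriptor extraction, and the structural bound checks
that every minimal descriptor must satisfy.

A *minimal descriptor* is an ARG in which every coalescent vertex except
the GMRCA is t-coalescent; it preserves both the samples S(G) and all M
marginal trees of the ARG it was extracted from, and has O(MK) vertices
even when the source is unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .arg_model import (
    Arg,
    ArgError,
    Strand,
    Violation,
    find_gmrca,
    is_t_coalescent,
    sg,
)
from .genetic_flow import compute_samples, samples_equal


@dataclass(frozen=True)
class EventCounts:
    """Non-leaf event tallies used by the O(MK) bounds.

    ``n_c``: coalescent vertices (>=2 children); ``n_e``: genetic-exchange
    events, each vertex with p parents encoding p-1 events (events at leaf
    vertices are excluded, matching the bound's accounting);
    ``n_exchange_vertices``: vertices with >=2 parents; ``n_v``: all
    non-leaf vertices.
    """

    n_c: int
    n_e: int
    n_v: int
    n_exchange_vertices: int


# ---------------------------------------------------------------------------
# Removal
# ---------------------------------------------------------------------------


def _removal_parents(arg: Arg, v: str) -> dict:
    """Map tree -> the unique incoming strand for each outgoing tree of ``v``;
    raises if removal is undefined (it presumes one parent per tree)."""
    obt = arg.out_by_tree(v)
    ibt = arg.in_by_tree(v)
    res = {}
    for i in obt:
        ins = ibt.get(i, [])
        if len(ins) != 1:
            raise ArgError(
                f"removal of {v} undefined: {len(ins)} parents in tree {i}"
            )
        res[i] = ins[0]
    return res


def is_removable(arg: Arg, v: str) -> bool:
    if v not in arg.vertices or arg.is_leaf(v):
        return False
    try:
        _removal_parents(arg, v)
    except ArgError:
        return False
    return True


def _min_leaf_below(arg: Arg, v: str, tree: int):
    """Smallest leaf identifier reachable from ``v`` along tree strands
    (``v`` itself if it is a leaf); None for a dangling branch."""
    if arg.is_leaf(v):
        return v
    reachable = arg.descendants(v, tree=tree) & set(arg.leaves)
    return min(reachable) if reachable else None


def remove_vertex(arg: Arg, v: str) -> Arg:
    """G \\ {v}: rewire each tree-i child of v to v's tree-i parent.

    Per tree, exactly one new strand carries the union of the old incoming
    and outgoing labels (avoiding duplicate mutations within an embedded
    tree) while the others keep their old labels.  The union goes to the
    strand whose child subtree contains the smallest reachable leaf of
    that tree: leaf reachability is invariant under further removals, so
    sequential multi-vertex removal is order-independent.
    """
    if v not in arg.vertices:
        raise ArgError(f"unknown vertex {v!r}")
    if arg.is_leaf(v):
        raise ArgError(f"cannot remove leaf {v}")
    parents = _removal_parents(arg, v)

    kept: dict = {}
    for s in arg.strands:
        if s.parent == v or s.child == v:
            continue
        kept[(s.parent, s.child, s.tree)] = set(s.labels)

    for i, outs in arg.out_by_tree(v).items():
        in_strand = parents[i]
        def rank(s):
            mn = _min_leaf_below(arg, s.child, i)
            return (mn is None, mn, s.child)
        for j, s in enumerate(sorted(outs, key=rank)):
            labels = set(s.labels)
            if j == 0:
                labels |= in_strand.labels
            key = (in_strand.parent, s.child, i)
            if key in kept:
                kept[key] |= labels  # rewired onto an existing same-color strand
            else:
                kept[key] = labels

    vertices = dict(arg.vertices)
    del vertices[v]
    strands = tuple(
        Strand(p, c, t, frozenset(lab)) for (p, c, t), lab in sorted(kept.items())
    )
    return arg.replace(vertices=vertices, strands=strands)


def remove_vertices(arg: Arg, U) -> Arg:
    """Sequential removal in sorted-identifier order; the samples of the
    result do not depend on the order."""
    cur = arg
    for v in sorted(U):
        cur = remove_vertex(cur, v)
    return cur


def is_resolvable(arg: Arg, v: str) -> bool:
    """Brute-force oracle: does removing ``v`` change the samples S(G)?"""
    return not samples_equal(
        compute_samples(arg), compute_samples(remove_vertex(arg, v))
    )


# ---------------------------------------------------------------------------
# Reduction and compactification
# ---------------------------------------------------------------------------


def reduce_arg(arg: Arg) -> Arg:
    """Remove vertices with exactly one descendant until fixpoint.

    Only vertices whose removal is defined (one parent per outgoing tree)
    are taken; unary vertices at a truncation top, having no parent, are
    left in place for :func:`compactify` to absorb.
    """
    cur = arg
    while True:
        cand = sorted(
            v
            for v in cur.vertices
            if not cur.is_leaf(v)
            and len(cur.children(v)) == 1
            and is_removable(cur, v)
        )
        if not cand:
            return cur
        cur = remove_vertex(cur, cand[0])


def compactify(arg: Arg) -> Arg:
    """1-vertex compactification of a GMRCA-less (truncated) ARG.

    A single apex vertex is added above the truncation surface.  Every
    parentless non-leaf vertex that is unary or not t-coalescent is a
    truncation artifact -- in the unbounded original it would sit on, or
    be removed into, an infinite chain -- and is dissolved: each of its
    outgoing strands becomes an apex strand onto its child, carrying the
    union of the labels accumulated from above (the apex stands in for the
    chain's missing parent, so the chains' per-tree label unions are
    preserved).  Dissolution repeats until only genuine tops (t-coalescent
    or leaf attachment points) remain, which the apex then dominates
    directly.  The apex is the GMRCA of the result.
    """
    if find_gmrca(arg) is not None:
        raise ArgError("ARG already has a GMRCA; nothing to compactify")

    apex = "v'"
    while apex in arg.vertices:
        apex += "'"
    vertices = dict(arg.vertices)
    strands = {(s.parent, s.child, s.tree): set(s.labels) for s in arg.strands}
    leafset = set(arg.leaves)

    def tops():
        """Vertices with no parent other than (possibly) the apex."""
        with_parent = {c for (p, c, _) in strands if p != apex}
        return sorted(
            v
            for v in vertices
            if v != apex and v not in leafset and v not in with_parent
        )

    while True:
        progressed = False
        for v in tops():
            out = [(key, lab) for key, lab in strands.items() if key[0] == v]
            by_tree: dict = {}
            for (_, c, i), lab in out:
                by_tree.setdefault(i, []).append((c, lab))
            if any(len(cs) >= 2 for cs in by_tree.values()):
                continue  # t-coalescent: a genuine marginal root, keep it
            # Dissolve the truncation artifact: its strands move to the
            # apex, folding in any labels already accumulated from above.
            inherited: dict = {}
            for key in [k for k in strands if k[0] == apex and k[1] == v]:
                inherited[key[2]] = strands.pop(key)
            for key, lab in out:
                _, c, i = key
                strands.pop(key)
                dest = strands.setdefault((apex, c, i), set())
                dest.update(lab)
                dest.update(inherited.get(i, ()))
            del vertices[v]
            progressed = True
            break
        if not progressed:
            break

    vertices[apex] = max(vertices.values()) + 1.0
    for top in tops():
        for i in sorted({i for (p, c, i) in strands if p == top}):
            strands.setdefault((apex, top, i), set())

    out = arg.replace(
        vertices=vertices,
        strands=tuple(
            Strand(p, c, t, frozenset(lab))
            for (p, c, t), lab in sorted(strands.items())
        ),
    )
    if find_gmrca(out) != apex:
        raise ArgError("compactification did not yield a unique GMRCA")
    return out


# ---------------------------------------------------------------------------
# Node merge
# ---------------------------------------------------------------------------


def node_merge(arg: Arg, v1: str, v2: str) -> Arg:
    """Merge two path-unrelated vertices with disjoint segment sets.

    The merged vertex inherits all incoming and outgoing strands of both.
    Its time is the later of the two; if that breaks the strict time
    ordering on any inherited strand the merge is rejected.
    """
    for v in (v1, v2):
        if v not in arg.vertices:
            raise ArgError(f"unknown vertex {v!r}")
    if v1 == v2:
        raise ArgError("cannot merge a vertex with itself")
    if v2 in arg.descendants(v1) or v1 in arg.descendants(v2):
        raise ArgError(f"directed path between {v1} and {v2}; merge would cycle")
    if sg(arg, v1) & sg(arg, v2):
        raise ArgError(f"sg({v1}) and sg({v2}) overlap; merge is not samples-safe")

    v3 = f"{v1}~{v2}"
    while v3 in arg.vertices:
        v3 += "'"
    t3 = max(arg.vertices[v1], arg.vertices[v2])
    vertices = {v: t for v, t in arg.vertices.items() if v not in (v1, v2)}
    vertices[v3] = t3
    strands = []
    for s in arg.strands:
        p = v3 if s.parent in (v1, v2) else s.parent
        c = v3 if s.child in (v1, v2) else s.child
        if not vertices[p] > vertices[c]:
            raise ArgError(
                f"merge time {t3} breaks ordering on strand {s.parent}->{s.child}"
            )
        strands.append(Strand(p, c, s.tree, s.labels))
    if arg.is_leaf(v1) or arg.is_leaf(v2):
        raise ArgError("cannot merge leaves")
    return arg.replace(vertices=vertices, strands=tuple(strands))


# ---------------------------------------------------------------------------
# Minimal descriptor
# ---------------------------------------------------------------------------


def minimal_descriptor(arg: Arg) -> Arg:
    """Extract the canonical minimal descriptor.

    Repeatedly removes every removable non-t-coalescent coalescent vertex
    other than the GMRCA (removal can expose new such vertices, so this
    iterates to a fixpoint), reduces to canonical form, and compactifies
    when no GMRCA remains.  The result is samples- and structure-preserving
    with respect to the input.
    """
    cur = arg
    while True:
        g = find_gmrca(cur)
        removed = False
        for v in sorted(cur.vertices):
            if (
                cur.is_leaf(v)
                or v == g
                or len(cur.children(v)) < 2
                or is_t_coalescent(cur, v)
                or not is_removable(cur, v)
            ):
                continue
            cur = remove_vertex(cur, v)
            removed = True
        if not removed:
            break
    cur = reduce_arg(cur)
    if find_gmrca(cur) is None:
        cur = compactify(cur)
    return cur


# ---------------------------------------------------------------------------
# Counts and bound checks
# ---------------------------------------------------------------------------


def event_counts(arg: Arg) -> EventCounts:
    n_c = n_e = n_v = n_x = 0
    for v in arg.vertices:
        if arg.is_leaf(v):
            continue
        n_v += 1
        if len(arg.children(v)) >= 2:
            n_c += 1
        p = len(arg.parents(v))
        if p >= 2:
            n_x += 1
        n_e += max(p - 1, 0)
    return EventCounts(n_c=n_c, n_e=n_e, n_v=n_v, n_exchange_vertices=n_x)


def md_check(arg: Arg, binary: bool = False) -> list:
    """Executable form of the minimal-descriptor theorems.

    Empty report iff: every non-GMRCA coalescent vertex is t-coalescent;
    each child of a coalescent vertex overlaps another child (the local
    overlap property); the GMRCA degree is at most MK; the generic event
    bounds 1 <= n_c <= M(K-1)+1 and n_e <= K(M-1)+M(K-1) hold; and, for
    ``binary=True`` (binary minimal descriptors under recombination-only
    exchange): out-degree <= 2 except the GMRCA, K-1 <= n_c,
    n_e <= K(M-1), and no vertex is gapped.
    """
    out: list = []
    K, M = arg.K, arg.M
    g = find_gmrca(arg)

    for v in sorted(arg.vertices):
        if arg.is_leaf(v) or v == g:
            continue
        kids = sorted(arg.children(v))
        if len(kids) >= 2:
            if not is_t_coalescent(arg, v):
                out.append(
                    Violation("non-t-coalescent", v, "coalescent but not t-coalescent")
                )
            sgs = {c: sg(arg, c) for c in kids}
            for c in kids:
                if not any(sgs[c] & sgs[d] for d in kids if d != c):
                    out.append(
                        Violation(
                            "no-overlap",
                            v,
                            f"child {c} overlaps no sibling",
                        )
                    )
        if binary and len(kids) > 2:
            out.append(
                Violation("binary-outdegree", v, f"{len(kids)} children (> 2)")
            )

    if g is not None and len(arg.children(g)) > M * K:
        out.append(
            Violation(
                "gmrca-degree",
                g,
                f"degree {len(arg.children(g))} > MK = {M * K}",
            )
        )

    ec = event_counts(arg)
    if not 1 <= ec.n_c <= M * (K - 1) + 1:
        out.append(
            Violation(
                "coalescent-bound",
                "n_c",
                f"n_c = {ec.n_c} outside [1, {M * (K - 1) + 1}]",
            )
        )
    if not 0 <= ec.n_e <= K * (M - 1) + M * (K - 1):
        out.append(
            Violation(
                "exchange-bound",
                "n_e",
                f"n_e = {ec.n_e} outside [0, {K * (M - 1) + M * (K - 1)}]",
            )
        )
    if binary:
        if ec.n_c < K - 1:
            out.append(
                Violation("binary-coalescent-bound", "n_c", f"n_c = {ec.n_c} < K-1")
            )
        if ec.n_e > K * (M - 1):
            out.append(
                Violation(
                    "binary-exchange-bound",
                    "n_e",
                    f"n_e = {ec.n_e} > K(M-1) = {K * (M - 1)}",
                )
            )
        for v in sorted(arg.vertices):
            s = sg(arg, v)
            if s and max(s) - min(s) + 1 != len(s):
                out.append(
                    Violation("gapped", v, f"sg = {sorted(s)} is not consecutive")
                )
    return out
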