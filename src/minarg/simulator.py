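"""Backwards-in-time sampling of binary ARGs with junction-restricted
recombination.

Two samplers are provided.

``simulate_binary_arg`` draws from the standard coalescent with
recombination (Hudson-style in continuous time; an optional
generation-by-generation mode allows simultaneous and multi-way events,
the *generic* relaxation).  Recombination breakpoints fall only on the
``M-1`` junctions between non-mixing segments, and a lineage is eligible
at a junction only while it carries ancestral material strictly on both
sides (standard ancestral-material pruning).  The minimal descriptor is
obtained afterwards with :func:`minarg.transforms.minimal_descriptor`.

``simulate_md_direct`` samples the subspace of binary minimal descriptors
directly: only lineage pairs with overlapping segment sets may coalesce,
so every coalescence is t-coalescent by construction.  Here strands keep
the full segment set of a lineage even after a segment has reached its
marginal MRCA — that material is genuinely ancestral, and keeping it is
what makes every carried set a contiguous run (no gapped vertex).  Event
eligibility (recombination spanning, the stopping rule) still considers
only the live, un-coalesced material, so the event process is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .arg_model import Arg, ArgError, Strand, marginal_lca
from .marginal_trees import extract_marginal_tree, tree_stats
from .transforms import compactify, event_counts, reduce_arg
from .arg_model import find_gmrca

_MAX_STEPS = 10_000_000


@dataclass(frozen=True)
class SimConfig:
    """All simulator parameters.

    ``N`` sets the per-generation population size ``2N``; pairwise
    coalescence rate is ``1/(2N)`` per generation.  ``junction_recomb_probs``
    is either one per-generation probability per junction (length ``M-1``)
    or a scalar ``r`` spread over the junctions in proportion to the gap
    between segment midpoints, ``r_j = r (s_j + s_{j+1}) / (2 sum s)``.
    ``mutation_rate`` is the expected number of mutations per tree, per
    lineage, per generation (scalar, applied to every tree, or one value
    per segment).
    """

    K: int
    N: float = 50.0
    M: int = 1
    segment_lengths: Optional[tuple] = None
    junction_recomb_probs: object = 0.0  # scalar or length M-1 sequence
    mutation_rate: object = 0.0  # scalar or length M sequence
    mode: str = "continuous"  # or "discrete"
    sampling: str = "standard-then-minimize"  # or "direct-overlap"
    seed: Optional[int] = None
    compactify: bool = False

    def __post_init__(self):
        if self.K < 2:
            raise ValueError(f"K={self.K}, need K > 1")
        if self.M < 1:
            raise ValueError(f"M={self.M}, need M >= 1")
        if self.N < 1:
            raise ValueError(f"N={self.N}, need N >= 1")
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sampling not in ("standard-then-minimize", "direct-overlap"):
            raise ValueError(f"unknown sampling {self.sampling!r}")
        lengths = self.segment_lengths
        if lengths is None:
            lengths = (1.0,) * self.M
        lengths = tuple(float(x) for x in lengths)
        if len(lengths) != self.M or any(x <= 0 for x in lengths):
            raise ValueError(f"need M={self.M} positive segment lengths, got {lengths}")
        object.__setattr__(self, "segment_lengths", lengths)
        for p in self.junction_rates():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"junction probability {p} outside [0, 1]")
        for m in self.tree_mutation_rates():
            if m < 0:
                raise ValueError(f"negative mutation rate {m}")

    def junction_rates(self) -> tuple:
        """Per-generation recombination probability at each of the M-1
        junctions."""
        r = self.junction_recomb_probs
        s = self.segment_lengths
        if np.isscalar(r):
            total = sum(s)
            return tuple(
                float(r) * (s[j] + s[j + 1]) / (2.0 * total)
                for j in range(self.M - 1)
            )
        r = tuple(float(x) for x in r)
        if len(r) != self.M - 1:
            raise ValueError(f"need M-1={self.M - 1} junction probabilities, got {r}")
        return r

    def tree_mutation_rates(self) -> tuple:
        mu = self.mutation_rate
        if np.isscalar(mu):
            return (float(mu),) * self.M
        mu = tuple(float(x) for x in mu)
        if len(mu) != self.M:
            raise ValueError(f"need M={self.M} mutation rates, got {mu}")
        return mu


class _Builder:
    """Accumulates vertices/strands while the lineage process runs."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.leaves = tuple(f"s{k}" for k in range(1, cfg.K + 1))
        self.vertices = {u: 0.0 for u in self.leaves}
        self.strands: list = []
        self.n_coal = 0
        self.n_rec = 0

    def new_coal(self, t: float) -> str:
        self.n_coal += 1
        v = f"c{self.n_coal}"
        self.vertices[v] = float(t)
        return v

    def new_rec(self, t: float) -> str:
        self.n_rec += 1
        v = f"r{self.n_rec}"
        self.vertices[v] = float(t)
        return v

    def connect(self, parent: str, child: str, trees) -> None:
        for i in sorted(trees):
            self.strands.append(Strand(parent, child, i, frozenset()))

    def build(self) -> Arg:
        return Arg(
            self.cfg.M,
            self.cfg.segment_lengths,
            self.vertices,
            tuple(self.strands),
            self.leaves,
        )


def _spans(segs, live, junction: int) -> bool:
    """Live material strictly on both sides of the junction between
    segments ``junction`` and ``junction+1``."""
    return any(i <= junction for i in live if i in segs) and any(
        i > junction for i in live if i in segs
    )


def _split(segs, junction: int):
    left = frozenset(i for i in segs if i <= junction)
    right = frozenset(i for i in segs if i > junction)
    return left, right


def _continuous(cfg: SimConfig, rng, overlap_only: bool) -> Arg:
    """Shared continuous-time event loop.

    ``overlap_only=False``: standard coalescent, pruned segment sets (a
    segment is dropped from the single remaining carrier once it reaches
    its marginal MRCA).  ``overlap_only=True``: only overlapping pairs may
    coalesce and segment sets are never pruned; live material is tracked
    separately for eligibility.
    """
    b = _Builder(cfg)
    rates = cfg.junction_rates()
    full = frozenset(range(1, cfg.M + 1))
    # lineage: [bottom vertex, carried segments, live segments]
    lineages = [[u, full, full] for u in b.leaves]
    rooted: set = set()
    t = 0.0

    for _ in range(_MAX_STEPS):
        if len(rooted) == cfg.M or len(lineages) < 2:
            break
        n = len(lineages)
        if overlap_only:
            pairs = [
                (a, c)
                for a in range(n)
                for c in range(a + 1, n)
                if lineages[a][1] & lineages[c][1]
            ]
        else:
            pairs = [(a, c) for a in range(n) for c in range(a + 1, n)]
        c_rate = len(pairs) / (2.0 * cfg.N)
        rec = [
            (a, j)
            for a in range(n)
            for j in range(1, cfg.M)
            if rates[j - 1] > 0 and _spans(lineages[a][1], lineages[a][2], j)
        ]
        r_rate = sum(rates[j - 1] for _, j in rec)
        total = c_rate + r_rate
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if rng.random() * total < c_rate:
            a, c = pairs[rng.integers(len(pairs))]
            la, lc = lineages[a], lineages[c]
            v = b.new_coal(t)
            b.connect(v, la[0], la[1])
            b.connect(v, lc[0], lc[1])
            segs = la[1] | lc[1]
            live = (la[2] | lc[2]) - rooted
            newly = set()
            for i in sorted(la[2] & lc[2]):
                if sum(1 for l in lineages if i in l[2]) == 2:
                    newly.add(i)  # both carriers just merged: tree i rooted
            rooted |= newly
            live -= newly
            if not overlap_only:
                segs = live  # pruned representation
            lineages = [l for k, l in enumerate(lineages) if k not in (a, c)]
            if live:
                # a lineage with no live material is inert: it can never
                # coalesce again, and compactify later attaches the apex
                # directly to its bottom vertex.
                lineages.append([v, segs, live])
        else:
            u = rng.random() * r_rate
            acc = 0.0
            for a, j in rec:
                acc += rates[j - 1]
                if u < acc:
                    break
            la = lineages[a]
            v = b.new_rec(t)
            b.connect(v, la[0], la[1])
            left, right = _split(la[1], j)
            lleft, lright = _split(frozenset(la[2]), j)
            lineages = [l for k, l in enumerate(lineages) if k != a]
            for segs, live in ((left, lleft), (right, lright)):
                if live:
                    lineages.append([v, segs, live])
    else:
        raise RuntimeError("simulation exceeded the step budget")
    return b.build()


def _discrete(cfg: SimConfig, rng) -> Arg:
    """Generation-by-generation Wright-Fisher sampling (generic relaxation:
    several events, including multi-way coalescences, may share a
    generation)."""
    b = _Builder(cfg)
    rates = cfg.junction_rates()
    full = frozenset(range(1, cfg.M + 1))
    lineages = [[u, full] for u in b.leaves]
    counts = {i: cfg.K for i in range(1, cfg.M + 1)}
    two_n = max(int(round(2 * cfg.N)), 2)
    t = 0

    for _ in range(_MAX_STEPS):
        if len(lineages) < 2:
            break
        t += 1
        parts = []  # (bottom, piece, slot)
        for bottom, segs in sorted(lineages, key=lambda l: l[0]):
            cuts = [
                j
                for j in range(1, cfg.M)
                if rates[j - 1] > 0
                and _spans(segs, segs, j)
                and rng.random() < rates[j - 1]
            ]
            pieces = []
            rest = segs
            for j in cuts:
                left, rest = _split(rest, j)
                if left:
                    pieces.append(left)
            if rest:
                pieces.append(rest)
            for piece in pieces:
                parts.append((bottom, piece, int(rng.integers(two_n))))

        slots: dict = {}
        for bottom, piece, slot in parts:
            slots.setdefault(slot, {}).setdefault(bottom, set()).update(piece)

        new_lineages = []
        merge_vertices = []
        for slot in sorted(slots):
            members = slots[slot]
            if len(members) == 1:
                ((bottom, segs),) = members.items()
                new_lineages.append([bottom, frozenset(segs)])
                continue
            v = b.new_coal(t)
            merged = set()
            for bottom in sorted(members):
                b.connect(v, bottom, members[bottom])
                merged |= members[bottom]
            new_lineages.append([v, frozenset(merged)])
            merge_vertices.append(v)

        # prune segments that reached their marginal MRCA this generation
        counts = {i: 0 for i in range(1, cfg.M + 1)}
        for _, segs in new_lineages:
            for i in segs:
                counts[i] += 1
        lineages = []
        for bottom, segs in new_lineages:
            kept = frozenset(i for i in segs if counts[i] >= 2)
            if kept:
                lineages.append([bottom, kept])
    else:
        raise RuntimeError("simulation exceeded the generation budget")
    return b.build()


def _strip_rejoins(arg: Arg) -> Arg:
    """Remove split-and-rejoin artifacts.

    When the two halves of a recombination coalesce with each other the
    event pair leaves vertices with one child and one parent -- chains,
    which a well-formed ARG excludes because they are uninformative.
    Their removal is samples-neutral."""
    from .transforms import is_removable, remove_vertex

    while True:
        cand = [
            v
            for v in sorted(arg.vertices)
            if not arg.is_leaf(v)
            and len(arg.children(v)) <= 1
            and len(arg.parents(v)) <= 1
            and is_removable(arg, v)
        ]
        if not cand:
            return arg
        arg = remove_vertex(arg, cand[0])


def simulate_binary_arg(cfg: SimConfig, rng=None) -> Arg:
    """Sample a standard ARG on K leaves (approach 1).

    Continuous mode is the standard coalescent with recombination (binary
    events); discrete mode is the generic per-generation relaxation.  With
    ``cfg.compactify`` a GMRCA apex is added when the raw output has none.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "continuous":
        arg = _strip_rejoins(_continuous(cfg, rng, overlap_only=False))
    else:
        arg = _discrete(cfg, rng)
    if cfg.compactify and find_gmrca(arg) is None:
        arg = compactify(arg)
    return arg


def simulate_md_direct(cfg: SimConfig, rng=None) -> Arg:
    """Sample a binary minimal descriptor directly (approach 2).

    Coalescence is restricted to overlapping lineage pairs (the local
    overlap property), so every coalescent vertex is t-coalescent by
    construction;
    the output is reduced to canonical form and compactified, and passes
    the binary minimal-descriptor checks without post-minimization.  The
    sampling law of this subspace walk is not claimed to equal the
    standard coalescent's.
    """
    if cfg.mode != "continuous":
        raise ArgError("direct minimal-descriptor sampling is continuous-time only")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    arg = _continuous(cfg, rng, overlap_only=True)
    arg = reduce_arg(arg)
    if find_gmrca(arg) is None:
        arg = compactify(arg)
    return arg


def simulate(cfg: SimConfig, rng=None) -> Arg:
    """Dispatch on ``cfg.sampling``."""
    if cfg.sampling == "direct-overlap":
        return simulate_md_direct(cfg, rng)
    return simulate_binary_arg(cfg, rng)


def annotate_mutations(arg: Arg, cfg: SimConfig, rng) -> Arg:
    """Scatter mutations on the marginal branches.

    For each tree the strands at or below the marginal LCA are visited in
    canonical order and receive a Poisson(rate_i * strand length) number of
    freshly minted labels; every label reaches a leaf by construction.
    """
    rates = cfg.tree_mutation_rates()
    new_labels: dict = {}
    counter = 0
    for i in range(1, arg.M + 1):
        if rates[i - 1] <= 0:
            continue
        lca = marginal_lca(arg, i)
        if lca is None:
            raise ArgError(f"tree {i} has no marginal LCA; cannot place mutations")
        below = arg.descendants(lca, tree=i)
        below.add(lca)
        for s in arg.canonical_strands():
            if s.tree != i or s.parent not in below:
                continue
            length = arg.vertices[s.parent] - arg.vertices[s.child]
            k = int(rng.poisson(rates[i - 1] * length))
            if k:
                minted = {f"m{i}.{counter + d}" for d in range(k)}
                counter += k
                new_labels[(s.parent, s.child, s.tree)] = minted
    if not new_labels:
        return arg
    strands = tuple(
        s.with_labels(s.labels | new_labels.get((s.parent, s.child, s.tree), set()))
        for s in arg.strands
    )
    return arg.replace(strands=strands)


def sim_summary(args) -> dict:
    """Aggregate structural and genealogical statistics over a batch."""
    args = list(args)
    if not args:
        raise ValueError("need at least one ARG")
    nv, nc, ne, nx = [], [], [], []
    tmrcas, totals = [], []
    for a in args:
        ec = event_counts(a)
        nv.append(ec.n_v)
        nc.append(ec.n_c)
        ne.append(ec.n_e)
        nx.append(ec.n_exchange_vertices)
        for i in range(1, a.M + 1):
            st = tree_stats(extract_marginal_tree(a, i))
            tmrcas.append(st["tmrca"])
            totals.append(st["total_length"])

    def moments(xs):
        x = np.asarray(xs, dtype=float)
        return {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "se": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        }

    from .genetic_flow import allele_frequencies, compute_samples

    sfs: dict = {}
    for a in args:
        for count in allele_frequencies(compute_samples(a)).values():
            sfs[count] = sfs.get(count, 0) + 1

    return {
        "n_args": len(args),
        "vertices": moments(nv),
        "coalescent_vertices": moments(nc),
        "exchange_events": moments(ne),
        "exchange_vertices": moments(nx),
        "tmrca": moments(tmrcas),
        "total_length": moments(totals),
        "allele_frequency_spectrum": dict(sorted(sfs.items())),
    }
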