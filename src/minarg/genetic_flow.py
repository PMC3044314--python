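"""Genetic flow: the extant samples S(G) and sample-level statistics.

Mutation labels ride on colored strands; the haplotype of leaf ``u`` for
segment ``i`` is the union of the labels on every tree-``i`` strand lying on
a tree-``i`` directed path down to ``u``.  Alleles are coded
presence/absence (a label is a one-shot duplication event; ancestral state
is absence).
"""

from __future__ import annotations

from dataclasses import dataclass

from .arg_model import Arg, ArgError, validate


@dataclass(frozen=True)
class SampleSet:
    """The K extant haplotypes as per-segment mutation-label sets.

    ``data[k][i-1]`` is the set of tree-``i`` mutations carried by leaf
    ``leaves[k]``.  Equality is position-wise set equality.
    """

    leaves: tuple
    M: int
    data: tuple  # tuple (per leaf) of tuple (per tree) of frozenset

    @property
    def K(self) -> int:
        return len(self.leaves)

    def mutations(self) -> set:
        return {m for row in self.data for cell in row for m in cell}

    def segment_of(self, mutation: str) -> int:
        for row in self.data:
            for i, cell in enumerate(row, 1):
                if mutation in cell:
                    return i
        raise KeyError(mutation)

    def carriers(self, mutation: str) -> frozenset:
        """Indices (into ``leaves``) of the leaves carrying ``mutation``."""
        return frozenset(
            k for k, row in enumerate(self.data) if any(mutation in c for c in row)
        )


def compute_samples(arg: Arg, check: bool = False) -> SampleSet:
    """Flow every tree's labels down its colored paths to the leaves.

    With ``check=True`` the ARG is structurally validated first and the
    first violation is raised as an error.  The default skips validation
    because intermediate graphs produced during vertex removal legitimately
    contain chains.
    """
    if check:
        report = validate(arg)
        if report:
            v = report[0]
            raise ArgError(f"invalid ARG: {v.code} at {v.subject}: {v.message}")

    memo: dict = {}  # (tree, vertex) -> frozenset of labels flowing into vertex

    def labels_above(tree: int, v: str) -> frozenset:
        key = (tree, v)
        if key in memo:
            return memo[key]
        acc: set = set()
        for s in arg.in_strands(v):
            if s.tree != tree:
                continue
            acc |= s.labels
            acc |= labels_above(tree, s.parent)
        res = frozenset(acc)
        memo[key] = res
        return res

    data = tuple(
        tuple(labels_above(i, u) for i in range(1, arg.M + 1)) for u in arg.leaves
    )
    return SampleSet(leaves=arg.leaves, M=arg.M, data=data)


def samples_equal(a: SampleSet, b: SampleSet) -> bool:
    """Position-wise set equality across all leaves and segments."""
    if a.K != b.K or a.M != b.M:
        raise ValueError(
            f"shape mismatch: ({a.K}, {a.M}) vs ({b.K}, {b.M})"
        )
    return a.data == b.data


def allele_frequencies(s: SampleSet) -> dict:
    """Carrier count per mutation; in a valid ARG every count is in 1..K."""
    counts: dict = {}
    for row in s.data:
        for cell in row:
            for m in cell:
                counts[m] = counts.get(m, 0) + 1
    return counts


def ld_r2(s: SampleSet, m1: str, m2: str) -> float:
    """Squared correlation of presence/absence over the K leaves.

    r^2 = D^2 / (p1 (1-p1) p2 (1-p2)) with D = p12 - p1 p2.  Both mutations
    must be polymorphic (0 < count < K), else the correlation is undefined.
    """
    k = s.K
    c1 = s.carriers(m1)
    c2 = s.carriers(m2)
    for m, c in ((m1, c1), (m2, c2)):
        if not 0 < len(c) < k:
            raise ValueError(f"mutation {m!r} is monomorphic (count {len(c)} of {k})")
    p1 = len(c1) / k
    p2 = len(c2) / k
    p12 = len(c1 & c2) / k
    d = p12 - p1 * p2
    return (d * d) / (p1 * (1 - p1) * p2 * (1 - p2))
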