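# Methods

## The model

An ancestral recombination graph (ARG) on `K` sampled chromosomes is
treated here as the union of `M` embedded marginal trees, one per
*non-mixing segment* — a chromosomal block that recombination never
splits.  The graph is a timed DAG: vertices carry a time in generations
(leaves at 0, increasing into the past) and every edge between a
parent/child pair decomposes into *strands*, at most one per tree index
`i ∈ 1..M`, each annotated with a set of mutation labels.  Mutations are
one-shot duplication events; a leaf's haplotype for segment `i` is the
union of labels on the tree-`i` strands above it, and the collection of
all `K × M` such sets is the sample set `S(G)`.  Chromosomal position
within a segment is deliberately not modeled: only segment membership
matters for the genetics, so positions appear only in the ms-style writer
as evenly spaced presentation values.

Local vertex classes drive everything else.  A vertex with ≥2 children is
*coalescent*; with ≥2 parents it is a *genetic-exchange* vertex (both at
once is allowed).  A coalescent vertex is *t-coalescent* when it
coalesces inside at least one embedded tree, i.e. carries two same-color
outgoing strands.  `sg(v)` is the set of tree indices incident on `v`; a
vertex is *gapped* when `sg(v)` is not a consecutive run.

## The minimal descriptor

Two invariants define losslessness: *samples-preserving* (`S(G)` equal
position-wise) and *structure-preserving* (all `M` marginal trees equal
in topology and branch lengths).  Removing a vertex (`G \ {v}`) rewires
each tree-`i` child of `v` to `v`'s unique tree-`i` parent; per tree,
exactly one new strand absorbs the union of the incoming and outgoing
labels so no mutation is duplicated within a tree.  The union-bearing
strand is the one whose child subtree contains the smallest
tree-reachable leaf.  That choice is deliberate: leaf reachability inside
an embedded tree is invariant under further removals, which makes
sequential multi-vertex removal order-independent — a smallest-child-id
rule is *not* order-commutative once t-coalescent vertices are removed,
which our pairwise brute-force test detects immediately.

A *minimal descriptor* is an ARG in which every coalescent vertex except
the GMRCA is t-coalescent.  `minimal_descriptor` removes removable
non-t-coalescent coalescent vertices to a fixpoint (a removal can expose
a new non-t coalescence at a formerly unary parent), reduces the result
to canonical form (no vertex with a single descendant), and, when no
GMRCA remains, applies 1-vertex compactification.  The extraction is
checked, not assumed: tests assert samples- and structure-preservation on
every instance, plus the structural bounds
`1 ≤ n_c ≤ M(K−1)+1`, `n_e ≤ K(M−1)+M(K−1)`, GMRCA degree `≤ MK`, and —
for binary minimal descriptors — `n_c ≥ K−1`, `n_e ≤ K(M−1)`, out-degree
≤ 2 away from the GMRCA, and no gapped vertex.  `n_e` counts exchange
*events* as Σ(max(parents−1, 0)) over non-leaf vertices (a single leaf
exchange node with `M` parents encodes `M−1` events, which the bound's
accounting excludes); exchange-vertex counts are reported separately.

### Compactification of truncated instances

Finite software must represent unbounded ARGs as truncations, and the
truncation surface is ragged: top vertices may have lost the per-tree
parents that vertex removal needs.  `compactify` therefore lets the new apex stand in
for the missing ancestry: every top vertex (no parent besides the apex)
that is unary or not t-coalescent is dissolved, its strands becoming apex
strands with the per-tree label unions carried along; this repeats until
only genuine marginal roots remain, which the apex then dominates
directly.  On chain-shaped truncations this is exactly the textbook
construction (replace each disjoint infinite chain by one labeled edge);
on ragged truncations it is its closure.  The apex receives time
`max(vertex times) + 1`; branch lengths above the marginal roots carry no
structural information because marginal trees end at their LCAs.  A
unique-GMRCA postcondition is asserted.

`node_merge` (merging two path-unrelated vertices with disjoint `sg`)
assigns the merged vertex the later of the two times and rejects the
merge if any inherited strand would violate the strict time ordering.
Merging can only be structure-safe when the merged vertices are either
unary pass-throughs of their trees (suppressed in marginal trees) or
contemporaneous, and the tests verify preservation through the sample
and marginal-tree oracles rather than assuming it.

## The samplers

`simulate_binary_arg` is a Hudson-style backwards-in-time sampler.
Pairwise coalescence occurs at rate `1/(2N)` per pair per generation;
recombination occurs only at the `M−1` junctions between segments, at a
per-generation probability `r_j` per lineage carrying ancestral material
strictly on both sides of junction `j` (standard ancestral-material
pruning; splits with an empty side are not events).  A scalar `r` is
spread over junctions in proportion to the gap between segment midpoints,
`r_j = r (s_j + s_{j+1}) / (2 Σ s)`, since segment lengths model varying
recombination rates without a prescribed formula.  The process stops at
the per-tree MRCAs; a GMRCA apex is supplied by compactification on
request.  Split-and-rejoin event pairs (the two halves of a recombination
coalescing with each other) leave uninformative chain vertices and are
stripped by samples-neutral removal.  The discrete mode runs the
generation-by-generation Wright–Fisher relaxation in which several
events, including multi-way coalescences, may share a generation; it is
the *generic* counterpart and is not used where binarity is assumed.

`simulate_md_direct` samples binary minimal descriptors directly: only
lineage pairs with overlapping segment sets may coalesce, so every
coalescence is t-coalescent by construction.  One representational choice
matters here: when a segment reaches its marginal MRCA inside a merged
lineage, it *stays* in the lineage's strand set (the material is
genuinely ancestral), while event eligibility and the stopping rule
consult only the live, un-coalesced material.  Pruning the rooted segment
instead would turn the contiguous `{1,2,3}` into a fabricated gapped
`{1,3}` and falsify the no-gapped-vertex property that this sampler is
meant to exhibit.  The sampler's subspace law is not claimed to equal the
standard coalescent's; approach 1 (standard sample, then minimize) is the
distributional reference.

`annotate_mutations` scatters Poisson(`μ_i` × branch length) fresh labels
per tree on the strands at or below the marginal LCA, so every label
reaches a leaf by construction; `μ_i` is per tree, per lineage, per
generation.

## What the generator emulates, and what it does not

The synthetic instances are neutral, panmictic, constant-size haploid
coalescent samples with junction-restricted recombination and
infinite-alleles mutation.  Real data add intra-segment recombination,
back-mutation and recurrent mutation, population structure, demography
and selection — none of which is modeled, so passing tests certify the
graph theory and the samplers' internal consistency, not fit to any
empirical dataset.  Calibration is against standard-coalescent closed
forms: mean pairwise TMRCA `2N`, mean K-leaf height `2N·2(1−1/K)`, mean
total length `2N·2·H_{K−1}`, each within 3 standard errors at 2000
replicates.

## Numerical and testing choices

* Times are floats; discrete mode produces integers exactly, so tree
  comparison uses `tol=0` there and a relative `1e-9` in continuous mode
  (`|a−b| ≤ tol·max(1, |a|, |b|)`).  Minimization never changes vertex
  times, so preservation checks are exact.
* Tree equality canonicalizes by sorting children on their minimal
  descendant leaf; the serialization writes vertices sorted by
  (time, id) and strands by (parent, child, tree), making
  `write ∘ read` the identity on written files and seeded runs bit-exact.
* Batch sizes: 100 random small ARGs (K ≤ 4, M ≤ 3, ≤ 12 vertices) for
  the exhaustive brute-force suites; 200 standard and 200 direct
  simulations over K ∈ {2,3,4,6} × M ∈ {1,2,3,4} at N = 50 with
  per-junction recombination probability 0.005 (ρ_j = 4N·r_j = 1) and
  mutation rate 0.02 per tree per generation (θ = 4N·μ = 4), enough for
  every instance to be polymorphic without bloating graphs.
* The redundancy comparison (reduced minimal descriptor vs reduced
  source) is made between GMRCA-completed canonical forms, because the
  pruned simulator output has no GMRCA vertex while minimization adds the
  apex; the observed mean vertex ratio is reported, not thresholded.
* Degenerate inputs: removal of a vertex with several same-tree parents
  is rejected rather than guessed; forests raise an explicit error
  listing the per-leaf tops; `ld_r2` refuses monomorphic mutations.

## Known limitations

* Minimal descriptors are not unique; the canonical construction here is
  the U-removal one, and no search over sample-equivalent ARGs is
  attempted.
* `find_gmrca` returns absent when the minimal common ancestor is not
  unique; that is the software meaning of "unbounded".
* The marginal-tree comparison is index-wise (segment `i` against
  segment `i`); a permuting bijection between tree multisets is not
  considered.
* The discrete mode can produce multifurcating (generic) events at small
  `2N`; it is excluded from binary-only claims by construction.
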