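# Methods

This note documents the models and conventions behind `orthoflow`: what
each stage computes, the defaults and why, what the simulator does and
does not emulate, and the numerical choices that make runs deterministic.

## Synthetic proteome evolution

**Model.** Gene families evolve down a rooted species tree whose branch
lengths are expected replacements per site.  The root sequence (default
300 aa) is drawn i.i.d. from stationary amino-acid frequencies π (default
uniform over the 20 canonical residues).  Along a branch of length `d`
each site is hit by at least one replacement event with probability
`1 − e^(−d)`; an event redraws the residue from π, possibly redrawing the
same letter.  Because every redraw is an independent π draw, two leaves at
path distance `D` share a site with probability

    E[identity] = e^(−D) + (1 − e^(−D)) · Σₐ πₐ²,

an exact closed form used throughout the tests as the oracle.  This
"redraw including identity" model was chosen over an empirical rate
matrix precisely because it admits this closed form: verifiability beats
realism for a ground-truth generator.

**Families.** Family specifications are sampled to a requested category
mixture (universal single-copy, universal multi-copy, lineage-only,
species-specific, present-at-half, patchy); every sampled copy-count
vector is verified against the group classifier before use, so generated
truth labels are consistent with the classification rules by
construction.  Duplications (copy count ≥ 2) branch at the midpoint of
the terminal branch of the duplicated lineage — a single unambiguous
convention — and evolve independently to the leaf.  Homology-only is a
downstream label for unclustered genes with hits; the generator does not
emit it, since a family cannot guarantee "has hits but never clusters"
by construction.

**Randomness.** One master seed; each family uses a substream keyed by a
CRC-32 hash of its family id, so family sets are reproducible under
reordering.  The pipeline derives named substreams (e.g. `bootstrap`)
from the config seed the same way; all derived seeds stay below 2³¹.

**What the simulator does not emulate.** No indels (family alignments are
gap-free by construction, so block extraction barely trims them), no
rate heterogeneity across sites or families, no composition bias, no
domain shuffling or partial homology.  Consequences for interpreting
tests: passing end-to-end tests shows the pipeline machinery is correct
under the stated model, not that it is robust to alignment error or rate
variation in real proteomes.  One visible effect: with a single rate for
all families, the two identities of the three-way comparison vary only
through sampling noise around fixed means, so the lowess smoother
explains little variance (R² near 0.1 on synthetic data).  In real data,
shared rate variation across genes spreads orthologs along the identity
range and pushes the smoother's R² toward 1; a high R² is a property of
that rate spread, not of the machinery tested here.

## Search and E-values

The built-in stage computes optimal local alignments (Smith–Waterman /
Gotoh affine gaps) via Biopython's pairwise aligner with BLOSUM62 and the
search-tool gap convention (a gap of length L costs `open + L·extend`,
default 11 + L).  E-values use the Karlin–Altschul form
`E = K·m·n·e^(−λS)` with the standard gapped BLOSUM62 constants
K = 0.041, λ = 0.267, actual sequence lengths, and no edge-effect
correction — only the ordering and the `E < 10⁻⁵` cut matter downstream.
Letters outside the matrix alphabet are either rejected or scored at the
matrix minimum (mapped to `*`), per flag.

Exhaustive DP over every gene pair is quadratic and meant for small gene
sets; for larger runs the search stage shells out to an installed
`blastp` (ids are mapped to safe tokens and back so pipe-delimited gene
ids survive), or imports precomputed hits in the 12-column tabular
format.  Imported E-values of 0 are floored to 1e-200 before log
transforms.  Whatever the route, at most one hit is kept per ordered
pair (best by E-value, ties to the higher bit score) and self-hits are
dropped.

## Clustering and categories

Reciprocal hits become an undirected graph; the edge weight is the mean
of the two `−log₁₀ E` values capped at 200.  Markov clustering runs on
the column-stochastic matrix with self-loops set to each node's maximum
incident weight: expansion (matrix squaring) alternates with inflation
(elementwise power 1.5, then renormalisation) and pruning of entries
below 1e-5, until the matrix changes by less than 1e-8 or 100 iterations
(non-convergence is flagged, and the current interpretation returned).
Clusters are the connected components of the limit matrix's symmetrised
support, which always partitions the node set.  When the full gene
universe is supplied, hit-less genes enter as isolated nodes and come
out as singleton groups, so the partition covers every gene.  No
OrthoMCL-style inparalog weight normalisation is applied: plain
reciprocal `−log₁₀ E` weighting is fully specifiable and preserves the
structure of the analysis.

Category rules over S species, in precedence order (first match wins):

1. **species-specific** — all members from one species;
2. **universal-single** — at most one genome deviates from exactly one
   copy (deviation = absence or duplication);
3. **universal-multi** — absent from at most one genome, but failing the
   single-copy tolerance;
4. **lineage-only** — present only inside the configured lineage and in
   at least three of its genomes;
5. **present-at-half** — present in at least ⌈S/2⌉ genomes;
6. **patchy** — the remainder.

The precedence order is a declared convention: the rules overlap (a
family present everywhere but duplicated in one genome reads as both
"single-copy tolerant" and "specific duplication"), and restricting
species-specific to single-species groups resolves the ambiguity one
way, recorded here.  The lineage is a config input, never inferred.
Single-copy selection for the supermatrix is strict by default (exactly
one copy in every selected species); tolerant mode applies the
universal-single rule instead.

## Alignment and conserved blocks

The built-in progressive aligner exists so the pipeline runs with no
external binary; imported alignments always take precedence.  Pairwise
global alignments give 1 − identity distances, average-linkage
clustering gives the guide tree, and profiles are merged by global
affine-gap DP on expectation-of-pairs column scores (`fᵃᵀ S fᵇ` over
residue frequencies; gap characters inside matched columns score 0
because their cost was paid at gap opening).  DP ties prefer substitution
over a gap in the first profile over a gap in the second, making the
output deterministic.

Block extraction classifies each column by the count of rows sharing its
majority (most frequent non-gap) residue: nonconserved below `b1`,
conserved from `b1`, highly conserved from `b2`.  Runs of more than `b3`
contiguous nonconserved columns are rejected; remaining candidate blocks
are trimmed to highly conserved flanks; blocks shorter than `b4` are
dropped.  Under the default gap policy any gap-containing column is
nonconserved and excluded even inside surviving blocks.  Defaults for
`n` rows: `b1 = ⌊n/2⌋+1`, `b2 = max(b1, ⌈0.85·n⌉)`, `b3 = 8`, `b4 = 10`
— the classic conserved-block defaults, configurable and recorded in
output metadata.  Majority-count ties break to the alphabetically
smaller residue (this affects only the recorded majority, not the
count).  Column indices are 0-based; block spans half-open.  For each
group the retained set is computed once, on the alignment containing all
analysed species, so every species pair is compared over the same
columns; groups missing a species are dropped and logged.  Retained
columns concatenate in lexicographic group order into the supermatrix,
with per-group partition offsets.

## Identity, three-way comparison, lowess

Percent identity is `100 · matches / comparable columns`, the denominator
counting retained columns where both rows are non-gap (a declared
convention, recorded in output metadata).  Distribution summaries use
linear-interpolation quartiles and the standard notch half-width
`1.58·IQR/√n`.  The three-way comparison labels a group "closer" to the
comparator whose identity to the focal species is larger by more than
`tie_eps` (default 0 — exact ties only); ties are reported separately.

The lowess smoother is the classic locally weighted regression: at each
observed x, a weighted straight line over the `⌈frac·n⌉` nearest
neighbours with tricube weights of scaled distance, then `robust_iters`
bisquare re-weighting passes on residuals (defaults frac = 2/3, 3
iterations, matching the conventional defaults of the widely used
implementations; the test suite checks agreement with an independent
reference implementation to 1e-6).  A coefficient of determination for a
smoother is not standard, so it is defined explicitly as
`1 − SS_res/SS_tot` using fitted values at the observed x; degenerate
inputs (constant x or constant y) are guarded as documented in the API.

## Supermatrix phylogeny

p-distances are `1 − matches/comparable` over both-non-gap supermatrix
columns.  Neighbor joining uses the Q criterion and the standard
branch-length formulas; exact ties in Q choose the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest
leaf), so taxon input order never matters.  Negative branch lengths are
clamped to zero and flagged.  Bootstrap resamples supermatrix columns
with replacement, rebuilds the NJ tree per replicate, and reports for
each internal bipartition of the original tree the percentage of
replicates containing it.  A distance method stands in for
maximum-likelihood inference deliberately: it is fully specifiable,
fast, and sufficient for the topology-recovery properties tested;
externally inferred trees can be supplied as newick where ML is wanted.
Output is unrooted; an outgroup flag roots for display only.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` recomputes, from scratch and seeded only by
`--seed`: simulator identity means over 100 families × 300 aa at path
distances 0.1 / 0.5 / 1.0 (against the closed form); end-to-end family
recovery on a 4-species, 500-family mixture (60% universal single-copy,
15% universal multi-copy, 15% species-specific, 10% present-at-half, all
pairwise path distances ≤ 0.7), preferring `blastp` for the
all-against-all stage and falling back to the built-in aligner;
the closest-relative fraction over 500 single-copy orthologs with the
focal species at distances 0.4 vs 0.8 and the smoother's R²; and NJ with
100 bootstrap replicates on a 6-species, 20-family (~6,000-column)
supermatrix.  These sizes keep the full script around a minute on one
CPU while leaving the statistical margins (3 standard errors, 95%
recovery thresholds) comfortably testable.

## Known limitations

* The simulator's gap-free, single-rate model exercises the machinery,
  not robustness to alignment error, indels, or rate variation.
* The built-in search stage is exhaustive DP — quadratic in gene count —
  and intended for small sets; use the blast engine or imported hits at
  scale.
* Ortholog/inparalog/co-ortholog sub-typing within groups and
  tree-reconciliation orthology are out of scope.
* The category rule set assumes a single designated lineage; nested
  lineage structures are not modelled.
* The progressive aligner does not iterate or refine; imported
  alignments from a dedicated aligner are preferred when quality
  matters.
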