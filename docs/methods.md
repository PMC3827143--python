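# Methods

This note records the models, estimators and numerical choices behind
`fourcbricks`, in the spirit of a statistical methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate system and counting

All coordinates are 0-based half-open; 1-based coordinates appear only in
human-readable output.  The genome is digested in silico at every
occurrence of the cutter motif (BglII, `AGATCT`), with the cut placed at
the motif start: downstream statistics depend only on a consistent tiling,
not on the in-vitro overhang position, and this convention conserves total
length exactly.  Reads are assigned to the fragment containing their 5′
coordinate; boundary ties go to the fragment starting at that coordinate.

Self-ligation and undigested-circle artifacts map to the viewpoint fragment
and its immediate neighbors.  The filter masks the viewpoint fragment plus
`exclusion_k = 2` fragments per side (configurable); masked counts are
excluded from the library size.  The radius is a judgment call — the
protocols this models only state that such reads were removed — and two
fragments per side (~8 kb at BglII density) covers the span an undigested
circle can reach.

## Signal stages and the background model

Counts are scaled to `counts × 10⁶ / library_size`, smoothed with a
centered 19-fragment running mean (shrinking symmetrically at chromosome
edges, so track length is preserved and no signal is fabricated), and
averaged pointwise over replicates.

The local background is modeled as

    E[y](d) = 10^a / d + b,

a power law with the slope pinned at −1 (the standard contact-decay
exponent at these scales) plus an additive floor `b` for random ligation.
The floor matters: without it every fragment far from the viewpoint sits
systematically above the bare power law after subtraction, and the rank
statistics downstream read that bias as a giant distal interaction.

Estimation alternates two robust steps until convergence (8 rounds):

* intercept: signal-weighted median of `log10(y − b) + log10(d)` over
  fragments within the fit range (default: outside the exclusion zone up
  to 2.5 Mb, both sides pooled).  The weighting is deliberate — an
  unweighted median is dominated by noisy distal fragments, and its
  estimation error, though small in relative terms, is amplified by the
  very large proximal counts into coherent proximal residuals.
* floor: median of `y − 10^a/d` over fragments beyond the fit range
  (clipped at zero; left at zero when the chromosome does not extend past
  the fit range, in which case the floor is unidentifiable).

The median (least-absolute-deviation with fixed slope) is robust to the
interaction peaks the pipeline exists to find.  Least squares is available
as an option, and a free-slope regression over the fit range is reported
as a diagnostic: on data that follow the model it returns a slope within
about ±0.1 of −1, and drifts far from −1 when the decay assumption fails.

Profile correction subtracts the fitted expectation; residuals keep their
sign, and the viewpoint exclusion zone becomes missing (NaN).  In the
pipeline the model is fitted on the *unsmoothed* replicate average:
smoothing first would leave the estimate unbiased but cut the effective
sample size of the floor step roughly 19-fold through autocorrelation.

## The Brick-calling track

The domainogram statistic below assumes exchangeable ranks under the null.
Two natural inputs fail that assumption:

* the smoothed corrected track — pre-smoothing correlates 19 neighboring
  ranks, inflating window z-scores by up to √19;
* subtraction (or Pearson) residuals of the unsmoothed track — the
  residual of a *fixed* count value varies monotonically with distance, so
  each count class forms a rank ramp and the chromosome's far end
  accumulates top ranks coherently.

The calling track therefore uses randomized quantile residuals of the
pooled replicate counts `T_i` against the fitted background: with `m_i`
the expected pooled count and `F`, `f` the Poisson cdf/pmf,

    z_i = Φ⁻¹( F(T_i − 1; m_i) + U_i · f(T_i; m_i) ),   U_i ~ U(0,1).

Under the null these are iid standard normal for every fragment regardless
of depth — exactly the exchangeability the window statistic needs — and a
genuine peak still lands at the top of the ranking.  The randomization
seed is an explicit parameter (default 0).  The smoothed and
subtraction-corrected tracks are retained for display and for the
condition ratio; Pearson residuals are available as an option.  The
multi-scale windows themselves provide all the smoothing the detection
step needs.

## Domainogram scoring and Brick selection

Scores are ranked per chromosome (average ranks on ties, scaled by the
number of non-missing fragments, so u ∈ (0, 1]).  For every start `i` and
width `w ≤ Wmax` (default 200 fragments, sub-megabase at BglII density)
the mean rank is computed by cumulative sums in O(n·Wmax) and converted to
an upper-tail p-value by the normal approximation to the mean of `w` iid
uniforms, `p = 1 − Φ((m − ½)√(12w))`.  Windows touching missing fragments
are skipped.

The normal approximation saturates in the extreme tail — a window whose
every fragment is top-ranked cannot exceed `z = ½√(12w)`, which makes
peaks spanning fewer than ~8 fragments undetectable however strong they
are.  P-values below 10⁻⁵ are therefore refined with the exact Irwin–Hall
survival function, evaluated only where its finite alternating series has
rapidly decaying terms (the far tail), so no catastrophic cancellation can
occur; elsewhere the normal value stands.  At very small n the discrete
rank null carries tie atoms of mass > 0.1 near the center, so agreement
with exhaustive enumeration is asserted (and holds, to ≤ 0.05) over the
decision-relevant tail.

Windows are split into two FDR tiers: those entirely inside the
short-range window (default: the ~25 Mb HSA7 interval around the deletion,
configurable) are tested at FDR 0.1, all others — long-range contacts are
more prone to random ligation — at 0.001; straddlers count as long-range.

Selection is sequential and strongest-first: the k-th accepted disjoint
window of a tier must satisfy `p ≤ q·k/m` (m = windows scored in the
tier), ties broken by smaller start.  This is the Benjamini–Hochberg bound
evaluated along the sequence of disjoint discoveries.  One-shot BH over
all windows (available as `method="bh"`) counts the thousands of partially
overlapping sub-threshold windows around each true peak in its rejection
set, which drags the threshold up an order of magnitude and admits
isolated noise windows; the sequential rule avoids that while keeping the
family-wise false-call probability below `q` on a null track (the first
acceptance still requires `p ≤ q/m`).  Consecutive Bricks separated by at
most `merge_gap = 1` fragment merge into interacting regions
(idempotent; summary p = minimum over members).

## Differential analysis

The condition contrast is `log2((max(case,0)+ε)/(max(ctrl,0)+ε))` per
fragment on the **smoothed** tracks.  The decay background is common to
the two conditions and cancels in the ratio, so a hemizygous deletion
reads out directly as log2 ≈ −1; running the ratio on
subtraction-corrected tracks instead would send both numerator and
denominator to ≈ 0 inside a deletion and the ratio to `log2(ε/ε) = 0`.
The pseudocount ε defaults to 5 % of the pooled median positive signal.
Swapping the conditions negates the track exactly.

Ratio Bricks are called by running the domainogram twice — on the natural
ordering (gains) and the reversed ordering (losses) — grouping each into
consecutive runs, then filtering: (1) gain/loss pairs overlapping by more
than 5 % of the shorter member are dropped from both sets (reciprocal mode
available); (2) genome gaps are subtracted from spans, splitting bisected
Bricks; (3) candidates overlapping no Brick selected in either condition
(≥ 1 bp) are discarded.  Per-step removal counts are returned as
provenance.  The whole construction is antisymmetric under condition swap.

Region-level validation compares, by a two-sided Wilcoxon rank-sum test,
the per-region mean of `log(ctrl+case reads + 1)` over member Bricks
against the same quantity for Bricks outside every region.  The exact null
is used when the smaller sample has ≤ 10 observations and no cross-sample
ties; otherwise the tie-corrected normal approximation.  All-tied input
yields p = 1 with a warning.  Interval-level change is summarized as the
median log2 ratio over fragments in the interval with a 95 % percentile
bootstrap CI over fragments (seeded; the underlying computation the CI
method mirrors is not specified by the original analysis, so the
percentile bootstrap is this package's choice).

## Enrichment

Regions are shuffled per chromosome: each region is placed independently
and uniformly at random outside excluded gap intervals with its length
preserved, and shuffled regions may overlap one another (shuffleBed
default semantics).  Admissible start offsets are enumerated exactly and
sampled uniformly, so no rejection loop is needed and an unplaceable
region raises immediately.  The overlap statistic is configurable —
regions hit (default), features hit, or intersection base pairs — because
the original analysis does not state which it used; the empirical p-value
uses plus-one smoothing, `p = (1 + #{null ≥ obs})/(N + 1)`, and so is
never zero.  Gene density is any-overlap gene count per kilobase of the
region union; the coverage matrix reports percent of the chromosome
covered by each viewpoint's Bricks (diagonal) and by pairwise
intersections (off-diagonal).

## Expression summaries

Fold changes are case/control ratios of AREL means, rounded half-up to 3
decimals to match the source expression table's presentation.  Genes below the
detection limit have no ratio and raise.  Welch's two-sample t-test is
computed from summary statistics; replicate counts are not part of the summary table and
must be supplied explicitly, so the resulting p-values are illustrative
rather than reproductions.

## The synthetic generator

`SimulationConfig` encodes the study conditions: one chromosome of 4.1 Mb
cut into ~1000 fragments (exponential lengths, mean 4096 bp = the expected
spacing of a 6-bp cutter), a viewpoint at 500 kb, expected fragment
intensity

    λ_i ∝ (c/d_i + β) × peak_fold(i) × allele_factor(i),

with decay constant c = 1, random-ligation floor β = 10⁻⁷ (a few percent
of total reads, comparable to the decay at megabase distances), four
planted peaks of fold 4–6 spanning 70–100 kb, and Poisson counts per
replicate scaled to a library of 10⁵ reads (negative-binomial mode,
size 10, for overdispersion stress tests; 2 replicates by default).
Viewpoint-zone fragments receive counts so the artifact filter is
genuinely exercised.  The deletion scenario halves λ inside a 300 kb
interval at 1.3–1.6 Mb for the case condition (one allele lost; two of the
planted peaks lie inside it, since a deleted interval interacts
extensively with its flanks before the rearrangement).  The geometry
mirrors the real design at reduced scale: the viewpoint sits 0.8 Mb from
the deletion border (the real viewpoints sit 0.7–1 Mb away) and the
deleted interval holds only a few percent of the chromosome-wide contact
mass, so total-read normalization is not distorted by its loss.

`simulate_genome` emits a random sequence whose digestion reproduces the
simulated map exactly (accidental motifs are disrupted, the motif is
planted at every internal boundary, and the result is verified by
re-digestion).  `simulate_features` places feature intervals inside
planted peaks with a configurable probability, giving an exact null at
probability 0 for calibration studies.  Every dataset can be written with
a YAML manifest of its generating parameters and seed.

What the generator does **not** emulate: trans contacts, fragment-end
mappability and GC biases, polymer-physics contact correlations beyond the
1/d mean, sequencing error, or the secondary NlaIII digestion's
circle-size effects.  Passing tests therefore demonstrate correctness of
the statistics under the stated generative assumptions, not performance on
real 4C libraries.

## Measured behavior and known limitations

The acceptance script and test suite compute, each run: a median log2
ratio inside the simulated deletion of ≈ −0.9 (the expected −1 shrunk
slightly by the pseudocount, total-read renormalization and smoothing at
the interval edges); planted-peak recall and region-level precision ≥ 0.9
at FDR 0.1; a null false-region rate at FDR 0.001 at or below the nominal
level within binomial error; and uniform null p-values for the permutation
and rank-sum tests.

Limitations worth knowing:

* Peaks spanning very few fragments (coarse maps) are detected only
  through the exact-tail refinement and may be missed when they cover
  ≤ 3 fragments and stronger peaks crowd the top ranks — a resolution
  limit of rank-based scoring, not of the data.
* The ratio pipeline deliberately has no replicate-level dispersion model
  (mirroring the two-condition design it reimplements); ratio-Brick
  significance is rank-based within track, not a calibrated
  between-condition test.
* The background fit assumes a single viewpoint per chromosome and cis
  signal only.
* The file-based CLI `bricks` command scores whatever track it is given;
  use the `.calling.bedgraph` emitted by `fourcbricks smooth` rather than
  the `.corrected.bedgraph` display track.
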