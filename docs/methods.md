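# Methods

## Scope and model

`panelcnv` implements tumor-only detection of gene *amplifications* from
targeted cfDNA sequencing depth. The signal model is a two-component
mixture: a fraction `p` of the cfDNA derives from tumor cells carrying
`ABCN` copies of a gene, the rest from diploid normal cells. The
expected depth ratio at that gene against a diploid reference is

    log2Ratio = log2((ABCN·p + 2·(1 − p)) / 2)

and the inverse, used for reporting absolute copy number, is

    ABCN = 2·(2^log2Ratio + p − 1) / p,

floored at 0 because noise can push the raw inversion slightly negative.
`ABCN·p + 2·(1 − p)` — the *effective copy number* of the mixture — is
the natural axis for dilution experiments: a 60-copy amplification
diluted to 0.3 % presents only 2.2 apparent copies, which is what a
detection limit at that fraction means physically.

Deletions are never called. At the tumor fractions typical of plasma
(often < 5 %), a single-copy loss shifts the ratio by at most
`log2(1 − p/2)` ≈ −0.04, far inside the noise envelope, and ctDNA ploidy
cannot be estimated reliably; attempting deletion calls would produce
mostly false positives.

## Normalization chain

**Median scaling.** Each sample is divided by its median probe depth.
The median rather than the mean keeps a handful of amplified probes from
deflating the rest of the profile.

**Combined covariate bias model.** Capture efficiency varies smoothly
with probe GC content and roughly linearly with probe overlap and
mappability. The model is fitted sequentially on the per-probe *median*
of the healthy cohort: first a local-quadratic (loess, tricube weights,
window fraction 0.4) regression on GC — local quadratic rather than
local linear because depth-vs-GC curves are dome-shaped, and a
degree-2 local fit reproduces such curvature without boundary
flattening; then an ordinary least-squares correction of the residual
ratio on centered overlap score and mappability. Keeping the two stages
separate makes each correction inspectable. A final scalar rescale
pins the median log2 residual on the training medians at exactly zero.
Predictions are floored at 0.01 relative depth so division never
explodes. Overlap score and mappability are accepted as panel-file
inputs (their upstream definition is assay-specific); the model only
assumes they are probe-level covariates on a roughly linear scale.

**Panel of normals.** Per probe, the PoN stores the median and a
MAD-based SD (1.4826·MAD) of the bias-corrected normal depths. Robust
statistics matter here: the reference design uses only ten donors, and
one outlier donor would otherwise corrupt mean/SD estimates. Probes
with PoN median below `min_depth = 0.2` (median-normalized units) are
masked — chronically under-covered probes dominate false positives.
Zero depths in a test sample are replaced by half the smallest positive
depth (pseudodepth) so dropouts yield a finite, strongly negative,
subsequently ignored ratio. The PoN is bound to its panel by an MD5
checksum over all probe fields, preventing silent mispairing.

Bias correction is applied *before* PoN division. Because the PoN
median itself removes any per-probe systematic effect, the bias model's
main contribution is variance reduction across samples with different
GC profiles, plus interpretability of the fitted curve.

## Segmentation

Circular binary segmentation, per chromosome. For a probe sequence
`x[0..n)` the statistic for arc `x[i:j]` against its complement is the
two-sample t-like quantity `(m_in − m_out) / (s·sqrt(1/k + 1/(n−k)))`
with `s` the pooled residual SD. The search over arcs is exhaustive and
vectorized (O(n²)), so segmentation involves no heuristic optimizer;
the only stochastic element is the permutation test (probe shuffling)
that decides whether the best arc is a real change point
(`alpha = 0.01`, `n_permutations = 1000` by default, seeded generator
consumed depth-first left-to-right — results are bit-reproducible).
Implementation notes:

- An edge arc `(i, n)` and its complement `(0, i)` describe the same
  split with mathematically equal statistics; both are canonicalized to
  the `(0, i)` form so tie-breaking is well defined.
- Permutations that merely rearrange the same value multiset reproduce
  the observed statistic up to float rounding; the exceedance comparison
  therefore uses a relative tolerance (1e-9) so such ties are counted
  consistently.
- The permutation loop stops early once the exceedance count guarantees
  `p ≥ alpha`; this changes how many random draws are consumed but not
  the decision.
- Small chromosomes are intrinsically hard for the permutation null:
  if an arc spans a large share of the chromosome, many permutations
  keep its values contiguous and the p-value cannot fall below alpha.
  This is a property of CBS itself, not of this implementation; panels
  should keep tens of probes per chromosome.

Masked probes are removed before segmentation; a segment's `n_probes`
counts contributing probes only. The probe-weighted mean of segment
means reproduces the mean of the input ratios to 1e-9 (conservation),
and adding a constant shifts all segment means without moving
boundaries.

## Calling

The per-sample threshold is `max(3 × SD, 0.1)` where SD is the
*population* standard deviation of segment-level mean log ratios —
per-segment, unweighted, since a long diploid baseline would otherwise
mask the spread among focal events. The 0.1 floor guards the degenerate
single-segment profile (SD = 0), where any positive ratio would
otherwise be called. A gene's log2 ratio is the probe-count-weighted
mean of the segment means overlapping its probes; status is *amplified*
on a strict `>` comparison. ABCN is attached when a positive tumor
fraction is available; with `p = 0` the status is still reported but
ABCN is undefined — the two outputs are separable.

A consequence of the self-referential threshold worth knowing: the
amplified segments themselves contribute to the SD, so a very strong
amplification on a small panel raises its own threshold. With ~20+
segments (chromosome count of a realistic panel) the effect is modest;
on toy panels with few chromosomes it can suppress calls entirely.

## Tumor fraction from fragment sizes

Tumor-derived cfDNA fragments are shorter than those of normal cells.
The estimator is intentionally simple: `p` = proportion of fragments
with template length strictly below 150 bp (paired-end |TLEN| of
first-in-pair reads, duplicates and non-proper pairs excluded). It is
exactly invariant to histogram rescaling. Its bias is transparent: for
any mixture, the estimate converges on the total mixture mass below
150 bp, so whenever the normal mode leaks below 150 bp (it does:
~3–4 % for a 167 ± 10 bp mode) the estimate exceeds the true tumor
weight at low fractions. `simulate.expected_short_fraction` computes
this closed form; the tests hold the estimator to it. Because ABCN
scales roughly as `1/p` at small ratios, an inflated `p` proportionally
deflates reported copy numbers — a limitation shared by any
fragment-proportion estimator.

## Synthetic data generator

The generator emulates, in depth space, the study conditions of the
reference validation:

- **Panel**: 150 genes × 10 probes over 22 chromosomes by default
  (counts configurable); GC ~ clipped N(0.45, 0.08), mappability ~
  clipped N(0.9, 0.05), overlap ~ clipped N(0.2, 0.1).
- **Healthy donors**: depth = `target_depth × bias(covariates) ×
  lognormal(0, σ)`, with a quadratic-in-GC, linear-in-mappability
  multiplicative bias whose ground truth is exposed for recovery tests.
  Defaults: 10 donors, σ = 0.05.
- **Cell line**: depth scaled by `ABCN/2` at amplified genes
  (ERBB2 = 60, EGFR = 20, MET = 13 — the validated cell-line values).
- **Spike-in**: median-relative profiles mixed as
  `(1−f)·background + f·tumor`, rescaled to target depth, Poisson
  resampled. Depth-space mixing with Poisson noise stands in for
  read-level down-sampling and merging: per-probe depth is the
  sufficient statistic for every downstream step, and it keeps the
  dilution-ladder experiment runnable in seconds. Median (not mean)
  scaling keeps amplified probes from deflating the diploid baseline,
  so the expected gene ratio follows the forward mixture model exactly.
- **Fragments**: lengths from a two-component truncated-normal mixture,
  tumor ~ N(145, 10), normal ~ N(167, 10), truncated to [50, 400] bp and
  rounded to integers — consistent with published cfDNA fragmentomics
  while remaining a declared synthetic choice.
- **Depth scale**: default 500× mean coverage. Deep panel assays run
  far deeper, but LOD behaviour in this pipeline is governed by the
  noise level relative to the 3·SD threshold, not absolute depth; 500×
  keeps every experiment desk-scale. All generators take composite
  seeds, so replicate PoN sets and sub-experiments draw from
  independent, reproducible streams.

What the generator does **not** emulate: GC bias that varies between
samples (it is fixed per panel), probe-to-probe correlated noise, UMI
artifacts, subclonal copy-number heterogeneity, and germline CNVs in
the donors. Passing tests therefore demonstrate correctness of the
method under the stated noise model, not performance on any particular
clinical assay.

## The LOD experiment

For each of 3 replicate sets, an independent cohort of 10 donors builds
the bias model and PoN; one further held-out donor is the dilution
background; the cell line is mixed in at 5 %, 4 %, 3 %, 2 %, 1 %,
0.6 %, 0.3 %; the full pipeline runs on each mixture. The LOD is the
smallest fraction detected in *all* replicate sets (the detection-rate
criterion is otherwise unspecified in this kind of design; requiring
all sets is the conservative choice). Results carry the full detection
matrix, the realized thresholds, and each set's fixed background offset
at the spiked genes, so the stochastic outcome can be compared against
the deterministic threshold-crossing prediction of the forward model.
Two cell lines are simulated separately (ERBB2 alone; EGFR and MET
together), mirroring the reference design and keeping their segments
from inflating each other's thresholds. Under default conditions the
simulated LODs land at 0.6 % (ERBB2), 1 % (EGFR) and ~2 % (MET); note
that for MET = 13 copies the effective-copies arithmetic at a 3 %
fraction gives 2.33, so a printed "2.5 copies at 3 %" for MET is not
reproducible from the stated copy number — the harness reports the
arithmetic consistently instead.

## Numerical and design choices

- Coordinates are BED-style 0-based half-open; probe length is
  `end − start`.
- Depth is mean per-base coverage, not read count, so probe length does
  not confound normalization.
- `min_mapq = 20` by default; duplicates, secondary and supplementary
  alignments are always excluded.
- The population (ddof = 0) SD is used for segment-level spread;
  configurable.
- Fisher's exact test accompanies the enrichment odds ratio; a zero
  cell triggers the Haldane (+0.5) correction for the OR only.
- Probe-order, row-order and read-order invariance of all parsers is
  tested; all randomness is behind explicit seeds.

## Test problem sizes

Unit tests use 40-gene panels; the operating-characteristic tests use
the default 150 × 10 panel with 100 specificity samples, 50 recovery
replicates, two dilution experiments × 3 PoN sets, and 200 random
instances (≤ 15 probes) for the exhaustive CBS oracle. The full suite
runs in under two minutes on one CPU.
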