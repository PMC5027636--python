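# Methods

`peasta` re-implements, as a tested pipeline, the complete computational
analysis of a combined single-cell protein (proximity extension assay, PEA)
and RNA (specific target amplification, STA) qPCR experiment: normalization,
background-calibrated detection, dilution-series probe qualification,
correlation and permutation statistics, in-silico gating, correlation
networks, classification, and trajectory clustering. This note records the
models, conventions, and design choices behind each stage.

## Measurement model and normalization

Both analytes are read out as qPCR cycle thresholds (Ct); lower Ct means more
template, and one cycle is one doubling. All statistics operate on ΔCt, a
nonnegative log2 abundance with 0 encoding "undetected":

* **RNA**: ΔCt = max(24 − Ct, 0). The 24-cycle ceiling is the assay's
  effective floor of quantification; reactions that never cross threshold are
  assigned 0.
* **Protein**: each PEA probe produces background signal even with no cell
  present, so background is estimated per assay from zero-cell capture
  sites: Ct values above 24 (including the undetected sentinel) are clipped
  to 24, then the mean and sample SD are taken over all zero-cell wells.
  ΔCt = max(bg_mean − Ct, 0) after the same clipping. Backgrounds are pooled
  across time points only when all pairwise two-sample t-tests on the
  zero-cell Ct values fail to reject homogeneity at α = 0.05; otherwise
  per-time-point backgrounds are used.
* **Dilution wells**: referenced to the mean lysis-buffer Ct of the assay,
  falling back to the 24-cycle ceiling for assays undetected in buffer.

No PCR-efficiency correction is applied anywhere; fidelity to the simple
ΔCt rules is preferred over added model complexity. A consequence worth
noting: for RNA, ΔCt = 0 means exactly "undetected or past the ceiling",
while for protein ΔCt = 0 conflates "undetected" with "at or below
background".

Cells expressing fewer than 35 reliable RNAs (ΔCt > 0) are culled before any
statistics. Detection for culling is the literal ΔCt > 0 rule rather than
the probabilistic call below, which is the closest reading of the
quality-control rule as stated ahead of the detection model; the threshold
and rule are both configurable.

## Detection model and limit of detection

Background on the ΔCt scale is modeled as one-sided normal noise centered at
0 with the assay's background SD. A value is called **detected** when it
exceeds z(1−α)·bg_sd, with α = 0.01 by default; the strict inequality means
a value exactly at the threshold is not detected. RNA assays have no
zero-cell background (a zero-cell site yields no RNA template at all), so
RNA detection falls back to ΔCt > 0 unless lysis-buffer wells supply a
background SD.

The **limit of detection** of a dilution series is the smallest quantity at
which at least 7 of 8 replicates are detected at α. Series with a different
replicate count apply the equivalent proportion (⌈7/8·n⌉), which is the only
sensible generalization of the stated rule.

## Dilution-series window selection and probe reliability

A probe's usable dynamic range is selected by exhaustive search: replicate
mean ΔCt is regressed (OLS) on log2 quantity over every contiguous window of
at least 3 levels, and the window maximizing R² − 0.03·(levels removed)
wins; ties prefer the longer window, then the lower start index. Windows of
fewer than 3 levels are disallowed because R² is degenerate at 2 points. A
zero-variance window has R² defined as 0. Published analyses of this kind
also adjust ranges by eye; that step is deliberately not automated here —
instead an optional per-target window override can be supplied, keeping
manual adjustments auditable.

With the 0.03-per-level cost, a window is only shortened when the excluded
levels break linearity badly (e.g. a steep high-concentration "hook", where
PEA probe pairs land on separate antigen molecules and signal collapses);
gently flattening flanks are retained, which matches how shallow the penalty
is by construction.

A probe is **reliable** when its selected window has positive slope, spans
1.3 cell equivalents (the single-cell scale), and the nearest level's mean is
detected. Failure modes: `NO_SIGNAL` (no level detected), `SATURATED`
(slope ≤ 0 while at least half the levels show signal — a testable surrogate
for "constantly saturated"), else `RANGE_EXCLUDES_SINGLE_CELL`.

## Correlation statistics

Per paired gene and time point, Spearman ρ between the RNA and protein ΔCt
vectors is computed over retained cells with zeros included — excluding
undetected cells would change n per gene and bias toward expressing cells; a
detected-only variant exists for sensitivity analysis. Changes in ρ between
time points are tested against a permutation null: cell labels are shuffled
10,000 times preserving group sizes, Δρ recomputed each time, and a
two-sided p-value read from a normal with the null's mean and SD. Two-sided
is the conservative choice where sidedness is not dictated. Distribution-
level comparisons use Lilliefors (normality), two-sample t (means) and F
(variances) tests on the per-gene ρ sets.

Empirical quantiles (for Q–Q comparison curves) use linear interpolation at
probabilities (i−0.5)/n — one convention fixed and documented.

## Expression models and differential testing

Single-cell ΔCt distributions are bimodal: a point mass at 0 plus a roughly
normal expressing component. Two models are fitted per target/time point —
a plain normal over all values, and a three-parameter model (fraction
expressing π, plus normal μ, σ over detected values). π is the detected
fraction at the calibrated threshold and μ, σ are ML estimates conditional
on detection rather than a joint EM — "fraction expressing" semantics imply
a cut, not a latent mixture. χ² goodness of fit uses equal-probability bins
with expected counts ≥ 5 and degrees of freedom reduced by the 2 fitted
parameters (so at least 4 bins, i.e. ~20 observations). Because neither
model fits universally, differential calls use two distribution-free tests:

* **Fisher's exact** on detected/undetected counts, run when the undetected
  total across both groups exceeds 10;
* **Mann–Whitney U** on detected values only, run when the detected total
  exceeds 10.

"Exceeds ten for the two populations" is read as the sum across both groups
(the more inclusive reading); a per-group variant is available. The
in-silico gating screen bifurcates cells by detection of each target in turn
and applies both tests to every other target, with Benjamini–Hochberg
correction within each gate's experiment (both test kinds pooled as one
family). Direction is the detected-proportion difference for Fisher and the
median difference for Mann–Whitney.

A note on BH: the step-up adjustment is monotone, order-preserving, and
capped at 1, but it is *not* idempotent as an operator (bh([1, 0.25]) =
[1, 0.5]; bh([1, 0.5]) = [1, 1]); tied vectors are exact fixed points. The
property tests assert exactly this.

## Correlation networks and circuits

Edge significance is calibrated from a permutation null computed per target
pair *within a time point*: one margin's cell labels are shuffled 10,000
times and the null ρ summarized by mean and variance; the edge threshold at
level α is null_mean + z(1−α)·√null_var. With ~70–90 cells per time point
the null variance is ≈ 1/(n−1) ≈ 0.015, giving a threshold of 0.29 at
α = 0.01 and motivating the working rule that ρ > 0.3 makes an edge.
Computing the null on pooled cells would roughly triple n and shrink the
threshold below 0.15 — partitioning by time point is part of the procedure,
not a detail.

Seed networks connect non-seed targets to seed members they correlate with
strictly above threshold, per time point; edge degree counts a target's
edges into the seed set. No transitive growth by default (a flag enables
it). Circuit-level cell clustering scales each circuit target to max 1,
correlates cells (Spearman; cells undetected across the whole circuit have
no defined ranks and are treated as uncorrelated), clusters 1−ρ distances
with average linkage, cuts at k = 2, and Fisher-tests cluster membership
against gate detection and unperturbed-vs-stimulated membership.

## Classification and trajectories

PCA standardizes every target (z-score) so protein and RNA assays contribute
equally, then decomposes by SVD with a deterministic sign convention
(largest-magnitude loading positive). The time-point classifier follows the
bootstrap scheme literally: training indices are ⌈0.8·n⌉ draws *with
replacement*, the never-drawn cells form the (randomly sized) test set, a
500-tree random forest is fit on all PC scores, and one-vs-rest ROC/AUC
(trapezoidal) is computed per class. A deterministic 80/20 split is
available by flag; realized set sizes are recorded.

Trajectory analysis bins each cell, per paired gene, into four joint
detection quadrants (P−R−, P−R+, P+R+, P+R−) at the calibrated cutoffs.
A gene's profile is its quadrant proportions concatenated time-ascending ×
fixed quadrant order (any fixed order works for rank correlation of matched
vectors); genes are clustered on 1 − Spearman ρ distances with average
linkage — the one linkage convention used throughout — and cut at height
0.75. A constant profile has no defined rank correlation and becomes a
singleton cluster with a warning.

## Synthetic data: what it emulates and what it does not

The generator reproduces the measurement structure the analysis relies on:

* **Bimodal expression**: per target and time point, a fraction π of cells
  express; expressing cells' ΔCt is normal truncated to (0, 24].
* **RNA–protein coupling**: a Gaussian copula per paired gene — one latent
  bivariate normal per cell with correlation `pair_rho` drives both
  detection (upper-π tail) and, conditional on detection, the level (the
  rescaled tail quantile feeds the truncated-normal inverse CDF). Margins
  stay exact while detection and level co-vary, as real dropout data do.
* **Backgrounds**: zero-cell wells draw protein Ct from the assay's
  background normal; RNA never amplifies there. ΔCt is generated first and
  Ct back-derived (RNA: 24 − ΔCt; protein: bg_mean − ΔCt), so ground truth
  lives on the scale the analysis uses.
* **Dilution ladders**: linear in log2 quantity inside a known window, flat
  at background below, saturated or declining (hook, with configurable
  steepness) above, plus lysis-buffer wells.
* **Per-cell quality**: one capture-efficiency value per cell shifts all
  detection probabilities on the logit scale (SD 0.6 for the study-scale
  conditions), spreading per-cell detected-RNA counts so the 35-RNA cull
  removes a realistic low tail.

The study-scale defaults (`study_like_params`) fix the panel at 89 RNA + 27
protein assays (27 paired genes), 91/79/83 cells and 5/17/13 zero-cell wells
at 0/24/48 hr, latent pair coupling 0.3 (whose dropout-attenuated observed
Spearman lands near 0.25), and a stimulated phenotype that is markedly
stronger on the protein panel (more responders, larger shifts in π and μ,
three temporal profiles: ramp, early saturation, overshoot). Proteins are
given higher detection fractions and tighter expressing-cell spreads than
RNA, reflecting translation buffering transcriptional bursting.

Not emulated: melt curves, splice isoforms, PCR-efficiency kinetics, plate
spatial effects, amplification carry-over between assays, and any real
biological network structure beyond the injected pairwise couplings. Passing
tests therefore demonstrate that the pipeline's statistics behave correctly
under the stated measurement model — calibrated nulls, recovered parameters,
controlled FDR — not that they would uncover any particular biology in a
real dataset.

## Numerical conventions and degenerate inputs

* Undetected raw Ct is NaN internally, never 999, so sentinels cannot leak
  into arithmetic; ΔCt uses 0 for undetected by construction.
* Spearman ρ of a constant vector is undefined and returned as NaN with the
  pair flagged/excluded; degenerate permutation nulls (SD 0) yield p = 1 at
  the center and 0 elsewhere, flagged.
* Zero-variance targets are excluded from PCA with a warning; an all-constant
  matrix is an error.
* Random draws all flow from `numpy.random.default_rng` seeded explicitly;
  seeds are recorded in outputs and the pipeline manifest. The classifier's
  bootstrap makes its test set random in size; everything else is
  deterministic given the seed.

## Problem sizes in the shipped analyses

The numbered drivers under `analysis/` and `scripts/acceptance.py` run the
study-scale simulation (253 cells × 116 assays), 10,000-permutation nulls
for edge calibration, 2,000-permutation Δρ tests per gene transition, the
full 116-gate screen (~26,000 tests), and 5 bootstrap splits for AUC
estimates; the property suite uses 100–200 seeded replicates per invariant
and n = 2000 for parameter-recovery checks. These sizes give stable
Monte-Carlo estimates while keeping a full run in the minutes range on one
CPU.
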