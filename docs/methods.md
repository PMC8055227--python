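# Methods

This note documents the models, numerical choices and simulation design
behind `hdxdiff`, and what the test suite does and does not demonstrate.

## From centroids to uptake

A DynamX cluster row carries the intensity-weighted centroid m/z of one
peptide ion (one charge state, one replicate injection, one exposure
time). We deconvolute to neutral mass, `M = (m/z − m_p)·z` with
`m_p = 1.00727646688` Da, and define deuterium uptake per row as the
neutral mass minus the peptide's reference mass: the intensity-weighted
mean neutral mass over all exposure-0 rows of the same (protein, state,
peptide) group. References are computed within state, matching the DynamX
grouping; a pooled cross-state reference is available behind a flag for
datasets whose non-deuterated control was acquired once per protein.
Exposure times are minutes throughout and are matched exactly (after
rounding to six decimals) — cluster files from one experiment share an
exposure grid, so no nearest-neighbour matching is attempted.

### Charge-state quality filter

Redundant or poor-quality charge states are removed per (peptide, state,
exposure) cell by two rules, iterated to a fixed point (which makes the
filter idempotent):

* intensity floor: rows carrying less than `min_intensity_frac` (default
  0.01) of the cell's summed intensity;
* robust outlier: rows whose uptake deviates from the cell's
  intensity-weighted median by more than `k_sigma` (default 3) times the
  robust SD, 1.4826 × median absolute deviation. When the MAD is zero the
  rule is skipped (no scale to judge against).

The last row of a cell is never removed, so aggregation is total. Both
parameters are exposed in the CLI and `RunConfig`.

### Aggregation

Per cell, `d_mean = Σ I·D / Σ I` and
`d_sd = sqrt(Σ I (D − d_mean)² / Σ I · n/(n−1))`, where `n` counts
distinct raw files rather than rows: multiple charge states of one
injection sample the same labelling event and are not independent
replicates. Single-replicate cells get `d_sd = 0` and are flagged rather
than dropped; all-zero intensities fall back to unweighted statistics
with a warning.

### Back-exchange correction

With a maximally-labelled control state, each peptide's observed maximum
uptake `D_max_obs` (control `d_mean` at its largest exposure) estimates
the recoverable label. The scalar correction factor
`N·f / D_max_obs` — with `N` the exchangeable-amide count
(`len(sequence) − 1` minus prolines after the first residue) and `f` the
deuterium fraction of the labelling buffer (default 0.9) — multiplies
both `d_mean` and `d_sd` of every analysis state. The per-peptide back
exchange, `100·(1 − D_max_obs/(N·f))` %, feeds the data-quality summary.
Correction is deliberately a single scalar per peptide
(timepoint-specific correction is out of scope); peptides absent from the
control or with non-positive `D_max_obs` pass through unchanged and
flagged. Factors outside [1, 5] are warned about: values below 1 imply
the control exceeded the theoretical maximum, values above 5 imply the
control barely retained label.

## Differential analysis

Peptide identity is (start, end, sequence, modification) — charge comes
out in aggregation, and the same span with a different modification is a
different molecule. ΔD = D̄_B − D̄_A (B minus the reference state A) with
`se = sqrt(sd_A²/n_A + sd_B²/n_B)`. Exposure-0 rows are carried through
the differential table flagged, for completeness of exports, but never
enter the statistics: the reference construction centres them at zero by
definition, so any "difference" there is noise.

## Significance models

### Peptide-level linear model

Replicate-level uptake of each common peptide is fit to
`D = β₀ + βₛ s + βₜ t + βₛₜ s·t + ε`, state and time categorical. Terms
are tested by extra sums of squares: main effects against the additive
model, the interaction against the full model, all with the full model's
residual mean square as denominator. On balanced designs this is exactly
the classical two-way ANOVA partition (the test suite verifies agreement
with an independent from-scratch sums-of-squares computation to 1e-8, and
with statsmodels' Type-II `anova_lm`). We chose this form over dropping a
main effect's dummy columns while keeping interaction columns, which with
treatment coding does not reproduce the classical partition. Fitting is
ordinary least squares via `numpy.linalg.lstsq`; rank, SSE and residual
df are exposed for audit.

Fitting on replicate-level rather than mean uptake keeps the per
observation error term meaningful and the residual df honest; the
alternative (fitting cell means) discards the within-cell variance that
the F tests need.

Saturated designs (one replicate per cell) drop the interaction, report
its p-value as NaN and test main effects against the additive model's
residual. Fewer than two non-zero exposures or fewer than two states is
an error.

Benjamini–Hochberg adjustment is applied across peptides separately for
the state family and the interaction family (m = number of peptides
tested): the two hypotheses answer different questions — a state offset
versus state-dependent kinetics. The adjustment scales the rank-i ordered
p-value by m/i, then enforces monotonicity with a cumulative minimum from
the largest rank down and clips at 1; without the step-up pass the scaled
values can decrease with rank, which would not be a valid adjusted
p-value. A peptide is significant when either family's adjusted p is
below α (default 0.05; 0.01/0.1 presets in the CLI); the time effect βₜ
is reported but never drives significance, since uptake trivially grows
with time. Direction comes from the sign of the peptide's summed ΔD.

### Hybrid test

The pooled variance of each state is the mean of the per-cell variances
across all peptide-exposure cells with at least two replicates; with
modal replicate counts n_A, n_B the global threshold is
`t(1 − α/2, n_A + n_B − 2) · sqrt(pooled_A/n_A + pooled_B/n_B)`. A cell
is significant when |ΔD| exceeds the threshold *and* its Welch t-test
(Satterthwaite df) gives p < α; a peptide is rolled up as significant if
any exposure passes. The threshold is global across exposures by
default; a per-exposure variant is available, useful when late
timepoints are much noisier. If a state shows zero pooled variance the
threshold degenerates to 0 with a warning — this only occurs on
noise-free synthetic data. Cells left with fewer than two replicates in
a state (e.g. after aggressive filtering) cannot be Welch-tested and are
reported with NaN p-values, never as significant.

## Synthetic data

The generator (`synthetic_fixtures`) emulates what the upstream Waters
pipeline exports, with every ground truth recorded in a manifest echo and
truth table:

* peptide spans (6–15 residues, random sequences) on a configurable
  protein, default 40 peptides on 120 residues;
* exponential exchange kinetics `D(t) = f · Σ_k (1 − e^(−k_k t))` with
  per-amide rates log-uniform over 10⁻²·⁵–10¹ min⁻¹ and f = 0.9,
  spanning the default exposure grid 0/0.5/5/30 min;
* state effects as uptake offsets (Da) per peptide, clipped to the
  physical range [0, f·N]; the truth table records the *realized*
  per-exposure difference after clipping;
* per-peptide back-exchange recovery factors uniform on 0.65–0.85
  (i.e. 15–35% back exchange, typical of unquenched-optimised setups);
* 3 replicates, 1–2 charge states per peptide (log-normal intensities,
  lower charge more intense);
* noise: Gaussian on neutral mass per row, split into a centroid
  determination component (0.01 Da, all rows) and a labelling component
  (0.05 Da, deuterated rows only). The split reflects that replicate
  scatter in HDX-MS comes mostly from the labelling/quench process,
  while the non-deuterated reference is measured with high mass
  precision; giving the reference the full labelling noise would induce
  a shared per-state mass offset that no peptide-level test could
  distinguish from a real effect.
* optionally, a maximally-labelled control state at the plateau `f·N`
  (times the back-exchange factor), for exercising the correction.

`simulate_replicate_table` additionally simulates replicate-level uptake
directly (uniform intensities, iid Gaussian noise), bypassing the file
and reference machinery — the clean setting used to calibrate type-I
error and p-value uniformity.

What the generator does **not** emulate: isotope envelopes and their
widths, EX1 bimodality, retention-time drift, peptide misassignment,
inter-day batch effects, or correlated replicate structure. Passing
calibration tests on this generator therefore demonstrates correctness
of the statistical machinery under its stated assumptions, not
robustness to every pathology of real data.

## Numerical and design choices

* Cluster CSV floats are written with 9 significant digits; the
  round-trip contract is equality to 6 significant digits.
* Plot tables are exported with fixed `%.6f` formatting and sorted keys,
  so identical inputs yield byte-identical files; the PNG renderings are
  views over those tables and only smoke-tested.
* Volcano y-values cap −log10 p at 16 (flagged) to keep zero p-values
  plottable.
* Protein length defaults to the maximum peptide end observed;
  constructs with uncovered termini should override it.
* The barcode consensus is unanimity-based: a residue-exposure is
  deprotected/protected only if *all* significant covering peptides
  agree in sign, `mixed` otherwise, `none` without significant coverage.
* Structure exports translate construct to structure numbering by a
  single integer offset per chain; alignment-based mapping is out of
  scope. The Chimera writer targets classic Chimera (`defattr` +
  command file); ChimeraX uses a different command dialect.
* Back-exchange controls are resolved per protein; a control state must
  contain the same protein's peptides.
* Duplicated identical rows in input are dropped with a warning;
  identical keys with conflicting values are fatal — silent averaging of
  corrupt exports is worse than a hard stop.

## Problem sizes used in validation

The statistical guarantees are exercised at: 10,000 random p-vectors
(length 1–500) for the BH oracle; 200 random balanced 2×3×3 designs for
the ANOVA oracle; 1,000 iid null peptides for type-I calibration (both
models ≤ 2α at α = 0.05, KS distance of raw state p-values < 0.05); and
60-peptide end-to-end datasets where 50 peptides carry three times the
hybrid threshold (≥ 90% recovery with correct direction by both models).
The acceptance script uses 40-peptide differential runs and 500-peptide
null calibrations.

## Known limitations

* The outlier filter runs before the tests; when it removes a replicate
  from a cell, the remaining pair can look artificially concordant and
  the Welch prong of the hybrid test becomes slightly anticonservative
  for that cell. On fully simulated datasets the peptide-level null flag
  rate stays near the 2α bound but can brush against it; with filtering
  disabled (`k_sigma` large) the rate drops well below α.
* The linear model treats rows as independent; charge states of one
  injection violate this mildly (they share labelling noise), which the
  replicate-count convention in the aggregation acknowledges but the
  regression does not.
* BH families are adjusted per run; combining multiple pairwise state
  comparisons requires a further correction that is left to the user.
* The hybrid threshold assumes approximately homogeneous per-cell
  variances within a state; strongly heteroscedastic datasets are better
  served by the per-exposure threshold option.
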