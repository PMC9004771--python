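# Methods

## Signal model

Each subject is an `R x T` matrix of region-mean BOLD signals sampled at
TR = 3 s, band-passed to 0.01–0.08 Hz, with T = 130 retained time points
(140 acquired, first 10 discarded for magnetisation equilibrium). The
inter-regional communication path between regions *j* (input) and *i*
(output) is modelled as a linear time-invariant system, `y = x * h`, so
in the frequency domain `Y(f) = X(f) H(f)`. The CorrTF estimator reads
the empirical ratio `DFT(x_i)[k] / DFT(x_j)[k]` as the transfer function
of that path; disease-related changes in the path appear as changes in
the ratio's gain.

This is a deliberately strong idealisation: it assumes a single-input
noiseless LTI path per pair and ignores hemodynamic variability, shared
drivers and feedback. The feature remains well defined without those
assumptions — it is then simply a frequency-resolved, directional
connectivity statistic rather than a literal system identification.

## Feature extraction

Per subject: complex ratio tensor `R x R x T` (full DFT length; with
R = 116, T = 130 this is 116 x 116 x 130), then Fisher r-to-z
(`arctanh`) of the ratio **magnitudes**, then the arithmetic mean over
all T frequency bins, diagonal zeroed, off-diagonal cells flattened
row-major into a length `R(R-1)` vector.

Numerical choices:

* **Complex-to-real.** The r-to-z transform needs a real argument; the
  magnitude (the gain of the path) is used by default. The real part is
  available (`mode="real"`) but is not the tested default.
* **arctanh domain.** Gains can exceed 1, where arctanh diverges;
  magnitudes are clipped to `1 - 1e-6` (clip count logged). This
  preserves ordering below the clip and guarantees finite features, at
  the cost of making all gains ≥ 1 indistinguishable — the synthetic
  defaults therefore plant gains < 1.
* **Denominator guard.** Bins where the denominator spectrum is below
  `1e-8` of its own maximum yield ratio 0 and a flag instead of a huge
  meaningless quotient. After band-passing, out-of-band bins are close
  to this regime.
* **Order of operations.** arctanh is applied per bin, then averaged.
  Averaging complex ratios first and transforming afterwards is the
  other defensible order; it is not the default and not what the
  acceptance checks exercise.
* **Band-limited averaging** (`band_limited=True`) restricts the mean
  to bins with 0.01 ≤ |f| ≤ 0.08 Hz. The default averages all T bins.
* **z-scoring.** Per-feature standardisation to zero mean / unit
  variance is *not* part of feature extraction; it happens inside the
  classifier pipeline using training-fold statistics only, to avoid
  test-set leakage.

## Preprocessing scope

Input volumes are assumed motion-corrected, slice-time-corrected,
normalised and smoothed upstream. This package only extracts label-mean
time series (background label 0 excluded, rows in ascending label
order) and band-passes them with a zero-phase forward–backward
Butterworth filter, order 5. Zero-phase filtering is essential because
CorrTF measures inter-regional phase. Filtering is applied to ROI means
(extract, then filter), and no detrending is performed. On records as
short as 130 samples, forward–backward IIR filtering leaves visible
edge transients; tests of the filter's response therefore measure the
central portion of the record or in-band spectral content, and
idempotence (refiltering changes little) holds for content strictly
inside the passband, not at the band edges where the order-5 response
already rolls off.

## Synthetic cohorts

The generator emulates the operating conditions above: base signals are
white Gaussian noise shaped in the DFT domain to the 0.01–0.08 Hz band,
then z-scored per row. The out-of-band spectrum is not zeroed but held
at a −60 dB floor (amplitude `1e-3`): out-of-band power stays ≤ 1e-4 of
the total (well under the 1% band-limitation budget) while every bin
keeps nonzero energy, so spectral ratios are well defined at all bins.

Planted couplings are circular convolutions of the (already z-scored)
source row with a finite impulse response, plus white Gaussian
observation noise of `noise_sd`; circularity makes the per-bin DFT
ratio identity exact. Kernel edges must form a DAG with at most one
kernel per target region, and kernels are applied in topological order,
so chained paths compose. Group differences are encoded purely as
different kernels per group on a shared edge set.

**DC identifiability.** z-scored sources have exactly zero mean, so the
DC bin of every denominator is guarded: the DC component of a kernel is
unidentifiable from zero-mean data. Recovery checks that quantify "the
kernel is recovered at every bin" therefore use zero-sum kernels
(`H(0) = 0`), for which the guarded ratio 0 is also the true value; for
general kernels the recovery statement holds at all bins except DC.

**Default study conditions** (chosen once, as the package's reference
synthetic experiment): 16 regions, 130 time points, 40 subjects per
class, `noise_sd = 0.1`, six planted directed edges carrying per-group
scalar gains: edges 1→2 and 3→4 separate AD from everyone (0.25 vs
0.80), 5→6 and 7→8 separate NC from the MCI stages (0.90 vs 0.65), and
9→10 and 11→12 separate EMCI from LMCI (0.80 vs 0.55, with NC/AD at the
midpoint 0.675). The gaps shrink down the hierarchy, emulating staging
data where advanced disease is easiest to recognise. At these settings
the per-edge group separation is several within-group standard
deviations, so both classification schemes saturate near 100% — the
end-to-end checks are structural (the pipeline recovers the planted
staging; the hierarchy does not trail the flat scheme), not a claim
about attainable accuracy on real cohorts. What the generator does
*not* emulate: hemodynamic response functions, head motion, scanner
noise spectra, inter-subject anatomical variability, or indirect /
shared-driver connectivity. Passing on synthetic cohorts demonstrates
correctness of the computation, not clinical performance.

## Feature selection

Two-sided Welch (unequal-variance) two-sample t-tests per directed
edge; edges with p strictly below alpha = 0.05 are selected. Directed
edges (i, j) and (j, i) are tested separately (the tensor is
asymmetric). No multiple-testing correction is applied by default —
edge-level raw p-values are the convention being mirrored — and this is
a known limitation; a Benjamini–Hochberg flag exists (`fdr=True`).
Edges where both groups are constant and identical get p = 1 and a
degenerate flag. If nothing survives selection, the classifier falls
back to all edges with a warning rather than fitting on an empty
matrix. For flat four-class training, where a two-sample test does not
directly apply, the selector keeps the union of all pairwise
class-contrast selections. Ranked "most discriminative connection"
tables sort ascending by p with ties broken by row-major edge position.

## Classification

Every unit classifier is a pipeline: per-feature z-scoring → t-test
selection → SVM with a linear kernel and C = 1 (configurable; the
high-dimensional small-n regime favours linear and avoids silent
hyperparameter fishing). The flat scheme is a single SVC (one-vs-one
voting). The hierarchical scheme trains one independent binary pipeline
per layer on the subjects belonging to that layer's super-classes —
AD vs {NC, EMCI, LMCI}, NC vs {EMCI, LMCI}, EMCI vs LMCI — and routes
each test subject through the layers, stopping at the first positive
decision. The layer ordering is fixed by default but
`pairwise_binary_accuracies` reports all pairwise CV accuracies so the
ordering can be re-derived from data.

Cross-validation is stratified k-fold (k = 10, shuffled with a
documented default seed of 42); scaling and selection are refit inside
each training fold. Outputs are both per-fold metrics (mean ± SD) and
the pooled confusion matrix accumulated over all test folds. Metric
arithmetic is exact (`fractions.Fraction`) before the final float; any
zero-denominator metric is reported as NaN with an explicit flag, never
silently 0. Macro averages over one-vs-rest reductions are used for the
4-class sensitivity/specificity/PPV/NPV; overall accuracy is
trace/total.

## Network analysis

"Connection strength" for thresholding is the group-mean Fisher-z
CorrTF value — the analysis needs a scalar per edge and this is the
feature the rest of the pipeline uses. Directionality is ignored by
taking the larger of the two directed strengths per pair, and the
boundary is inclusive (≥ 0.1): an edge supra-threshold in either
direction survives. Counts per network pair use six groupings (SMC, VC,
EAN, DMN, SN, Cereb); within-network edges count once on the diagonal,
so the upper-triangle total equals the edge count. The bundled
AAL116→network table is a documented reconstruction (no canonical
assignment is published for this grouping); it is an editable TSV and
analyses that depend on exact per-network counts should review it.
Export is plain-text node/edge lists for external connectome viewers.

## Known limitations

* The LTI single-path interpretation of spectral ratios is heuristic;
  ratios between regions that are not actually coupled are heavy-tailed
  and land mostly in the clipped regime, contributing a constant offset
  plus noise to the features.
* The 0.1 strength threshold is calibrated to z-transformed magnitudes
  of real cohorts; on the synthetic cohorts the baseline feature level
  sits well above it, so thresholding there keeps all edges.
* No multiple-testing correction by default (see above).
* Synthetic validation covers computational correctness only; no claim
  transfers to clinical data without a real cohort.
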