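# Methods

## Analysis model

A recording is a set of spike trains aligned to stimulation onset (t = 0)
and partitioned into three half-open windows: BE = [−20, 0) s, TT = [0, 1) s,
PE = [1, 21) s. The defaults follow the ±20 s analysis span around a 1 s,
100 Hz stimulation train; all windows are configurable but must stay
contiguous with TT starting at 0. A spike exactly on a boundary belongs to
the window (or PETH bin) on its right.

Per neuron, the window rates are counts divided by durations
(M_BE, M_TT, M_PE). Group-level ("pooled") rates divide the summed count by
`n_neurons × duration`, matching the normalisation of summed peri-event
histograms; with equal durations this equals the mean of per-neuron rates
(asserted to 1e-12 in the tests). PETHs use 1 s bins by default; the
difference curve is the per-neuron averaged bin rate minus the pooled BE
rate of the same neurons. An uneven bin width truncates the last partial
bin and flags the result.

### Response classification

The peri-stimulus label is TD when `M_TT < M_BE(1 − ε)`, TP when
`M_TT > M_BE(1 + ε)`, otherwise "no response" (NR); the post-stimulus label
(PTD/PTP/NR) applies the same rule to M_PE. The relative dead-band defaults
to ε = 0.05: the source workflow states no quantitative criterion for
"decrease"/"increase", so a symmetric 5 % band is the package's documented
choice. Conventions: a silent baseline with any later firing counts as an
increase; an all-zero triple is NR. NR neurons are excluded from the
four-type proportion table, which reports percentages of classified neurons
(exact values retained, integers for table parity).

Fold changes use the magnitude convention `max/min ≥ 1`, because the
reported ratio tables print values above 1 for both excitatory and
inhibitory types — a directional quotient cannot reproduce both halves.
Group ratios are computed from pooled window rates of each type's members,
not by averaging per-neuron ratios: the 1 s TT window holds only a handful
of spikes per neuron, and ratios of small counts are badly biased. If one
pooled rate is zero the ratio is capped (default 1e6) and recognisable as
such; 0/0 is NaN.

## Synthetic cohorts

Each generated neuron fires as a piecewise-homogeneous Poisson process with
rates (r_be, r_tt, r_pe). The baseline r_be is uniform on 8–12 Hz by
default: nigral tonic firing spans roughly 1–8 Hz, and the upper end of that
range is used (slightly inflated) so the 1 s TT window carries enough counts
for sign classification; no per-neuron rate distribution is reported for the
original cohorts, so the uniform choice is a modelling decision, not a data
fact. r_tt and r_pe divide or multiply r_be by the response type's
configured fold change (depression divides, potentiation multiplies), making
the generating ratios exact.

Response types are allocated by largest-remainder quota over the configured
mixture, not by independent multinomial draws, so realised counts equal the
target mixture exactly and proportion-recovery experiments are clean.
Six presets encode the observed condition summaries (control / rotenone /
rotenone + bacterial melanin × SNc / SNr): type mixtures, per-type fold
pairs, and recorded cohort sizes (107, 105, 95, 135, 184, 141). One reported
total (622 neurons) is inconsistent with the per-condition sizes (sum 767);
the per-condition numbers are treated as authoritative here.

A dispersion knob (squared ISI coefficient of variation) switches the
process to gamma renewal for over-/under-dispersed regimes; it defaults to
1 (Poisson) because only mean window rates enter the analysis. Randomness is
keyed by `(seed, neuron index)`, so cohorts are reproducible element-wise;
the package-wide default seed is 20250528 and every pipeline run logs it.

Raw traces place a biphasic template (peak 0.15 mV, the middle of the
recorded 0.12–0.18 mV amplitude range; ~1 ms wide) at each spike time on a
20 kHz grid and add white Gaussian noise; true spike times are retained for
scoring.

### What the generator does not emulate

Burst firing and serial ISI correlations, slow rate drift, per-trial
structure (each neuron is a single pass around one event), electrode drift
and waveform variability, overlapping units, and any pharmacological
mechanism — the group labels are labels only. Passing recovery tests
therefore shows that the analysis correctly inverts its own generative
assumptions at realistic rates and cohort sizes, not that it is robust to
every property of real recordings.

## Spike detection

A candidate event is a contiguous run of samples beyond the threshold
(polarity-aware); the run's extremum must fall inside the configured
amplitude window — the extremum-in-window rule mirrors hardware window
discriminators. Accepted events closer than the refractory period
(default 1 ms) to the previous accepted event are dropped; times are
reported at the extremum sample. Scoring matches detected to true times
greedily one-to-one within 1 ms; with zero detections precision is reported
as 1 and flagged, since an empty answer makes no false claims.

Numerical note on scoring at Poisson rates: at 10 Hz about 1 % of true
inter-spike intervals are shorter than 1 ms, so with the default refractory
the expected recall ceiling is ≈ 0.99 regardless of noise level. Detection
fidelity benchmarks in the test suite therefore score with the refractory
set to the template's supra-threshold lobe width (0.3 ms), which suppresses
double counting within one waveform without erasing resolvable neighbours;
at amplitude SNR 15 recall and precision both exceed 0.99.

## Statistics

Two-proportion comparisons use the pooled-variance two-sided z-test
(statsmodels), replaced by Fisher's exact test (flagged) whenever an
expected cell is below 5. On all 2×2 tables with margins ≤ 15 the z branch
stays within 0.2 of the exact mid-p value and within 0.35 of the
conservative Fisher p (the fallback reproduces the exact enumeration to
1e-9). Under a null with n = 100 per arm its type-I error at α = 0.05 is
calibrated to [0.03, 0.07]. When only percentages are reported, counts are
reconstructed as `round(p × n)` before testing.

Student's t is equal-variance by default (Welch optional) with Cohen's d
(df-weighted pooled SD) attached; degenerate zero-variance inputs are
flagged rather than raised. One-way ANOVA and Tukey HSD use scipy; with two
groups F = t² and the Tukey p equals the t-test p (both asserted).
Normality is checked per group by Shapiro–Wilk (skipped with a flag below
n = 3) and variance homogeneity by mean-centered Levene. α is fixed at
0.05 throughout and no multiplicity correction is applied across the
type × region comparison grid, matching the source convention of starring
raw p < 0.05. Which observations underlie the reported effect sizes is not
stated in the source; rate comparisons here use per-neuron post-event
window rates and label that assumption in the output.

## Known limitations

* **Weak fold changes are not classifiable in single 20 s windows.** For a
  post-event fold f applied to baseline r_be, the normal-approximation
  z-score of the PTD decision at ε = 0.05 is roughly
  `r_be(0.95 − 1/f) / sqrt(r_be(1/f + 0.95²)/20)`; at f = 1.12 and 10 Hz
  this is ≈ 0.6, i.e. ~27 % of such neurons fall in or across the dead-band,
  and driving the error below 1e-3 would require baselines of hundreds of
  Hz. The same applies at fold ≈ 2 in the 1 s TT window (~0.5–2 % error).
  Measured per-neuron misclassification on 10 000-neuron cohorts is 1.1 %
  (control-SNc), 7.9 % (bm-SNc, dominated by its fold-1.12 type) and 0.2 %
  (rotenone-SNr). Consequently, mixed-cohort proportion recovery is exact
  only for conditions whose smallest fold is well separated from the
  dead-band; columns containing near-unity folds shift by one or two points.
* Ratio recovery precision is set by pooled TT counts: a 500-neuron cohort
  at 10 Hz baseline and fold ~5 pools ≈ 900 TT spikes, giving ~3 % relative
  SE — comfortably inside 10 % but not much tighter.
* Problem sizes used by the test and acceptance runs: 500-neuron cohorts
  for ratio recovery, 100 for proportion recovery, 10 000 for
  misclassification estimates, 10 000 simulated tables for test
  calibration; these keep full runs in the minutes range on one core.
* The pipeline analyses one pass per neuron; trial-averaged PETHs from
  repeated stimulation events would sharpen every estimate but are not part
  of the data model.
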