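# Methods

## Generative model for synthetic cohorts

Each subject's EEG is driven by a hidden microstate sequence and an
alpha-band carrier:

```
x(t) = A · sin(2π f t + φ(t)) · T_{s(t)} + ε(t)
```

* `s(t)` — semi-Markov state sequence. Run lengths are gamma-distributed
  (shape 2 by default) with per-state, per-group mean dwell times;
  defaults are the group-level values reported for adolescent narcolepsy
  patients and matched controls (A/B/C/D, ms): patients
  87.58 / 90.47 / 75.92 / 61.14, controls 101.44 / 80.02 / 72.92 / 61.54.
  The next state is uniform over the other K−1 classes unless a
  transition kernel is configured. The gamma shape is a modeling choice
  (real dwell-time distributions for this population are not published);
  it is config-exposed. Run lengths round to ≥1 sample, which biases the
  mean by <0.5% at the default 100 ms / 125 Hz scale.
* `T_k` — unit-norm, average-referenced templates. The first four are
  canonical-style patterns (two oblique posterior–anterior gradients,
  an occipital–frontal gradient, a fronto-central focus) plus a smooth
  unit-norm random perturbation (15% relative by default); pairwise
  |spatial correlation| is enforced ≤ 0.7. Higher K adds random smooth
  bump maps.
* Carrier — a *signed* 10 Hz sinusoid with random-walk phase drift
  (SD 0.05 rad/sample). GFP maxima therefore fall at alpha half-cycle
  extrema and the field flips polarity each half-cycle, which is the
  physical reason microstate maps are treated as polarity-invariant.
  A rectified (|sin|) envelope would look identical to every
  polarity-invariant stage (same GFP series) but carries most of its
  envelope power at DC, which the pipeline's own 1 Hz high-pass removes;
  the filtered envelope would then cross zero ~40×/s and artificially
  fragment backfitted dwell times. The signed carrier keeps the signal
  inside the 1–40 Hz analysis band.
* `ε(t)` — spatially white Gaussian noise scaled so that the RMS of the
  state signal over all channels and samples is `snr` (default 3) times
  the noise RMS. Spatially correlated noise is deliberately not
  modeled: it would make the effective SNR direction-dependent and hard
  to interpret.

RSN component time courses are generated on the microstate sequence
itself: per state, a 0/1 occupancy boxcar on a 100 Hz grid is convolved
with the canonical double-gamma HRF and sampled at the TR (2.2 s,
270 volumes by default); component `c` is the coupling-weighted sum
`Σ_k coupling[k, c] · regressor_k` plus AR(1) noise (coefficient 0.3,
marginal SD 0.5). The default coupling drives two components (2, 10)
from state A and one each from B, C, D — a planted "one network per
microstate, A special" pattern whose recovery the tests score.

Subject metadata (ages uniform on 13–20 years, mixed gender) exists so
the covariate machinery is exercised; the generator does **not** give
covariates any real effect.

### What the generator does not emulate

No MR gradient/cardioballistic artifacts, eye blinks, sleep-stage
dynamics, volumetric fMRI, spatially correlated noise — and, most
importantly, no *between-subject variability in dwell times*: all
subjects of a group share the same configured means, so between-subject
variance is pure sampling noise. Passing recovery and power tests
therefore demonstrates correctness of the estimators and statistics
under the stated model, not effect sizes or power attainable on real
cohorts (real power will be lower).

## Pipeline numerics

**Preprocessing.** Zero-phase Butterworth band-pass (order 8,
1–40 Hz, `sosfiltfilt` so GFP peak latencies are not shifted), then
polyphase resampling to 125 Hz, then average reference. Filtering
precedes resampling so band edges are defined on the original rate.

**GFP and peaks.** GFP is the population (divide-by-C) standard
deviation of the average-referenced topography. Peaks are interior
strict local maxima; plateaus count once at their first sample;
endpoints never count. Peaks above `median + 5·(1.4826·MAD)` are
excluded — a deterministic surrogate for the visual rejection of
artifact-contaminated peaks; the threshold is config-exposed
(`exclusion_z`).

**Clustering.** Modified K-means on pooled peak maps: assign each map to
the template with highest |spatial correlation| (Pearson across
channels of average-referenced maps), then re-estimate each template as
the polarity-aligned mean of its members (each map multiplied by the
sign of its correlation before averaging), re-centered and
re-normalized. An `"eigen"` update variant replaces the mean with the
GFP²-weighted principal eigenvector of the member maps — the exact GEV
optimizer for a fixed assignment, used when bit-comparable optimality
matters (the mean update typically lands within 1% of the optimum).
Convergence: relative GEV change < 1e-6, max 100 iterations, 50 random
restarts by default, best restart by total GEV. Empty clusters re-seed
from the worst-fit map. Peaks with zero GFP must be excluded upstream
(they carry no topography).

**Choice of K.** `CV(K) = σ̂² · ((C−1)/(C−1−K))²` with σ̂² the mean
per-peak residual variance after projecting each map on its assigned
unit template. Near-ties (within 1e-12 of the data variance scale)
resolve to the smallest K. On noise-free single-class data the
criterion is exactly zero from K=1 upward, hence the tie rule.

**Canonical labels.** Recovered templates are matched one-to-one to
geometric reference patterns (built from the montage at runtime;
synthetic stand-ins for the normative A–D maps of the resting-state
literature, used only to anchor label order) by Hungarian assignment on
|correlation| — identical to exhaustive permutation search.

**TANOVA.** Statistic: global map dissimilarity between the two
group-mean maps, each normalized to unit GFP and polarity-aligned;
p-value from group-label permutations with the observed split counted
in numerator and denominator (`n_perm="exact"` enumerates all splits).
Individual peak maps carry arbitrary alpha polarity, so callers should
align maps (e.g., by their clustering polarity) before group averaging;
the analysis driver does this per class.

**Backfitting.** Per sample, `argmax_k |ρ|`, ties to the lowest template
index. Samples whose GFP falls below 0.5× the median GFP inherit the
previous label (a leading low-GFP stretch takes the first valid label).
Derivation of the floor: with unit-norm templates and white noise at
snr 3, the noise alone contributes GFP ≈ 0.33× the median — so any
floor below that never fires — while samples below ~0.5× median have
signal-to-template correlation ≲ 0.74 and mislabel often enough to
fragment runs (measured: ~30% label error in the bottom GFP decile,
cutting estimated mean duration by ~a third). The floor shifts run
*boundaries* by at most a couple of samples but does not create or
destroy runs, so duration estimates stay unbiased. Config-exposed
(`gfp_floor_frac`); set 0 to disable. No temporal smoothing or
minimum-segment rejection is applied by default.

**Temporal metrics.** Mean duration = mean run length × 1000/fs;
occurrence = runs per second; ratio of total time = labeled-sample
share; per-state GEV over all samples with GFP weighting. Edge runs
(touching the recording boundary) are included by default; with
`trim_edges=True` the first and last run are dropped, and then
`mean_duration_s × occurrence_per_s = ratio_total_time` holds exactly.
The transition matrix is sample-to-sample with the diagonal included
(staying in a state is an observable event at the sampling rate); a
run-level, diagonal-free matrix is also returned for comparability with
other conventions. A never-visited state reports zero
duration/occurrence, is flagged, and its transition row is set uniform
to keep the matrix stochastic.

**Group statistics.** The K per-state values per subject are reduced to
K−1 within-subject differences; the multivariate group effect on that
difference vector — exactly the group × state interaction — is tested
with Wilks' Λ (Rao's F approximation, via statsmodels MANOVA) in a
model with group, age and gender. Post hoc: per state, regress the
parameter on age and gender with groups pooled, then equal-variance
two-sample t on the unstandardized residuals; threshold 0.05/K. This
residualization convention is stated explicitly because residual-based
post hoc t statistics are not uniquely defined across software;
magnitudes from other conventions are not comparable. Transition
probabilities enter the multivariate comparison as the flattened
off-diagonal entries. A singular design (e.g., constant covariate) is
reported as degenerate rather than silently dropped.

**Temporal sorting.** State boxcars are built on a 100 Hz grid before
HRF convolution — microstate runs (~100 ms) are far below the TR and
would alias if binned at the TR first. HRF: double gamma, peak 6 s,
undershoot 16 s, peak:undershoot 6:1, length 32 s (config-exposed).
Regressors are mean-centered and compete in one multiple regression per
component (joint fit; a rank-deficient design yields NaN slopes rather
than an arbitrary solution). Z-scores standardize the group-mean slopes
across *components* within each microstate × group cell (population SD;
an all-equal cell yields a zero Z row), making "Z ≥ 1" a per-heat-map-row
criterion; only positive excursions are flagged, mirroring the decision
not to interpret negative couplings. Standardizing across microstates
instead would answer a different question ("which state does this
component prefer") and can be had by transposing the slope matrix.

## Problem sizes in the test suite

The acceptance-level tests and `scripts/acceptance.py` run the full
machinery at the study's recording conditions (64 channels, 125 Hz,
snr 3, 16 subjects/group where group-level aggregation is under test)
but with shorter recordings (60–120 s) and 10–20 replicate cohorts;
statistical calibration uses 200 null cohorts of 8/group on
label-sequence metrics, which is sufficient because the statistics
consume metrics, not raw EEG. The exhaustive clustering oracle runs on
10 maps × 4 channels, where all 2¹⁰/3¹⁰ assignments are enumerable.

## Known limitations

* The cross-validation criterion's penalty is weak at C = 64; with
  heavily blended or overlapping templates it can prefer K above the
  generative truth. The analysis driver reports the full CV curve and
  accepts a `--k` override.
* Post hoc t magnitudes depend on the residualization convention (see
  above) and should not be compared across software.
* The TANOVA assumes maps entering a group mean are polarity-aligned;
  raw GFP-peak maps are not.
* The EDF writer quantizes to 16 bits over each channel's range
  (relative error ~3e-5); round-trip tests on EEG use that tolerance,
  while TSV round-trips are exact to 1e-9.
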