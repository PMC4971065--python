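# microstate-rsn

EEG microstate analysis with temporal coupling to fMRI resting-state
networks (RSNs), built for two-group resting-state studies — the kind of
design used to compare clinical populations (e.g., adolescents with
narcolepsy) against matched controls — and exercisable end to end on
synthetic cohorts with known ground truth.

The resting scalp field moves through brief (~60–120 ms) epochs of
quasi-stable topography ("microstates", conventionally labeled A–D).
The pipeline implements the standard analysis chain:

1. **GFP peaks.** Global field power `GFP(t) = std_c(x_c(t))` (population
   standard deviation over channels of the average-referenced
   topography); local GFP maxima are the moments of highest topographic
   signal-to-noise and supply the clustering input.
2. **Polarity-invariant modified K-means.** Peak maps from all subjects
   are pooled and clustered by absolute spatial correlation; a map and
   its negation belong to the same class. The objective is the global
   explained variance

   `GEV = Σ_p (GFP_p · ρ_p)² / Σ_p GFP_p²`,

   with `ρ_p` the spatial correlation between peak map `p` and its
   assigned template. The number of classes is chosen by the
   cross-validation criterion `CV(K) = σ̂² ((C−1)/(C−1−K))²` (mean
   per-peak residual variance, penalized per class), templates are
   labeled A–D by optimal matching against canonical reference patterns,
   and topographic consistency between groups is verified with a
   permutation TANOVA on global map dissimilarity.
3. **Backfitting and temporal statistics.** Templates are fitted back
   competitively to the continuous EEG (`argmax_k |ρ|` per sample);
   run-length statistics give mean duration (ms), occurrence (runs/s),
   ratio of total time, per-state GEV and the transition matrix.
4. **Group statistics.** Repeated-measures multivariate ANOVA (Wilks'
   Λ) of the group × microstate interaction with age and gender as
   covariates; post hoc per-state t-tests on covariate-adjusted
   residuals at the Bonferroni threshold 0.05/K.
5. **Temporal sorting of RSNs.** Each microstate's onsets/durations are
   convolved with the canonical double-gamma HRF, sampled at the
   scanner TR, and the K regressors jointly predict each RSN component
   time course per subject. Group-mean slopes are standardized to
   Z-scores across components within each microstate × group cell;
   pairings with Z ≥ 1 are flagged.

A synthetic-data module generates two-group cohorts (default: 64-channel
10-20 EEG at 125 Hz, 16 subjects/group, semi-Markov dwell times with
group-specific means, 15 RSN time courses at TR 2.2 s coupled to the
microstate sequence through a known slope matrix), so every stage can be
scored against ground truth.

## Worked example

The analysis is driven by numbered scripts; each reads the previous
stage's outputs from `results/`:

```sh
python analysis/01_simulate.py --seed 1     # cohort EEG (EDF) + RSN time courses
python analysis/02_segment.py  --seed 1     # GFP peaks, clustering, backfitting
python analysis/03_metrics.py               # temporal parameters per subject
python analysis/04_stats.py                 # group comparison
python analysis/05_sort_rsn.py --heatmap    # EEG->RSN temporal sorting
```

With the scaled default cohort (8 subjects/group, 120 s EEG each) this
prints, among other things:

```
cross-validation criterion: {2: 8.2709, 3: 3.4713, 4: 1.1846, 5: 1.1934, 6: 1.2057} -> K = 4
clustering: GEV = 0.959 (per template [0.289 0.257 0.226 0.186])
cohort-mean dwell times (ms):
state        A     B     C     D
control  100.4  78.9  70.2  62.0
patient   86.5  89.2  73.1  62.4
 mean_duration: Wilks' lambda = 0.094, F(3,10) = 32.14, p = 0.0000 (significant at alpha=0.05)
      post hoc A: t = 6.17, p = 2.44e-05
flagged microstate-RSN pairings (Z >= 1):
   control: [('A', 2), ('A', 10), ('B', 5), ...] — 5/5 true couplings recovered
```

Reading: the cross-validation criterion recovers the four planted
classes; clustering explains 96% of the GFP-weighted topographic
variance; backfitted dwell times reproduce the configured group profile
(controls dwell longer in A, patients in B) within a few percent; the
multivariate group × microstate interaction is detected and the post hoc
test localizes it to microstate A; and the temporal sorting flags the
RSN components that were actually coupled to each microstate.
`--full` on `01_simulate.py` switches to the study-sized cohort
(16/group, 600 s, 270 volumes).

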