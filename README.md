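# chronophase

Analysis toolkit for circadian **chronotypes** in *Drosophila*: flies, like
humans, split into early-rising "larks" and late-rising "owls", and the phase
at which an adult emerges from its pupal case (**eclosion**) is a convenient,
circadian-gated readout of that preference. Given eclosion times for an early
(E) and a late (L) strain and RNA-seq expression time courses collected over
the day before eclosion, the questions are: *do the strains differ in
eclosion phase?* and *is their gene expression merely phase shifted, or more
fundamentally divergent?*

`chronophase` answers both with a tested, reusable pipeline:

- **`eclosion_io`** — parse TriKinetics DAM2-style activity-monitor files,
  take the first beam crossing per channel as that fly's eclosion, and convert
  clock times to Zeitgeber time (ZT; hours since lights-on).
- **`circular_stats`** — circular descriptive statistics on the 24 h circle
  (mean direction, mean resultant length R̄, circular SD `s = √(−2 ln R̄)`,
  95% CI) and the **Watson–Williams two-sample test**
  `F = (N−2)(R₁+R₂−R)/(N−R₁−R₂)`, including a reconstruction mode that
  recovers F from published summary statistics alone.
- **`timeseries_xcorr`** — the core screen. For each transcript, the Pearson
  correlation between the E and L replicate-averaged time courses is computed
  at every circular lag of the 6-point, 4 h sampling grid; the maximal
  correlation `r_max` locates the best phase alignment. A high `r_max` means
  "same waveform, possibly shifted"; a low one means divergent expression.
  Significance is judged against a time-label-permuted null ensemble at 5%
  empirical FDR, jointly with the FPKM variance (constitutive transcripts
  correlate spuriously). Also: z-score normalisation and hierarchical
  clustering for expression heatmaps, and gene-list overlap reports.
- **`enrichment_network`** — hypergeometric over-representation analysis with
  Benjamini–Hochberg FDR, PSI-MI TAB (BioGRID) parsing, and first-neighbour
  interaction subnetworks around a DEG seed list.
- **`synthetic_data`** — generators that emulate the study designs with
  planted ground truth: a threshold-accumulation **eclosion-gate simulator**,
  a von Mises phase sampler, and a two-condition expression generator with
  constitutive / shared-rhythmic / phase-shifted / divergent transcripts.
- **`pipeline` / `chronophase` CLI** — end-to-end orchestration from a YAML
  config with seeded, byte-reproducible outputs.

## Worked example

Screen a synthetic expression table with planted structure, then compare the
labels against the planted truth:

```python
from chronophase import synthetic_data as sd, timeseries_xcorr as tx

m, truths = sd.simulate_expression_timeseries(
    {"phase_shifted": 500, "divergent": 500, "constitutive": 1000}, seed=11
)
screen = tx.run_xcorr_screen(m, n_perm=50, alpha=0.05, variance_floor=10.0, seed=12)
lags = {r.transcript_id: r.best_lag_hours for r in screen.results}
rep = sd.recovery_report(truths, screen.labels, best_lags_hours=lags)
print(f"threshold  = {screen.threshold.threshold_score:.3f}")
print(f"lag recovery = {rep['lag_recovery_rate']:.3f}")
print(f"divergent sensitivity = {rep['divergent_sensitivity']:.3f}")
```

prints

```
threshold  = 0.906
lag recovery = 1.000
divergent sensitivity = 0.974
```

i.e. the 5% FDR cut-off on the maximal-correlation score is 0.906; every
phase-shifted transcript has its planted lag recovered exactly, and 97.4% of
truly divergent transcripts are labelled divergent (the rest slip above the
threshold by chance).

Comparing two eclosion-phase samples from published summaries alone:

```python
from chronophase.circular_stats import ww_from_summaries
res = ww_from_summaries(1.47, 2.71, 94, 6.36, 4.79, 95)
print(f"F(1,{res.df2}) = {res.f_statistic:.2f}, p = {res.p_value:.2e}")
# F(1,187) = 54.97, p = 4.13e-12
```

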