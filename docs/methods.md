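# Methods

## Phases on the circle

Eclosion times are treated as points on a 24 h circle via
`angle = ZT × 2π/24`, ZT 0 = lights-on, angles increasing with time.
Timestamps are naive local clock times; timezone and DST are ignored.

For a sample of n angles the mean resultant length is
`R̄ = |mean(e^{iθ})|` and the mean direction is the angle of that vector
(undefined at R̄ = 0, reported as NaN, never an exception — an antipodal pair
is a legitimate input). Dispersion is the **circular SD**
`s = √(−2 ln R̄)` radians, converted to hours by 24 h = 2π. The alternative
convention, the angular deviation `√(2(1−R̄))`, is deliberately not used:
only the `√(−2 ln R̄)` convention lets a published F statistic be
reconstructed correctly from summary statistics via its inverse
`R̄ = exp(−s²/2)` (see below). The 95% CI of the mean direction uses the
standard large-sample form with separate branches for R̄ ≤ 0.9 and R̄ > 0.9;
when the sample is too dispersed for the approximation to yield a real angle
the CI is NaN.

## Watson–Williams test

Two samples with group resultant lengths R₁, R₂ and pooled resultant length
R give

```
F = (N − 2) (R₁ + R₂ − R) / (N − R₁ − R₂),   df = (1, N − 2)
```

F-distributed under the null of equal mean directions when concentration is
high. The high-concentration correction `F × (1 + 3/(8κ̂))`, with κ̂ the ML
concentration solved numerically from `A(κ) = I₁(κ)/I₀(κ) = (R₁+R₂)/N`, is
available behind a flag but **off by default** — the uncorrected statistic is
the one that round-trips through the summary-based reconstruction, and which
convention a given legacy analysis used is rarely stated. When κ̂ < 2 a
warning (not an error) notes that the test's assumptions are strained.

`ww_from_summaries` reconstructs F from printed group summaries: each
circular SD (hours) is converted to radians, `R̄ᵢ = exp(−s²/2)`, a resultant
vector of length `nᵢR̄ᵢ` is placed at the printed mean direction, and the
pooled R comes from the vector sum. When only the total df is known, N is
split as evenly as possible (189 → 94/95). On the 25 °C chronotype summaries
this reproduces the printed F(1,187) = 55.78 to within 1.5%; the 18 °C
summaries (much wider dispersions, unstated group sizes) give a finite
positive F under either correction convention but do not pin down the printed
value — that reconstruction is reported, not asserted.

## The lagged cross-correlation screen

Design: six time points at 4 h intervals spanning 24 h, two replicates, two
conditions (and separate LD/DD experiments). Replicates are **averaged
before correlation**; the replicate-averaged E and L series of each
transcript are compared by Pearson correlation at every **circular** lag
j ∈ {0, …, 5} steps (`r_j = corr(E_t, L_{(t+j) mod 6})`). Circular rather than
truncated lags are justified by the 24 h period of the grid: lag 20 h and lag
−4 h are the same alignment. The score is `r_max = max_j r_j`; the best lag
is reported as signed hours in [−12, 12), ties broken toward the smallest
|lag| and then the negative lag, so results are deterministic.

Variance is the population variance of the 12 replicate-averaged FPKM values
pooled across both conditions; an optional log2(FPKM+1) transform exists but
defaults off. Transcripts below a variance floor are set aside as
`low_variance` (their correlations are spurious); the floor defaults to 0
(no filtering) and should be set to the scale of the data at hand.
Constant series are flagged `degenerate` and excluded from both observed and
null score sets.

### Permutation null and FDR threshold

For each transcript and each of `n_perm` rounds, the L series' six time
labels are permuted uniformly (fresh draw per transcript per round, identity
permutation included) and `r_max` against the unpermuted E series is pooled
into the null ensemble. All draws flow from one explicit seed; reruns are
bit-identical.

The default threshold is the **null-quantile** rule: the smallest observed
score c with `#{null ≥ c}/n_null ≤ α`, i.e. the score a permuted dataset
exceeds at rate α — the convention behind drawing a single "5% FDR" line on
a score axis. It is calibrated: when observed and null scores share a
distribution, ≈ α of observations pass, which is what the suite's all-null
calibration test asserts. Two alternatives are provided: `plugin`, the
pooled plug-in false-discovery proportion
`[#{null ≥ c}/n_null] · n_obs / #{obs ≥ c} ≤ α`, which is far more
conservative (under a complete null it admits essentially nothing, because
the estimated FDR is ≈ 1 at every cut-off); and `bh`, Benjamini–Hochberg on
permutation p-values `(1 + #{null ≥ r_i})/(1 + n_null)`. The choice of
default follows from the calibration property; all three agree on
well-separated score sets.

Classification: `variance < floor → low_variance`; else
`r_max ≥ threshold → phase_concordant` (with the best lag as the estimated
phase shift); else `divergent`.

### Normalisation and clustering

Heatmap rows are z-scored to mean 0 and **population** variance 1 (ddof = 0,
so "variance 1" holds exactly); constant rows are flagged rather than
raising. Hierarchical clustering uses 1 − Pearson or Euclidean distance with
average or complete linkage via SciPy's deterministic agglomeration.

## Enrichment and networks

ORA is the inclusive upper-tail hypergeometric `P(X ≥ k)` with universe N,
annotation K (intersected with the universe), draw n and overlap k; fold
enrichment is `(k/n)/(K/N)`; `P(X ≥ 0) = 1` by convention. Adjustment across
sets is Benjamini–Hochberg (via statsmodels). mitab 2.5 parsing keeps the
first identifier of a configurable column pair (BioGRID puts gene ids in the
alternative-id columns), strips database prefixes, deduplicates undirected
edges, drops and counts self-loops, and skips and counts rows lacking ids —
no remote identifier lookups. First-neighbour subnetworks use the
**induced-subgraph** convention: seeds present in the graph plus their direct
neighbours, with *all* parent-graph edges among the selected nodes including
neighbour–neighbour edges. Induced edges are the convention consistent with
published chronotype networks whose edge counts far exceed their node counts
(e.g. 89 seeds + 618 partners carrying 5057 edges); reproducing those exact
counts is out of scope since they depend on a specific DEG list and BioGRID
release.

## Synthetic generators

All generators are pure functions of (parameters, seed).

**Eclosion gate.** Each fly accumulates an eclosion factor linearly at an
individual rate a (lognormal, mean and CV given) toward an individual
threshold θ (truncated normal, floored at 1% of its mean); the crossing time
is θ/a from ZT 0 of day 0. Eclosion happens at the crossing if it falls in
the daily gate `[gate_open, gate_open + width)` (midnight wrap handled),
otherwise at the next gate opening; flies beyond `max_days` are non-eclosed.
The functional forms — linear accumulation, lognormal rates, truncated-normal
thresholds, a hard gate — are the simplest that exhibit the qualitative
phenomenology of interest: fast accumulation concentrates crossings inside
the first reachable gate but spreads them across it (high first-gate
fraction, larger within-gate circular SD), while slow accumulation overshoots
the gate so flies pile up synchronously at the next opening. Temperature
enters only through the rate mean. Defaults (threshold 100, CV 0.05; rate CV
0.125; gate ZT 0–6; fast/slow rate means 3.7 vs 1.85 units·h⁻¹, i.e. mean
crossings at ~27 h vs ~54 h against gates at 24–30 h and 48–54 h) were chosen
to place the fast regime's crossing distribution inside a gate and the slow
regime's half past one; they are illustrative of the mechanism and are **not**
estimates for any real strain.

**von Mises phases.** κ is solved numerically (Brent on the Bessel ratio
A(κ) = I₁/I₀) so the distribution's mean resultant equals `exp(−s²/2)` for
the requested circular SD; sampling uses numpy's generator.

**Expression time series.** Transcript classes on the 6 × 4 h × 2-replicate
two-condition grid: `constitutive` (flat baseline both conditions),
`shared_rhythmic` (identical sinusoid, uniform random phase per transcript),
`phase_shifted` (L = E circularly shifted by a planted lag of 1–5 steps,
recorded), and `divergent` (E rhythmic; L either flat — "silenced" — or a
second-harmonic 12 h waveform — "distorted" — chosen per transcript and
recorded). The second harmonic is orthogonal to the first on the uniform
6-point grid under every circular shift, so a distorted transcript's maximal
correlation is exactly 0 at zero noise — a divergence that no lag can explain,
by construction. Replicate noise is multiplicative lognormal with sigma
`noise_sd` (mean 1), floored at 0 FPKM. Defaults — baseline 20 FPKM,
amplitude 15, noise sigma 0.1, variance floor 10 for recovery scenarios —
put the rhythmic signal variance (~amplitude²/2 ≈ 112) well above the
replicate-noise variance (~(baseline·σ)²/2 ≈ 2) with the floor between them,
matching an amplitude-to-noise ratio ≥ 3.

What the generators do **not** emulate: read-count mean–variance coupling
(FPKM noise is homoscedastic on the log scale), transcript-length effects,
correlated transcripts, batch effects, or waveforms beyond first/second
harmonics. Passing recovery tests therefore demonstrates that the screen's
machinery is correct and calibrated under its stated model, not that real
RNA-seq data meet that model.

## Pipeline reproducibility

One base seed fans out to per-stage seeds as
`SHA-256("<base>:<stage>") mod 2³¹`, so any stage can be rerun in isolation
with the same randomness. Identical (config, inputs, seed) yield
byte-identical TSV/JSON outputs. Stage failures abort with a stage-tagged
error after writing the partial report.

## Problem sizes used in the test suite

The calibration test uses 2000 transcripts × 50 permutations (≈ 10⁵ pooled
null scores); the recovery scenario uses 500 phase-shifted, 500 divergent and
1000 constitutive transcripts; the gate comparison uses 2000 flies per
regime; von Mises recovery uses n = 5000. These sizes give binomial/Monte
Carlo error comfortably inside the asserted bounds while the whole suite runs
in seconds.

## Known limitations

- The Watson–Williams test assumes von Mises-like, similarly concentrated
  samples; at κ̂ < 2 the F approximation degrades (warned, not blocked).
- The summary-based F reconstruction inherits the printed precision of the
  summaries and the even-split assumption for group sizes.
- With six time points, lag resolution is 4 h and the per-transcript null has
  only 6! = 720 distinct permutations; pooling across transcripts is what
  makes the null ensemble fine-grained.
- The screen tests waveform similarity only; it does not model replicate
  variance within conditions (replicates are averaged first).
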