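"""Synthetic data generators with planted ground truth.

Three generators emulate the data-generating processes behind a chronotype
study so every analysis stage can be tested end to end without external data:

* a threshold-accumulation eclosion-gate simulator: each fly accumulates an
  eclosion factor linearly at an individual rate and ecloses when it crosses
  an individual threshold, but only inside a daily circadian gate — crossing
  outside the gate defers emergence to the next gate opening.  Fast
  accumulation puts most crossings inside the first available gate, spread
  across it; slow accumulation overshoots the gate, so flies pile up at the
  next opening (synchronous, next-day emergence);
* a von Mises phase sampler whose concentration is solved from a requested
  circular SD, as a stand-in for observed eclosion-phase clouds;
* a two-condition expression time-series generator on the 6-time-point, 4 h,
  2-replicate design, planting constitutive, shared-rhythmic, phase-shifted
  and divergent transcripts with recorded truth for recovery scoring.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chronophase.circular_stats import PhaseSample, solve_kappa, zt_to_rad
from chronophase.timeseries_xcorr import ExpressionMatrix

__all__ = [
    "GateModelParams",
    "EclosionOutcome",
    "SyntheticExpressionTruth",
    "simulate_eclosion_gate",
    "compare_gate_regimes",
    "sample_von_mises_phases",
    "simulate_expression_timeseries",
    "recovery_report",
    "DEFAULT_TIMEPOINTS",
]

DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)


@dataclass(frozen=True)
class GateModelParams:
    """Parameters of the threshold-accumulation gate model.

    Rates are lognormal with mean ``accumulation_rate_mean`` (threshold
    units/h) and coefficient of variation ``accumulation_rate_cv``;
    thresholds are truncated normal (floor at 1% of the mean).  The daily
    gate opens at ``gate_open_zt`` for ``gate_width_h`` hours.  Defaults are
    illustrative of the qualitative mechanism, not estimates for any real
    strain.
    """

    accumulation_rate_mean: float = 3.7
    accumulation_rate_cv: float = 0.125
    threshold: float = 100.0
    threshold_cv: float = 0.05
    gate_open_zt: float = 0.0
    gate_width_h: float = 6.0
    max_days: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.accumulation_rate_mean <= 0 or self.threshold <= 0:
            raise ValueError("rate mean and threshold must be positive")
        if self.accumulation_rate_cv < 0 or self.threshold_cv < 0:
            raise ValueError("CVs must be non-negative")
        if not 0.0 <= self.gate_open_zt < 24.0:
            raise ValueError("gate_open_zt must lie in [0, 24)")
        if not 0.0 < self.gate_width_h <= 24.0:
            raise ValueError("gate_width_h must lie in (0, 24]")


@dataclass(frozen=True)
class EclosionOutcome:
    """One simulated fly: eclosion day and phase, or non-eclosion."""

    day_index: int
    zt_hours: float
    eclosed: bool = True


def _lognormal_with_mean_cv(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _truncated_normal(rng: np.random.Generator, mean: float, cv: float, floor: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, mean * cv, size=n)
    # resample the (rare) values below the floor rather than clipping
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(mean, mean * cv, size=int(bad.sum()))
        bad = out < floor
    return out


def simulate_eclosion_gate(params: GateModelParams, n_flies: int) -> list[EclosionOutcome]:
    """Simulate gated eclosion for *n_flies* under the threshold model.

    Each fly draws a rate and a threshold; its crossing time (from ZT 0 of
    day 0) is threshold/rate.  If the crossing falls inside a daily gate the
    fly ecloses at that instant; otherwise it ecloses at the opening of the
    next gate.  Flies whose event would exceed ``max_days`` are reported as
    non-eclosed.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(params.seed)
    rates = _lognormal_with_mean_cv(rng, params.accumulation_rate_mean, params.accumulation_rate_cv, n_flies)
    thresholds = _truncated_normal(
        rng, params.threshold, params.threshold_cv, 0.01 * params.threshold, n_flies
    )
    crossing = thresholds / rates
    out: list[EclosionOutcome] = []
    open_, width = params.gate_open_zt, params.gate_width_h
    for t in crossing:
        # hours since the most recent gate opening (gates may wrap midnight)
        since_open = (t - open_) % 24.0
        if since_open < width:
            event_day = int(t // 24.0)
            event_zt = t % 24.0
        else:
            # defer to the next opening, at open_ + 24k hours from day-0 ZT 0
            event_day = int(math.ceil((t - open_) / 24.0))
            event_zt = open_
        if event_day > params.max_days:
            out.append(EclosionOutcome(day_index=event_day, zt_hours=event_zt, eclosed=False))
        else:
            out.append(EclosionOutcome(day_index=event_day, zt_hours=event_zt))
    return out


def _within_gate_circular_sd(outcomes: Sequence[EclosionOutcome]) -> float:
    zts = np.array([o.zt_hours for o in outcomes if o.eclosed])
    a = zt_to_rad(zts)
    rbar = float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))
    rbar = min(rbar, 1.0)
    if rbar <= 0.0:
        return math.inf
    return math.sqrt(-2.0 * math.log(rbar)) * 24.0 / (2.0 * math.pi)


def compare_gate_regimes(
    n_flies: int = 2000,
    fast_rate_mean: float = 3.7,
    slow_rate_mean: float = 1.85,
    seed: int = 0,
    base_params: GateModelParams | None = None,
) -> dict:
    """Contrast fast vs slow accumulation regimes under the same gate.

    Reports, per regime: the fraction of eclosed flies emerging on the first
    gated day (the earliest day with any eclosion in that regime), the
    fraction deferred to later days, and the circular SD of eclosion phases
    within the gate.  Fast accumulation concentrates crossings inside the
    first gate but spreads them across it; slow accumulation overshoots, so
    more flies defer to a later opening and emerge synchronously.
    """
    base = base_params or GateModelParams()
    report = {}
    for label, rate in (("fast", fast_rate_mean), ("slow", slow_rate_mean)):
        p = GateModelParams(
            accumulation_rate_mean=rate,
            accumulation_rate_cv=base.accumulation_rate_cv,
            threshold=base.threshold,
            threshold_cv=base.threshold_cv,
            gate_open_zt=base.gate_open_zt,
            gate_width_h=base.gate_width_h,
            max_days=base.max_days,
            seed=seed,
        )
        outcomes = [o for o in simulate_eclosion_gate(p, n_flies) if o.eclosed]
        days = np.array([o.day_index for o in outcomes])
        first_day = int(days.min())
        report[label] = {
            "first_gate_fraction": float((days == first_day).mean()),
            "later_day_fraction": float((days > first_day).mean()),
            "within_gate_circ_sd_hours": _within_gate_circular_sd(outcomes),
            "first_gated_day": first_day,
            "n_eclosed": len(outcomes),
        }
    return report


def sample_von_mises_phases(
    mean_zt: float, circ_sd_hours: float, n: int, seed: int
) -> PhaseSample:
    """Draw n phases from a von Mises distribution on the 24 h circle.

    The concentration kappa is solved numerically so the distribution's mean
    resultant length A(kappa) equals ``exp(-s_rad^2/2)``, i.e. so the
    requested circular SD is recovered in expectation.
    """
    if circ_sd_hours <= 0:
        raise ValueError("circ_sd_hours must be positive")
    s_rad = circ_sd_hours * 2.0 * math.pi / 24.0
    rbar = math.exp(-(s_rad**2) / 2.0)
    if not 0.0 < rbar < 1.0:
        raise ValueError(f"circular SD {circ_sd_hours} h implies Rbar outside (0, 1)")
    kappa = solve_kappa(rbar)
    rng = np.random.default_rng(seed)
    angles = rng.vonmises(zt_to_rad(mean_zt), kappa, size=n)
    return PhaseSample(phases_zt=np.mod(angles * 24.0 / (2.0 * math.pi), 24.0))


@dataclass(frozen=True)
class SyntheticExpressionTruth:
    """Generating parameters of one synthetic transcript."""

    transcript_id: str
    truth_class: str  # constitutive | shared_rhythmic | phase_shifted | divergent
    baseline: float
    amplitude: float
    noise_sd: float
    planted_lag_steps: int = 0
    divergent_mode: str = ""  # silenced | distorted (divergent class only)


def _rhythmic_profile(timepoints: np.ndarray, baseline: float, amplitude: float, phase_rad: float) -> np.ndarray:
    return baseline + amplitude * np.sin(2.0 * math.pi * timepoints / 24.0 + phase_rad)


def simulate_expression_timeseries(
    n_per_class: Mapping[str, int],
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    baseline: float = 20.0,
    amplitude: float = 15.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    experiment_label: str = "LD",
    n_replicates: int = 2,
) -> tuple[ExpressionMatrix, list[SyntheticExpressionTruth]]:
    """Generate a two-condition FPKM matrix with planted transcript classes.

    Classes: ``constitutive`` (flat baseline in both conditions),
    ``shared_rhythmic`` (identical sinusoid in both), ``phase_shifted`` (the
    L series is the E series circularly shifted by a planted lag of 1-5 grid
    steps, drawn per transcript) and ``divergent`` (E rhythmic while L is
    either flat — "silenced" — or a second-harmonic distorted waveform that
    no circular shift aligns with the E sinusoid; the per-transcript choice
    is recorded).  Replicate noise is multiplicative lognormal with sigma
    ``noise_sd``; values are floored at 0.  Rhythmic phases are drawn
    uniformly per transcript.  Deterministic given *seed*.
    """
    tps = np.asarray(timepoints, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    T = tps.size
    rows: dict[str, np.ndarray] = {}
    truths: list[SyntheticExpressionTruth] = []
    columns = [
        (cond, zt, rep)
        for cond in ("E", "L")
        for zt in tps
        for rep in range(1, n_replicates + 1)
    ]
    counter = 0
    for cls in ("constitutive", "shared_rhythmic", "phase_shifted", "divergent"):
        for _ in range(int(n_per_class.get(cls, 0))):
            counter += 1
            tid = f"TX{counter:05d}"
            phase = rng.uniform(0.0, 2.0 * math.pi)
            lag_steps = 0
            mode = ""
            if cls == "constitutive":
                e = np.full(T, baseline)
                l = e.copy()
            elif cls == "shared_rhythmic":
                e = _rhythmic_profile(tps, baseline, amplitude, phase)
                l = e.copy()
            elif cls == "phase_shifted":
                lag_steps = int(rng.integers(1, T))
                e = _rhythmic_profile(tps, baseline, amplitude, phase)
                l = np.roll(e, lag_steps)  # L_t = E_{t - lag}
            else:  # divergent
                e = _rhythmic_profile(tps, baseline, amplitude, phase)
                if rng.random() < 0.5:
                    mode = "silenced"
                    l = np.full(T, baseline)
                else:
                    mode = "distorted"
                    # second harmonic (12 h period): orthogonal to the E
                    # sinusoid on the uniform grid under every circular shift
                    l = baseline + amplitude * np.sin(4.0 * math.pi * tps / 24.0 + phase)
            values = []
            for cond_series in (e, l):
                for t in range(T):
                    for _rep in range(n_replicates):
                        v = cond_series[t]
                        if noise_sd > 0:
                            v *= rng.lognormal(-(noise_sd**2) / 2.0, noise_sd)
                        values.append(max(v, 0.0))
            rows[tid] = np.asarray(values)
            truths.append(
                SyntheticExpressionTruth(
                    transcript_id=tid,
                    truth_class=cls,
                    baseline=baseline,
                    amplitude=amplitude,
                    noise_sd=noise_sd,
                    planted_lag_steps=lag_steps,
                    divergent_mode=mode,
                )
            )
    if not rows:
        raise ValueError("no transcripts requested")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(columns, names=["condition", "zt", "replicate"])
    df.index.name = "transcript_id"
    return ExpressionMatrix(data=df, experiment_label=experiment_label), truths


def recovery_report(
    truths: Sequence[SyntheticExpressionTruth],
    labels: Mapping[str, str],
    best_lags_hours: Mapping[str, float] | None = None,
    dt_hours: float = 4.0,
) -> dict:
    """Score screen labels (and recovered lags) against planted truth.

    Returns a confusion table of truth class vs assigned label, per-class
    sensitivity (fraction of the class receiving its expected label:
    phase_shifted and shared_rhythmic -> phase_concordant, divergent ->
    divergent, constitutive -> low_variance), divergent-class specificity,
    and — when *best_lags_hours* is given — the fraction of phase_shifted
    transcripts whose recovered lag equals the planted one exactly.
    """
    truth_ids = {t.transcript_id for t in truths}
    if truth_ids != set(labels):
        raise ValueError("transcript ids of truth and labels differ")
    expected = {
        "constitutive": "low_variance",
        "shared_rhythmic": "phase_concordant",
        "phase_shifted": "phase_concordant",
        "divergent": "divergent",
    }
    confusion: dict[str, dict[str, int]] = {}
    sens: dict[str, float] = {}
    period = None
    lag_hits = 0
    lag_total = 0
    for t in truths:
        confusion.setdefault(t.truth_class, {}).setdefault(labels[t.transcript_id], 0)
        confusion[t.truth_class][labels[t.transcript_id]] += 1
    for cls, row in confusion.items():
        total = sum(row.values())
        sens[cls] = row.get(expected[cls], 0) / total if total else math.nan
    if best_lags_hours is not None:
        for t in truths:
            if t.truth_class != "phase_shifted":
                continue
            lag_total += 1
            # generator: L_t = E_{t-k}, so E leads and the best circular lag
            # in screen convention is +k steps, canonicalized to [-12, 12)
            if period is None:
                period = dt_hours * 6
            planted_h = (t.planted_lag_steps * dt_hours) % period
            if planted_h >= period / 2:
                planted_h -= period
            if abs(best_lags_hours[t.transcript_id] - planted_h) < 1e-9:
                lag_hits += 1
    report = {
        "confusion": confusion,
        "sensitivity": sens,
        "divergent_sensitivity": sens.get("divergent", math.nan),
    }
    if best_lags_hours is not None:
        report["lag_recovery_rate"] = lag_hits / lag_total if lag_total else math.nan
    return report
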