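"""Lagged cross-correlation screening of short expression time courses.

The screen asks, per transcript, whether the expression profiles of two
conditions (early vs late chronotype) are the same curve up to a circular
phase shift.  Because samples are taken on a diel grid (six time points at
4 h intervals covering 24 h), lags are circular: the Pearson correlation
between the E series and the L series rotated by j steps is computed for
every j, and the maximum over lags is the transcript's score.  A high maximal
correlation means "same waveform, possibly phase shifted"; a low one means
the profiles diverge more fundamentally.  Constitutively expressed
transcripts (low variance) correlate spuriously, so scores are interpreted
jointly with the variance of the replicate-averaged FPKM values, and the
significance cut-off is derived from a label-permuted null ensemble.

Also provides the row normalisation (z-score to mean 0, variance 1) and
deterministic hierarchical clustering used for expression heatmaps.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import distance

from chronophase.enrichment_network import bh_fdr

__all__ = [
    "ExpressionMatrix",
    "XCorrResult",
    "FdrThreshold",
    "PermutationNull",
    "ScreenResult",
    "DegenerateSeriesError",
    "load_fpkm_table",
    "write_fpkm_table",
    "average_replicates",
    "zscore_rows",
    "hierarchical_cluster_rows",
    "lagged_xcorr",
    "max_xcorr",
    "fpkm_variance",
    "permutation_null",
    "fdr_threshold",
    "classify_transcripts",
    "run_xcorr_screen",
    "list_overlap_report",
]

_SAMPLE_COL_RE = re.compile(r"^(?P<cond>[A-Za-z]+)_ZT(?P<zt>\d+(?:\.\d+)?)_rep(?P<rep>\d+)$")


class DegenerateSeriesError(ValueError):
    """A constant series has no defined correlation."""


@dataclass
class ExpressionMatrix:
    """Transcripts x (condition, time point, replicate) FPKM values.

    ``data`` is indexed by transcript id with a 3-level column MultiIndex
    ``(condition, zt, replicate)``; FPKM values are non-negative and both
    conditions share the same time grid.
    """

    data: pd.DataFrame
    experiment_label: str = "LD"

    def __post_init__(self):
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 3:
            raise ValueError("data needs a (condition, zt, replicate) column MultiIndex")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated transcript ids: {dups}")
        if self.data.isna().any().any():
            raise ValueError("missing FPKM cells")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        grids = {
            cond: tuple(sorted({zt for c, zt, r in cols if c == cond}))
            for cond in self.conditions
        }
        if len(set(grids.values())) > 1:
            raise ValueError(f"conditions sampled on different time grids: {grids}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return sorted({c for c, _, _ in self.data.columns})

    @property
    def timepoints_zt(self) -> list[float]:
        return sorted({zt for _, zt, _ in self.data.columns})


def load_fpkm_table(
    source: TextIO | str,
    id_column: str = "transcript_id",
    experiment_label: str = "LD",
) -> ExpressionMatrix:
    """Read a per-transcript FPKM TSV into an :class:`ExpressionMatrix`.

    Sample columns are named ``<COND>_ZT<hh>_rep<k>`` (e.g. ``E_ZT02_rep1``).
    Raises on missing cells, negative FPKM, duplicated transcript ids and
    unrecognised column names.
    """
    df = pd.read_csv(source, sep="\t")
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    df = df.set_index(id_column)
    if df.shape[0] == 0:
        raise ValueError("no transcripts in table")
    tuples = []
    for col in df.columns:
        m = _SAMPLE_COL_RE.match(str(col))
        if not m:
            raise ValueError(f"unrecognised sample column {col!r}")
        tuples.append((m["cond"], float(m["zt"]), int(m["rep"])))
    df.columns = pd.MultiIndex.from_tuples(tuples, names=["condition", "zt", "replicate"])
    return ExpressionMatrix(data=df.astype(float), experiment_label=experiment_label)


def write_fpkm_table(m: ExpressionMatrix, sink: TextIO, id_column: str = "transcript_id") -> None:
    """Write the matrix back as a flat TSV with ``<COND>_ZT<hh>_rep<k>`` columns."""
    flat = m.data.copy()
    flat.columns = [f"{c}_ZT{int(zt):02d}_rep{r}" for c, zt, r in flat.columns]
    flat.index.name = id_column
    flat.to_csv(sink, sep="\t")


def average_replicates(m: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean FPKM over replicates, per (transcript, condition, zt)."""
    return m.data.T.groupby(level=["condition", "zt"]).mean().T


def zscore_rows(values: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each row to mean 0 and population variance 1.

    Returns ``(normalized, constant_mask)``; rows with zero variance are
    flagged in the mask and set to NaN (callers exclude them from clustering).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-d array with >= 2 columns")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (ddof=0)
    constant = sd[:, 0] == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[constant] = np.nan
    return z, constant


def hierarchical_cluster_rows(
    matrix: pd.DataFrame | np.ndarray,
    distance_metric: str = "correlation",
    linkage_method: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of rows; returns (linkage matrix, leaf order).

    ``distance_metric`` is ``"correlation"`` (1 - Pearson) or ``"euclidean"``;
    ``linkage_method`` is ``"average"`` or ``"complete"``.  Constant rows are
    rejected under correlation distance (their correlation is undefined) —
    filter them first, e.g. with the mask from :func:`zscore_rows`.
    The agglomeration is deterministic; equal-distance merges resolve to the
    lowest row indices per SciPy's ordering.
    """
    if distance_metric not in ("correlation", "euclidean"):
        raise ValueError(f"unsupported distance {distance_metric!r}")
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if distance_metric == "correlation" and (arr.std(axis=1) == 0.0).any():
        raise ValueError(
            "constant rows have undefined correlation distance; "
            "filter them (see zscore_rows constant mask) before clustering"
        )
    d = distance.pdist(arr, metric=distance_metric)
    Z = hierarchy.linkage(d, method=linkage_method)
    return Z, hierarchy.leaves_list(Z)


def _check_series(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series, dtype=float).ravel()
    if s.size < 3:
        raise ValueError("series must have length >= 3")
    if s.std() == 0.0:
        raise DegenerateSeriesError("constant series: correlation undefined")
    return s


def lagged_xcorr(series_e: Sequence[float], series_l: Sequence[float]) -> np.ndarray:
    """Pearson correlation of E against circular rotations of L, one per lag.

    Entry j is the correlation of pairs ``(E_t, L_{(t+j) mod T})`` over all T
    time points; for the 6-point, 4 h grid this gives lags 0, 4, ..., 20 h.
    The circular shift is justified by the 24 h period of the sampling grid.
    """
    e = _check_series(series_e)
    l = _check_series(series_l)
    if e.size != l.size:
        raise ValueError("series lengths differ")
    ze = (e - e.mean()) / e.std()
    zl = (l - l.mean()) / l.std()
    T = e.size
    r = np.array([(ze * np.roll(zl, -j)).mean() for j in range(T)])
    return np.clip(r, -1.0, 1.0)


def _signed_lag_hours(n_lags: int, dt_hours: float) -> np.ndarray:
    period = n_lags * dt_hours
    h = np.arange(n_lags) * dt_hours
    return np.where(h >= period / 2.0, h - period, h)


def _pick_best_lag(r_by_lag: np.ndarray, dt_hours: float) -> tuple[float, float]:
    lags_h = _signed_lag_hours(r_by_lag.size, dt_hours)
    r_max = float(np.max(r_by_lag))
    # ties: smallest |lag| wins, then the negative lag
    order = sorted(range(r_by_lag.size), key=lambda j: (abs(lags_h[j]), lags_h[j]))
    for j in order:
        if r_by_lag[j] >= r_max - 1e-12:
            return r_max, float(lags_h[j])
    raise AssertionError("unreachable")


def max_xcorr(
    series_e: Sequence[float], series_l: Sequence[float], dt_hours: float = 4.0
) -> tuple[float, float]:
    """Maximal lagged correlation and its lag as signed hours in [-period/2, period/2)."""
    r = lagged_xcorr(series_e, series_l)
    return _pick_best_lag(r, dt_hours)


def fpkm_variance(avg_e: Sequence[float], avg_l: Sequence[float], log2_transform: bool = False) -> float:
    """Population variance of the replicate-averaged FPKM values, pooled
    across both conditions (12 values on the standard design)."""
    vals = np.concatenate([np.asarray(avg_e, float).ravel(), np.asarray(avg_l, float).ravel()])
    if log2_transform:
        vals = np.log2(vals + 1.0)
    return float(vals.var())


@dataclass(frozen=True)
class XCorrResult:
    transcript_id: str
    r_by_lag: np.ndarray
    r_max: float
    best_lag_hours: float
    fpkm_variance: float
    significant: bool = False
    note: str = "ok"


@dataclass(frozen=True)
class PermutationNull:
    """Pooled null maximal-correlation scores with provenance."""

    scores: np.ndarray
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class FdrThreshold:
    alpha: float
    threshold_score: float
    n_observed: int
    n_null: int
    n_permutations: int
    seed: int
    method: str = "null_quantile"


def _averaged_condition_arrays(
    m: ExpressionMatrix,
) -> tuple[list[str], np.ndarray, np.ndarray, float]:
    conds = m.conditions
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    avg = average_replicates(m)
    tps = m.timepoints_zt
    if len(tps) < 3:
        raise ValueError("need >= 3 time points")
    steps = np.diff(tps)
    if not np.allclose(steps, steps[0]):
        raise ValueError("time points must be evenly spaced")
    e = avg[conds[0]].loc[:, tps].to_numpy(float)
    l = avg[conds[1]].loc[:, tps].to_numpy(float)
    return list(avg.index), e, l, float(steps[0])


def _zscore_or_nan(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = a.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - a.mean(axis=1, keepdims=True)) / sd
    return z, ok


def _rmax_rows(ze: np.ndarray, zl: np.ndarray) -> np.ndarray:
    T = ze.shape[1]
    r = np.empty((ze.shape[0], T))
    for j in range(T):
        r[:, j] = (ze * np.roll(zl, -j, axis=1)).mean(axis=1)
    return np.clip(r, -1.0, 1.0)


def permutation_null(
    m: ExpressionMatrix, n_perm: int, seed: int
) -> PermutationNull:
    """Null maximal-correlation scores from time-label permutation.

    For each transcript and each of *n_perm* rounds, the replicate-averaged L
    series has its time labels permuted (uniformly over all orderings, a
    fresh draw per transcript per round, identity included) and the maximal
    lagged correlation against the unpermuted E series is recorded.  Constant
    (degenerate) series contribute no scores.  Deterministic given *seed*.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _, e, l, _ = _averaged_condition_arrays(m)
    ze, ok_e = _zscore_or_nan(e)
    zl, ok_l = _zscore_or_nan(l)
    ok = ok_e & ok_l
    ze, zl = ze[ok], zl[ok]
    n, T = ze.shape
    rng = np.random.default_rng(seed)
    rows = np.arange(n)[:, None]
    scores = []
    for _ in range(n_perm):
        idx = np.argsort(rng.random((n, T)), axis=1)
        scores.append(_rmax_rows(ze, zl[rows, idx]).max(axis=1))
    pooled = np.concatenate(scores) if scores else np.empty(0)
    return PermutationNull(scores=pooled, n_permutations=n_perm, seed=seed)


def fdr_threshold(
    observed: Sequence[float],
    null: PermutationNull | Sequence[float],
    alpha: float = 0.05,
    method: str = "null_quantile",
) -> FdrThreshold:
    """Score cut-off at the requested empirical false-discovery level.

    Candidate cut-offs are the observed scores; the threshold is the smallest
    observed score ``c`` accepted by the chosen estimator, or ``+inf`` when
    none qualifies (nothing significant).

    Methods
    -------
    ``"null_quantile"`` (default)
        Accept ``c`` when the fraction of null scores >= c is at most alpha,
        i.e. the cut-off where a permuted dataset yields a rate alpha of
        calls.  This is the single-permuted-dataset convention for drawing an
        "alpha FDR" line on a score axis and is calibrated: when observed and
        null scores share a distribution, ~alpha of observations pass.
    ``"plugin"``
        Accept ``c`` when the plug-in false-discovery proportion
        ``[(#null >= c)/n_null] * n_observed / (#observed >= c)`` is at most
        alpha.  Conservative: under a complete null it admits essentially
        nothing.
    ``"bh"``
        Benjamini-Hochberg on permutation p-values
        ``p_i = (1 + #null >= score_i) / (1 + n_null)``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(null, PermutationNull):
        null_scores = np.asarray(null.scores, float)
        n_perm, seed = null.n_permutations, null.seed
    else:
        null_scores = np.asarray(null, float).ravel()
        n_perm, seed = 0, 0
    obs = np.asarray(observed, float).ravel()
    if obs.size == 0 or null_scores.size == 0:
        raise ValueError("observed and null score sets must be non-empty")
    null_sorted = np.sort(null_scores)
    n_null = null_scores.size

    def n_null_ge(c: float) -> int:
        return n_null - int(np.searchsorted(null_sorted, c, side="left"))

    threshold = math.inf
    if method == "null_quantile":
        for c in np.sort(obs):
            if n_null_ge(c) / n_null <= alpha:
                threshold = float(c)
                break
    elif method == "plugin":
        obs_sorted = np.sort(obs)
        for i, c in enumerate(obs_sorted):
            n_obs_ge = obs.size - i
            est = (n_null_ge(c) / n_null) * obs.size / n_obs_ge
            if est <= alpha:
                threshold = float(c)
                break
    elif method == "bh":
        pvals = np.array([(1 + n_null_ge(c)) / (1 + n_null) for c in obs])
        q = bh_fdr(pvals)
        passing = obs[q <= alpha]
        threshold = float(passing.min()) if passing.size else math.inf
    else:
        raise ValueError(f"unknown method {method!r}")
    return FdrThreshold(
        alpha=alpha,
        threshold_score=threshold,
        n_observed=obs.size,
        n_null=n_null,
        n_permutations=n_perm,
        seed=seed,
        method=method,
    )


def classify_transcripts(
    results: Iterable[XCorrResult],
    threshold: FdrThreshold,
    variance_floor: float = 0.0,
) -> dict[str, str]:
    """Label each transcript phase_concordant / divergent / low_variance.

    Low-variance transcripts are set aside first (their correlations are
    spurious); among the rest, a maximal correlation at or above the
    threshold means the profiles match up to the reported phase shift, and
    anything below diverges in shape, not just phase.  Degenerate transcripts
    are reported as low_variance.
    """
    labels: dict[str, str] = {}
    for res in results:
        if res.note == "degenerate" or res.fpkm_variance < variance_floor:
            labels[res.transcript_id] = "low_variance"
        elif res.r_max >= threshold.threshold_score:
            labels[res.transcript_id] = "phase_concordant"
        else:
            labels[res.transcript_id] = "divergent"
    return labels


@dataclass
class ScreenResult:
    """Full output of the cross-correlation screen."""

    results: list[XCorrResult]
    threshold: FdrThreshold
    labels: dict[str, str]
    variance_floor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in self.results],
                "r_max": [r.r_max for r in self.results],
                "best_lag_hours": [r.best_lag_hours for r in self.results],
                "fpkm_variance": [r.fpkm_variance for r in self.results],
                "note": [r.note for r in self.results],
                "label": [self.labels[r.transcript_id] for r in self.results],
            }
        ).set_index("transcript_id")


def run_xcorr_screen(
    m: ExpressionMatrix,
    n_perm: int = 50,
    alpha: float = 0.05,
    variance_floor: float = 0.0,
    seed: int = 0,
    fdr_method: str = "null_quantile",
    log2_variance: bool = False,
) -> ScreenResult:
    """Per-transcript maximal lagged correlation, permutation threshold, labels."""
    ids, e, l, dt_hours = _averaged_condition_arrays(m)
    ze, ok_e = _zscore_or_nan(e)
    zl, ok_l = _zscore_or_nan(l)
    ok = ok_e & ok_l
    r_all = np.where(ok[:, None], _rmax_rows(np.nan_to_num(ze), np.nan_to_num(zl)), np.nan)
    results: list[XCorrResult] = []
    for i, tid in enumerate(ids):
        var = fpkm_variance(e[i], l[i], log2_transform=log2_variance)
        if not ok[i]:
            results.append(
                XCorrResult(tid, np.full(e.shape[1], np.nan), math.nan, math.nan, var, False, "degenerate")
            )
            continue
        r_max, best_lag = _pick_best_lag(r_all[i], dt_hours)
        note = "ok" if var >= variance_floor else "low_variance"
        results.append(XCorrResult(tid, r_all[i], r_max, best_lag, var, False, note))
    null = permutation_null(m, n_perm=n_perm, seed=seed)
    observed = [r.r_max for r in results if r.note != "degenerate"]
    thr = fdr_threshold(observed, null, alpha=alpha, method=fdr_method)
    labels = classify_transcripts(results, thr, variance_floor=variance_floor)
    results = [
        XCorrResult(
            r.transcript_id,
            r.r_by_lag,
            r.r_max,
            r.best_lag_hours,
            r.fpkm_variance,
            labels[r.transcript_id] == "phase_concordant",
            r.note,
        )
        for r in results
    ]
    return ScreenResult(results=results, threshold=thr, labels=labels, variance_floor=variance_floor)


def list_overlap_report(list_a: Iterable[str], list_b: Iterable[str]) -> dict[str, int]:
    """Set overlap between two gene lists, with the percentage of the smaller
    list present in both (rounded half-up to an integer)."""
    a, b = set(list_a), set(list_b)
    inter = len(a & b)
    smaller = min(len(a), len(b))
    pct = int(math.floor(100.0 * inter / smaller + 0.5)) if smaller else 0
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": inter,
        "pct_of_smaller": pct,
    }
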