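import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TIMEPOINTS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)


def make_monitor_lines(count_rows, date="1 Jan 15", times=None, n_channels=32):
    """Build DAM2-style monitor lines: index, date, time, 7 status columns,
    then one count column per channel."""
    times = times or [f"{8 + i // 60:02d}:{i % 60:02d}:00" for i in range(len(count_rows))]
    lines = []
    for i, counts in enumerate(count_rows):
        full = list(counts) + [0] * (n_channels - len(counts))
        fields = [str(i + 1), date, times[i]] + ["0"] * 7 + [str(c) for c in full]
        lines.append("\t".join(fields))
    return lines


def make_expression_matrix(values_by_transcript, timepoints=TIMEPOINTS, label="LD"):
    """ExpressionMatrix from {tid: (e_series, l_series)} with two identical
    replicates per cell (or {tid: flat 24-vector} for explicit replicates)."""
    from chronophase.timeseries_xcorr import ExpressionMatrix

    cols = pd.MultiIndex.from_tuples(
        [(c, zt, r) for c in ("E", "L") for zt in timepoints for r in (1, 2)],
        names=["condition", "zt", "replicate"],
    )
    rows = {}
    for tid, val in values_by_transcript.items():
        if isinstance(val, tuple):
            e, l = (np.asarray(v, float) for v in val)
            flat = np.concatenate([np.repeat(e, 2), np.repeat(l, 2)])
        else:
            flat = np.asarray(val, float)
        rows[tid] = flat
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = cols
    df.index.name = "transcript_id"
    return ExpressionMatrix(data=df, experiment_label=label)


@pytest.fixture
def monitor_lines():
    return make_monitor_lines


@pytest.fixture
def expression_matrix_factory():
    return make_expression_matrix
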