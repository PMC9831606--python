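"""Sensory-neuron excitability and current-density summary statistics.

Voltage-clamp side: current traces (pA, uniform sampling, typically
50 kHz) around a depolarizing voltage step are zero-subtracted against
the 0.14 s of holding current before the step; the drug-sensitive
component is the samplewise difference of pre- and post-drug traces; the
early window mean (0.4-1 ms after the step) and the windowed peak
(0.4-8 ms) are reported as current densities (pA/pF).  Inward currents
are negative and "peak" means the extremum of the signed trace (most
negative by default).

Current-clamp side: per-cell tables of rheobase (minimal step current
evoking one action potential) and action-potential counts per stimulus
train at several frequencies, before and during drug.  Derived metrics
are the rheobase change (%) and the remaining APs (%): drug AP count as
a percentage of the baseline count at the same frequency.  Percentages
are rounded half-away-from-zero to one decimal, and group means / SEMs
average those one-decimal per-cell values (the convention of the source
tables this module mirrors).

Window convention: half-open [t0, t1), aligned to sample times at or
after t0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CurrentTrace",
    "zero_subtract",
    "window_mean_density",
    "peak_density_and_time",
    "subtract_traces",
    "round_half_away",
    "remaining_ap_percent",
    "rheobase_change_percent",
    "load_cell_table",
    "cell_metrics",
    "summarize_cells",
    "two_group_ttest",
    "AP_FREQUENCIES_HZ",
]

#: Stimulation frequencies of the standard AP-train protocol.
AP_FREQUENCIES_HZ = (0.1, 1.0, 3.0, 10.0)


@dataclass
class CurrentTrace:
    """A current recording at uniform sampling around a voltage step."""

    samples: np.ndarray  # pA
    sample_rate: float  # Hz
    step_onset: float  # s from record start
    capacitance: float | None = None  # pF, needed for densities

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 <= self.step_onset <= len(self.samples) / self.sample_rate:
            raise ValueError("step_onset outside the record")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def to_csv(self, path: str | Path) -> None:
        """Write time_s,current_pA plus a YAML metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "current_pA": self.samples}).to_csv(
            path, index=False
        )
        meta = {
            "sample_rate": float(self.sample_rate),
            "step_onset": float(self.step_onset),
            "capacitance": None if self.capacitance is None else float(self.capacitance),
        }
        path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurrentTrace":
        path = Path(path)
        df = pd.read_csv(path)
        meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
        return cls(
            samples=df["current_pA"].to_numpy(),
            sample_rate=meta["sample_rate"],
            step_onset=meta["step_onset"],
            capacitance=meta.get("capacitance"),
        )


def zero_subtract(trace: CurrentTrace, baseline_window: float = 0.14) -> CurrentTrace:
    """Subtract the mean holding current of the pre-step baseline window."""
    if baseline_window <= 0:
        raise ValueError("baseline_window must be positive")
    start = trace.step_onset - baseline_window
    if start < -0.5 / trace.sample_rate:
        raise ValueError(
            f"baseline window {baseline_window} s does not fit before the step at "
            f"{trace.step_onset} s"
        )
    t = trace.times
    mask = (t >= max(start, 0.0)) & (t < trace.step_onset)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return replace(trace, samples=trace.samples - trace.samples[mask].mean())


def _window_mask(trace: CurrentTrace, t0: float, t1: float) -> np.ndarray:
    rel = trace.times - trace.step_onset
    mask = (rel >= t0 - 1e-12) & (rel < t1 - 1e-12)
    if not mask.any():
        raise ValueError(f"window [{t0}, {t1}) s after the step contains no samples")
    return mask


def window_mean_density(
    trace: CurrentTrace, t0: float = 0.4e-3, t1: float = 1.0e-3
) -> float:
    """Mean current in [t0, t1) after the step, per capacitance (pA/pF)."""
    if trace.capacitance is None:
        raise ValueError("capacitance required for current density")
    mask = _window_mask(trace, t0, t1)
    return float(trace.samples[mask].mean() / trace.capacitance)


def peak_density_and_time(
    trace: CurrentTrace,
    t0: float = 0.4e-3,
    t1: float = 8.0e-3,
    polarity: str = "inward",
) -> tuple[float, float]:
    """Windowed peak current density (pA/pF) and its time after the step (ms).

    ``polarity="inward"`` takes the most negative sample (inward current
    convention); ``"outward"`` the most positive.
    """
    if trace.capacitance is None:
        raise ValueError("capacitance required for current density")
    mask = _window_mask(trace, t0, t1)
    idx = np.flatnonzero(mask)
    window = trace.samples[idx]
    if polarity == "inward":
        k = int(np.argmin(window))
    elif polarity == "outward":
        k = int(np.argmax(window))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    peak_time_ms = (trace.times[idx[k]] - trace.step_onset) * 1e3
    return float(window[k] / trace.capacitance), float(peak_time_ms)


def subtract_traces(pre_drug: CurrentTrace, post_drug: CurrentTrace) -> CurrentTrace:
    """Drug-sensitive component: pre minus post, samplewise and exact.

    Conservation holds by construction: sensitive + post == pre.
    """
    if len(pre_drug.samples) != len(post_drug.samples):
        raise ValueError("traces differ in length")
    if pre_drug.sample_rate != post_drug.sample_rate:
        raise ValueError("traces differ in sample rate")
    if pre_drug.step_onset != post_drug.step_onset:
        raise ValueError("traces differ in step onset")
    return replace(pre_drug, samples=pre_drug.samples - post_drug.samples)


# ---------------------------------------------------------------------------
# Per-cell AP/rheobase metrics


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def remaining_ap_percent(ap_drug: int, ap_baseline: int) -> float:
    """100 x ap_drug / ap_baseline to one decimal; NaN if baseline is zero.

    A zero baseline makes the percentage undefined; NaN is returned so
    the cell drops out of that frequency's average.
    """
    if ap_drug < 0 or ap_baseline < 0:
        raise ValueError("AP counts must be non-negative")
    if ap_baseline == 0:
        return float("nan")
    return round_half_away(100.0 * ap_drug / ap_baseline)


def rheobase_change_percent(r_drug: float, r_baseline: float) -> float:
    """100 x (r_drug - r_baseline) / r_baseline, to one decimal."""
    if r_baseline <= 0:
        raise ValueError("baseline rheobase must be positive")
    return round_half_away(100.0 * (r_drug - r_baseline) / r_baseline)


def _freq_columns(df: pd.DataFrame) -> dict[float, str]:
    cols = {}
    for col in df.columns:
        if col.startswith("aps_") and col.endswith("Hz"):
            cols[float(col[4:-2])] = col
    return cols


def load_cell_table(source: str | Path) -> pd.DataFrame:
    """Load a per-cell table: cell_id, dose, rheobase_pA, aps_<freq>Hz...

    ``dose`` is kept as a string; the row with dose ``"baseline"`` defines
    the denominators of the percentage metrics.  An optional boolean
    ``include`` column (e.g. for excluding TTX-insensitive cells) is
    honoured by dropping excluded cells.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        df = pd.read_csv(source, dtype={"dose": str})
    else:
        df = pd.read_csv(StringIO(str(source)), dtype={"dose": str})
    required = {"cell_id", "dose", "rheobase_pA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table lacks columns {sorted(missing)}")
    if not _freq_columns(df):
        raise ValueError("cell table has no aps_<freq>Hz columns")
    if "include" in df.columns:
        excluded_cells = df.loc[~df["include"].astype(bool), "cell_id"].unique()
        df = df[~df["cell_id"].isin(excluded_cells)].drop(columns="include")
    for cell, grp in df.groupby("cell_id"):
        if "baseline" not in set(grp["dose"]):
            raise ValueError(f"cell {cell!r} has no baseline row")
        if (grp["rheobase_pA"] <= 0).any():
            raise ValueError(f"cell {cell!r} has non-positive rheobase")
    return df.reset_index(drop=True)


def cell_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Derive per-cell percentage metrics from the raw counts.

    Returns a long table with columns cell_id, dose, metric
    (``rheobase_change`` or ``remaining_ap``), frequency_Hz (NaN for
    rheobase) and value (one-decimal percent; NaN where undefined).
    """
    freq_cols = _freq_columns(table)
    rows = []
    for cell, grp in table.groupby("cell_id", sort=False):
        base = grp[grp["dose"] == "baseline"].iloc[0]
        for _, row in grp.iterrows():
            rows.append(
                (
                    cell,
                    row["dose"],
                    "rheobase_change",
                    float("nan"),
                    rheobase_change_percent(row["rheobase_pA"], base["rheobase_pA"]),
                )
            )
            for freq, col in sorted(freq_cols.items()):
                rows.append(
                    (
                        cell,
                        row["dose"],
                        "remaining_ap",
                        freq,
                        remaining_ap_percent(int(row[col]), int(base[col])),
                    )
                )
    return pd.DataFrame(
        rows, columns=["cell_id", "dose", "metric", "frequency_Hz", "value"]
    )


def summarize_cells(
    table: pd.DataFrame, metric: str = "remaining_ap"
) -> pd.DataFrame:
    """Group mean and SEM of a per-cell percentage metric.

    Groups are dose (x frequency for AP metrics).  The SEM uses the
    sample standard deviation (n-1) over sqrt(n); both are reported to
    one decimal, computed from the one-decimal per-cell values.  Cells
    with an undefined value (NaN) drop out of their group; a group of
    one reports its mean with SEM NaN (flagged undefined).
    """
    metrics = cell_metrics(table)
    sub = metrics[metrics["metric"] == metric]
    if sub.empty:
        raise ValueError(f"unknown metric {metric!r}")
    keys = ["dose"] if metric == "rheobase_change" else ["dose", "frequency_Hz"]
    rows = []
    for key, grp in sub.groupby(keys, sort=False, dropna=False):
        values = grp["value"].dropna().to_numpy()
        if len(values) == 0:
            continue
        mean = round_half_away(values.mean())
        sem = (
            round_half_away(values.std(ddof=1) / math.sqrt(len(values)))
            if len(values) > 1
            else float("nan")
        )
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, mean, sem, len(values)))
    return pd.DataFrame(rows, columns=[*keys, "mean", "sem", "n"])


def two_group_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired two-sided Student's t-test: (statistic, df, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)
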