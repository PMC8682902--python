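"""Reference-interval aggregation for per-subject measurements.

Summaries are the small-cohort descriptives actually reportable at n = 6:
mean, SD (n-1 denominator), median and range — not parametric 95%
intervals.  Weight-gain bookkeeping and flagging against published
intervals live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Flag = Literal["below", "within", "above"]


@dataclass
class ReferenceInterval:
    """Descriptive summary of one analyte / measurement."""

    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    source: str = "internal"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError("need min <= median <= max")
        if np.isfinite(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def sd_defined(self) -> bool:
        return bool(np.isfinite(self.sd))


@dataclass
class WeightRecord:
    """Weekly body weights (g) for one subject."""

    subject_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise ValueError("weights must be a non-empty 1D array")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")


@dataclass
class AnalytePanel:
    """Long-format analyte table with per-entry exclusion flags.

    ``data`` columns: subject, week, analyte, value (+ optional units).
    Censored entries (value NaN, e.g. below detection limit) and flagged
    entries are excluded from all summaries.
    """

    data: pd.DataFrame
    exclusion_log: list[dict] = field(default_factory=list)

    REQUIRED = ("subject", "week", "analyte", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing required columns: {missing}")
        if "excluded" not in self.data.columns:
            self.data = self.data.assign(excluded=False)

    def included(self) -> pd.DataFrame:
        d = self.data
        return d[~d["excluded"] & d["value"].notna()]


def summarize(values: Iterable[float], source: str = "internal") -> ReferenceInterval:
    """Mean, SD (n-1), median and range of a sample.

    SD is NaN (flagged undefined) for a single value.  Raises on an empty
    sample — degenerate inputs are reported as no-data, never as zeros.
    """
    arr = np.asarray([v for v in values if np.isfinite(v)], float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return ReferenceInterval(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        minimum=float(np.min(arr)),
        maximum=float(np.max(arr)),
        source=source,
    )


def weight_gain_per_measure(record: WeightRecord) -> np.ndarray:
    """Percent change per interval: 100 * (w_i - w_{i-1}) / w_{i-1}."""
    w = record.weights
    if w.size < 2:
        raise ValueError("need >= 2 weights for gain computation")
    return 100.0 * np.diff(w) / w[:-1]


def final_weight_gain(record: WeightRecord | Sequence[float]) -> float:
    """Percent gain between the first and last weight.

    Accepts a single subject's record or a sequence of (group-mean)
    weights, applying the same first-to-last formula.
    """
    w = record.weights if isinstance(record, WeightRecord) else np.asarray(record, float)
    if w.size < 2:
        raise ValueError("need first and last weights")
    return float(100.0 * (w[-1] - w[0]) / w[0])


def flag_against_interval(
    value: float, interval: ReferenceInterval | tuple[float, float]
) -> Flag:
    """Classify a value against interval bounds; boundary values are within."""
    if isinstance(interval, ReferenceInterval):
        lower, upper = interval.minimum, interval.maximum
    else:
        lower, upper = interval
    if not lower <= upper:
        raise ValueError(f"bounds out of order: ({lower}, {upper})")
    if value < lower:
        return "below"
    if value > upper:
        return "above"
    return "within"


def apply_exclusions(panel: AnalytePanel, rules: Sequence[dict]) -> AnalytePanel:
    """Flag entries named by exclusion rules; returns a new panel + log.

    Each rule: ``{"analyte": str, "weeks": [int, ...], "reason": str}``.
    """
    data = panel.data.copy()
    log = list(panel.exclusion_log)
    for rule in rules:
        for key in ("analyte", "weeks", "reason"):
            if key not in rule:
                raise ValueError(f"exclusion rule missing {key!r}: {rule}")
        hit = data["analyte"].eq(rule["analyte"]) & data["week"].isin(rule["weeks"])
        data.loc[hit, "excluded"] = True
        log.append(
            {
                "analyte": rule["analyte"],
                "weeks": list(rule["weeks"]),
                "reason": rule["reason"],
                "n_excluded": int(hit.sum()),
            }
        )
    return AnalytePanel(data=data, exclusion_log=log)


def summarize_panel(panel: AnalytePanel) -> pd.DataFrame:
    """Per-analyte, per-week summaries over included entries.

    Analyte/week cells with no usable data appear with n = 0 and NaN
    statistics rather than being dropped silently.
    """
    rows = []
    for (analyte, week), grp in panel.data.groupby(["analyte", "week"], sort=True):
        usable = grp[~grp["excluded"] & grp["value"].notna()]["value"]
        if usable.empty:
            rows.append(
                {"analyte": analyte, "week": week, "n": 0, "mean": np.nan,
                 "sd": np.nan, "median": np.nan, "min": np.nan, "max": np.nan}
            )
            continue
        ri = summarize(usable)
        rows.append(
            {"analyte": analyte, "week": week, "n": ri.n, "mean": ri.mean,
             "sd": ri.sd, "median": ri.median, "min": ri.minimum, "max": ri.maximum}
        )
    return pd.DataFrame(rows)
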