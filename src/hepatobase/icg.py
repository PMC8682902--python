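"""Indocyanine-green (ICG) plasma-clearance kinetics.

Clearance percentages relative to a reference sample, the two-point
per-minute retention/decay pair (d, R), and the semilog elimination
constant ICG-K fitted over the exponential phase.

Conventions: logarithms are base 10 throughout (R is invariant to the base
used in the two-point formula, since the exponent and logarithm cancel);
the exponential-phase window defaults to [1, 5] minutes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default exponential-phase fitting window (minutes post-injection).
DEFAULT_WINDOW: tuple[float, float] = (1.0, 5.0)


@dataclass
class ConcentrationSeries:
    """Timestamped plasma ICG concentrations for one subject.

    ``concentrations`` are replicate means in μg/mL; ``replicate_sd`` is
    the optional per-timepoint replicate SD.
    """

    subject_id: str
    times: np.ndarray
    concentrations: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.concentrations = np.asarray(self.concentrations, float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be matching 1D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, float)
            if self.replicate_sd.shape != self.times.shape:
                raise ValueError("replicate_sd must match times")


@dataclass
class ClearanceResult:
    """Derived clearance summaries for one subject.

    ``icg_k`` is the negated slope of log10 concentration vs time (per
    minute); ``d`` the per-minute retention fraction 10**(-icg_k); ``r`` the
    per-minute decay rate 1 - d; ``clearance_pct`` percent cleared at each
    series time relative to the first retained timepoint.
    """

    subject_id: str
    icg_k: float
    d: float
    r: float
    window: tuple[float, float]
    clearance_pct: np.ndarray = field(default_factory=lambda: np.array([]))


def clearance_percent(series: ConcentrationSeries, ref_time: float) -> np.ndarray:
    """Percent ICG cleared at each time: 100 * (1 - C(t)/C(ref_time)).

    The entry at the reference time is exactly 0.
    """
    idx = np.flatnonzero(np.isclose(series.times, ref_time))
    if idx.size == 0:
        raise ValueError(f"reference time {ref_time} not in series times")
    c_ref = series.concentrations[idx[0]]
    if not c_ref > 0:
        raise ValueError(f"reference concentration must be > 0, got {c_ref}")
    pct = 100.0 * (1.0 - series.concentrations / c_ref)
    pct[idx[0]] = 0.0
    return pct


def decay_rate(c1: float, t1: float, c2: float, t2: float) -> tuple[float, float]:
    """Two-point retention/decay pair from the semilog decline.

    log10 d = (log10 C2 - log10 C1) / (t2 - t1);  R = 1 - d.
    Both are per-minute fractions.
    """
    if not (c1 > 0 and c2 > 0):
        raise ValueError("concentrations must be > 0")
    if not t2 > t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    d = 10.0 ** ((np.log10(c2) - np.log10(c1)) / (t2 - t1))
    return float(d), float(1.0 - d)


def fit_icg_k(
    series: ConcentrationSeries,
    window: tuple[float, float] = DEFAULT_WINDOW,
    detection_limit: float = 0.0,
) -> ClearanceResult:
    """Least-squares semilog fit over the exponential-phase window.

    Fits a line to (t, log10 C) for points inside ``window`` (inclusive);
    ``icg_k`` is the negated slope.  Points with concentration <= max(0,
    detection_limit) are dropped with a warning before the log transform.
    With exactly two usable points the result coincides with
    :func:`decay_rate`.
    """
    t_lo, t_hi = window
    if not t_hi > t_lo:
        raise ValueError(f"invalid window {window}")
    in_win = (series.times >= t_lo) & (series.times <= t_hi)
    usable = series.concentrations > max(0.0, detection_limit)
    if np.any(in_win & ~usable):
        n_bad = int(np.sum(in_win & ~usable))
        warnings.warn(
            f"{series.subject_id}: dropped {n_bad} point(s) at/below the "
            f"detection limit before the log transform",
            stacklevel=2,
        )
    keep = in_win & usable
    if keep.sum() < 2:
        raise ValueError(
            f"{series.subject_id}: need >=2 positive points in window "
            f"[{t_lo}, {t_hi}], have {int(keep.sum())}"
        )
    t = series.times[keep]
    logc = np.log10(series.concentrations[keep])
    slope, _ = np.polyfit(t, logc, 1)
    icg_k = float(-slope)
    d = float(10.0 ** slope)
    ref_time = series.times[np.flatnonzero(usable)[0]]
    return ClearanceResult(
        subject_id=series.subject_id,
        icg_k=icg_k,
        d=d,
        r=1.0 - d,
        window=(float(t_lo), float(t_hi)),
        clearance_pct=clearance_percent(series, ref_time),
    )


def group_decay_rate(
    series_list: Sequence[ConcentrationSeries],
    t1: float,
    t2: float,
    mode: Literal["averaged-concentrations", "per-subject"] = "averaged-concentrations",
) -> tuple[float, float]:
    """Group-level (d, R) under either averaging convention.

    ``averaged-concentrations`` applies the two-point formula to the group
    mean concentrations at t1 and t2; ``per-subject`` averages the
    per-subject (d, R) pairs.  Both are provided because either reading of
    "calculated from average concentration values" is defensible.
    """

    def _conc_at(s: ConcentrationSeries, t: float) -> float:
        idx = np.flatnonzero(np.isclose(s.times, t))
        if idx.size == 0:
            raise ValueError(f"{s.subject_id}: no sample at t={t}")
        return float(s.concentrations[idx[0]])

    c1s = np.array([_conc_at(s, t1) for s in series_list])
    c2s = np.array([_conc_at(s, t2) for s in series_list])
    if mode == "averaged-concentrations":
        return decay_rate(float(c1s.mean()), t1, float(c2s.mean()), t2)
    if mode == "per-subject":
        pairs = [decay_rate(a, t1, b, t2) for a, b in zip(c1s, c2s)]
        d = float(np.mean([p[0] for p in pairs]))
        return d, 1.0 - d
    raise ValueError(f"unknown mode {mode!r}")
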