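"""Doppler waveform features and derived hemodynamic indices.

Per-cycle extraction follows the acquisition conventions used for rat
vessels: systolic peaks found by prominence-based picking, cycles
delimited peak-to-peak, PSV the maximum within a cycle, EDV the minimum
between consecutive systolic peaks, VTI the trapezoidal integral of
velocity over the cycle and TAV = VTI / cycle duration.

Units: velocities mm/s, VTI mm, areas mm^2, diameters/radii mm, rates
bpm; CO and RBF in mL/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

#: Plausible rat heart-rate band (bpm) used for peak-distance gating.
DEFAULT_HR_BAND: tuple[float, float] = (150.0, 500.0)


@dataclass
class VelocityTrace:
    """Uniformly sampled velocity waveform for one vessel."""

    samples: np.ndarray
    fs: float
    vessel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class CycleFeatures:
    """Waveform features over one cardiac cycle."""

    psv: float
    edv: float
    vti: float
    tav: float
    cycle_bounds: tuple[int, int]


@dataclass
class VesselMeasurement:
    """Repeated caliper measurement of a vessel (diameter in mm)."""

    diameter: float
    n_measurements: int = 1

    def __post_init__(self) -> None:
        if not self.diameter >= 0:
            raise ValueError("diameter must be >= 0")
        if self.n_measurements < 1:
            raise ValueError("need at least one measurement")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def area(self) -> float:
        """Cross-sectional area mm^2, circular lumen assumption."""
        return math.pi * self.radius**2


@dataclass
class HemodynamicIndices:
    """Derived scalar indices for one subject."""

    ri: float | None = None
    pci: float | None = None
    ap_ratio: float | None = None
    sv: float | None = None
    hr: float | None = None
    co: float | None = None
    rbf: float | None = None


def detect_cycles(
    trace: VelocityTrace,
    min_cycles: int = 5,
    hr_band: tuple[float, float] = DEFAULT_HR_BAND,
    prominence_frac: float = 0.25,
    smooth_s: float = 0.005,
) -> list[tuple[int, int]]:
    """Locate systolic peaks and return peak-to-peak cycle bounds.

    The trace is lightly smoothed (``smooth_s`` moving average) for peak
    picking only; feature extraction stays on the raw samples.  Peaks must
    be separated by at least one period at the upper end of ``hr_band`` and
    have prominence >= ``prominence_frac`` of the smoothed amplitude.
    Raises if fewer than ``min_cycles`` full cycles are found.
    """
    v = trace.samples
    w = max(1, int(round(trace.fs * smooth_s)))
    if w > 1:
        # edge-replicating moving average: no boundary dips on flat traces
        v = uniform_filter1d(v, size=w, mode="nearest")
    amplitude = float(v.max() - v.min())
    if amplitude <= 0:
        raise ValueError("trace has no amplitude: no systolic peaks detectable")
    min_distance = max(1, int(round(trace.fs * 60.0 / hr_band[1])))
    peaks, _ = find_peaks(v, distance=min_distance, prominence=prominence_frac * amplitude)
    cycles = list(zip(peaks[:-1], peaks[1:]))
    if len(cycles) < min_cycles:
        raise ValueError(
            f"detected {len(peaks)} peak(s) -> {len(cycles)} cycle(s); "
            f"need >= {min_cycles} (trace {trace.duration:.2f} s at fs={trace.fs} Hz)"
        )
    return [(int(a), int(b)) for a, b in cycles]


def cycle_features(
    trace: VelocityTrace, cycles: Sequence[tuple[int, int]]
) -> tuple[list[CycleFeatures], CycleFeatures]:
    """Per-cycle features plus their average.

    PSV = max within the cycle; EDV = min strictly between the delimiting
    systolic peaks; VTI = trapezoidal integral over the cycle; TAV =
    VTI / cycle duration.  The returned average carries the full span as
    its bounds.
    """
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    dt = 1.0 / trace.fs
    feats: list[CycleFeatures] = []
    for start, end in cycles:
        if not (0 <= start < end < trace.samples.size):
            raise ValueError(f"cycle bounds ({start}, {end}) outside trace")
        seg = trace.samples[start : end + 1]
        vti = float(np.trapezoid(seg, dx=dt))
        duration = (end - start) * dt
        interior = trace.samples[start + 1 : end]
        edv = float(interior.min()) if interior.size else float(seg.min())
        feats.append(
            CycleFeatures(
                psv=float(seg.max()),
                edv=edv,
                vti=vti,
                tav=vti / duration,
                cycle_bounds=(start, end),
            )
        )
    avg = CycleFeatures(
        psv=float(np.mean([f.psv for f in feats])),
        edv=float(np.mean([f.edv for f in feats])),
        vti=float(np.mean([f.vti for f in feats])),
        tav=float(np.mean([f.tav for f in feats])),
        cycle_bounds=(cycles[0][0], cycles[-1][1]),
    )
    return feats, avg


def resistance_index(psv: float, edv: float) -> float:
    """Resistive index (PSV - EDV) / PSV."""
    if not psv > 0:
        raise ValueError(f"PSV must be > 0, got {psv}")
    return (psv - edv) / psv


def portal_congestion_index(portal_area: float, portal_psv: float) -> float:
    """Portal congestion index: portal mean area / portal mean PSV."""
    if not portal_psv > 0:
        raise ValueError(f"portal PSV must be > 0, got {portal_psv}")
    return portal_area / portal_psv


def ap_ratio(ha_value: float, portal_value: float) -> float:
    """Hepatic-artery / portal velocity ratio (same summary in both slots)."""
    if not portal_value > 0:
        raise ValueError(f"portal velocity must be > 0, got {portal_value}")
    return ha_value / portal_value


def renal_blood_flow(hr: float, vti: float, radius: float) -> float:
    """Renal blood flow HR * VTI * pi r^2, returned in mL/min.

    With HR in bpm, VTI in mm per beat and radius in mm the product is
    mm^3/min; divide by 1000 for mL/min.
    """
    if hr < 0 or vti < 0 or radius < 0:
        raise ValueError("hr, vti and radius must all be >= 0")
    return hr * vti * math.pi * radius**2 / 1000.0


def cardiac_output(sv: float, hr: float) -> float:
    """Cardiac output SV (mL) * HR (bpm) -> mL/min."""
    if sv < 0 or hr < 0:
        raise ValueError("sv and hr must be >= 0")
    return sv * hr
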