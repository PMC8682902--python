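"""Seeded synthetic generators for the three analysis stages.

These stand in for animal data: a one-compartment ICG decay with
multiplicative measurement noise, pulsatile/quasi-steady Doppler velocity
traces, and voxelised liver phantoms with parenchyma / capsule / fat /
vessel compartments on the HU scale.

All generators are deterministic under a fixed seed.  Anatomical realism
is a non-goal; the statistical structure each downstream stage assumes is
the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from hepatobase.ct import HU_MAX, HU_MIN, CTVolume
from hepatobase.doppler import VelocityTrace
from hepatobase.icg import ConcentrationSeries

# --------------------------------------------------------------------------
# ICG decay
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ICGSimParams:
    """One-compartment elimination-phase decay, C(t) = C0 * 10**(-k t).

    The distribution phase lasts only seconds, so simulation starts
    directly in the elimination phase; there is no absorption term.
    ``noise_cv`` is the coefficient of variation of mean-preserving
    multiplicative lognormal measurement noise.
    """

    c0: float = 155.99
    k: float = 0.1754
    t_grid: tuple[float, ...] = (1.0, 5.0, 10.0)
    noise_cv: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise ValueError(f"C0 must be > 0, got {self.c0}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        t = np.asarray(self.t_grid, float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be non-negative and strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def icg_true_concentration(params: ICGSimParams, t: np.ndarray) -> np.ndarray:
    """Noise-free decay curve C0 * 10**(-k t)."""
    return params.c0 * 10.0 ** (-params.k * np.asarray(t, float))


def simulate_icg_series(params: ICGSimParams) -> ConcentrationSeries:
    """Draw a replicate-averaged concentration series.

    Replicates are lognormal with mean equal to the true curve and the
    stated CV (the lognormal location carries the -sigma^2/2 correction, so
    the replicate mean is unbiased).
    """
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.t_grid, float)
    mean = icg_true_concentration(params, t)
    if params.noise_cv == 0:
        reps = np.tile(mean, (params.n_replicates, 1))
    else:
        sigma2 = np.log1p(params.noise_cv**2)
        factors = rng.lognormal(
            mean=-sigma2 / 2.0,
            sigma=np.sqrt(sigma2),
            size=(params.n_replicates, t.size),
        )
        reps = mean[None, :] * factors
    conc = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if params.n_replicates > 1 else None
    return ConcentrationSeries(
        subject_id=params.subject_id,
        times=t,
        concentrations=conc,
        replicate_sd=sd,
    )


# --------------------------------------------------------------------------
# Doppler velocity traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveformSimParams:
    """Raised-cosine systolic pulses on an end-diastolic baseline.

    Each cardiac cycle holds one pulse occupying ``pulse_width_frac`` of the
    period; within the pulse the velocity rises from ``edv_true`` to
    ``psv_true`` and back along a raised cosine, so the per-cycle maximum
    and inter-peak minimum are unambiguous.
    """

    hr: float = 331.5
    psv_true: float = 864.37
    edv_true: float = 424.33
    pulse_width_frac: float = 0.35
    duration: float = 2.0
    fs: float = 4000.0
    noise_sd: float = 0.0
    seed: int = 0
    vessel: str = "hepatic artery"

    def __post_init__(self) -> None:
        if not self.hr > 0:
            raise ValueError("hr must be > 0")
        if not (self.psv_true >= self.edv_true >= 0):
            raise ValueError("need psv_true >= edv_true >= 0")
        if not 0 < self.pulse_width_frac < 1:
            raise ValueError("pulse_width_frac must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        period = 60.0 / self.hr
        if self.fs * period < 20:
            raise ValueError(
                f"fs={self.fs} Hz gives {self.fs * period:.1f} samples/cycle; "
                "need >= 20 to resolve pulses"
            )
        if self.duration / period < 5:
            raise ValueError(
                f"duration {self.duration} s covers {self.duration / period:.1f} "
                "cycles; need >= 5 consecutive cardiac cycles"
            )


def simulate_velocity_trace(params: WaveformSimParams) -> VelocityTrace:
    """Sample the pulsatile waveform, optionally with additive Gaussian noise."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    period = 60.0 / params.hr
    phase = (t % period) / period
    v = np.full(n, params.edv_true)
    in_pulse = phase < params.pulse_width_frac
    u = phase[in_pulse] / params.pulse_width_frac
    v[in_pulse] += (params.psv_true - params.edv_true) * 0.5 * (1 - np.cos(2 * np.pi * u))
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, size=n)
    return VelocityTrace(samples=v, fs=params.fs, vessel=params.vessel)


# --------------------------------------------------------------------------
# CT liver phantoms
# --------------------------------------------------------------------------


class PhantomLabel(IntEnum):
    BACKGROUND = 0
    FAT = 1
    PARENCHYMA = 2
    CAPSULE = 3
    VESSEL = 4


@dataclass(frozen=True)
class PhantomParams:
    """Ellipsoidal liver with shell capsule, cylindrical vessels and a fat pocket.

    HU assignments follow the healthy-rat design centres: parenchyma around
    135 HU, capsule drawn uniformly in [150, 200] HU, blood-like vessels
    and sub-zero fat.  ``parenchyma_hu_sd`` is tissue heterogeneity;
    ``noise_sd`` is additive Gaussian acquisition noise over the whole grid.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_pitch: float = 0.125
    liver_semiaxes: tuple[float, float, float] = (5.0, 4.2, 3.6)
    parenchyma_hu_mean: float = 135.0
    parenchyma_hu_sd: float = 2.0
    capsule_hu_range: tuple[float, float] = (150.0, 200.0)
    capsule_thickness: float = 0.25
    vessel_hu: float = 45.0
    vessel_radii: tuple[float, ...] = (0.45, 0.3)
    fat_hu_mean: float = -100.0
    fat_pocket_radius: float = 0.8
    background_hu: float = -1000.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.voxel_pitch > 0:
            raise ValueError("voxel_pitch must be > 0")
        if not 0 < self.parenchyma_hu_mean < 1000:
            raise ValueError("parenchyma_hu_mean must lie in (0, 1000)")
        if self.fat_hu_mean >= 0:
            raise ValueError("fat_hu_mean must be < 0")
        if self.capsule_hu_range[0] > self.capsule_hu_range[1]:
            raise ValueError("capsule_hu_range must be (low, high)")
        extent = np.asarray(self.grid_shape) * self.voxel_pitch
        if np.any(2 * np.asarray(self.liver_semiaxes) >= extent):
            raise ValueError("liver does not fit in the grid with margin")


def generate_liver_phantom(params: PhantomParams) -> tuple[CTVolume, np.ndarray]:
    """Build the HU volume and a co-registered ground-truth label grid.

    Labels follow :class:`PhantomLabel`; liver = fat | parenchyma | capsule
    | vessel, so exact ground-truth volumes are voxel-count arithmetic.
    """
    if 0 < params.capsule_thickness < params.voxel_pitch:
        warnings.warn(
            f"capsule thickness {params.capsule_thickness} mm is below the "
            f"voxel pitch {params.voxel_pitch} mm; capsule may be unresolved",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    shape = params.grid_shape
    pitch = params.voxel_pitch
    centre = (np.asarray(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    # world coordinates (mm) relative to the grid centre
    x = (ii - centre[0]) * pitch
    y = (jj - centre[1]) * pitch
    z = (kk - centre[2]) * pitch

    a, b, c = params.liver_semiaxes
    outer = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    th = params.capsule_thickness
    if th > 0:
        ai, bi, ci = (max(s - th, pitch) for s in (a, b, c))
        inner = (x / ai) ** 2 + (y / bi) ** 2 + (z / ci) ** 2 <= 1.0
    else:
        inner = outer

    labels = np.zeros(shape, dtype=np.uint8)
    labels[inner] = PhantomLabel.PARENCHYMA
    labels[outer & ~inner] = PhantomLabel.CAPSULE

    if params.fat_pocket_radius > 0:
        fx, fy, fz = a / 2.5, -b / 3.0, 0.0  # fixed eccentric site
        fat = (x - fx) ** 2 + (y - fy) ** 2 + (z - fz) ** 2 <= params.fat_pocket_radius**2
        labels[fat & inner] = PhantomLabel.FAT

    # axis-aligned cylinders through the liver interior, stacked in z
    for m, r in enumerate(params.vessel_radii):
        off = (m - (len(params.vessel_radii) - 1) / 2.0) * c / 2.0
        cyl = (y**2 + (z - off) ** 2) <= r**2
        labels[cyl & inner & (labels != PhantomLabel.FAT)] = PhantomLabel.VESSEL

    hu = np.full(shape, params.background_hu, dtype=float)
    par = labels == PhantomLabel.PARENCHYMA
    if params.parenchyma_hu_sd > 0:
        hu[par] = rng.normal(params.parenchyma_hu_mean, params.parenchyma_hu_sd, int(par.sum()))
    else:
        hu[par] = params.parenchyma_hu_mean
    cap = labels == PhantomLabel.CAPSULE
    hu[cap] = rng.uniform(*params.capsule_hu_range, int(cap.sum()))
    hu[labels == PhantomLabel.VESSEL] = params.vessel_hu
    hu[labels == PhantomLabel.FAT] = params.fat_hu_mean
    if params.noise_sd > 0:
        hu += rng.normal(0.0, params.noise_sd, shape)
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    return CTVolume(voxels=hu, pitch=pitch), labels


def label_volume_cm3(labels: np.ndarray, which: PhantomLabel | None, pitch: float) -> float:
    """Exact volume of one label (or the whole liver when ``which`` is None)."""
    if which is None:
        count = int(np.count_nonzero(labels))
    else:
        count = int(np.count_nonzero(labels == which))
    return count * pitch**3 / 1000.0
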