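"""File I/O, run configuration and the end-to-end pipeline.

Tabular inputs are long-format CSV (one value per row); volumes are NIfTI
with HU stored as int16 and voxel pitch in the header.  ``run_pipeline``
ties the stages together: seeded simulation, per-stage CSV outputs, a
combined Markdown report and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

import hepatobase
from hepatobase import ct, datasets, doppler, icg, reference, synthetic

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Tabular I/O
# --------------------------------------------------------------------------

#: Known input schemas: required columns -> required dtype kind.
SCHEMAS = {
    "icg": {
        "columns": ["subject", "time_min", "concentration_ugml"],
        "numeric": ["time_min", "concentration_ugml"],
        "key": ["subject", "time_min"],
    },
    "weights": {
        "columns": ["subject", "week", "weight_g"],
        "numeric": ["week", "weight_g"],
        "key": ["subject", "week"],
    },
    "traces": {
        "columns": ["subject", "vessel", "time_s", "velocity_mms"],
        "numeric": ["time_s", "velocity_mms"],
        "key": ["subject", "vessel", "time_s"],
    },
    "analytes": {
        "columns": ["subject", "week", "analyte", "value"],
        "numeric": ["week"],
        "key": ["subject", "week", "analyte"],
    },
}


def read_measurements(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Malformed numeric cells are reported with their 1-based file line
    numbers; missing required columns, empty files and duplicate keys are
    errors.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in spec["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        df[col] = coerced
    dup = df.duplicated(subset=spec["key"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise ValueError(f"{path}: duplicate {spec['key']} keys at line(s) {lines}")
    return df


def icg_series_from_table(df: pd.DataFrame) -> list[icg.ConcentrationSeries]:
    """Split a validated long-format ICG table into per-subject series."""
    out = []
    for subject, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("time_min")
        sd = grp["replicate_sd"].to_numpy() if "replicate_sd" in grp else None
        out.append(
            icg.ConcentrationSeries(
                subject_id=str(subject),
                times=grp["time_min"].to_numpy(),
                concentrations=grp["concentration_ugml"].to_numpy(),
                replicate_sd=sd,
            )
        )
    return out


# --------------------------------------------------------------------------
# Volume I/O (NIfTI, int16 HU, isotropic pitch in the header)
# --------------------------------------------------------------------------


def write_volume(volume: ct.CTVolume, path: str | Path) -> Path:
    """Write a CTVolume as int16 NIfTI with pitch in the header zooms."""
    path = Path(path)
    data = np.rint(np.asarray(volume.voxels)).astype(np.int16)
    affine = np.diag([volume.pitch, volume.pitch, volume.pitch, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((volume.pitch,) * 3)
    nib.save(img, str(path))
    return path


def write_mask(mask: np.ndarray, pitch: float, path: str | Path) -> Path:
    """Write a binary mask as uint8 NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(mask, np.uint8), np.diag([pitch, pitch, pitch, 1.0])
    )
    img.header.set_zooms((pitch,) * 3)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ct.CTVolume:
    """Read a NIfTI volume as a CTVolume.

    Anisotropic zooms are accepted with a warning (pitch taken as the mean);
    missing/zero pixel sizes are an error.  Voxel values outside the HU
    scale warn via CTVolume itself.
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not z or not np.isfinite(z) for z in zooms):
        raise ValueError(f"{path}: missing or zero pixel-size metadata {zooms}")
    if not np.allclose(zooms, zooms[0]):
        warnings.warn(
            f"{path}: anisotropic voxels {zooms}; using mean pitch", stacklevel=2
        )
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.asanyarray(img.dataobj).astype(float)
    return ct.CTVolume(voxels=data, pitch=float(np.mean(zooms)), origin=origin)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


class IcgConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ref_time: float = 1.0
    window: tuple[float, float] = (1.0, 5.0)
    n_subjects: int = Field(6, ge=1)
    c0: float = Field(155.99, gt=0)
    k: float = Field(0.1754, ge=0)
    noise_cv: float = Field(0.05, ge=0)
    n_replicates: int = Field(3, ge=1)


class DopplerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_cycles: int = Field(5, ge=1)
    ap_mode: str = "psv"  # or "tav"

    @field_validator("ap_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("psv", "tav"):
            raise ValueError("ap_mode must be 'psv' or 'tav'")
        return v


class CtConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sweep: list[float] = [0.0, 50.0, 100.0, 120.0]
    upper_hu: float = 1000.0
    connectivity: int = 26
    component_policy: str = "largest-component"
    grid: int = Field(96, ge=16)

    @field_validator("sweep")
    @classmethod
    def _ascending(cls, v: list[float]) -> list[float]:
        if v != sorted(v):
            raise ValueError("sweep lower bounds must be ascending")
        return v

    @field_validator("connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        return v


class RunConfig(BaseModel):
    """Validated end-to-end run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    stages: list[str] = ["icg", "doppler", "ct", "reference"]
    seed: int = 0
    out_dir: str = "hepatobase_out"
    verbosity: str = "info"
    icg: IcgConfig = IcgConfig()
    doppler: DopplerConfig = DopplerConfig()
    ct: CtConfig = CtConfig()
    exclusion_rules: list[dict] = [
        {"analyte": "prothrombin_time", "weeks": [1, 2], "reason": "laboratory error"}
    ]

    @field_validator("stages")
    @classmethod
    def _stages(cls, v: list[str]) -> list[str]:
        known = {"icg", "doppler", "ct", "reference"}
        bad = [s for s in v if s not in known]
        if bad:
            raise ValueError(f"unknown stages {bad}; choose from {sorted(known)}")
        return v


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _fmt(df: pd.DataFrame) -> str:
    # fenced plain-text table: avoids an optional tabulate dependency
    return "```\n" + df.round(2).to_string(index=False) + "\n```"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write the report bundle.

    Inputs are simulated from the run seed (ICG series, Doppler traces,
    one CT phantom) or taken from the bundled baseline tables (weights,
    biochemistry).  Writes per-stage CSVs, ``report.md`` and
    ``manifest.json`` under ``config.out_dir``; returns a summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    summary: dict = {"stages": {}}
    report: list[str] = ["# hepatobase run report", ""]

    if "icg" in config.stages:
        cfg = config.icg
        rows = []
        for i in range(cfg.n_subjects):
            params = synthetic.ICGSimParams(
                c0=cfg.c0,
                k=cfg.k,
                t_grid=(1.0, 5.0, 10.0),
                noise_cv=cfg.noise_cv,
                n_replicates=cfg.n_replicates,
                seed=int(root.integers(2**31)),
                subject_id=f"sim{i + 1}",
            )
            series = synthetic.simulate_icg_series(params)
            fit = icg.fit_icg_k(series, window=cfg.window)
            pct = icg.clearance_percent(series, cfg.ref_time)
            for t, c, p in zip(series.times, series.concentrations, pct):
                rows.append(
                    {
                        "subject": series.subject_id,
                        "time_min": t,
                        "concentration_ugml": c,
                        "clearance_pct": p,
                        "icg_k": fit.icg_k,
                        "decay_rate_r": fit.r,
                    }
                )
        df = pd.DataFrame(rows)
        df.to_csv(out / "icg_clearance.csv", index=False)
        by_time = (
            df.groupby("time_min")[["concentration_ugml", "clearance_pct"]]
            .agg(["mean", "std"])
            .round(4)
        )
        by_time.columns = ["_".join(c) for c in by_time.columns]
        report += ["## ICG plasma clearance", "", _fmt(by_time.reset_index()), ""]
        summary["stages"]["icg"] = {
            "n_subjects": cfg.n_subjects,
            "mean_icg_k": float(df.groupby("subject")["icg_k"].first().mean()),
        }

    if "doppler" in config.stages:
        cfg = config.doppler
        hemo = datasets.load_hemodynamics()
        rows = []
        for _, rat in hemo.iterrows():
            params = synthetic.WaveformSimParams(
                hr=rat["hr"],
                psv_true=rat["ha_psv"],
                edv_true=rat["ha_edv"],
                noise_sd=5.0,
                seed=int(root.integers(2**31)),
                vessel="hepatic artery",
            )
            trace = synthetic.simulate_velocity_trace(params)
            cycles = doppler.detect_cycles(trace, min_cycles=cfg.min_cycles)
            _, avg = doppler.cycle_features(trace, cycles)
            rows.append(
                {
                    "subject": rat["subject"],
                    "psv": avg.psv,
                    "edv": avg.edv,
                    "vti": avg.vti,
                    "tav": avg.tav,
                    "ri": doppler.resistance_index(avg.psv, avg.edv),
                    "pci": doppler.portal_congestion_index(
                        rat["portal_area"], rat["portal_psv"]
                    ),
                    "ap_ratio": doppler.ap_ratio(avg.psv, rat["portal_psv"]),
                    "rbf_ml_min": doppler.renal_blood_flow(
                        rat["hr"], rat["renal_vti"], rat["lrad"] / 2.0
                    ),
                    "co_ml_min": rat["co"],
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "doppler_indices.csv", index=False)
        mean_sd = pd.DataFrame(
            {"mean": df.drop(columns="subject").mean(), "sd": df.drop(columns="subject").std()}
        ).reset_index(names="index")
        report += ["## Doppler hemodynamic indices", "", _fmt(mean_sd), ""]
        summary["stages"]["doppler"] = {"n_subjects": len(df)}

    if "ct" in config.stages:
        cfg = config.ct
        extent = cfg.grid * 0.125  # mm, default pitch
        params = synthetic.PhantomParams(
            grid_shape=(cfg.grid,) * 3,
            liver_semiaxes=(0.40 * extent, 0.35 * extent, 0.30 * extent),
            seed=int(root.integers(2**31)),
        )
        volume, labels = synthetic.generate_liver_phantom(params)
        write_volume(volume, out / "phantom.nii")
        results, mono = ct.threshold_sweep(
            volume,
            lower_list=cfg.sweep,
            upper_hu=cfg.upper_hu,
            component_policy=cfg.component_policy,
            connectivity=cfg.connectivity,
        )
        write_mask(results[0].mask, volume.pitch, out / "liver_mask.nii")
        df = pd.DataFrame(
            {
                "lower_hu": [r.lower_hu for r in results],
                "upper_hu": [r.upper_hu for r in results],
                "volume_cm3": [r.volume_cm3 for r in results],
                "mean_hu": [r.mean_hu for r in results],
                "n_voxels": [r.n_voxels for r in results],
            }
        )
        df.to_csv(out / "ct_sweep.csv", index=False)
        report += ["## CT threshold sweep", "", _fmt(df), ""]
        truth = synthetic.label_volume_cm3(labels, None, volume.pitch)
        summary["stages"]["ct"] = {
            "monotone": mono,
            "ground_truth_volume_cm3": truth,
        }

    if "reference" in config.stages:
        weights = datasets.load_weights()
        rows = []
        for subject, grp in weights.groupby("subject"):
            rec = reference.WeightRecord(
                subject_id=str(subject),
                weights=grp.sort_values("week")["weight_g"].to_numpy(),
            )
            rows.append(
                {
                    "subject": subject,
                    "final_gain_pct": reference.final_weight_gain(rec),
                }
            )
        gains = pd.DataFrame(rows)
        mean_by_week = weights.groupby("week")["weight_g"].mean().to_numpy()
        gains.to_csv(out / "weight_gain.csv", index=False)
        panel = reference.AnalytePanel(data=datasets.load_biochemistry())
        panel = reference.apply_exclusions(panel, config.exclusion_rules)
        panel_summary = reference.summarize_panel(panel)
        panel_summary.to_csv(out / "biochemistry_summary.csv", index=False)
        report += [
            "## Weight and biochemistry reference summaries",
            "",
            _fmt(gains),
            "",
            f"Group final weight gain: "
            f"{reference.final_weight_gain(mean_by_week):.2f}%",
            "",
        ]
        summary["stages"]["reference"] = {
            "group_final_gain_pct": reference.final_weight_gain(mean_by_week),
            "exclusions": panel.exclusion_log,
        }

    (out / "report.md").write_text("\n".join(report))
    cfg_json = config.model_dump_json()
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "versions": {
            "hepatobase": hepatobase.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["out_dir"] = str(out)
    return summary
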