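# hepatobase

Non-invasive liver baseline assessment toolkit for the healthy rat:

- **ICG kinetics** (`hepatobase.icg`) — indocyanine-green plasma clearance
  percentages, the two-point per-minute retention/decay pair `(d, R)` with
  `log10 d = (log10 C2 − log10 C1)/(t2 − t1)` and `R = 1 − d`, and the
  semilog elimination constant ICG-K fitted over the exponential phase
  (default window 1–5 min).
- **Doppler hemodynamics** (`hepatobase.doppler`) — per-cardiac-cycle
  waveform features (PSV, EDV, VTI, TAV) from sampled velocity traces,
  plus derived indices: resistive index, portal congestion index,
  hepatic-artery/portal ratio, cardiac output and renal blood flow
  (`HR × VTI × πr²`).
- **CT volumetry** (`hepatobase.ct`) — cubic VOI attenuation statistics
  with vessel exclusion, HU-window threshold segmentation with an optional
  largest-26-connected-component policy, lower-bound threshold sweeps with
  monotonicity reporting, and segmented-fraction bookkeeping.
- **Reference intervals** (`hepatobase.reference`) — small-cohort
  summaries (mean, SD with n−1 denominator, median, range), weight-gain
  computation, flagging against published intervals, and rule-based
  analyte exclusions.
- **Synthetic data** (`hepatobase.synthetic`) — seeded generators for all
  of the above: one-compartment ICG decay with mean-preserving lognormal
  noise, raised-cosine pulsatile velocity traces, and voxelised liver
  phantoms (parenchyma ≈135 HU, capsule 150–200 HU, sub-zero fat,
  blood-like vessels) with ground-truth labels.
- **I/O + CLI** (`hepatobase.io`, `hepatobase.cli`) — long-format CSV
  reading with schema validation, NIfTI volume round-tripping (int16 HU),
  a validated run configuration, and an end-to-end pipeline that writes
  per-stage CSVs, a Markdown report and a reproducibility manifest.

A small bundled dataset (`hepatobase.datasets`) carries the published
per-subject baseline tables from a six-rat longitudinal characterisation
(weights, ICG concentrations, hemodynamics, selected biochemistry with
literature intervals); it serves as validation fixture and demo input.

## CLI

```bash
# generate seeded synthetic inputs (CSV series/trace, NIfTI phantom)
hepatobase simulate --all --seed 7 --out sim_out

# per-subject ICG clearance, ICG-K, d and R
hepatobase icg sim_out/icg_series.csv --ref-time 1 --window 1 5

# waveform features from raw traces
hepatobase doppler sim_out/velocity_trace.csv --min-cycles 5

# HU-threshold sweep volumetry
hepatobase ct sim_out/phantom.nii --sweep 0,50,100,120 --upper 1000 --component largest

# analyte reference summaries with exclusion rules
hepatobase reference --exclusions rules.json

# full pipeline: report bundle + manifest
hepatobase run --seed 7 --out run_out
```

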