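# mrtdose

Dosimetry simulation and analysis for synchrotron **microbeam radiation
therapy (MRT)** at a bending-magnet beamline, modelled on the first
microbeam irradiation station at a 2.4 GeV storage ring: a filtered
pink beam split by a tungsten multi-slit collimator (MSC) into an array of
quasi-parallel 50 µm microbeams at 400 µm centre-to-centre distance, used
to irradiate plated melanoma cell cultures at ~70 Gy s⁻¹.

The package is aimed at beamline physicists and radiobiology groups who
need a desk-scale, fully scripted stand-in for the beamline chain:

* **`xray_physics`** — vertically integrated Schwinger spectrum of the
  bending magnet (critical energy ε_c = 0.665 E²[GeV] B[T] keV ≈ 5.55 keV),
  embedded mass-attenuation tables for Be / Al / W / water / air, filter
  transmission, flux-weighted mean energy, spectral sampling.
* **`beam_geometry`** — analytic ray tracing of the 8 mm-deep tungsten
  lamella comb; divergence-induced narrowing of edge microbeams
  (≈42 µm at the ±15 mm acceptance edge vs 50 µm on axis).
* **`mc_transport`** — simplified Monte Carlo photon transport with
  kerma-approximation scoring in 5 µm × 100 µm voxels of a 1 mm water
  layer behind the culture-vessel wall; deterministic tungsten
  attenuation, slit-angle importance sampling and forced first
  interaction make 10⁹ analogue-equivalent histories a ~30 s run.
* **`scan_dose`** — the constant-speed vertical scan: virtual source
  stepping, the dose-on-sample formula
  `D = beam height / speed × dose rate`, absolute anchoring to the
  measured peak dose.
* **`dose_analysis`** — horizontal profiles, peak detection, and the
  **peak-to-valley dose ratio** PVDR = D_peak(±20 µm) / D_valley
  (central 100 µm between beams), with batch-statistics uncertainties.
* **`film_dosimetry`** — Gafchromic EBT3 / HD-V2 workflow: net optical
  density, monotone calibration `D = a·netOD + b·netODⁿ`, dose maps,
  40 µm × 100 µm peak-region analysis.
* **`synthetic_data`** — generators for film images and triplicate cell
  counts with known ground truth.
* **`cell_response`** — survival fractions and significance tests for
  irradiated-vs-control counts.

## Worked example

The end-to-end pipeline (spectrum → static Monte Carlo → vertical scan →
absolute normalization → PVDR analysis) runs from Python or the CLI:

```sh
mrtdose run --seed 1 --out demo_out
```

equivalently:

```python
import dataclasses, json
from mrtdose import RunConfig, run_pipeline

cfg = RunConfig(output_dir="demo_out", seed=1)
cfg.transport = dataclasses.replace(cfg.transport, n_histories=1e9)
print(json.dumps(run_pipeline(cfg), indent=1, sort_keys=True))
```

which prints (≈40 s on one CPU):

```json
{
 "config_hash": "faf900fee7ae",
 "mean_energy_kev": 28.167844,
 "n_effective_histories": 1000000000.0,
 "peak_dose_gy": 64.102564,
 "peak_err_gy": 0.235442,
 "pvdr": 132.1288,
 "pvdr_err": 3.3201,
 "seed": 1,
 "surface_dose_gy": 64.102564,
 "valley_dose_gy": 0.485152,
 "valley_err_gy": 0.011829
}
```

Reading: the 2 mm Be + 3.5 mm Al filtered beam has a flux-weighted mean
energy of ≈28 keV; scanning the sample at 1.638 mm s⁻¹ through the
1.5 mm (FWHM) high beam at 70 Gy s⁻¹ delivers a peak dose of 64.1 Gy
("approximately 65 Gy"); the valley dose between microbeams is ≈0.49 Gy
(<1 Gy), giving a central-beam PVDR of ≈132 ± 3 — the high ratio that
underlies the normal-tissue sparing of MRT.  Intermediate artifacts
(spectrum, dose grids, profile) are written as delimited text beside the
JSON summary.

Other entry points: `mrtdose spectrum`, `geometry`, `simulate`, `scan`,
`analyze`, `film-calibrate`, `film-analyze`, `cells`,
`synth film`, `synth cells` (see `--help`).

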