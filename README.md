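# weldtherm

Simulation and analysis toolkit for high-frequency electrosurgical vessel
welding: a coupled electro-thermal voxel solver with temperature-dependent
tissue properties, plus the downstream analyses used to characterise a weld
— infrared temperature-profile comparison, Raman amide-III band ratios,
T-peel strength statistics and welding-phase classification — with
deterministic synthetic-data generators so every stage is testable offline.

## What's inside

| Module | Purpose |
| --- | --- |
| `weldtherm.materials` | Material constants and the affine `k(T)` / `sigma(T)` laws for tissue; constant copper-electrode properties; optional perfusion source |
| `weldtherm.solver` | Voxel weld geometry (tissue slab clamped between electrode blocks), quasi-static potential solve with Joule heating, implicit transient conduction, the coupled time loop, and drive calibration against temperature-crossing anchors |
| `weldtherm.ir` | Thermal-profile extraction from frames or simulated fields, the percentage agreement metric (R-squared on the `x >= 1 mm` window), heat-diffusion width, isotherm z-deviation |
| `weldtherm.raman` | Savitzky-Golay smoothing, iterative polynomial baseline removal, 800-2000 1/cm windowing, pseudo-Voigt (Gauss-Lorentz) peak fitting, amide-III (~1247 / ~1325 1/cm) band ratios and group means |
| `weldtherm.strength` | F-unit (N/mm) normalisation of T-peel forces, damaged-sample filtering, per-group max/min/mean, inter-group change rates |
| `weldtherm.phases` | Phase I/II/III classification (40 / 60 degC thresholds), threshold-crossing times, temperature-window intersection |
| `weldtherm.synth` | Seed-deterministic generators: IR frame sequences with sensor noise and artifacts, pseudo-Voigt Raman spectra with polynomial baselines, truncated-normal strength samples |

## CLI

The `weldtherm` entry point wraps the pipeline stages:

```bash
weldtherm simulate --config sim.yaml --out outdir/      # coupled run -> CSVs
weldtherm calibrate --config sim.yaml --anchors "11.5:40,23.5:60"
weldtherm analyze-ir --sim sim_profile.csv --meas meas_profile.csv --window 1.0
weldtherm analyze-raman --manifest manifest.csv --bands 1247,1325
weldtherm analyze-strength --in strength.csv
weldtherm phases --history outdir/timeseries.csv --ranges 40:60,53:71,53:62
weldtherm synth ir|raman|strength --seed 1 --out outdir/
```

Simulation configs are YAML with lengths in millimetres; see
`weldtherm.io.load_simulation_config` for the schema (every key has a
default, so `{}` is a valid config).

## Numerical design notes

* The RF drive is idealised to its RMS-equivalent constant voltage; thermal
  dynamics (seconds) never resolve individual cycles.
* The conduction step is implicit and dimension-split: three backward-Euler
  tridiagonal sweeps per step (exact batched Thomas solves), conservative to
  round-off and unconditionally stable, with distance-weighted harmonic face
  conductivities across material interfaces and per-layer z spacing (fine in
  tissue, coarse in copper).
* The potential system is solved per step with iterative refinement on a
  cached sparse LU that is refactored automatically as `sigma(T)` drifts;
  fresh solves are direct-solver accurate.
* All generators and the coupled solver are deterministic for a fixed config
  and seed.
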