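# pharynxflow

Desk-scale re-implementation of an upper-airway computational-fluid-dynamics
analysis of incisor-retraction treatment: parametric pharyngeal phantoms stand
in for patient CBCT reconstructions, a steady laminar incompressible
axisymmetric SIMPLE solver computes inspiratory flow, slice-based outcome
metrics (regional volumes, minimum cross-sectional area, pressure drops,
resistances) are extracted per millimetre, and a paired-cohort statistics
layer applies paired t tests with step-down Bonferroni (Holm) correction,
Pearson correlations, Dahlberg method error and ICC reliability.

## Layout

| module | role |
| --- | --- |
| `pharynxflow.synthetic_anatomy` | phantom specs, profile builder, paired pre/post cohort sampler, voxel/HU segmentation stand-in, STL/CSV export |
| `pharynxflow.meshing` | structured body-fitted axisymmetric grids, refinement series, grid-independence protocol, VTK legacy export |
| `pharynxflow.flow_solver` | waveform/peak-flow closure, boundary conditions, staggered finite-volume SIMPLE solver |
| `pharynxflow.airway_metrics` | per-millimetre slice sweep, pressure-drop/area/resistance outcome metrics |
| `pharynxflow.cohort_stats` | paired t, Holm correction, Pearson, Dahlberg ME, ICC |
| `pharynxflow.cli_io` | pipeline orchestration, YAML configuration, CLI |

## CLI

```bash
pharynxflow phantom --out phantom            # profile CSV + STL surface
pharynxflow cohort -n 30 --seed 1 --out cohort.json
pharynxflow solve --out solve                # one phantom: VTK/residuals/slices/metrics
pharynxflow metrics --slices solve_slices.csv --boundary1 17.7 --boundary2 82.7 -q 471.2
pharynxflow stats --table pipeline_out/cohort_table.csv
pharynxflow pipeline --seed 1 -n 30 --out pipeline_out
```

`pipeline` runs the full paired pre/post workflow: sample a synthetic cohort,
build and mesh both phantoms per case, solve steady inspiratory flow at the
peak of the 600 mL / 4 s half-sine waveform, extract metrics, and emit the
cohort table, the Holm-corrected paired-test table and the correlation table
(CSV), plus a JSON manifest with the seed and wall-clock. Runs are
reproducible byte-for-byte from (config, seed).

## Notes

- Geometry units are mm/cm²/cm³ (matching the clinical tables); the solver is
  SI internally; conversions live in `pharynxflow.units`.
- Reported pressures are hydrostatic-corrected by default when gravity is
  enabled, so pressure-drop metrics reflect flow resistance only.
- Resistance is computed as ΔP/Q (the printed form Q/ΔP is inconsistent with
  ΔP tracking resistance at constant flow; see `AirwayMetrics.notes`).
- The published A_min/A_mean ratio rises after treatment in the source table
  but falls in the source text; the generator keeps airway length fixed under
  retraction, which reproduces the *text* (ratio decreases).
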