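# actotrap

Single-molecule optical-trap and stopped-flow analysis of acto-myosin
mechanochemistry, with a matched synthetic-data generator so that every
estimator can be validated by parameter recovery.

The package models a single-headed motor cycling through
`detached -> post-stroke/ADP -> rigor -> detached`, with load-dependent
exit rates `k(F) = k0 exp(-F d / kT)`, a two-substep working stroke, and
state-dependent crossbridge stiffness. It provides:

- `actotrap.crossbridge` — closed-form cycle algebra: load-dependent
  rates, attached times, duty ratio, predicted gliding velocity, stall
  force, rigor occupancy.
- `actotrap.synthetics` — synthetic data: Markov state sequences,
  overdamped-Langevin traces of the two trapped beads + actin dumbbell
  (exact piecewise-OU integration, optional 100-Hz sinusoidal forcing,
  static trap offsets for load sweeps), and stopped-flow transients.
  Every trace carries full metadata and ground-truth state annotations.
- `actotrap.detection` — variance-based binding-event detection
  (forcing removal, rolling variance, auto dual-threshold hysteresis,
  edge refinement) producing per-event dwell, displacement and mean load.
- `actotrap.dwells` — cumulative dwell-time double-exponential fits,
  ATP-dependence classification into k1 (ADP release) and k2 (second-
  order ATP binding), Gaussian working-stroke fit, duty ratio / on-rate.
- `actotrap.ensemble` — start/end-synchronised ensemble averaging with
  the short-event extension rule, single-exponential fits, per-cycle
  stiffness demodulation and ensemble stiffness time courses.
- `actotrap.loadkin` — load binning and Bell-relation fits (k0, d).
- `actotrap.stoppedflow` — single-exponential transient fits with a
  lag-phase runs test, and k_obs-vs-[ATP] second-order slopes.
- `actotrap.pipeline` / `actotrap.cli` — end-to-end orchestration with
  deterministic per-stage seeding, trace/transient file formats
  (TSV + JSON sidecar, optional HDF5), and a `click` CLI.

Motor-variant parameter sets (`WT`, `S267A`, `S267E`) ship as a YAML
registry (`actotrap/data/variants.yaml`); all quantities are in
nm / s / pN / mM, with kT = 4.07 pN nm at 22 °C.

## CLI

```sh
actotrap model -v S267E --atp 0.1          # closed-form cycle numbers
actotrap simulate -v S267E --atp 0.1 --duration 120 --seed 1 -o trace.tsv
actotrap detect trace.tsv -o events.tsv
actotrap dwellfit events10.tsv events100.tsv --atp 0.01 --atp 0.1
actotrap stroke events.tsv
actotrap ensemble trace.tsv events.tsv --alignment start
actotrap stiffness trace_forced.tsv events.tsv --atp 0.1
actotrap bellfit events.tsv --edges="-1,0,1,2,3"
actotrap sf-fit sf1.tsv sf2.tsv sf3.tsv --atp 0.5 --atp 1 --atp 2
actotrap run -v S267E --seed 1 --out-dir run1   # full pipeline + report
```

`actotrap run` writes `report.tsv` / `report.json` (per-variant k1, k2,
working stroke, stiffness plateaus, d1/d2, duty ratio, stall force) plus
the fully resolved configuration next to the outputs; identical
configuration and seed reproduce the report bit-for-bit.

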