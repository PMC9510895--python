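# doxodyn

Compartmental population-dynamics modeling of cultured tumor cells under
repeated chemotherapy dosing. The package simulates, calibrates, and
analyzes a hybrid ODE model in which each drug dose splits the proliferating
population into surviving cells and an irreversibly damaged subpopulation
whose net growth rate decays exponentially from proliferation toward death.

It covers the full analysis loop on time-resolved cell-count data:

- **data_model** — domain types (time courses, treatment schedules, model
  parameters, fit results), CSV/JSON I/O, and enumeration of the three
  experimental designs (varying concentration, inter-treatment interval, and
  dose number).
- **preprocessing** — truncation at confluence / major drops / repeated
  discontinuities, derivative-smoothing normalization of media-handling
  discontinuities, and moving-median (MAD) outlier removal.
- **dynamics** — event-driven forward simulation (logistic growth before the
  first dose; coupled surviving/damaged compartments afterwards) with an
  adaptive Runge-Kutta 4(5) integrator.
- **fitting** — bounded trust-region least squares (tolerances 1e-6, up to
  20,000 evaluations), the two-pass treated-carrying-capacity fixing policy,
  and asymptotic 95% parameter and prediction confidence intervals.
- **gof_stats** — NRMSE (mean-normalized, percent), R², Pearson and
  concordance correlation, two-sided rank-sum tests, and the
  constant-vs-adaptive model-version decision.
- **empirical_formulas** — concentration-dependent parameter formulas
  (exponential decays, an offset exponential, a Morse-potential well, a
  saturating exponential) fitted to per-concentration medians, plus Latin
  hypercube propagation of their 95% bands into simulation envelopes.
- **synthetic_data** — ground-truth generators with configurable measurement
  artifacts (lognormal noise, outlier spikes, step discontinuities), used
  throughout the test suite for parameter-recovery checks.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which exercises the
acceptance criteria end to end (design enumeration, dynamics oracles,
normalization-constant oracle, metric brute-force agreement, parameter and
formula recovery, model-selection behavior, and LHS stratification). The full
run takes a few minutes on one CPU.

## CLI

The `doxodyn` entry point chains the pipeline stages:

```bash
# synthetic replicate set for design 1 (varying concentration)
doxodyn synth --design 1 --seed 42 --out raw.csv --truth truth.json

# clean: truncate, normalize discontinuities, remove outliers
doxodyn preprocess --in raw.csv --out clean.csv --theta-u 53873 --report report.json

# calibrate the model per replicate (capacity policy applied per experiment)
doxodyn fit --in clean.csv --mode constant --out fits.json

# goodness-of-fit table and model-version comparison
doxodyn gof --fits fits.json --out gof.csv
doxodyn compare --constant fitsA.json --adaptive fitsB.json --out decision.json

# concentration->parameter formulas and uncertainty envelope
doxodyn formulas --fits fits.json --out formulas.json
doxodyn band --formulas formulas.json --conc 75 --n 200 --seed 17 --out band.csv

# forward simulation from a parameter file
doxodyn simulate --params params.json --schedule schedule.json --t-end 800 --dt 2 --out traj.csv

# everything, from a YAML config, with a hashed run manifest
doxodyn run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
design: 1
seed: 7
cv: 0.02
output_dir: run1
```

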