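# pkpdkit

A pharmacometric toolkit for determining an oral dosing regimen from a
single-dose PK/PD study in dogs:

- **pharmacokinetics** — closed-form one-compartment oral absorption
  (Bateman function with lag time), iteratively reweighted (1/ŷ²)
  polyexponential fitting with AIC model selection, IV non-compartmental
  analysis (linear-up/log-down AUC, automatic terminal-point selection),
  and sparse-sampling terminal half-life by log-linear regression.
- **effect_metrics** — percent-improvement transformation anchored by
  healthy (T−) and inflamed (T+) baselines, plateau detection and
  effect-duration summaries.
- **indirect_response** — three turnover (indirect-response) model forms
  (stimulation of loss, inhibition of loss, inhibition of production) with
  sigmoid Hill drug effects; ODE simulation and per-subject sequential
  PK→PD least-squares estimation with bounds (Hill n ≤ 10, Imax ≤ 1,
  production-inhibition cap fixed at 1).
- **dose_simulation** — effect–time trajectories over an oral dose grid
  (default 0.1–8 mg/kg, 48 h horizon) with peak-effect and
  duration-above-threshold summaries and all-endpoints dose selection.
- **population_stats** — extensive/poor-metabolizer detection by exact
  1-D two-means clustering of log half-lives with a bimodality flag,
  Welch t-test subgroup comparison with fold ratios, and one-way breed
  ANOVA with Tukey-HSD compact letter display and CVs.
- **synthetic_data** — reproducible virtual cohorts (log-normal
  between-subject variability, EM/PM structure, optional breed effects)
  with concentration and effect tables on the study sampling schedules,
  proportional assay noise and below-LOQ flagging.
- **interface** — CSV/JSON I/O, mass↔molar unit conversion, and an
  end-to-end study pipeline with stage-tagged logging.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (desk-scale
worked examples, noise-free and stochastic parameter recovery, analytic
ODE/NCA oracles, ANOVA type-I error calibration, metabolizer
classification, dose-grid monotonicity), one test per criterion.

## CLI

A single `pkpdkit` entry point with subcommands:

```bash
pkpdkit simulate-cohort --n-subjects 12 --schedule oral_study1 --seed 1 --out cohort/
pkpdkit fit-pk --input cohort/concentrations.csv --route oral --out pk.csv
pkpdkit classify-metabolizers --input halflives.csv
pkpdkit nca --input iv_concentrations.csv
pkpdkit halflife-sparse --input sparse_concentrations.csv
pkpdkit breed-anova --input breed_halflives.csv
pkpdkit fit-pkpd --conc conc.csv --effect effect.csv --endpoint creeping_speed --out pd/
pkpdkit simulate-dose --pk pk.json --pd pd.json --endpoint body_temperature --out dose/
pkpdkit run-study1 --conc conc.csv --effect effect.csv --seed 1 --out report/
```

Concentration tables are header-first CSV with columns
`subject_id,route,dose_mg_per_kg,time_h,conc_ug_per_L,bql`; effect tables
use `subject_id,endpoint,time_h,value,t_minus,t_plus`. Parameter bundles
are JSON. Every subcommand that draws random numbers honors `--seed` and
is deterministic under identical invocation.

## Conventions

Doses are mg/kg (converted internally to μg/kg) so concentrations are
μg/L (≡ ng/mL) throughout; EC50/IC50 in ng/mL are numerically identical
to μg/L. The default assay limit of quantification is 10 μg/L; values
below it are flagged and excluded from fitting. Absorption is constrained
faster than elimination (k01 > k10) to resolve flip-flop ambiguity.
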