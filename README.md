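# modelreduce

Systematic reduction of mechanistic simulation models by constant
replacement.  Internal model variables are replaced, one at a time and then
in combination, by constants fitted against observations; an informal
pseudo-likelihood turns the resulting fit changes into per-variable
*replacement probabilities* that separate

- **noise** variables (probability near 1): replacing them *improves* the fit,
- **redundant** variables (near 0.5): replacement barely matters,
- **contributing** variables (near 0): the model needs them.

The toolkit contains:

| module | purpose |
| --- | --- |
| `modelreduce.model_core` | declarative daily-time-step models (YAML), safe expression rules, fast simulation under any replacement state |
| `modelreduce.skill_metrics` | weighted RSS, Nash–Sutcliffe efficiency, pseudo-likelihood and normalisation |
| `modelreduce.screening` | one-at-a-time replacement with bounded constant fitting, candidate selection |
| `modelreduce.factorial` | Metropolis–Hastings walk over replacement combinations, exhaustive small-N oracle, probability/joint/trace tables |
| `modelreduce.synthetic` | bundled toy crop model + weather/observation generator with planted variable roles |
| `modelreduce.config` / `pipeline` / `cli` | YAML config, end-to-end pipeline, reports, CLI |

## Quick start (CLI)

```bash
# write a complete synthetic study: model.yaml, drivers.csv,
# observations.csv, truth_roles.json and a ready-to-run config.yaml
modelreduce synth --seed 1 --out study

# full pipeline: screen -> select -> MH search -> reports
modelreduce run -c study/config.yaml

# individual stages
modelreduce screen -c study/config.yaml
modelreduce search -c study/config.yaml
modelreduce oracle -c study/config.yaml      # exhaustive, small N only
modelreduce evaluate -c study/config.yaml --replace cum_rain=0 --replace ctsw=0
```

`run` writes to the configured output directory:

- `screening.csv` — fitted constant, bounds, RSS ratio per variable
- `probabilities.csv` — replacement probability per variable and α, with
  noise/redundant/contributing classification
- `joint.csv` — pairwise joint probabilities and independence ratios
- `trace.csv` — probability evolution vs unique-model count
- `skill.csv` — per-stream and pooled RSS / Nash–Sutcliffe of the full model
- `manifest.json` — seed, settings, α values, versions, stage statistics

## Python API sketch

```python
from modelreduce import (
    ToyCropConfig, build_toy_crop_model, generate_weather,
    generate_observations, load_drivers, screen_all, select_candidates,
    mh_search, SearchSettings, replacement_probabilities,
)

cfg = ToyCropConfig(seed=1)
spec, truth = build_toy_crop_model(cfg)
drivers = load_drivers(generate_weather(cfg))
obs = generate_observations(spec, drivers, cfg, truth)

rows = screen_all(spec, drivers, obs, exclusions=truth.exclusions)
candidates = select_candidates(rows, threshold=1.1)
result = mh_search(spec, drivers, obs, candidates, SearchSettings(seed=1))
print(replacement_probabilities(result))
```

## Model documents

A model is a YAML mapping with `parameters`, `drivers`, `outputs` and an
ordered list of `variables`.  Each variable has a `rule` — an arithmetic
expression over parameters, drivers and other variables (`min`, `max`,
`abs`, `exp`, `log`, `sqrt`, comparisons and `a if cond else b` are
allowed).  A variable may reference its own previous-day value (lag-1);
same-day cycles between distinct variables are rejected.  `replaceable`,
`is_switch`/`off_value`, `init` and `tags` are optional per variable.
Drivers are CSV with columns `site, day, <stream...>` (day 0-based);
observations are CSV with `stream, site, day, value`.

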