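"""Bundled toy crop model and observation generator.

A small daily crop-like simulator with *planted* variable roles so the whole
reduction pipeline can be exercised and validated without external data:

* **essential** variables carry real signal (thermal-time accumulation rate,
  leaf number, a drought factor that bites at the droughted site, canopy
  light interception) — replacing any of them with a constant visibly
  degrades the fit;
* **redundant** variables are near-neutral over the generated driver range
  (a tiny soil-temperature adjustment, a vernalisation factor that
  saturates within days, a switch-controlled canopy-temperature adjustment,
  and a cumulative-rain tally that nothing consumes) — replacement barely
  moves the RSS;
* **noise** variables inject spurious, driver-correlated bias into biomass
  growth and grain fill; observations are generated from the model with
  these terms held at their neutral value, so replacing them *improves*
  the fit.

Redundancy here is conditional on the driver range, exactly as in real
model-reduction exercises: widen the weather envelope and some "redundant"
terms would start to matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model_core import (
    Drivers,
    ModelSpec,
    ReplacementState,
    load_drivers,
    parse_model_spec,
    simulate,
)
from .skill_metrics import ObservationSet

__all__ = [
    "ToyCropConfig",
    "TruthRoles",
    "build_toy_crop_model",
    "generate_weather",
    "generate_observations",
    "truth_state",
]

DEFAULT_SE_FRACTIONS = {"biomass": 0.10, "grain": 0.10, "lai": 0.20}

VALID_ROLES = ("essential", "redundant", "noise")


@dataclass(frozen=True)
class ToyCropConfig:
    """Knobs of the bundled fixture."""

    n_sites: int = 3
    season_length: int = 140
    seed: int = 0
    sampling_start: int = 35
    sampling_interval: int = 10
    se_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SE_FRACTIONS)
    )
    roles: dict[str, str] | None = None  # override of the planted roles
    duplicate_drought: bool = False  # adds an engineered either/or pair

    @property
    def sampling_days(self) -> list[int]:
        return list(
            range(self.sampling_start, self.season_length, self.sampling_interval)
        )

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigError("need at least 2 sites (drought contrast)")
        if self.season_length < 60:
            raise ConfigError("season_length must be >= 60 days")
        if not self.sampling_days:
            raise ConfigError("no sampling days fall within the season")
        if max(self.sampling_days) >= self.season_length:
            raise ConfigError("sampling days must fall within the season")
        for s, f in self.se_fractions.items():
            if not 0 <= f <= 1:
                raise ConfigError(f"se fraction for {s!r} out of range: {f}")


@dataclass(frozen=True)
class TruthRoles:
    """Planted role and mechanism for every replaceable fixture variable."""

    roles: dict[str, str]
    mechanisms: dict[str, str]
    exclusions: tuple[str, ...]
    neutral_constants: dict[str, float]  # noise variables -> truth value

    @property
    def candidates(self) -> list[str]:
        return [n for n in self.roles if n not in self.exclusions]

    def of_role(self, role: str) -> list[str]:
        return [n for n in self.candidates if self.roles[n] == role]


_TOY_MODEL_YAML = """
name: toycrop
parameters:
  tbase: 0.0
  phyllo: 95.0
  flnum: 9.0
  tt_anth: 1150.0
  vern_tt: 30.0
  k_ext: 0.62
  rue: 1.15
  rad_ref: 14.0
  sw_crit: 55.0
  sw_cap: 120.0
  transp_c: 2.1
  lai_rate: 0.0009
  sen_rate: 0.055
  fill_rate: 9.0
  trans_cap: 0.6
  topt: 18.0
drivers: [tmin, tmax, rad, rain]
outputs: [biomass, grain, lai]
variables:
  - name: tmean
    rule: "(tmin + tmax) / 2.0"
    tags: [operational]
  - name: soil_adj
    rule: "0.004 * (rad - rad_ref)"
  - name: tsoil
    rule: "tmean + soil_adj"
    tags: [intermediate]
  - name: tt_rate
    rule: "max(0.0, tsoil - tbase)"
  - name: tt
    rule: "tt + tt_rate"
    tags: [mass-balance]
  - name: vern_f
    rule: "min(1.0, tt / vern_tt)"
  - name: leaf_num
    rule: "min(flnum, tt / phyllo) if tt >= (1.0 - vern_f) * vern_tt else 0.0"
  - name: dev
    rule: "tt / tt_anth"
    tags: [intermediate]
  - name: ctsw
    rule: "1.0"
    is_switch: true
    off_value: 0.0
  - name: tcanopy
    rule: "tmean + ctsw * 0.04 * (rad - rad_ref)"
    tags: [intermediate]
  - name: transp
    rule: "transp_c * min(1.0, leaf_num / flnum) * (0.55 + 0.45 * rad / rad_ref)"
    tags: [mass-balance]
  - name: soil_water
    rule: "min(sw_cap, max(0.0, soil_water + rain - transp))"
    init: 70.0
    tags: [mass-balance]
{DROUGHT_BLOCK}
  - name: rue_mod
    rule: "1.0 + 0.3 * (rad / rad_ref - 1.0)"
  - name: lai
    rule: "max(0.0, lai + (lai_rate * leaf_num * drought_f * max(0.0, tmean) if dev < 1.0 else 0.0) - (sen_rate * lai if dev >= 1.0 else 0.0))"
    init: 0.02
    tags: [mass-balance]
  - name: fint
    rule: "1.0 - exp(-k_ext * lai)"
  - name: dbio
    rule: "rue * rad * fint * rue_mod * drought_f"
    tags: [intermediate]
  - name: biomass
    rule: "biomass + dbio"
    init: 1.0
    tags: [mass-balance]
  - name: fill_mod
    rule: "1.0 + 1.2 * (tmean / (tmean + 6.0) - 0.62)"
  - name: tfac
    rule: "max(0.2, 1.0 - abs(tcanopy - topt) / 25.0)"
    tags: [intermediate]
  - name: grain
    rule: "min(trans_cap * biomass, grain + (fill_rate * fill_mod * tfac if dev >= 1.0 else 0.0))"
    tags: [mass-balance]
  - name: cum_rain
    rule: "cum_rain + rain"
    tags: [diagnostic-tally]
  - name: harvest_index
    rule: "grain / max(biomass, 1.0)"
    replaceable: false
    tags: [diagnostic]
"""

_SINGLE_DROUGHT_BLOCK = """\
  - name: drought_f
    rule: "min(1.0, soil_water / sw_crit)"
"""

_DUPLICATE_DROUGHT_BLOCK = """\
  - name: dr_a
    rule: "min(1.0, soil_water / sw_crit)"
  - name: dr_b
    rule: "min(1.0, (soil_water + 4.0) / sw_crit)"
  - name: drought_f
    rule: "min(dr_a, dr_b)"
"""

#: Variables that are replaceable in principle but excluded from candidacy by
#: the documented curation list: accumulators and pure intermediates whose
#: replacement would break mass balance or merely split another variable's
#: rule.  This mirrors the manual mechanistic-curation step and is an
#: explicit user choice, never automated.
_DEFAULT_EXCLUSIONS = (
    "tmean",
    "tsoil",
    "tt",
    "dev",
    "tcanopy",
    "transp",
    "soil_water",
    "lai",
    "dbio",
    "biomass",
    "tfac",
    "grain",
)

_ROLES = {
    "soil_adj": ("redundant", "radiation adjustment of at most a few hundredths of a degree; invisible downstream"),
    "tt_rate": ("essential", "sites differ in temperature, so one constant rate mistimes phenology everywhere"),
    "vern_f": ("redundant", "on/off gate on early leaf growth; the gate opens within days over the generated weather"),
    "leaf_num": ("essential", "drives canopy expansion; a constant wrecks the early LAI trajectory"),
    "ctsw": ("redundant", "switch gating a small canopy-temperature adjustment; off value 0 is near-neutral"),
    "drought_f": ("essential", "water stress differs across sites; no single constant fits both regimes"),
    "rue_mod": ("noise", "radiation-correlated seasonal distortion of biomass growth absent from the observations"),
    "fint": ("essential", "nonlinear light interception; a constant linearises biomass accumulation"),
    "fill_mod": ("noise", "temperature-correlated bias on grain fill absent from the observations"),
    "cum_rain": ("redundant", "tally that no other rule reads; replacement is a strict no-op"),
}

_DUPLICATE_ROLES = {
    "dr_a": ("redundant", "duplicated stress signal; min() lets the twin stand in when one is pinned high"),
    "dr_b": ("redundant", "duplicated stress signal; min() lets the twin stand in when one is pinned high"),
}

#: Truth values used when generating observations: noise variables are held
#: at their neutral value, so their fluctuation exists only in the model.
_NEUTRAL_CONSTANTS = {"rue_mod": 1.0, "fill_mod": 1.0}


def build_toy_crop_model(config: ToyCropConfig) -> tuple[ModelSpec, TruthRoles]:
    """Construct the fixture spec (via the YAML parser) and its truth roles."""
    config.validate()
    block = (
        _DUPLICATE_DROUGHT_BLOCK if config.duplicate_drought else _SINGLE_DROUGHT_BLOCK
    )
    spec = parse_model_spec(_TOY_MODEL_YAML.replace("{DROUGHT_BLOCK}", block))
    role_map = dict(_ROLES)
    if config.duplicate_drought:
        role_map.update(_DUPLICATE_ROLES)
    roles = {name: role for name, (role, _) in role_map.items()}
    mechanisms = {name: mech for name, (_, mech) in role_map.items()}
    # replaceable-but-excluded variables carry their exclusion reason as role
    # documentation; only candidate roles participate in recovery checks
    for name in _DEFAULT_EXCLUSIONS:
        if spec.variable(name).replaceable:
            roles.setdefault(name, "essential")
            mechanisms.setdefault(
                name, "accumulator/intermediate; excluded from candidacy by curation"
            )
    if config.roles:
        unknown = set(config.roles) - set(roles)
        if unknown:
            raise ConfigError(f"role override names unknown variable(s): {sorted(unknown)}")
        bad = {r for r in config.roles.values() if r not in VALID_ROLES}
        if bad:
            raise ConfigError(f"invalid role(s): {sorted(bad)}")
        roles.update(config.roles)
    truth = TruthRoles(
        roles=roles,
        mechanisms=mechanisms,
        exclusions=_DEFAULT_EXCLUSIONS,
        neutral_constants=dict(_NEUTRAL_CONSTANTS),
    )
    present = {truth.roles[n] for n in truth.candidates}
    missing = set(VALID_ROLES) - present
    if missing:
        raise ConfigError(f"fixture needs at least one variable per role; missing {sorted(missing)}")
    return spec, truth


# site profiles cycled over n_sites: (label, temp offset, rain probability,
# mean wet-day rain, drought window as (start, stop, factor) or None)
_SITE_PROFILES = [
    ("wellwatered", 1.5, 0.55, 6.5, None),
    ("droughted", -1.5, 0.45, 5.0, (40, 120, 0.04)),
    ("intermediate", 0.0, 0.45, 5.0, (60, 100, 0.35)),
]


def _site_name(index: int) -> str:
    label = _SITE_PROFILES[index % len(_SITE_PROFILES)][0]
    return label if index < len(_SITE_PROFILES) else f"{label}_{index}"


def generate_weather(config: ToyCropConfig) -> pd.DataFrame:
    """Seeded per-site daily weather with a seasonal trend.

    At least one site carries a mid-season drought window and one is kept
    well watered, giving the water-stress contrast the drought factor needs
    to be identifiable.  tmin <= tmax by construction.
    """
    config.validate()
    n = config.season_length
    frames = []
    for i in range(config.n_sites):
        _, offset, p_wet, wet_mean, window = _SITE_PROFILES[i % len(_SITE_PROFILES)]
        rng = np.random.default_rng((config.seed, 101, i))
        d = np.arange(n)
        tmean = 8.5 + 9.5 * d / n + offset + rng.normal(0.0, 1.3, n)
        spread = np.maximum(3.0, 7.5 + rng.normal(0.0, 1.2, n))
        rad = np.clip(
            11.0
            + 8.0 * np.sin(np.pi * (d + 12) / (n + 24))
            + rng.normal(0.0, 1.8, n),
            2.0,
            26.0,
        )
        rain = np.where(
            rng.random(n) < p_wet, rng.exponential(wet_mean, n), 0.0
        )
        if window is not None:
            start, stop, factor = window
            in_window = (d >= start) & (d < stop)
            rain = np.where(in_window, rain * factor, rain)
        frames.append(
            pd.DataFrame(
                {
                    "site": _site_name(i),
                    "day": d,
                    "tmin": np.round(tmean - spread / 2.0, 3),
                    "tmax": np.round(tmean + spread / 2.0, 3),
                    "rad": np.round(rad, 3),
                    "rain": np.round(rain, 3),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_state(truth: TruthRoles) -> ReplacementState:
    """Replacement state pinning the noise variables to their neutral values."""
    return ReplacementState(dict(truth.neutral_constants))


def generate_observations(
    spec: ModelSpec,
    drivers,
    config: ToyCropConfig,
    truth: TruthRoles | None = None,
) -> ObservationSet:
    """Noisy observations of the truth run.

    Truth = the model with noise-role variables held at their neutral
    values (the spurious terms exist only in the model, not in "nature").
    Observations are truth times ``1 + fraction * eps`` with ``eps`` a
    standard normal truncated below at -3, floored at zero.  Grain is only
    observed after anthesis; biomass and LAI throughout the season.
    """
    config.validate()
    if truth is None:
        _, truth = build_toy_crop_model(config)
    drivers = load_drivers(drivers)
    traj = simulate(spec, drivers, truth_state(truth))
    rng = np.random.default_rng((config.seed, 202))
    records = []
    for site in drivers.sites:
        dev = traj.series(site, "dev")
        past_anth = np.flatnonzero(dev >= 1.0)
        anth_day = int(past_anth[0]) if past_anth.size else config.season_length
        for stream in ("biomass", "grain", "lai"):
            series = traj.series(site, stream)
            for day in config.sampling_days:
                if stream == "grain" and day < anth_day + 3:
                    continue
                frac = config.se_fractions.get(stream, 0.0)
                eps = max(float(rng.standard_normal()), -3.0)
                value = max(0.0, float(series[day]) * (1.0 + frac * eps))
                records.append(
                    {"stream": stream, "site": site, "day": day, "value": value}
                )
    frame = pd.DataFrame(records)
    return ObservationSet(frame, dict(config.se_fractions))
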