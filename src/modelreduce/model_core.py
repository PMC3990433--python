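"""Declarative daily-time-step models and their simulation.

A model is a list of named variables, each with an update rule evaluated once
per day in topological order.  A rule may reference parameters, driver
streams, other variables (their same-day value) and the variable's *own*
previous-day value (the self-reference is the lag-1 read, so accumulators
like ``tt = tt + tt_rate`` are natural).  Same-day cycles between distinct
variables are rejected at parse time.

Any replaceable variable can be pinned to a constant for a whole run via a
:class:`ReplacementState`; downstream variables then see the constant.
"""

from __future__ import annotations

import graphlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CycleError,
    LookupError_,
    SimulationError,
    SpecError,
)
from .expressions import EVAL_GLOBALS, RESERVED_NAMES, Expression

__all__ = [
    "VariableDef",
    "ModelSpec",
    "ReplacementState",
    "TrajectorySet",
    "Drivers",
    "parse_model_spec",
    "serialize_model_spec",
    "load_drivers",
    "simulate",
    "variable_range",
    "list_replaceable",
]


@dataclass(frozen=True)
class VariableDef:
    """One internal model variable and its daily update rule."""

    name: str
    rule: str
    init: float = 0.0
    replaceable: bool = True
    is_switch: bool = False
    off_value: float = 0.0
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.is_switch and not self.replaceable:
            raise SpecError(f"switch variable {self.name!r} must be replaceable")


class ModelSpec:
    """A validated model: variables, parameters, drivers and outputs.

    Validation resolves every rule's symbols, computes a same-day evaluation
    order and rejects intra-step cycles.
    """

    def __init__(
        self,
        variables: list[VariableDef],
        parameters: dict[str, float],
        drivers: list[str],
        outputs: list[str],
        name: str = "model",
    ):
        self.name = name
        self.variables = list(variables)
        self.parameters = {k: float(v) for k, v in parameters.items()}
        self.drivers = list(drivers)
        self.outputs = list(outputs)
        self._validate()
        self._expressions = {
            v.name: Expression(v.rule, context=v.name) for v in self.variables
        }
        self.order = self._toposort()
        self._index = {v.name: v for v in self.variables}
        self._runner = None  # compiled lazily

    # -- validation -------------------------------------------------------

    def _validate(self):
        var_names = [v.name for v in self.variables]
        if len(set(var_names)) != len(var_names):
            dupes = sorted({n for n in var_names if var_names.count(n) > 1})
            raise SpecError(f"duplicate variable names: {dupes}")
        all_names = var_names + list(self.parameters) + self.drivers
        if len(set(all_names)) != len(all_names):
            dupes = sorted({n for n in all_names if all_names.count(n) > 1})
            raise SpecError(f"names used in more than one role: {dupes}")
        for n in all_names:
            if not n.isidentifier() or n.startswith("_"):
                raise SpecError(f"invalid identifier: {n!r}")
            if n in RESERVED_NAMES:
                raise SpecError(f"name {n!r} shadows a builtin rule function")
        missing = set(self.outputs) - set(var_names)
        if missing:
            raise SpecError(f"outputs are not variables: {sorted(missing)}")

    def _toposort(self) -> list[str]:
        known = (
            {v.name for v in self.variables}
            | set(self.parameters)
            | set(self.drivers)
        )
        var_names = {v.name for v in self.variables}
        deps: dict[str, set[str]] = {}
        for v in self.variables:
            refs = self._expressions[v.name].names
            unknown = refs - known
            if unknown:
                raise SpecError(
                    f"rule for {v.name!r} references unknown name(s): "
                    f"{', '.join(sorted(unknown))}"
                )
            # self-reference is the lag-1 read, not a same-day dependency
            deps[v.name] = (refs & var_names) - {v.name}
        try:
            sorter = graphlib.TopologicalSorter(deps)
            order = list(sorter.static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1][:-1] if len(exc.args) > 1 else []
            raise CycleError(cycle) from None
        # stable: keep spec order among variables at the same dependency depth
        depth: dict[str, int] = {}
        for n in order:
            depth[n] = 1 + max((depth[d] for d in deps[n]), default=0)
        spec_pos = {v.name: i for i, v in enumerate(self.variables)}
        return sorted(order, key=lambda n: (depth[n], spec_pos[n]))

    # -- accessors --------------------------------------------------------

    def variable(self, name: str) -> VariableDef:
        try:
            return self._index[name]
        except KeyError:
            raise LookupError_(f"unknown variable: {name!r}") from None

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def expression(self, name: str) -> Expression:
        return self._expressions[name]

    def runner(self) -> "_CompiledRunner":
        if self._runner is None:
            self._runner = _CompiledRunner(self)
        return self._runner

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parameters": dict(self.parameters),
            "drivers": list(self.drivers),
            "outputs": list(self.outputs),
            "variables": [
                {
                    "name": v.name,
                    "rule": v.rule,
                    "init": v.init,
                    "replaceable": v.replaceable,
                    "is_switch": v.is_switch,
                    "off_value": v.off_value,
                    "tags": list(v.tags),
                }
                for v in self.variables
            ],
        }


def parse_model_spec(text: str) -> ModelSpec:
    """Parse a YAML model document into a validated :class:`ModelSpec`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SpecError(f"model document is not valid YAML: {exc}") from None
    if not isinstance(doc, dict):
        raise SpecError("model document must be a mapping")
    for key in ("variables",):
        if key not in doc:
            raise SpecError(f"model document missing required key {key!r}")
    variables = []
    for entry in doc["variables"]:
        if not isinstance(entry, dict) or "name" not in entry or "rule" not in entry:
            raise SpecError(f"variable entries need 'name' and 'rule': {entry!r}")
        variables.append(
            VariableDef(
                name=str(entry["name"]),
                rule=str(entry["rule"]),
                init=float(entry.get("init", 0.0)),
                replaceable=bool(entry.get("replaceable", True)),
                is_switch=bool(entry.get("is_switch", False)),
                off_value=float(entry.get("off_value", 0.0)),
                tags=tuple(entry.get("tags", ()) or ()),
            )
        )
    return ModelSpec(
        variables=variables,
        parameters=doc.get("parameters", {}) or {},
        drivers=list(doc.get("drivers", ()) or ()),
        outputs=list(doc.get("outputs", ()) or ()),
        name=str(doc.get("name", "model")),
    )


def serialize_model_spec(spec: ModelSpec) -> str:
    """Round-trippable YAML form of a spec."""
    return yaml.safe_dump(spec.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class ReplacementState:
    """Which variables are pinned to constants; empty = full model."""

    constants: dict[str, float] = field(default_factory=dict)

    @property
    def replaced(self) -> frozenset[str]:
        return frozenset(self.constants)

    def validate(self, spec: ModelSpec) -> None:
        for name in self.constants:
            var = spec.variable(name)  # raises LookupError_ if unknown
            if not var.replaceable:
                raise SpecError(f"variable {name!r} is not replaceable")

    @classmethod
    def empty(cls) -> "ReplacementState":
        return cls({})

    def __bool__(self):
        return bool(self.constants)


class Drivers:
    """Per-site daily driver series.

    Built from a long table with columns ``site, day, <stream...>``; day is a
    0-based contiguous integer index from the start of the run.
    """

    def __init__(self, frame: pd.DataFrame):
        if "site" not in frame.columns or "day" not in frame.columns:
            raise SpecError("driver table needs 'site' and 'day' columns")
        self.streams = [c for c in frame.columns if c not in ("site", "day")]
        self.sites: list[str] = []
        self._arrays: dict[str, dict[str, list[float]]] = {}
        self.n_days: dict[str, int] = {}
        for site, grp in frame.groupby("site", sort=False):
            site = str(site)
            grp = grp.sort_values("day")
            days = grp["day"].to_numpy()
            if not np.array_equal(days, np.arange(len(days))):
                raise SpecError(
                    f"driver days for site {site!r} must be contiguous from 0"
                )
            self.sites.append(site)
            self.n_days[site] = len(days)
            # plain lists: fastest scalar indexing in the inner loop
            self._arrays[site] = {
                s: grp[s].astype(float).tolist() for s in self.streams
            }

    def site_arrays(self, site: str) -> dict[str, list[float]]:
        try:
            return self._arrays[site]
        except KeyError:
            raise LookupError_(f"unknown site: {site!r}") from None

    def require(self, streams) -> None:
        missing = set(streams) - set(self.streams)
        if missing:
            raise SpecError(f"driver table missing stream(s): {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            n = self.n_days[site]
            data = {"site": [site] * n, "day": list(range(n))}
            data.update({s: self._arrays[site][s] for s in self.streams})
            rows.append(pd.DataFrame(data))
        return pd.concat(rows, ignore_index=True)


def load_drivers(source) -> Drivers:
    """Build :class:`Drivers` from a DataFrame or a CSV path."""
    if isinstance(source, Drivers):
        return source
    if isinstance(source, pd.DataFrame):
        return Drivers(source)
    return Drivers(pd.read_csv(source))


class TrajectorySet:
    """Simulated series for every variable, per site, plus global ranges."""

    def __init__(self, data: dict[str, dict[str, np.ndarray]]):
        self.data = data
        self.sites = list(data)
        self._ranges: dict[str, tuple[float, float]] | None = None

    def series(self, site: str, name: str) -> np.ndarray:
        try:
            site_data = self.data[site]
        except KeyError:
            raise LookupError_(f"unknown site: {site!r}") from None
        try:
            return site_data[name]
        except KeyError:
            raise LookupError_(f"unknown variable: {name!r}") from None

    def variable_range(self, name: str) -> tuple[float, float]:
        if self._ranges is None:
            self._ranges = {}
            for var in next(iter(self.data.values())):
                lo = min(float(self.data[s][var].min()) for s in self.sites)
                hi = max(float(self.data[s][var].max()) for s in self.sites)
                self._ranges[var] = (lo, hi)
        try:
            return self._ranges[name]
        except KeyError:
            raise LookupError_(f"unknown variable: {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            for var, series in self.data[site].items():
                rows.append(
                    pd.DataFrame(
                        {
                            "site": site,
                            "day": np.arange(len(series)),
                            "variable": var,
                            "value": series,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class _CompiledRunner:
    """Generates and compiles one straight-line Python function per spec.

    The generated function runs a whole site season with parameters baked in
    as literals and replacement flags hoisted out of the day loop, which
    makes repeated model evaluations (screening, MH search) cheap.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        src = ["def _run(_n, _drv, _repl, _con):"]
        for pname, pval in spec.parameters.items():
            src.append(f"    {pname} = {pval!r}")
        for dname in spec.drivers:
            src.append(f"    _d_{dname} = _drv[{dname!r}]")
        for i, vname in enumerate(spec.order):
            var = spec.variable(vname)
            src.append(f"    _r{i} = {vname!r} in _repl")
            src.append(f"    _c{i} = _con.get({vname!r}, 0.0)")
            src.append(f"    {vname} = {float(var.init)!r}")
            src.append(f"    _o{i} = [0.0] * _n")
        src.append("    for _t in _range(_n):")
        for dname in spec.drivers:
            src.append(f"        {dname} = _d_{dname}[_t]")
        for i, vname in enumerate(spec.order):
            rule = spec.expression(vname).source
            src.append(f"        {vname} = _c{i} if _r{i} else ({rule})")
            src.append(f"        _o{i}[_t] = {vname}")
        ret = ", ".join(f"{v!r}: _o{i}" for i, v in enumerate(spec.order))
        src.append("    return {" + ret + "}")
        namespace = dict(EVAL_GLOBALS)
        namespace["_range"] = range
        exec(compile("\n".join(src), f"<model:{spec.name}>", "exec"), namespace)
        self._fn = namespace["_run"]
        self.source = "\n".join(src)

    def run_site(self, n_days, site_arrays, replaced, constants):
        return self._fn(n_days, site_arrays, replaced, constants)


def _diagnose_failure(spec, drivers, state, site) -> SimulationError:
    """Slow per-rule interpreter used only to localise a failed run."""
    arrays = drivers.site_arrays(site)
    n = drivers.n_days[site]
    ns = dict(spec.parameters)
    for v in spec.variables:
        ns[v.name] = float(v.init)
    constants = state.constants
    for t in range(n):
        for dname in spec.drivers:
            ns[dname] = arrays[dname][t]
        # same-day updates land immediately, mirroring the compiled runner:
        # earlier variables expose today's value, later/self reads see lag-1
        for vname in spec.order:
            if vname in constants:
                val = constants[vname]
            else:
                try:
                    val = spec.expression(vname).evaluate(ns)
                except (ZeroDivisionError, ValueError, OverflowError) as exc:
                    return SimulationError(
                        f"rule for {vname!r} failed on day {t} at site "
                        f"{site!r}: {exc}",
                        variable=vname,
                        day=t,
                        site=site,
                    )
            if not math.isfinite(val):
                return SimulationError(
                    f"non-finite value for {vname!r} on day {t} at site {site!r}",
                    variable=vname,
                    day=t,
                    site=site,
                )
            ns[vname] = val
    return SimulationError(f"simulation failed at site {site!r}")


def simulate(spec: ModelSpec, drivers, state: ReplacementState | None = None) -> TrajectorySet:
    """Run the model for every site under a replacement state.

    Replaced variables hold their constant on every day; everything
    downstream sees the constant.  Deterministic: same spec/drivers/state
    gives bit-identical trajectories.

    Raises
    ------
    SimulationError
        If any rule produces a non-finite value, naming variable/day/site.
    """
    drivers = load_drivers(drivers)
    drivers.require(spec.drivers)
    state = state or ReplacementState.empty()
    state.validate(spec)
    runner = spec.runner()
    replaced = frozenset(state.constants)
    constants = {k: float(v) for k, v in state.constants.items()}
    out: dict[str, dict[str, np.ndarray]] = {}
    for site in drivers.sites:
        n = drivers.n_days[site]
        arrays = drivers.site_arrays(site)
        try:
            raw = runner.run_site(n, arrays, replaced, constants)
        except (ZeroDivisionError, ValueError, OverflowError):
            raise _diagnose_failure(spec, drivers, state, site) from None
        site_out = {k: np.asarray(v, dtype=float) for k, v in raw.items()}
        bad_day, bad_var = None, None
        for vname in spec.order:
            finite = np.isfinite(site_out[vname])
            if not finite.all():
                day = int(np.argmin(finite))
                if bad_day is None or day < bad_day:
                    bad_day, bad_var = day, vname
        if bad_var is not None:
            raise SimulationError(
                f"non-finite value for {bad_var!r} on day {bad_day} "
                f"at site {site!r}",
                variable=bad_var,
                day=bad_day,
                site=site,
            )
        out[site] = site_out
    return TrajectorySet(out)


def variable_range(traj: TrajectorySet, name: str) -> tuple[float, float]:
    """Global (min, max) of a simulated variable across all sites."""
    return traj.variable_range(name)


def list_replaceable(spec: ModelSpec, exclusions=()) -> list[str]:
    """Replaceable variables minus exclusions, in spec order."""
    known = set(spec.variable_names)
    unknown = set(exclusions) - known
    if unknown:
        raise LookupError_(f"exclusions name unknown variable(s): {sorted(unknown)}")
    excl = set(exclusions)
    return [v.name for v in spec.variables if v.replaceable and v.name not in excl]
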