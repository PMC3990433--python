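"""Reduction-run configuration: one YAML document drives every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .factorial import DEFAULT_ALPHA_FRACTIONS, DEFAULT_BANDS, SearchSettings
from .screening import DEFAULT_GRID_POINTS, DEFAULT_THRESHOLD

__all__ = ["ReductionConfig", "ScreeningSettings", "ReportSettings"]


@dataclass(frozen=True)
class ScreeningSettings:
    threshold: float = DEFAULT_THRESHOLD
    grid_points: int = DEFAULT_GRID_POINTS

    def validate(self):
        if self.threshold <= 0:
            raise ConfigError(f"screening.threshold must be > 0: {self.threshold}")
        if self.grid_points < 2:
            raise ConfigError(f"screening.grid_points must be >= 2: {self.grid_points}")


@dataclass(frozen=True)
class ReportSettings:
    bands: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    trace_interval: int = 100

    def validate(self):
        if set(self.bands) != {"noise", "contributing"}:
            raise ConfigError("report.bands needs exactly 'noise' and 'contributing'")
        if not 0 < self.bands["contributing"] <= self.bands["noise"] < 1:
            raise ConfigError(f"report.bands out of order: {self.bands}")
        if self.trace_interval < 1:
            raise ConfigError("report.trace_interval must be >= 1")


@dataclass(frozen=True)
class ReductionConfig:
    """Paths plus per-stage settings for a full reduction analysis."""

    model_path: Path
    drivers_path: Path
    observations_path: Path
    output_dir: Path
    se_fractions: dict[str, float] = field(default_factory=dict)
    exclusions: tuple[str, ...] = ()
    screening: ScreeningSettings = field(default_factory=ScreeningSettings)
    search: SearchSettings = field(default_factory=SearchSettings)
    report: ReportSettings = field(default_factory=ReportSettings)

    def validate(self, check_paths: bool = True) -> None:
        if check_paths:
            for label, p in (
                ("model", self.model_path),
                ("drivers", self.drivers_path),
                ("observations", self.observations_path),
            ):
                if not Path(p).exists():
                    raise ConfigError(f"{label} file does not exist: {p}")
        if not self.se_fractions:
            raise ConfigError("se_fractions must map every observed stream")
        for s, f in self.se_fractions.items():
            if not 0 < f <= 1:
                raise ConfigError(f"se fraction for {s!r} must be in (0, 1]: {f}")
        self.screening.validate()
        self.report.validate()
        if self.search.n_unique < 1:
            raise ConfigError("search.n_unique must be >= 1")

    def with_overrides(self, **kwargs) -> "ReductionConfig":
        """Copy with selected fields replaced (CLI flag overrides)."""
        search_over = {
            k: v for k, v in kwargs.items() if k in ("seed", "n_unique") and v is not None
        }
        cfg = self
        if search_over:
            cfg = replace(cfg, search=replace(cfg.search, **search_over))
        if kwargs.get("output_dir") is not None:
            cfg = replace(cfg, output_dir=Path(kwargs["output_dir"]))
        return cfg

    @classmethod
    def from_dict(cls, doc: dict, base_dir: Path | str = ".") -> "ReductionConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        base = Path(base_dir)

        def _path(key):
            if key not in doc:
                raise ConfigError(f"config missing required key {key!r}")
            return base / str(doc[key])

        known = {
            "model",
            "drivers",
            "observations",
            "output_dir",
            "se_fractions",
            "exclusions",
            "screening",
            "search",
            "report",
        }
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        scr = doc.get("screening", {}) or {}
        sea = doc.get("search", {}) or {}
        rep = doc.get("report", {}) or {}
        try:
            screening = ScreeningSettings(**scr)
            search = SearchSettings(
                **{
                    **sea,
                    "alpha_fractions": tuple(
                        sea.get("alpha_fractions", DEFAULT_ALPHA_FRACTIONS)
                    ),
                }
            )
            report = ReportSettings(**rep)
        except TypeError as exc:
            raise ConfigError(f"bad stage settings: {exc}") from None
        cfg = cls(
            model_path=_path("model"),
            drivers_path=_path("drivers"),
            observations_path=_path("observations"),
            output_dir=base / str(doc.get("output_dir", "reports")),
            se_fractions={
                str(k): float(v) for k, v in (doc.get("se_fractions") or {}).items()
            },
            exclusions=tuple(doc.get("exclusions", ()) or ()),
            screening=screening,
            search=search,
            report=report,
        )
        cfg.validate(check_paths=False)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ReductionConfig":
        path = Path(path)
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from None
        return cls.from_dict(doc, base_dir=path.parent)

    def to_dict(self) -> dict:
        return {
            "model": str(self.model_path),
            "drivers": str(self.drivers_path),
            "observations": str(self.observations_path),
            "output_dir": str(self.output_dir),
            "se_fractions": dict(self.se_fractions),
            "exclusions": list(self.exclusions),
            "screening": {
                "threshold": self.screening.threshold,
                "grid_points": self.screening.grid_points,
            },
            "search": {
                "n_unique": self.search.n_unique,
                "flips": self.search.flips,
                "alpha_fractions": list(self.search.alpha_fractions),
                "driving_alpha_index": self.search.driving_alpha_index,
                "seed": self.search.seed,
                "max_iterations": self.search.max_iterations,
                "stall_limit": self.search.stall_limit,
            },
            "report": {
                "bands": dict(self.report.bands),
                "trace_interval": self.report.trace_interval,
            },
        }
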