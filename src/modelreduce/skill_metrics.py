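"""Model skill: weighted RSS, Nash-Sutcliffe efficiency and pseudo-likelihood.

Residuals are standardised by per-observation standard errors taken as a
fixed fraction of the observed value (stream-specific fractions, e.g. 10%
for biomass and grain, 20% for leaf area index).  Belief in a reduced model
is expressed by an informal pseudo-likelihood that halves for every ``alpha``
of weighted RSS above the full model's RSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateDataError,
    LookupError_,
    ParameterError,
)
from .model_core import TrajectorySet

__all__ = [
    "ObservationSet",
    "SkillSummary",
    "weighted_rss",
    "nash_sutcliffe",
    "pseudo_likelihood",
    "normalize_q",
    "skill_summary",
]

#: Fraction of the stream's mean observed value used to floor O_j before the
#: fractional standard error is applied, so zero observations keep s_j > 0.
SE_FLOOR_FRACTION = 0.01


class ObservationSet:
    """Observed stream values with per-point fractional standard errors.

    Parameters
    ----------
    frame:
        Long table with columns ``stream, site, day, value``.
    se_fractions:
        Mapping stream name -> fractional standard error (e.g. 0.10).
        Ignored for records where the table carries an explicit ``s`` column
        (useful when per-point standard errors are known directly).
    """

    def __init__(self, frame: pd.DataFrame, se_fractions: dict[str, float]):
        needed = {"stream", "site", "day", "value"}
        missing = needed - set(frame.columns)
        if missing:
            raise ParameterError(f"observation table missing columns: {sorted(missing)}")
        frame = frame.reset_index(drop=True).copy()
        frame["site"] = frame["site"].astype(str)
        frame["stream"] = frame["stream"].astype(str)
        streams = set(frame["stream"])
        if "s" not in frame.columns:
            missing_frac = streams - set(se_fractions)
            if missing_frac:
                raise ParameterError(
                    f"no standard-error fraction for stream(s): {sorted(missing_frac)}"
                )
        for s, f in se_fractions.items():
            if not 0 < f <= 1:
                raise ParameterError(f"se fraction for {s!r} must be in (0, 1]: {f}")
        self.se_fractions = dict(se_fractions)
        if "s" in frame.columns:
            s = frame["s"].to_numpy(dtype=float)
            if np.any(s <= 0) or not np.all(np.isfinite(s)):
                raise ParameterError("explicit 's' column must be positive and finite")
        else:
            # s_j = fraction * max(O_j, floor), floor = 1% of the stream mean,
            # so zero-valued observations do not produce zero standard errors
            s = np.empty(len(frame), dtype=float)
            for stream, grp in frame.groupby("stream"):
                vals = grp["value"].to_numpy(dtype=float)
                floor = SE_FLOOR_FRACTION * float(np.mean(np.abs(vals)))
                if floor <= 0.0:
                    floor = SE_FLOOR_FRACTION
                s[grp.index.to_numpy()] = self.se_fractions[str(stream)] * np.maximum(
                    np.abs(vals), floor
                )
        frame["s"] = s
        self.frame = frame
        # pre-grouped index for fast repeated RSS evaluation
        self._groups: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray]] = []
        for (site, stream), grp in frame.groupby(["site", "stream"], sort=False):
            self._groups.append(
                (
                    str(site),
                    str(stream),
                    grp["day"].to_numpy(dtype=int),
                    grp["value"].to_numpy(dtype=float),
                    grp["s"].to_numpy(dtype=float),
                )
            )

    def __len__(self):
        return len(self.frame)

    @property
    def streams(self) -> list[str]:
        return sorted(set(self.frame["stream"]))

    def residuals(self, traj: TrajectorySet, stream: str | None = None) -> pd.DataFrame:
        """Standardised residual table ``(O - M)/s`` for matched records."""
        rows = []
        for site, strm, days, obs, s in self._groups:
            if stream is not None and strm != stream:
                continue
            try:
                series = traj.series(site, strm)
            except LookupError_ as exc:
                raise CoverageError(
                    f"no prediction for stream {strm!r} at site {site!r}: {exc}"
                ) from None
            if days.max(initial=-1) >= len(series) or days.min(initial=0) < 0:
                bad = days[(days >= len(series)) | (days < 0)]
                raise CoverageError(
                    f"observation day(s) {bad.tolist()} outside the simulated "
                    f"season for stream {strm!r} at site {site!r}"
                )
            pred = series[days]
            rows.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "stream": strm,
                        "day": days,
                        "observed": obs,
                        "predicted": pred,
                        "s": s,
                        "z": (obs - pred) / s,
                    }
                )
            )
        if not rows:
            raise CoverageError(
                f"no observations in scope (stream={stream!r})"
            )
        return pd.concat(rows, ignore_index=True)


def weighted_rss(obs: ObservationSet, traj: TrajectorySet, stream: str | None = None) -> float:
    """Sum of squared standardised residuals ``sum(((O-M)/s)^2)``."""
    total = 0.0
    matched = False
    for site, strm, days, o, s in obs._groups:
        if stream is not None and strm != stream:
            continue
        matched = True
        try:
            series = traj.series(site, strm)
        except LookupError_ as exc:
            raise CoverageError(
                f"no prediction for stream {strm!r} at site {site!r}: {exc}"
            ) from None
        if len(days) and (days.max() >= len(series) or days.min() < 0):
            raise CoverageError(
                f"observation days outside simulated season for {strm!r} "
                f"at site {site!r}"
            )
        z = (o - series[days]) / s
        total += float(np.dot(z, z))
    if not matched:
        raise CoverageError(f"no observations in scope (stream={stream!r})")
    return total


def nash_sutcliffe(obs: ObservationSet, traj: TrajectorySet, stream: str | None = None) -> float:
    """Weighted Nash-Sutcliffe efficiency.

    ``NS = 1 - sum(((O-M)/s)^2) / sum(((O-Obar)/s)^2)`` where ``Obar`` is the
    unweighted mean of the observations in scope.  When pooling across
    streams each deviation is taken from its own stream's mean, so streams
    with different magnitudes stay commensurate.  NS <= 1 and can be
    negative for a model worse than the mean predictor.
    """
    res = obs.residuals(traj, stream=stream)
    num = float(np.sum(res["z"] ** 2))
    den = 0.0
    for _, grp in res.groupby("stream"):
        o = grp["observed"].to_numpy()
        s = grp["s"].to_numpy()
        obar = float(np.mean(o))
        den += float(np.sum(((o - obar) / s) ** 2))
    if den == 0.0:
        raise DegenerateDataError(
            f"all observed values identical in scope (stream={stream!r}); "
            "Nash-Sutcliffe undefined"
        )
    return 1.0 - num / den


def pseudo_likelihood(rss_i: float, rss_full: float, alpha: float) -> float:
    """Unnormalised pseudo-likelihood of a reduced model.

    ``q = exp(-ln(0.5) * (rss_full - rss_i) / alpha)``: equals 1 when the
    reduced model matches the full model's RSS and halves for every ``alpha``
    of RSS above it (models that *improve* on the full model score above 1).
    The normalisation constant is applied separately by :func:`normalize_q`
    and cancels wherever only ratios matter.
    """
    if alpha <= 0:
        raise ParameterError(f"alpha must be positive: {alpha}")
    exponent = -math.log(0.5) * (rss_full - rss_i) / alpha
    if exponent > 700.0:  # avoid float overflow for absurdly good fits
        return math.inf
    return math.exp(exponent)


def normalize_q(values) -> np.ndarray:
    """Scale positive pseudo-likelihoods so they sum to exactly one."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot normalise an empty set of pseudo-likelihoods")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ParameterError("pseudo-likelihoods must be finite and non-negative")
    total = arr.sum()
    if total <= 0:
        raise ParameterError("pseudo-likelihoods sum to zero; cannot normalise")
    return arr / total


@dataclass(frozen=True)
class SkillSummary:
    """Per-stream and pooled skill of one model variant."""

    rss: float
    ns: float
    per_stream: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stream": s, "rss": v["rss"], "ns": v["ns"]}
            for s, v in self.per_stream.items()
        ]
        rows.append({"stream": "pooled", "rss": self.rss, "ns": self.ns})
        return pd.DataFrame(rows)


def skill_summary(obs: ObservationSet, traj: TrajectorySet) -> SkillSummary:
    """RSS and NS per stream plus pooled, for reporting."""
    per_stream = {}
    for stream in obs.streams:
        per_stream[stream] = {
            "rss": weighted_rss(obs, traj, stream=stream),
            "ns": nash_sutcliffe(obs, traj, stream=stream),
        }
    return SkillSummary(
        rss=weighted_rss(obs, traj),
        ns=nash_sutcliffe(obs, traj),
        per_stream=per_stream,
    )
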