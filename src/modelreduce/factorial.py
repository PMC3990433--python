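"""Multi-factorial exploration of the replacement space.

Every combination of candidate replacements is a bitmask over the candidate
order.  A Metropolis-Hastings walk flips a fixed number of candidate states
per iteration (default one) and accepts a trial whenever the ratio of
pseudo-likelihoods exceeds a fresh uniform draw.  Because the proposal is
symmetric no Hastings correction is needed.  Every evaluated combination is
cached by bitmask, so revisits are free; all probability tables are
q-weighted sums over the *unique* cached models, not over chain visits.

For small candidate sets :func:`exhaustive_enumeration` evaluates all
``2^N`` combinations and serves as the exact reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SimulationError
from .model_core import ModelSpec, ReplacementState, simulate
from .screening import CandidateSet
from .skill_metrics import ObservationSet, pseudo_likelihood, weighted_rss

__all__ = [
    "SearchSettings",
    "EvaluatedModel",
    "SearchResult",
    "mh_search",
    "exhaustive_enumeration",
    "replacement_probabilities",
    "joint_probabilities",
    "convergence_trace",
    "classify",
    "accept_step",
    "DEFAULT_BANDS",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHA_FRACTIONS = (0.025, 0.05, 0.10)

#: Reporting bands anchored at the verbal interpretation: probability near 1
#: marks a noise variable, near 0.5 a redundant one, near 0 a contributing
#: one.  Configurable; these are the defaults.
DEFAULT_BANDS = {"noise": 0.6, "contributing": 0.4}


@dataclass(frozen=True)
class SearchSettings:
    """Knobs of the factorial search."""

    n_unique: int = 10_000
    flips: int = 1
    alpha_fractions: tuple[float, ...] = DEFAULT_ALPHA_FRACTIONS
    driving_alpha_index: int = 1
    seed: int = 0
    max_iterations: int = 2_000_000
    stall_limit: int = 20_000

    def __post_init__(self):
        if self.n_unique < 1:
            raise ParameterError("n_unique must be >= 1")
        if self.flips < 1:
            raise ParameterError("flips must be >= 1")
        if not self.alpha_fractions:
            raise ParameterError("need at least one alpha fraction")
        if not 0 <= self.driving_alpha_index < len(self.alpha_fractions):
            raise ParameterError("driving_alpha_index out of range")


@dataclass(frozen=True)
class EvaluatedModel:
    """One unique replacement combination and its score."""

    key: int
    rss: float
    q: dict[float, float]  # alpha fraction -> unnormalised pseudo-likelihood


@dataclass
class SearchResult:
    """All unique evaluated models plus chain metadata."""

    candidates: CandidateSet
    order: list[int]  # bitmask keys in discovery order
    rss: dict[int, float]  # bitmask -> weighted RSS (inf = failed run)
    chain: list[int]  # accepted bitmasks, starts at 0 (all-normal)
    rss_full: float
    settings: SearchSettings | None
    termination: str  # 'target' | 'exhausted' | 'stalled' | 'max_iterations'
    n_iterations: int

    @property
    def n_unique(self) -> int:
        return len(self.order)

    def state_for(self, key: int) -> ReplacementState:
        return _state_for(key, self.candidates)

    def models(self, alpha_fractions=DEFAULT_ALPHA_FRACTIONS) -> list[EvaluatedModel]:
        out = []
        for key in self.order:
            rss = self.rss[key]
            q = {
                f: _q_of(rss, self.rss_full, f * self.rss_full)
                for f in alpha_fractions
            }
            out.append(EvaluatedModel(key=key, rss=rss, q=q))
        return out


def _state_for(key: int, candidates: CandidateSet) -> ReplacementState:
    constants = {
        name: candidates.constants[name]
        for i, name in enumerate(candidates.names)
        if key >> i & 1
    }
    return ReplacementState(constants)


def _q_of(rss_i: float, rss_full: float, alpha: float) -> float:
    """Pseudo-likelihood with failed runs (inf RSS) pinned to zero weight."""
    if not math.isfinite(rss_i):
        return 0.0
    return pseudo_likelihood(rss_i, rss_full, alpha)


def _evaluate(spec, drivers, obs, candidates, key) -> float:
    try:
        traj = simulate(spec, drivers, _state_for(key, candidates))
    except SimulationError:
        return math.inf
    return weighted_rss(obs, traj)


def accept_step(q_trial: float, q_current: float, r: float) -> bool:
    """Acceptance rule: take the trial state iff q_trial/q_current > r."""
    if q_current <= 0.0:
        return q_trial > 0.0
    return q_trial / q_current > r


def mh_search(
    spec: ModelSpec,
    drivers,
    obs: ObservationSet,
    candidates: CandidateSet,
    settings: SearchSettings,
) -> SearchResult:
    """Metropolis-Hastings walk over replacement combinations.

    Starts from the all-normal (full) model.  Runs until the unique-model
    cache reaches ``min(n_unique, 2^N)`` or the walk stalls (no new unique
    model for ``stall_limit`` iterations, which happens when the reachable
    region is smaller than the budget) or ``max_iterations`` is hit.
    Reproducible from the seed.
    """
    n = len(candidates)
    if n == 0:
        raise ParameterError("candidate set is empty")
    rng = np.random.default_rng(settings.seed)
    target = min(settings.n_unique, 2**n)
    alpha_fraction = settings.alpha_fractions[settings.driving_alpha_index]

    rss_full = _evaluate(spec, drivers, obs, candidates, 0)
    if not math.isfinite(rss_full):
        raise SimulationError("full model failed to simulate")
    alpha = alpha_fraction * rss_full

    rss_cache: dict[int, float] = {0: rss_full}
    order = [0]
    chain = [0]
    current = 0
    q_current = 1.0
    termination = "target" if target == 1 else None
    iters = 0
    stall = 0
    while termination is None:
        iters += 1
        if iters > settings.max_iterations:
            termination = "max_iterations"
            break
        flips = rng.choice(n, size=settings.flips, replace=False)
        trial = current
        for pos in flips:
            trial ^= 1 << int(pos)
        if trial in rss_cache:
            stall += 1
            rss_trial = rss_cache[trial]
        else:
            rss_trial = _evaluate(spec, drivers, obs, candidates, trial)
            rss_cache[trial] = rss_trial
            order.append(trial)
            stall = 0
        q_trial = _q_of(rss_trial, rss_full, alpha)
        if accept_step(q_trial, q_current, float(rng.random())):
            current = trial
            q_current = q_trial
            chain.append(trial)
        if len(order) >= target:
            termination = "exhausted" if target == 2**n else "target"
        elif stall >= settings.stall_limit:
            termination = "stalled"
    log.info(
        "MH search: %d unique models, %d iterations, %d accepted steps (%s)",
        len(order),
        iters,
        len(chain) - 1,
        termination,
    )
    return SearchResult(
        candidates=candidates,
        order=order,
        rss=rss_cache,
        chain=chain,
        rss_full=rss_full,
        settings=settings,
        termination=termination,
        n_iterations=iters,
    )


def exhaustive_enumeration(
    spec: ModelSpec,
    drivers,
    obs: ObservationSet,
    candidates: CandidateSet,
    cap: int = 15,
) -> SearchResult:
    """Evaluate every one of the 2^N combinations (small-N exact reference)."""
    n = len(candidates)
    if n == 0:
        raise ParameterError("candidate set is empty")
    if n > cap:
        raise ParameterError(
            f"{n} candidates means 2^{n} combinations; refusing above cap={cap}"
        )
    rss_cache = {}
    order = list(range(2**n))
    for key in order:
        rss_cache[key] = _evaluate(spec, drivers, obs, candidates, key)
    rss_full = rss_cache[0]
    if not math.isfinite(rss_full):
        raise SimulationError("full model failed to simulate")
    return SearchResult(
        candidates=candidates,
        order=order,
        rss=rss_cache,
        chain=[0],
        rss_full=rss_full,
        settings=None,
        termination="exhaustive",
        n_iterations=2**n,
    )


def _weights(result: SearchResult, alpha_fraction: float, upto: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Normalised pseudo-likelihood per unique model (optionally a prefix)."""
    keys = np.asarray(result.order[:upto] if upto is not None else result.order)
    alpha = alpha_fraction * result.rss_full
    q = np.array([_q_of(result.rss[int(k)], result.rss_full, alpha) for k in keys])
    total = q.sum()
    if total <= 0:
        raise ParameterError("all pseudo-likelihoods are zero")
    return keys, q / total


def replacement_probabilities(
    result: SearchResult,
    alpha_fractions=DEFAULT_ALPHA_FRACTIONS,
) -> pd.DataFrame:
    """Per-variable replacement probability for each alpha.

    For each alpha the unnormalised pseudo-likelihoods of all unique models
    are normalised to one; a variable's probability is the summed weight of
    the models in which it is replaced.
    """
    names = result.candidates.names
    data = {"variable": list(names)}
    for frac in alpha_fractions:
        keys, w = _weights(result, frac)
        probs = []
        for i in range(len(names)):
            mask = (keys >> i & 1).astype(bool)
            probs.append(float(w[mask].sum()))
        data[f"p_alpha_{frac:g}"] = probs
    return pd.DataFrame(data)


def joint_probabilities(
    result: SearchResult,
    alpha_fraction: float = 0.05,
) -> pd.DataFrame:
    """Pairwise joint replacement probabilities and independence ratios.

    ``ratio = P(A and B) / (P(A) P(B))``; below one the two replacements
    tend to exclude each other (an either/or redundancy), above one they
    travel together.
    """
    names = result.candidates.names
    if len(names) < 2:
        raise ParameterError("need at least two candidates for joint table")
    keys, w = _weights(result, alpha_fraction)
    marg = {
        i: float(w[(keys >> i & 1).astype(bool)].sum()) for i in range(len(names))
    }
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            both = ((keys >> i & 1) & (keys >> j & 1)).astype(bool)
            p_joint = float(w[both].sum())
            denom = marg[i] * marg[j]
            rows.append(
                {
                    "var_a": names[i],
                    "var_b": names[j],
                    "p_a": marg[i],
                    "p_b": marg[j],
                    "p_joint": p_joint,
                    "independence_ratio": p_joint / denom if denom > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def convergence_trace(
    result: SearchResult,
    interval: int = 100,
    alpha_fraction: float = 0.05,
) -> pd.DataFrame:
    """Replacement probabilities recomputed over the growing unique cache.

    One block every ``interval`` unique evaluations (plus the final full
    cache), so stabilisation can be checked by inspection; the last block
    equals the full-table values.
    """
    if interval < 1:
        raise ParameterError("interval must be >= 1")
    names = result.candidates.names
    counts = list(range(interval, result.n_unique, interval)) + [result.n_unique]
    rows = []
    for upto in counts:
        keys, w = _weights(result, alpha_fraction, upto=upto)
        for i, name in enumerate(names):
            mask = (keys >> i & 1).astype(bool)
            rows.append(
                {
                    "unique_count": upto,
                    "variable": name,
                    "probability": float(w[mask].sum()),
                }
            )
    return pd.DataFrame(rows)


def classify(probability: float, bands: dict[str, float] | None = None) -> str:
    """Label a replacement probability as noise / redundant / contributing."""
    bands = bands or DEFAULT_BANDS
    if probability >= bands["noise"]:
        return "noise"
    if probability <= bands["contributing"]:
        return "contributing"
    return "redundant"
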