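"""Replicated trial experiments comparing removal policies.

Each experiment simulates many independent trials, applies both the
sensitivity-guided (proposed) and the random removal policy to *identical*
trajectories (paired replication: both policies share the per-replicate
simulation seed and diverge only in whom they remove), analyses the final
outcomes with the matched-pair posterior, and compares the across-replicate
spread of the maximum-a-posteriori differential-effect estimates.

The headline statistic is the percent reduction in the standard deviation of
the MAP estimate achieved by the proposed policy relative to the random
baseline, ``100 * (1 - sd_proposed / sd_random)``.

Shipped experiment designs (removal always from a 180-participant cohort,
phi = 0.01 and k_max = 100 unless stated):

1. single removal of n=70 at k=50, pre-removal data kept;
2. removal of n=50 at k in {30, 50, 70};
3. removal of n in {30, 50, 70} at k=50;
4. removal of n=50 at k=50 for phi in {0.005, 0.01, 0.02};
5. sequential design: one participant removed per step for the first 120
   steps of a k_max=150 trial, with ALL data of removed participants
   discarded, tracking the MAP estimate and sub-group sizes per step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._errors import AdaptationExhaustedError, AnalysisError, ConfigurationError
from .adaptation import RemovalPolicy, matched_pairs_at, remove_participants
from .posterior import posterior_differential
from .simulate import (
    TrialConfig,
    TrialState,
    ground_truth_differential,
    init_trial,
    run_to,
    stratify,
)

__all__ = [
    "ExperimentSpec",
    "ReplicateResult",
    "ExperimentResult",
    "experiment_spec",
    "run_replicate",
    "run_experiment",
    "run_sequential_replicate",
    "stddev_reduction",
]

DataPolicy = Literal["keep_pre_removal", "discard_removed"]


@dataclass(frozen=True)
class ExperimentSpec:
    """Settings of one experiment condition."""

    experiment: int
    n_replicates: int = 100
    removal_step: int = 50
    n_removed: int = 70
    phi: float = 0.01
    k_max: int = 100
    data_policy: DataPolicy = "keep_pre_removal"
    seed: int = 0
    sequential: bool = False
    removal_start: int = 1        # sequential design: first removal step
    max_removals: int = 120       # sequential design: total removals
    grid_points: int = 2001

    def __post_init__(self) -> None:
        if not self.sequential:
            if not 0 < self.removal_step <= self.k_max:
                raise ConfigurationError("removal_step must lie in (0, k_max]")
            if self.n_removed < 0:
                raise ConfigurationError("n_removed must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    def trial_config(self, seed: int) -> TrialConfig:
        return TrialConfig(phi=self.phi, k_max=self.k_max, seed=seed)


def experiment_spec(experiment: int, **overrides) -> list[ExperimentSpec]:
    """The shipped experiment designs, one spec per condition."""
    base = dict(n_replicates=100, phi=0.01, k_max=100, seed=0)
    base.update(overrides)
    if experiment == 1:
        return [ExperimentSpec(1, removal_step=50, n_removed=70, **base)]
    if experiment == 2:
        return [
            ExperimentSpec(2, removal_step=k, n_removed=50, **base)
            for k in (30, 50, 70)
        ]
    if experiment == 3:
        return [
            ExperimentSpec(3, removal_step=50, n_removed=n, **base)
            for n in (30, 50, 70)
        ]
    if experiment == 4:
        phis = (0.005, 0.01, 0.02)
        base.pop("phi", None)
        return [
            ExperimentSpec(4, removal_step=50, n_removed=50, phi=phi, **base)
            for phi in phis
        ]
    if experiment == 5:
        base.setdefault("k_max", 150)
        base["k_max"] = overrides.get("k_max", 150)
        return [
            ExperimentSpec(
                5,
                sequential=True,
                data_policy="discard_removed",
                n_removed=0,
                removal_step=1,
                **base,
            )
        ]
    raise ConfigurationError(f"unknown experiment id {experiment}")


@dataclass(frozen=True)
class ReplicateResult:
    replicate: int
    policy: str
    map_estimate: float
    posterior_sd: float
    ground_truth: float
    n_pairs_used: int
    failed: bool = False

    @property
    def error(self) -> float:
        return self.map_estimate - self.ground_truth


def _derived_seeds(master: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds below 2**31."""
    return np.random.SeedSequence(master).generate_state(n, dtype=np.uint32) % (2**31)


def _final_pairs(state: TrialState, spec: ExperimentSpec):
    """Matched pairs for the final analysis under the spec's data policy."""
    if spec.data_policy == "keep_pre_removal":
        # Removed participants contribute their last observed outcome and
        # stratify by their last observed questionnaire response.
        return matched_pairs_at(state, include_removed=True)
    return matched_pairs_at(state, include_removed=False)


def run_replicate(
    spec: ExperimentSpec, policy_kind: str, replicate_seed: int
) -> ReplicateResult:
    """Simulate one trial, apply one policy, analyse the final outcomes."""
    sim_seed, rem_seed = (int(s) for s in _derived_seeds(replicate_seed, 2))
    # Removal randomness differs per policy so the two arms of the paired
    # comparison diverge only at removal, not in the simulated trajectories.
    offset = 0 if policy_kind == "proposed" else 1
    cfg = spec.trial_config(sim_seed)
    state = run_to(init_trial(cfg), spec.removal_step)
    policy = RemovalPolicy(policy_kind, seed=rem_seed + offset)
    if spec.n_removed > 0:
        state, _ = remove_participants(state, spec.n_removed, policy)
    run_to(state, spec.k_max)
    truth = ground_truth_differential(spec.k_max, cfg)
    pairs = list(_final_pairs(state, spec).values())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = posterior_differential(pairs, grid_points=spec.grid_points)
    except AnalysisError:
        return ReplicateResult(
            replicate=-1, policy=policy_kind, map_estimate=math.nan,
            posterior_sd=math.nan, ground_truth=truth, n_pairs_used=0, failed=True,
        )
    return ReplicateResult(
        replicate=-1,
        policy=policy_kind,
        map_estimate=post.map_estimate,
        posterior_sd=post.sd,
        ground_truth=truth,
        n_pairs_used=len(post.weights or {}),
    )


def stddev_reduction(
    proposed: Sequence[float], random: Sequence[float]
) -> float:
    """Percent reduction of across-replicate sd relative to the baseline:
    ``100 * (1 - sd(proposed) / sd(random))``."""
    p = np.asarray(proposed, dtype=float)
    r = np.asarray(random, dtype=float)
    if len(p) < 2 or len(r) < 2:
        raise ValueError("need at least 2 results per policy")
    sd_r = float(np.std(r, ddof=1))
    if sd_r == 0:
        raise ZeroDivisionError("baseline standard deviation is zero")
    return 100.0 * (1.0 - float(np.std(p, ddof=1)) / sd_r)


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    replicates: pd.DataFrame          # one row per (replicate, policy)
    summary: dict

    def maps(self, policy: str) -> np.ndarray:
        df = self.replicates
        sel = df[(df["policy"] == policy) & (~df["failed"])]
        return sel["map_estimate"].to_numpy()


def run_experiment(spec: ExperimentSpec, progress: bool = False) -> ExperimentResult:
    """Run all paired replicates of one condition and summarise."""
    seeds = _derived_seeds(spec.seed, spec.n_replicates)
    rows = []
    for i, rep_seed in enumerate(seeds):
        for policy in ("proposed", "random"):
            if spec.sequential:
                traj = run_sequential_replicate(spec, policy, int(rep_seed))
                final = traj.iloc[-1]
                res = ReplicateResult(
                    replicate=i, policy=policy,
                    map_estimate=float(final["map"]),
                    posterior_sd=float(final["posterior_sd"]),
                    ground_truth=float(final["ground_truth"]),
                    n_pairs_used=int(final["n_pairs"]),
                    failed=bool(np.isnan(final["map"])),
                )
            else:
                res = run_replicate(spec, policy, int(rep_seed))
            rows.append(
                {
                    "replicate": i,
                    "policy": policy,
                    "map_estimate": res.map_estimate,
                    "posterior_sd": res.posterior_sd,
                    "ground_truth": res.ground_truth,
                    "error": res.error,
                    "n_pairs": res.n_pairs_used,
                    "failed": res.failed,
                }
            )
        if progress:
            print(f"replicate {i + 1}/{spec.n_replicates} done", flush=True)
    df = pd.DataFrame(rows)
    result = ExperimentResult(spec=spec, replicates=df, summary={})
    truth = float(df["ground_truth"].iloc[0])
    summary: dict = {
        "experiment": spec.experiment,
        "removal_step": spec.removal_step,
        "n_removed": spec.n_removed if not spec.sequential else spec.max_removals,
        "phi": spec.phi,
        "n_replicates": spec.n_replicates,
        "ground_truth": truth,
    }
    for policy in ("proposed", "random"):
        ok = df[(df["policy"] == policy) & (~df["failed"])]
        summary[policy] = {
            "n_ok": int(len(ok)),
            "n_failed": int(spec.n_replicates - len(ok)),
            "mean_map": float(ok["map_estimate"].mean()),
            "sd_map": float(ok["map_estimate"].std(ddof=1)),
            "mean_error": float(ok["error"].mean()),
            "relative_error_pct": float(
                abs(ok["map_estimate"].mean() - truth) / abs(truth) * 100.0
            ),
        }
    try:
        summary["stddev_reduction_pct"] = stddev_reduction(
            result.maps("proposed"), result.maps("random")
        )
    except (ValueError, ZeroDivisionError) as err:
        summary["stddev_reduction_pct"] = None
        summary["stddev_reduction_undefined"] = str(err)
    result.summary = summary
    return result


def run_sequential_replicate(
    spec: ExperimentSpec, policy_kind: str, replicate_seed: int
) -> pd.DataFrame:
    """One replicate of the sequential design (one removal per step).

    Returns a per-step table: MAP estimate (from currently active
    participants only, since removed data is discarded), ground truth,
    active count and the six sub-group sizes.
    """
    sim_seed, rem_seed = (int(s) for s in _derived_seeds(replicate_seed, 2))
    offset = 0 if policy_kind == "proposed" else 1
    cfg = spec.trial_config(sim_seed)
    state = init_trial(cfg)
    policy = RemovalPolicy(policy_kind, seed=rem_seed + offset)
    rng = policy.rng()
    removed = 0
    rows = []
    for k in range(1, spec.k_max + 1):
        run_to(state, k)
        if removed < spec.max_removals and k >= spec.removal_start:
            try:
                state, _ = remove_participants(state, 1, policy, rng=rng)
                removed += 1
            except AdaptationExhaustedError:
                pass
        pairs = list(matched_pairs_at(state, include_removed=False).values())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                post = posterior_differential(pairs, grid_points=spec.grid_points)
            mp, sd, npairs = post.map_estimate, post.sd, len(post.weights or {})
        except AnalysisError:
            mp, sd, npairs = math.nan, math.nan, 0
        sizes = {
            key.label: len(v) for key, v in stratify(state).items()
        }
        rows.append(
            {
                "step": k,
                "policy": policy_kind,
                "map": mp,
                "posterior_sd": sd,
                "ground_truth": ground_truth_differential(k, cfg),
                "n_active": int(state.active.sum()),
                "n_removed": removed,
                "n_pairs": npairs,
                **sizes,
            }
        )
    return pd.DataFrame(rows)
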