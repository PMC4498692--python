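"""Sequential sample-size reduction.

The proposed policy removes one participant at a time: stratify the active
cohort, form the matched control/treatment pair for each questionnaire tier,
compute the expected sensitivity of each eligible pair's superiority
probability to each of its two sides, and remove a uniformly random member
of the sub-group with the smallest |sensitivity| -- the sub-group whose
shrinkage perturbs the evidence least.  Sensitivities are recomputed from
scratch after every removal, because they depend on the current sizes.
Within the chosen sub-group outcomes are exchangeable, so the victim is
drawn uniformly.  The random baseline removes uniformly from the whole
active cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._errors import AdaptationExhaustedError
from .posterior import MatchedPair, make_sample
from .sensitivity import SensitivityEstimate, expected_sensitivity
from .simulate import ALL_SUBGROUPS, CONTROL, SubGroupKey, TrialState, stratify

__all__ = [
    "RemovalPolicy",
    "RemovalEvent",
    "RemovalLog",
    "matched_pairs_at",
    "choose_target_subgroup",
    "remove_participants",
]


@dataclass(frozen=True)
class RemovalPolicy:
    """How participants are selected for removal.

    ``proposed`` ranks sub-groups by sensitivity; ``random`` ignores strata.
    ``min_subgroup_size`` is the smallest size at which a sub-group may still
    lose members (its matched partner must also be at least this large); the
    sensitivity machinery additionally needs three observations per side, so
    the effective floor is max(min_subgroup_size, 3).
    """

    kind: Literal["proposed", "random"] = "proposed"
    seed: int = 0
    min_subgroup_size: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("proposed", "random"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.min_subgroup_size < 2:
            raise ValueError("min_subgroup_size must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class RemovalEvent:
    """One logged removal with the sensitivity snapshot that justified it."""

    order: int                       # sequence number of the removal
    step: int                        # trial step at which it happened
    participant_id: int
    subgroup: SubGroupKey
    sensitivities: dict[SubGroupKey, SensitivityEstimate] | None


@dataclass
class RemovalLog:
    events: list[RemovalEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            row = {
                "order": ev.order,
                "step": ev.step,
                "id": ev.participant_id,
                "arm": ev.subgroup.arm,
                "response": ev.subgroup.response,
            }
            for key in ALL_SUBGROUPS:
                est = (ev.sensitivities or {}).get(key)
                row[f"sens_{key.label}"] = est.value if est is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        recs = []
        for ev in self.events:
            recs.append(
                {
                    "order": ev.order,
                    "step": ev.step,
                    "id": ev.participant_id,
                    "subgroup": ev.subgroup.label,
                    "sensitivities": {
                        k.label: est.value
                        for k, est in (ev.sensitivities or {}).items()
                    },
                }
            )
        return json.dumps(recs, indent=1)


def matched_pairs_at(
    state: TrialState, k: int | None = None, include_removed: bool = False
) -> dict[int, MatchedPair]:
    """Matched pairs (by questionnaire tier) from outcomes at step ``k``.

    Outcomes are the simulator's effect values, which already live in the
    additive (transformed) domain of the normal model.
    """
    groups = stratify(state, k, include_removed=include_removed)
    if k is None:
        k = state.k

    def outcomes(pids: np.ndarray) -> np.ndarray:
        if include_removed:
            return np.array([state.observed_outcome(p) for p in pids])
        return state.effects[pids, k]

    pairs = {}
    for tier in (-1, 0, 1):
        c_ids = groups[SubGroupKey(CONTROL, tier)]
        t_ids = groups[SubGroupKey("treatment", tier)]
        pairs[tier] = MatchedPair(
            response=tier,
            control=make_sample(outcomes(c_ids)),
            treatment=make_sample(outcomes(t_ids)),
        )
    return pairs


def _eligible_candidates(
    state: TrialState, k: int, min_size: int
) -> tuple[dict[SubGroupKey, SensitivityEstimate], dict[SubGroupKey, np.ndarray]]:
    """Sensitivity of every eligible sub-group at step ``k``."""
    floor = max(min_size, 3)
    groups = stratify(state, k)
    pairs = matched_pairs_at(state, k)
    snapshot: dict[SubGroupKey, SensitivityEstimate] = {}
    for tier, pair in pairs.items():
        nc, nt = pair.control.n, pair.treatment.n
        if nc < floor or nt < floor:
            continue
        if pair.control.ss <= 0 or pair.treatment.ss <= 0:
            continue
        for side in (CONTROL, "treatment"):
            key = SubGroupKey(side, tier)
            snapshot[key] = expected_sensitivity(
                pair, side, subgroup=key
            )
    return snapshot, groups


def choose_target_subgroup(
    state: TrialState,
    k: int | None = None,
    policy: RemovalPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SubGroupKey, dict[SubGroupKey, SensitivityEstimate]]:
    """Sub-group with minimal |expected sensitivity| among eligible ones.

    Ties break toward the larger sub-group, then by a seeded uniform draw.
    Returns the chosen key and the full sensitivity snapshot.
    """
    if k is None:
        k = state.k
    policy = policy or RemovalPolicy()
    rng = rng if rng is not None else policy.rng()
    snapshot, groups = _eligible_candidates(state, k, policy.min_subgroup_size)
    if not snapshot:
        raise AdaptationExhaustedError(
            "no sub-group pair is large enough to remove from"
        )
    mags = {key: est.magnitude for key, est in snapshot.items()}
    best = min(mags.values())
    tied = [key for key, m in mags.items() if m == best]
    if len(tied) > 1:
        sizes = {key: len(groups[key]) for key in tied}
        big = max(sizes.values())
        tied = [key for key in tied if sizes[key] == big]
        if len(tied) > 1:
            tied = [tied[rng.integers(len(tied))]]
    return tied[0], snapshot


def remove_participants(
    state: TrialState,
    n_rem: int,
    policy: RemovalPolicy,
    k: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrialState, RemovalLog]:
    """Remove ``n_rem`` participants sequentially at trial step ``k``.

    Mutates ``state`` in place (copy first to keep the original).  Under the
    proposed policy the sensitivity ranking is recomputed after every single
    removal.  Raises :class:`AdaptationExhaustedError` with the partial log
    attached (``.log``) if eligibility runs out early.
    """
    if k is None:
        k = state.k
    if n_rem > int(state.active.sum()):
        raise AdaptationExhaustedError(
            f"cannot remove {n_rem} of {int(state.active.sum())} active participants"
        )
    rng = rng if rng is not None else policy.rng()
    log = RemovalLog()
    for j in range(n_rem):
        if policy.kind == "random":
            pool = np.flatnonzero(state.active)
            victim = int(pool[rng.integers(len(pool))])
            resp = int(state.responses[victim, k])
            key = SubGroupKey(str(state.arm[victim]), resp)
            snapshot = None
        else:
            try:
                key, snapshot = choose_target_subgroup(state, k, policy, rng)
            except AdaptationExhaustedError as err:
                err.log = log  # partial log for diagnosis
                raise
            members = stratify(state, k)[key]
            victim = int(members[rng.integers(len(members))])
        state.active[victim] = False
        state.removal_step[victim] = k
        log.events.append(
            RemovalEvent(
                order=j, step=k, participant_id=victim,
                subgroup=key, sensitivities=snapshot,
            )
        )
    return state, log
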