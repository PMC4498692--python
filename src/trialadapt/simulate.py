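"""Stochastic simulator of an imperfectly blinded two-arm trial.

The generative model tracks, for every participant, a cumulative treatment
effect and a latent *belief* about their own arm assignment.  Effects
accumulate through exponentially damped normal increments,

    e_i(k+1) = e_i(k) + w_i(k+1) * exp(-(k+1)/tau),    e_i(0) = 0,

with w ~ N(mu_arm, sd_arm), so the expected treatment-minus-control
differential converges geometrically to
``(mu_t - mu_c) * r / (1 - r)`` with ``r = exp(-1/tau)``.

Beliefs drift in proportion to the participant's own accumulated effect,

    b_i(k+1) = b_i(k) + phi * e_i(k+1) + omega_i(k+1),

where ``phi`` is the outcome-perceptibility coefficient and omega is small
normal noise.  Beliefs are thresholded into a three-tier blinding
questionnaire (believes-control / uncertain / believes-treatment), and the
cross of arm and questionnaire tier partitions the cohort into the six
sub-groups G_C-, G_C0, G_C+, G_T-, G_T0, G_T+ used by the adaptive analysis.

Randomness is organised as one seeded substream per participant (ordered by
participant id), so a participant's trajectory is reproducible regardless of
what happens to the rest of the cohort -- in particular, two removal policies
applied to the same simulated trial see identical survivor trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DomainError

CONTROL = "control"
TREATMENT = "treatment"
ARMS = (CONTROL, TREATMENT)

#: Questionnaire tiers, coded as integers.
BELIEVES_CONTROL = -1
UNCERTAIN = 0
BELIEVES_TREATMENT = 1

TIER_LABELS = {
    BELIEVES_CONTROL: "believes_control",
    UNCERTAIN: "uncertain",
    BELIEVES_TREATMENT: "believes_treatment",
}


class SubGroupKey(NamedTuple):
    """One of the six (arm x questionnaire-tier) strata."""

    arm: str
    response: int

    @property
    def label(self) -> str:
        sign = {-1: "-", 0: "0", 1: "+"}[self.response]
        return f"G_{'C' if self.arm == CONTROL else 'T'}{sign}"


#: The six sub-groups in canonical order (control tiers then treatment tiers).
ALL_SUBGROUPS = tuple(
    SubGroupKey(arm, tier) for arm in ARMS for tier in (-1, 0, 1)
)


def default_initial_beliefs(n: int = 90) -> np.ndarray:
    """Initial belief vector for one arm: a conservative majority at 0 with
    small pessimistic (-1) and optimistic (+1) minorities.

    For the reference cohort of 90 per arm the split is 8 / 73 / 9; other
    sizes are split proportionally (largest-remainder rounding).
    """
    if n < 1:
        raise ConfigurationError("arm size must be >= 1")
    if n == 90:
        counts = (8, 73, 9)
    else:
        frac = np.array([8, 73, 9]) / 90.0 * n
        counts = np.floor(frac).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(frac - np.floor(frac)))
        for j in range(rem):
            counts[order[j % 3]] += 1
        counts = tuple(int(c) for c in counts)
    return np.repeat([-1.0, 0.0, 1.0], counts)


@dataclass(frozen=True)
class TrialConfig:
    """Full parameterisation of one simulated trial.

    Parameters
    ----------
    n_control, n_treatment
        Arm sizes.
    k_max
        Number of discrete time steps to simulate.
    phi
        Outcome perceptibility: coupling of accumulated effect into belief
        drift (dimensionless).
    w_treat_mean, w_treat_sd, w_ctrl_mean, w_ctrl_sd
        Mean and standard deviation of the per-step effect increments, per
        arm, in outcome units.
    omega_sd
        Standard deviation of the per-step belief noise.
    decay_scale
        Time constant tau of the exp(-(k+1)/tau) damping of increments.
    belief_thresholds
        (lower, upper) cut points of the three-tier questionnaire.  The
        closed interval [lower, upper] maps to "uncertain".
    init_beliefs_control, init_beliefs_treatment
        Per-participant initial beliefs; default is the 8/73/9 split at
        (-1, 0, +1) in each arm.
    seed
        Master seed; per-participant substreams are spawned from it.
    noise_scale_is_sd
        If False, the w_* and omega scale parameters are read as variances
        instead of standard deviations.
    """

    n_control: int = 90
    n_treatment: int = 90
    k_max: int = 100
    phi: float = 0.01
    w_treat_mean: float = 0.02
    w_treat_sd: float = 0.05
    w_ctrl_mean: float = 0.00
    w_ctrl_sd: float = 0.05
    omega_sd: float = 0.005
    decay_scale: float = 10.0
    belief_thresholds: tuple[float, float] = (-1.0, 1.0)
    init_beliefs_control: Sequence[float] | None = None
    init_beliefs_treatment: Sequence[float] | None = None
    seed: int = 0
    noise_scale_is_sd: bool = True

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_treatment < 1:
            raise ConfigurationError("arm sizes must be >= 1")
        if self.k_max < 1:
            raise ConfigurationError("k_max must be >= 1")
        # 0 is allowed: it switches the corresponding noise source off, which
        # makes the recursion deterministic and testable against closed forms.
        for name in ("w_treat_sd", "w_ctrl_sd", "omega_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.decay_scale <= 0:
            raise ConfigurationError("decay_scale must be > 0")
        lo, hi = self.belief_thresholds
        if not lo < hi:
            raise ConfigurationError("belief_thresholds must be strictly increasing")
        for attr, n in (
            ("init_beliefs_control", self.n_control),
            ("init_beliefs_treatment", self.n_treatment),
        ):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ConfigurationError(
                    f"{attr} has length {len(v)}, expected {n}"
                )

    def initial_beliefs(self, arm: str) -> np.ndarray:
        v = (
            self.init_beliefs_control
            if arm == CONTROL
            else self.init_beliefs_treatment
        )
        n = self.n_control if arm == CONTROL else self.n_treatment
        if v is None:
            return default_initial_beliefs(n)
        return np.asarray(v, dtype=float).copy()

    def increment_params(self, arm: str) -> tuple[float, float]:
        """(mean, standard deviation) of the effect increment for an arm."""
        if arm == CONTROL:
            mean, scale = self.w_ctrl_mean, self.w_ctrl_sd
        else:
            mean, scale = self.w_treat_mean, self.w_treat_sd
        sd = scale if self.noise_scale_is_sd else math.sqrt(scale)
        return mean, sd

    @property
    def omega_scale(self) -> float:
        return (
            self.omega_sd if self.noise_scale_is_sd else math.sqrt(self.omega_sd)
        )


def questionnaire_response(
    belief: float, thresholds: tuple[float, float] = (-1.0, 1.0)
) -> int:
    """Map a scalar belief to a questionnaire tier.

    The interval [lower, upper] is closed at both ends and maps to
    ``UNCERTAIN``; below maps to ``BELIEVES_CONTROL``, above to
    ``BELIEVES_TREATMENT``.
    """
    if not np.isfinite(belief):
        raise DomainError(f"belief must be finite, got {belief!r}")
    lo, hi = thresholds
    if belief < lo:
        return BELIEVES_CONTROL
    if belief > hi:
        return BELIEVES_TREATMENT
    return UNCERTAIN


def _responses_of(beliefs: np.ndarray, thresholds: tuple[float, float]) -> np.ndarray:
    lo, hi = thresholds
    out = np.zeros(beliefs.shape, dtype=np.int8)
    out[beliefs < lo] = BELIEVES_CONTROL
    out[beliefs > hi] = BELIEVES_TREATMENT
    return out


def ground_truth_differential(k: int | float | None, config: TrialConfig) -> float:
    """Expected treatment-minus-control effect at step ``k``.

    ``E[e_t(k)] - E[e_c(k)] = (mu_t - mu_c) * sum_{j=1}^{k} exp(-j/tau)``.
    ``k=None`` (or ``inf``) returns the geometric-series asymptote
    ``(mu_t - mu_c) * r / (1 - r)`` with ``r = exp(-1/tau)``.
    """
    dmu = config.w_treat_mean - config.w_ctrl_mean
    r = math.exp(-1.0 / config.decay_scale)
    if k is None or (isinstance(k, float) and math.isinf(k)):
        return dmu * r / (1.0 - r)
    if k < 0:
        raise DomainError("k must be >= 0")
    k = int(k)
    return dmu * r * (1.0 - r**k) / (1.0 - r)


@dataclass
class ParticipantRecord:
    """Read-only view of one participant's trajectory."""

    id: int
    arm: str
    effects: np.ndarray
    beliefs: np.ndarray
    responses: np.ndarray
    active: bool
    removal_step: int | None


@dataclass
class TrialState:
    """Cohort state up to the current step ``k``.

    Trajectory arrays have shape ``(n_participants, k_max + 1)``; columns
    beyond the current step are NaN.  Increment noise is pre-drawn per
    participant from that participant's own substream, which makes every
    trajectory independent of iteration order and of removals elsewhere in
    the cohort.
    """

    config: TrialConfig
    k: int
    arm: np.ndarray            # object array of arm labels
    effects: np.ndarray        # (n, k_max+1) float
    beliefs: np.ndarray        # (n, k_max+1) float
    responses: np.ndarray      # (n, k_max+1) int8
    active: np.ndarray         # (n,) bool
    removal_step: np.ndarray   # (n,) int, -1 for never removed
    _w: np.ndarray = field(repr=False, default=None)      # (n, k_max) increments
    _omega: np.ndarray = field(repr=False, default=None)  # (n, k_max) belief noise

    @property
    def n_participants(self) -> int:
        return self.arm.shape[0]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_participants)

    def record(self, pid: int) -> ParticipantRecord:
        stop = self.k if self.active[pid] else int(self.removal_step[pid])
        sl = slice(0, stop + 1)
        return ParticipantRecord(
            id=int(pid),
            arm=str(self.arm[pid]),
            effects=self.effects[pid, sl].copy(),
            beliefs=self.beliefs[pid, sl].copy(),
            responses=self.responses[pid, sl].copy(),
            active=bool(self.active[pid]),
            removal_step=None if self.active[pid] else int(self.removal_step[pid]),
        )

    def copy(self) -> "TrialState":
        return TrialState(
            config=self.config,
            k=self.k,
            arm=self.arm.copy(),
            effects=self.effects.copy(),
            beliefs=self.beliefs.copy(),
            responses=self.responses.copy(),
            active=self.active.copy(),
            removal_step=self.removal_step.copy(),
            _w=self._w,
            _omega=self._omega,
        )

    # -- observation accessors -------------------------------------------
    def last_observed_step(self, pid: int) -> int:
        return self.k if self.active[pid] else int(self.removal_step[pid])

    def observed_outcome(self, pid: int) -> float:
        return float(self.effects[pid, self.last_observed_step(pid)])

    def observed_response(self, pid: int) -> int:
        return int(self.responses[pid, self.last_observed_step(pid)])


def init_trial(config: TrialConfig) -> TrialState:
    """Build the step-0 state: zero effects, configured beliefs, all active."""
    n = config.n_control + config.n_treatment
    arm = np.array(
        [CONTROL] * config.n_control + [TREATMENT] * config.n_treatment,
        dtype=object,
    )
    beliefs0 = np.concatenate(
        [config.initial_beliefs(CONTROL), config.initial_beliefs(TREATMENT)]
    )

    shape = (n, config.k_max + 1)
    effects = np.full(shape, np.nan)
    beliefs = np.full(shape, np.nan)
    responses = np.zeros(shape, dtype=np.int8)
    effects[:, 0] = 0.0
    beliefs[:, 0] = beliefs0
    responses[:, 0] = _responses_of(beliefs0, config.belief_thresholds)

    # Per-participant substreams, ordered by id.
    children = np.random.SeedSequence(config.seed).spawn(n)
    w = np.empty((n, config.k_max))
    omega = np.empty((n, config.k_max))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        mean, sd = config.increment_params(str(arm[i]))
        w[i] = rng.normal(mean, sd, config.k_max)
        omega[i] = rng.normal(0.0, config.omega_scale, config.k_max)

    return TrialState(
        config=config,
        k=0,
        arm=arm,
        effects=effects,
        beliefs=beliefs,
        responses=responses,
        active=np.ones(n, dtype=bool),
        removal_step=np.full(n, -1, dtype=int),
        _w=w,
        _omega=omega,
    )


def step(state: TrialState, k: int | None = None) -> TrialState:
    """Advance active participants from step ``k`` to ``k + 1`` (in place).

    Effects gain a damped normal increment; beliefs drift by ``phi`` times
    the *new* effect plus noise; responses are re-thresholded.  Inactive
    participants are untouched.
    """
    cfg = state.config
    if k is None:
        k = state.k
    if k != state.k:
        raise DomainError(f"state is at step {state.k}, cannot step from {k}")
    if not 0 <= k < cfg.k_max:
        raise DomainError(f"step index {k} outside [0, {cfg.k_max})")

    damp = math.exp(-(k + 1) / cfg.decay_scale)
    act = state.active
    state.effects[act, k + 1] = state.effects[act, k] + state._w[act, k] * damp
    state.beliefs[act, k + 1] = (
        state.beliefs[act, k]
        + cfg.phi * state.effects[act, k + 1]
        + state._omega[act, k]
    )
    state.responses[act, k + 1] = _responses_of(
        state.beliefs[act, k + 1], cfg.belief_thresholds
    )
    state.k = k + 1
    return state


def run_to(state: TrialState, k_stop: int) -> TrialState:
    """Step the state forward until ``state.k == k_stop``."""
    while state.k < k_stop:
        step(state)
    return state


def stratify(
    state: TrialState, k: int | None = None, include_removed: bool = False
) -> dict[SubGroupKey, np.ndarray]:
    """Partition participants into the six sub-groups by response at ``k``.

    By default only active participants are stratified (their response at
    step ``k``); with ``include_removed`` every participant is placed by
    their last observed response (used by keep-pre-removal analyses).
    Always returns all six keys; empty sub-groups map to empty arrays.
    """
    if k is None:
        k = state.k
    n = state.n_participants
    resp = np.empty(n, dtype=np.int8)
    mask = np.zeros(n, dtype=bool)
    for pid in range(n):
        if state.active[pid]:
            resp[pid] = state.responses[pid, k]
            mask[pid] = True
        elif include_removed:
            resp[pid] = state.observed_response(pid)
            mask[pid] = True
    out: dict[SubGroupKey, np.ndarray] = {}
    for key in ALL_SUBGROUPS:
        sel = mask & (state.arm == key.arm) & (resp == key.response)
        out[key] = np.flatnonzero(sel)
    return out


def to_frame(state: TrialState, replicate: int = 0) -> pd.DataFrame:
    """Long-format trajectory table: one row per (participant, observed step)."""
    rows = []
    for pid in range(state.n_participants):
        stop = state.last_observed_step(pid)
        for kk in range(stop + 1):
            rows.append(
                (
                    replicate,
                    pid,
                    state.arm[pid],
                    kk,
                    state.effects[pid, kk],
                    state.beliefs[pid, kk],
                    TIER_LABELS[int(state.responses[pid, kk])],
                    bool(state.active[pid]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "id",
            "arm",
            "step",
            "effect",
            "belief",
            "response",
            "active",
        ],
    )
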