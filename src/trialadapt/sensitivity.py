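"""Expected sensitivity of the superiority functional to sub-group size.

The removal policy ranks sub-groups by E[d rho* / d n], the change in the
matched pair's treatment-superiority probability per participant added to or
removed from one side.  Enumerating actual subsets is intractable, so the
derivative is taken of the *expected* functional form of rho*: the side's
sufficient statistics (n, s1, s2) are continued to real nu as
(nu, nu*mean1, nu*mean2), holding the per-datum means fixed.  Under this
continuation the normalized marginal kernel of the side remains a
location-scale Student-t,

    df = nu - 2,  loc = mean1,  scale^2 = (nu+1)(mean2 - mean1^2)/(nu - 2),

so rho_bar*(nu) is smooth in nu and can be differentiated either numerically
(central difference; the normative definition) or analytically by
differentiating the normalized kernel under the integral sign (digamma and
log terms from d/d nu of the t density).  Both paths differentiate the
*normalized* probability: the derivative of the normalization is included,
since sub-groups of different sizes are compared by these numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import digamma

from ._errors import DegenerateDataError, EligibilityError
from .posterior import (
    MatchedPair,
    OutcomeSample,
    TDist,
    predictive,
    superiority_probability,
    superiority_quadrature,
)
from .simulate import SubGroupKey

__all__ = [
    "ScaledStats",
    "SensitivityEstimate",
    "scaled_stats",
    "continued_predictive",
    "rho_bar",
    "expected_sensitivity",
]

#: Default finite-difference step in participants.
DEFAULT_H = 0.1
#: Fixed quadrature order used inside sensitivity evaluations.  A fixed rule
#: keeps node placement identical across the differenced evaluations so the
#: quadrature error cancels in the difference.
DEFAULT_NODES = 801


@dataclass(frozen=True)
class ScaledStats:
    """Per-datum sufficient statistics enabling real-valued sample size."""

    n_effective: float
    mean1: float  # mean of x
    mean2: float  # mean of x^2

    @property
    def variance(self) -> float:
        return max(self.mean2 - self.mean1**2, 0.0)


@dataclass(frozen=True)
class SensitivityEstimate:
    """Expected per-participant change of rho* for one sub-group."""

    subgroup: SubGroupKey | None
    value: float
    method: str
    tolerance_used: float

    @property
    def magnitude(self) -> float:
        return abs(self.value)


def scaled_stats(sample: OutcomeSample) -> ScaledStats:
    if sample.n < 2:
        raise EligibilityError("scaled_stats requires n >= 2")
    return ScaledStats(
        n_effective=float(sample.n),
        mean1=sample.s1 / sample.n,
        mean2=sample.s2 / sample.n,
    )


def continued_predictive(st: ScaledStats, nu: float):
    """Predictive t of a side continued to real sample size ``nu``."""
    if nu <= 2:
        raise EligibilityError(
            f"continued predictive needs nu > 2, got {nu:g}"
        )
    if st.variance <= 0:
        raise DegenerateDataError("zero-variance side in continuation")
    scale = math.sqrt((nu + 1) * st.variance / (nu - 2))
    return TDist(df=nu - 2, loc=st.mean1, scale=scale)


def _sides(pair: MatchedPair, side: str) -> tuple[OutcomeSample, OutcomeSample]:
    if side == "treatment":
        return pair.treatment, pair.control
    if side == "control":
        return pair.control, pair.treatment
    raise ValueError(f"side must be 'control' or 'treatment', got {side!r}")


def rho_bar(
    pair: MatchedPair,
    side: Literal["control", "treatment"],
    nu: float,
    nodes: int = DEFAULT_NODES,
) -> float:
    """Superiority probability with ``side`` continued to real size ``nu``.

    At ``nu`` equal to the side's actual n this coincides with ``rho_star``
    of the pair (same kernels, same quadrature rule).
    """
    varied, fixed = _sides(pair, side)
    dv = continued_predictive(scaled_stats(varied), nu)
    df = predictive(fixed)
    center, scale = superiority_quadrature(pair)
    if side == "treatment":
        return superiority_probability(dv, df, center, scale, nodes=nodes)
    # P(X_t > X_c) = 1 - int f_c(y) F_t(y) dy
    return 1.0 - superiority_probability(dv, df, center, scale, nodes=nodes)


# ---------------------------------------------------------------------------
# Analytic path: d/d nu of the normalized t kernel under the integral sign
# ---------------------------------------------------------------------------

def _dlogf_dnu(x: np.ndarray, st: ScaledStats, nu: float) -> np.ndarray:
    """d log f(x; nu) / d nu for the continued predictive t density.

    With d = nu - 2, u = (x - loc)/s, s^2 = (nu+1) V / (nu-2):

        log f = lgamma((d+1)/2) - lgamma(d/2) - (1/2) log(d pi)
                - ((d+1)/2) log(1 + u^2/d) - log s

    The nu-dependence enters through d (directly) and s (hence u); the
    log-derivative collects the digamma and logarithm terms, the analogue of
    the ln-sigma terms that appear when the sigma-marginalized kernel is
    differentiated with respect to n.
    """
    d = nu - 2.0
    s = math.sqrt((nu + 1) * st.variance / d)
    u = (x - st.mean1) / s
    L = 0.5 * (1.0 / (nu + 1) - 1.0 / d)  # d log s / d nu
    q = 1.0 + u * u / d
    term_d = (
        0.5 * digamma((d + 1) / 2)
        - 0.5 * digamma(d / 2)
        - 1.0 / (2 * d)
        - 0.5 * np.log(q)
        + (d + 1) * u * u / (2 * d * d * q)
    )
    term_s = L * ((d + 1) * u * u / (d * q) - 1.0)
    return term_d + term_s


def _analytic_sensitivity(
    pair: MatchedPair, side: str, nodes: int
) -> float:
    varied, fixed = _sides(pair, side)
    st = scaled_stats(varied)
    nu = st.n_effective
    dv = continued_predictive(st, nu)
    dfix = predictive(fixed)
    center, scale = superiority_quadrature(pair)

    from .posterior import _tangent_nodes  # shared node rule

    x, w = _tangent_nodes(center, scale, nodes)
    integrand = dv.pdf(x) * _dlogf_dnu(x, st, nu) * dfix.cdf(x)
    val = float(np.sum(w * integrand))
    if side == "treatment":
        # d/d nu_t of int f_t F_c
        return val
    # rho = 1 - int f_c F_t  =>  d rho / d nu_c = -val
    return -val


def expected_sensitivity(
    pair: MatchedPair,
    side: Literal["control", "treatment"],
    method: Literal["finite_difference", "analytic"] = "finite_difference",
    h: float = DEFAULT_H,
    nodes: int = DEFAULT_NODES,
    subgroup: SubGroupKey | None = None,
) -> SensitivityEstimate:
    """Expected derivative of rho* with respect to one side's size.

    ``finite_difference`` (the reference): central difference of the
    continued, normalized superiority probability with step ``h``; falls back
    to a one-sided second-order difference when ``nu - h`` would leave the
    proper region (nu - h <= 2).  ``analytic``: differentiation under the
    integral sign of the same normalized kernel.
    """
    varied, fixed = _sides(pair, side)
    if varied.n < 3 or fixed.n < 3:
        raise EligibilityError(
            "expected_sensitivity requires at least 3 observations per side"
        )
    if varied.ss <= 0 or fixed.ss <= 0:
        raise DegenerateDataError("zero-variance sub-group in sensitivity")

    nu = float(varied.n)
    if method == "analytic":
        value = _analytic_sensitivity(pair, side, nodes)
        tol = 0.0
    elif method == "finite_difference":
        if nu - h > 2.0 + 1e-9:
            hi = rho_bar(pair, side, nu + h, nodes=nodes)
            lo = rho_bar(pair, side, nu - h, nodes=nodes)
            value = (hi - lo) / (2 * h)
        else:
            f0 = rho_bar(pair, side, nu, nodes=nodes)
            f1 = rho_bar(pair, side, nu + h, nodes=nodes)
            f2 = rho_bar(pair, side, nu + 2 * h, nodes=nodes)
            value = (-3 * f0 + 4 * f1 - f2) / (2 * h)
        tol = h
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(value):
        raise DegenerateDataError("sensitivity evaluation returned non-finite value")
    return SensitivityEstimate(
        subgroup=subgroup, value=float(value), method=method, tolerance_used=tol
    )
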