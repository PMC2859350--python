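"""Coverage probability (CP) at a fixed boundary and its lower bound.

The CP at a boundary ``kappa`` is the proportion of absolute paired
differences it captures, ``p_kappa = P(|D| < kappa)``.  It is the inverse of
the TDI: the TDI at proportion ``p`` is the boundary whose CP is ``p``.  A
one-sided lower confidence bound for the CP follows from the same
non-central-t relation that yields the TDI tolerance bound: the lower bound
is the proportion ``p`` whose tolerance bound equals ``kappa``, found by a
binary search over the proportion scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

from .core import DEFAULT_SETTINGS, SearchSettings, solve_p1
from .exceptions import ConfigurationError, NumericError
from .model_fit import DifferenceParams
from .tolerance import DEFAULT_POLICY, TIPolicy, noncentral_t_quantile

__all__ = ["CPResult", "cp_estimate", "cp_lower_bound", "cp_hypothesis_test", "CPDecision"]


@dataclass(frozen=True)
class CPResult:
    """CP point estimate and one-sided lower confidence bound at ``kappa``."""

    kappa: float
    p_kappa_hat: float
    lower_bound: float
    confidence: float
    iterations: int

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (0.0 <= self.lower_bound <= self.p_kappa_hat + eps):
            raise NumericError(
                f"lower bound {self.lower_bound} exceeds estimate {self.p_kappa_hat}"
            )


def cp_estimate(mu_D: float, sigma_D: float, kappa: float) -> float:
    """Proportion of ``N(mu_D, sigma_D)`` mass inside ``(-kappa, kappa)``."""
    if sigma_D <= 0:
        raise ConfigurationError("sigma_D must be > 0")
    if kappa <= 0:
        raise ConfigurationError("kappa must be > 0")
    mu = abs(mu_D)
    return float(ndtr((kappa - mu) / sigma_D) - ndtr((-kappa - mu) / sigma_D))


def cp_lower_bound(
    params: DifferenceParams,
    kappa: float,
    policy: TIPolicy = DEFAULT_POLICY,
    settings: SearchSettings = DEFAULT_SETTINGS,
) -> CPResult:
    """One-sided ``(1-alpha)`` lower confidence bound for the CP at ``kappa``.

    Searches the proportion ``p`` in ``(0, 1)`` whose non-centrality
    ``sqrt(N) z_{p1(p)}`` makes the tolerance bound hit the observed
    studentized boundary ``T = sqrt(N) (kappa - |mu_hat|) / sigma_hat``:
    bisection on ``p`` with the same delta-shrinking bracket as the p1
    search.  By
    construction it is dual to the TDI tolerance bound: evaluated at
    ``kappa = UB_p`` it returns ``p`` (to within the search tolerance).
    """
    if kappa <= 0:
        raise ConfigurationError("kappa must be > 0")
    ratio = abs(params.mu_D) / params.sigma_D
    sqrt_n = math.sqrt(params.N)
    t_obs = sqrt_n * (kappa - abs(params.mu_D)) / params.sigma_D

    delta = settings.tol

    def discrepancy(p_mid: float) -> float:
        p1 = solve_p1(ratio, p_mid, settings)
        tq = noncentral_t_quantile(policy.confidence, params.nu, sqrt_n * ndtri(p1))
        return t_obs - tq

    low, high = 0.0, 1.0
    iterations = 0
    max_iter = settings.max_iter
    mid = 0.5
    for iterations in range(1, max_iter + 1):
        mid = (low + high) / 2.0
        if not (0.0 < mid < 1.0):
            break
        d = discrepancy(mid)
        if abs(d) < delta or (high - low) < delta:
            break
        if d > 0:
            low = mid + delta
        else:
            high = mid - delta
    else:
        raise NumericError(
            f"CP lower-bound search did not converge; bracket [{low}, {high}]"
        )
    lower = min(max(mid, 0.0), 1.0)
    estimate = cp_estimate(params.mu_D, params.sigma_D, kappa)
    # the bound is one-sided below the estimate; clamp hairline overshoot
    lower = min(lower, estimate)
    return CPResult(
        kappa=kappa,
        p_kappa_hat=estimate,
        lower_bound=lower,
        confidence=policy.confidence,
        iterations=iterations,
    )


@dataclass(frozen=True)
class CPDecision:
    """Outcome of the CP agreement test ``H0: p_kappa <= p0``."""

    kappa: float
    p0: float
    alpha: float
    lower_bound: float
    reject_h0: bool
    conclusion: str
    result: CPResult


def cp_hypothesis_test(
    params: DifferenceParams,
    kappa: float,
    p0: float,
    policy: TIPolicy = DEFAULT_POLICY,
    settings: SearchSettings = DEFAULT_SETTINGS,
) -> CPDecision:
    """Test ``H0: p_kappa <= p0`` — reject (conclude agreement) iff the CP
    lower bound exceeds ``p0``.  Dual to the TDI test with ``kappa0 = kappa``
    and ``p = p0``."""
    if not (0.0 < p0 < 1.0):
        raise ConfigurationError(f"p0 must be in (0, 1), got {p0}")
    result = cp_lower_bound(params, kappa, policy, settings)
    reject = result.lower_bound > p0
    alpha = 1.0 - policy.confidence
    if reject:
        conclusion = (
            f"boundary {kappa:g} captures more than {p0:.0%} of absolute "
            f"differences (alpha={alpha:g})"
        )
    else:
        conclusion = (
            f"cannot conclude that boundary {kappa:g} captures {p0:.0%} of "
            f"absolute differences"
        )
    return CPDecision(
        kappa=kappa,
        p0=p0,
        alpha=alpha,
        lower_bound=result.lower_bound,
        reject_h0=bool(reject),
        conclusion=conclusion,
        result=result,
    )
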