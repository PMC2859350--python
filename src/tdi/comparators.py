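"""Benchmark TDI inference methods: Lin's log-MSD bound and Choudhary's
MLE plug-in bound.

Both competitors work on the log scale: the TDI estimate is log-transformed,
a delta-method standard error is attached, and the upper bound is
``exp(log kappa_hat + z_{1-alpha} * se_log)``.

* Lin: the mean-squared-deviation approximation
  ``kappa = z_{(1+p)/2} sqrt(mu_D^2 + sigma_D^2)`` with moment (working
  independence GEE) parameter estimates.
* Choudhary: the exact non-central chi-square TDI with maximum-likelihood
  parameter estimates (identical, as a point estimate, to the
  probability-interval TDI evaluated at the same parameter values).

The original publications' closed-form delta-method variances are not
reproduced here; gradients are differentiated numerically against the
balanced-stratum moment/ML covariances, which preserves the structure of
both methods (log-scale normal-theory bounds).  Reported as approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .core import tdi_msd_approx, tdi_ncx2_exact
from .data_io import AgreementData
from .exceptions import ConfigurationError, DataError, DegenerateDistributionError
from .model_fit import _balanced_ss, _vc_from_ss

__all__ = ["ComparatorResult", "lin_tdi_ub", "choudhary_tdi_ub"]


@dataclass(frozen=True)
class ComparatorResult:
    """A comparator's TDI point estimate and log-scale upper bound."""

    method: str
    kappa_hat: float
    upper_bound: float
    se_log: float
    estimation: str
    p: float
    confidence: float

    def __post_init__(self) -> None:
        if self.se_log <= 0:
            raise DegenerateDistributionError("se_log must be > 0")
        if self.upper_bound < self.kappa_hat:
            raise ConfigurationError("upper bound below point estimate")


def _grad_log_kappa(kappa_fn, theta: np.ndarray) -> np.ndarray:
    """Central-difference gradient of log kappa(theta)."""
    grad = np.empty_like(theta)
    for i, t in enumerate(theta):
        h = 1e-6 * max(abs(t), 1.0)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (math.log(kappa_fn(up)) - math.log(kappa_fn(dn))) / (2.0 * h)
    return grad


def _sigma2_d(theta: np.ndarray, ss: dict, include_interaction: bool, restricted: bool) -> float:
    """Total-difference variance as a smooth function of the stratum mean
    squares theta = (mu, ms_c, ms_w); truncation is not applied inside the
    delta-method gradient."""
    _, ms_c, ms_w = theta
    n, m = ss["n"], ss["m"]
    if include_interaction:
        sigma2_gamma = (ms_c - ms_w) / m
        return 2.0 * sigma2_gamma + 2.0 * ms_w
    df_c = (n - 1) if restricted else n
    df_w = 2 * n * (m - 1)
    pooled = (df_c * ms_c + df_w * ms_w) / (df_c + df_w)
    return 2.0 * pooled


def _stratum_stats(data: AgreementData, include_interaction: bool, restricted: bool):
    """Moment/ML sufficient statistics: theta = (mu, ms_c, ms_w) and its
    asymptotic (diagonal) covariance from the balanced strata."""
    if not data.balanced:
        raise DataError("comparator methods require balanced data")
    if data.m < 2:
        raise DataError("comparator methods require m >= 2 replicates")
    ss = _balanced_ss(data.balanced_values())
    n, m = ss["n"], ss["m"]
    df_c = (n - 1) if restricted else n
    df_w = 2 * n * (m - 1)
    ms_c = ss["ss_c"] / df_c
    ms_w = ss["ss_w"] / df_w
    mu = ss["beta_diff"]
    theta = np.array([mu, ms_c, ms_w])
    # Var(mu_hat) = 2*lambda_C/(n*m); stratum mean squares ~ 2*lambda^2/df
    cov = np.diag([2.0 * ms_c / (n * m), 2.0 * ms_c**2 / df_c, 2.0 * ms_w**2 / df_w])
    return ss, theta, cov


def lin_tdi_ub(
    data: AgreementData,
    p: float,
    confidence: float = 0.95,
    include_interaction: bool = False,
) -> ComparatorResult:
    """Lin's TDI upper bound: MSD approximation with moment (GEE working
    independence) estimates and a numeric delta-method log-scale variance."""
    ss, theta, cov = _stratum_stats(data, include_interaction, restricted=True)

    def kappa_fn(th: np.ndarray) -> float:
        s2 = _sigma2_d(th, ss, include_interaction, restricted=True)
        return tdi_msd_approx(th[0], math.sqrt(s2), p)

    kappa = kappa_fn(theta)
    grad = _grad_log_kappa(kappa_fn, theta)
    se_log = float(math.sqrt(grad @ cov @ grad))
    ub = math.exp(math.log(kappa) + ndtri(confidence) * se_log)
    return ComparatorResult(
        method="lin",
        kappa_hat=kappa,
        upper_bound=ub,
        se_log=se_log,
        estimation="GEE-moment",
        p=p,
        confidence=confidence,
    )


def choudhary_tdi_ub(
    data: AgreementData,
    p: float,
    confidence: float = 0.95,
    include_interaction: bool = False,
) -> ComparatorResult:
    """Choudhary's TDI upper bound: non-central chi-square plug-in at the MLE
    with a numeric delta-method log-scale variance (observed-information
    stratum covariance)."""
    ss, theta, cov = _stratum_stats(data, include_interaction, restricted=False)

    def kappa_fn(th: np.ndarray) -> float:
        s2 = _sigma2_d(th, ss, include_interaction, restricted=False)
        return tdi_ncx2_exact(th[0], math.sqrt(s2), p)

    kappa = kappa_fn(theta)
    grad = _grad_log_kappa(kappa_fn, theta)
    se_log = float(math.sqrt(grad @ cov @ grad))
    ub = math.exp(math.log(kappa) + ndtri(confidence) * se_log)
    return ComparatorResult(
        method="choudhary",
        kappa_hat=kappa,
        upper_bound=ub,
        se_log=se_log,
        estimation="MLE",
        p=p,
        confidence=confidence,
    )


def mle_components(data: AgreementData, include_interaction: bool = False) -> dict:
    """Closed-form balanced MLE of (beta_diff, sigma2_alpha, sigma2_gamma,
    sigma2_e); the parameter set Choudhary's plug-in uses."""
    if not data.balanced:
        raise DataError("closed-form MLE requires balanced data")
    ss = _balanced_ss(data.balanced_values())
    vc = _vc_from_ss(ss, include_interaction, restricted=False)
    return {
        "beta_diff": ss["beta_diff"],
        "intercept": ss["intercept"],
        **{k: vc[k] for k in ("sigma2_alpha", "sigma2_gamma", "sigma2_e", "truncated")},
    }
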