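"""One-sided tolerance-interval inference for the TDI estimate.

The studentized TDI limit follows a non-central Student-t distribution with
``nu`` residual degrees of freedom and non-centrality ``sqrt(N) * z_{p1}``,
where ``N`` is the number of paired-measurement differences that inform the
estimate.  The ``(1-alpha)`` one-sided upper bound on the TDI is therefore
the exact one-sided normal tolerance bound (Hahn's tolerance factor) for at
least a ``p1`` proportion of the difference population:

    UB = |mu_hat| + sigma_hat * t'_{1-alpha; nu; sqrt(N) z_{p1}} / sqrt(N)

Rejecting ``H0: kappa_p >= kappa_0`` at level ``alpha`` (i.e. UB < kappa_0)
supports the claim that the devices agree to within ``kappa_0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtri
from scipy.stats import nct

from .core import DEFAULT_SETTINGS, SearchSettings, TDIResult, solve_p1
from .exceptions import ConfigurationError, NumericError
from .model_fit import DifferenceParams, MixedModelFit

__all__ = [
    "TIPolicy",
    "AgreementDecision",
    "residual_df",
    "noncentral_t_quantile",
    "tdi_upper_bound",
    "tdi_hypothesis_test",
    "tdi_analysis",
]

#: non-centrality beyond which the normal approximation of the non-central-t
#: quantile replaces the library routine.
LARGE_NC_FALLBACK = 5000.0


@dataclass(frozen=True)
class TIPolicy:
    """Inference policy: confidence level and degrees-of-freedom convention.

    ``df_convention`` choices (for a balanced design with ``n`` subjects and
    ``m`` replicates per device):

    * ``interaction``     — nu = 2n(m-1): all fixed and random effects
      consume degrees of freedom (conservative ANOVA position).
    * ``no_interaction``  — nu = 2nm - (n + m - 1): no subject x device
      interaction term in the model (default when the fit has none).
    * ``fixed_only``      — nu = 2nm - 2: only fixed effects consume df.
    * ``satterthwaite``   — Welch-style effective df combining per-device
      error-variance estimates (unequal error variances).
    """

    confidence: float = 0.95
    df_convention: str = "auto"

    def __post_init__(self) -> None:
        if not (0.5 < self.confidence < 1.0):
            raise ConfigurationError(
                f"confidence must be in (0.5, 1), got {self.confidence}"
            )


DEFAULT_POLICY = TIPolicy()


def residual_df(
    n: int,
    m: int,
    convention: str,
    fit: MixedModelFit | None = None,
) -> float:
    """Residual degrees of freedom under the chosen convention."""
    if n < 2 or m < 1:
        raise ConfigurationError(f"need n >= 2, m >= 1; got n={n}, m={m}")
    if convention == "interaction":
        if m < 2:
            raise ConfigurationError("interaction convention needs m >= 2")
        return float(2 * n * (m - 1))
    if convention == "no_interaction":
        return float(2 * n * m - (n + m - 1))
    if convention == "fixed_only":
        return float(2 * n * m - 2)
    if convention == "satterthwaite":
        if fit is None or fit.equal_error_variances or fit.error_df is None:
            raise ConfigurationError(
                "satterthwaite df needs a fit with per-device error variances"
            )
        v1, v2 = fit.sigma2_e1, fit.sigma2_e2
        d1, d2 = fit.error_df
        return (v1 + v2) ** 2 / (v1**2 / d1 + v2**2 / d2)
    raise ConfigurationError(f"unknown df convention {convention!r}")


def noncentral_t_quantile(q: float, df: float, nc: float) -> float:
    """Upper ``q`` quantile of the non-central t distribution.

    Uses the library routine; beyond ``LARGE_NC_FALLBACK`` (or on numerical
    failure) it switches to the standard normal approximation

        t' ~ (nc + z_q * sqrt(1 + (nc^2 - z_q^2)/(2 nu))) / (1 - z_q^2/(2 nu))

    which is the closed-form one-sided tolerance-factor approximation.
    """
    z = ndtri(q)

    def _approx() -> float:
        a = 1.0 - z**2 / (2.0 * df)
        if a <= 0:
            raise NumericError(
                f"normal approximation invalid at df={df}; "
                "increase df or lower the confidence level"
            )
        disc = nc**2 * z**2 / (2.0 * df) + a * z**2
        return (nc + math.copysign(math.sqrt(disc), z)) / a

    if abs(nc) > LARGE_NC_FALLBACK:
        return _approx()
    value = float(nct.ppf(q, df, nc))
    if not math.isfinite(value):
        return _approx()
    return value


def _p1_for(
    params: DifferenceParams,
    p: float,
    settings: SearchSettings,
    mode: str,
    total_params: DifferenceParams | None,
) -> tuple[float, int]:
    if params.kind == "intra":
        return (1.0 + p) / 2.0, 0
    if params.kind == "inter" and mode == "paper_compat":
        if total_params is None:
            raise ConfigurationError("paper_compat mode requires total_params")
        ratio = total_params.mu_D / total_params.sigma_D
    else:
        ratio = params.mu_D / params.sigma_D
    return solve_p1(ratio, p, settings, full_output=True)


def tdi_upper_bound(
    params: DifferenceParams,
    p: float,
    policy: TIPolicy = DEFAULT_POLICY,
    settings: SearchSettings = DEFAULT_SETTINGS,
    mode: str = "strict",
    total_params: DifferenceParams | None = None,
) -> TDIResult:
    """TDI point estimate and its one-sided ``(1-alpha)`` tolerance bound.

    For the intra-method kind the mean term is zero and ``p1 = (1+p)/2``
    exactly; otherwise ``p1`` comes from the binary search (see
    :func:`tdi.core.tdi_inter` for the two inter-method modes).  The bound
    exceeds the estimate for any finite ``N`` and converges to it as
    ``N, nu -> infinity``.
    """
    if not (0.0 < p < 1.0):
        raise ConfigurationError(f"p must be in (0, 1), got {p}")
    p1, iterations = _p1_for(params, p, settings, mode, total_params)
    z_p1 = ndtri(p1)
    mu_abs = abs(params.mu_D)
    kappa = mu_abs + params.sigma_D * z_p1
    sqrt_n = math.sqrt(params.N)
    tq = noncentral_t_quantile(policy.confidence, params.nu, sqrt_n * z_p1)
    ub = mu_abs + params.sigma_D * tq / sqrt_n
    return TDIResult(
        p=p,
        p1=p1,
        kappa_hat=kappa,
        kind=params.kind,
        mode=mode,
        upper_bound=ub,
        confidence=policy.confidence,
        iterations=iterations,
        df_convention=params.df_convention,
        N=params.N,
        nu=params.nu,
    )


@dataclass(frozen=True)
class AgreementDecision:
    """Outcome of the TDI agreement test ``H0: kappa_p >= kappa_0``."""

    kappa0: float
    p: float
    alpha: float
    upper_bound: float
    reject_h0: bool
    conclusion: str
    result: TDIResult

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "reject H0" if self.reject_h0 else "retain H0"
        return f"{verdict}: {self.conclusion}"


def tdi_hypothesis_test(
    params: DifferenceParams,
    kappa0: float,
    p: float,
    policy: TIPolicy = DEFAULT_POLICY,
    settings: SearchSettings = DEFAULT_SETTINGS,
    mode: str = "strict",
    total_params: DifferenceParams | None = None,
) -> AgreementDecision:
    """Test ``H0: kappa_p >= kappa0`` (disagreement) against agreement.

    ``H0`` is rejected at level ``alpha = 1 - confidence`` iff the one-sided
    tolerance bound falls below ``kappa0``; rejection supports the claim
    that the devices agree to within ``kappa0`` (interchangeability).
    """
    if kappa0 <= 0:
        raise ConfigurationError("kappa0 must be > 0")
    result = tdi_upper_bound(params, p, policy, settings, mode, total_params)
    reject = result.upper_bound < kappa0
    alpha = 1.0 - policy.confidence
    if reject:
        conclusion = (
            f"at least {p:.0%} of absolute differences are below {kappa0:g} "
            f"(alpha={alpha:g}); devices interchangeable at this criterion"
        )
    else:
        conclusion = (
            f"cannot conclude that {p:.0%} of absolute differences are below "
            f"{kappa0:g}; devices not interchangeable at this criterion"
        )
    return AgreementDecision(
        kappa0=kappa0,
        p=p,
        alpha=alpha,
        upper_bound=result.upper_bound,
        reject_h0=bool(reject),
        conclusion=conclusion,
        result=result,
    )


def tdi_analysis(
    fit: MixedModelFit,
    p_levels=(0.80, 0.85, 0.90, 0.95),
    kinds=("total", "intra", "inter"),
    policy: TIPolicy = DEFAULT_POLICY,
    settings: SearchSettings = DEFAULT_SETTINGS,
    inter_mode: str = "strict",
) -> list[TDIResult]:
    """Full agreement table: estimates and bounds for every requested
    proportion and difference kind (the shape of a concordance report)."""
    from .model_fit import difference_params

    results = []
    total = difference_params(fit, "total", policy.df_convention)
    for p in p_levels:
        for kind in kinds:
            prm = difference_params(fit, kind, policy.df_convention)
            results.append(
                tdi_upper_bound(
                    prm, p, policy, settings,
                    mode=inter_mode if kind == "inter" else "strict",
                    total_params=total if kind == "inter" else None,
                )
            )
    return results
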