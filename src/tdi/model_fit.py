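"""Mixed-model estimation and paired-difference distribution parameters.

The measurement model for subject ``i``, device ``j``, replicate ``l`` is

    y_ijl = x_ijl' delta + beta_j + alpha_i + gamma_ij + e_ijl

with ``alpha_i ~ N(0, sigma2_alpha)`` (subject), ``gamma_ij ~ N(0,
sigma2_gamma)`` (subject x device interaction) and ``e_ijl ~ N(0,
sigma2_e)`` (error; optionally device-specific).  The paired-difference
distributions derived from the fit are

* total  (any one replicate per device):
  ``D ~ N(mu_D, 2*sigma2_gamma + 2*sigma2_e)``
* intra  (two replicates, same device): ``D ~ N(0, 2*sigma2_e)``
* inter  (replicate averages across devices):
  ``D ~ N(mu_D, 2*sigma2_gamma + 2*sigma2_e/m)``

with ``mu_D = beta_2 - beta_1`` under the declared device ordering.

For balanced designs without covariates, :func:`fit_balanced_vc` uses the
closed-form ANOVA/REML estimators (they coincide when no variance component
truncates at zero); :func:`fit_reml_general` fits the same model numerically
via ``statsmodels`` ``MixedLM`` and additionally supports covariates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AgreementData
from .exceptions import ConfigurationError, DataError, DegenerateDistributionError, FitError

__all__ = [
    "MixedModelFit",
    "DifferenceParams",
    "fit_balanced_vc",
    "fit_reml_general",
    "difference_params",
]


@dataclass(frozen=True)
class MixedModelFit:
    """Fixed effects and variance components of the agreement model.

    ``sigma2_e`` is the pooled error variance; when
    ``equal_error_variances`` is false it is the average of the per-device
    ``sigma2_e1``/``sigma2_e2`` (kept for symmetry, not used for inference).
    ``truncated`` lists variance components whose closed-form solution was
    negative and was clipped to zero.
    """

    beta_diff: float
    intercept: float
    sigma2_alpha: float
    sigma2_gamma: float
    sigma2_e: float
    n: int
    m: int
    method: str
    devices: tuple[str, str] = ("1", "2")
    include_interaction: bool = False
    equal_error_variances: bool = True
    sigma2_e1: float | None = None
    sigma2_e2: float | None = None
    covariate_effects: dict = field(default_factory=dict)
    loglik: float | None = None
    aic: float | None = None
    truncated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sigma2_alpha", "sigma2_gamma", "sigma2_e"):
            if getattr(self, name) < 0:
                raise FitError(f"{name} negative after fitting")
        if self.n < 2 or self.m < 1:
            raise DataError(f"need n >= 2 subjects and m >= 1 replicates, got n={self.n}, m={self.m}")
        if self.include_interaction and self.m < 2:
            raise ConfigurationError("interaction variance needs m >= 2 replicates")

    @property
    def error_df(self) -> tuple[float, float] | None:
        """Per-device error-variance degrees of freedom (unequal-variance fits)."""
        if self.equal_error_variances:
            return None
        df = self.n * (self.m - 1)
        return (df, df)


@dataclass(frozen=True)
class DifferenceParams:
    """Distribution of the relevant paired difference plus tolerance-interval
    bookkeeping: ``D ~ N(mu_D, sigma_D^2)``, ``N`` paired differences and
    ``nu`` residual degrees of freedom."""

    mu_D: float
    sigma_D: float
    kind: str
    N: int
    nu: float
    df_convention: str = "no_interaction"

    def __post_init__(self) -> None:
        if self.sigma_D <= 0:
            raise DegenerateDistributionError("sigma_D must be > 0")
        if self.kind == "intra" and self.mu_D != 0:
            raise ConfigurationError("intra-method differences have mean 0")
        if self.N < 2 or self.nu < 1:
            raise ConfigurationError(f"need N >= 2 and nu >= 1, got N={self.N}, nu={self.nu}")


# ---------------------------------------------------------------------------
# balanced closed-form estimation


def _balanced_ss(values: np.ndarray) -> dict:
    """Sums of squares of the balanced two-device design.

    ``values`` has shape (n, 2, m).  Returns the subject (A), subject x
    device contrast (C) and within-cell (W) sums of squares; the C stratum
    carries eigenvalue ``sigma2_e + m*sigma2_gamma`` and W carries
    ``sigma2_e``.
    """
    n, two, m = values.shape
    cell = values.mean(axis=2)                     # (n, 2)
    subj = cell.mean(axis=1)                       # (n,)
    dev = cell.mean(axis=0)                        # (2,)
    grand = subj.mean()
    ss_w = float(((values - cell[:, :, None]) ** 2).sum())
    ss_w_dev = ((values - cell[:, :, None]) ** 2).sum(axis=(0, 2))  # per device
    ss_c = float(m * ((cell - subj[:, None] - dev[None, :] + grand) ** 2).sum())
    ss_a = float(2 * m * ((subj - grand) ** 2).sum())
    return {
        "n": n, "m": m,
        "ss_a": ss_a, "ss_c": ss_c, "ss_w": ss_w,
        "ss_w_dev": (float(ss_w_dev[0]), float(ss_w_dev[1])),
        "beta_diff": float(dev[1] - dev[0]),
        "intercept": float(grand),
    }


def _vc_from_ss(
    ss: dict,
    include_interaction: bool,
    equal_error_variances: bool = True,
    restricted: bool = True,
) -> dict:
    """Variance components from the balanced strata.

    ``restricted=True`` gives the ANOVA/REML solution (fixed effects consume
    one df in the subject stratum and one in the device-contrast stratum);
    ``restricted=False`` the maximum-likelihood solution (stratum divisors
    ``n``).  Negative solutions are truncated at zero and flagged.
    """
    n, m = ss["n"], ss["m"]
    df_a = (n - 1) if restricted else n
    df_c = (n - 1) if restricted else n
    df_w = 2 * n * (m - 1)
    truncated = []

    if include_interaction:
        if m < 2:
            raise ConfigurationError("interaction variance needs m >= 2 replicates")
        sigma2_e = ss["ss_w"] / df_w
        lam_c = ss["ss_c"] / df_c
        sigma2_gamma = (lam_c - sigma2_e) / m
        if sigma2_gamma < 0:
            sigma2_gamma = 0.0
            truncated.append("sigma2_gamma")
        stratum_below = sigma2_e + m * sigma2_gamma
    else:
        if m >= 2:
            sigma2_e = (ss["ss_c"] + ss["ss_w"]) / (df_c + df_w)
        else:
            sigma2_e = ss["ss_c"] / df_c
        sigma2_gamma = 0.0
        stratum_below = sigma2_e

    lam_a = ss["ss_a"] / df_a
    sigma2_alpha = (lam_a - stratum_below) / (2 * m)
    if sigma2_alpha < 0:
        sigma2_alpha = 0.0
        truncated.append("sigma2_alpha")

    out = {
        "sigma2_alpha": sigma2_alpha,
        "sigma2_gamma": sigma2_gamma,
        "sigma2_e": sigma2_e,
        "truncated": tuple(truncated),
        "sigma2_e1": None,
        "sigma2_e2": None,
    }
    if not equal_error_variances:
        if m < 2:
            raise ConfigurationError("per-device error variances need m >= 2")
        df = n * (m - 1)
        e1 = ss["ss_w_dev"][0] / df
        e2 = ss["ss_w_dev"][1] / df
        out.update(sigma2_e1=e1, sigma2_e2=e2, sigma2_e=(e1 + e2) / 2.0)
    return out


def fit_balanced_vc(
    data: AgreementData,
    include_interaction: bool = False,
    equal_error_variances: bool = True,
) -> MixedModelFit:
    """Closed-form ANOVA estimators for balanced, covariate-free data.

    These coincide with REML whenever no component truncates at zero.  The
    error variance comes from within-cell replicate scatter (pooled with the
    subject x device stratum when no interaction term is fitted, or split by
    device when ``equal_error_variances`` is false), the interaction variance
    from the subject x device mean square, and the subject variance from the
    subject mean square minus the stratum below, divided by ``2m``.
    """
    if not data.balanced:
        raise DataError("fit_balanced_vc requires balanced data")
    if data.covariates:
        raise ConfigurationError(
            "fit_balanced_vc does not support covariates; use fit_reml_general"
        )
    if data.n < 2:
        raise DataError("need at least 2 subjects")
    ss = _balanced_ss(data.balanced_values())
    vc = _vc_from_ss(ss, include_interaction, equal_error_variances, restricted=True)
    return MixedModelFit(
        beta_diff=ss["beta_diff"],
        intercept=ss["intercept"],
        n=data.n,
        m=data.m,
        method="balanced-ANOVA/REML",
        devices=data.devices,
        include_interaction=include_interaction,
        equal_error_variances=equal_error_variances,
        sigma2_alpha=vc["sigma2_alpha"],
        sigma2_gamma=vc["sigma2_gamma"],
        sigma2_e=vc["sigma2_e"],
        sigma2_e1=vc["sigma2_e1"],
        sigma2_e2=vc["sigma2_e2"],
        truncated=vc["truncated"],
    )


def fit_reml_general(
    data: AgreementData,
    covariate_names: tuple[str, ...] | None = None,
    include_interaction: bool = False,
    reml: bool = True,
) -> MixedModelFit:
    """Numerical REML (or ML with ``reml=False``) fit via statsmodels MixedLM.

    Supports covariates and unbalanced data.  On balanced covariate-free
    data the estimates agree with :func:`fit_balanced_vc` to optimizer
    tolerance.
    """
    import statsmodels.formula.api as smf

    frame = data.frame.copy()
    frame["device"] = pd.Categorical(frame["device"], categories=list(data.devices))
    covariate_names = tuple(covariate_names if covariate_names is not None else data.covariates)
    for c in covariate_names:
        if c not in frame.columns:
            raise ConfigurationError(f"covariate {c!r} not present in data")
        col = frame[c]
        if col.nunique() < 2:
            raise FitError(f"covariate {c!r} is constant (confounded with the intercept)")

    rhs = ["device"] + list(covariate_names)
    formula = "value ~ " + " + ".join(rhs)
    vc_formula = {"interaction": "0 + C(device)"} if include_interaction else None
    if include_interaction and (data.m or 0) < 2:
        raise ConfigurationError("interaction variance needs m >= 2 replicates")

    model = smf.mixedlm(
        formula, data=frame, groups=frame["subject"],
        re_formula="1", vc_formula=vc_formula,
    )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise FitError("rank-deficient fixed-effects design (collinear covariates)")

    result = None
    last_error: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # BFGS at a tight gradient tolerance recovers the balanced closed
        # form to ~1e-10 relative; fall back to the more robust default
        # optimizers if it stumbles.
        for fit_kwargs in (
            {"method": "bfgs", "gtol": 1e-10, "maxiter": 2000},
            {"method": ["lbfgs", "powell"], "maxiter": 2000},
        ):
            try:
                candidate = model.fit(reml=reml, **fit_kwargs)
            except Exception as exc:
                last_error = exc
                continue
            if candidate.converged:
                result = candidate
                break
    if result is None:
        raise FitError(f"mixed-model fit did not converge ({last_error!r})")

    params = result.fe_params
    device_key = [k for k in params.index if k.startswith("device[")]
    if len(device_key) != 1:
        raise FitError(f"could not identify the device effect among {list(params.index)}")
    beta_diff = float(params[device_key[0]])
    covariate_effects = {
        k: float(v)
        for k, v in params.items()
        if k not in ("Intercept",) and not k.startswith("device[")
    }
    sigma2_alpha = float(np.asarray(result.cov_re)[0, 0])
    sigma2_gamma = float(result.vcomp[0]) if include_interaction else 0.0
    sigma2_e = float(result.scale)
    k_params = len(params) + 1 + (1 if include_interaction else 0) + 1  # + alpha, gamma, scale
    llf = float(result.llf)
    counts = frame.groupby(["subject", "device"], observed=True).size()
    m = data.m if data.m is not None else int(round(counts.mean()))
    return MixedModelFit(
        beta_diff=beta_diff,
        intercept=float(params["Intercept"]),
        n=data.n,
        m=m,
        method="general-REML" if reml else "MLE",
        devices=data.devices,
        include_interaction=include_interaction,
        equal_error_variances=True,
        sigma2_alpha=max(sigma2_alpha, 0.0),
        sigma2_gamma=max(sigma2_gamma, 0.0),
        sigma2_e=sigma2_e,
        covariate_effects=covariate_effects,
        loglik=llf,
        aic=-2.0 * llf + 2.0 * k_params,
    )


# ---------------------------------------------------------------------------
# difference distributions


_CONVENTIONS = ("interaction", "no_interaction", "fixed_only", "satterthwaite")


def _residual_df_for(fit: MixedModelFit, convention: str) -> float:
    from .tolerance import residual_df  # local import to avoid a cycle

    return residual_df(fit.n, fit.m, convention, fit=fit)


def difference_params(
    fit: MixedModelFit,
    kind: str = "total",
    df_convention: str = "auto",
    device: str | None = None,
) -> DifferenceParams:
    """Distribution parameters of the total, intra- or inter-method paired
    difference, with the ``N`` and ``nu`` bookkeeping used by the
    tolerance-interval bound.

    ``df_convention='auto'`` resolves to ``interaction`` when the fit
    includes the interaction term, ``satterthwaite`` for unequal error
    variances, and ``no_interaction`` otherwise.  ``N = 2*n*m`` (the total
    possible paired-measurement differences) for every kind.  For
    ``kind='intra'`` with unequal error variances, ``device`` selects which
    device's repeatability is measured.
    """
    if kind not in ("total", "intra", "inter"):
        raise ConfigurationError(f"unknown difference kind {kind!r}")
    if df_convention == "auto":
        if not fit.equal_error_variances:
            df_convention = "satterthwaite"
        elif fit.include_interaction:
            df_convention = "interaction"
        else:
            df_convention = "no_interaction"
    if df_convention not in _CONVENTIONS:
        raise ConfigurationError(f"unknown df convention {df_convention!r}")

    if fit.equal_error_variances:
        e_sum = 2.0 * fit.sigma2_e            # sigma2_e1 + sigma2_e2
    else:
        e_sum = fit.sigma2_e1 + fit.sigma2_e2

    if kind == "total":
        mu = fit.beta_diff
        var = 2.0 * fit.sigma2_gamma + e_sum
    elif kind == "inter":
        mu = fit.beta_diff
        var = 2.0 * fit.sigma2_gamma + e_sum / fit.m
    else:  # intra
        mu = 0.0
        if fit.equal_error_variances:
            var = 2.0 * fit.sigma2_e
        else:
            if device is None:
                raise ConfigurationError(
                    "intra-method TDI with unequal error variances needs a device"
                )
            try:
                idx = fit.devices.index(str(device))
            except ValueError:
                raise ConfigurationError(f"unknown device {device!r}") from None
            var = 2.0 * (fit.sigma2_e1, fit.sigma2_e2)[idx]

    if var <= 0:
        raise DegenerateDistributionError(
            f"{kind} difference distribution is degenerate (variance {var})"
        )
    nu = _residual_df_for(fit, df_convention)
    return DifferenceParams(
        mu_D=mu,
        sigma_D=math.sqrt(var),
        kind=kind,
        N=2 * fit.n * fit.m,
        nu=nu,
        df_convention=df_convention,
    )
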