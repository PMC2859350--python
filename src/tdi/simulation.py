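"""Scenario generator and Monte-Carlo harness for the TDI inference methods.

Scenarios emulate a blood-pressure device-comparison study: two devices,
``m = 2`` replicates each, a large between-subject variance, and a grid of
device effects (0 / 2.174 / 5 mmHg), error variances (16 / 52.867 mmHg^2)
and sample sizes (20 / 100 subjects).  Each replicate draws every subject's
``2m``-vector from a multivariate normal whose covariance is
``sigma2_alpha * J + sigma2_e * I`` (no subject x device interaction),
fits the no-interaction model, and computes the TDI estimate with its
one-sided 95% bound for each requested method.

Summary metrics per (scenario, p, method):

* ``mean_log_estimate`` — mean of log TDI estimates,
* ``mse_log_x1000``    — 1000 x mean squared error of the log estimate
  against the analytic truth,
* ``ec_percent``       — empirical confidence: percent of replicates whose
  true log TDI lies at or below the log upper bound,

each with its Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .core import SearchSettings, solve_p1, tdi_msd_approx, tdi_ncx2_exact
from .data_io import AgreementData
from .exceptions import ConfigurationError, FitError
from .model_fit import _balanced_ss, _vc_from_ss
from .tolerance import noncentral_t_quantile

__all__ = [
    "SimulationScenario",
    "true_log_tdi",
    "generate_dataset",
    "run_scenario",
    "replicate_table3",
    "DEFAULT_GRID",
]

#: study-condition defaults: device effects, error variances and sample sizes
DEFAULT_GRID = {
    "beta_diff": (0.0, 2.174, 5.0),
    "sigma2_e": (16.0, 52.867),
    "n": (20, 100),
}

METHODS = ("TI", "lin", "choudhary")


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    Defaults mirror the blood-pressure case: intercept 133.369 mmHg,
    between-subject variance 380.187 mmHg^2, ``m = 2`` replicates, 1000
    replicates per scenario, nominal 95% one-sided bounds, and a search
    tolerance of 1e-4 for the per-replicate binary searches.
    """

    beta_diff: float = 2.174
    sigma2_e: float = 52.867
    n: int = 100
    m: int = 2
    intercept: float = 133.369
    sigma2_alpha: float = 380.187
    n_sims: int = 1000
    seed: int = 20100408
    p_levels: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95)
    alpha: float = 0.05
    methods: tuple[str, ...] = ("TI",)
    search_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.sigma2_e < 0 or self.sigma2_alpha < 0:
            raise ConfigurationError("variances must be >= 0")
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")
        if self.n < 2 or self.m < 1:
            raise ConfigurationError("need n >= 2 and m >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")

    @property
    def sigma_D(self) -> float:
        """True total-difference standard deviation (no interaction
        simulated): sqrt(2*sigma2_e)."""
        return math.sqrt(2.0 * self.sigma2_e)


def true_log_tdi(scenario: SimulationScenario, p: float) -> float:
    """Analytic log TDI of the generating distribution via the non-central
    chi-square definition."""
    return math.log(tdi_ncx2_exact(scenario.beta_diff, scenario.sigma_D, p))


def _generate_values(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    """Raw measurements of one replicate dataset, shape (n, 2, m).

    Equivalent to a draw from MVN(X(delta, beta), sigma2_alpha*J +
    sigma2_e*I) per subject, realised as subject effect + error.
    """
    n, m = scenario.n, scenario.m
    subj = rng.normal(0.0, math.sqrt(scenario.sigma2_alpha), size=n)
    errors = rng.normal(0.0, math.sqrt(scenario.sigma2_e), size=(n, 2, m))
    mean = np.array([scenario.intercept, scenario.intercept + scenario.beta_diff])
    return mean[None, :, None] + subj[:, None, None] + errors


def generate_dataset(
    scenario: SimulationScenario, rng: np.random.Generator | int | None = None
) -> AgreementData:
    """One simulated balanced dataset as :class:`AgreementData`.

    Deterministic for a fixed generator state / integer seed; defaults to
    the scenario's own seed.
    """
    if rng is None:
        rng = scenario.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = _generate_values(scenario, rng)
    n, _, m = values.shape
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, n + 1), 2 * m),
            "device": np.tile(np.repeat(["device1", "device2"], m), n),
            "replicate": np.tile(np.arange(1, m + 1), 2 * n),
            "value": values.reshape(-1),
        }
    )
    return AgreementData.from_frame(frame, device_order=("device1", "device2"))


def _scenario_rng(scenario: SimulationScenario) -> np.random.Generator:
    """Independent, reproducible stream per scenario cell: the master seed is
    combined with the scenario coordinates."""
    key = (
        scenario.seed,
        int(round(scenario.beta_diff * 1000)),
        int(round(scenario.sigma2_e * 1000)),
        scenario.n,
        scenario.m,
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def _replicate_metrics(scenario, values, settings, z_conf):
    """Per-replicate estimates/bounds for every method and p level."""
    n, m = scenario.n, scenario.m
    ss = _balanced_ss(values)
    out = {}

    if "TI" in scenario.methods:
        vc = _vc_from_ss(ss, include_interaction=False, restricted=True)
        sigma_d = math.sqrt(2.0 * vc["sigma2_e"])
        mu = abs(ss["beta_diff"])
        N = 2 * n * m
        nu = 2 * n * m - (n + m - 1)
        sqrt_n = math.sqrt(N)
        for p in scenario.p_levels:
            p1 = solve_p1(mu / sigma_d, p, settings)
            z1 = ndtri(p1)
            kappa = mu + sigma_d * z1
            ub = mu + sigma_d * noncentral_t_quantile(1 - scenario.alpha, nu, sqrt_n * z1) / sqrt_n
            out[("TI", p)] = (math.log(kappa), math.log(ub))

    if "lin" in scenario.methods or "choudhary" in scenario.methods:
        from .comparators import _grad_log_kappa, _sigma2_d

        df_w = 2 * n * (m - 1)
        for method, restricted in (("lin", True), ("choudhary", False)):
            if method not in scenario.methods:
                continue
            df_c = (n - 1) if restricted else n
            theta = np.array([ss["beta_diff"], ss["ss_c"] / df_c, ss["ss_w"] / df_w])
            cov = np.diag(
                [2.0 * theta[1] / (n * m), 2.0 * theta[1] ** 2 / df_c, 2.0 * theta[2] ** 2 / df_w]
            )
            for p in scenario.p_levels:
                if method == "lin":
                    def kappa_fn(th, _p=p):
                        return tdi_msd_approx(
                            th[0], math.sqrt(_sigma2_d(th, ss, False, True)), _p
                        )
                else:
                    def kappa_fn(th, _p=p):
                        return tdi_ncx2_exact(
                            th[0], math.sqrt(_sigma2_d(th, ss, False, False)), _p
                        )
                kappa = kappa_fn(theta)
                grad = _grad_log_kappa(kappa_fn, theta)
                se_log = math.sqrt(float(grad @ cov @ grad))
                log_ub = math.log(kappa) + z_conf * se_log
                out[(method, p)] = (math.log(kappa), log_ub)
    return out


def run_scenario(scenario: SimulationScenario) -> pd.DataFrame:
    """Monte-Carlo summary for one scenario: one row per (p, method).

    Columns: scenario coordinates, ``true_log_kappa``, ``mean_log_estimate``,
    ``mean_log_ub``, ``mse_log_x1000``, ``ec_percent``, Monte-Carlo standard
    errors, replicate counts and the seed.  Replicates whose fit fails are
    dropped; more than 1% failures aborts the summary.
    """
    rng = _scenario_rng(scenario)
    settings = SearchSettings(tol=scenario.search_tol)
    z_conf = ndtri(1.0 - scenario.alpha)

    logs = {(meth, p): [] for meth in scenario.methods for p in scenario.p_levels}
    log_ubs = {key: [] for key in logs}
    failures = 0
    for _ in range(scenario.n_sims):
        values = _generate_values(scenario, rng)
        try:
            metrics = _replicate_metrics(scenario, values, settings, z_conf)
        except Exception:
            failures += 1
            continue
        for key, (lk, lub) in metrics.items():
            logs[key].append(lk)
            log_ubs[key].append(lub)
    if failures > 0.01 * scenario.n_sims:
        raise FitError(
            f"{failures}/{scenario.n_sims} replicates failed to fit; "
            "scenario summary aborted"
        )

    rows = []
    for (method, p), lk in logs.items():
        lk = np.asarray(lk)
        lub = np.asarray(log_ubs[(method, p)])
        truth = true_log_tdi(scenario, p)
        covered = lub >= truth
        ec = 100.0 * covered.mean()
        n_used = len(lk)
        rows.append(
            {
                "mu_D": scenario.beta_diff,
                "sigma2_e": scenario.sigma2_e,
                "sigma_D": scenario.sigma_D,
                "n": scenario.n,
                "m": scenario.m,
                "p": p,
                "method": method,
                "true_log_kappa": truth,
                "mean_log_estimate": lk.mean(),
                "mean_log_ub": lub.mean(),
                "mse_log_x1000": 1000.0 * ((lk - truth) ** 2).mean(),
                "ec_percent": ec,
                "mc_se_mean": lk.std(ddof=1) / math.sqrt(n_used) if n_used > 1 else np.nan,
                "mc_se_ec": 100.0 * math.sqrt(max(covered.mean() * (1 - covered.mean()), 0.0) / n_used),
                "n_sims": n_used,
                "n_failed": failures,
                "seed": scenario.seed,
            }
        )
    return pd.DataFrame(rows)


def replicate_table3(
    grid: dict | None = None,
    n_sims: int = 1000,
    seed: int = 20100408,
    methods: tuple[str, ...] = ("TI",),
    p_levels: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95),
    base: SimulationScenario | None = None,
) -> pd.DataFrame:
    """Run the full scenario grid and stack the summaries into one table
    (one row per scenario x p x method).

    ``grid`` holds lists for ``beta_diff``, ``sigma2_e`` and ``n``; missing
    keys fall back to the default design.
    """
    grid = {**DEFAULT_GRID, **(grid or {})}
    extra = set(grid) - set(DEFAULT_GRID)
    if extra:
        raise ConfigurationError(f"unknown grid keys: {sorted(extra)}")
    base = base or SimulationScenario()
    frames = []
    for s2e in grid["sigma2_e"]:
        for mu in grid["beta_diff"]:
            for n in grid["n"]:
                scenario = replace(
                    base,
                    beta_diff=float(mu),
                    sigma2_e=float(s2e),
                    n=int(n),
                    n_sims=n_sims,
                    seed=seed,
                    methods=tuple(methods),
                    p_levels=tuple(p_levels),
                )
                frames.append(run_scenario(scenario))
    return pd.concat(frames, ignore_index=True)
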