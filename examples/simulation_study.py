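"""Monte-Carlo operating characteristics of the three TDI inference methods.

Runs one scenario of the evaluation design (no device effect, error variance
16, 20 subjects) at a reduced replicate count and compares the tolerance
interval (TI) bound with Lin's log-MSD and Choudhary's MLE plug-in bounds:
mean and MSE of the log TDI estimate and the empirical confidence (EC) of
each method's nominal 95% upper bound.
"""

from tdi import SimulationScenario, run_scenario

scenario = SimulationScenario(
    beta_diff=0.0,
    sigma2_e=16.0,
    n=20,
    n_sims=300,          # the full design uses 1000
    p_levels=(0.80, 0.95),
    methods=("TI", "lin", "choudhary"),
    seed=20100408,
)
table = run_scenario(scenario)
cols = ["method", "p", "true_log_kappa", "mean_log_estimate",
        "mse_log_x1000", "ec_percent", "mc_se_ec"]
print(table[cols].round(3).to_string(index=False))
# With a zero device effect the symmetric TI bound over-covers (EC above the
# nominal 95), the known conservative regime of this approach, while the two
# competitors sit nearer 95.  The mean log estimates show the slight upward
# bias of the TDI estimate at this small sample size.
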