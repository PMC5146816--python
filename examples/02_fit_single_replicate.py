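"""Fit both analysis models to a single simulated replicate and compare.

With shape a=1 the generating hazard is constant, so the semi-parametric
Cox fit and the parametric Weibull fit estimate the same log hazard
ratio; their estimates should agree to well within one standard error.
"""

from survpower import SimulationConfig, fit_cox, fit_weibull, simulate_dataset

sim = SimulationConfig(
    n_subjects=500,
    maf=0.3,
    shape_a=1.0,
    baseline_scale_d0=0.1,
    beta_snp=0.4,
    scenario=2,
    end_of_study_Z=5.0,
    censor_scale=4.0,
    seed=7,
)
ds = simulate_dataset(sim)
print(f"{ds.n} subjects, {ds.n_events} events\n")

cox = fit_cox(ds, ("snp",))
wb = fit_weibull(ds, ("snp",))

print("model    beta_snp     SE        Wald p    extra")
print(
    f"cox      {cox.coef['snp']:+.4f}   {cox.se['snp']:.4f}   "
    f"{cox.pvalue['snp']:.2e}  ({cox.n_iter} NR iterations)"
)
print(
    f"weibull  {wb.coef['snp']:+.4f}   {wb.se['snp']:.4f}   "
    f"{wb.pvalue['snp']:.2e}  shape={wb.shape:.3f}, "
    f"baseline rate={2.718281828 ** wb.intercept:.4f}"
)
print(
    "\nbeta_snp is the log hazard ratio per minor allele (true value 0.4). "
    "The Weibull shape estimate should sit near the generating a=1, and its "
    "baseline rate near d0=0.1."
)
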