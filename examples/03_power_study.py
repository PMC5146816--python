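"""Run a full Monte-Carlo power study, including interaction power.

Data are generated with SNP, treatment and SNP-treatment interaction
effects under scenario 4; the analysis fits the correctly specified joint
Weibull model. Power for each term is the fraction of replicates whose
Wald p-value falls below alpha = 0.05.
"""

from survpower import AnalysisConfig, SimulationConfig, run_power_study

sim = SimulationConfig(
    n_subjects=500,
    maf=0.3,
    treat_prob=0.5,
    shape_a=1.0,
    baseline_scale_d0=0.1,
    beta_snp=0.4,
    beta_trt=0.3,
    beta_int=0.2,
    scenario=4,
    end_of_study_Z=5.0,
    recruit_end_R=2.0,
    censor_scale=4.0,
    seed=42,
)
analysis = AnalysisConfig(
    model="weibull", covariates="snp+trt+int", alpha=0.05, n_replicates=500
)

result = run_power_study(sim, analysis)
print(result.format_summary())
print(
    "power_snp is the probability of detecting the per-allele effect "
    f"(true beta_s={sim.beta_snp}) at alpha={analysis.alpha}; "
    "power_interaction is the same for the pharmacogenetic interaction "
    f"(true beta_gamma={sim.beta_int}), which needs far larger samples. "
    "mc_se_* are binomial Monte-Carlo standard errors; mean_beta_snp should "
    "sit near the true 0.4 because the analysis model is correctly specified."
)
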