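"""Reproduce the bias caused by analysing only the SNP when the data
contain treatment and interaction effects.

Data carry beta_snp=0.4 plus a positive treatment and interaction effect.
A SNP-only analysis absorbs part of the interaction into the SNP term, so
its estimates centre above 0.4 (near 0.4 + beta_int * E[x]); the joint
model is unbiased.
"""

import numpy as np

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
    seed=9,
)

for label, covariates in (("SNP only (misspecified)", "snp"),
                          ("joint SNP+trt+int      ", "snp+trt+int")):
    r = run_power_study(
        sim, AnalysisConfig(model="weibull", covariates=covariates, n_replicates=300)
    )
    h = r.hist_beta_snp
    mcse = h.sd / np.sqrt(h.n)
    print(f"{label}: mean beta_snp = {h.mean:.3f} (MC-SE {mcse:.3f}), "
          f"power_snp = {r.power_snp:.2f}")

print(
    "\nTrue beta_snp is 0.4. The misspecified analysis centres near "
    "0.4 + beta_int*E[treatment] = 0.5 — biased but apparently more "
    "'powerful' because it tests an inflated effect. Histogram data for "
    "plotting are in result.hist_beta_snp.to_frame()."
)
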