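# survpower

Monte-Carlo power calculations for genetic association studies with
time-to-event outcomes, aimed at pharmacogenetic designs: how large a
cohort is needed to detect a SNP effect — or a SNP-treatment
interaction — on survival, remission time, or time to an adverse drug
reaction, given realistic censoring and recruitment patterns?

## The model

Each replicate simulates `n` subjects. Genotypes are additive minor-allele
counts `S ∈ {0,1,2}` drawn Binomial(2, q) under Hardy-Weinberg
equilibrium; an optional treatment arm `x ∈ {0,1}` is Bernoulli(p).
Latent event times follow a Weibull proportional-hazards law with hazard

    h_i(t) = a · b_i · t^(a−1),   b_i = d0 · exp(β_s S_i + β_x x_i + β_γ S_i x_i)

so `β_s`, `β_x`, `β_γ` are log hazard ratios at any shape `a` (`a = 1`
gives a constant hazard, `a > 1` an increasing one). Observed
`(time, event)` pairs come from one of four study designs:

1. administrative censoring at the end-of-study horizon `Z`;
2. plus exponential drop-out with mean `censor_scale` (smaller mean ⇒ more censoring);
3. plus a staggered recruitment period (entry times uniform on `{0,…,R}`,
   shrinking each subject's horizon to `Z − r_i`);
4. drop-out and recruitment combined.

Each replicate is analysed with either a **Cox proportional-hazards
model** (Breslow/Efron partial likelihood, Newton-Raphson) or a
**parametric Weibull regression** (full maximum likelihood with analytic
gradient and Hessian), fitting the SNP alone, SNP + treatment, or
SNP + treatment + interaction. Power at threshold `φ` is the fraction of
replicates whose Wald p-value for the coefficient of interest falls below
`φ`, with a binomial Monte-Carlo standard error; `φ = 5×10⁻⁸` gives
genome-wide power, `φ = 0.05` single-SNP power.

## Worked example

500 subjects, MAF 0.3, a 1:1 treatment arm, constant baseline hazard
(`a=1`, `d0=0.1`), true effects `β_s=0.4`, `β_x=0.3`, `β_γ=0.2`, with
drop-out (mean 4) and a recruitment period (`R=2`, `Z=5`) — scenario 4 —
analysed with the correctly specified joint Weibull model:

```python
from survpower import AnalysisConfig, SimulationConfig, run_power_study

sim = SimulationConfig(
    n_subjects=500, maf=0.3, treat_prob=0.5, shape_a=1.0,
    baseline_scale_d0=0.1, beta_snp=0.4, beta_trt=0.3, beta_int=0.2,
    scenario=4, end_of_study_Z=5.0, recruit_end_R=2.0, censor_scale=4.0,
    seed=42,
)
analysis = AnalysisConfig(model="weibull", covariates="snp+trt+int",
                          alpha=0.05, n_replicates=500)
print(run_power_study(sim, analysis).format_summary())
```

prints

```
replicates        500
converged         500
inestimable_snp   0
evaluable         500
alpha             0.05
power_snp         0.6080
mc_se_snp         0.0218
power_interaction 0.1100
mc_se_interaction 0.0140
mean_beta_snp     0.4121
sd_beta_snp       0.1932
```

i.e. this design detects the per-allele effect in ~61% of studies at
α = 0.05 (±2.2% Monte-Carlo error) but the interaction in only ~11% —
interaction effects need far larger cohorts. `mean_beta_snp` sits at the
true 0.4 because the analysis model matches the generative model; the
`examples/04_misspecification_bias.py` script shows how a SNP-only
analysis of the same data centres near 0.5 instead.

The same study runs from the shell:

```sh
survpower --n 500 --maf 0.3 --treat-prob 0.5 --baseline-scale 0.1 \
  --beta-snp 0.4 --beta-trt 0.3 --beta-int 0.2 --scenario 4 \
  --end-of-study 5 --recruit-end 2 --censor-scale 4 \
  --model weibull --covariates snp+trt+int --replicates 500 --seed 42 \
  --out-dir out/
```

writing a power summary (text + JSON), a per-replicate results table,
histogram data for the effect estimates and −log10 p-values, a run
manifest that reproduces the run bit-identically, and (with
`--save-sample` / `--save-all-replicates`) the simulated datasets as
R-readable delimited text. `examples/` contains one short narrative
script per capability.

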