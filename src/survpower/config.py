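"""Configuration objects and cross-field validation.

Two configuration records drive a power study: :class:`SimulationConfig`
describes the generative model (one SNP under Hardy-Weinberg equilibrium,
an optional binary treatment arm, Weibull proportional-hazards event times,
and one of four censoring/recruitment scenarios), and
:class:`AnalysisConfig` describes the fitted model and the significance
threshold used to declare a replicate significant.

The records are plain containers; :func:`validate_configs` collects every
cross-field violation instead of raising on the first, so a command-line
run can report all problems at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "SimulationConfig",
    "AnalysisConfig",
    "COVARIATE_SETS",
    "validate_configs",
]

#: Allowed analysis covariate sets, keyed by the shorthand used on the
#: command line.  Values are ordered tuples of design-matrix column names.
COVARIATE_SETS = {
    "snp": ("snp",),
    "snp+trt": ("snp", "treatment"),
    "snp+trt+int": ("snp", "treatment", "interaction"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one study design.

    Parameters
    ----------
    n_subjects
        Cohort size per replicate.
    maf
        Minor-allele frequency q in (0, 0.5]; genotypes are Binomial(2, q)
        draws (additive coding 0/1/2) under Hardy-Weinberg equilibrium.
    shape_a
        Weibull shape a > 0 of the event-time distribution. a = 1 gives a
        constant hazard (exponential times); a > 1 an increasing hazard.
    baseline_scale_d0
        Baseline Weibull rate d0 > 0. The subject-level rate is
        b_i = d0 * exp(beta_snp*S_i + beta_trt*x_i + beta_int*S_i*x_i) and
        the hazard is h_i(t) = a * b_i * t**(a-1) (rate convention: the
        betas are log-hazard-ratio effects).
    beta_snp, beta_trt, beta_int
        Log-hazard effects per minor allele, of active treatment, and of
        the SNP-treatment interaction.
    scenario
        Study design: 1 end-of-study censoring only; 2 adds exponential
        drop-out; 3 adds a staggered recruitment period; 4 combines both.
    end_of_study_Z
        Administrative follow-up horizon Z > 0.
    recruit_end_R
        End of the recruitment period, 0 <= R < Z (scenarios 3 and 4).
        Recruitment times are discrete uniform on {0, ..., floor(R)}.
    censor_scale
        Mean of the exponential drop-out-time distribution (scenarios 2
        and 4).  This is a *mean-scale* convention, deliberately different
        from the event-time rate convention: smaller values mean earlier
        drop-out and hence more censoring.
    treat_prob
        Probability of allocation to the active arm; ``None`` means no
        treatment arm is simulated.
    seed
        Master RNG seed.  Each replicate uses an independent child stream
        derived from (seed, replicate index).
    continuous_recruitment
        If True, recruitment times are continuous uniform on [0, R]
        instead of the default discrete uniform on integers.
    """

    n_subjects: int
    maf: float
    shape_a: float
    baseline_scale_d0: float
    beta_snp: float
    scenario: int
    end_of_study_Z: float
    seed: int = 0
    treat_prob: Optional[float] = None
    beta_trt: float = 0.0
    beta_int: float = 0.0
    recruit_end_R: Optional[float] = None
    censor_scale: Optional[float] = None
    continuous_recruitment: bool = False

    @property
    def has_treatment(self) -> bool:
        return self.treat_prob is not None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side parameters.

    Parameters
    ----------
    model
        ``"cox"`` (partial-likelihood) or ``"weibull"`` (parametric ML).
    covariates
        One of ``"snp"``, ``"snp+trt"``, ``"snp+trt+int"``.
    alpha
        Significance threshold phi in (0, 1) for the Wald test; power is
        the proportion of replicates with p < alpha.  Genome-wide values
        such as 5e-8 are accepted verbatim.
    n_replicates
        Number of Monte-Carlo replicates m.
    nonconvergence_policy
        ``"exclude"`` removes non-converged / inestimable replicates from
        the power denominator and reports their count;
        ``"nonsignificant"`` keeps them in the denominator as failures to
        reject (conservative).
    ties
        Tie handling for the Cox partial likelihood: "breslow" (default)
        or "efron".
    """

    model: str = "cox"
    covariates: str = "snp"
    alpha: float = 0.05
    n_replicates: int = 1000
    nonconvergence_policy: str = "exclude"
    ties: str = "breslow"

    @property
    def covariate_names(self) -> tuple:
        return COVARIATE_SETS[self.covariates]

    def to_dict(self) -> dict:
        return asdict(self)


def validate_configs(sim: SimulationConfig, analysis: AnalysisConfig) -> list:
    """Return every configuration violation (empty list means valid).

    Checks both within-record ranges and the cross-record rules: the
    analysis cannot adjust for a treatment arm that was never simulated,
    and each scenario must be given the parameters it needs.
    """
    v: list = []

    if sim.n_subjects < 1:
        v.append("n_subjects must be a positive integer")
    if not (0.0 < sim.maf <= 0.5):
        v.append(f"maf must be in (0, 0.5], got {sim.maf}")
    if sim.shape_a <= 0:
        v.append(f"shape_a must be > 0, got {sim.shape_a}")
    if sim.baseline_scale_d0 <= 0:
        v.append(f"baseline_scale_d0 must be > 0, got {sim.baseline_scale_d0}")
    if sim.scenario not in (1, 2, 3, 4):
        v.append(f"scenario must be one of 1-4, got {sim.scenario}")
    if sim.end_of_study_Z <= 0:
        v.append(f"end_of_study_Z must be > 0, got {sim.end_of_study_Z}")

    if sim.treat_prob is not None and not (0.0 <= sim.treat_prob <= 1.0):
        v.append(f"treat_prob must be in [0, 1], got {sim.treat_prob}")
    if sim.treat_prob is None and (sim.beta_trt != 0.0 or sim.beta_int != 0.0):
        v.append("beta_trt / beta_int require a treatment arm (set treat_prob)")

    if sim.scenario in (2, 4):
        if sim.censor_scale is None:
            v.append(f"scenario {sim.scenario} requires censor_scale")
        elif sim.censor_scale <= 0:
            v.append(f"censor_scale must be > 0, got {sim.censor_scale}")
    if sim.scenario in (3, 4):
        if sim.recruit_end_R is None:
            v.append(f"scenario {sim.scenario} requires recruit_end_R")
        elif not (0.0 <= sim.recruit_end_R < sim.end_of_study_Z):
            v.append(
                "recruit_end_R must satisfy 0 <= R < end_of_study_Z "
                f"(got R={sim.recruit_end_R}, Z={sim.end_of_study_Z}); "
                "R >= Z would permit non-positive follow-up"
            )

    if analysis.model not in ("cox", "weibull"):
        v.append(f"model must be 'cox' or 'weibull', got {analysis.model!r}")
    if analysis.covariates not in COVARIATE_SETS:
        v.append(
            f"covariates must be one of {sorted(COVARIATE_SETS)}, "
            f"got {analysis.covariates!r}"
        )
    elif "treatment" in COVARIATE_SETS[analysis.covariates] and not sim.has_treatment:
        v.append(
            "treatment (or interaction) cannot be an analysis covariate "
            "when no treatment effect is included in the simulation model"
        )
    if not (0.0 < analysis.alpha <= 1.0):
        v.append(f"alpha must be in (0, 1], got {analysis.alpha}")
    if analysis.n_replicates < 1:
        v.append("n_replicates must be a positive integer")
    if analysis.nonconvergence_policy not in ("exclude", "nonsignificant"):
        v.append(
            "nonconvergence_policy must be 'exclude' or 'nonsignificant', "
            f"got {analysis.nonconvergence_policy!r}"
        )
    if analysis.ties not in ("breslow", "efron"):
        v.append(f"ties must be 'breslow' or 'efron', got {analysis.ties!r}")

    return v
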