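"""Simulation of one replicate of censored pharmacogenetic survival data.

One replicate contains, per subject: a SNP genotype S in {0,1,2} (minor
allele count under Hardy-Weinberg equilibrium), an optional binary
treatment indicator x, a latent Weibull event time anchored at study
entry, and the observed (time, event) pair produced by one of four
censoring / recruitment scenarios:

1. administrative censoring at the end-of-study horizon Z;
2. scenario 1 plus exponential drop-out;
3. scenario 1 plus a staggered recruitment period (each subject's
   administrative horizon shrinks to Z - r_i);
4. scenarios 2 and 3 combined.

Event times follow the rate-convention Weibull: hazard
h_i(t) = a * b_i * t**(a-1) with subject rate
b_i = d0 * exp(beta_snp*S_i + beta_trt*x_i + beta_int*S_i*x_i), so the
betas are exactly log hazard ratios at any shape a.  Drop-out times use
the *mean-scale* exponential convention (mean = censor_scale), so smaller
scales produce more censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "Dataset",
    "simulate_genotypes",
    "simulate_treatment",
    "simulate_event_times",
    "simulate_censoring_times",
    "simulate_recruitment",
    "apply_scenario",
    "simulate_dataset",
    "inverse_transform_time",
]


@dataclass
class Dataset:
    """One simulated replicate.

    ``observed_time`` and ``event`` are what the fitters see; the latent
    event time (entry-anchored) and recruitment time are retained so that
    the censoring logic can be audited subject by subject.
    """

    genotype: np.ndarray
    observed_time: np.ndarray
    event: np.ndarray
    treatment: Optional[np.ndarray] = None
    recruit_time: Optional[np.ndarray] = None
    latent_event_time: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.genotype)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: columns ``id time event snp [treatment]``."""
        cols = {
            "id": np.arange(1, self.n + 1),
            "time": self.observed_time,
            "event": self.event.astype(int),
            "snp": self.genotype.astype(int),
        }
        if self.treatment is not None:
            cols["treatment"] = self.treatment.astype(int)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        treatment = (
            df["treatment"].to_numpy(dtype=np.int64)
            if "treatment" in df.columns
            else None
        )
        return cls(
            genotype=df["snp"].to_numpy(dtype=np.int64),
            observed_time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=np.int64),
            treatment=treatment,
        )


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n additive-coded genotypes, Binomial(2, maf) under HWE.

    Coding counts minor alleles: AA=0, AB=1, BB=2, with expected
    frequencies ((1-q)^2, 2q(1-q), q^2).
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    return rng.binomial(2, maf, size=n)


def simulate_treatment(n: int, treat_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(treat_prob) allocation; 0 = placebo, 1 = active."""
    if not (0.0 <= treat_prob <= 1.0):
        raise ValueError(f"treat_prob must be in [0, 1], got {treat_prob}")
    return rng.binomial(1, treat_prob, size=n)


def inverse_transform_time(shape_a: float, rate_b, u) -> np.ndarray:
    """Closed-form Weibull draw t = (-log u / b)**(1/a).

    With u ~ Uniform(0,1) this samples the survivor function
    S(t) = exp(-b t^a), i.e. hazard a*b*t^(a-1).
    """
    if shape_a <= 0:
        raise ValueError(f"shape_a must be > 0, got {shape_a}")
    rate_b = np.asarray(rate_b, dtype=float)
    if np.any(rate_b <= 0):
        raise ValueError("rate parameter b must be > 0")
    return (-np.log(u) / rate_b) ** (1.0 / shape_a)


def simulate_event_times(
    config: SimulationConfig,
    genotype: np.ndarray,
    treatment: Optional[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent event times, entry-anchored, under the PH-Weibull model.

    The linear predictor is beta_snp*S (+ beta_trt*x + beta_int*S*x when
    a treatment arm is present); the subject rate multiplies the baseline
    d0 by exp(linear predictor).
    """
    if config.shape_a <= 0:
        raise ValueError(f"shape_a must be > 0, got {config.shape_a}")
    if config.baseline_scale_d0 <= 0:
        raise ValueError(
            f"baseline_scale_d0 must be > 0, got {config.baseline_scale_d0}"
        )
    eta = config.beta_snp * genotype.astype(float)
    if treatment is not None:
        x = treatment.astype(float)
        eta = eta + config.beta_trt * x + config.beta_int * genotype * x
    rate = config.baseline_scale_d0 * np.exp(eta)
    u = rng.uniform(size=len(genotype))
    return inverse_transform_time(config.shape_a, rate, u)


def simulate_censoring_times(
    n: int, censor_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Exponential drop-out times with mean ``censor_scale``.

    Shape-1 Weibull in the mean-scale convention: small scales give early
    drop-out and therefore more censored observations.
    """
    if censor_scale <= 0:
        raise ValueError(f"censor_scale must be > 0, got {censor_scale}")
    return rng.exponential(scale=censor_scale, size=n)


def simulate_recruitment(
    n: int,
    recruit_end_R: float,
    rng: np.random.Generator,
    continuous: bool = False,
) -> np.ndarray:
    """Recruitment (entry) times on [0, R].

    Default is the discrete uniform on the integers {0, 1, ..., floor(R)};
    ``continuous=True`` switches to the continuous uniform on [0, R].
    """
    if recruit_end_R < 0:
        raise ValueError(f"recruit_end_R must be >= 0, got {recruit_end_R}")
    if continuous:
        return rng.uniform(0.0, recruit_end_R, size=n)
    return rng.integers(0, int(np.floor(recruit_end_R)) + 1, size=n).astype(float)


def apply_scenario(
    config: SimulationConfig,
    latent_times: np.ndarray,
    censor_times: Optional[np.ndarray] = None,
    recruit_times: Optional[np.ndarray] = None,
):
    """Observed (time, event) under the configured scenario.

    All times are anchored at each subject's study entry.  The follow-up
    horizon is H_i = Z (scenarios 1-2) or Z - r_i (3-4); drop-out is
    C_i = c_i (scenarios 2 and 4) or absent.  Then

        observed_time = min(t_i, C_i, H_i)
        event         = 1  iff  t_i <= min(C_i, H_i).

    A subject whose latent event time exceeds the horizon is
    administratively censored at H_i; one who drops out first is censored
    at the drop-out time.
    """
    scenario = config.scenario
    Z = config.end_of_study_Z
    t = np.asarray(latent_times, dtype=float)
    if np.any(t < 0):
        raise ValueError("latent event times must be non-negative")
    n = len(t)

    if scenario in (2, 4):
        if censor_times is None:
            raise ValueError(f"scenario {scenario} requires censoring times")
        c = np.asarray(censor_times, dtype=float)
        if np.any(c < 0):
            raise ValueError("censoring times must be non-negative")
    else:
        c = np.full(n, np.inf)

    if scenario in (3, 4):
        if recruit_times is None:
            raise ValueError(f"scenario {scenario} requires recruitment times")
        r = np.asarray(recruit_times, dtype=float)
        if np.any(r < 0):
            raise ValueError("recruitment times must be non-negative")
        horizon = Z - r
        if np.any(horizon <= 0):
            raise ValueError("recruitment at or after end of study (R >= Z)")
    else:
        horizon = np.full(n, Z)

    cens = np.minimum(c, horizon)
    observed = np.minimum(t, cens)
    event = (t <= cens).astype(np.int64)
    return observed, event


def simulate_dataset(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Dataset:
    """Generate one full replicate from a :class:`SimulationConfig`.

    Draw order (genotype, treatment, event times, drop-out, recruitment)
    is fixed so a given generator state always yields the same replicate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    genotype = simulate_genotypes(n, config.maf, rng)
    treatment = (
        simulate_treatment(n, config.treat_prob, rng) if config.has_treatment else None
    )
    latent = simulate_event_times(config, genotype, treatment, rng)
    censor = (
        simulate_censoring_times(n, config.censor_scale, rng)
        if config.scenario in (2, 4)
        else None
    )
    recruit = (
        simulate_recruitment(
            n, config.recruit_end_R, rng, continuous=config.continuous_recruitment
        )
        if config.scenario in (3, 4)
        else np.zeros(n)
    )

    observed, event = apply_scenario(
        config,
        latent,
        censor_times=censor,
        recruit_times=recruit if config.scenario in (3, 4) else None,
    )
    return Dataset(
        genotype=genotype,
        observed_time=observed,
        event=event,
        treatment=treatment,
        recruit_time=recruit,
        latent_event_time=latent,
    )
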