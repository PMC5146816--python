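"""Replicate orchestration and Monte-Carlo power estimation.

Power to detect the SNP effect (and the SNP-treatment interaction, when
that term is fitted) is approximated by the proportion of replicates whose
Wald p-value falls below the significance threshold.  Each replicate draws
from an independent child RNG stream derived from (master seed, replicate
index), so any single replicate can be regenerated in isolation and the
result is invariant to execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SimulationConfig, validate_configs
from .coxph import fit_cox
from .results import FitError
from .simdata import simulate_dataset
from .weibullreg import fit_weibull

__all__ = [
    "HistogramSummary",
    "PowerResult",
    "replicate_rng",
    "run_power_study",
    "summarize_estimates",
]

logger = logging.getLogger(__name__)


@dataclass
class HistogramSummary:
    """Binned counts plus mean/SD for one per-replicate statistic.

    Bin edges follow the Freedman-Diaconis rule (numpy's "fd"), which is
    deterministic given the data; a degenerate sample occupies one bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class PowerResult:
    """Outcome of one power study.

    ``power_snp`` is #{p_snp < alpha} / #evaluable; the Monte-Carlo
    standard error is the binomial sqrt(p(1-p)/m) over the same
    denominator.  ``table`` holds one row per replicate for downstream
    summaries and export.
    """

    power_snp: float
    mc_se_snp: float
    n_replicates: int
    n_converged: int
    n_inestimable: int
    n_evaluable: int
    alpha: float
    table: pd.DataFrame
    power_interaction: Optional[float] = None
    mc_se_interaction: Optional[float] = None
    hist_beta_snp: Optional[HistogramSummary] = None
    hist_neglog10_p: Optional[HistogramSummary] = None

    def to_json_dict(self) -> dict:
        d = {
            "power_snp": self.power_snp,
            "mc_se_snp": self.mc_se_snp,
            "alpha": self.alpha,
            "n_replicates": self.n_replicates,
            "n_converged": self.n_converged,
            "n_inestimable": self.n_inestimable,
            "n_evaluable": self.n_evaluable,
        }
        if self.power_interaction is not None:
            d["power_interaction"] = self.power_interaction
            d["mc_se_interaction"] = self.mc_se_interaction
        if self.hist_beta_snp is not None:
            d["mean_beta_snp"] = self.hist_beta_snp.mean
            d["sd_beta_snp"] = self.hist_beta_snp.sd
        return d

    def format_summary(self) -> str:
        lines = [
            f"replicates        {self.n_replicates}",
            f"converged         {self.n_converged}",
            f"inestimable_snp   {self.n_inestimable}",
            f"evaluable         {self.n_evaluable}",
            f"alpha             {self.alpha:g}",
            f"power_snp         {self.power_snp:.4f}",
            f"mc_se_snp         {self.mc_se_snp:.4f}",
        ]
        if self.power_interaction is not None:
            lines += [
                f"power_interaction {self.power_interaction:.4f}",
                f"mc_se_interaction {self.mc_se_interaction:.4f}",
            ]
        if self.hist_beta_snp is not None:
            lines += [
                f"mean_beta_snp     {self.hist_beta_snp.mean:.4f}",
                f"sd_beta_snp       {self.hist_beta_snp.sd:.4f}",
            ]
        return "\n".join(lines) + "\n"


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent child stream for one replicate (1-based index)."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(replicate,))
    )


def summarize_estimates(values: np.ndarray) -> Optional[HistogramSummary]:
    """Freedman-Diaconis histogram plus mean/SD of one statistic.

    Returns ``None`` (with a warning) for an empty input; a constant
    sample collapses to a single occupied bin.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        logger.warning("no evaluable replicates: histogram summary absent")
        return None
    if np.ptp(values) == 0.0:
        center = float(values[0])
        half = max(abs(center) * 1e-6, 1e-12)
        edges = np.array([center - half, center + half])
        counts = np.array([len(values)])
    else:
        counts, edges = np.histogram(values, bins="fd")
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n=len(values),
    )


def _fit_one(dataset, analysis: AnalysisConfig):
    if analysis.model == "cox":
        return fit_cox(dataset, analysis.covariate_names, ties=analysis.ties)
    return fit_weibull(dataset, analysis.covariate_names)


def run_power_study(sim: SimulationConfig, analysis: AnalysisConfig) -> PowerResult:
    """Simulate, fit and aggregate m replicates into a power estimate.

    Raises on invalid configuration (all violations listed) and when every
    replicate fails to produce a fit.  Non-converged or SNP-inestimable
    replicates are handled per ``analysis.nonconvergence_policy``:
    excluded from the power denominator (default) or counted as
    non-significant.
    """
    violations = validate_configs(sim, analysis)
    if violations:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(violations))

    with_int = "interaction" in analysis.covariate_names
    rows = []
    n_fit_errors = 0
    for j in range(1, analysis.n_replicates + 1):
        rng = replicate_rng(sim.seed, j)
        dataset = simulate_dataset(sim, rng)
        try:
            fit = _fit_one(dataset, analysis)
        except FitError as exc:
            n_fit_errors += 1
            logger.warning("replicate %d: %s (seed=%s)", j, exc, sim.seed)
            rows.append(
                {
                    "replicate": j,
                    "converged": False,
                    "estimable_snp": False,
                    "beta_snp": np.nan,
                    "se_snp": np.nan,
                    "p_snp": np.nan,
                }
                | (
                    {"beta_int": np.nan, "se_int": np.nan, "p_int": np.nan}
                    if with_int
                    else {}
                )
            )
            continue
        if not fit.converged:
            logger.warning(
                "replicate %d: non-convergence after %d iterations (seed=%s)",
                j,
                fit.n_iter,
                sim.seed,
            )
        row = {
            "replicate": j,
            "converged": fit.converged,
            "estimable_snp": fit.is_estimable("snp"),
            "beta_snp": fit.coef["snp"],
            "se_snp": fit.se["snp"],
            "p_snp": fit.pvalue["snp"],
        }
        if with_int:
            row["beta_int"] = fit.coef["interaction"]
            row["se_int"] = fit.se["interaction"]
            row["p_int"] = fit.pvalue["interaction"]
        rows.append(row)

    table = pd.DataFrame(rows)
    if n_fit_errors == analysis.n_replicates:
        raise RuntimeError(
            f"all {analysis.n_replicates} replicates failed to fit "
            "(e.g. zero events in every replicate); check the configuration"
        )

    ok = table["converged"] & table["estimable_snp"] & np.isfinite(table["p_snp"])
    n_converged = int(table["converged"].sum())
    n_inestimable = int((~table["estimable_snp"]).sum())

    def _power(pvals_ok: pd.Series):
        if analysis.nonconvergence_policy == "exclude":
            m = int(ok.sum())
            hits = int((pvals_ok[ok] < analysis.alpha).sum())
        else:  # nonsignificant: failures stay in the denominator as non-rejections
            m = analysis.n_replicates
            hits = int((pvals_ok[ok] < analysis.alpha).sum())
        if m == 0:
            raise RuntimeError("no evaluable replicates: power undefined")
        p_hat = hits / m
        return p_hat, float(np.sqrt(p_hat * (1 - p_hat) / m)), m

    power_snp, mc_se_snp, n_eval = _power(table["p_snp"])
    power_int = mc_se_int = None
    if with_int:
        power_int, mc_se_int, _ = _power(table["p_int"])

    return PowerResult(
        power_snp=power_snp,
        mc_se_snp=mc_se_snp,
        power_interaction=power_int,
        mc_se_interaction=mc_se_int,
        n_replicates=analysis.n_replicates,
        n_converged=n_converged,
        n_inestimable=n_inestimable,
        n_evaluable=n_eval,
        alpha=analysis.alpha,
        table=table,
        hist_beta_snp=summarize_estimates(table.loc[ok, "beta_snp"].to_numpy()),
        hist_neglog10_p=summarize_estimates(
            -np.log10(np.clip(table.loc[ok, "p_snp"].to_numpy(), 1e-300, None))
        ),
    )
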