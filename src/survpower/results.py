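"""Shared fit-result containers and the design-matrix builder."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Tuple

import numpy as np

from .simdata import Dataset

__all__ = ["FitError", "FitResult", "WeibullFit", "build_design"]


class FitError(ValueError):
    """Raised when a model cannot be fit at all (e.g. zero events)."""


@dataclass
class FitResult:
    """Per-replicate estimates and Wald tests for one fitted model.

    Coefficients that could not be estimated (constant covariate column,
    rank deficiency) are listed in ``inestimable`` and carry NaN entries;
    a fit that diverged (monotone likelihood) has ``converged=False`` but
    still reports the final iterate for diagnostics.
    """

    covariates: Tuple[str, ...]
    coef: Dict[str, float]
    se: Dict[str, float]
    zstat: Dict[str, float]
    pvalue: Dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    inestimable: FrozenSet[str] = frozenset()

    def is_estimable(self, name: str) -> bool:
        return name in self.covariates and name not in self.inestimable


@dataclass
class WeibullFit(FitResult):
    """FitResult plus the Weibull intercept (log baseline rate) and shape.

    The shape is estimated on the log scale; ``shape_se`` is the
    delta-method standard error of the shape itself.
    """

    intercept: float = np.nan
    intercept_se: float = np.nan
    shape: float = np.nan
    shape_se: float = np.nan


def build_design(dataset: Dataset, covariates: Tuple[str, ...]):
    """Design matrix for the requested covariate set.

    Returns ``(X, names, inestimable)`` where X holds only the estimable
    columns.  A column is inestimable when it is constant in the sample
    (monomorphic SNP, single-arm treatment draw, degenerate interaction)
    or linearly dependent on earlier columns.
    """
    allowed = ("snp", "treatment", "interaction")
    for name in covariates:
        if name not in allowed:
            raise ValueError(f"unknown covariate {name!r}")
    if "interaction" in covariates and "treatment" not in covariates:
        raise ValueError("'interaction' requires 'treatment' in the covariate set")
    if ("treatment" in covariates or "interaction" in covariates) and (
        dataset.treatment is None
    ):
        raise ValueError("dataset has no treatment arm for the requested covariates")

    columns = {}
    columns["snp"] = dataset.genotype.astype(float)
    if dataset.treatment is not None:
        columns["treatment"] = dataset.treatment.astype(float)
        columns["interaction"] = columns["snp"] * columns["treatment"]

    inestimable = set()
    kept: list = []
    kept_names: list = []
    for name in covariates:
        col = columns[name]
        if np.ptp(col) == 0.0:
            inestimable.add(name)
            continue
        candidate = np.column_stack(kept + [col]) if kept else col[:, None]
        if np.linalg.matrix_rank(candidate) <= len(kept):
            inestimable.add(name)
            continue
        kept.append(col)
        kept_names.append(name)

    X = np.column_stack(kept) if kept else np.empty((dataset.n, 0))
    return X, tuple(kept_names), frozenset(inestimable)
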