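"""Drivers of utilitarian redundancy: Gaussian GLMs with AIC model selection.

The Index of Variance per plot is regressed on up to six plot covariates
(basal area, felled trees, canopy height, distance from village, trails,
elevation) with Gaussian errors and an identity link — i.e. ordinary least
squares. Every predictor subset (64 models including intercept-only) is
fitted and ranked by AIC; Akaike weights exp(-delta/2) normalized over the
candidate set express each model's relative support, and models with
delta AIC < 2 form the "supported" set.

The AIC parameter count is k = p + 2 (intercept, p slopes, and the Gaussian
error variance); delta AIC and the weights are invariant to that constant.
Predictors enter untransformed and unstandardized, so coefficients are on
the covariates' raw scales. Reported df is n - (p + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import COVARIATE_COLUMNS
from .errors import CollinearityError, InsufficientDataError, SchemaError

logger = logging.getLogger(__name__)

DELTA_AIC_SUPPORT = 2.0


@dataclass(frozen=True)
class ModelFit:
    """One Gaussian-identity GLM fit of IV on a covariate subset."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]   # "intercept" + one entry per predictor
    bse: dict[str, float]            # standard errors, same keys
    rss: float
    loglik: float
    k: int                           # p + 2: intercept, slopes, error variance
    aic: float
    r2: float
    n: int

    @property
    def df(self) -> int:
        return self.n - (len(self.predictors) + 1)

    @property
    def label(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "intercept-only"


@dataclass(frozen=True)
class ModelSelectionTable:
    """All candidate fits ranked by AIC, with delta AIC and Akaike weights."""

    table: pd.DataFrame              # model, df, aic, delta_aic, akaike_weight, r2
    fits: tuple[ModelFit, ...]       # same order as table rows

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def supported(self) -> pd.DataFrame:
        """Rows with delta AIC below 2 — convincing support."""
        return self.table[self.table["delta_aic"] < DELTA_AIC_SUPPORT]


def _align(covariates: pd.DataFrame, iv_values: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    common = covariates.index.intersection(iv_values.index)
    n_dropped = max(len(covariates), len(iv_values)) - len(common)
    if n_dropped:
        logger.warning("dropping %d plots without matched covariates and IV", n_dropped)
    if len(common) == 0:
        raise SchemaError("no plots shared between covariates and IV values")
    return covariates.loc[common], iv_values.loc[common]


def fit_gaussian_glm(
    predictors,
    covariates: pd.DataFrame,
    iv_values: pd.Series,
) -> ModelFit:
    """OLS fit of IV on the named covariates (Gaussian errors, identity link).

    The log-likelihood uses the Gaussian MLE variance RSS/n, so
    aic = -2 loglik + 2k with k = p + 2.
    """
    predictors = tuple(predictors)
    unknown = [p for p in predictors if p not in covariates.columns]
    if unknown:
        raise SchemaError(f"unknown predictors: {unknown}")
    x_frame, y = _align(covariates, iv_values)
    n = len(y)
    p = len(predictors)
    k = p + 2
    if n <= k:
        raise InsufficientDataError(f"n={n} too small for {p} predictors (k={k})")

    design = sm.add_constant(x_frame[list(predictors)].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(f"rank-deficient design for predictors {predictors}")

    res = sm.OLS(y.to_numpy(dtype=float), design).fit()
    names = ("intercept",) + predictors
    return ModelFit(
        predictors=predictors,
        coefficients=dict(zip(names, (float(b) for b in res.params))),
        bse=dict(zip(names, (float(s) for s in res.bse))),
        rss=float(res.ssr),
        loglik=float(res.llf),
        k=k,
        aic=float(-2.0 * res.llf + 2.0 * k),
        r2=float(res.rsquared),
        n=n,
    )


def all_subsets_selection(
    covariates: pd.DataFrame,
    iv_values: pd.Series,
    predictors: tuple[str, ...] = COVARIATE_COLUMNS,
) -> ModelSelectionTable:
    """Fit every predictor subset (including intercept-only) and rank by AIC."""
    fits: list[ModelFit] = []
    for size in range(len(predictors) + 1):
        for subset in combinations(predictors, size):
            try:
                fits.append(fit_gaussian_glm(subset, covariates, iv_values))
            except (CollinearityError, InsufficientDataError) as exc:
                logger.warning("subset %s skipped: %s", subset, exc)
    if not fits:
        raise InsufficientDataError("no candidate model could be fitted")

    fits.sort(key=lambda f: (f.aic, len(f.predictors)))
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    weights = np.exp(-delta / 2.0)
    weights /= weights.sum()
    table = pd.DataFrame(
        {
            "model": [f.label for f in fits],
            "df": [f.df for f in fits],
            "aic": aic,
            "delta_aic": delta,
            "akaike_weight": weights,
            "r2": [f.r2 for f in fits],
        }
    )
    return ModelSelectionTable(table=table, fits=tuple(fits))
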