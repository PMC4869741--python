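"""Transforms from raw measurement scale to the analysis scale.

The causal analysis assumes approximately multivariate-normal inputs:
the risk factor is winsorised and log-transformed, metabolites are
log- (or rank-inverse-normal-) transformed and standardized to mean 0,
SD 1 per column.  Missingness is handled by dropping metabolites with
too many missing values here and by listwise deletion within each
statistical test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix, MetaboliteMatrix, PhenotypeTable

__all__ = [
    "winsorise",
    "log_transform",
    "transform_metabolites",
    "filter_missingness",
    "harmonize_samples",
    "prepare_outcome",
    "MetaboliteScaler",
]


def winsorise(
    values: np.ndarray | pd.Series, lower_q: float = 0.01, upper_q: float = 0.99
) -> tuple[np.ndarray, tuple[float, float]]:
    """Clamp values to the [lower_q, upper_q] empirical quantiles.

    Quantiles use linear interpolation between order statistics (the
    numpy default), computed on non-missing entries only; missing
    entries pass through untouched.  Returns the clamped vector and the
    (lower, upper) bounds applied.
    """
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    arr = np.asarray(values, dtype=float)
    finite = ~np.isnan(arr)
    if finite.sum() < 2:
        raise ValueError("winsorise needs at least 2 non-missing values")
    lo, hi = np.quantile(arr[finite], [lower_q, upper_q])
    out = arr.copy()
    out[finite] = np.clip(arr[finite], lo, hi)
    if isinstance(values, pd.Series):
        out = pd.Series(out, index=values.index, name=values.name)
    return out, (float(lo), float(hi))


def log_transform(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Natural log, elementwise; non-positive values are a hard error."""
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isnan(arr) & (arr <= 0))
    if bad.size:
        if isinstance(values, pd.Series):
            names = list(values.index[bad[:5]])
        else:
            names = list(bad[:5])
        raise ValueError(f"log_transform requires positive values; offending entries: {names}")
    out = np.log(arr)
    if isinstance(values, pd.Series):
        out = pd.Series(out, index=values.index, name=values.name)
    return out


def _rank_inverse_normal(col: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform: Phi^-1((r - 3/8)/(n + 1/4))."""
    out = np.full_like(col, np.nan, dtype=float)
    obs = ~np.isnan(col)
    n = obs.sum()
    ranks = stats.rankdata(col[obs])  # ties averaged
    out[obs] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


class MetaboliteScaler(BaseEstimator, TransformerMixin):
    """Per-column normalising transform + standardization.

    Parameters
    ----------
    method : {"log_standardize", "rank_inverse_normal"}
        ``log_standardize`` takes natural logs (values must be
        positive) then z-scores each column.  ``rank_inverse_normal``
        maps ranks through the normal quantile function with the Blom
        offset 3/8, which is invariant to any strictly monotone
        transform of the input, then z-scores.
    """

    def __init__(self, method: str = "log_standardize"):
        self.method = method

    def fit(self, X: pd.DataFrame, y=None) -> "MetaboliteScaler":
        X = self._validate(X)
        T = self._normalise(X)
        self.means_ = T.mean(axis=0, skipna=True)
        self.sds_ = T.std(axis=0, ddof=0, skipna=True)
        zero = self.sds_[self.sds_ == 0]
        if len(zero):
            raise ValueError(f"zero-variance columns: {list(zero.index)}")
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        T = self._normalise(X)
        return (T - self.means_) / self.sds_

    def _validate(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        return X

    def _normalise(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.method == "log_standardize":
            return X.apply(log_transform)
        if self.method == "rank_inverse_normal":
            return X.apply(lambda c: pd.Series(_rank_inverse_normal(c.to_numpy(float)), index=c.index))
        raise ValueError(f"unknown method {self.method!r}")


def transform_metabolites(
    m: MetaboliteMatrix, method: str = "log_standardize"
) -> MetaboliteMatrix:
    """Normalise and standardize a raw metabolite matrix (thin wrapper
    over :class:`MetaboliteScaler`)."""
    if m.scale_state != "raw":
        raise ValueError(f"expected raw-scale matrix, got {m.scale_state!r}")
    scaler = MetaboliteScaler(method=method)
    values = scaler.fit_transform(m.values)
    return MetaboliteMatrix(values=values, scale_state="standardized")


@dataclass
class MissingnessReport:
    dropped: dict[str, float]
    threshold: float


def filter_missingness(
    m: MetaboliteMatrix, max_missing_frac: float = 0.2
) -> tuple[MetaboliteMatrix, MissingnessReport]:
    """Drop metabolites whose missing fraction exceeds the threshold."""
    frac = m.values.isna().mean(axis=0)
    drop = frac[frac > max_missing_frac]
    kept = m.values.drop(columns=drop.index)
    report = MissingnessReport(dropped={k: float(v) for k, v in drop.items()},
                               threshold=max_missing_frac)
    return MetaboliteMatrix(values=kept, scale_state=m.scale_state), report


def harmonize_samples(
    genotypes: GenotypeMatrix,
    metabolites: MetaboliteMatrix,
    phenotypes: PhenotypeTable,
) -> tuple[GenotypeMatrix, MetaboliteMatrix, PhenotypeTable]:
    """Restrict all layers to the shared samples, identically ordered.

    Order follows the metabolite matrix (restricted to the
    intersection) so that downstream row-wise alignment is positional
    as well as id-based.
    """
    common = metabolites.sample_ids.intersection(genotypes.sample_ids).intersection(
        phenotypes.sample_ids
    )
    if len(common) == 0:
        raise ValueError("no samples shared across genotype, metabolite and phenotype layers")
    ordered = metabolites.sample_ids[metabolites.sample_ids.isin(common)]
    g = GenotypeMatrix(genotypes.dosages.loc[ordered], genotypes.variants)
    m = MetaboliteMatrix(metabolites.values.loc[ordered], metabolites.scale_state)
    cov = phenotypes.covariates.loc[ordered] if len(phenotypes.covariates) else phenotypes.covariates
    p = PhenotypeTable(
        visits=phenotypes.visits.loc[ordered],
        covariates=cov,
        transform_log=dict(phenotypes.transform_log),
    )
    return g, m, p


def prepare_outcome(
    phenotypes: PhenotypeTable,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
) -> PhenotypeTable:
    """Winsorise and log-transform every visit's outcome vector.

    Bounds are recorded per visit in ``transform_log``; standardization
    happens later, within each visit's analysis sample.
    """
    out = {}
    log = {}
    for visit in phenotypes.visit_names:
        w, bounds = winsorise(phenotypes.visits[visit], lower_q, upper_q)
        out[visit] = log_transform(w)
        log[visit] = {"lower": bounds[0], "upper": bounds[1],
                      "lower_q": lower_q, "upper_q": upper_q}
    return PhenotypeTable(
        visits=pd.DataFrame(out, index=phenotypes.sample_ids),
        covariates=phenotypes.covariates,
        transform_log=log,
    )
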