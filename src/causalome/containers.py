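"""Shared data containers for the analysis layers.

Three layers of data move through the pipeline: genotypes (samples x
variants, additive minor-allele dosages), metabolite abundances
(samples x metabolites) and a longitudinal phenotype table (the risk
factor measured at repeated visits, plus per-sample covariates).
All containers wrap pandas objects so sample alignment is always by id,
never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "MetaboliteMatrix", "PhenotypeTable"]


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes with variant metadata.

    Parameters
    ----------
    dosages : DataFrame, shape (n_samples, n_variants)
        Minor-allele counts in {0, 1, 2}; NaN marks a missing call.
    variants : DataFrame indexed by variant id
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and
        optionally ``block`` (simulated LD block label).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosages.columns]
        if not self.variants.index.is_unique:
            raise ValueError("variant ids must be unique")
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    def maf(self) -> pd.Series:
        """Per-variant minor-allele frequency, folded to [0, 0.5]."""
        freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)


@dataclass
class MetaboliteMatrix:
    """Metabolite abundances with an explicit scale state.

    ``scale_state`` tracks where the matrix sits in the preprocessing
    chain: ``raw`` (positive abundances as measured), ``transformed``
    (log or rank-based normalisation applied) or ``standardized``
    (per-column mean 0, SD 1).
    """

    values: pd.DataFrame
    scale_state: str = "raw"

    _STATES = ("raw", "transformed", "standardized")

    def __post_init__(self) -> None:
        if self.scale_state not in self._STATES:
            raise ValueError(f"scale_state must be one of {self._STATES}")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("sample and metabolite ids must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class PhenotypeTable:
    """Risk-factor measurements over visits plus per-sample covariates.

    ``visits`` holds one column per visit (``V1``, ``V2``, ...); NaN
    means the sample was not examined at that visit.  ``transform_log``
    records winsorisation bounds applied per visit so the preprocessing
    is auditable.
    """

    visits: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    transform_log: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.visits.index

    @property
    def visit_names(self) -> list[str]:
        return list(self.visits.columns)

    def visit_mask(self, visit: str) -> pd.Series:
        return self.visits[visit].notna()

    def visit_counts(self) -> pd.Series:
        return self.visits.notna().sum(axis=0)
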