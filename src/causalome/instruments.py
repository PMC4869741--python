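"""Genome-wide instrument construction.

Two stages: (1) reduce the SNP panel to linkage-disequilibrium (LD)
proxies — SNPs nearly perfectly correlated (r^2 above a threshold,
default 0.80) carry redundant information, so hierarchical clustering
on 1 - r^2 picks one representative per cluster; (2) per metabolite,
scan the proxies for marginal association and combine the qualifying
ones into a weighted allele score, the genomic instrumental variable
used to orient the metabolite network.  Instrument strength is
summarised by the first-stage R^2 and F statistic; weak instruments
(F < f_min, default 10) are flagged and excluded from orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix

__all__ = [
    "ld_r2",
    "ld_r2_matrix",
    "cluster_proxies",
    "marginal_scan",
    "build_instrument",
    "LDClustering",
    "Instrument",
    "InstrumentSet",
    "LDProxyReducer",
    "GenomicInstrumentBuilder",
]


def ld_r2(g: GenotypeMatrix, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Squared Pearson correlation of dosage vectors, pairwise-complete.

    Zero-variance variants give an undefined r^2, reported as NaN with
    a reason instead of raising.
    """
    rows = []
    for a, b in pairs:
        x = g.dosages[a].to_numpy(float)
        y = g.dosages[b].to_numpy(float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 2:
            rows.append((a, b, np.nan, "fewer than 2 complete pairs"))
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            rows.append((a, b, np.nan, "zero variance"))
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        rows.append((a, b, r * r, ""))
    return pd.DataFrame(rows, columns=["a", "b", "r2", "reason"])


def ld_r2_matrix(dosages: pd.DataFrame) -> np.ndarray:
    """Full r^2 matrix; missing dosages are mean-imputed per variant
    (adequate for low missingness; the pairwise ``ld_r2`` is exact)."""
    X = dosages.to_numpy(float)
    if np.isnan(X).any():
        mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = np.take(mean, idx[1])
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / Z.shape[0]
    return np.clip(corr * corr, 0.0, 1.0)


@dataclass
class LDClustering:
    clusters: dict[int, list[str]]
    proxies: dict[int, str]
    r2_threshold: float

    @property
    def proxy_ids(self) -> list[str]:
        return [self.proxies[k] for k in sorted(self.proxies)]

    def cluster_of(self) -> dict[str, int]:
        return {v: k for k, members in self.clusters.items() for v in members}


def cluster_proxies(
    g: GenotypeMatrix, r2_threshold: float = 0.80, method: str = "average"
) -> LDClustering:
    """Agglomerative clustering of variants on distance 1 - r^2.

    The dendrogram is cut at height 1 - r2_threshold, so (under average
    linkage) merged clusters have mean pairwise r^2 >= r2_threshold.
    Each cluster's proxy is the member with the least missingness, ties
    broken by the highest minor-allele frequency, then lexicographic id.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    ids = list(g.variant_ids)
    if len(ids) == 1:
        return LDClustering({1: ids}, {1: ids[0]}, r2_threshold)
    r2 = ld_r2_matrix(g.dosages)
    dist = 1.0 - r2
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, dist.T)  # enforce symmetry against fp noise
    Z = scipy_linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(Z, t=1.0 - r2_threshold + 1e-12, criterion="distance")

    missing = g.missing_fraction()
    maf = g.maf()
    clusters: dict[int, list[str]] = {}
    for vid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(vid)
    proxies = {
        lab: min(members, key=lambda v: (missing[v], -maf[v], v))
        for lab, members in clusters.items()
    }
    return LDClustering(clusters=clusters, proxies=proxies, r2_threshold=r2_threshold)


def marginal_scan(
    proxies: pd.DataFrame, metabolite: pd.Series, min_pairs: int = 30
) -> pd.DataFrame:
    """Per-proxy simple regression of the metabolite on standardized dosage.

    Returns a frame indexed by proxy id with columns ``beta``, ``se``,
    ``p``, ``n`` and ``reason`` (non-empty when the proxy was excluded,
    e.g. constant dosage).  Two-sided p-values from the t distribution
    with n - 2 degrees of freedom.
    """
    y_all = metabolite.to_numpy(float)
    out = []
    X = proxies.to_numpy(float)
    y_ok = ~np.isnan(y_all)
    clean = not np.isnan(X).any() and y_ok.all()
    if clean:
        n = X.shape[0]
        sd = X.std(axis=0)
        const = sd == 0
        sd_safe = np.where(const, 1.0, sd)
        Z = (X - X.mean(axis=0)) / sd_safe
        y = y_all - y_all.mean()
        sy = y.std()
        r = (Z.T @ y) / (n * (sy if sy > 0 else 1.0))
        r = np.clip(r, -0.999999999999, 0.999999999999)
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        beta = r * sy
        se = np.abs(beta / np.where(tstat == 0, np.inf, tstat))
        se = np.where(tstat == 0, sy / np.sqrt(n - 2), se)
        for j, vid in enumerate(proxies.columns):
            if const[j]:
                out.append((vid, np.nan, np.nan, np.nan, n, "zero variance"))
            else:
                out.append((vid, beta[j], se[j], p[j], n, ""))
    else:
        for vid in proxies.columns:
            x = proxies[vid].to_numpy(float)
            ok = ~np.isnan(x) & y_ok
            n = int(ok.sum())
            if n < min_pairs:
                out.append((vid, np.nan, np.nan, np.nan, n, f"fewer than {min_pairs} complete pairs"))
                continue
            xs, ys = x[ok], y_all[ok]
            if xs.std() == 0:
                out.append((vid, np.nan, np.nan, np.nan, n, "zero variance"))
                continue
            z = (xs - xs.mean()) / xs.std()
            r = float(np.corrcoef(z, ys)[0, 1])
            r = float(np.clip(r, -0.999999999999, 0.999999999999))
            tstat = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(tstat), df=n - 2)
            beta = r * ys.std()
            se = abs(beta / tstat) if tstat != 0 else ys.std() / np.sqrt(n - 2)
            out.append((vid, beta, se, p, n, ""))
    return pd.DataFrame(
        out, columns=["proxy", "beta", "se", "p", "n", "reason"]
    ).set_index("proxy")


@dataclass
class Instrument:
    metabolite: str
    members: list[str]
    weights: dict[str, float]
    score: pd.Series | None
    r2: float
    f_stat: float
    flag: str  # "ok" | "weak" | "uninstrumented"


@dataclass
class InstrumentSet:
    instruments: dict[str, Instrument]
    assoc_threshold: float

    def scores(self) -> pd.DataFrame:
        cols = {
            mid: inst.score
            for mid, inst in self.instruments.items()
            if inst.score is not None
        }
        return pd.DataFrame(cols)

    def usable(self, f_min: float = 10.0) -> list[str]:
        return [
            mid
            for mid, inst in self.instruments.items()
            if inst.score is not None and inst.f_stat >= f_min
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metabolite": inst.metabolite,
                "members": ",".join(inst.members),
                "n_members": len(inst.members),
                "first_stage_r2": inst.r2,
                "f_stat": inst.f_stat,
                "flag": inst.flag,
            }
            for inst in self.instruments.values()
        ]
        return pd.DataFrame(rows).set_index("metabolite")


def first_stage_strength(score: np.ndarray, metabolite: np.ndarray) -> tuple[float, float]:
    """First-stage R^2 and F = R^2 (n-2) / (1 - R^2) of metabolite ~ score."""
    ok = ~np.isnan(score) & ~np.isnan(metabolite)
    n = ok.sum()
    r = np.corrcoef(score[ok], metabolite[ok])[0, 1]
    r2 = float(r * r)
    f = r2 * (n - 2) / (1.0 - r2) if r2 < 1.0 else np.inf
    return r2, float(f)


def build_instrument(
    scan: pd.DataFrame,
    proxies: pd.DataFrame,
    metabolite: pd.Series,
    metabolite_id: str,
    assoc_threshold: float = 5e-8,
    max_members: int = 20,
    f_min: float = 10.0,
) -> Instrument:
    """Weighted allele score from marginally associated proxies.

    Members are the proxies with p < assoc_threshold, capped at
    ``max_members`` by ascending p (ties by id); weights are the
    marginal regression betas.  Missing dosages are mean-imputed within
    each member for score construction only.  A metabolite with no
    qualifying proxy gets a null instrument flagged ``uninstrumented``.
    """
    ok = scan[(scan["reason"] == "") & (scan["p"] < assoc_threshold)]
    ok = ok.sort_index().sort_values("p", kind="mergesort")  # p ascending, ties by id
    members = list(ok.index[:max_members])
    if not members:
        return Instrument(metabolite_id, [], {}, None, 0.0, 0.0, "uninstrumented")
    weights = {m: float(scan.loc[m, "beta"]) for m in members}
    X = proxies[members].to_numpy(float)
    if np.isnan(X).any():
        mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = np.take(mean, idx[1])
    raw = X @ np.array([weights[m] for m in members])
    sd = raw.std()
    if sd == 0:
        return Instrument(metabolite_id, [], {}, None, 0.0, 0.0, "uninstrumented")
    score = pd.Series((raw - raw.mean()) / sd, index=proxies.index, name=metabolite_id)
    r2, f = first_stage_strength(score.to_numpy(), metabolite.to_numpy(float))
    flag = "ok" if f >= f_min else "weak"
    return Instrument(metabolite_id, members, weights, score, r2, f, flag)


class LDProxyReducer(BaseEstimator, TransformerMixin):
    """Transformer reducing a genotype matrix to one proxy SNP per LD
    cluster (hierarchical clustering on 1 - r^2, cut at the threshold).

    Parameters
    ----------
    r2_threshold : float, default 0.80
        Minimum (average within-cluster) squared correlation for SNPs
        to share a proxy.
    linkage : {"average", "single", "complete"}
    """

    def __init__(self, r2_threshold: float = 0.80, linkage: str = "average"):
        self.r2_threshold = r2_threshold
        self.linkage = linkage

    def fit(self, X: GenotypeMatrix, y=None) -> "LDProxyReducer":
        self.clustering_ = cluster_proxies(X, self.r2_threshold, method=self.linkage)
        self.n_features_in_ = X.dosages.shape[1]
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        keep = [v for v in X.variant_ids if v in set(self.clustering_.proxy_ids)]
        return GenotypeMatrix(X.dosages[keep], X.variants.loc[keep])


class GenomicInstrumentBuilder(BaseEstimator):
    """Estimator building one genomic instrument score per metabolite.

    ``fit(G, M)`` takes proxy dosages (GenotypeMatrix or DataFrame) and
    a standardized metabolite matrix (DataFrame), runs the marginal
    scan per metabolite and assembles weighted allele scores; the
    result is available as ``instrument_set_`` and ``scores_``.
    """

    def __init__(
        self,
        assoc_threshold: float = 5e-8,
        max_members: int = 20,
        f_min: float = 10.0,
        exclusive_members: bool = True,
    ):
        self.assoc_threshold = assoc_threshold
        self.max_members = max_members
        self.f_min = f_min
        self.exclusive_members = exclusive_members

    def fit(self, G, M: pd.DataFrame, y=None) -> "GenomicInstrumentBuilder":
        dosages = G.dosages if isinstance(G, GenotypeMatrix) else G
        if not dosages.index.equals(M.index):
            raise ValueError("genotype and metabolite sample ids must be aligned")
        scans = {mid: marginal_scan(dosages, M[mid]) for mid in M.columns}
        # A proxy associated with several metabolites (e.g. via a
        # metabolite -> metabolite effect) would contaminate downstream
        # instruments and break the exclusion restriction; assign each
        # proxy to the metabolite it is most strongly associated with.
        if self.exclusive_members:
            pmat = pd.DataFrame({mid: s["p"] for mid, s in scans.items()})
            best = pmat.idxmin(axis=1)
            for mid in M.columns:
                foreign = best.index[(best != mid) & best.notna()]
                scans[mid] = scans[mid].drop(index=foreign, errors="ignore")
        instruments = {}
        for mid in M.columns:
            instruments[mid] = build_instrument(
                scans[mid], dosages, M[mid], mid,
                assoc_threshold=self.assoc_threshold,
                max_members=self.max_members,
                f_min=self.f_min,
            )
        self.instrument_set_ = InstrumentSet(instruments, self.assoc_threshold)
        self.scores_ = self.instrument_set_.scores()
        return self
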