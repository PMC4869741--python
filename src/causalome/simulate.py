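"""Synthetic cohort generator with known causal ground truth.

Emulates the statistical structure of a genomics + metabolomics +
longitudinal risk-factor study: LD-blocked genotypes, metabolites from
a sparse linear-Gaussian structural equation model (SEM) with per-
metabolite genetic effects and a shared confounder, and a log-normal
outcome (triglyceride-like) measured over several visits with sample
attrition.  Every draw is governed by a single seed, and the generating
DAG, coefficients, instrument assignment and direct-parent set are
returned as an explicit :class:`GroundTruth` so downstream inference
can be scored against the truth.

The model, on the latent (log) scale, is

    x_j = sum_k B[j, k] x_k + a * g_j + c * C + eps_j,

with ``B`` strictly lower-triangular in a random topological order
(hence acyclic), ``g_j`` the standardized allele score of the LD block
assigned to metabolite j, ``C`` a standard-normal confounder shared by
all metabolites and the outcome, and ``eps_j ~ N(0, noise_sd^2)``.
Raw abundances are returned exponentiated, so the log/winsorise
preprocessing downstream has real work to do.  The outcome at visit v is

    log y_v = m^(v-1) * sum_j beta_j z_j + c * C + eps_v,

where ``z_j`` are the standardized latent values of the direct-parent
metabolites, ``beta_j`` the planted direct effects (SD units) and
``m`` a per-visit attenuation multiplier (default 1: persistent
effects).  Visit membership is nested and missing completely at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MetaboliteMatrix, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_metabolite_dag",
    "simulate_metabolites",
    "simulate_outcome_visits",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study dimensions and generative parameters.

    Defaults mirror the cohort the package targets: 2479 samples with
    metabolomics at baseline, 122 metabolites, 9 direct parents of the
    outcome with effects drawn from +/-[0.07, 0.17] SD, five visits
    with attrition 2479/1920/1629/1398/700, and ~2000 LD proxy blocks.
    """

    n_samples: int = 2479
    n_snps: int = 4000
    n_ld_blocks: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.4)
    n_metabolites: int = 122
    dag_edge_prob: float = 0.02
    dag_coef_range: tuple[float, float] = (0.2, 0.6)
    snp_effect_size: float = 0.3
    n_direct_parents: int = 9
    direct_effect_range: tuple[float, float] = (0.07, 0.17)
    noise_sd: float = 1.0
    visit_sizes: tuple[int, ...] = (2479, 1920, 1629, 1398, 700)
    confounder_strength: float = 0.2
    visit_attenuation: float = 1.0
    flip_prob: float = 0.01
    pleiotropy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_snps": self.n_snps,
            "n_ld_blocks": self.n_ld_blocks,
            "n_metabolites": self.n_metabolites,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_snps < self.n_ld_blocks:
            raise ConfigurationError("n_snps must be >= n_ld_blocks")
        if not (0.0 <= self.dag_edge_prob <= 1.0):
            raise ConfigurationError("dag_edge_prob must be in [0, 1]")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] < 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 0.5")
        if self.n_direct_parents > self.n_metabolites:
            raise ConfigurationError("n_direct_parents must be <= n_metabolites")
        if self.n_direct_parents < 0:
            raise ConfigurationError("n_direct_parents must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not self.visit_sizes:
            raise ConfigurationError("visit_sizes must be non-empty")
        if self.visit_sizes[0] != self.n_samples:
            raise ConfigurationError("visit_sizes[0] must equal n_samples")
        if any(b > a for a, b in zip(self.visit_sizes, self.visit_sizes[1:])):
            raise ConfigurationError("visit_sizes must be non-increasing")
        if not (0.0 <= self.flip_prob < 0.5):
            raise ConfigurationError("flip_prob must be in [0, 0.5)")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index([f"S{i + 1:05d}" for i in range(self.n_samples)], name="sample_id")

    @property
    def metabolite_ids(self) -> pd.Index:
        return pd.Index([f"M{i + 1:03d}" for i in range(self.n_metabolites)], name="metabolite")


@dataclass
class GroundTruth:
    """The generating model: DAG, coefficients, instruments, parents.

    ``B[i, j]`` is the structural coefficient of metabolite j on
    metabolite i (row = child); strictly lower-triangular under
    ``order``.  ``direct_parents`` maps metabolite id to its planted
    effect on the log outcome, in SD units of the metabolite.
    """

    metabolite_ids: list[str]
    B: np.ndarray
    order: np.ndarray
    snp_assignment: dict[str, list[str]]
    instrumented: list[str]
    direct_parents: dict[str, float]
    snp_effect_size: float
    confounder_strength: float
    noise_sd: float
    visit_attenuation: float

    # -- graph views ---------------------------------------------------

    def adjacency(self) -> np.ndarray:
        return self.B != 0.0

    def parent_sets(self) -> dict[str, list[str]]:
        ids = self.metabolite_ids
        adj = self.adjacency()
        return {ids[i]: [ids[j] for j in np.flatnonzero(adj[i])] for i in range(len(ids))}

    def skeleton_edges(self) -> set[frozenset]:
        adj = self.adjacency()
        ids = self.metabolite_ids
        return {
            frozenset((ids[i], ids[j]))
            for i, j in zip(*np.nonzero(adj))
        }

    def directed_edges(self) -> set[tuple[str, str]]:
        adj = self.adjacency()
        ids = self.metabolite_ids
        return {(ids[j], ids[i]) for i, j in zip(*np.nonzero(adj))}

    def moral_edges(self) -> set[frozenset]:
        """Skeleton plus edges between parents that share a child."""
        edges = set(self.skeleton_edges())
        adj = self.adjacency()
        ids = self.metabolite_ids
        for i in range(len(ids)):
            parents = np.flatnonzero(adj[i])
            for a_pos, a in enumerate(parents):
                for b in parents[a_pos + 1:]:
                    edges.add(frozenset((ids[a], ids[b])))
        return edges

    def is_acyclic(self) -> bool:
        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(len(self.order))
        rows, cols = np.nonzero(self.B)
        return bool(np.all(inv[rows] > inv[cols]))

    # -- population moments --------------------------------------------

    def exogenous_covariance(self) -> np.ndarray:
        m = len(self.metabolite_ids)
        inst = np.array([mid in self.instrumented for mid in self.metabolite_ids])
        cov = np.diag(self.snp_effect_size**2 * inst + self.noise_sd**2)
        cov += self.confounder_strength**2 * np.ones((m, m))
        return cov

    def population_covariance(self) -> np.ndarray:
        """Latent-scale covariance (I - B)^-1 E (I - B)^-T."""
        m = len(self.metabolite_ids)
        A = np.linalg.inv(np.eye(m) - self.B)
        return A @ self.exogenous_covariance() @ A.T

    def _systematic_variance(self, visit: int = 1) -> tuple[np.ndarray, float, np.ndarray]:
        """Cov(x, systematic part of log y), its variance, and the
        latent-scale outcome coefficients b = mult * beta / sd."""
        m = len(self.metabolite_ids)
        sigma = self.population_covariance()
        sds = np.sqrt(np.diag(sigma))
        mult = self.visit_attenuation ** (visit - 1)
        b = np.zeros(m)
        for mid, beta in self.direct_parents.items():
            j = self.metabolite_ids.index(mid)
            b[j] = mult * beta / sds[j]
        A = np.linalg.inv(np.eye(m) - self.B)
        cov_x_conf = self.confounder_strength * A @ np.ones(m)
        cov_xs = sigma @ b + self.confounder_strength * cov_x_conf
        var_s = (
            b @ sigma @ b
            + 2.0 * self.confounder_strength * b @ cov_x_conf
            + self.confounder_strength**2
        )
        return cov_xs, float(var_s), b

    def outcome_noise_sd(self, visit: int = 1) -> float:
        """Noise SD that gives the log outcome unit population variance,
        so planted direct effects are effects in outcome-SD units
        (floored at a small positive value for extreme configurations)."""
        _, var_s, _ = self._systematic_variance(visit)
        return float(np.sqrt(max(1.0 - var_s, 0.05)))

    def _outcome_moments(self, visit: int = 1) -> tuple[np.ndarray, float, np.ndarray]:
        """Cov(x, log y), Var(log y) and the latent outcome coefficients."""
        cov_xs, var_s, b = self._systematic_variance(visit)
        var_y = var_s + self.outcome_noise_sd(visit) ** 2
        return cov_xs, float(var_y), b

    def true_direct_coefs_sd(self, visit: int = 1) -> pd.Series:
        """Population regression of the standardized log outcome on the
        standardized direct parents, i.e. the estimand of the direct-
        effect fit when selection recovers the true parent set."""
        if not self.direct_parents:
            return pd.Series(dtype=float)
        sigma = self.population_covariance()
        sds = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(sds, sds)
        cov_xy, var_y, _ = self._outcome_moments(visit)
        rho_xy = cov_xy / (sds * np.sqrt(var_y))
        idx = [self.metabolite_ids.index(mid) for mid in self.direct_parents]
        coefs = np.linalg.solve(corr[np.ix_(idx, idx)], rho_xy[idx])
        return pd.Series(coefs, index=list(self.direct_parents))

    def true_total_effects_sd(self, visit: int = 1) -> pd.Series:
        """Total causal effect of each metabolite on the log outcome in
        SD units: path-sum through the full SEM including the outcome."""
        m = len(self.metabolite_ids)
        cov_xy, var_y, b = self._outcome_moments(visit)
        sigma = self.population_covariance()
        sds = np.sqrt(np.diag(sigma))
        B_full = np.zeros((m + 1, m + 1))
        B_full[:m, :m] = self.B
        B_full[m, :m] = b
        T = np.linalg.inv(np.eye(m + 1) - B_full) - np.eye(m + 1)
        te_latent = T[m, :m]
        return pd.Series(te_latent * sds / np.sqrt(var_y), index=self.metabolite_ids)

    # -- serialisation ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "metabolite_ids": self.metabolite_ids,
            "edges": [
                {"parent": self.metabolite_ids[j], "child": self.metabolite_ids[i],
                 "coef": float(self.B[i, j])}
                for i, j in zip(*np.nonzero(self.B))
            ],
            "order": [self.metabolite_ids[k] for k in self.order],
            "snp_assignment": self.snp_assignment,
            "instrumented": self.instrumented,
            "direct_parents": self.direct_parents,
            "snp_effect_size": self.snp_effect_size,
            "confounder_strength": self.confounder_strength,
            "noise_sd": self.noise_sd,
            "visit_attenuation": self.visit_attenuation,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        ids = payload["metabolite_ids"]
        m = len(ids)
        B = np.zeros((m, m))
        for e in payload["edges"]:
            B[ids.index(e["child"]), ids.index(e["parent"])] = e["coef"]
        order = np.array([ids.index(k) for k in payload["order"]])
        return cls(
            metabolite_ids=ids, B=B, order=order,
            snp_assignment=payload["snp_assignment"],
            instrumented=payload["instrumented"],
            direct_parents=payload["direct_parents"],
            snp_effect_size=payload["snp_effect_size"],
            confounder_strength=payload["confounder_strength"],
            noise_sd=payload["noise_sd"],
            visit_attenuation=payload["visit_attenuation"],
        )


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    metabolites: MetaboliteMatrix          # raw (exponentiated) scale
    latent: pd.DataFrame                   # latent log-scale values (convenience)
    phenotypes: PhenotypeTable
    covariates: pd.DataFrame
    truth: GroundTruth

    def __post_init__(self) -> None:
        if not self.truth.is_acyclic():
            raise ValueError("ground-truth DAG must be acyclic")
        visits = self.phenotypes.visits
        masks = visits.notna()
        first = masks.iloc[:, 0]
        for col in visits.columns[1:]:
            if (masks[col] & ~first).any():
                raise ValueError(f"visit {col} not nested in visit 1")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rng_for(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw LD-blocked genotypes by noisy duplication of latent haplotypes.

    Each block has a single MAF drawn uniformly from ``maf_range`` and a
    latent pair of haplotypes per sample; every SNP in the block is a
    copy of that pair with independent per-allele flip noise
    (``flip_prob``), so within-block r^2 is high and between-block
    r^2 ~ 0.
    """
    rng = _rng_for(config, rng)
    n, p, nb = config.n_samples, config.n_snps, config.n_ld_blocks
    base, extra = divmod(p, nb)
    sizes = np.full(nb, base)
    sizes[:extra] += 1
    block_of = np.repeat(np.arange(nb), sizes)

    maf_block = rng.uniform(config.maf_range[0], config.maf_range[1], size=nb)
    hap = rng.random((n, 2, nb)) < maf_block  # latent haplotype pair per block
    flips = rng.random((n, 2, p)) < config.flip_prob
    alleles = hap[:, :, block_of] ^ flips
    dosages = alleles.sum(axis=1).astype(np.float64)

    within = np.concatenate([np.arange(s) for s in sizes])
    ids = pd.Index(
        [f"rs{b:05d}_{k}" for b, k in zip(block_of, within)], name="variant_id"
    )
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, p + 1) * 1000,  # 1-based, spaced
            "ref": "A",
            "alt": "G",
            "block": block_of,
        },
        index=ids,
    )
    dos = pd.DataFrame(dosages, index=config.sample_ids, columns=ids)
    return GenotypeMatrix(dosages=dos, variants=variants)


def simulate_metabolite_dag(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random DAG: Bernoulli(edge_prob) mask, lower-triangular under a
    random topological order; coefficients uniform on +/-dag_coef_range.

    Returns ``(B, order)`` with ``B[child, parent]`` conventions.
    """
    rng = _rng_for(config, rng)
    m = config.n_metabolites
    order = rng.permutation(m)
    lo, hi = config.dag_coef_range
    B = np.zeros((m, m))
    # positions k < l in topological order: order[k] may parent order[l]
    mask = rng.random((m, m)) < config.dag_edge_prob
    coefs = rng.uniform(lo, hi, size=(m, m)) * rng.choice([-1.0, 1.0], size=(m, m))
    for l_pos in range(m):
        child = order[l_pos]
        for k_pos in range(l_pos):
            parent = order[k_pos]
            if mask[l_pos, k_pos]:
                B[child, parent] = coefs[l_pos, k_pos]
    return B, order


def simulate_ground_truth(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw the DAG, direct-parent set and instrument assignment."""
    rng = _rng_for(config, rng)
    B, order = simulate_metabolite_dag(config, rng)
    ids = list(config.metabolite_ids)

    n_inst = min(config.n_metabolites, config.n_ld_blocks)
    blocks = genotypes.variants["block"].to_numpy()
    snp_assignment: dict[str, list[str]] = {}
    for j in range(n_inst):
        snp_assignment[ids[j]] = list(genotypes.variant_ids[blocks == j])
    if config.pleiotropy and n_inst >= 2:
        # one block feeds two metabolites (robustness knob, off by default)
        snp_assignment[ids[1]] = snp_assignment[ids[1]] + snp_assignment[ids[0]]

    parents = rng.choice(config.n_metabolites, size=config.n_direct_parents, replace=False)
    lo, hi = config.direct_effect_range
    effects = rng.uniform(lo, hi, size=config.n_direct_parents) * rng.choice(
        [-1.0, 1.0], size=config.n_direct_parents
    )
    direct_parents = {ids[j]: float(e) for j, e in zip(parents, effects)}

    return GroundTruth(
        metabolite_ids=ids,
        B=B,
        order=order,
        snp_assignment=snp_assignment,
        instrumented=sorted(snp_assignment, key=ids.index),
        direct_parents=direct_parents,
        snp_effect_size=config.snp_effect_size,
        confounder_strength=config.confounder_strength,
        noise_sd=config.noise_sd,
        visit_attenuation=config.visit_attenuation,
    )


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def simulate_metabolites(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
    confounder: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Generate metabolites from the SEM in topological order.

    Returns the raw (exponentiated) matrix and the latent log-scale
    values used to generate the outcome.
    """
    rng = _rng_for(config, rng)
    n, m = config.n_samples, config.n_metabolites
    ids = truth.metabolite_ids
    known = set(genotypes.variant_ids)
    for mid, snps in truth.snp_assignment.items():
        missing = [s for s in snps if s not in known]
        if missing:
            raise ValueError(f"instrument assignment for {mid} references unknown SNPs: {missing[:3]}")

    scores = np.zeros((n, m))
    for j, mid in enumerate(ids):
        snps = truth.snp_assignment.get(mid)
        if snps:
            raw = genotypes.dosages[snps].to_numpy().sum(axis=1)
            scores[:, j] = _standardize(raw[:, None])[:, 0]

    conf = confounder.to_numpy()
    noise = rng.standard_normal((n, m)) * config.noise_sd
    X = np.zeros((n, m))
    for node in truth.order:
        parent_idx = np.flatnonzero(truth.B[node])
        X[:, node] = (
            X[:, parent_idx] @ truth.B[node, parent_idx]
            + config.snp_effect_size * scores[:, node]
            + config.confounder_strength * conf
            + noise[:, node]
        )
    latent = pd.DataFrame(X, index=config.sample_ids, columns=ids)
    raw = MetaboliteMatrix(values=np.exp(latent), scale_state="raw")
    return raw, latent


def simulate_outcome_visits(
    latent: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    confounder: pd.Series,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Log-normal outcome at each visit with nested random attrition.

    Later visits redraw the noise and optionally attenuate the direct
    effects by ``visit_attenuation**(v-1)``; each visit's sample set is
    a random subset of the previous visit's.  The noise SD is chosen so
    the log outcome has unit population variance, which makes the
    planted direct effects effects in outcome-SD units.
    """
    rng = _rng_for(config, rng)
    n = config.n_samples
    z = _standardize(latent.to_numpy())
    beta = np.zeros(latent.shape[1])
    for mid, eff in truth.direct_parents.items():
        beta[latent.columns.get_loc(mid)] = eff
    conf = confounder.to_numpy()

    visits = {}
    member = np.arange(n)
    for v, size in enumerate(config.visit_sizes, start=1):
        if size > len(member):
            raise ValueError("visit sizes must be non-increasing (non-nested mask)")
        if v > 1:
            member = np.sort(rng.choice(member, size=size, replace=False))
        mult = config.visit_attenuation ** (v - 1)
        log_y = mult * (z @ beta) + config.confounder_strength * conf \
            + rng.standard_normal(n) * truth.outcome_noise_sd(v)
        col = np.full(n, np.nan)
        col[member] = np.exp(log_y[member])
        visits[f"V{v}"] = col
    table = pd.DataFrame(visits, index=latent.index)
    return PhenotypeTable(visits=table)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """End-to-end generation of a fully specified synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    truth = simulate_ground_truth(config, genotypes, rng)
    confounder = pd.Series(
        rng.standard_normal(config.n_samples), index=config.sample_ids, name="BMI"
    )
    metabolites, latent = simulate_metabolites(genotypes, truth, config, confounder, rng)
    phenotypes = simulate_outcome_visits(latent, truth, config, confounder, rng)
    covariates = confounder.to_frame()
    phenotypes.covariates = covariates
    return SimulatedStudy(
        genotypes=genotypes,
        metabolites=metabolites,
        latent=latent,
        phenotypes=phenotypes,
        covariates=covariates,
        truth=truth,
    )
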