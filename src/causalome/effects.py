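"""Risk-factor integration: direct vs indirect effects, in SD units.

With the metabolite network fixed, the risk factor (triglycerides,
winsorised + log-transformed + standardized) enters the model as a
sink: no metabolite is allowed to be its descendant.  Metabolites with
a *direct* effect are found by Markov-boundary selection — forward
inclusion of the candidate with the smallest conditional-independence
p-value below alpha, backward elimination of members that lose
significance given the others, iterated to a fixed point.  Metabolites
that are not direct but have a directed path to the risk factor
through a direct one are *indirect*; the rest have no effect.

Effects are quantified on a linear SEM over the fixed DAG: each node
is regressed on its parents, and the total effect of a metabolite on
the outcome is the sum over directed paths of products of edge
coefficients, computed as ((I - B)^-1 - I) rather than by path
enumeration.  Because all variables are standardized, effects are in
SD units of the outcome per SD of metabolite.  Standard errors come
from a nonparametric sample bootstrap on the fixed graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import PhenotypeTable
from .network import CausalGraph, _CITester

__all__ = [
    "ConvergenceError",
    "identify_direct",
    "classify_indirect",
    "attach_risk_factor",
    "fit_edge_coefficients",
    "total_effect",
    "total_effect_matrix",
    "bootstrap_se",
    "per_visit_analysis",
    "DirectEffectAnalyzer",
]

RISK_FACTOR = "TG"


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[str]):
        super().__init__(message)
        self.trace = trace


def _as_series(y, index: pd.Index) -> pd.Series:
    if isinstance(y, pd.Series):
        return y
    return pd.Series(np.asarray(y, dtype=float), index=index)


def _standardize_series(y: pd.Series) -> pd.Series:
    obs = y.dropna()
    sd = obs.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        raise ValueError("outcome has zero variance")
    return (y - obs.mean()) / sd


def identify_direct(
    X: pd.DataFrame,
    y: pd.Series,
    alpha: float = 0.001,
    covariates: pd.DataFrame | None = None,
    candidates: list[str] | None = None,
    max_sweeps: int = 50,
) -> tuple[list[str], pd.Series]:
    """Markov-boundary selection of metabolites with direct effects.

    Forward step: among unselected candidates, test the partial
    correlation of each with the outcome given the current selection
    (plus covariates, when supplied); include the smallest p if it is
    below alpha.  Backward step: drop any member whose p given the
    rest of the selection rises to alpha or above.  Iterate until
    stable.  Returns the stable set and each member's p-value given
    the other members.
    """
    y = _standardize_series(_as_series(y, X.index))
    yname = "__outcome__"
    frames = [X, y.rename(yname)]
    cov_names: tuple[str, ...] = ()
    if covariates is not None and covariates.shape[1] > 0:
        frames.append(covariates)
        cov_names = tuple(covariates.columns)
    data = pd.concat(frames, axis=1)
    tester = _CITester(data=data)

    pool = sorted(candidates if candidates is not None else X.columns)
    selected: list[str] = []
    trace: list[str] = []
    for sweep in range(max_sweeps):
        changed = False
        # forward inclusion
        while True:
            best, best_p = None, np.inf
            for c in pool:
                if c in selected:
                    continue
                S = tuple(sorted(selected)) + cov_names
                res = tester.test(yname, c, S)
                if res.p < best_p:
                    best, best_p = c, res.p
            if best is not None and best_p < alpha:
                selected.append(best)
                trace.append(f"+{best} (p={best_p:.3g})")
                changed = True
            else:
                break
        # backward elimination
        while True:
            worst, worst_p = None, -np.inf
            for m in sorted(selected):
                others = tuple(sorted(v for v in selected if v != m)) + cov_names
                res = tester.test(yname, m, others)
                if res.p > worst_p:
                    worst, worst_p = m, res.p
            if worst is not None and worst_p >= alpha:
                selected.remove(worst)
                trace.append(f"-{worst} (p={worst_p:.3g})")
                changed = True
            else:
                break
        if not changed:
            pvals = {}
            for m in selected:
                others = tuple(sorted(v for v in selected if v != m)) + cov_names
                pvals[m] = tester.test(yname, m, others).p
            series = pd.Series(pvals, dtype=float).sort_values()
            return sorted(selected), series
    raise ConvergenceError(
        f"Markov-boundary selection did not stabilise in {max_sweeps} sweeps", trace
    )


def conditional_pvalues(
    X: pd.DataFrame,
    y: pd.Series,
    members: list[str],
    given: list[str],
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """p-value of each member's partial correlation with the outcome,
    conditioning on the other ``given`` metabolites (and covariates)."""
    y = _standardize_series(_as_series(y, X.index))
    yname = "__outcome__"
    frames = [X, y.rename(yname)]
    cov_names: tuple[str, ...] = ()
    if covariates is not None and covariates.shape[1] > 0:
        frames.append(covariates)
        cov_names = tuple(covariates.columns)
    tester = _CITester(data=pd.concat(frames, axis=1))
    out = {}
    for m in members:
        S = tuple(sorted(v for v in given if v != m)) + cov_names
        out[m] = tester.test(yname, m, S).p
    return pd.Series(out, dtype=float)


def attach_risk_factor(
    graph: CausalGraph, direct: list[str], risk_factor: str = RISK_FACTOR
) -> CausalGraph:
    """Return a copy of the graph with the risk factor added as a sink
    receiving one directed edge from each direct metabolite."""
    g = graph.copy()
    g.add_node(risk_factor)
    for m in direct:
        g.add_directed(m, risk_factor, "direct effect on risk factor")
    return g


def classify_indirect(
    graph: CausalGraph, direct: list[str], risk_factor: str = RISK_FACTOR
) -> dict[str, str]:
    """Partition metabolites into direct / indirect / none.

    Indirect metabolites have a directed path to the risk factor (i.e.
    into a direct metabolite) but no direct edge themselves.  Only
    confidently directed edges count as paths; undirected or
    conflicted edges do not establish ancestry.
    """
    if risk_factor not in set(graph.nodes):
        graph = attach_risk_factor(graph, direct, risk_factor)
    dg = graph.directed_graph()
    ancestors = nx.ancestors(dg, risk_factor)
    status = {}
    for node in graph.nodes:
        if node == risk_factor or node in graph.instrument_nodes:
            continue
        if node in direct:
            status[node] = "direct"
        elif node in ancestors:
            status[node] = "indirect"
        else:
            status[node] = "none"
    return status


def fit_edge_coefficients(
    graph: CausalGraph, data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Structural coefficients of the linear SEM on a fixed DAG.

    Each node is regressed on its directed parents (instrument nodes
    and undirected/conflict edges excluded).  Returns ``B`` with
    ``B.loc[child, parent]`` conventions and the residual variances.
    """
    nodes = [v for v in graph.nodes if v not in graph.instrument_nodes and v in data.columns]
    B = pd.DataFrame(0.0, index=nodes, columns=nodes)
    resid = pd.Series(0.0, index=nodes)
    for node in nodes:
        parents = [p for p in graph.parents(node) if p in nodes]
        sub = data[[node, *parents]].dropna()
        yv = sub[node].to_numpy(float)
        if not parents:
            resid[node] = float(yv.var())
            continue
        Xm = sub[parents].to_numpy(float)
        Xc = np.column_stack([np.ones(len(sub)), Xm])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError(f"collinear parent set for {node}: {parents}")
        coef, *_ = np.linalg.lstsq(Xc, yv, rcond=None)
        B.loc[node, parents] = coef[1:]
        resid[node] = float((yv - Xc @ coef).var())
    return B, resid


def total_effect_matrix(B: pd.DataFrame) -> pd.DataFrame:
    """All-pairs total effects: ((I - B)^-1 - I)[target, source]."""
    m = B.shape[0]
    Bm = B.to_numpy(float)
    T = np.linalg.inv(np.eye(m) - Bm) - np.eye(m)
    return pd.DataFrame(T, index=B.index, columns=B.columns)


def total_effect(B: pd.DataFrame, source: str, target: str) -> float:
    """Sum over directed paths source -> target of coefficient products."""
    if target not in B.index or source not in B.columns:
        raise ValueError(f"node not in graph: {source if source not in B.columns else target}")
    return float(total_effect_matrix(B).loc[target, source])


def bootstrap_se(
    graph: CausalGraph,
    data: pd.DataFrame,
    sources: list[str],
    target: str = RISK_FACTOR,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Bootstrap SEs of total effects on the fixed graph.

    Rows are resampled with replacement; coefficients are refit and
    total effects recomputed per replicate.  Replicates with a singular
    fit are dropped and counted; more than 10% drops triggers a
    warning.  Deterministic given the seed.
    """
    if n_boot < 50:
        raise ValueError("need at least 50 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = np.zeros((n_boot, len(sources)))
    dropped = 0
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        try:
            Bb, _ = fit_edge_coefficients(graph, sample)
            Tb = total_effect_matrix(Bb)
            draws[kept] = [Tb.loc[target, s] for s in sources]
            kept += 1
        except (ValueError, np.linalg.LinAlgError):
            dropped += 1
    if dropped > 0.1 * n_boot:
        warnings.warn(f"{dropped}/{n_boot} bootstrap replicates dropped (singular fits)")
    se = draws[:kept].std(axis=0, ddof=1) if kept > 1 else np.full(len(sources), np.nan)
    return pd.Series(se, index=sources), dropped


def per_visit_analysis(
    graph: CausalGraph,
    X: pd.DataFrame,
    phenotypes: PhenotypeTable,
    alpha: float = 0.001,
    covariates: pd.DataFrame | None = None,
    restrict_to_baseline: bool = True,
    min_visit_n: int = 100,
    n_boot: int = 200,
    seed: int = 0,
    adjust_selection: bool = False,
) -> pd.DataFrame:
    """Full effect table across visits.

    Baseline metabolites are tested against the outcome at every visit
    (restricted to that visit's samples).  By default later visits
    re-test only the baseline direct set; full re-discovery per visit
    is available via ``restrict_to_baseline=False``.  Visits with
    fewer than ``min_visit_n`` samples are skipped with a warning.
    A covariate-adjusted p-value column is produced when covariates
    are supplied; with ``adjust_selection=True`` the covariates also
    enter every conditioning set of the selection itself.
    """
    rows = []
    baseline_direct: list[str] | None = None
    for k, visit in enumerate(phenotypes.visit_names, start=1):
        y = phenotypes.visits[visit]
        mask = y.notna()
        n = int(mask.sum())
        if n < min_visit_n:
            warnings.warn(f"visit {visit}: only {n} samples (< {min_visit_n}), skipped")
            continue
        Xv = X.loc[mask]
        yv = _standardize_series(y.loc[mask])
        cov_v = covariates.loc[mask] if covariates is not None else None

        if k == 1 or not restrict_to_baseline:
            cand = None
        else:
            cand = baseline_direct
        sel_cov = cov_v if adjust_selection else None
        direct, _ = identify_direct(Xv, yv, alpha=alpha, covariates=sel_cov, candidates=cand)
        if k == 1:
            baseline_direct = direct
        report_members = sorted(set(direct) | set(cand or []))
        pvals = conditional_pvalues(Xv, yv, report_members, given=direct, covariates=sel_cov)

        status = classify_indirect(graph, direct)
        g_tg = attach_risk_factor(graph, direct)
        data_v = Xv.copy()
        data_v[RISK_FACTOR] = yv
        B, _ = fit_edge_coefficients(g_tg, data_v)
        T = total_effect_matrix(B)
        reported = [m for m in X.columns if status.get(m) in ("direct", "indirect")]
        if reported:
            se, _ = bootstrap_se(g_tg, data_v, reported, RISK_FACTOR, n_boot=n_boot, seed=seed + k)
        else:
            se = pd.Series(dtype=float)

        adj_pvals: dict[str, float] = {}
        if cov_v is not None and cov_v.shape[1] > 0 and report_members:
            adj_pvals = dict(
                conditional_pvalues(Xv, yv, report_members, given=direct, covariates=cov_v)
            )

        for m in X.columns:
            eff = float(T.loc[RISK_FACTOR, m]) if m in T.columns else 0.0
            se_m = float(se.get(m, np.nan))
            if np.isfinite(se_m) and se_m > 0:
                p_total = 2.0 * stats.norm.sf(abs(eff) / se_m)
            else:
                p_total = np.nan
            rows.append(
                {
                    "metabolite": m,
                    "visit": visit,
                    "status": status.get(m, "none"),
                    "p_direct": float(pvals.get(m, np.nan)),
                    "total_effect": eff,
                    "se": se_m,
                    "p_total": p_total,
                    "p_adjusted": float(adj_pvals.get(m, np.nan)),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


class DirectEffectAnalyzer(BaseEstimator):
    """Estimator separating direct, indirect and null metabolites and
    quantifying effects on the risk factor in SD units.

    Parameters
    ----------
    alpha : float, default 0.001
        Significance level of the direct-effect tests.
    n_boot : int, default 200
        Bootstrap replicates for standard errors.
    seed : int, default 0
        Bootstrap seed.
    restrict_to_baseline : bool, default True
        Later visits re-test only the baseline direct set.
    min_visit_n : int, default 100
        Visits with fewer samples are skipped.

    Attributes
    ----------
    direct_ : list of str
        Baseline Markov-boundary of the risk factor.
    indirect_ : list of str
    status_ : dict mapping metabolite -> {"direct", "indirect", "none"}
    pvalues_ : Series of direct-test p-values (baseline)
    effect_table_ : DataFrame (per metabolite x visit) when phenotypes
        were supplied, otherwise a single-visit table.
    graph_tg_ : CausalGraph with the risk factor attached as a sink.
    """

    def __init__(
        self,
        alpha: float = 0.001,
        n_boot: int = 200,
        seed: int = 0,
        restrict_to_baseline: bool = True,
        min_visit_n: int = 100,
        adjust_selection: bool = False,
    ):
        self.alpha = alpha
        self.n_boot = n_boot
        self.seed = seed
        self.restrict_to_baseline = restrict_to_baseline
        self.min_visit_n = min_visit_n
        self.adjust_selection = adjust_selection

    def fit(
        self,
        X: pd.DataFrame,
        y: pd.Series | PhenotypeTable,
        graph: CausalGraph | None = None,
        covariates: pd.DataFrame | None = None,
    ) -> "DirectEffectAnalyzer":
        if graph is None:
            graph = CausalGraph(list(X.columns))
        if isinstance(y, PhenotypeTable):
            phen = y
        else:
            phen = PhenotypeTable(visits=pd.DataFrame({"V1": y}, index=X.index))
        table = per_visit_analysis(
            graph,
            X,
            phen,
            alpha=self.alpha,
            covariates=covariates,
            restrict_to_baseline=self.restrict_to_baseline,
            min_visit_n=self.min_visit_n,
            n_boot=self.n_boot,
            seed=self.seed,
            adjust_selection=self.adjust_selection,
        )
        self.effect_table_ = table
        first = table[table["visit"] == table["visit"].iloc[0]] if len(table) else table
        self.direct_ = sorted(first.loc[first["status"] == "direct", "metabolite"])
        self.indirect_ = sorted(first.loc[first["status"] == "indirect", "metabolite"])
        self.status_ = dict(zip(first["metabolite"], first["status"]))
        self.pvalues_ = (
            first.set_index("metabolite")["p_direct"].dropna().sort_values()
        )
        self.graph_tg_ = attach_risk_factor(graph, self.direct_)
        self.n_features_in_ = X.shape[1]
        return self
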