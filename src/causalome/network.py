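"""Causal network discovery over metabolites.

Topology first, direction second.  The topology (skeleton) comes from
Gaussian conditional-independence tests: an edge x - y is kept when x
and y remain dependent given the other variables.  Testing against
*all* other variables at once yields the moral graph of the generating
DAG (spouse edges included), so an optional PC-style second stage
searches small conditioning subsets of the current neighborhoods to
prune spouse edges and record separating sets.  Direction then comes
from three sources, in order: genomic instrumental variables (an
instrument G_x for metabolite x that is marginally associated with y
but independent of y given x supports x -> y — the exclusion
restriction), collider orientation from the recorded separating sets,
and Meek's propagation rules.  All traversals are lexicographic, so
results do not depend on input column order, and every orientation
decision is logged with its provenance.

The only tuning parameter of the discovery procedure is the
significance level alpha (default 0.001); everything else is
deterministic given the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .instruments import InstrumentSet

__all__ = [
    "CITestResult",
    "CausalGraph",
    "partial_correlation",
    "fisher_z_test",
    "learn_topology",
    "orient_with_instruments",
    "CausalNetworkLearner",
]


@dataclass
class CITestResult:
    x: str
    y: str
    S: tuple[str, ...]
    r: float
    statistic: float
    p: float
    n_effective: int


def _pcorr_from_cov(cov: np.ndarray) -> float:
    """Partial correlation of variables 0 and 1 given the rest, from the
    covariance of the stacked set, via the precision matrix."""
    try:
        # Cholesky fails on non-positive-definite input, catching exact
        # collinearity that a plain inverse would silently pass through
        L = np.linalg.cholesky(cov)
        d = np.diag(L)
        if (d.min() / d.max()) ** 2 < 1e-12:  # numerically singular pivot
            raise ValueError("singular conditioning design")
        prec = np.linalg.inv(L).T @ np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular conditioning design") from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise ValueError("singular conditioning design")
    return float(-prec[0, 1] / np.sqrt(denom))


def partial_correlation(
    data: pd.DataFrame, x: str, y: str, S: tuple[str, ...] | list[str] = ()
) -> float:
    """Partial correlation of x and y given S (listwise deletion).

    Computed through the precision matrix of {x, y} | S; algebraically
    identical to correlating the residuals of x ~ S and y ~ S.
    """
    S = tuple(S)
    if x == y or x in S or y in S:
        raise ValueError("x, y and S must be distinct")
    cols = [x, y, *S]
    sub = data[cols].dropna()
    if len(sub) <= len(S) + 3:
        raise ValueError(f"too few complete cases ({len(sub)}) for |S|={len(S)}")
    cov = np.cov(sub.to_numpy(float), rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        return _pcorr_from_cov(cov)
    except ValueError as exc:
        raise ValueError(f"singular conditioning design for {x}, {y} given {S}") from exc


def fisher_z_test(
    r: float, n: int, s_size: int, x: str = "", y: str = "", S: tuple[str, ...] = ()
) -> CITestResult:
    """Fisher z test of a (partial) correlation.

    z = atanh(r); statistic = sqrt(n - |S| - 3) * z, compared with the
    standard normal, two-sided.
    """
    df = n - s_size - 3
    if df <= 0:
        raise ValueError(f"need n - |S| - 3 > 0, got n={n}, |S|={s_size}")
    if abs(r) >= 1.0:
        stat = np.inf if r > 0 else -np.inf
        return CITestResult(x, y, S, float(np.sign(r)), stat, 0.0, n)
    z = np.arctanh(r)
    stat = np.sqrt(df) * z
    p = 2.0 * stats.norm.sf(abs(stat))
    return CITestResult(x, y, S, float(r), float(stat), float(p), n)


class CausalGraph:
    """Mixed graph over metabolites (plus instruments and a risk factor).

    Edges progress from ``undirected`` through orientation to
    ``directed``; irreconcilable orientation evidence leaves an edge in
    the ``conflict`` state.  The directed subgraph is kept acyclic: an
    orientation that would close a cycle is refused and logged.
    """

    def __init__(self, nodes):
        self.nodes: list[str] = list(nodes)
        self._node_set = set(self.nodes)
        self.undirected: set[frozenset] = set()
        self.directed: set[tuple[str, str]] = set()
        self.conflicts: set[frozenset] = set()
        self.sepsets: dict[frozenset, tuple[str, ...]] = {}
        self.instrument_nodes: set[str] = set()
        self.alpha: float | None = None
        self.log: list[str] = []

    # -- construction ---------------------------------------------------

    def add_node(self, node: str, instrument: bool = False) -> None:
        if node not in self._node_set:
            self.nodes.append(node)
            self._node_set.add(node)
        if instrument:
            self.instrument_nodes.add(node)

    def add_undirected(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        self.undirected.add(frozenset((u, v)))

    def add_directed(self, u: str, v: str, reason: str = "") -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        self.directed.add((u, v))
        if not self.is_acyclic():
            self.directed.discard((u, v))
            raise ValueError(f"edge {u}->{v} would create a cycle")
        if reason:
            self.log.append(f"{u}->{v}: {reason}")

    def remove_edge(self, u: str, v: str) -> None:
        self.undirected.discard(frozenset((u, v)))
        self.directed.discard((u, v))
        self.directed.discard((v, u))
        self.conflicts.discard(frozenset((u, v)))

    # -- queries ----------------------------------------------------------

    def has_skeleton_edge(self, u: str, v: str) -> bool:
        key = frozenset((u, v))
        return (
            key in self.undirected
            or key in self.conflicts
            or (u, v) in self.directed
            or (v, u) in self.directed
        )

    def neighbors(self, u: str) -> list[str]:
        out = set()
        for e in self.undirected | self.conflicts:
            if u in e:
                out.add(next(iter(e - {u})))
        for a, b in self.directed:
            if a == u:
                out.add(b)
            elif b == u:
                out.add(a)
        return sorted(out)

    def undirected_neighbors(self, u: str) -> list[str]:
        return sorted(next(iter(e - {u})) for e in self.undirected if u in e)

    def parents(self, u: str) -> list[str]:
        return sorted(a for a, b in self.directed if b == u)

    def children(self, u: str) -> list[str]:
        return sorted(b for a, b in self.directed if a == u)

    def in_degree(self, u: str) -> int:
        return sum(1 for _, b in self.directed if b == u)

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.directed_graph())

    # -- orientation -----------------------------------------------------

    def orient(self, u: str, v: str, reason: str) -> bool:
        """Turn the undirected edge u - v into u -> v.

        Returns False (and logs) if the edge is absent, already
        directed the other way, in conflict, or if directing it would
        close a cycle (the orientation is then reverted).
        """
        key = frozenset((u, v))
        if (u, v) in self.directed:
            return True
        if (v, u) in self.directed:
            self.conflicts.add(key)
            self.directed.discard((v, u))
            self.log.append(f"conflict {u}-{v}: opposing orientations ({reason})")
            return False
        if key in self.conflicts:
            return False
        if key not in self.undirected:
            return False
        self.undirected.discard(key)
        self.directed.add((u, v))
        if not self.is_acyclic():
            self.directed.discard((u, v))
            self.undirected.add(key)
            self.log.append(f"refused {u}->{v}: would create a cycle ({reason})")
            return False
        self.log.append(f"{u}->{v}: {reason}")
        return True

    def mark_conflict(self, u: str, v: str, reason: str) -> None:
        key = frozenset((u, v))
        self.undirected.discard(key)
        self.conflicts.add(key)
        self.log.append(f"conflict {u}-{v}: {reason}")

    # -- export -----------------------------------------------------------

    def edge_states(self) -> list[tuple[str, str, str]]:
        rows = [(a, b, "directed") for a, b in sorted(self.directed)]
        rows += [tuple(sorted(e)) + ("undirected",) for e in self.undirected]
        rows += [tuple(sorted(e)) + ("conflict",) for e in self.conflicts]
        return sorted(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edge_states(), columns=["source", "target", "state"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node, instrument=node in self.instrument_nodes)
        for a, b, state in self.edge_states():
            g.add_edge(a, b, state=state)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "CausalGraph":
        graph = cls(g.nodes)
        for node, attrs in g.nodes(data=True):
            if attrs.get("instrument"):
                graph.instrument_nodes.add(node)
        for a, b, attrs in g.edges(data=True):
            state = attrs.get("state", "directed")
            if state == "directed":
                graph.directed.add((a, b))
            elif state == "undirected":
                graph.add_undirected(a, b)
            elif state == "conflict":
                graph.conflicts.add(frozenset((a, b)))
        return graph

    def copy(self) -> "CausalGraph":
        g = CausalGraph(self.nodes)
        g.undirected = set(self.undirected)
        g.directed = set(self.directed)
        g.conflicts = set(self.conflicts)
        g.sepsets = dict(self.sepsets)
        g.instrument_nodes = set(self.instrument_nodes)
        g.alpha = self.alpha
        g.log = list(self.log)
        return g


class _CITester:
    """Conditional-independence tests against a dataset or a covariance.

    With complete data (or an explicit covariance), partial
    correlations come from submatrices of a single covariance; with
    missing data each test falls back to listwise deletion.
    """

    def __init__(
        self,
        data: pd.DataFrame | None = None,
        cov: np.ndarray | None = None,
        n: int | None = None,
        columns: list[str] | None = None,
    ):
        if data is not None:
            self.columns = list(data.columns)
            self.data = data
            complete = data.dropna()
            self.n_complete = len(complete)
            self.has_missing = self.n_complete < len(data)
            arr = complete.to_numpy(float)
            self.cov = np.cov(arr, rowvar=False) if self.n_complete > 1 else None
        else:
            if cov is None or n is None or columns is None:
                raise ValueError("need either data or (cov, n, columns)")
            self.columns = list(columns)
            self.data = None
            self.cov = np.asarray(cov, float)
            self.n_complete = int(n)
            self.has_missing = False
        self.index = {c: i for i, c in enumerate(self.columns)}

    def test(self, x: str, y: str, S: tuple[str, ...]) -> CITestResult:
        if self.data is not None and self.has_missing:
            cols = [x, y, *S]
            sub = self.data[cols].dropna()
            n = len(sub)
            if n <= len(S) + 3:
                raise ValueError(f"too few complete cases for test {x},{y}|{S}")
            cov = np.atleast_2d(np.cov(sub.to_numpy(float), rowvar=False))
            r = _pcorr_from_cov(cov)
        else:
            ix = [self.index[c] for c in (x, y, *S)]
            cov = self.cov[np.ix_(ix, ix)]
            r = _pcorr_from_cov(cov)
            n = self.n_complete
        r = float(np.clip(r, -1.0, 1.0))
        return fisher_z_test(r, n, len(S), x, y, S)


def learn_topology(
    data: pd.DataFrame | None = None,
    alpha: float = 0.001,
    max_order: int = 3,
    stage2: bool = True,
    cov: np.ndarray | None = None,
    n: int | None = None,
    columns: list[str] | None = None,
    shrinkage: bool = False,
) -> CausalGraph:
    """Learn the undirected topology over metabolites.

    Stage 1 keeps edge x - y iff x and y are dependent given *all*
    other variables (full-conditional screen; this is the moral graph
    of a generating DAG).  Stage 2 (optional, on by default) prunes
    spouse edges PC-style by searching conditioning subsets of the
    current neighborhoods up to ``max_order``, recording separating
    sets for later collider orientation.

    Accepts either a samples x variables DataFrame or a precomputed
    covariance with an effective sample size (for population-level
    checks).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if data is not None:
        p = data.shape[1]
        complete = data.dropna()
        if len(complete) <= p + 3 and not shrinkage:
            raise ValueError(
                f"only {len(complete)} complete cases for {p} variables; "
                "Stage 1 conditions on all others and needs n > p + 3 — "
                "use shrinkage=True for a Ledoit-Wolf regularized covariance"
            )
        if shrinkage:
            from sklearn.covariance import LedoitWolf

            lw = LedoitWolf().fit(complete.to_numpy(float))
            tester = _CITester(cov=lw.covariance_, n=len(complete), columns=list(data.columns))
            tester.data = data  # keep listwise path available for small sets
            tester.has_missing = False
        else:
            tester = _CITester(data=data)
        names = list(data.columns)
    else:
        tester = _CITester(cov=cov, n=n, columns=columns)
        names = list(columns)

    graph = CausalGraph(names)
    graph.alpha = alpha

    # Stage 1: full-conditional screen via the precision matrix
    order_names = sorted(names)
    for i, x in enumerate(order_names):
        for y in order_names[i + 1:]:
            S = tuple(c for c in order_names if c not in (x, y))
            res = tester.test(x, y, S)
            if res.p < alpha:
                graph.add_undirected(x, y)
    graph.log.append(f"stage1: {len(graph.undirected)} edges at alpha={alpha}")

    if not stage2:
        return graph

    # Stage 2: PC-style subset pruning over current neighborhoods
    for level in range(0, max_order + 1):
        removed_any = False
        for e in sorted(graph.undirected, key=lambda e: tuple(sorted(e))):
            x, y = sorted(e)
            candidates: list[tuple[str, ...]] = []
            seen = set()
            for anchor, other in ((x, y), (y, x)):
                nbrs = [v for v in graph.undirected_neighbors(anchor) if v != other]
                for S in itertools.combinations(nbrs, level):
                    if S not in seen:
                        seen.add(S)
                        candidates.append(S)
            for S in candidates:
                res = tester.test(x, y, S)
                if res.p >= alpha:
                    graph.remove_edge(x, y)
                    graph.sepsets[frozenset((x, y))] = S
                    graph.log.append(
                        f"stage2: removed {x}-{y} (independent given {S}, p={res.p:.3g})"
                    )
                    removed_any = True
                    break
        if not removed_any and level > 0:
            pass  # still advance the level: larger subsets may separate
    graph.log.append(f"stage2: {len(graph.undirected)} edges remain")
    return graph


def _apply_meek_rules(graph: CausalGraph) -> None:
    """Meek's propagation rules R1-R4, iterated to closure."""
    changed = True
    while changed:
        changed = False
        for e in sorted(graph.undirected, key=lambda e: tuple(sorted(e))):
            a, b = sorted(e)
            for u, v in ((a, b), (b, a)):
                # R1: w -> u, u - v, w and v non-adjacent  =>  u -> v
                if any(
                    w != v and not graph.has_skeleton_edge(w, v)
                    for w in graph.parents(u)
                ):
                    if graph.orient(u, v, "meek R1"):
                        changed = True
                        break
                # R2: u -> w -> v and u - v  =>  u -> v
                if any(w in graph.parents(v) for w in graph.children(u)):
                    if graph.orient(u, v, "meek R2"):
                        changed = True
                        break
                # R3: u - w1, u - w2, w1 -> v, w2 -> v, w1/w2 non-adjacent => u -> v
                und = graph.undirected_neighbors(u)
                par_v = set(graph.parents(v))
                ws = [w for w in und if w in par_v]
                if any(
                    not graph.has_skeleton_edge(w1, w2)
                    for i, w1 in enumerate(ws)
                    for w2 in ws[i + 1:]
                ):
                    if graph.orient(u, v, "meek R3"):
                        changed = True
                        break
                # R4: u - d, d -> c, c -> v, d and v non-adjacent, u - v => u -> v
                fired = False
                for d in graph.undirected_neighbors(u):
                    if d == v or graph.has_skeleton_edge(d, v):
                        continue
                    if any(c in graph.parents(v) for c in graph.children(d)):
                        if graph.orient(u, v, "meek R4"):
                            changed = True
                            fired = True
                        break
                if fired:
                    break
            if changed:
                break


def orient_with_instruments(
    topology: CausalGraph,
    instruments: InstrumentSet,
    data: pd.DataFrame,
    alpha: float = 0.001,
    f_min: float = 10.0,
) -> CausalGraph:
    """Orient an undirected topology using genomic instruments.

    For each undirected edge x - y with a usable (non-weak) instrument
    G_x: marginal association of G_x with y (p < alpha) together with
    independence of G_x and y given x (p >= alpha) — the exclusion
    restriction — supports x -> y.  The symmetric check runs with G_y;
    opposing evidence leaves the edge in the conflict state.  Collider
    orientation from recorded separating sets and Meek propagation
    complete the orientation; instruments are exogenous by construction
    (in-degree 0) and the directed subgraph is kept acyclic throughout.
    """
    graph = topology.copy()
    usable = [m for m in instruments.usable(f_min) if m in set(graph.nodes)]
    scores = instruments.scores()
    iv_name = {m: f"IV_{m}" for m in usable}

    iv_cols = pd.DataFrame(
        {iv_name[m]: scores[m].reindex(data.index) for m in usable}, index=data.index
    )
    joined = pd.concat([data, iv_cols], axis=1)
    tester = _CITester(data=joined)

    for m in usable:
        graph.add_node(iv_name[m], instrument=True)
        graph.add_directed(iv_name[m], m, "instrument exogeneity")

    # (2) instrument-based edge orientation
    for e in sorted(topology.undirected, key=lambda e: tuple(sorted(e))):
        x, y = sorted(e)
        evidence = []
        for a, b in ((x, y), (y, x)):
            if a not in iv_name:
                continue
            g = iv_name[a]
            marginal = tester.test(g, b, ())
            if marginal.p >= alpha:
                continue
            conditional = tester.test(g, b, (a,))
            if conditional.p >= alpha:
                evidence.append((a, b))
        if len(evidence) == 2:
            graph.mark_conflict(x, y, "instruments support both directions")
        elif len(evidence) == 1:
            a, b = evidence[0]
            graph.orient(a, b, f"instrument IV_{a}: associated with {b}, independent given {a}")

    # (3) collider orientation from separating sets; instrument-derived
    # orientations take precedence (exogenous evidence), so only fully
    # undirected unshielded triples are eligible
    met_nodes = [v for v in topology.nodes]
    for z in sorted(met_nodes):
        nbrs = [v for v in graph.neighbors(z) if v in set(met_nodes)]
        for x, y in itertools.combinations(sorted(nbrs), 2):
            if graph.has_skeleton_edge(x, y):
                continue
            sep = graph.sepsets.get(frozenset((x, y)))
            if sep is None or z in sep:
                continue
            if (
                frozenset((x, z)) not in graph.undirected
                or frozenset((y, z)) not in graph.undirected
            ):
                continue
            graph.orient(x, z, f"collider {x}->{z}<-{y} (sepset {sep})")
            graph.orient(y, z, f"collider {x}->{z}<-{y} (sepset {sep})")

    # (4) Meek propagation
    _apply_meek_rules(graph)

    undecided = sorted(tuple(sorted(e)) for e in graph.undirected)
    graph.log.append(f"orientation: {len(undecided)} edges undecided")
    assert graph.is_acyclic()
    for node in graph.instrument_nodes:
        assert graph.in_degree(node) == 0
    return graph


class CausalNetworkLearner(BaseEstimator):
    """Estimator learning a (partially) directed causal graph over
    standardized metabolites.

    Parameters
    ----------
    alpha : float, default 0.001
        Significance level of every conditional-independence test — the
        procedure's single tuning parameter.
    max_order : int, default 3
        Largest conditioning-subset size in the Stage-2 pruning search.
    stage2 : bool, default True
        Disable to keep the literal full-conditional (moral) topology.
    f_min : float, default 10.0
        Instruments with first-stage F below this are not used for
        orientation.

    Attributes
    ----------
    graph_ : CausalGraph
        Final mixed graph (directed / undirected / conflict edges).
    topology_ : CausalGraph
        The undirected topology before orientation.
    """

    def __init__(
        self,
        alpha: float = 0.001,
        max_order: int = 3,
        stage2: bool = True,
        f_min: float = 10.0,
        shrinkage: bool = False,
    ):
        self.alpha = alpha
        self.max_order = max_order
        self.stage2 = stage2
        self.f_min = f_min
        self.shrinkage = shrinkage

    def fit(
        self, X: pd.DataFrame, y=None, instruments: InstrumentSet | None = None
    ) -> "CausalNetworkLearner":
        self.topology_ = learn_topology(
            X,
            alpha=self.alpha,
            max_order=self.max_order,
            stage2=self.stage2,
            shrinkage=self.shrinkage,
        )
        if instruments is not None:
            self.graph_ = orient_with_instruments(
                self.topology_, instruments, X, alpha=self.alpha, f_min=self.f_min
            )
        else:
            self.graph_ = self.topology_.copy()
        self.n_features_in_ = X.shape[1]
        return self
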