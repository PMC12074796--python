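"""Piecewise structural equation modelling for site-level stability drivers.

A piecewise SEM is a directed acyclic graph over observed variables fitted as
a set of local ordinary-least-squares regressions (one per endogenous
variable).  Global structure is tested through the graph's d-separation basis
set: every implied conditional-independence claim is tested by the p-value of
the omitted variable in the corresponding regression, and the claims combine
into Fisher's C = -2 * sum(log p), compared to a chi-square with 2k degrees
of freedom.  A non-significant C means no important path is missing.

Community stability enters as a deterministic sink: it is fully determined by
its two components (average species stability and asynchrony), so its "path
coefficients" are the standardized coefficients of the sink regression
(r-squared ~ 1) and it takes no part in the basis set.

All modelled variables are z-standardized before fitting so coefficients are
directly comparable path coefficients; total effects of a driver on an
outcome are accumulated by summing coefficient products over directed paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathModelSpec",
    "PathFit",
    "PiecewiseSEM",
    "select_covariates",
    "fit_piecewise",
    "fishers_c",
    "accumulate_effects",
    "ols",
]


@dataclass
class OLSResult:
    names: list
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    rss: float
    n: int

    def pvalue(self, name: str) -> float:
        return float(self.p[self.names.index(name)])


def ols(y: np.ndarray, X: np.ndarray, names: list) -> OLSResult:
    """Plain OLS with an intercept prepended; t-based two-sided p-values."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    k = Xd.shape[1]
    if n <= k:
        raise ValueError("not enough observations for the regression")
    coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < k:
        raise ValueError("perfect collinearity among predictors")
    resid = y - Xd @ coef
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return OLSResult(["(intercept)"] + list(names), coef, se, t, p, r2, rss, n)


def _aicc(rss: float, n: int, n_slopes: int) -> float:
    # k counts intercept, slopes and the residual variance, as in MuMIn
    k = n_slopes + 2
    if n - k - 1 <= 0:
        return np.inf
    aic = n * np.log(rss / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def select_covariates(
    response: str,
    candidates,
    data: pd.DataFrame,
    delta: float | None = None,
) -> tuple:
    """Exhaustive all-subsets OLS selection ranked by AICc.

    Returns the predictor set of the best-ranked model (possibly empty:
    intercept-only).  With ``delta`` set, returns instead the union of
    predictors over all models within ``delta`` AICc of the best.
    """
    candidates = list(candidates)
    n = len(data)
    if n <= len(candidates) + 2:
        raise ValueError("need more sites than candidates plus two")
    y = data[response].to_numpy(dtype=float)
    Xfull = data.loc[:, candidates].to_numpy(dtype=float)
    if candidates and np.linalg.matrix_rank(
        np.column_stack([np.ones(n), Xfull])
    ) < len(candidates) + 1:
        raise ValueError("perfect collinearity among candidates")

    scored = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(range(len(candidates)), r):
            X = Xfull[:, list(subset)]
            Xd = np.column_stack([np.ones(n), X])
            coef, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
            rss = float(((y - Xd @ coef) ** 2).sum())
            scored.append((_aicc(max(rss, 1e-300), n, r), subset))
    scored.sort(key=lambda s: (s[0], len(s[1])))
    if delta is None:
        best = scored[0][1]
        return tuple(candidates[i] for i in best)
    best_score = scored[0][0]
    keep: set = set()
    for score, subset in scored:
        if score - best_score <= delta:
            keep.update(subset)
    return tuple(c for i, c in enumerate(candidates) if i in keep)


@dataclass
class PathModelSpec:
    """Fitted structure of the path model.

    ``edges`` maps each endogenous variable to its ordered parent tuple.
    ``correlated_errors`` lists unordered variable pairs whose residual
    correlation is estimated rather than directed (default in the stability
    model: average species stability with asynchrony).  ``sink`` names the
    deterministic community-stability node and its two component parents;
    it is excluded from the d-separation basis set.
    """

    edges: dict
    correlated_errors: list = field(default_factory=list)
    sink: tuple | None = None  # (node, (parent1, parent2))
    exclude_pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.edges = {r: tuple(p) for r, p in self.edges.items()}
        self.correlated_errors = [frozenset(p) for p in self.correlated_errors]
        self.exclude_pairs = [frozenset(p) for p in self.exclude_pairs]
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        directed = {frozenset((u, v)) for u, v in g.edges}
        if any(p in directed for p in self.correlated_errors):
            raise ValueError("correlated-error pair duplicates a directed edge")

    def graph(self, include_sink: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        for resp, parents in self.edges.items():
            for p in parents:
                g.add_edge(p, resp)
            g.add_node(resp)
        if include_sink and self.sink is not None:
            node, parents = self.sink
            if len(parents) != 2:
                raise ValueError("the sink must have exactly two component parents")
            for p in parents:
                g.add_edge(p, node)
        return g

    @property
    def nodes(self) -> list:
        return list(self.graph().nodes)


@dataclass
class PathFit:
    """Result of a piecewise fit: submodels, basis-set tests, global C."""

    spec: PathModelSpec
    coefficients: pd.DataFrame  # response, predictor, coef, se, p
    coef_map: dict  # (parent, child) -> standardized coefficient
    r2: dict
    resid_corr: dict
    basis: pd.DataFrame  # u, v, conditioning, p
    fisher_c: float
    df: int
    p_value: float
    saturated: bool = False


class PiecewiseSEM:
    """Piecewise SEM estimator.

    Parameters
    ----------
    spec : PathModelSpec
        The directed structure to fit (post covariate selection).

    After :meth:`fit`, exposes ``coefficients_`` (standardized path
    coefficients), ``r2_``, ``resid_corr_``, ``basis_``, ``fisher_c_``,
    ``df_`` and ``p_value_``, plus the full :class:`PathFit` as ``fit_``.
    """

    def __init__(self, spec: PathModelSpec):
        self.spec = spec

    def fit(self, data: pd.DataFrame) -> "PiecewiseSEM":
        fit = fit_piecewise(self.spec, data)
        self.fit_ = fit
        self.coefficients_ = fit.coefficients
        self.coef_map_ = fit.coef_map
        self.r2_ = fit.r2
        self.resid_corr_ = fit.resid_corr
        self.basis_ = fit.basis
        self.fisher_c_ = fit.fisher_c
        self.df_ = fit.df
        self.p_value_ = fit.p_value
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "PiecewiseSEM":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def _standardize(data: pd.DataFrame, columns) -> pd.DataFrame:
    z = data.loc[:, list(columns)].astype(float).copy()
    sd = z.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance variables: {bad}")
    return (z - z.mean()) / sd


def fit_piecewise(spec: PathModelSpec, data: pd.DataFrame) -> PathFit:
    """Fit every local regression on z-standardized data and test the basis set."""
    nodes = spec.nodes
    missing = [v for v in nodes if v not in data.columns]
    if missing:
        raise ValueError(f"variables missing from the data: {missing}")
    if data.loc[:, nodes].isna().any().any():
        raise ValueError("path-model data must be complete (no missing values)")
    z = _standardize(data, nodes)

    responses = dict(spec.edges)
    if spec.sink is not None:
        node, parents = spec.sink
        responses[node] = tuple(parents)

    rows = []
    coef_map = {}
    r2 = {}
    resids = {}
    for resp, parents in responses.items():
        res = ols(z[resp].to_numpy(), z.loc[:, list(parents)].to_numpy(), list(parents))
        r2[resp] = res.r2
        resids[resp] = z[resp].to_numpy() - np.column_stack(
            [np.ones(len(z))] + [z[p].to_numpy() for p in parents]
        ) @ res.coef
        for name, c, s, p in zip(res.names, res.coef, res.se, res.p):
            if name == "(intercept)":
                continue
            coef_map[(name, resp)] = float(c)
            rows.append({"response": resp, "predictor": name,
                         "coef": float(c), "se": float(s), "p": float(p)})
    coefficients = pd.DataFrame(rows)

    resid_corr = {}
    for pair in spec.correlated_errors:
        a, b = sorted(pair)
        ra = resids.get(a, z[a].to_numpy())
        rb = resids.get(b, z[b].to_numpy())
        resid_corr[(a, b)] = float(np.corrcoef(ra, rb)[0, 1])

    basis = _basis_set_tests(spec, z)
    c_stat, df, p_global, saturated = _fisher_from_basis(basis)
    return PathFit(spec, coefficients, coef_map, r2, resid_corr, basis,
                   c_stat, df, p_global, saturated)


def _basis_set_tests(spec: PathModelSpec, z: pd.DataFrame) -> pd.DataFrame:
    """Test every d-separation claim of the DAG (Shipley's basis set).

    Claims are the non-adjacent variable pairs, conditioned on the union of
    both variables' parents; pairs of exogenous variables (free covariances),
    declared correlated-error pairs, explicitly excluded pairs, and anything
    involving the deterministic sink are skipped.  Each claim is tested by
    the p-value of the omitted variable added to the regression of the
    causally downstream variable on the conditioning set.
    """
    g = spec.graph(include_sink=False)
    order = list(nx.topological_sort(g))
    pos = {v: i for i, v in enumerate(order)}
    parents = {v: set(g.predecessors(v)) for v in g.nodes}
    exog = {v for v in g.nodes if not parents[v]}
    skip = set(spec.correlated_errors) | set(spec.exclude_pairs)
    sink_node = spec.sink[0] if spec.sink else None

    rows = []
    for u, v in itertools.combinations(order, 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        if u in exog and v in exog:
            continue
        if frozenset((u, v)) in skip:
            continue
        if sink_node in (u, v):
            continue
        if nx.has_path(g, u, v):
            resp, other = v, u
        elif nx.has_path(g, v, u):
            resp, other = u, v
        else:
            resp, other = (v, u) if pos[v] > pos[u] else (u, v)
        cond = sorted((parents[u] | parents[v]) - {u, v})
        names = cond + [other]
        res = ols(z[resp].to_numpy(), z.loc[:, names].to_numpy(), names)
        rows.append({"u": other, "v": resp,
                     "conditioning": ", ".join(cond), "p": res.pvalue(other)})
    return pd.DataFrame(rows, columns=["u", "v", "conditioning", "p"])


def _fisher_from_basis(basis: pd.DataFrame) -> tuple[float, int, float, bool]:
    if len(basis) == 0:
        return 0.0, 0, 1.0, True
    p = np.clip(basis["p"].to_numpy(dtype=float), 1e-300, 1.0)
    c = float(-2.0 * np.sum(np.log(p)))
    df = 2 * len(p)
    return c, df, float(stats.chi2.sf(c, df)), False


def fishers_c(spec: PathModelSpec, data: pd.DataFrame) -> tuple[float, int, float]:
    """Fisher's C statistic, its degrees of freedom and global p-value.

    C = -2 * sum(ln p_k) over the k basis-set claims, compared to a
    chi-square with 2k degrees of freedom; an empty basis set (saturated
    model) gives C = 0, df = 0, p = 1.
    """
    z = _standardize(data, spec.nodes)
    basis = _basis_set_tests(spec, z)
    c, df, p, _ = _fisher_from_basis(basis)
    return c, df, p


def accumulate_effects(
    fit: PathFit | dict,
    drivers=None,
    outcomes=None,
) -> pd.DataFrame:
    """Direct / indirect / total effects by path-product accumulation.

    The indirect effect of a driver on an outcome is the sum, over all
    directed paths of length >= 2, of the product of standardized
    coefficients along the path; the direct effect is the coefficient of the
    direct edge (0 if absent); total = direct + indirect.  Because the
    deterministic community-stability sink carries its two component edges
    in the coefficient map, its totals are automatically the weighted sum of
    the component effects.

    Computed by nilpotent matrix accumulation: total = sum_k B^k restricted
    to (driver, outcome), exact on a DAG.
    """
    coef_map = fit.coef_map if isinstance(fit, PathFit) else dict(fit)
    nodes = {n for edge in coef_map for n in edge}
    nodes |= set(drivers or ()) | set(outcomes or ())
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    B = np.zeros((n, n))
    for (pa, ch), beta in coef_map.items():
        B[idx[ch], idx[pa]] = beta
    g = nx.DiGraph([(pa, ch) for pa, ch in coef_map])
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("effect accumulation requires an acyclic fitted graph")

    total = np.zeros((n, n))
    power = B.copy()
    for _ in range(n):
        if not power.any():
            break
        total += power
        power = power @ B

    if drivers is None:
        drivers = [v for v in nodes if not any(ch == v for _, ch in coef_map)]
    if outcomes is None:
        outcomes = [v for v in nodes if any(ch == v for _, ch in coef_map)]
    rows = []
    for d in drivers:
        for o in outcomes:
            if d == o:
                continue
            tot = float(total[idx[o], idx[d]])
            direct = float(B[idx[o], idx[d]])
            rows.append({"driver": d, "outcome": o, "direct": direct,
                         "indirect": tot - direct, "total": tot})
    return pd.DataFrame(rows)
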