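"""Causal DAG construction, orientation, cycle removal and role extraction.

The discovery pipeline proceeds in four steps: (1) candidate-parent
identification per target variable via linear Shapley attributions,
bootstrapping and density-based clustering of the attribution summaries;
(2) pairwise edge orientation under an additive-noise model, choosing the
direction whose regression residual is most independent of the predictor
(HSIC); (3) cycle removal driven by a Shapley-discrepancy score; and
(4) selection between the discovered DAG and an expert-supplied DAG by a
stability criterion that perturbs the direct treatment->outcome edge and
scores the consistency of the derived confounder/mediator/instrument sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN
from sklearn.linear_model import LinearRegression

__all__ = [
    "CausalDAG",
    "SkeletonMatrix",
    "RoleAssignment",
    "DiscoveryConfig",
    "linear_shap",
    "bootstrap_parent_candidates",
    "hsic_statistic",
    "orient_edge",
    "shap_discrepancy",
    "remove_cycles",
    "discover_dag",
    "extract_roles",
    "stability_score",
    "select_dag",
    "ground_truth_dag",
]


@dataclass
class CausalDAG:
    """Directed acyclic variable graph with a provenance tag."""

    nodes: tuple
    edges: tuple  # (source, target, weight) triples; weight may be None
    provenance: str = "expert"  # expert | discovered | selected

    def __post_init__(self):
        g = self.to_networkx()
        if any(u == v for u, v, _ in self.edges):
            raise ValueError("self-loops are not allowed")
        for u, v, _ in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint not in nodes: ({u}, {v})")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for u, v, w in sorted(self.edges, key=lambda e: (e[0], e[1])):
            g.add_edge(u, v, weight=w)
        return g

    def has_edge(self, u, v) -> bool:
        return any(a == u and b == v for a, b, _ in self.edges)

    @classmethod
    def from_networkx(cls, g: nx.DiGraph, provenance: str) -> "CausalDAG":
        edges = tuple(sorted((u, v, d.get("weight")) for u, v, d in g.edges(data=True)))
        return cls(nodes=tuple(sorted(g.nodes)), edges=edges, provenance=provenance)

    @classmethod
    def from_edge_list(cls, path, provenance: str = "expert",
                       extra_nodes=()) -> "CausalDAG":
        """Read a 2-column tab-separated edge list; '#' comments allowed."""
        edges = []
        nodes = set(extra_nodes)
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            edges.append((u, v, None))
            nodes.update((u, v))
        return cls(nodes=tuple(sorted(nodes)), edges=tuple(sorted(edges)),
                   provenance=provenance)

    def write_edge_list(self, path) -> None:
        lines = [f"{u}\t{v}" for u, v, _ in sorted(self.edges)]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def write_graphml(self, path) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for u, v, w in sorted(self.edges):
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=float(w))
        nx.write_graphml(g, path)


@dataclass
class SkeletonMatrix:
    """Bootstrap parent-selection frequencies and their binarization."""

    frequency: np.ndarray  # p x p, frequency[j, i] = rate X_j selected as parent of X_i
    threshold: float
    columns: tuple

    @property
    def adjacency(self) -> np.ndarray:
        return (self.frequency >= self.threshold).astype(int)


@dataclass
class RoleAssignment:
    """Confounder / mediator / instrument sets for a (treatment, outcome) pair."""

    confounders: frozenset
    mediators: frozenset
    instruments: frozenset

    def as_dict(self) -> dict:
        return {
            "confounders": sorted(self.confounders),
            "mediators": sorted(self.mediators),
            "instruments": sorted(self.instruments),
        }


@dataclass
class DiscoveryConfig:
    bootstrap: int = 20
    tau_sel: float = 0.5
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 2
    cluster_gap: float = 1.0    # required standardized separation of the
                                # winning cluster from the remaining features
    anm_degree: int = 3         # polynomial order of the orientation fits
    hsic_tie_tol: float = 1.0   # tie band in units of 1/n (HSIC null scale)
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap < 1:
            raise ValueError("bootstrap count must be >= 1")
        if not 0 < self.tau_sel <= 1:
            raise ValueError("tau_sel must lie in (0, 1]")
        if self.dbscan_eps <= 0:
            raise ValueError("dbscan_eps must be positive")


# ---------------------------------------------------------------------------
# Shapley attribution for linear models
# ---------------------------------------------------------------------------

def linear_shap(coefficients: np.ndarray, intercept: float,
                background_means: np.ndarray, x_row: np.ndarray) -> np.ndarray:
    """Exact Shapley attributions of a linear model.

    For f(x) = b0 + sum_j beta_j x_j the Shapley value of feature j relative
    to a background of feature means collapses to beta_j * (x_j - mean_j),
    and the attributions sum to f(x) - f(means) (efficiency).
    """
    coefficients = np.asarray(coefficients, float)
    background_means = np.asarray(background_means, float)
    x_row = np.asarray(x_row, float)
    if not (coefficients.shape == background_means.shape == x_row.shape):
        raise ValueError("coefficients, background_means and x_row must share a shape")
    return coefficients * (x_row - background_means)


def _attribution_matrix(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-sample linear-Shapley attributions of a regression of target on X."""
    model = LinearRegression().fit(X, target)
    return model.coef_ * (X - X.mean(axis=0))


def bootstrap_parent_candidates(X: pd.DataFrame, target_index: int,
                                config: DiscoveryConfig | None = None,
                                rng: np.random.Generator | None = None) -> np.ndarray:
    """One row of the parent-selection frequency matrix for a target column.

    Per bootstrap resample the target is regressed linearly on the remaining
    columns, each feature is summarized by (mean |attribution|, attribution
    SD), the standardized summaries are DBSCAN-clustered, and the cluster
    with the highest mean absolute attribution is marked as candidate
    parents — provided it separates from the remaining features by at least
    ``cluster_gap`` standardized units (so featureless noise rarely marks
    anything). A cluster swallowing every feature carries no contrast and
    marks nothing. Returns marks / B per feature (self-frequency 0).
    """
    config = config or DiscoveryConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cols = list(X.columns)
    p = len(cols)
    if p < 2:
        raise ValueError("need at least two columns")
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 rows")
    target_col = cols[target_index]
    others = [c for c in cols if c != target_col]
    y = X[target_col].to_numpy(float)
    freq = pd.Series(0.0, index=cols)
    if np.var(y) == 0:
        warnings.warn(f"constant target column {target_col!r}; returning zeros")
        return freq.to_numpy()
    Xo = X[others].to_numpy(float)
    for _ in range(config.bootstrap):
        idx = rng.integers(0, n, n)
        Xb, yb = Xo[idx], y[idx]
        if np.var(yb) == 0:
            continue
        phi = _attribution_matrix(Xb, yb)
        summary = np.column_stack([np.abs(phi).mean(axis=0), phi.std(axis=0)])
        mu, sd = summary.mean(axis=0), summary.std(axis=0)
        sd[sd == 0] = 1.0
        standardized = (summary - mu) / sd
        labels = DBSCAN(eps=config.dbscan_eps,
                        min_samples=config.dbscan_min_samples).fit_predict(standardized)
        clusters: dict[int, list[int]] = {}
        next_singleton = labels.max(initial=-1) + 1
        for j, lab in enumerate(labels):
            if lab == -1:  # noise points act as singleton clusters
                clusters[next_singleton] = [j]
                next_singleton += 1
            else:
                clusters.setdefault(lab, []).append(j)
        best = max(clusters, key=lambda c: np.abs(phi[:, clusters[c]]).mean())
        members = clusters[best]
        if len(members) == len(others) > 1:
            continue  # no separation: no distinguishable parents this round
        rest = [j for j in range(len(others)) if j not in members]
        if rest and (standardized[members, 0].min()
                     - standardized[rest, 0].max()) < config.cluster_gap:
            continue  # winning cluster not separated from the field
        for j in members:
            freq[others[j]] += 1.0
    return (freq / config.bootstrap).to_numpy()


# ---------------------------------------------------------------------------
# HSIC and additive-noise-model orientation
# ---------------------------------------------------------------------------

def _gaussian_gram(v: np.ndarray) -> np.ndarray | None:
    """Gaussian Gram matrix with median-heuristic bandwidth; None if constant."""
    d = pdist(v.reshape(-1, 1), metric="sqeuclidean")
    positive = d[d > 0]
    if positive.size == 0:
        return None
    sigma2 = np.median(np.sqrt(positive)) ** 2
    return np.exp(-squareform(d) / (2.0 * sigma2))


def hsic_statistic(u: np.ndarray, v: np.ndarray) -> float:
    """Biased HSIC V-statistic with Gaussian kernels (median heuristic).

    Computed as <Kc, L> / n^2 where Kc is the doubly centered Gram matrix of
    u; zero for constant inputs.
    """
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    if u.shape != v.shape:
        raise ValueError("u and v must have equal length")
    n = len(u)
    if n < 5:
        raise ValueError("need at least 5 observations")
    K = _gaussian_gram(u)
    L = _gaussian_gram(v)
    if K is None or L is None:
        return 0.0
    Kc = K - K.mean(axis=0, keepdims=True)
    Kc -= Kc.mean(axis=1, keepdims=True)
    Lc = L - L.mean(axis=0, keepdims=True)
    Lc -= Lc.mean(axis=1, keepdims=True)
    return float(max((Kc * Lc).sum() / n**2, 0.0))


def orient_edge(x_i: np.ndarray, x_j: np.ndarray,
                config: DiscoveryConfig | None = None) -> tuple[str, float, float]:
    """Orient an undirected edge (i, j) by residual independence.

    Returns (direction, hsic_j_to_i, hsic_i_to_j) where direction is one of
    'j->i', 'i->j', or 'ambiguous'. Both variables are standardized, each is
    regressed on the other with a low-order polynomial (an additive-noise
    mechanism leaves the forward residual independent of its cause only if
    the regression can absorb the mechanism), and the direction whose
    residual is most independent of the predictor wins. The tie band scales
    as 1/n, the order of the HSIC V-statistic under independence; ties and
    degenerate regressions are ambiguous.
    """
    config = config or DiscoveryConfig()
    x_i = np.asarray(x_i, float).ravel()
    x_j = np.asarray(x_j, float).ravel()
    if np.var(x_i) == 0 or np.var(x_j) == 0:
        return "ambiguous", np.nan, np.nan
    n = len(x_i)
    a = (x_i - x_i.mean()) / x_i.std()
    b = (x_j - x_j.mean()) / x_j.std()
    # discrete regressors support only as many polynomial terms as levels
    deg_a = min(config.anm_degree, max(1, n - 2), len(np.unique(a)) - 1)
    deg_b = min(config.anm_degree, max(1, n - 2), len(np.unique(b)) - 1)
    # X_i = f(X_j) + r_{i|j}  -> candidate direction j->i
    r_i_given_j = a - np.polyval(np.polyfit(b, a, deg_b), b)
    r_j_given_i = b - np.polyval(np.polyfit(a, b, deg_a), a)
    h_j_to_i = hsic_statistic(b, r_i_given_j)
    h_i_to_j = hsic_statistic(a, r_j_given_i)
    if abs(h_j_to_i - h_i_to_j) <= config.hsic_tie_tol / n:
        return "ambiguous", h_j_to_i, h_i_to_j
    if h_j_to_i < h_i_to_j:
        return "j->i", h_j_to_i, h_i_to_j
    return "i->j", h_j_to_i, h_i_to_j


def shap_discrepancy(phi_j: np.ndarray, x_i: np.ndarray) -> float:
    """Edge-strength discrepancy: 1 - r^2 between attributions and target."""
    phi_j = np.asarray(phi_j, float).ravel()
    x_i = np.asarray(x_i, float).ravel()
    if phi_j.shape != x_i.shape:
        raise ValueError("phi_j and x_i must have equal length")
    if np.var(phi_j) == 0 or np.var(x_i) == 0:
        warnings.warn("zero-variance input to shap_discrepancy; returning 1.0")
        return 1.0
    r = np.corrcoef(phi_j, x_i)[0, 1]
    return float(1.0 - r**2)


# ---------------------------------------------------------------------------
# Cycle removal and full discovery
# ---------------------------------------------------------------------------

def remove_cycles(g: nx.DiGraph, delta: dict[tuple, float]) -> nx.DiGraph:
    """Delete, per remaining cycle, the edge with maximal discrepancy.

    Cycle enumeration is a deterministic DFS from the lexicographically
    smallest node; ties on the discrepancy break lexicographically by
    (source, target).
    """
    g = g.copy()
    while True:
        try:
            cycle = nx.find_cycle(g, source=sorted(g.nodes))
        except nx.NetworkXNoCycle:
            return g
        worst = max(cycle, key=lambda e: (delta.get((e[0], e[1]), 0.0), e[0], e[1]))
        g.remove_edge(worst[0], worst[1])


def discover_dag(X: pd.DataFrame, config: DiscoveryConfig | None = None) -> CausalDAG:
    """Run skeleton -> orientation -> cycle removal on a numeric table."""
    config = config or DiscoveryConfig()
    cols = list(X.columns)
    p = len(cols)
    if p < 2:
        return CausalDAG(nodes=tuple(sorted(cols)), edges=(), provenance="discovered")
    rng = np.random.default_rng(config.seed)
    freq = np.zeros((p, p))
    for i in range(p):
        freq[:, i] = bootstrap_parent_candidates(X, i, config, rng=rng)
    skeleton = SkeletonMatrix(frequency=freq, threshold=config.tau_sel,
                              columns=tuple(cols))
    adj = skeleton.adjacency
    undirected = sorted(
        (cols[min(i, j)], cols[max(i, j)])
        for i in range(p) for j in range(p)
        if i != j and (adj[i, j] or adj[j, i])
    )
    undirected = sorted(set(undirected))

    g = nx.DiGraph()
    g.add_nodes_from(sorted(cols))
    for a, b in undirected:
        direction, _, _ = orient_edge(X[a].to_numpy(), X[b].to_numpy(), config)
        # orient_edge(x_i=a, x_j=b): 'j->i' means b -> a
        if direction == "j->i":
            g.add_edge(b, a)
        elif direction == "i->j":
            g.add_edge(a, b)
        # ambiguous edges are dropped

    delta: dict[tuple, float] = {}
    phi_cache: dict[str, pd.DataFrame] = {}
    for u, v in g.edges:
        if v not in phi_cache:
            others = [c for c in cols if c != v]
            phi = _attribution_matrix(X[others].to_numpy(float), X[v].to_numpy(float))
            phi_cache[v] = pd.DataFrame(phi, columns=others)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delta[(u, v)] = shap_discrepancy(phi_cache[v][u].to_numpy(),
                                             X[v].to_numpy())
    g = remove_cycles(g, delta)
    return CausalDAG.from_networkx(g, provenance="discovered")


# ---------------------------------------------------------------------------
# Roles, stability and final selection
# ---------------------------------------------------------------------------

def extract_roles(dag: CausalDAG, treatment: str, outcome: str) -> RoleAssignment:
    """Derive confounders, mediators and instruments from a DAG.

    Confounders have a directed path to the treatment and a directed path to
    the outcome that avoids the treatment. Mediators sit on a directed
    treatment->outcome path. Instruments are parents of the treatment whose
    only routes to the outcome pass through the treatment.
    """
    g = dag.to_networkx()
    if treatment not in g or outcome not in g:
        raise ValueError("treatment and outcome must be nodes of the DAG")
    g_minus_t = g.copy()
    g_minus_t.remove_node(treatment)

    anc_t = nx.ancestors(g, treatment)
    desc_t = nx.descendants(g, treatment)
    anc_y_avoiding_t = (
        nx.ancestors(g_minus_t, outcome) if outcome in g_minus_t else set()
    )

    confounders = {
        v for v in anc_t
        if v != outcome and v in anc_y_avoiding_t
    }
    mediators = {
        v for v in desc_t
        if v not in (treatment, outcome) and outcome in nx.descendants(g, v)
    }
    instruments = {
        v for v in g.predecessors(treatment)
        if v != outcome
        and v not in anc_y_avoiding_t
        and v not in confounders
    }
    return RoleAssignment(
        confounders=frozenset(confounders - mediators),
        mediators=frozenset(mediators),
        instruments=frozenset(instruments - mediators - confounders),
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def stability_score(dag: CausalDAG, treatment: str, outcome: str) -> float:
    """Sensitivity of role sets to deleting the direct treatment->outcome edge.

    Returns the mean Jaccard similarity of the confounder, mediator and
    instrument sets before vs after the perturbation; 1.0 when the direct
    edge is absent (no-op perturbation).
    """
    before = extract_roles(dag, treatment, outcome)
    if not dag.has_edge(treatment, outcome):
        return 1.0
    g = dag.to_networkx()
    g.remove_edge(treatment, outcome)
    after = extract_roles(CausalDAG.from_networkx(g, dag.provenance),
                          treatment, outcome)
    return float(np.mean([
        _jaccard(before.confounders, after.confounders),
        _jaccard(before.mediators, after.mediators),
        _jaccard(before.instruments, after.instruments),
    ]))


def select_dag(expert_dag: CausalDAG, discovered_dag: CausalDAG,
               treatment: str, outcome: str) -> CausalDAG:
    """Pick the more role-stable DAG; the expert DAG wins ties."""
    s_expert = stability_score(expert_dag, treatment, outcome)
    s_discovered = stability_score(discovered_dag, treatment, outcome)
    return expert_dag if s_expert >= s_discovered else discovered_dag


def ground_truth_dag() -> CausalDAG:
    """The simulator's ground-truth graph over the observed variables.

    Age (X0), immune status (X2) and comorbidity (X4) confound treatment and
    outcome; geography (X8) acts only through the instrument Z; the mediator
    M carries part of the treatment effect to the outcome. X1, X5, X6 and X9
    are present but disconnected.
    """
    nodes = ("M", "T", "X0", "X1", "X2", "X3", "X4", "X5", "X6", "X8", "X9", "Y", "Z")
    edges = (
        ("M", "Y", None),
        ("T", "M", None),
        ("T", "Y", None),
        ("X0", "T", None),
        ("X0", "Y", None),
        ("X2", "T", None),
        ("X2", "Y", None),
        ("X3", "M", None),
        ("X4", "T", None),
        ("X4", "Y", None),
        ("X8", "Z", None),
        ("Z", "T", None),
    )
    return CausalDAG(nodes=nodes, edges=edges, provenance="expert")
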