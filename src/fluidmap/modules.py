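"""Phenotype-driven greedy module identification.

A *candidate module* is a connected node set of one network level.  Its
representative R_M is the average z-score of all member metabolites (for
pathway-level modules: the set union of the pathways' metabolites).  The
module score is -log10 of the p-value of the phenotype coefficient beta_1 in
the OLS fit

    R_M ~ beta_0 + beta_1 * P + beta_2 * gender + beta_3 * age + beta_4 * BMI

(the covariate list is configurable; a phenotype never appears in its own
covariate set, so a gender analysis drops gender as a covariate).  A
single-node module's score is its univariate association under the same
formula.

The greedy search grows a module from a seed node: each iteration adds the
neighbor yielding the highest score, but only if the new score strictly
exceeds both the current score and every member's single-node score.
Overlapping per-seed optima are consolidated into *maximal modules* (union
over each connected component of the overlap graph) and rescored.  A maximal
module is reported iff its p-value beats the node-level Bonferroni threshold
alpha / n_nodes and its score strictly exceeds its best member's univariate
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnnotationTable,
    CorrelationNetwork,
    Module,
    ModuleReport,
    PhenotypeTable,
    split_node_id,
)

__all__ = [
    "SCORE_CAP",
    "module_representative",
    "score_module",
    "RegressionScorer",
    "greedy_search",
    "consolidate",
    "filter_significant",
    "run_module_identification",
]

SCORE_CAP = 300.0  # -log10 p underflows beyond this


def _zscore(arr: np.ndarray) -> np.ndarray:
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance member metabolite")
    return (arr - arr.mean(axis=0)) / sd


def module_representative(
    data: pd.DataFrame, member_features: list[str]
) -> np.ndarray:
    """Average z-score of the member metabolites (columns of ``data``)."""
    if not member_features:
        raise ValueError("empty member set")
    arr = data[list(member_features)].to_numpy(dtype=float)
    return _zscore(arr).mean(axis=1)


@dataclass
class _Design:
    """Precomputed OLS machinery for a fixed design matrix [1, P, covs]."""

    X: np.ndarray
    pinv: np.ndarray
    se_factor: float  # sqrt of [(X'X)^-1]_PP
    df: int

    @classmethod
    def build(cls, phenotype: np.ndarray, covariates: np.ndarray) -> "_Design":
        n = phenotype.shape[0]
        X = np.column_stack([np.ones(n), phenotype, covariates])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("rank-deficient design (collinear covariates?)")
        xtx_inv = np.linalg.inv(X.T @ X)
        return cls(
            X=X,
            pinv=xtx_inv @ X.T,
            se_factor=float(np.sqrt(xtx_inv[1, 1])),
            df=n - X.shape[1],
        )

    def pvalue(self, y: np.ndarray) -> float:
        beta = self.pinv @ y
        resid = y - self.X @ beta
        rss = float(resid @ resid)
        if self.df <= 0:
            raise ValueError("not enough samples for the design")
        sigma2 = rss / self.df
        if sigma2 <= 0:
            return 0.0
        t = beta[1] / (np.sqrt(sigma2) * self.se_factor)
        return float(2.0 * stats.t.sf(abs(t), self.df))


def score_module(
    representative: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Score one representative vector: (-log10 p, p) of the P coefficient."""
    y = np.asarray(representative, dtype=float)
    P = np.asarray(phenotype, dtype=float)
    if y.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant module representative")
    if np.ptp(P) == 0:
        raise ValueError("constant phenotype")
    cov = np.empty((y.shape[0], 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float)
    )
    if cov.shape[0] != y.shape[0]:
        cov = cov.T
    design = _Design.build(P, cov)
    p = design.pvalue(y)
    score = SCORE_CAP if p <= 0 else min(-np.log10(p), SCORE_CAP)
    return score, p


class RegressionScorer:
    """Caches z-scored data and the OLS design; scores node sets.

    ``node_members`` maps each network node to the feature ids whose
    z-scores enter the representative (at metabolite level each node maps to
    its own feature; at pathway levels to all metabolites annotated to the
    pathway).  Member features of a multi-node module are the set union.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        node_members: dict[str, list[str]],
        phenotype: np.ndarray,
        covariates: np.ndarray | None = None,
    ) -> None:
        self.node_members = {k: list(v) for k, v in node_members.items()}
        feats = sorted({f for v in self.node_members.values() for f in v})
        self._cols = {f: i for i, f in enumerate(feats)}
        self._z = _zscore(data[feats].to_numpy(dtype=float))
        P = np.asarray(phenotype, dtype=float)
        cov = (
            np.empty((len(P), 0))
            if covariates is None
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        )
        if cov.shape[0] != len(P):
            cov = cov.T
        self._design = _Design.build(P, cov)
        self._cache: dict[frozenset, tuple[float, float]] = {}

    def members(self, nodes: frozenset) -> list[str]:
        out: set[str] = set()
        for n in nodes:
            out.update(self.node_members[n])
        return sorted(out)

    def representative(self, nodes: frozenset) -> np.ndarray:
        idx = [self._cols[f] for f in self.members(nodes)]
        if not idx:
            raise ValueError("empty member set")
        return self._z[:, idx].mean(axis=1)

    def __call__(self, nodes: frozenset) -> tuple[float, float]:
        nodes = frozenset(nodes)
        hit = self._cache.get(nodes)
        if hit is not None:
            return hit
        y = self.representative(nodes)
        if np.ptp(y) == 0:
            raise ValueError("constant module representative")
        p = self._design.pvalue(y)
        score = SCORE_CAP if p <= 0 else min(-np.log10(p), SCORE_CAP)
        self._cache[nodes] = (score, p)
        return score, p


def greedy_search(
    network: CorrelationNetwork, seed: str, scorer
) -> Module:
    """Grow an optimal module from one seed by greedy score maximization.

    ``scorer`` maps a frozenset of nodes to (score, p_value).  Each step
    evaluates every network neighbor v of the module M, takes the best v*
    (lexicographically smallest node id on ties) and accepts it iff
    score(M + v*) strictly exceeds score(M) and the single-node score of
    every member of M + v*.
    """
    if seed not in set(network.nodes):
        raise ValueError(f"seed {seed!r} not in network")
    adj = network.adjacency()
    current = frozenset([seed])
    score, p = scorer(current)
    max_single = scorer(frozenset([seed]))[0]
    while True:
        neighbors = sorted(
            set().union(*(adj[n] for n in current)) - current
        )
        if not neighbors:
            break
        best_node, best_score, best_p = None, -np.inf, 1.0
        for v in neighbors:
            s, pv = scorer(current | {v})
            if s > best_score:
                best_node, best_score, best_p = v, s, pv
        cand_max_single = max(max_single, scorer(frozenset([best_node]))[0])
        if best_score > score and best_score > cand_max_single:
            current = current | {best_node}
            score, p = best_score, best_p
            max_single = cand_max_single
        else:
            break
    return Module(
        nodes=current, score=score, p_value=p,
        seeds=frozenset([seed]), status="optimal",
    )


def consolidate(optimal_modules: list[Module], scorer) -> list[Module]:
    """Merge overlapping optima into maximal modules and rescore them.

    Modules sharing at least one node land in the same connected component
    of the overlap graph; each component's node union is one maximal module.
    The result is pairwise disjoint.
    """
    if not optimal_modules:
        return []
    n = len(optimal_modules)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    node_owner: dict[str, int] = {}
    for i, m in enumerate(optimal_modules):
        for node in m.nodes:
            if node in node_owner:
                union(i, node_owner[node])
            else:
                node_owner[node] = i
    comps: dict[int, list[Module]] = {}
    for i, m in enumerate(optimal_modules):
        comps.setdefault(find(i), []).append(m)
    out = []
    for ms in comps.values():
        nodes = frozenset().union(*(m.nodes for m in ms))
        seeds = frozenset().union(*(m.seeds for m in ms))
        score, p = scorer(nodes)
        out.append(
            Module(nodes=nodes, score=score, p_value=p, seeds=seeds,
                   status="maximal")
        )
    return sorted(out, key=lambda m: (-m.score, sorted(m.nodes)))


def filter_significant(
    maximal_modules: list[Module],
    n_nodes: int,
    scorer,
    alpha: float = 0.05,
    level: str = "metabolite",
    phenotype: str = "P",
) -> ModuleReport:
    """Node-level Bonferroni + single-component dominance filter.

    A module is reported iff p < alpha / n_nodes *and* its score strictly
    exceeds the maximum single-node score among its members (a single-node
    module can never satisfy the strict inequality against itself).
    """
    if n_nodes == 0:
        raise ValueError("network has no nodes")
    thresh = alpha / n_nodes
    kept = []
    for m in maximal_modules:
        if m.p_value >= thresh:
            continue
        best_single = max(scorer(frozenset([u]))[0] for u in m.nodes)
        if m.score > best_single:
            kept.append(m)
    kept = sorted(kept, key=lambda m: (-m.score, sorted(m.nodes)))
    return ModuleReport(
        modules=kept, level=level, phenotype=phenotype,
        n_nodes=n_nodes, alpha=alpha,
    )


def _node_members_for_level(
    network: CorrelationNetwork,
    level: str,
    annotations: AnnotationTable | None,
    data_columns,
) -> dict[str, list[str]]:
    cols = set(data_columns)
    if level == "metabolite":
        if annotations is None:
            return {n: [split_node_id(n)[1]] for n in network.nodes}
        by_node = {
            annotations.metabolite_node(f): [f]
            for f in annotations.feature_ids if f in cols
        }
        return {n: by_node[n] for n in network.nodes}
    if annotations is None:
        raise ValueError("pathway levels need an annotation table")
    groups = (
        annotations.members_of_sub_pathways()
        if level == "sub_pathway"
        else annotations.members_of_super_pathways()
    )
    return {
        n: [f for f in groups[n] if f in cols] for n in network.nodes
    }


def run_module_identification(
    hierarchical_map,
    phenotypes: PhenotypeTable,
    level: str = "metabolite",
    alpha: float = 0.05,
) -> ModuleReport:
    """Full module search at one level of a hierarchical map.

    Every node of the chosen network serves as a seed; per-seed greedy
    optima are consolidated and filtered.  Sample alignment is by inner join
    between the map's data matrix and the phenotype table.  The phenotype is
    dropped from its own covariate list automatically.
    """
    network = hierarchical_map.network(level)
    data = hierarchical_map.data
    ids = [s for s in data.index if s in phenotypes.table.index]
    if not ids:
        raise ValueError("no overlapping samples between data and phenotypes")
    pheno = phenotypes.aligned(ids)
    node_members = _node_members_for_level(
        network, level, hierarchical_map.annotations, data.columns
    )
    scorer = RegressionScorer(
        data.loc[ids],
        node_members,
        pheno.phenotype_vector(),
        pheno.covariate_matrix(),
    )
    optima = [greedy_search(network, seed, scorer) for seed in sorted(network.nodes)]
    maximal = consolidate(optima, scorer)
    report = filter_significant(
        maximal, n_nodes=network.n_nodes, scorer=scorer, alpha=alpha,
        level=level, phenotype=pheno.phenotype,
    )
    for m in report.modules:
        m.member_features = tuple(scorer.members(m.nodes))
    return report
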