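"""Three-level hierarchical map construction.

Level 1 (metabolite): GGM on all metabolites, unknowns included.
Level 2 (sub-pathway): one *eigenmetabolite* per fluid-resolved sub-pathway
  (first principal component of its z-scored member metabolites), then a GGM
  on the eigenmetabolite matrix.
Level 3 (super-pathway): the sub-pathway GGM collapsed — two super-pathway
  nodes are linked iff at least one pair of their member sub-pathways is
  connected.  Super-pathway representatives are deliberately never computed
  by PCA: broad groups such as 'Lipid' are too heterogeneous for a single
  component to represent them, so collapsing is the only route to level 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ggm
from .datatypes import AnnotationTable, CorrelationNetwork

__all__ = [
    "EigenRepresentation",
    "eigenmetabolite",
    "build_subpathway_network",
    "collapse_to_superpathway",
    "HierarchicalMap",
    "build_hierarchical_map",
    "explained_variance_table",
]


@dataclass
class EigenRepresentation:
    """First-principal-component representative of one sub-pathway."""

    node: str
    members: list[str]
    scores: np.ndarray  # eigenmetabolite over samples, zero mean
    explained_variance: float
    loadings: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.explained_variance <= 1.0 + 1e-12:
            raise ValueError(
                f"explained variance out of (0, 1]: {self.explained_variance}"
            )


def eigenmetabolite(x_members: pd.DataFrame, node: str = "") -> EigenRepresentation:
    """Eigenmetabolite of a fully observed member matrix (samples x members).

    Members are z-scored, the leading principal component score vector is
    the representative, and the explained variance is the leading eigenvalue
    of the member correlation matrix divided by its trace.  The sign is
    fixed so the eigenmetabolite correlates non-negatively with the mean of
    the z-scored members, which makes the result deterministic.
    """
    arr = x_members.to_numpy(dtype=float)
    n, m = arr.shape
    if m < 1:
        raise ValueError("pathway with no members")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [x_members.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance member(s): {bad}")
    z = (arr - arr.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    ev = float(s[0] ** 2 / (s**2).sum())
    mean_z = z.mean(axis=1)
    if np.dot(scores, mean_z) < 0:
        scores = -scores
        loadings = -loadings
    return EigenRepresentation(
        node=node,
        members=list(x_members.columns),
        scores=scores,
        explained_variance=ev,
        loadings=loadings,
    )


def build_subpathway_network(
    x: pd.DataFrame,
    annotations: AnnotationTable,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    shrinkage: float | None = None,
    null_fit: str = "mixture",
) -> tuple[CorrelationNetwork, list[EigenRepresentation]]:
    """Sub-pathway eigenmetabolite GGM.

    ``x`` is the fully observed, preprocessed samples x metabolites matrix
    (column ids are feature ids).  Only known metabolites participate;
    unknowns cannot be assigned to a pathway.
    """
    groups = annotations.members_of_sub_pathways()
    reps: list[EigenRepresentation] = []
    for node in sorted(groups):
        members = [f for f in groups[node] if f in x.columns]
        if not members:
            continue
        reps.append(eigenmetabolite(x[members], node=node))
    if len(reps) < 2:
        raise ValueError("need at least 2 sub-pathway nodes")
    eigen_matrix = pd.DataFrame(
        {rep.node: rep.scores for rep in reps}, index=x.index
    )
    net = ggm.build_ggm(
        eigen_matrix,
        covariates=covariates,
        alpha=alpha,
        shrinkage=shrinkage,
        null_fit=null_fit,
        level="sub_pathway",
    )
    return net, reps


def collapse_to_superpathway(
    subnet: CorrelationNetwork, sub_to_super: dict[str, str]
) -> CorrelationNetwork:
    """Collapse a sub-pathway network onto fluid-resolved super-pathways.

    Two distinct super-pathway nodes are linked iff >= 1 sub-pathway edge
    connects their members; intra-super-pathway sub-pathway edges would be
    self-loops and are dropped.  Edges carry the member-edge count.
    """
    unmapped = [n for n in subnet.nodes if n not in sub_to_super]
    if unmapped:
        raise ValueError(f"sub-pathway nodes without super-pathway: {unmapped}")
    super_nodes = sorted(set(sub_to_super[n] for n in subnet.nodes))
    counts: dict[tuple[str, str], int] = {}
    for (u, v) in subnet.edges:
        su, sv = sub_to_super[u], sub_to_super[v]
        if su == sv:
            continue
        key = (su, sv) if su < sv else (sv, su)
        counts[key] = counts.get(key, 0) + 1
    return CorrelationNetwork(
        level="super_pathway", nodes=super_nodes, edges=dict(counts)
    )


@dataclass
class HierarchicalMap:
    """The three networks plus the pieces the module search needs."""

    metabolite: CorrelationNetwork
    sub_pathway: CorrelationNetwork
    super_pathway: CorrelationNetwork
    eigen: list[EigenRepresentation]
    annotations: AnnotationTable
    data: pd.DataFrame  # preprocessed samples x features (feature ids)

    def network(self, level: str) -> CorrelationNetwork:
        try:
            return getattr(self, level)
        except AttributeError:
            raise ValueError(f"unknown level {level!r}") from None


def build_hierarchical_map(
    x: pd.DataFrame,
    annotations: AnnotationTable,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    include_unknowns: bool = True,
    shrinkage: float | None = None,
    null_fit: str = "mixture",
) -> HierarchicalMap:
    """Build all three levels from a preprocessed complete matrix.

    Metabolite-level nodes are named ``FLUID::feature``; unknown metabolites
    participate at this level (they carry correlation information) unless
    ``include_unknowns=False``, and never at the pathway levels.
    """
    feats = [f for f in x.columns if f in set(annotations.feature_ids)]
    if not include_unknowns:
        known = set(annotations.known_features())
        feats = [f for f in feats if f in known]
    met_nodes = [annotations.metabolite_node(f) for f in feats]
    met_net = ggm.build_ggm(
        x[feats],
        variables=met_nodes,
        covariates=covariates,
        alpha=alpha,
        shrinkage=shrinkage,
        null_fit=null_fit,
        level="metabolite",
    )
    sub_net, reps = build_subpathway_network(
        x, annotations,
        covariates=covariates, alpha=alpha,
        shrinkage=shrinkage, null_fit=null_fit,
    )
    super_net = collapse_to_superpathway(sub_net, annotations.sub_to_super())
    return HierarchicalMap(
        metabolite=met_net,
        sub_pathway=sub_net,
        super_pathway=super_net,
        eigen=reps,
        annotations=annotations,
        data=x,
    )


def explained_variance_table(reps: list[EigenRepresentation]) -> pd.DataFrame:
    """Per-pathway explained-variance summary (pathway node, m, EV)."""
    return pd.DataFrame(
        [
            {
                "pathway": rep.node,
                "n_members": len(rep.members),
                "explained_variance": rep.explained_variance,
            }
            for rep in sorted(reps, key=lambda r: r.node)
        ]
    )
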