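"""Core data containers for multifluid metabolomics matrices and networks.

Everything downstream (preprocessing, network inference, module search)
operates on these containers.  Matrices are held as pandas DataFrames with
samples on the rows and features on the columns; missing intensities are
encoded as NaN (raw ion counts are strictly positive, so no in-band sentinel
is possible).

Node identity throughout the package is the string ``"<FLUID>::<name>"``,
e.g. ``"P::m017"`` for a plasma metabolite or ``"U::Sterol"`` for a urine
sub-pathway, so that the same metabolite measured in two fluids yields two
distinct network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "node_id",
    "split_node_id",
    "IntensityMatrix",
    "AnnotationTable",
    "PhenotypeTable",
    "EdgeStats",
    "CorrelationNetwork",
    "Module",
    "ModuleReport",
]

NODE_SEP = "::"


def node_id(fluid: str, name: str) -> str:
    """Build the canonical ``FLUID::name`` node identity string."""
    return f"{fluid}{NODE_SEP}{name}"


def split_node_id(node: str) -> tuple[str, str]:
    """Inverse of :func:`node_id`; splits on the first ``::``."""
    fluid, _, name = node.partition(NODE_SEP)
    if not _:
        raise ValueError(f"not a FLUID::name node id: {node!r}")
    return fluid, name


@dataclass
class IntensityMatrix:
    """Samples x features intensity matrix with run-day and fluid labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are feature ids.  Entries are
        strictly positive intensities or NaN (missing).  After log transform
        the positivity invariant no longer applies; ``log_scale`` records
        which scale the values are on.
    runday
        Series mapping each sample id to its run-day label.
    fluid
        Series mapping each feature id to its fluid label (e.g. P/U/S).
    log_scale
        True once the matrix has been log2-transformed.
    """

    values: pd.DataFrame
    runday: pd.Series
    fluid: pd.Series
    log_scale: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        self.runday = self.runday.reindex(v.index)
        if self.runday.isna().any():
            missing = self.runday.index[self.runday.isna()].tolist()
            raise ValueError(f"samples without run-day label: {missing}")
        self.fluid = self.fluid.reindex(v.columns)
        if self.fluid.isna().any():
            missing = self.fluid.index[self.fluid.isna()].tolist()
            raise ValueError(f"features without fluid label: {missing}")
        if not self.log_scale:
            arr = v.to_numpy(dtype=float)
            bad = np.asarray((arr <= 0) & ~np.isnan(arr)).nonzero()
            if bad[0].size:
                i, j = bad[0][0], bad[1][0]
                raise ValueError(
                    "non-positive intensity at sample "
                    f"{v.index[i]!r}, feature {v.columns[j]!r}: {arr[i, j]}"
                )

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.runday.copy(), self.fluid.copy(),
            log_scale=self.log_scale,
        )

    def select_features(self, feature_ids: Iterable[str]) -> "IntensityMatrix":
        cols = list(feature_ids)
        return IntensityMatrix(
            self.values[cols], self.runday, self.fluid.loc[cols],
            log_scale=self.log_scale,
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "IntensityMatrix":
        rows = list(sample_ids)
        return IntensityMatrix(
            self.values.loc[rows], self.runday.loc[rows], self.fluid,
            log_scale=self.log_scale,
        )


@dataclass
class AnnotationTable:
    """Per-feature pathway annotation.

    A feature is *known* iff both its sub-pathway and super-pathway are
    annotated; unknowns carry neither.  Every sub-pathway maps to exactly one
    super-pathway (within and across fluids: the mapping is by pathway name).
    """

    table: pd.DataFrame  # columns: fluid, known, sub_pathway, super_pathway

    REQUIRED = ("fluid", "sub_pathway", "super_pathway")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate feature ids in annotation table")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        sub = t["sub_pathway"]
        sup = t["super_pathway"]
        has_sub, has_sup = sub.notna(), sup.notna()
        if (has_sub != has_sup).any():
            bad = t.index[has_sub != has_sup].tolist()
            raise ValueError(
                f"features with only one of sub/super-pathway set: {bad}"
            )
        if "known" in t.columns:
            if (t["known"].astype(bool) != has_sub).any():
                bad = t.index[t["known"].astype(bool) != has_sub].tolist()
                raise ValueError(f"known flag inconsistent with pathways: {bad}")
        else:
            t = t.copy()
            t["known"] = has_sub
            self.table = t
        mapping = t.loc[has_sub, ["sub_pathway", "super_pathway"]].drop_duplicates()
        counts = mapping.groupby("sub_pathway")["super_pathway"].nunique()
        if (counts > 1).any():
            bad = counts.index[counts > 1].tolist()
            raise ValueError(
                f"sub-pathways mapped to multiple super-pathways: {bad}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def known_features(self) -> list[str]:
        return list(self.table.index[self.table["known"].astype(bool)])

    def fluid_of(self, feature_id: str) -> str:
        return str(self.table.at[feature_id, "fluid"])

    def metabolite_node(self, feature_id: str) -> str:
        return node_id(self.fluid_of(feature_id), feature_id)

    def sub_pathway_node(self, feature_id: str) -> str:
        row = self.table.loc[feature_id]
        if pd.isna(row["sub_pathway"]):
            raise ValueError(f"feature {feature_id!r} has no sub-pathway")
        return node_id(str(row["fluid"]), str(row["sub_pathway"]))

    def sub_to_super(self) -> dict[str, str]:
        """Fluid-resolved sub-pathway node -> super-pathway node mapping."""
        t = self.table[self.table["known"].astype(bool)]
        out: dict[str, str] = {}
        for _, row in t.iterrows():
            sub = node_id(str(row["fluid"]), str(row["sub_pathway"]))
            sup = node_id(str(row["fluid"]), str(row["super_pathway"]))
            out[sub] = sup
        return out

    def members_of_sub_pathways(self) -> dict[str, list[str]]:
        """Sub-pathway node -> sorted member feature ids (known only)."""
        t = self.table[self.table["known"].astype(bool)]
        groups: dict[str, list[str]] = {}
        for fid, row in t.iterrows():
            groups.setdefault(
                node_id(str(row["fluid"]), str(row["sub_pathway"])), []
            ).append(fid)
        return {k: sorted(v) for k, v in groups.items()}

    def members_of_super_pathways(self) -> dict[str, list[str]]:
        t = self.table[self.table["known"].astype(bool)]
        groups: dict[str, list[str]] = {}
        for fid, row in t.iterrows():
            groups.setdefault(
                node_id(str(row["fluid"]), str(row["super_pathway"])), []
            ).append(fid)
        return {k: sorted(v) for k, v in groups.items()}


@dataclass
class PhenotypeTable:
    """Phenotype of interest plus covariates, aligned to samples by id."""

    table: pd.DataFrame
    phenotype: str
    covariates: tuple[str, ...] = ("age", "gender", "BMI")

    def __post_init__(self) -> None:
        if self.phenotype not in self.table.columns:
            raise ValueError(f"phenotype column {self.phenotype!r} missing")
        # the phenotype never appears twice in the model (gender rule)
        self.covariates = tuple(
            c for c in self.covariates if c != self.phenotype
        )
        for c in self.covariates:
            if c not in self.table.columns:
                raise ValueError(f"covariate column {c!r} missing")
        if self.table[self.phenotype].nunique(dropna=True) < 2:
            raise ValueError("phenotype must take at least 2 distinct values")

    def aligned(self, sample_ids: Iterable[str]) -> "PhenotypeTable":
        ids = [s for s in sample_ids if s in self.table.index]
        return PhenotypeTable(self.table.loc[ids], self.phenotype, self.covariates)

    def phenotype_vector(self) -> np.ndarray:
        return self.table[self.phenotype].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((len(self.table), 0))
        return self.table[list(self.covariates)].to_numpy(dtype=float)


@dataclass(frozen=True)
class EdgeStats:
    """Correlation statistics attached to a metabolite/sub-pathway edge."""

    pearson_r: float
    partial_r: float
    pearson_p: float
    partial_p: float


@dataclass
class CorrelationNetwork:
    """Undirected network at one level of the hierarchical map.

    ``edges`` maps sorted node pairs to :class:`EdgeStats` at the metabolite
    and sub-pathway levels; collapsed super-pathway edges carry only a member
    edge count (``int``).
    """

    level: str  # metabolite | sub_pathway | super_pathway
    nodes: list[str]
    edges: dict[tuple[str, str], object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate nodes")
        self.nodes = list(self.nodes)
        node_set = set(self.nodes)
        canon: dict[tuple[str, str], object] = {}
        for (u, v), stats in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not a node: {(u, v)}")
            key = (u, v) if u < v else (v, u)
            if key in canon:
                raise ValueError(f"duplicate edge {key}")
            canon[key] = stats
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def to_networkx(self):
        """Export to a :class:`networkx.Graph` with deterministic ordering."""
        import networkx as nx

        g = nx.Graph(level=self.level)
        for n in sorted(self.nodes):
            fluid, name = split_node_id(n)
            g.add_node(n, fluid=fluid, name=name, level=self.level)
        for (u, v) in sorted(self.edges):
            stats = self.edges[(u, v)]
            if isinstance(stats, EdgeStats):
                g.add_edge(
                    u, v,
                    pearson_r=float(stats.pearson_r),
                    partial_r=float(stats.partial_r),
                    pearson_p=float(stats.pearson_p),
                    partial_p=float(stats.partial_p),
                )
            else:
                g.add_edge(u, v, member_edges=int(stats))
        return g


@dataclass
class Module:
    """A connected node set scored against a phenotype.

    ``score`` is the negative log10 p-value of the phenotype coefficient in
    the representative's regression; ``status`` distinguishes a single seed's
    greedy optimum from a consolidated maximal module.
    """

    nodes: frozenset[str]
    score: float
    p_value: float
    seeds: frozenset[str]
    status: str = "optimal"  # optimal | maximal
    member_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.seeds = frozenset(self.seeds)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)


@dataclass
class ModuleReport:
    """Result of a module identification run at one network level."""

    modules: list[Module]
    level: str
    phenotype: str
    n_nodes: int
    alpha: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        if self.n_nodes == 0:
            raise ValueError("empty network")
        return self.alpha / self.n_nodes

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "phenotype": self.phenotype,
            "n_nodes": self.n_nodes,
            "alpha": self.alpha,
            "bonferroni_threshold": self.bonferroni_threshold,
            "modules": [
                {
                    "nodes": m.sorted_nodes(),
                    "score": m.score,
                    "p_value": m.p_value,
                    "seeds": sorted(m.seeds),
                    "status": m.status,
                    "member_features": sorted(m.member_features),
                }
                for m in self.modules
            ],
        }
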