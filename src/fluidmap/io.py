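"""Readers and writers: TSV matrices and annotations, GraphML/edge-list
networks, JSON module reports.

All writers use deterministic (lexicographic) node and edge ordering so that
outputs are diffable; all readers are exact inverses of their writers.
"""

from __future__ import annotations

import json

import pandas as pd

from .datatypes import (
    AnnotationTable,
    CorrelationNetwork,
    EdgeStats,
    IntensityMatrix,
    ModuleReport,
    PhenotypeTable,
)

__all__ = [
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_annotations",
    "write_annotations",
    "read_phenotypes",
    "write_network",
    "read_network",
    "write_module_report",
]

_NA = ""  # missing values serialize as empty fields


def read_intensity_tsv(path, metadata_path, log_scale: bool = False) -> IntensityMatrix:
    """Read an intensity matrix plus its sample/feature metadata.

    ``path``: TSV, header row = feature ids, first column = sample ids,
    missing entries empty or ``NA``.  ``metadata_path``: TSV with two blocks
    of rows, ``sample<TAB>id<TAB>runday`` and ``feature<TAB>id<TAB>fluid``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    meta = pd.read_csv(
        metadata_path, sep="\t", header=None,
        names=["kind", "id", "label"], dtype=str,
    )
    runday = meta[meta["kind"] == "sample"].set_index("id")["label"]
    fluid = meta[meta["kind"] == "feature"].set_index("id")["label"]
    return IntensityMatrix(values, runday, fluid, log_scale=log_scale)


def write_intensity_tsv(x: IntensityMatrix, path, metadata_path) -> None:
    x.values.to_csv(path, sep="\t", na_rep=_NA, index_label="sample_id")
    with open(metadata_path, "w") as fh:
        for sid in x.sample_ids:
            fh.write(f"sample\t{sid}\t{x.runday.loc[sid]}\n")
        for fid in x.feature_ids:
            fh.write(f"feature\t{fid}\t{x.fluid.loc[fid]}\n")


def read_annotations(path) -> AnnotationTable:
    """Read a feature annotation TSV.

    Columns: ``feature_id, fluid, sub_pathway, super_pathway``; empty pathway
    fields mean the feature is an unknown (no structural identification).
    """
    t = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=False)
    t = t.set_index("feature_id")
    t.index.name = None
    return AnnotationTable(t)


def write_annotations(ann: AnnotationTable, path) -> None:
    cols = ["fluid", "sub_pathway", "super_pathway"]
    ann.table[cols].to_csv(path, sep="\t", na_rep=_NA, index_label="feature_id")


def read_phenotypes(path, phenotype: str, covariates=("age", "gender", "BMI")) -> PhenotypeTable:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    return PhenotypeTable(t, phenotype, tuple(covariates))


def write_network(net: CorrelationNetwork, path, format: str = "graphml") -> None:
    """Serialize a network as yEd-readable GraphML or an edge-list TSV."""
    if format == "graphml":
        import networkx as nx

        nx.write_graphml(net.to_networkx(), path)
    elif format == "tsv":
        rows = []
        for (u, v) in sorted(net.edges):
            stats = net.edges[(u, v)]
            if isinstance(stats, EdgeStats):
                rows.append(
                    {
                        "source": u, "target": v,
                        "pearson_r": stats.pearson_r,
                        "partial_r": stats.partial_r,
                        "pearson_p": stats.pearson_p,
                        "partial_p": stats.partial_p,
                    }
                )
            else:
                rows.append({"source": u, "target": v, "member_edges": stats})
        cols = (
            ["source", "target", "pearson_r", "partial_r", "pearson_p", "partial_p"]
            if net.level != "super_pathway"
            else ["source", "target", "member_edges"]
        )
        pd.DataFrame(rows, columns=cols).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
        # edge-list TSV drops isolated nodes; GraphML keeps them
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, level: str | None = None) -> CorrelationNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    import networkx as nx

    g = nx.read_graphml(path)
    lvl = level or g.graph.get("level", "metabolite")
    edges: dict[tuple[str, str], object] = {}
    for u, v, d in g.edges(data=True):
        if "member_edges" in d:
            edges[(u, v)] = int(d["member_edges"])
        else:
            edges[(u, v)] = EdgeStats(
                pearson_r=float(d["pearson_r"]),
                partial_r=float(d["partial_r"]),
                pearson_p=float(d["pearson_p"]),
                partial_p=float(d["partial_p"]),
            )
    return CorrelationNetwork(level=lvl, nodes=sorted(g.nodes), edges=edges)


def write_module_report(report: ModuleReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_module_table(report: ModuleReport, path) -> None:
    """Human-readable one-row-per-module TSV companion to the JSON report."""
    rows = [
        {
            "module": ";".join(m.sorted_nodes()),
            "n_nodes": len(m.nodes),
            "score": m.score,
            "p_value": m.p_value,
            "threshold": report.bonferroni_threshold,
        }
        for m in report.modules
    ]
    pd.DataFrame(
        rows, columns=["module", "n_nodes", "score", "p_value", "threshold"]
    ).to_csv(path, sep="\t", index=False)
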