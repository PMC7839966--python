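"""Flatten competing triplets into node/edge tables for network tools.

Each triplet contributes three undirected edges (miRNA-lncRNA, miRNA-mRNA,
lncRNA-mRNA); node and edge weights count the triplets containing them, the
convention used to size nodes and lines in network viewers.  Output is two
TSV attribute tables plus a SIF file importable by Cytoscape-like tools.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pairs import LNCRNA_MRNA, MIRNA_LNCRNA, MIRNA_MRNA


def export_network(triplets: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the competing-triplet network.

    Parameters
    ----------
    triplets : pandas.DataFrame
        Deduplicated triplets with columns ``lncrna, mirna, mrna`` (one row
        per triplet).

    Returns
    -------
    (nodes, edges)
        ``nodes``: columns ``id, rna_class, triplet_count``;
        ``edges``: columns ``source, target, edge_type, triplet_count``.
        Both sorted by count descending, then id — so the heaviest hubs
        come first.
    """
    nodes_cols = ["id", "rna_class", "triplet_count"]
    edges_cols = ["source", "target", "edge_type", "triplet_count"]
    if triplets.empty:
        return pd.DataFrame(columns=nodes_cols), pd.DataFrame(columns=edges_cols)

    node_rows = []
    edge_rows = []
    for _, t in triplets.iterrows():
        l, m, g = t["lncrna"], t["mirna"], t["mrna"]
        node_rows += [(l, "lncRNA"), (m, "miRNA"), (g, "mRNA")]
        edge_rows += [
            (m, l, MIRNA_LNCRNA),
            (m, g, MIRNA_MRNA),
            (l, g, LNCRNA_MRNA),
        ]
    nodes = (
        pd.DataFrame(node_rows, columns=["id", "rna_class"])
        .groupby(["id", "rna_class"], sort=True)
        .size()
        .reset_index(name="triplet_count")
        .sort_values(["triplet_count", "id"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    edges = (
        pd.DataFrame(edge_rows, columns=["source", "target", "edge_type"])
        .groupby(["source", "target", "edge_type"], sort=True)
        .size()
        .reset_index(name="triplet_count")
        .sort_values(["triplet_count", "source", "target"],
                     ascending=[False, True, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return nodes[nodes_cols], edges[edges_cols]


def write_network(
    nodes: pd.DataFrame, edges: pd.DataFrame, outdir: str | Path,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write nodes/edges TSVs and a SIF file; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": outdir / f"{prefix}_nodes.tsv",
        "edges": outdir / f"{prefix}_edges.tsv",
        "sif": outdir / f"{prefix}.sif",
    }
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep="\t", index=False)
    with open(paths["sif"], "w") as fh:
        for _, e in edges.iterrows():
            fh.write(f"{e['source']}\t{e['edge_type']}\t{e['target']}\n")
    return paths
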