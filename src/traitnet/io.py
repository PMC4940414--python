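"""Plain-text readers and writers for every pipeline artifact.

Long-format tables, matrices and statistics travel as TSV at full double
precision; planted truth and reports as JSON; networks as GraphML plus a
Cytoscape-compatible edge table.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import BlupMatrix, NormalizedMatrix, ReplicateProfileTable

SUPPORTED_NETWORK_FORMATS = ("graphml", "edge_table")


def write_table(table: ReplicateProfileTable, data_path, annotation_path) -> None:
    table.data.to_csv(data_path, sep="\t", index=False, float_format="%.17g")
    table.annotations.to_csv(annotation_path, sep="\t")


def read_table(data_path, annotation_path) -> ReplicateProfileTable:
    data = pd.read_csv(
        data_path, sep="\t", float_precision="round_trip",
        dtype={"line_id": str, "replicate_id": str, "feature_id": str},
    )
    if "plate_id" in data.columns:
        data["plate_id"] = data["plate_id"].astype("string")
    annotations = pd.read_csv(annotation_path, sep="\t", index_col="feature_id")
    return ReplicateProfileTable(data, annotations)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def write_normalized(matrix: NormalizedMatrix, values_path, provenance_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", float_format="%.17g")
    matrix.provenance.to_csv(provenance_path, sep="\t")


def read_normalized(values_path, provenance_path=None,
                    annotations: pd.DataFrame | None = None) -> NormalizedMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=[0, 1],
                         float_precision="round_trip")
    prov = None
    if provenance_path and Path(provenance_path).exists():
        prov = pd.read_csv(provenance_path, sep="\t", index_col=[0, 1])
    return NormalizedMatrix(values, prov, annotations)


def write_blups(blups: BlupMatrix, values_path, means_path) -> None:
    blups.values.to_csv(values_path, sep="\t", float_format="%.17g")
    blups.grand_means.rename("grand_mean").to_csv(means_path, sep="\t", float_format="%.17g")


def read_blups(values_path, means_path=None,
               annotations: pd.DataFrame | None = None) -> BlupMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    if means_path and Path(means_path).exists():
        means = pd.read_csv(means_path, sep="\t", index_col=0,
                            float_precision="round_trip")["grand_mean"]
    else:
        means = values.mean(axis=0) * 0.0
    return BlupMatrix(values, means, annotations)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def export_network(G: nx.Graph, outdir, stem: str = "network",
                   formats=SUPPORTED_NETWORK_FORMATS) -> list[Path]:
    """Write the network as GraphML and/or a Cytoscape edge table.

    Unknown format names raise ValueError listing the supported ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt not in SUPPORTED_NETWORK_FORMATS:
            raise ValueError(
                f"unsupported network format {fmt!r}; supported: "
                f"{SUPPORTED_NETWORK_FORMATS}"
            )
        if fmt == "graphml":
            path = outdir / f"{stem}.graphml"
            nx.write_graphml(G, path)
        else:
            path = outdir / f"{stem}_edges.tsv"
            rows = [
                {
                    "source": a,
                    "interaction": d.get("sign", "+"),
                    "target": b,
                    "rho": d.get("rho"),
                    "p": d.get("p"),
                    "q": d.get("q"),
                }
                for a, b, d in G.edges(data=True)
            ]
            pd.DataFrame(
                rows, columns=["source", "interaction", "target", "rho", "p", "q"]
            ).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
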