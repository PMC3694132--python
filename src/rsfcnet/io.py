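"""Plain-text readers/writers for the pipeline's artifacts.

Time series and matrices travel as TSV (node labels in the first column /
header), partitions as two-column TSV, thresholded graphs additionally as
GraphML, cohort manifests as YAML.  Writers accept a ``config_hash`` that is
embedded as a leading ``#``-comment (or a graph attribute for GraphML) so any
output can be traced to the configuration that produced it.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .connectivity import ThresholdedGraph, WeightMatrix
from .modules import Partition
from .synthetic import TimeSeriesMatrix


def _write_tsv(path: Path, frame: pd.DataFrame, config_hash: str | None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_timeseries_tsv(
    path: str | Path, ts: TimeSeriesMatrix, config_hash: str | None = None
) -> None:
    frame = pd.DataFrame(ts.values, columns=[f"v{i}" for i in range(ts.n_volumes)])
    frame.insert(0, "node", ts.node_ids)
    _write_tsv(Path(path), frame, config_hash)


def read_timeseries_tsv(path: str | Path, tr_seconds: float = 2.5) -> TimeSeriesMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#")
    node_ids = frame.iloc[:, 0].astype(str).tolist()
    values = frame.iloc[:, 1:].to_numpy(dtype=float)
    return TimeSeriesMatrix(values, tr_seconds=tr_seconds, node_ids=node_ids)


def write_matrix_tsv(
    path: str | Path,
    values: np.ndarray,
    node_ids: list[str],
    config_hash: str | None = None,
) -> None:
    frame = pd.DataFrame(values, index=node_ids, columns=node_ids)
    frame.index.name = "node"
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, sep="\t")


def read_weight_matrix_tsv(path: str | Path) -> WeightMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return WeightMatrix(frame.to_numpy(dtype=float), node_ids=[str(c) for c in frame.columns])


def write_partition_tsv(
    path: str | Path, p: Partition, config_hash: str | None = None
) -> None:
    node_ids = p.node_ids or [f"node{i}" for i in range(p.n_nodes)]
    frame = pd.DataFrame({"node": node_ids, "module": p.labels})
    _write_tsv(Path(path), frame, config_hash)


def read_partition_tsv(path: str | Path) -> Partition:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return Partition(
        labels=frame["module"].to_numpy(dtype=int),
        node_ids=frame["node"].astype(str).tolist(),
    )


def write_graphml(
    path: str | Path, g: ThresholdedGraph, config_hash: str | None = None
) -> None:
    graph = g.to_networkx()
    graph.graph["cost"] = g.cost
    graph.graph["mode"] = g.mode
    if config_hash:
        graph.graph["config_hash"] = config_hash
    nx.relabel_nodes(graph, dict(enumerate(g.node_ids)), copy=False)
    nx.write_graphml(graph, str(path))


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
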