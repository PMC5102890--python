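"""Plain-text persistence: dense CSV matrices, GraphML graphs, TSV partitions,
JSON instance metadata.

An instance directory contains::

    matrix.csv      dense matrix, header row of node ids n0..n{N-1}
    graph.graphml   weighted undirected graph (zero entries omitted)
    partition.tsv   two columns: node_id, community
    meta.json       condition id, replicate, seed, matrix type
"""

from __future__ import annotations

import json
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd

from .types import BenchmarkInstance, MatrixType, Partition, SimilarityMatrix

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_graphml",
    "write_partition_tsv",
    "read_partition_tsv",
    "write_instance",
    "read_instance",
]


def _node_ids(n: int) -> list[str]:
    return [f"n{i}" for i in range(n)]


def write_matrix_csv(matrix: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=_node_ids(matrix.n_nodes))
    df.to_csv(path, index=False, float_format="%.10g")


def read_matrix_csv(path, matrix_type: MatrixType | str) -> SimilarityMatrix:
    values = pd.read_csv(path).to_numpy(float)
    return SimilarityMatrix(values, MatrixType(matrix_type), diagonal_zeroed=True)


def write_graphml(matrix: SimilarityMatrix, path) -> None:
    w = matrix.values
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    vals = w[iu]
    mask = vals != 0.0
    g = ig.Graph(n, np.column_stack((iu[0][mask], iu[1][mask])).tolist())
    g.vs["id"] = _node_ids(n)
    g.es["weight"] = vals[mask]
    g.write_graphml(str(path))


def write_partition_tsv(partition: Partition, path) -> None:
    pd.DataFrame(
        {"node_id": _node_ids(partition.n_nodes), "community": partition.labels}
    ).to_csv(path, sep="\t", index=False)


def read_partition_tsv(path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    return Partition(df["community"].to_numpy())


def write_instance(instance: BenchmarkInstance, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(instance.matrix, out / "matrix.csv")
    write_graphml(instance.matrix, out / "graph.graphml")
    write_partition_tsv(instance.truth, out / "partition.tsv")
    meta = {
        "condition_id": instance.condition_id,
        "matrix_type": instance.matrix_type.value,
        "replicate": instance.replicate,
        "seed": instance.seed,
        "n_nodes": instance.matrix.n_nodes,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out


def read_instance(in_dir) -> BenchmarkInstance:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    matrix = read_matrix_csv(src / "matrix.csv", meta["matrix_type"])
    truth = read_partition_tsv(src / "partition.tsv")
    return BenchmarkInstance(
        matrix=matrix,
        truth=truth,
        condition_id=meta["condition_id"],
        matrix_type=MatrixType(meta["matrix_type"]),
        replicate=meta["replicate"],
        seed=meta["seed"],
    )
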