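"""File formats: edge lists, GraphML, interaction tables, prediction tables.

All tabular formats are TSV with a single header row; lines starting with
``#`` are comments and carry provenance (tool version, seed, config hash).
Gene and drug identifiers are opaque strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from drugnet import __version__ as _VERSION

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ["drug_id", "gene_id", "label"]
PREDICTION_COLUMNS = [
    "drug_id",
    "gene_id",
    "mean_score",
    "mc_variance",
    "aleatoric",
    "raw_score",
    "z",
    "percentile",
    "probability_pct",
]


def provenance_header(seed=None, config=None) -> str:
    """One-line ``#`` comment recording version, seed and a config digest."""
    blob = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"# drugnet {_VERSION} seed={seed} config_sha={digest}"


def read_network(path) -> nx.Graph:
    """Read an undirected simple graph from an edge list or GraphML file.

    Edge lists are whitespace/TAB separated, two node identifiers per line,
    ``#`` comments allowed. Self-loops are dropped (logged) and duplicate
    edges collapse silently into one.
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in raw.nodes())
        g.add_edges_from((str(u), str(v)) for u, v in raw.edges())
    else:
        g = nx.Graph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two node identifiers, got {line!r}"
                    )
                g.add_edge(parts[0], parts[1])
    n_loops = nx.number_of_selfloops(g)
    if n_loops:
        g.remove_edges_from(nx.selfloop_edges(g))
        logger.warning("dropped %d self-loop(s) from %s", n_loops, path)
    return g


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# drugnet edge list\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def read_interactions(path) -> pd.DataFrame:
    """Read labeled (drug_id, gene_id, label) triples; labels must be 0/1."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"drug_id": str, "gene_id": str})
    for col in INTERACTION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(df) and not df["label"].isin([0, 1]).all():
        bad = df.loc[~df["label"].isin([0, 1]), "label"].iloc[0]
        raise ValueError(f"{path}: label outside {{0,1}}: {bad!r}")
    df["label"] = df["label"].astype(int)
    return df[INTERACTION_COLUMNS + [c for c in df.columns if c not in INTERACTION_COLUMNS]]


def write_interactions(df: pd.DataFrame, path, seed=None, config=None) -> None:
    _write_tsv(df[INTERACTION_COLUMNS], path, seed=seed, config=config)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"drug_id": str, "gene_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_predictions(df: pd.DataFrame, path, seed=None, config=None) -> None:
    extra = [c for c in df.columns if c not in PREDICTION_COLUMNS]
    _write_tsv(df[PREDICTION_COLUMNS + extra], path, seed=seed, config=config)


def _write_tsv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_clusters(path) -> dict:
    """Read a (gene, cluster) TSV into a node -> int label mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    gene_col, cluster_col = df.columns[:2]
    return {str(g): int(c) for g, c in zip(df[gene_col], df[cluster_col])}

def write_clusters(labels: dict, path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {"gene": list(labels.keys()), "cluster": [int(v) for v in labels.values()]}
    ).sort_values(["cluster", "gene"], kind="stable")
    _write_tsv(df, path, seed=seed, config=config)


def read_drug_library(path) -> pd.DataFrame:
    """Read a drug library TSV with columns drug_id and smiles."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_gene_labels(path) -> dict:
    """Read a (gene_id, label) TSV of disease-gene indicators."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    gene_col, label_col = df.columns[:2]
    labels = {str(g): int(y) for g, y in zip(df[gene_col], df[label_col])}
    if any(v not in (0, 1) for v in labels.values()):
        raise ValueError(f"{path}: gene labels must be 0/1")
    return labels


def load_yaml_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return cfg
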