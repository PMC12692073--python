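"""Pearson correlation matrices, top cross-block pairs and thresholded
correlation networks.

Two correlation modes are exposed and labeled explicitly: ``replicate``
correlates features over all samples; ``class_mean`` first averages the
replicates within each class and correlates over the class means — the
mode that reproduces printed assay correlation tables computed from class
summary statistics.

The network connects features whose absolute replicate correlation meets
an edge threshold (default |r| >= 0.60), flags the strongest edges as bold
(default |r| >= 0.80), keeps isolated nodes, and is laid out with the
Fruchterman-Reingold spring algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .blocks import FeatureBlock, MultiBlock, concatenate_blocks


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    mode: str  # "replicate" | "class_mean"
    blocks: dict[str, str] | None = None  # feature -> block tag


def _frame_and_labels(X) -> tuple[pd.DataFrame, pd.Series | None, dict | None]:
    if isinstance(X, MultiBlock):
        fused = concatenate_blocks(X)
        tags = {c: c.split("::", 1)[0] for c in fused.data.columns}
        return fused.data, fused.labels, tags
    if isinstance(X, FeatureBlock):
        tags = {c: X.block_id for c in X.data.columns}
        return X.data, X.labels, tags
    return pd.DataFrame(X), None, None


def pearson_matrix(X, mode: str = "replicate", labels=None) -> CorrelationMatrix:
    """Pairwise Pearson correlations among all features of ``X``.

    ``mode="class_mean"`` averages within class first (labels taken from
    the block, or passed explicitly for a bare DataFrame).  Zero-variance
    columns are rejected by name.
    """
    data, blk_labels, tags = _frame_and_labels(X)
    if labels is None:
        labels = blk_labels
    if mode == "class_mean":
        if labels is None:
            raise ValueError("class_mean mode needs class labels")
        data = data.groupby(pd.Series(labels, index=data.index), observed=True).mean()
    elif mode != "replicate":
        raise ValueError(f"unknown mode {mode!r}")
    if len(data) < 3:
        raise ValueError(f"need >= 3 effective rows, have {len(data)}")
    sd = data.to_numpy(dtype=float).std(axis=0)
    zero = [c for c, s in zip(data.columns, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    r = pd.DataFrame(np.corrcoef(data.to_numpy(dtype=float), rowvar=False),
                     index=data.columns, columns=data.columns)
    return CorrelationMatrix(r=r, mode=mode, blocks=tags)


def cross_block_pearson(A: FeatureBlock, B: FeatureBlock,
                        mode: str = "replicate") -> pd.DataFrame:
    """Rectangular Pearson matrix between the features of two aligned
    blocks (rows = features of A, columns = features of B)."""
    if not A.sample_ids.equals(B.sample_ids):
        raise ValueError("blocks are not aligned on sample ids")
    joint = MultiBlock([A, B])
    full = pearson_matrix(joint, mode=mode).r
    rows = [f"{A.block_id}::{c}" for c in A.data.columns]
    cols = [f"{B.block_id}::{c}" for c in B.data.columns]
    sub = full.loc[rows, cols]
    sub.index = list(A.data.columns)
    sub.columns = list(B.data.columns)
    return sub


def cross_block_top_pairs(A: FeatureBlock, B: FeatureBlock, k: int = 5,
                          mode: str = "replicate") -> pd.DataFrame:
    """The k cross-block feature pairs with the largest |r|, signed r kept.

    Ties in |r| break lexicographically by (feature_a, feature_b) for
    deterministic output.
    """
    r = cross_block_pearson(A, B, mode=mode)
    long = r.stack()
    long.index.names = ["feature_a", "feature_b"]
    df = long.rename("r").reset_index()
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(["abs_r", "feature_a", "feature_b"],
                        ascending=[False, True, True], kind="stable")
    out = df.head(k).drop(columns="abs_r").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def build_network(C: CorrelationMatrix, edge_threshold: float = 0.60,
                  bold_threshold: float = 0.80) -> nx.Graph:
    """Correlation network over a square correlation matrix.

    Nodes carry a ``block`` attribute (analytical origin); edges carry the
    signed ``r`` and a ``bold`` flag at the higher threshold.  Isolated
    nodes are retained.
    """
    if not (0 < edge_threshold <= 1) or not (0 < bold_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if bold_threshold < edge_threshold:
        raise ValueError("bold_threshold must be >= edge_threshold")
    r = C.r
    if r.shape[0] != r.shape[1] or not r.index.equals(r.columns):
        raise ValueError("build_network needs a square correlation matrix")
    G = nx.Graph()
    tags = C.blocks or {}
    for feat in r.index:
        G.add_node(feat, block=tags.get(feat, "unknown"),
                   label=feat.split("::", 1)[-1])
    feats = list(r.index)
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            val = float(r.loc[a, b])
            if abs(val) >= edge_threshold:
                G.add_edge(a, b, r=val, bold=bool(abs(val) >= bold_threshold))
    return G


def spring_layout(G: nx.Graph, seed: int = 0, iterations: int = 50) -> dict:
    """Deterministic Fruchterman-Reingold layout; a single node sits at the
    origin."""
    if G.number_of_nodes() == 0:
        raise ValueError("layout needs at least one node")
    if G.number_of_nodes() == 1:
        return {next(iter(G.nodes)): np.zeros(2)}
    return nx.spring_layout(G, seed=seed, iterations=iterations)


def write_network(G: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    """GraphML and/or edge-list CSV export (source, target, r, bold)."""
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    if edgelist_path is not None:
        rows = [
            {"source": a, "target": b, "r": d["r"], "bold": d["bold"]}
            for a, b, d in G.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "bold"]).to_csv(
            edgelist_path, index=False
        )
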