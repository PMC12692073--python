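"""End-to-end orchestration: one call simulates the study design and runs
every stage — texture profiling, band tables, univariate statistics,
single-/cross-/multi-block discriminant models and the correlation network
— writing CSV/JSON/GraphML outputs plus a deterministic summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import _tables, datagen
from .blocks import FeatureBlock, MultiBlock, autoscale, concatenate_blocks
from .fusion import CVResult, cv_accuracy, lda_fit
from .imgtex import texture_profile
from .network import (
    CorrelationMatrix,
    build_network,
    cross_block_top_pairs,
    pearson_matrix,
    spring_layout,
    write_network,
)
from .stats import compare_classes

log = logging.getLogger("peelfusion")

FUSION_BLOCKS = ("ftir", "spectro", "physico")


@dataclass
class PipelineConfig:
    seed: int = 42
    n_per_class: int = 10
    blocks: tuple = FUSION_BLOCKS
    edge_threshold: float = 0.60
    bold_threshold: float = 0.80
    alpha: float = 0.05
    folds: int = 5
    scale_mode: str = "global"
    out_dir: str | None = None
    with_texture: bool = True

    def __post_init__(self):
        unknown = [b for b in self.blocks if b not in FUSION_BLOCKS]
        if unknown:
            raise ValueError(f"unknown fusion block(s) {unknown}")
        if not (0 < self.edge_threshold <= self.bold_threshold <= 1):
            raise ValueError("need 0 < edge_threshold <= bold_threshold <= 1")


def reproduce_table3() -> CorrelationMatrix:
    """Class-mean Pearson matrix over the four spectrophotometric assays
    (TPC, TFC, FRAP, ABTS), computed from the built-in class means."""
    rows = {
        label: {f: _tables.SPECTRO[label][f][0] for f in _tables.SPECTRO_FEATURES}
        for label in _tables.CLASS_LABELS
    }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "sample_id"
    labels = pd.Series(data.index, index=data.index, name="class")
    block = FeatureBlock("spectro", data, labels)
    return pearson_matrix(block, mode="class_mean")


def class_mean_assay_correlations() -> pd.Series:
    """The six off-diagonal class-mean assay correlations, keyed
    ``"tpc~tfc"`` etc., in canonical assay order."""
    r = reproduce_table3().r
    out = {}
    feats = list(r.index)
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            out[f"{a}~{b}"] = float(r.loc[a, b])
    return pd.Series(out)


def texture_block(cfg: PipelineConfig) -> FeatureBlock:
    """Simulate one peel image per replicate and profile it into the
    ``texture`` feature block (15 features, ROI-averaged)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(7,)))
    rows, ids, labels = [], [], []
    for label in _tables.CLASS_LABELS:
        spec = datagen.BUILTIN_IMAGE_SPECS[label]
        for i in range(cfg.n_per_class):
            img = datagen.generate_texture_image(spec, seed=int(rng.integers(0, 2**31 - 1)))
            rows.append(texture_profile(img).mean.as_series())
            ids.append(f"{label}_{i+1:02d}")
            labels.append(label)
    index = pd.Index(ids, name="sample_id")
    return FeatureBlock("texture", pd.DataFrame(rows, index=index),
                        pd.Series(labels, index=index, name="class"))


def fusion_combinations(block_ids=FUSION_BLOCKS) -> list[tuple[str, ...]]:
    """The 3 single, 3 cross and 1 multi-block combinations."""
    combos = [(b,) for b in block_ids]
    combos += list(combinations(block_ids, 2))
    combos += [tuple(block_ids)]
    return combos


def fused_cv_accuracies(mb: MultiBlock, cfg: PipelineConfig) -> dict[str, CVResult]:
    """Auto-scale each block once, then stratified CV accuracy for every
    block combination."""
    scaled = MultiBlock([autoscale(mb[bid]).block for bid in cfg.blocks])
    out = {}
    for combo in fusion_combinations(cfg.blocks):
        fused = concatenate_blocks(scaled, list(combo))
        out["+".join(combo)] = cv_accuracy(
            fused.data, fused.labels, folds=cfg.folds, seed=cfg.seed,
            scale_mode=cfg.scale_mode,
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate the study and run every stage; returns the summary dict
    (also written as ``summary.json`` when ``cfg.out_dir`` is set)."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage=simulate seed=%d n_per_class=%d", cfg.seed, cfg.n_per_class)
    gen_cfg = datagen.GeneratorConfig(n_per_class=cfg.n_per_class, seed=cfg.seed)
    mb = datagen.generate_replicate_blocks(cfg=gen_cfg)
    if out:
        datagen.write_blocks(mb, out / "blocks")

    blocks = list(mb)
    if cfg.with_texture:
        log.info("stage=texture")
        tex = texture_block(cfg)
        blocks.append(tex)
        if out:
            tex.data.to_csv(out / "texture_features.csv")

    log.info("stage=stats alpha=%.3f", cfg.alpha)
    stats_tables = {b.block_id: compare_classes(b, alpha=cfg.alpha) for b in blocks}
    if out:
        for bid, table in stats_tables.items():
            table.to_csv(out / f"stats_{bid}.csv")

    log.info("stage=fusion folds=%d scale_mode=%s", cfg.folds, cfg.scale_mode)
    cv = fused_cv_accuracies(mb, cfg)
    scaled = MultiBlock([autoscale(mb[bid]).block for bid in cfg.blocks])
    fused_all = concatenate_blocks(scaled, list(cfg.blocks))
    lda = lda_fit(fused_all.data, fused_all.labels)
    if out:
        lda.scores.to_csv(out / "lda_scores_multiblock.csv")

    log.info("stage=network edge=%.2f bold=%.2f", cfg.edge_threshold, cfg.bold_threshold)
    corr = pearson_matrix(scaled, mode="replicate")
    net = build_network(corr, cfg.edge_threshold, cfg.bold_threshold)
    layout = spring_layout(net, seed=cfg.seed)
    top_pairs = {
        f"{a}+{b}": cross_block_top_pairs(mb[a], mb[b], k=5)
        for a, b in combinations(cfg.blocks, 2)
    }
    if out:
        corr.r.to_csv(out / "correlation_replicate.csv")
        write_network(net, out / "network.graphml", out / "network_edges.csv")
        pd.DataFrame(
            [(n, float(x), float(y)) for n, (x, y) in sorted(layout.items())],
            columns=["node", "x", "y"],
        ).to_csv(out / "network_layout.csv", index=False)
        for name, table in top_pairs.items():
            table.to_csv(out / f"top_pairs_{name.replace('+', '_')}.csv", index=False)

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items() if k != "out_dir"},
        "n_samples": int(mb.labels.size),
        "class_counts": mb.labels.value_counts().sort_index().to_dict(),
        "cv_accuracy": {
            name: {"mean": res.mean, "sd": res.sd,
                   "folds": [float(a) for a in res.fold_accuracies]}
            for name, res in cv.items()
        },
        "multiblock_explained_variance": [float(v) for v in lda.explained_variance],
        "network": {
            "nodes": int(net.number_of_nodes()),
            "edges": int(net.number_of_edges()),
            "bold_edges": int(sum(1 for *_, d in net.edges(data=True) if d["bold"])),
        },
        "class_mean_assay_correlations": class_mean_assay_correlations().round(6).to_dict(),
    }
    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
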