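"""Block data model and preprocessing shared by all pipeline stages.

An analytical *block* is a samples x features matrix from one instrument
family (FTIR band intensities, spectrophotometric assays, physicochemical
parameters, or image texture features).  Blocks that share sample indexing
can be auto-scaled and horizontally concatenated into a fused matrix for
multi-block modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

VALID_BLOCK_IDS = ("ftir", "spectro", "physico", "texture")


@dataclass
class FeatureBlock:
    """One analytical matrix with aligned class labels.

    Parameters
    ----------
    block_id : str
        One of ``ftir``, ``spectro``, ``physico``, ``texture``.
    data : pandas.DataFrame
        Samples x features, indexed by sample id, no missing cells.
    labels : pandas.Series
        Class label per sample, same index as ``data``.
    units : dict, optional
        Feature name -> unit string.
    """

    block_id: str
    data: pd.DataFrame
    labels: pd.Series
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.block_id not in VALID_BLOCK_IDS:
            raise ValueError(f"unknown block_id {self.block_id!r}; expected one of {VALID_BLOCK_IDS}")
        if self.data.isna().any().any():
            raise ValueError(f"block {self.block_id!r} contains missing cells")
        if not self.data.index.equals(self.labels.index):
            raise ValueError(f"block {self.block_id!r}: sample index and labels misaligned")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"block {self.block_id!r}: duplicate feature names {dupes}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


class MultiBlock:
    """Ordered collection of :class:`FeatureBlock` with identical sample
    indexing; the unit of data fusion."""

    def __init__(self, blocks: list[FeatureBlock]):
        if not blocks:
            raise ValueError("MultiBlock requires at least one block")
        self.blocks = {b.block_id: b for b in blocks}
        if len(self.blocks) != len(blocks):
            raise ValueError("duplicate block_id in MultiBlock")
        report = validate_alignment(self)
        if not report.ok:
            raise ValueError("misaligned blocks: " + "; ".join(report.problems))

    def __getitem__(self, block_id: str) -> FeatureBlock:
        return self.blocks[block_id]

    def __contains__(self, block_id: str) -> bool:
        return block_id in self.blocks

    def __iter__(self):
        return iter(self.blocks.values())

    @property
    def block_ids(self) -> list[str]:
        return list(self.blocks)

    @property
    def labels(self) -> pd.Series:
        return next(iter(self.blocks.values())).labels


@dataclass
class AlignmentReport:
    ok: bool
    problems: list[str]


def validate_alignment(mb: MultiBlock | list[FeatureBlock]) -> AlignmentReport:
    """Check that all blocks share sample ids and class labels *in order*."""
    blocks = list(mb) if not isinstance(mb, list) else mb
    problems: list[str] = []
    ref = blocks[0]
    for b in blocks[1:]:
        if not b.sample_ids.equals(ref.sample_ids):
            problems.append(
                f"block {b.block_id!r} sample ids differ from block {ref.block_id!r}"
            )
        elif not b.labels.equals(ref.labels):
            problems.append(
                f"block {b.block_id!r} class labels differ from block {ref.block_id!r}"
            )
    return AlignmentReport(ok=not problems, problems=problems)


def dw_convert(value, residual_moisture: float):
    """Convert an amount per g of freeze-dried sample to a dry-weight basis.

    ``value / (1 - residual_moisture)``, where ``residual_moisture`` is the
    moisture fraction remaining in the freeze-dried material (not the fresh
    peel moisture, which is a measured variable in its own right).
    """
    if not 0 <= residual_moisture < 1:
        raise ValueError(f"residual_moisture must be in [0, 1), got {residual_moisture}")
    return np.asarray(value, dtype=float) / (1.0 - residual_moisture) if np.ndim(value) else value / (1.0 - residual_moisture)


class BlockScaler(BaseEstimator, TransformerMixin):
    """Auto-scaler: per-feature mean centering and division by the population
    standard deviation (ddof 0), the convention of the standard chemometric
    auto-scaling step.

    Fitted attributes
    -----------------
    mean_ : ndarray of shape (n_features,)
    scale_ : ndarray of shape (n_features,)
    feature_names_in_ : list of str (when fit on a DataFrame)
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        self.feature_names_in_ = list(X.columns)
        values = X.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0)
        self.scale_ = values.std(axis=0, ddof=0)
        zero = np.flatnonzero(self.scale_ == 0)
        if zero.size:
            names = [self.feature_names_in_[i] for i in zero]
            raise ValueError(f"zero-variance feature(s) cannot be auto-scaled: {names}")
        return self

    def transform(self, X):
        X = self._as_frame(X, like_fit=True)
        out = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_in_)

    def inverse_transform(self, X):
        X = self._as_frame(X, like_fit=True)
        out = X.to_numpy(dtype=float) * self.scale_ + self.mean_
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_in_)

    def _as_frame(self, X, like_fit=False):
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        cols = self.feature_names_in_ if like_fit else [f"x{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=cols)


@dataclass
class ScaledBlock:
    """A :class:`FeatureBlock` after auto-scaling, keeping the fitted scaler
    so new data can be transformed with the training parameters."""

    block: FeatureBlock
    scaler: BlockScaler

    @property
    def data(self) -> pd.DataFrame:
        return self.block.data

    @property
    def block_id(self) -> str:
        return self.block.block_id

    @property
    def labels(self) -> pd.Series:
        return self.block.labels


def autoscale(block: FeatureBlock) -> ScaledBlock:
    """Auto-scale a block (mean 0, population SD 1 per feature)."""
    scaler = BlockScaler().fit(block.data)
    scaled = scaler.transform(block.data)
    out = FeatureBlock(block.block_id, scaled, block.labels, dict(block.units))
    return ScaledBlock(block=out, scaler=scaler)


def concatenate_blocks(mb: MultiBlock, which: list[str] | None = None) -> FeatureBlock:
    """Horizontally concatenate (auto-scaled) blocks into one fused matrix.

    Feature names are namespaced ``"<block_id>::<feature>"`` to prevent
    collisions across blocks.  Row order is preserved.  Returns a
    :class:`FeatureBlock`; its ``block_id`` is that of the first constituent
    (the fused identity lives in the namespaced columns).
    """
    which = list(which) if which is not None else mb.block_ids
    unknown = [w for w in which if w not in mb]
    if unknown:
        raise KeyError(f"unknown block_id(s) {unknown}; available: {mb.block_ids}")
    parts = []
    for bid in which:
        b = mb[bid]
        part = b.data.copy()
        part.columns = [f"{bid}::{c}" for c in part.columns]
        parts.append(part)
    fused = pd.concat(parts, axis=1)
    first = mb[which[0]]
    return FeatureBlock(first.block_id, fused, first.labels)


def block_to_tidy(block: FeatureBlock) -> pd.DataFrame:
    """Long-format view: columns sample_id, class, block, feature, value."""
    long = block.data.stack().rename("value").reset_index()
    long.columns = ["sample_id", "feature", "value"]
    long.insert(1, "class", block.labels.loc[long["sample_id"]].to_numpy())
    long.insert(2, "block", block.block_id)
    return long
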