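"""Synthetic replicate tables, FTIR spectra and peel-texture images.

The study design this emulates: six citrus peel classes (yellow grapefruit,
red grapefruit, lemon, orange, clementine, kumquat) with ten replicates per
class, measured on three analytical blocks — 3 physicochemical parameters,
4 spectrophotometric assays and 37 ATR-FTIR band intensities.  Only class
means and standard deviations are published, so replicates are drawn as
independent Gaussians per feature at those printed statistics, clipped at
zero (all quantities are non-negative); a band absent in a class contributes
zero absorbance.  Peel appearance is emulated as a noisy gray field with
dark elliptical blotches; uniform classes get few blotches and little noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _tables
from .blocks import FeatureBlock, MultiBlock

CLASS_LABELS = _tables.CLASS_LABELS


@dataclass(frozen=True)
class FeatureSpec:
    """Per-feature generative parameters within one class."""

    name: str
    block: str
    mean: float
    sd: float
    present: bool = True

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if self.mean < 0:
            raise ValueError(f"{self.name}: mean must be >= 0")
        if not self.present and (self.mean != 0 or self.sd != 0):
            raise ValueError(f"{self.name}: absent feature must have mean = sd = 0")


@dataclass(frozen=True)
class ClassSpec:
    """Generative description of one citrus peel class."""

    class_label: str
    features: tuple[FeatureSpec, ...]

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")

    def block_features(self, block_id: str) -> tuple[FeatureSpec, ...]:
        return tuple(f for f in self.features if f.block == block_id)


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_class: int = 10
    seed: int = 0
    clip_at_zero: bool = True

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")


@dataclass(frozen=True)
class ImageClassSpec:
    """Parameters of the synthetic peel-appearance model.

    ``blotch_density`` is expressed as blotches per 10^4 pixels;
    ``blotch_scale`` is the typical blotch semi-axis in pixels.
    """

    base_intensity: float = 148.0
    noise_sd: float = 4.0
    blotch_density: float = 5.0
    blotch_scale: float = 4.0
    size: tuple[int, int] = (192, 192)

    def __post_init__(self):
        if not 0 <= self.base_intensity <= 255:
            raise ValueError("base_intensity must be within [0, 255]")
        if self.noise_sd < 0 or self.blotch_density < 0:
            raise ValueError("noise_sd and blotch_density must be >= 0")


def builtin_citrus_specs() -> tuple[ClassSpec, ...]:
    """The six built-in class specs: 3 physicochemical + 4 spectrophotometric
    + 37 FTIR band features per class, parameterized from the printed class
    means and SDs.  Bands not detected in a class are encoded absent
    (mean = sd = 0, ``present=False``)."""
    specs = []
    for label in CLASS_LABELS:
        feats: list[FeatureSpec] = []
        for name in _tables.PHYSICO_FEATURES:
            mean, sd = _tables.PHYSICO[label][name]
            feats.append(FeatureSpec(name, "physico", mean, sd))
        for name in _tables.SPECTRO_FEATURES:
            mean, sd = _tables.SPECTRO[label][name]
            feats.append(FeatureSpec(name, "spectro", mean, sd))
        col = _tables.FTIR_CLASS_ORDER.index(label)
        for band, cells in _tables.FTIR_BANDS.items():
            cell = cells[col]
            if cell is None:
                feats.append(FeatureSpec(band, "ftir", 0.0, 0.0, present=False))
            else:
                feats.append(FeatureSpec(band, "ftir", cell[0], cell[1]))
        specs.append(ClassSpec(label, tuple(feats)))
    return tuple(specs)


def _substream(seed: int, *key: int) -> np.random.Generator:
    # one master seed; deterministic per-(block, class) substreams
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_replicate_blocks(
    specs: tuple[ClassSpec, ...] | list[ClassSpec] | None = None,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> MultiBlock:
    """Draw replicate tables for every block present in ``specs``.

    Each present feature is sampled independently from Normal(mean, sd);
    draws are clipped at zero when ``cfg.clip_at_zero``; absent features are
    exactly zero.  All blocks share identical sample indexing
    (``<class>_<replicate>`` in canonical class order).  Fully reproducible
    from ``cfg.seed``.
    """
    specs = tuple(specs) if specs is not None else builtin_citrus_specs()
    block_ids = []
    for f in specs[0].features:
        if f.block not in block_ids:
            block_ids.append(f.block)
    # all specs must agree on the per-block feature sets, in order
    for s in specs[1:]:
        for bid in block_ids:
            if [f.name for f in s.block_features(bid)] != [
                f.name for f in specs[0].block_features(bid)
            ]:
                raise ValueError(
                    f"class {s.class_label!r} has a different {bid!r} feature set "
                    f"than class {specs[0].class_label!r}"
                )

    n = cfg.n_per_class
    sample_ids = [f"{s.class_label}_{i+1:02d}" for s in specs for i in range(n)]
    labels = pd.Series(
        [s.class_label for s in specs for _ in range(n)],
        index=pd.Index(sample_ids, name="sample_id"),
        name="class",
    )

    blocks = []
    for b_idx, bid in enumerate(block_ids):
        cols = [f.name for f in specs[0].block_features(bid)]
        rows = []
        for c_idx, s in enumerate(specs):
            rng = _substream(cfg.seed, b_idx, c_idx)
            mat = np.zeros((n, len(cols)))
            for j, f in enumerate(s.block_features(bid)):
                if not f.present:
                    continue
                draws = rng.normal(f.mean, f.sd, size=n)
                if cfg.clip_at_zero:
                    draws = np.clip(draws, 0.0, None)
                mat[:, j] = draws
            rows.append(mat)
        data = pd.DataFrame(
            np.vstack(rows), index=labels.index, columns=cols
        )
        blocks.append(FeatureBlock(bid, data, labels))
    return MultiBlock(blocks)


DEFAULT_GRID = (4000.0, 499.0, 1.0)


def generate_spectrum(
    band_means: dict,
    peak_width: float = 4.0,
    noise_sd: float = 0.0,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    seed: int = 0,
):
    """Synthesize an absorbance trace as a sum of Gaussian peaks plus noise.

    ``band_means`` maps peak center (cm-1) to amplitude; ``grid`` is
    (high, low, step) with wavenumbers descending, the fingerprint
    acquisition convention.  Deterministic per seed.  Returns a
    :class:`peelfusion.spectra.Spectrum`.
    """
    from .spectra import Spectrum  # local import to avoid a cycle

    high, low, step = grid
    if high < low:
        raise ValueError("grid must descend: expected (high, low, step) with high >= low")
    if peak_width <= 0:
        raise ValueError("peak_width must be > 0")
    wn = np.arange(high, low - step / 2, -step)
    absorb = np.zeros_like(wn)
    for center, amp in band_means.items():
        c = float(center)
        if not (wn.min() <= c <= wn.max()):
            raise ValueError(f"band center {c} cm-1 outside grid [{wn.min()}, {wn.max()}]")
        absorb += amp * np.exp(-0.5 * ((wn - c) / peak_width) ** 2)
    if noise_sd > 0:
        absorb = absorb + np.random.default_rng(seed).normal(0.0, noise_sd, wn.shape)
    return Spectrum(wavenumbers=wn, absorbance=absorb)


def generate_class_spectra(
    specs=None,
    cfg: GeneratorConfig = GeneratorConfig(),
    peak_width: float = 4.0,
    amplitude_noise: bool = True,
    trace_noise_sd: float = 0.0,
):
    """Per-replicate synthetic FTIR spectra from the class band tables.

    Band amplitudes are drawn per replicate from Normal(mean, sd) (clipped
    at zero) when ``amplitude_noise``; otherwise fixed at the class means.
    Returns ``(spectra, labels)`` where ``spectra`` is an ordered dict
    sample_id -> Spectrum.
    """
    from .spectra import band_center, builtin_band_definitions

    specs = tuple(specs) if specs is not None else builtin_citrus_specs()
    centers = {b.label: band_center(b) for b in builtin_band_definitions()}
    spectra: dict[str, object] = {}
    labels: dict[str, str] = {}
    for c_idx, s in enumerate(specs):
        rng = _substream(cfg.seed, 100, c_idx)
        bands = s.block_features("ftir")
        for i in range(cfg.n_per_class):
            sid = f"{s.class_label}_{i+1:02d}"
            band_means = {}
            for f in bands:
                if not f.present:
                    continue
                amp = rng.normal(f.mean, f.sd) if amplitude_noise else f.mean
                band_means[centers[f.name]] = max(amp, 0.0)
            spectra[sid] = generate_spectrum(
                band_means,
                peak_width=peak_width,
                noise_sd=trace_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            labels[sid] = s.class_label
    return spectra, pd.Series(labels, name="class")


#: Image specs emulating the observed peel-uniformity ranking: lemon and
#: yellow grapefruit most uniform, orange and kumquat intermediate,
#: clementine and red grapefruit least uniform.
BUILTIN_IMAGE_SPECS = {
    "lemon": ImageClassSpec(base_intensity=164.0, noise_sd=2.0, blotch_density=1.0, blotch_scale=3.0),
    "yellow_grapefruit": ImageClassSpec(base_intensity=156.0, noise_sd=2.5, blotch_density=2.0, blotch_scale=3.0),
    "orange": ImageClassSpec(base_intensity=140.0, noise_sd=5.0, blotch_density=12.0, blotch_scale=3.5),
    "kumquat": ImageClassSpec(base_intensity=132.0, noise_sd=5.5, blotch_density=15.0, blotch_scale=3.5),
    "red_grapefruit": ImageClassSpec(base_intensity=120.0, noise_sd=9.0, blotch_density=40.0, blotch_scale=4.0),
    "clementine": ImageClassSpec(base_intensity=116.0, noise_sd=10.0, blotch_density=45.0, blotch_scale=4.0),
}


def generate_texture_image(spec: ImageClassSpec, seed: int = 0) -> np.ndarray:
    """Synthetic grayscale peel image: uniform base field + Gaussian pixel
    noise + dark elliptical blotches, clipped to [0, 255] uint8.

    The blotch count is Poisson with mean ``blotch_density * n_pixels/1e4``;
    each blotch darkens an ellipse of random orientation and semi-axes
    around ``blotch_scale`` by 45% of the base intensity.  Deterministic
    per (spec, seed).
    """
    rows, cols = spec.size
    if rows < 64 or cols < 64:
        raise ValueError("image size must be at least 64x64")
    rng = np.random.default_rng(seed)
    img = np.full((rows, cols), spec.base_intensity, dtype=float)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    n_blotches = 0
    if spec.blotch_density > 0:
        n_blotches = int(rng.poisson(spec.blotch_density * rows * cols / 1e4))
    if n_blotches:
        rr, cc = np.mgrid[0:rows, 0:cols]
        depth = 0.45 * spec.base_intensity
        for _ in range(n_blotches):
            cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
            a = spec.blotch_scale * rng.uniform(0.6, 1.6)
            b = spec.blotch_scale * rng.uniform(0.6, 1.6)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (rr - cy) * ct + (cc - cx) * st
            v = -(rr - cy) * st + (cc - cx) * ct
            img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] -= depth
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def write_blocks(mb: MultiBlock, out_dir) -> None:
    """Write one wide CSV per block plus a tidy long-format CSV."""
    from pathlib import Path

    from .blocks import block_to_tidy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tidy = []
    for b in mb:
        wide = b.data.copy()
        wide.insert(0, "class", b.labels)
        wide.to_csv(out / f"block_{b.block_id}.csv")
        tidy.append(block_to_tidy(b))
    pd.concat(tidy, ignore_index=True).to_csv(out / "tidy.csv", index=False)
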