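"""Grayscale texture profiling of peel images.

Fifteen features per region of interest: four first-order histogram
statistics (mean intensity, standard deviation, skewness, kurtosis), six
gray-level co-occurrence matrix (GLCM) statistics (contrast, dissimilarity,
energy, homogeneity, correlation, angular second moment) and five gray-level
run-length matrix (GLRLM) statistics (short/long run emphasis, gray-level
and run-length non-uniformity, run percentage).

Conventions: GLCM at distance 1 over the four standard directions
(0, 45, 90, 135 degrees), symmetrized, summed over directions and normalized
to probabilities; GLRLM run counts are likewise summed over the same four
directions.  Images are quantized to ``levels`` equal-width gray bins
before either matrix is built.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

#: Canonical order of the 15 texture feature names.
FEATURE_NAMES = (
    "mean_intensity", "std", "skewness", "kurtosis",
    "contrast", "dissimilarity", "energy", "homogeneity", "correlation", "asm",
    "sre", "lre", "gln", "rln", "rp",
)

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
# (row, col) steps for run tracing, matching the four GLCM directions
_DIRECTION_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance conversion, rounded half-up to uint8.

    ``gray = 0.299 R + 0.587 G + 0.114 B``.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {rgb.shape}")
    lum = rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114
    return np.floor(lum + 0.5).astype(np.uint8)


def quantize(img: np.ndarray, levels: int, max_value: int = 255) -> np.ndarray:
    """Equal-width quantization of [0, max_value] into ``levels`` bins."""
    img = np.asarray(img)
    q = (img.astype(np.int64) * levels) // (max_value + 1)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


@dataclass(frozen=True)
class ROI:
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("ROI must be at least 8x8")

    def crop(self, img: np.ndarray) -> np.ndarray:
        if self.row0 < 0 or self.col0 < 0 or self.row0 + self.height > img.shape[0] \
                or self.col0 + self.width > img.shape[1]:
            raise ValueError(f"ROI {self} does not fit inside image {img.shape}")
        return img[self.row0:self.row0 + self.height, self.col0:self.col0 + self.width]


def extract_rois(img, roi_size: int, k: int, strategy: str = "grid", seed=None) -> list[ROI]:
    """Select ``k`` square ROIs of side ``roi_size``.

    ``grid`` places ROIs on a deterministic corner-anchored grid (k=1 is a
    centered ROI); ``random`` draws seeded positions, avoiding overlap when
    enough room exists.
    """
    h, w = np.asarray(img).shape[:2]
    if roi_size > h or roi_size > w:
        raise ValueError(f"roi_size {roi_size} exceeds image {h}x{w}")
    if strategy == "grid":
        if k == 1:
            return [ROI((h - roi_size) // 2, (w - roi_size) // 2, roi_size, roi_size)]
        per_row = h // roi_size
        per_col = w // roi_size
        if k > per_row * per_col:
            raise ValueError(
                f"k={k} exceeds the {per_row * per_col} non-overlapping grid positions"
            )
        g = int(np.ceil(np.sqrt(k)))
        g = min(g, per_row, per_col)
        while g * min(per_row, per_col) < k:  # widen if a square grid is too small
            g += 1
        rows = np.round(np.linspace(0, h - roi_size, num=max(g, 2) if k > 1 else 1)).astype(int)
        cols = np.round(np.linspace(0, w - roi_size, num=max(g, 2) if k > 1 else 1)).astype(int)
        rois = [ROI(int(r), int(c), roi_size, roi_size) for r in rows for c in cols]
        return rois[:k]
    if strategy == "random":
        rng = np.random.default_rng(seed)
        rois: list[ROI] = []
        attempts = 0
        while len(rois) < k and attempts < 200 * k:
            attempts += 1
            r = int(rng.integers(0, h - roi_size + 1))
            c = int(rng.integers(0, w - roi_size + 1))
            cand = ROI(r, c, roi_size, roi_size)
            if all(abs(cand.row0 - o.row0) >= roi_size or abs(cand.col0 - o.col0) >= roi_size
                   for o in rois):
                rois.append(cand)
        while len(rois) < k:  # overlap unavoidable; fill with seeded positions
            rois.append(ROI(int(rng.integers(0, h - roi_size + 1)),
                            int(rng.integers(0, w - roi_size + 1)), roi_size, roi_size))
        return rois
    raise ValueError(f"unknown strategy {strategy!r}")


def first_order_features(img) -> tuple[float, float, float, float]:
    """Population moments of the gray histogram: mean, SD, skewness
    (m3/sigma^3) and Fisher kurtosis (m4/sigma^4 - 3); a constant image has
    skewness = kurtosis = 0 by convention."""
    x = np.asarray(img, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    mean = x.mean()
    centered = x - mean
    var = np.mean(centered**2)
    std = np.sqrt(var)
    if std == 0:
        return float(mean), 0.0, 0.0, 0.0
    skew = np.mean(centered**3) / std**3
    kurt = np.mean(centered**4) / std**4 - 3.0
    return float(mean), float(std), float(skew), float(kurt)


@dataclass
class GLCMatrix:
    """Normalized, symmetric co-occurrence probability matrix summed over
    directions."""

    P: np.ndarray
    distance: int
    angles: tuple
    levels: int


def compute_glcm(img, distance: int = 1, angles=_ANGLES, levels: int = 32,
                 symmetric: bool = True) -> GLCMatrix:
    """Pair-probability matrix of quantized gray levels.

    ``img`` must already hold values in ``[0, levels)``.  Counts are
    accumulated per direction at the given offset, symmetrized, summed over
    directions and normalized to sum to 1.
    """
    img = np.asarray(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if img.max() >= levels:
        raise ValueError(f"image holds value {img.max()} >= levels={levels}; quantize first")
    if min(img.shape) <= distance and max(img.shape) <= distance:
        raise ValueError("image smaller than the co-occurrence offset")
    counts = graycomatrix(img.astype(np.uint8), [distance], list(angles),
                          levels=levels, symmetric=symmetric, normed=False)
    P = counts[:, :, 0, :].sum(axis=2).astype(float)
    total = P.sum()
    if total == 0:
        raise ValueError("no pixel pairs at the requested offset")
    return GLCMatrix(P=P / total, distance=distance, angles=tuple(angles), levels=levels)


def glcm_features(glcm: GLCMatrix | np.ndarray) -> dict:
    """Contrast, dissimilarity, energy, homogeneity, correlation and angular
    second moment of a normalized co-occurrence matrix.  When either
    marginal SD is zero (constant image) correlation is 1 by convention."""
    P = glcm.P if isinstance(glcm, GLCMatrix) else np.asarray(glcm, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("co-occurrence matrix must be normalized (sum to 1)")
    n = P.shape[0]
    i, j = np.indices((n, n))
    diff = i - j
    asm = float((P**2).sum())
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    sig_i = np.sqrt(((i - mu_i) ** 2 * P).sum())
    sig_j = np.sqrt(((j - mu_j) ** 2 * P).sum())
    if sig_i * sig_j == 0:
        corr = 1.0
    else:
        corr = float((((i - mu_i) * (j - mu_j) * P).sum()) / (sig_i * sig_j))
    return {
        "contrast": float((P * diff**2).sum()),
        "dissimilarity": float((P * np.abs(diff)).sum()),
        "energy": float(np.sqrt(asm)),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "correlation": corr,
        "asm": asm,
    }


@dataclass
class RunLengthMatrix:
    """Run counts ``r[level, length-1]`` summed over directions.

    ``n_pixels`` counts every pixel once per direction, so the pixel
    conservation identity sum_j j * r(i, j) == n_pixels holds for the summed
    matrix as well.
    """

    r: np.ndarray
    directions: tuple
    levels: int
    n_runs: int
    n_pixels: int


def _run_lengths_of_line(line: np.ndarray):
    # (value, length) pairs of maximal equal-value runs
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    for s, e in zip(starts, ends):
        yield int(line[s]), int(e - s)


def _directed_lines(img: np.ndarray, direction: int):
    if direction == 0:
        yield from img
    elif direction == 90:
        yield from img.T
    else:
        flipped = img[:, ::-1] if direction == 135 else img
        h, w = flipped.shape
        for offset in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=offset)


def compute_glrlm(img, directions=(0, 45, 90, 135), levels: int = 32) -> RunLengthMatrix:
    """Gray-level run-length matrix over the given directions (degrees).

    ``img`` must already hold values in ``[0, levels)``.  A run is a maximal
    straight sequence of pixels with equal quantized level.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if img.max() >= levels:
        raise ValueError(f"image holds value {img.max()} >= levels={levels}; quantize first")
    max_len = max(img.shape)
    r = np.zeros((levels, max_len), dtype=np.int64)
    for d in directions:
        if d not in _DIRECTION_STEPS:
            raise ValueError(f"unsupported direction {d}; use 0/45/90/135")
        for line in _directed_lines(img, d):
            for level, length in _run_lengths_of_line(np.asarray(line)):
                r[level, length - 1] += 1
    n_runs = int(r.sum())
    return RunLengthMatrix(r=r, directions=tuple(directions), levels=levels,
                           n_runs=n_runs, n_pixels=img.size * len(directions))


def glrlm_features(rlm: RunLengthMatrix) -> dict:
    """Galloway run-length statistics: SRE, LRE, GLN, RLN and RP."""
    if rlm.n_runs < 1:
        raise ValueError("run-length matrix holds no runs")
    r = rlm.r.astype(float)
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    n_r = float(rlm.n_runs)
    return {
        "sre": float((r / j**2).sum() / n_r),
        "lre": float((r * j**2).sum() / n_r),
        "gln": float((r.sum(axis=1) ** 2).sum() / n_r),
        "rln": float((r.sum(axis=0) ** 2).sum() / n_r),
        "rp": float(n_r / rlm.n_pixels),
    }


@dataclass(frozen=True)
class TextureFeatures:
    """The 15 texture statistics for one ROI (or a ROI average)."""

    mean_intensity: float
    std: float
    skewness: float
    kurtosis: float
    contrast: float
    dissimilarity: float
    energy: float
    homogeneity: float
    correlation: float
    asm: float
    sre: float
    lre: float
    gln: float
    rln: float
    rp: float

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in dc_fields(self)})


@dataclass
class TextureProfile:
    """Per-ROI feature table plus its ROI average."""

    per_roi: pd.DataFrame
    mean: TextureFeatures
    rois: list[ROI]


def _roi_features(roi_img: np.ndarray, levels: int, distance: int) -> TextureFeatures:
    mean, std, skew, kurt = first_order_features(roi_img)
    q = quantize(roi_img, levels)
    gl = glcm_features(compute_glcm(q, distance=distance, levels=levels))
    rl = glrlm_features(compute_glrlm(q, levels=levels))
    return TextureFeatures(mean, std, skew, kurt, **gl, **rl)


def texture_profile(img, roi_size: int = 64, k: int = 4, strategy: str = "grid",
                    levels: int = 32, distance: int = 1, seed=None) -> TextureProfile:
    """Full 15-feature texture profile of a grayscale image.

    Features are computed per ROI; the per-image record is the mean over
    ROIs.  First-order statistics use the raw 8-bit gray levels; GLCM and
    GLRLM use the image quantized to ``levels`` bins.
    """
    img = np.asarray(img)
    if img.ndim == 3:
        img = to_grayscale(img)
    rois = extract_rois(img, roi_size=roi_size, k=k, strategy=strategy, seed=seed)
    records = [_roi_features(roi.crop(img), levels, distance) for roi in rois]
    per_roi = pd.DataFrame([r.as_series() for r in records])
    per_roi.index.name = "roi"
    mean = TextureFeatures(**per_roi.mean().to_dict())
    return TextureProfile(per_roi=per_roi, mean=mean, rois=rois)
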