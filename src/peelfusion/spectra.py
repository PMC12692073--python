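"""FTIR spectrum handling and band-intensity table construction.

A spectrum is a wavenumber-indexed absorbance trace over the mid-infrared
fingerprint range (4000-499 cm-1).  Band intensities are extracted as the
maximum absorbance inside a +/- window around each nominal band position
(range labels such as ``"1016-1012"`` use the range midpoint), optionally
after subtracting a linear local baseline through the window endpoints.
Stacking per-sample band intensities yields the ``ftir`` feature block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _tables
from .blocks import FeatureBlock


@dataclass
class Spectrum:
    """Absorbance trace sorted by descending wavenumber (cm-1)."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D and the same length")
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if (self.wavenumbers < 0).any():
            raise ValueError("negative wavenumbers")
        order = np.argsort(-self.wavenumbers, kind="stable")
        self.wavenumbers = self.wavenumbers[order]
        self.absorbance = self.absorbance[order]
        if (np.diff(self.wavenumbers) >= 0).any():
            raise ValueError("wavenumbers must be strictly monotonic")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavenumber": self.wavenumbers, "absorbance": self.absorbance}
        ).to_csv(path, index=False)


def read_spectrum(path) -> Spectrum:
    """Parse a two-column numeric CSV (wavenumber, absorbance); the result
    is sorted by descending wavenumber regardless of file order."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, absorbance)")
    wn = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    ab = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if wn.isna().any() or ab.isna().any():
        bad = df[wn.isna() | ab.isna()].index.tolist()
        raise ValueError(f"{path}: non-numeric rows at positions {bad}")
    return Spectrum(wn.to_numpy(), ab.to_numpy())


@dataclass(frozen=True)
class BandDefinition:
    """A named absorption region.

    ``low == high`` for single-position bands; range labels keep their
    printed form.  ``window`` widens the extraction interval on both sides.
    """

    label: str
    low: float
    high: float
    window: float = 8.0
    annotation: str | None = None

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.low > self.high:
            raise ValueError(f"band {self.label!r}: low > high")


def band_center(band: BandDefinition) -> float:
    return (band.low + band.high) / 2.0


def parse_band_label(label: str, window: float = 8.0) -> BandDefinition:
    """Build a BandDefinition from a label like ``"1600"`` or ``"1016-1012"``."""
    parts = label.replace("–", "-").split("-")
    nums = [float(p) for p in parts]
    low, high = (min(nums), max(nums))
    return BandDefinition(label=label, low=low, high=high, window=window,
                          annotation=_tables.BAND_ANNOTATIONS.get(label))


def builtin_band_definitions(window: float = 8.0) -> tuple[BandDefinition, ...]:
    """The 37 built-in band regions of the citrus study, ordered by
    descending wavenumber, with chemical annotation strings attached."""
    return tuple(parse_band_label(label, window=window) for label in _tables.FTIR_BANDS)


def pick_band_intensity(s: Spectrum, band: BandDefinition,
                        baseline: bool = False, mode: str = "max") -> float:
    """Band intensity within ``[low - window, high + window]``.

    ``mode="max"`` (default) returns the maximum absorbance in the window —
    a peak height, matching single-value band tables; ``mode="area"``
    integrates over the window (trapezoid).  With ``baseline=True`` a
    straight line through the window endpoints is subtracted first.
    """
    lo, hi = band.low - band.window, band.high + band.window
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"band {band.label!r} window [{lo}, {hi}] does not intersect the "
            f"spectrum range [{s.wavenumbers.min()}, {s.wavenumbers.max()}]"
        )
    wn = s.wavenumbers[mask]
    ab = s.absorbance[mask]
    if baseline and wn.size >= 2:
        x0, x1 = wn[0], wn[-1]
        y0, y1 = ab[0], ab[-1]
        ab = ab - (y0 + (wn - x0) * (y1 - y0) / (x1 - x0))
    if mode == "max":
        return float(ab.max())
    if mode == "area":
        return float(np.trapezoid(ab[::-1], wn[::-1]))
    raise ValueError(f"unknown mode {mode!r}")


def build_band_block(spectra: dict[str, Spectrum], bands=None,
                     labels: pd.Series | dict | None = None,
                     baseline: bool = False) -> FeatureBlock:
    """Assemble the n_samples x n_bands ``ftir`` block from per-sample
    spectra.  Columns follow the band list order (descending wavenumber);
    a band with no peak in a spectrum simply yields its windowed value
    (typically ~0), never a missing cell."""
    bands = tuple(bands) if bands is not None else builtin_band_definitions()
    sample_ids = list(spectra)
    rows = [
        [pick_band_intensity(spectra[sid], b, baseline=baseline) for b in bands]
        for sid in sample_ids
    ]
    index = pd.Index(sample_ids, name="sample_id")
    data = pd.DataFrame(rows, index=index, columns=[b.label for b in bands])
    if labels is None:
        lab = pd.Series(["unknown"] * len(sample_ids), index=index, name="class")
    else:
        lab = pd.Series(labels, name="class").reindex(index)
        if lab.isna().any():
            missing = lab[lab.isna()].index.tolist()
            raise ValueError(f"no class label for samples {missing}")
    return FeatureBlock("ftir", data, lab)


def write_band_table(block: FeatureBlock, path) -> None:
    out = block.data.copy()
    out.insert(0, "class", block.labels)
    out.to_csv(Path(path))
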