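"""Spectral post-processing: referencing, bucketing, water removal, scaling.

The processing contract is deliberately minimal and mirrors a standard serum
metabolomics protocol: spectra are shift-referenced to the alanine methyl
doublet, bucketed over 9.0-0.5 ppm at a 0.002 ppm bucket width, the water
region (5.15-4.38 ppm) is removed, **no normalization is applied**, and the
resulting matrix is Pareto scaled before multivariate modelling.

Bucket intervals are half-open ``(low, high]`` descending in ppm, anchored
at the grid's upper bound, so bucket counts are deterministic:
floor((upper - lower) / width) buckets, 4250 for the default grid.
Exclusion is by bucket *center*: a bucket is dropped iff its center lies in
the closed exclusion window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .panel import WATER_WINDOW
from .spectra import Spectrum


@dataclass(frozen=True)
class BucketGrid:
    """Uniform bucket grid over a descending ppm range."""

    upper: float = 9.0
    lower: float = 0.5
    width: float = 0.002
    exclusions: tuple[tuple[float, float], ...] = (WATER_WINDOW,)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bucket width must be > 0")
        if self.upper <= self.lower:
            raise ValueError("grid upper bound must exceed lower bound")
        for lo, hi in self.exclusions:
            if lo > hi:
                raise ValueError(f"exclusion window [{lo}, {hi}] inverted")
            if hi < self.lower or lo > self.upper:
                continue  # fully outside is allowed (no-op)
            if lo < self.lower or hi > self.upper:
                raise ValueError(
                    f"exclusion window [{lo}, {hi}] extends outside the grid")

    @property
    def n_buckets(self) -> int:
        return int(np.floor((self.upper - self.lower) / self.width + 1e-9))

    @property
    def edges(self) -> np.ndarray:
        """Descending bucket edges, ``n_buckets + 1`` values from upper down."""
        return self.upper - self.width * np.arange(self.n_buckets + 1)

    @property
    def centers(self) -> np.ndarray:
        """Descending bucket centers."""
        edges = self.edges
        return (edges[:-1] + edges[1:]) / 2.0


@dataclass
class BucketTable:
    """Samples x buckets intensity matrix with a retained-bucket mask."""

    sample_ids: list[str]
    centers: np.ndarray  # descending, all buckets (masked and not)
    matrix: np.ndarray  # n_samples x n_buckets, all buckets
    mask: np.ndarray  # True = retained
    grid: BucketGrid
    meta: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def values(self) -> np.ndarray:
        """Matrix restricted to retained buckets (one column per bucket)."""
        return self.matrix[:, self.mask]

    @property
    def retained_centers(self) -> np.ndarray:
        return self.centers[self.mask]

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def to_csv(self, path: str | Path) -> None:
        """Write retained buckets as CSV with a ppm header row."""
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=[f"{c:.4f}" for c in self.retained_centers])
        df.index.name = "sample_id"
        df.to_csv(path)


def reference_to_alanine(
    spectrum: Spectrum,
    search_window: tuple[float, float] = (1.3, 1.7),
    *,
    target: float = 1.48,
    min_prominence: float | None = None,
) -> Spectrum:
    """Shift the ppm axis so the alanine methyl doublet sits at ``target``.

    The doublet is detected among local maxima inside ``search_window``:
    peak pairs with a doublet-like splitting (0.5-2x the 7 Hz coupling at
    400 MHz, i.e. ~0.009-0.035 ppm) and comparable heights are candidate
    doublets; the candidate whose midpoint lies closest to ``target`` wins,
    so nearby strong signals (lactate doublet, lipid CH2) do not hijack the
    reference.  If no pair qualifies, the single peak closest to ``target``
    is used.  When no peak exceeds the prominence floor (default: 5% of the
    window's dynamic range) the spectrum is returned unshifted with
    ``reference_failed`` set and a warning is emitted.

    Intensities are never altered, only the axis.
    """
    lo, hi = min(search_window), max(search_window)
    sel = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not sel.any():
        warnings.warn(f"{spectrum.sample_id}: referencing window outside spectrum")
        return replace(spectrum, reference_failed=True)
    # work on ascending axis for find_peaks
    ppm_w = spectrum.ppm[sel][::-1]
    y_w = spectrum.intensity[sel][::-1]
    span = float(y_w.max() - y_w.min())
    prom = min_prominence if min_prominence is not None else 0.05 * span
    if span <= 0 or prom <= 0:
        warnings.warn(f"{spectrum.sample_id}: flat referencing window, not referenced")
        return replace(spectrum, reference_failed=True)
    peaks, _ = find_peaks(y_w, prominence=prom)
    if peaks.size == 0:
        warnings.warn(f"{spectrum.sample_id}: no alanine doublet found, not referenced")
        return replace(spectrum, reference_failed=True)
    j_ppm = 7.0 / 400.0  # doublet splitting at 400 MHz
    candidates: list[float] = []
    for a in range(peaks.size):
        for b in range(a + 1, peaks.size):
            spacing = abs(ppm_w[peaks[b]] - ppm_w[peaks[a]])
            if not 0.5 * j_ppm <= spacing <= 2.0 * j_ppm:
                continue
            ha, hb = y_w[peaks[a]], y_w[peaks[b]]
            if min(ha, hb) <= 0 or max(ha, hb) / min(ha, hb) > 3.0:
                continue  # doublet lines have comparable heights
            candidates.append(float((ppm_w[peaks[a]] + ppm_w[peaks[b]]) / 2.0))
    if not candidates:  # fall back to the single peak nearest the target
        candidates = [float(ppm_w[k]) for k in peaks]
    center = min(candidates, key=lambda c: abs(c - target))
    out = spectrum.shifted(target - center)
    out.referenced = True
    out.reference_failed = False
    return out


def bucket(spectrum: Spectrum, grid: BucketGrid) -> np.ndarray:
    """Sum intensities into the grid's buckets.

    Bucket ``i`` collects points with ppm in ``(edges[i+1], edges[i]]``
    (half-open, descending).  The spectrum must cover the grid range.
    """
    if not spectrum.covers(grid.lower, grid.upper):
        raise ValueError(
            f"spectrum [{spectrum.ppm.min():.3f}, {spectrum.ppm.max():.3f}] ppm "
            f"does not cover the grid [{grid.lower}, {grid.upper}]")
    edges_asc = grid.edges[::-1]  # ascending: lower ... upper
    # membership in (a, b] on ascending edges
    idx = np.searchsorted(edges_asc, spectrum.ppm, side="left") - 1
    valid = (idx >= 0) & (idx < grid.n_buckets)
    sums = np.bincount(idx[valid], weights=spectrum.intensity[valid],
                       minlength=grid.n_buckets)
    # ascending bucket k maps to descending bucket n-1-k
    return sums[::-1].copy()


def bucket_spectra(spectra: Sequence[Spectrum], grid: BucketGrid) -> BucketTable:
    """Bucket a set of spectra into a :class:`BucketTable` (no exclusions yet)."""
    if not spectra:
        raise ValueError("no spectra to bucket")
    matrix = np.vstack([bucket(s, grid) for s in spectra])
    meta = pd.DataFrame({
        "sample_id": [s.sample_id for s in spectra],
        "patient_id": [s.patient_id for s in spectra],
        "timepoint": [s.timepoint for s in spectra],
        "channel": [s.channel for s in spectra],
    })
    return BucketTable(
        sample_ids=[s.sample_id for s in spectra],
        centers=grid.centers,
        matrix=matrix,
        mask=np.ones(grid.n_buckets, dtype=bool),
        grid=grid,
        meta=meta,
    )


def exclude_water(table: BucketTable,
                  window: tuple[float, float] = WATER_WINDOW) -> BucketTable:
    """Mask out buckets whose center lies inside the closed ``window``.

    An empty intersection leaves the table unchanged.  Returns a new table;
    the input is not modified.
    """
    lo, hi = min(window), max(window)
    inside = (table.centers >= lo) & (table.centers <= hi)
    return BucketTable(
        sample_ids=list(table.sample_ids),
        centers=table.centers,
        matrix=table.matrix,
        mask=table.mask & ~inside,
        grid=table.grid,
        meta=table.meta,
    )


def pareto_scale(matrix: np.ndarray) -> np.ndarray:
    """Pareto-scale columns: mean-center, divide by sqrt(sample SD, n-1).

    Zero-variance columns are set to zero after centering.  Requires at
    least two rows (no variance is definable otherwise).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pareto_scale requires a matrix with >= 2 rows")
    centered = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.sqrt(sd, where=sd > 0, out=np.ones_like(sd))
    out = np.divide(centered, scale, where=sd > 0, out=np.zeros_like(centered))
    return out


class ParetoScaler:
    """Fit/transform wrapper so external test sets reuse training statistics."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ParetoScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("ParetoScaler requires a matrix with >= 2 rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, np.sqrt(sd, where=sd > 0,
                                               out=np.ones_like(sd)), np.inf)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("ParetoScaler is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
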