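"""Spectrum normalization, feature lists and ion-image filters.

The pipeline works on root-mean-square (RMS) normalized pixel spectra: each
pixel's intensities are divided by the RMS of that pixel's intensity vector,
which removes per-pixel ionization efficiency differences while preserving
relative peak heights.  Feature lists are built from the cohort mean spectrum
with a sliding-window peak picker; each feature is an apex m/z with a ±ppm
window, materialized to a half-open Da interval [lo, hi) on use so adjacent
windows never double count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MSImageDataset, PixelSpectrum

__all__ = [
    "FeatureList",
    "rms_factor",
    "normalize_dataset",
    "mean_spectrum",
    "sliding_window_peaks",
    "refine_feature_list",
    "extract_feature_table",
    "feature_image",
    "export_image",
    "hotspot_clip",
    "median_denoise",
    "deisotope",
    "remove_background_features",
]

#: 13C − 12C isotopologue spacing, Da.
C13_DELTA = 1.00336
#: Na−H and K−H replacement offsets, Da (salt-adduct duplicates of a feature).
NA_H_DELTA = 21.98194
K_H_DELTA = 37.95588


@dataclass
class FeatureList:
    """Ordered m/z features: apex m/z with a ±ppm half-width each."""

    mz: np.ndarray
    ppm: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.ppm = np.broadcast_to(np.asarray(self.ppm, dtype=float), self.mz.shape).copy()
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("feature apex m/z must be strictly ascending")
        if np.any(self.ppm <= 0):
            raise ValueError("window half-widths must be positive")
        if not self.labels:
            self.labels = [f"mz_{m:.4f}" for m in self.mz]
        if len(self.labels) != self.mz.size:
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return int(self.mz.size)

    def windows(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open Da windows [lo, hi) from the ppm half-widths."""
        half = self.mz * self.ppm * 1e-6
        return self.mz - half, self.mz + half

    def subset(self, idx) -> "FeatureList":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureList(self.mz[idx], self.ppm[idx], [self.labels[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "ppm": self.ppm, "label": self.labels})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "FeatureList":
        df = pd.read_csv(path, sep="\t")
        return cls(df["mz"].to_numpy(), df["ppm"].to_numpy(), df["label"].astype(str).tolist())


def rms_factor(spectrum: PixelSpectrum) -> float:
    """Root mean square of a pixel's intensities (0.0 for an all-zero pixel,
    which callers treat as 'flagged: leave unnormalized')."""
    if spectrum.intensity.size == 0:
        raise ValueError("empty spectrum has no RMS factor")
    return float(np.sqrt(np.mean(np.square(spectrum.intensity))))


def normalize_dataset(dataset: MSImageDataset) -> MSImageDataset:
    """RMS-normalize every pixel; all-zero pixels are kept as zeros."""
    out = []
    for s in dataset.spectra:
        if s.intensity.size == 0:
            out.append(s)
            continue
        f = rms_factor(s)
        inten = s.intensity / f if f > 0 else s.intensity
        out.append(PixelSpectrum(s.mz, inten, s.x, s.y))
    return dataset.copy_with(spectra=out, normalized=True)


def mean_spectrum(
    datasets: Sequence[MSImageDataset],
    bin_ppm: float = 1.0,
) -> PixelSpectrum:
    """Average spectrum over all pixels of all sections on a common log-spaced
    m/z grid of ``bin_ppm`` resolution.  Zero bins are dropped; the returned
    m/z values are bin centers (geometric)."""
    if not datasets:
        raise ValueError("need at least one dataset")
    lo = min(float(s.mz[0]) for d in datasets for s in d if s.mz.size)
    hi = max(float(s.mz[-1]) for d in datasets for s in d if s.mz.size)
    step = np.log1p(bin_ppm * 1e-6)
    n_bins = int(np.floor((np.log(hi) - np.log(lo)) / step)) + 1
    acc = np.zeros(n_bins)
    n_pixels = 0
    log_lo = np.log(lo)
    for d in datasets:
        for s in d:
            n_pixels += 1
            if s.mz.size == 0:
                continue
            idx = np.floor((np.log(s.mz) - log_lo) / step).astype(int)
            np.clip(idx, 0, n_bins - 1, out=idx)
            np.add.at(acc, idx, s.intensity)
    acc /= n_pixels
    nz = np.flatnonzero(acc)
    centers = lo * np.exp((nz + 0.5) * step)
    return PixelSpectrum(centers, acc[nz], 1, 1)


def sliding_window_peaks(
    mean: PixelSpectrum,
    half_width_ppm: float = 5.0,
    min_intensity: float | None = None,
) -> FeatureList:
    """Pick apexes from a mean spectrum: intensity-ordered greedy selection
    with suppression of any candidate within one ±ppm window of an accepted
    apex (the higher apex wins).

    ``min_intensity`` defaults to 3x the median absolute intensity of the mean
    spectrum's full binned grid; since that grid is overwhelmingly empty this
    is effectively the lowest possible threshold, matching how the feature
    list is meant to start as a large permissive peak list.
    """
    if half_width_ppm <= 0:
        raise ValueError("half width must be positive")
    if min_intensity is None:
        min_intensity = 3.0 * float(np.median(np.abs(mean.intensity)))
    order = np.argsort(mean.intensity)[::-1]
    kept: list[int] = []
    kept_mz: list[float] = []
    for i in order:
        inten = mean.intensity[i]
        if inten < min_intensity or inten <= 0:
            break
        m = mean.mz[i]
        if kept_mz:
            arr = np.asarray(kept_mz)
            if np.any(np.abs(m - arr) <= arr * half_width_ppm * 1e-6):
                continue
        kept.append(int(i))
        kept_mz.append(float(m))
    kept.sort()
    return FeatureList(mean.mz[kept], np.full(len(kept), half_width_ppm))


def refine_feature_list(
    features: FeatureList,
    mean: PixelSpectrum,
    new_half_width_ppm: float = 3.0,
) -> FeatureList:
    """Re-center each apex on the intensity-weighted mean m/z within its
    current window, then tighten the window to ``new_half_width_ppm``.

    Mirrors the manual curation step of checking that each feature interval
    sits on the apex of its peak before narrowing the tolerance.
    """
    lo, hi = features.windows()
    new_mz = features.mz.copy()
    for i in range(len(features)):
        sel = (mean.mz >= lo[i]) & (mean.mz < hi[i])
        if np.any(sel):
            w = mean.intensity[sel]
            new_mz[i] = float(np.sum(mean.mz[sel] * w) / np.sum(w))
    order = np.argsort(new_mz)
    return FeatureList(
        new_mz[order],
        np.full(len(features), new_half_width_ppm),
        [features.labels[i] for i in order],
    )


def extract_feature_table(
    dataset: MSImageDataset,
    features: FeatureList,
    agg: str = "sum",
) -> np.ndarray:
    """(n_pixels, n_features) abundances: per pixel, the sum (default) or max
    of intensities with m/z inside each feature's half-open window."""
    lo, hi = features.windows()
    if lo.size and (lo[-1] > max((s.mz[-1] for s in dataset if s.mz.size), default=np.inf)):
        warnings.warn("some feature windows lie beyond the acquisition range")
    out = np.zeros((len(dataset.spectra), len(features)))
    for p, s in enumerate(dataset.spectra):
        if s.mz.size == 0:
            continue
        i0 = np.searchsorted(s.mz, lo, side="left")
        i1 = np.searchsorted(s.mz, hi, side="left")
        cum = np.concatenate([[0.0], np.cumsum(s.intensity)])
        if agg == "sum":
            out[p] = cum[i1] - cum[i0]
        elif agg == "max":
            out[p] = [s.intensity[a:b].max() if b > a else 0.0 for a, b in zip(i0, i1)]
        else:
            raise ValueError(f"unknown aggregation {agg!r}")
    return out


def feature_image(
    dataset: MSImageDataset,
    features: FeatureList,
    index: int,
    table: np.ndarray | None = None,
) -> np.ndarray:
    """Render one feature's abundances onto the section grid (absent pixels
    are NaN)."""
    if table is None:
        table = extract_feature_table(dataset, features.subset([index]))
        col = table[:, 0]
    else:
        col = table[:, index]
    img = np.full(dataset.shape, np.nan)
    rc = dataset.pixel_grid_index()
    img[rc[:, 0], rc[:, 1]] = col
    return img


def export_image(image: np.ndarray, path: str | Path) -> Path:
    """Save a feature image as PNG (intensity-scaled 8-bit) or, for any
    other suffix, as a tab-delimited grid."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        finite = np.nan_to_num(image, nan=0.0)
        top = finite.max()
        scaled = (finite / top * 255).astype(np.uint8) if top > 0 else finite.astype(np.uint8)
        Image.fromarray(scaled).save(path)
    else:
        np.savetxt(path, image, delimiter="\t", fmt="%.6g")
    return path


def hotspot_clip(image: np.ndarray, quantile: float = 0.99) -> np.ndarray:
    """Clip intensities above the given quantile to the quantile value."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    cap = np.nanquantile(image, quantile)
    return np.fmin(image, cap)


def median_denoise(image: np.ndarray, strength: str = "weak") -> np.ndarray:
    """Median-filter an ion image: 'weak' = one 3x3 pass, 'strong' = two 5x5
    passes, both with reflected borders.  NaN pixels (off-tissue) are treated
    as zero for filtering and restored afterwards."""
    nan_mask = np.isnan(image)
    work = np.where(nan_mask, 0.0, image)
    if strength == "weak":
        work = ndimage.median_filter(work, size=3, mode="reflect")
    elif strength == "strong":
        for _ in range(2):
            work = ndimage.median_filter(work, size=5, mode="reflect")
    else:
        raise ValueError("strength must be 'weak' or 'strong'")
    work[nan_mask] = np.nan
    return work


def deisotope(
    features: FeatureList,
    abundances: np.ndarray,
    delta_da: float = C13_DELTA,
    tol_ppm: float = 5.0,
    remove_salt_adducts: bool = False,
) -> FeatureList:
    """Drop redundant isotope (and optionally salt-adduct) features.

    A feature is removed when it lies ``delta_da`` (±tol) above a *more
    abundant* feature — the 13C satellite pattern.  With
    ``remove_salt_adducts`` the +21.98194 / +37.95588 Da offsets of a retained
    feature (Na/K replacing H) are removed as duplicates as well, regardless
    of relative abundance.
    """
    abundances = np.asarray(abundances, dtype=float)
    if abundances.shape != (len(features),):
        raise ValueError("need one total abundance per feature")
    mz = features.mz
    keep = np.ones(len(features), dtype=bool)
    for i in range(len(features)):
        tol = mz[i] * tol_ppm * 1e-6
        below = np.abs(mz[i] - mz - delta_da) <= tol
        if np.any(below & (abundances > abundances[i])):
            keep[i] = False
    if remove_salt_adducts:
        for i in range(len(features)):
            if not keep[i]:
                continue
            tol = mz[i] * tol_ppm * 1e-6
            for off in (NA_H_DELTA, K_H_DELTA):
                m = keep & (np.abs(mz[i] - mz - off) <= tol)
                if np.any(m):
                    keep[i] = False
                    break
    return features.subset(keep)


def remove_background_features(
    features: FeatureList,
    background_mz: Sequence[float],
    tol_ppm: float = 5.0,
) -> FeatureList:
    """Drop features matching known matrix/embedding ions within ±tol ppm."""
    if len(features) == 0 or len(background_mz) == 0:
        return features
    bg = np.asarray(background_mz, dtype=float)
    keep = np.array(
        [not np.any(np.abs(m - bg) <= m * tol_ppm * 1e-6) for m in features.mz]
    )
    return features.subset(keep)
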