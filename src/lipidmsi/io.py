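"""imzML-backed containers for mass spectrometry imaging sections.

A section is a raster of pixels, each carrying a centroided mass spectrum.
Storage follows the imzML convention: 1-based integer coordinates with x as
the column and y as the row, m/z in float64 (ppm-level fidelity), intensities
in float32.  Files are written in *processed* mode (one m/z axis per pixel),
which is what a per-pixel-calibrated FTICR acquisition produces.

Writing is deterministic: the imzML UUID is derived from a SHA-1 of the pixel
data rather than drawn at random, so identical datasets produce byte-identical
file pairs — a property the reproducibility tests rely on.
"""

from __future__ import annotations

import hashlib
import uuid as _uuid
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator
from unittest import mock

import numpy as np
import pandas as pd
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

__all__ = [
    "PixelSpectrum",
    "SectionMetadata",
    "MSImageDataset",
    "read_dataset",
    "write_dataset",
    "read_samples_file",
    "write_samples_file",
]

GROUP_LABELS = ("sham", "injured")


@dataclass
class PixelSpectrum:
    """Centroided spectrum of one pixel; coordinates are 1-based (x=col, y=row)."""

    mz: np.ndarray
    intensity: np.ndarray
    x: int
    y: int

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity arrays must be 1-D and equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"m/z axis not strictly increasing at pixel ({self.x}, {self.y})")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity at pixel ({self.x}, {self.y})")


@dataclass(frozen=True)
class SectionMetadata:
    """Identity of one imaged section within the cohort."""

    section_id: str
    animal_id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")


@dataclass
class MSImageDataset:
    """One section's pixel grid of spectra.

    ``shape`` is (n_rows, n_cols); pixel (x, y) maps to grid[y-1, x-1].
    """

    spectra: list[PixelSpectrum]
    shape: tuple[int, int]
    pitch_um: float = 50.0
    metadata: SectionMetadata | None = None
    mode: str = "processed"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        nrow, ncol = self.shape
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            if not (1 <= s.x <= ncol and 1 <= s.y <= nrow):
                raise ValueError(f"pixel ({s.x}, {s.y}) outside {ncol}x{nrow} grid")
            if (s.x, s.y) in seen:
                raise ValueError(f"duplicate pixel coordinate ({s.x}, {s.y})")
            seen.add((s.x, s.y))

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[PixelSpectrum]:
        return iter(self.spectra)

    def coords(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) coordinates, in pixel order."""
        return np.array([(s.x, s.y) for s in self.spectra], dtype=int)

    def pixel_grid_index(self) -> np.ndarray:
        """Flat pixel index → (row, col) grid index pairs (0-based)."""
        c = self.coords()
        return np.column_stack([c[:, 1] - 1, c[:, 0] - 1])

    def copy_with(self, **kw) -> "MSImageDataset":
        return replace(self, **kw)


def _content_uuid(dataset: MSImageDataset) -> _uuid.UUID:
    h = hashlib.sha1()
    for s in dataset.spectra:
        h.update(np.int64([s.x, s.y]).tobytes())
        h.update(s.mz.astype(np.float64).tobytes())
        h.update(s.intensity.astype(np.float32).tobytes())
    return _uuid.UUID(bytes=h.digest()[:16])


def write_dataset(dataset: MSImageDataset, path: str | Path) -> Path:
    """Write a dataset as an imzML/ibd pair (processed mode, centroided).

    Byte layout is deterministic for a fixed dataset: the file UUID is
    content-derived.
    """
    if len(dataset.spectra) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    uid = _content_uuid(dataset)
    # pyimzml draws uuid4 at writer construction; pin it for reproducibility.
    with mock.patch("uuid.uuid4", return_value=uid):
        with ImzMLWriter(
            str(path),
            mz_dtype=np.float64,
            intensity_dtype=np.float32,
            mode="processed",
            spec_type="centroid",
            polarity="positive",
        ) as writer:
            for s in dataset.spectra:
                writer.addSpectrum(s.mz, s.intensity, (s.x, s.y, 1))
    # the writer records the absolute path as the run id; normalize to the
    # stem so identical datasets yield identical bytes wherever written
    abs_stem = str(path.with_suffix(""))
    text = path.read_text()
    path.write_text(text.replace(f'id="{abs_stem}"', f'id="{path.stem}"'))
    return path


def read_dataset(
    path: str | Path,
    pitch_um: float = 50.0,
    metadata: SectionMetadata | None = None,
) -> MSImageDataset:
    """Load an imzML file (continuous or processed mode) losslessly.

    The grid shape is taken from the maximum pixel coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # pragma: no cover - depends on corruption kind
        raise ValueError(f"malformed imzML file {path}: {exc}") from exc
    spectra: list[PixelSpectrum] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        try:
            mz, inten = parser.getspectrum(i)
        except Exception as exc:
            raise ValueError(
                f"missing or malformed binary pair for spectrum {i} at ({x}, {y}) in {path}"
            ) from exc
        spectra.append(PixelSpectrum(np.asarray(mz), np.asarray(inten), int(x), int(y)))
    if not spectra:
        raise ValueError(f"{path} contains no spectra")
    mode = "processed"
    try:
        if "continuous" in parser.metadata.file_description.param_by_name:
            mode = "continuous"
    except AttributeError:
        pass
    nrow = max(s.y for s in spectra)
    ncol = max(s.x for s in spectra)
    return MSImageDataset(
        spectra=spectra,
        shape=(nrow, ncol),
        pitch_um=pitch_um,
        metadata=metadata,
        mode=mode,
    )


def write_samples_file(metadata: list[SectionMetadata], path: str | Path) -> Path:
    """Write the cohort samples table (section id, animal id, group) as TSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "section_id": [m.section_id for m in metadata],
            "animal_id": [m.animal_id for m in metadata],
            "group": [m.group for m in metadata],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_samples_file(path: str | Path) -> list[SectionMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"section_id", "animal_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"samples file {path} must have columns {sorted(required)}")
    return [
        SectionMetadata(row.section_id, row.animal_id, row.group)
        for row in df.itertuples()
    ]
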