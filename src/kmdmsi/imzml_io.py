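"""MSI dataset container and imzML round-trip.

A dataset is a pixel-indexed collection of mass spectra on a regular
raster.  Pixel coordinates are 0-based ``(x=column, y=row)`` with the
origin at the top-left; the imzML layer converts to/from the format's
1-based convention.  Both imzML dialects are supported: "processed"
(per-pixel m/z axis) and "continuous" (one shared axis).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["MSIDataset", "write_imzml", "read_imzml"]


@dataclass
class MSIDataset:
    """Pixel-indexed spectra with spatial coordinates.

    ``mzs[i]`` and ``intensities[i]`` belong to ``coordinates[i]``.
    ``shape`` is ``(height, width)`` of the raster grid.
    """

    mzs: List[np.ndarray]
    intensities: List[np.ndarray]
    coordinates: List[Tuple[int, int]]  # (x, y), 0-based
    shape: Tuple[int, int]
    pixel_size_um: float = 50.0
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.coordinates)
        if not (len(self.mzs) == len(self.intensities) == n):
            raise ValueError("mzs, intensities and coordinates lengths differ")
        for mz, it in zip(self.mzs, self.intensities):
            if len(mz) != len(it):
                raise ValueError("m/z and intensity arrays must have equal length")

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    def spectrum(self, x: int, y: int) -> Tuple[np.ndarray, np.ndarray]:
        """Spectrum at pixel (x, y); raises KeyError if absent."""
        try:
            i = self.coordinates.index((x, y))
        except ValueError:
            raise KeyError(f"no spectrum at pixel ({x}, {y})") from None
        return self.mzs[i], self.intensities[i]

    def tic(self) -> np.ndarray:
        """Per-pixel total ion current as an image grid (height x width)."""
        grid = np.zeros(self.shape)
        for (x, y), it in zip(self.coordinates, self.intensities):
            grid[y, x] = float(np.sum(it))
        return grid


def write_imzml(dataset: MSIDataset, path: str, mode: str = "processed") -> str:
    """Write a dataset to imzML (plus the paired .ibd binary file).

    ``mode`` is the imzML dialect: "processed" stores one m/z axis per
    pixel, "continuous" stores a single shared axis (all pixel axes
    must then be identical).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if dataset.n_pixels == 0:
        raise ValueError("refusing to write an empty dataset")
    if mode not in ("processed", "continuous"):
        raise ValueError(f"unknown imzML mode {mode!r}")
    if mode == "continuous":
        first = dataset.mzs[0]
        for mz in dataset.mzs[1:]:
            if len(mz) != len(first) or not np.allclose(mz, first, rtol=0, atol=0):
                raise ValueError("continuous mode requires an identical m/z axis per pixel")
    with ImzMLWriter(path, mode=mode) as writer:
        for mz, it, (x, y) in zip(dataset.mzs, dataset.intensities, dataset.coordinates):
            writer.addSpectrum(mz, it, (x + 1, y + 1, 1))
    return path


def read_imzml(path: str, pixel_size_um: float = 50.0) -> MSIDataset:
    """Read an imzML file (either dialect) into an :class:`MSIDataset`."""
    from pyimzml.ImzMLParser import ImzMLParser

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    parser = ImzMLParser(path)
    mzs: List[np.ndarray] = []
    intensities: List[np.ndarray] = []
    coordinates: List[Tuple[int, int]] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        try:
            mz, it = parser.getspectrum(i)
        except Exception as exc:  # pragma: no cover - corrupt input path
            raise ValueError(f"failed to parse spectrum for pixel index {i}") from exc
        mzs.append(np.asarray(mz, dtype=float))
        intensities.append(np.asarray(it, dtype=float))
        coordinates.append((int(x) - 1, int(y) - 1))
    if not coordinates:
        raise ValueError(f"{path} contains no spectra")
    width = max(x for x, _ in coordinates) + 1
    height = max(y for _, y in coordinates) + 1
    return MSIDataset(
        mzs=mzs,
        intensities=intensities,
        coordinates=coordinates,
        shape=(height, width),
        pixel_size_um=pixel_size_um,
        metadata={"source": path},
    )
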