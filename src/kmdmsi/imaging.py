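"""Ion-image reconstruction and region-enrichment statistics.

Images are ``(height, width)`` grids in the dataset's raster, origin
top-left, pixel (x, y) = (column, row), 0-based.  Reconstruction is
purely additive over aligned-matrix bins, so cloud/TIC images equal
the sum of their member ion images exactly; display-time clipping is
never applied to stored data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .spectral import AlignedPeakMatrix

__all__ = [
    "IonImage",
    "ion_image",
    "cloud_tic_image",
    "tic_image",
    "normalize_image",
    "region_enrichment",
    "save_image_png",
]


@dataclass
class IonImage:
    """A reconstructed intensity grid plus its provenance."""

    data: np.ndarray  # (height, width), intensities >= 0
    pixel_size_um: float = 50.0
    provenance: Dict = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def total(self) -> float:
        return float(self.data.sum())


def _bins_to_image(matrix: AlignedPeakMatrix, bin_idx: np.ndarray) -> np.ndarray:
    grid = np.zeros(matrix.shape)
    if bin_idx.size == 0:
        return grid
    per_pixel = matrix.intensities[bin_idx].sum(axis=0)
    for col, (x, y) in enumerate(matrix.pixels):
        grid[y, x] = per_pixel[col]
    return grid


def ion_image(
    matrix: AlignedPeakMatrix,
    target_mz: float,
    ppm_window: float = 3.0,
    mz_range: Tuple[float, float] = (200.0, 1400.0),
    pixel_size_um: float = 50.0,
) -> IonImage:
    """Image of the summed intensity within ±``ppm_window`` of ``target_mz``.

    A zero window selects only bins exactly equal to the target.
    Pixels with no matching bin are 0.
    """
    if ppm_window < 0:
        raise ValueError("ppm window must be >= 0")
    if not (mz_range[0] <= target_mz <= mz_range[1]):
        raise ValueError(
            f"target m/z {target_mz} outside instrument range {mz_range}"
        )
    if matrix.n_bins:
        dev = np.abs(matrix.mz - target_mz) / target_mz * 1e6
        idx = np.flatnonzero(dev <= ppm_window)
    else:
        idx = np.array([], dtype=int)
    grid = _bins_to_image(matrix, idx)
    return IonImage(
        data=grid,
        pixel_size_um=pixel_size_um,
        provenance={"target_mz": target_mz, "ppm_window": ppm_window, "n_bins": int(idx.size)},
    )


def cloud_tic_image(
    matrix: AlignedPeakMatrix,
    members: Sequence[int],
    pixel_size_um: float = 50.0,
    name: str = "cloud",
) -> IonImage:
    """Pixel-wise summed intensity of the member bins (deduplicated).

    Exactly additive: the image of a union of disjoint member sets is
    the sum of their images.
    """
    if len(members) == 0:
        raise ValueError("cloud has no members")
    idx = np.unique(np.asarray(members, dtype=int))
    if idx.min() < 0 or idx.max() >= matrix.n_bins:
        raise ValueError("member bin index out of range")
    return IonImage(
        data=_bins_to_image(matrix, idx),
        pixel_size_um=pixel_size_um,
        provenance={"members": idx.tolist(), "name": name},
    )


def tic_image(matrix: AlignedPeakMatrix, pixel_size_um: float = 50.0) -> IonImage:
    """Total-ion-current image over every bin."""
    return IonImage(
        data=_bins_to_image(matrix, np.arange(matrix.n_bins)),
        pixel_size_um=pixel_size_um,
        provenance={"name": "TIC"},
    )


def normalize_image(
    image: IonImage, mode: str = "none", tic: Optional[IonImage] = None
) -> IonImage:
    """Return the image unchanged ("none") or divided by per-pixel TIC.

    Zero-TIC pixels map to 0 (guarded division).
    """
    if mode == "none":
        return IonImage(image.data.copy(), image.pixel_size_um, dict(image.provenance))
    if mode == "per-pixel-TIC":
        if tic is None:
            raise ValueError("per-pixel-TIC normalization needs a TIC image")
        if tic.data.shape != image.data.shape:
            raise ValueError("TIC image shape mismatch")
        out = np.divide(
            image.data, tic.data, out=np.zeros_like(image.data), where=tic.data > 0
        )
        prov = dict(image.provenance)
        prov["normalization"] = "per-pixel-TIC"
        return IonImage(out, image.pixel_size_um, prov)
    raise ValueError(f"unknown normalization mode {mode!r}")


def region_enrichment(image: IonImage, mask: np.ndarray) -> float:
    """Fraction of the image's total intensity inside ``mask`` (0 if empty)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.data.shape:
        raise ValueError("mask shape does not match image shape")
    total = image.data.sum()
    if total <= 0:
        return 0.0
    return float(image.data[mask].sum() / total)


def save_image_png(image: IonImage, path: str, cmap: str = "viridis", clip_percentile: float = 99.0) -> str:
    """Render to PNG for display; clipping applies only to the rendering."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.percentile(image.data, clip_percentile) if image.data.any() else 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image.data, cmap=cmap, vmax=vmax if vmax > 0 else None, origin="upper")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return path
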