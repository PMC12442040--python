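"""Profile spectra to a consensus aligned peak matrix.

Stages: per-pixel peak picking (centroiding), optional simplified
lock-mass recalibration, cross-pixel centroid alignment, and TIC/mean
summaries.  Defaults follow the acquisition-processing settings of the
workflow this package implements: intensity threshold 200,000 counts,
prominence 0, minimum peak distance 5 data points, 3 ppm alignment
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PickingParams",
    "CentroidPeak",
    "pick_peaks",
    "pick_dataset",
    "RecalibrationSummary",
    "recalibrate",
    "AlignedPeakMatrix",
    "align_centroids",
    "tic_and_mean",
]


@dataclass(frozen=True)
class PickingParams:
    """Peak-picking parameters (threshold in counts, distance in data points)."""

    intensity_threshold: float = 200_000.0
    prominence: float = 0.0
    min_distance: int = 5

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity threshold must be >= 0")
        if self.min_distance < 1:
            raise ValueError("minimum peak distance must be >= 1")


@dataclass(frozen=True)
class CentroidPeak:
    mz: float
    intensity: float
    pixel: Tuple[int, int] = (0, 0)  # (x, y)


def _parabolic_refine(mz: np.ndarray, it: np.ndarray, i: int) -> Tuple[float, float]:
    """3-point parabolic interpolation of the apex around index ``i``.

    Returns the refined (m/z, intensity).  Falls back to the grid apex
    at array edges or for degenerate (flat) triplets.
    """
    if i == 0 or i == len(it) - 1:
        return float(mz[i]), float(it[i])
    y0, y1, y2 = float(it[i - 1]), float(it[i]), float(it[i + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:  # not a concave triplet
        return float(mz[i]), y1
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    if delta >= 0:
        mz_ref = mz[i] + delta * (mz[i + 1] - mz[i])
    else:
        mz_ref = mz[i] + delta * (mz[i] - mz[i - 1])
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(mz_ref), float(height)


def pick_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    params: PickingParams = PickingParams(),
    pixel: Tuple[int, int] = (0, 0),
) -> List[CentroidPeak]:
    """Centroid a profile spectrum.

    Local maxima with apex intensity >= threshold, prominence >= the
    configured prominence, and index separation >= ``min_distance``
    (ties resolved in favour of the higher peak, as in
    :func:`scipy.signal.find_peaks`); each apex is refined by 3-point
    parabolic interpolation.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size != intensity.size:
        raise ValueError("m/z and intensity arrays must have equal length")
    if mz.size < 3:
        return []
    kwargs = dict(height=params.intensity_threshold, distance=params.min_distance)
    if params.prominence > 0:
        kwargs["prominence"] = params.prominence
    idx, _props = find_peaks(intensity, **kwargs)
    out = []
    for i in idx:
        mz_ref, h_ref = _parabolic_refine(mz, intensity, int(i))
        out.append(CentroidPeak(mz=mz_ref, intensity=h_ref, pixel=pixel))
    return out


def pick_dataset(dataset, params: PickingParams = PickingParams()) -> List[List[CentroidPeak]]:
    """Pick peaks for every pixel of an :class:`~kmdmsi.imzml_io.MSIDataset`."""
    return [
        pick_peaks(mz, it, params, pixel=coord)
        for mz, it, coord in zip(dataset.mzs, dataset.intensities, dataset.coordinates)
    ]


@dataclass
class RecalibrationSummary:
    """Fit of the linear ppm drift model ppm(m) = a + b*m."""

    a: float = 0.0
    b: float = 0.0
    n_matched: int = 0
    residual_rms_ppm: float = 0.0
    applied: bool = False
    warning: Optional[str] = None


def recalibrate(
    peaks: Sequence[CentroidPeak],
    reference_mz: Sequence[float],
    tolerance_ppm: float = 5.0,
) -> Tuple[List[CentroidPeak], RecalibrationSummary]:
    """Lock-mass style linear recalibration.

    Matches observed centroids to reference m/z values within
    ``tolerance_ppm``, fits ppm(m) = a + b*m by least squares and
    applies the inverse correction to every peak.  Intensities are
    never modified.  With fewer than two reference matches the peaks
    are returned unchanged and the summary carries a warning.
    """
    refs = np.sort(np.asarray(reference_mz, dtype=float))
    matches: List[Tuple[float, float]] = []  # (observed, reference)
    for p in peaks:
        if refs.size == 0:
            break
        j = int(np.searchsorted(refs, p.mz))
        for k in (j - 1, j):
            if 0 <= k < refs.size:
                ppm = (p.mz - refs[k]) / refs[k] * 1e6
                if abs(ppm) <= tolerance_ppm:
                    matches.append((p.mz, float(refs[k])))
                    break
    if len(matches) < 2:
        summary = RecalibrationSummary(
            applied=False, n_matched=len(matches),
            warning="fewer than 2 reference matches; recalibration skipped",
        )
        return list(peaks), summary
    obs = np.array([m[0] for m in matches])
    ref = np.array([m[1] for m in matches])
    drift_ppm = (obs - ref) / ref * 1e6
    b, a = np.polyfit(obs, drift_ppm, 1)
    corrected = [
        CentroidPeak(mz=p.mz / (1.0 + (a + b * p.mz) * 1e-6), intensity=p.intensity, pixel=p.pixel)
        for p in peaks
    ]
    obs_corr = obs / (1.0 + (a + b * obs) * 1e-6)
    resid = (obs_corr - ref) / ref * 1e6
    summary = RecalibrationSummary(
        a=float(a), b=float(b), n_matched=len(matches),
        residual_rms_ppm=float(np.sqrt(np.mean(resid**2))), applied=True,
    )
    return corrected, summary


@dataclass
class AlignedPeakMatrix:
    """Consensus m/z bins x pixels intensity matrix.

    ``mz`` holds the intensity-weighted representative m/z per bin
    (strictly increasing); ``intensities`` is dense with absent peaks
    stored as 0.  ``pixels`` lists the (x, y) coordinate of each
    column; ``shape`` is the source raster grid.
    """

    mz: np.ndarray
    intensities: np.ndarray  # (n_bins, n_pixels)
    pixels: List[Tuple[int, int]]
    shape: Tuple[int, int]
    tolerance_ppm: float

    @property
    def n_bins(self) -> int:
        return int(self.mz.size)

    def bin_total_intensity(self) -> np.ndarray:
        return self.intensities.sum(axis=1)

    def nearest_bin(self, target_mz: float) -> int:
        return int(np.argmin(np.abs(self.mz - target_mz)))


def align_centroids(
    peak_lists: Sequence[Sequence[CentroidPeak]],
    tolerance_ppm: float = 3.0,
    shape: Optional[Tuple[int, int]] = None,
) -> AlignedPeakMatrix:
    """Align per-pixel centroids into consensus m/z bins.

    Single-linkage gap clustering on the pooled sorted centroid list: a
    new bin opens whenever the gap to the previous centroid exceeds
    ``tolerance_ppm`` (relative to the heavier member).  The bin
    representative is the intensity-weighted mean m/z; several peaks of
    one pixel falling into one bin are summed, conserving TIC.  The
    result is independent of the pixel ordering.
    """
    if len(peak_lists) < 1:
        raise ValueError("need at least one pixel")
    pixels = sorted({p.pixel for plist in peak_lists for p in plist} |
                    {plist[0].pixel for plist in peak_lists if plist})
    # Preserve one column per input list even when some lists are empty:
    # derive the pixel set from all peaks; empty pixels still get columns
    # if their coordinate appears nowhere else only when provided a shape.
    all_peaks = [p for plist in peak_lists for p in plist]
    if not all_peaks:
        mzs = np.array([])
        cols = [(0, 0)]
        return AlignedPeakMatrix(mzs, np.zeros((0, 1)), cols, shape or (1, 1), tolerance_ppm)
    col_index: Dict[Tuple[int, int], int] = {px: i for i, px in enumerate(pixels)}
    order = sorted(all_peaks, key=lambda p: p.mz)
    bins: List[List[CentroidPeak]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        gap_ppm = (cur.mz - prev.mz) / cur.mz * 1e6
        if gap_ppm > tolerance_ppm:
            bins.append([cur])
        else:
            bins[-1].append(cur)
    mz_repr = np.empty(len(bins))
    matrix = np.zeros((len(bins), len(pixels)))
    for bi, members in enumerate(bins):
        weights = np.array([m.intensity for m in members])
        mzv = np.array([m.mz for m in members])
        wsum = weights.sum()
        mz_repr[bi] = float((mzv * weights).sum() / wsum) if wsum > 0 else float(mzv.mean())
        for m in members:
            matrix[bi, col_index[m.pixel]] += m.intensity
    if shape is None:
        width = max(x for x, _ in pixels) + 1
        height = max(y for _, y in pixels) + 1
        shape = (height, width)
    return AlignedPeakMatrix(mz_repr, matrix, pixels, shape, tolerance_ppm)


def tic_and_mean(matrix: AlignedPeakMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel TIC vector and mean spectrum (average over pixels per bin)."""
    if matrix.n_bins == 0:
        return np.zeros(len(matrix.pixels)), np.array([])
    tic = matrix.intensities.sum(axis=0)
    mean = matrix.intensities.mean(axis=1)
    return tic, mean
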