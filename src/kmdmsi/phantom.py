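"""Ground-truthed phantom MSI datasets.

Generates a schematic "phantom organism" — a 2D label image with
organ-shaped regions (cuticle ring, brain, chelicerae, heart, ovary,
silk glands, digestive tubules on a gelatin background) — and a forward
model of positive-mode MALDI FT-ICR acquisition over it: Gaussian
profile peaks whose width follows the FT-ICR 1/m resolving-power law,
ppm-scale mass jitter, H/Na/K adduct distributions, carbon-13
isotopologues, multiplicative log-normal intensity noise, and CHCA
matrix-cluster ions present in every pixel.

Every simulated peak carries a ground-truth record, so downstream
stages (picking, alignment, KMD grouping, collapsing, annotation,
imaging) can be scored exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .imzml_io import MSIDataset
from .masses import (
    C13_MASS_SHIFT,
    C13_NATURAL_ABUNDANCE,
    get_adduct,
    ion_mz,
    monoisotopic_mass,
    parse_composition,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "SpeciesAssignment",
    "default_assignments",
    "InstrumentModel",
    "CHCA_FORMULA",
    "matrix_ion_set",
    "simulate_pixel_spectrum",
    "simulate_dataset",
]

#: Organ regions of the phantom, in paint order (later regions only
#: claim pixels still free).  Label 0 is the gelatin background.
REGION_NAMES = (
    "cuticle",
    "brain",
    "chelicerae",
    "heart",
    "ovary",
    "silk_glands",
    "digestive_tubules",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the phantom raster.

    The anatomy is drawn in fractional coordinates so any grid from
    16x16 upwards produces the same layout; the default 64x64 grid at
    50 um pitch corresponds to a ~3 mm body.
    """

    height: int = 64
    width: int = 64
    pixel_size_um: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom grid must be at least 16x16")


@dataclass
class Phantom:
    spec: PhantomSpec
    labels: np.ndarray  # int grid, 0 = background
    region_masks: Dict[str, np.ndarray]  # organ name -> boolean grid
    sub_masks: Dict[str, np.ndarray]  # e.g. ovary_shell / ovary_core

    def mask(self, name: str) -> np.ndarray:
        if name in self.region_masks:
            return self.region_masks[name]
        if name in self.sub_masks:
            return self.sub_masks[name]
        raise KeyError(f"unknown region {name!r}")

    @property
    def background(self) -> np.ndarray:
        return self.labels == 0


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy * h) / (ry * h)) ** 2 + ((xx - cx * w) / (rx * w)) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Draw the phantom label image.

    Deterministic (the geometry is fixed; the seed only matters for the
    later acquisition simulation).  Returns the label grid plus boolean
    masks per organ region and the ovary shell/core sub-masks used for
    region-dependent adduct weighting.
    """
    h, w = spec.height, spec.width
    prosoma = _ellipse(h, w, 0.50, 0.22, 0.145, 0.16)
    abdomen = _ellipse(h, w, 0.50, 0.66, 0.27, 0.25)
    body = prosoma | abdomen
    rim = max(1, round(0.03 * min(h, w)))
    interior = ndimage.binary_erosion(body, iterations=rim)
    cuticle = body & ~interior

    shapes = {
        "cuticle": cuticle,
        "brain": _ellipse(h, w, 0.50, 0.20, 0.055, 0.055),
        "chelicerae": _ellipse(h, w, 0.50, 0.13, 0.045, 0.045),
        "heart": _ellipse(h, w, 0.33, 0.66, 0.045, 0.11),
        "ovary": _ellipse(h, w, 0.56, 0.68, 0.105, 0.15),
        "silk_glands": (
            _ellipse(h, w, 0.60, 0.84, 0.05, 0.045)
            | _ellipse(h, w, 0.70, 0.78, 0.045, 0.04)
        ),
        "digestive_tubules": (
            _ellipse(h, w, 0.40, 0.52, 0.055, 0.055)
            | _ellipse(h, w, 0.42, 0.80, 0.05, 0.05)
            | _ellipse(h, w, 0.70, 0.55, 0.05, 0.05)
        ),
    }

    labels = np.zeros((h, w), dtype=int)
    masks: Dict[str, np.ndarray] = {}
    free = body.copy()
    for lab, name in enumerate(REGION_NAMES, start=1):
        m = shapes[name] & free if name != "cuticle" else shapes[name]
        masks[name] = m
        labels[m] = lab
        free &= ~m
        if not m.any():
            raise ValueError(f"region {name!r} does not fit a {h}x{w} grid")

    shell_rim = max(1, round(0.025 * min(h, w)))
    ovary_core = ndimage.binary_erosion(masks["ovary"], iterations=shell_rim)
    ovary_core &= masks["ovary"]
    ovary_shell = masks["ovary"] & ~ovary_core
    if not ovary_core.any() or not ovary_shell.any():
        raise ValueError(f"ovary shell/core split does not fit a {h}x{w} grid")
    sub = {"ovary_shell": ovary_shell, "ovary_core": ovary_core}
    return Phantom(spec=spec, labels=labels, region_masks=masks, sub_masks=sub)


@dataclass(frozen=True)
class SpeciesAssignment:
    """One species planted in one region.

    ``adduct_weights`` gives the relative intensity of the [M+H]+,
    [M+Na]+ and [M+K]+ forms; ``base_intensity`` (counts) scales the
    whole family.  ``family`` tags CH2-homologous groups so recovery of
    series can be scored against ground truth.
    """

    region: str
    species: str
    formula: str
    adduct_weights: Mapping[str, float]
    base_intensity: float
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base intensity must be positive")
        ws = dict(self.adduct_weights)
        if not ws or min(ws.values()) < 0 or max(ws.values()) <= 0:
            raise ValueError("adduct weights must be non-negative with one positive")
        parse_composition(self.formula)  # validates


def default_assignments() -> List[SpeciesAssignment]:
    """The bundled study conditions.

    Triacyl-/monoacylglyceride homologous series in the cuticle,
    phosphatidic acids in the ovary with potassium-weighted adducts on
    the shell and sodium-weighted in the core, phosphatidylcholines in
    brain/heart/digestive tubules, lysophospholipids in the ovary,
    sterols in the chelicerae and an acylcarnitine in the silk glands.
    Base intensities sit in the 1e8-1e10 counts range typical of
    averaged MALDI FT-ICR lipid signals.
    """
    na_major = {"[M+H]+": 0.05, "[M+Na]+": 1.0, "[M+K]+": 0.4}
    k_shell = {"[M+H]+": 0.05, "[M+Na]+": 0.1, "[M+K]+": 1.0}
    na_core = {"[M+H]+": 0.05, "[M+Na]+": 1.0, "[M+K]+": 0.1}
    h_major = {"[M+H]+": 1.0, "[M+Na]+": 0.3, "[M+K]+": 0.1}
    mixed = {"[M+H]+": 0.4, "[M+Na]+": 1.0, "[M+K]+": 0.6}

    out: List[SpeciesAssignment] = []
    # Cuticle: TG series (one horizontal CH2 family per double-bond count,
    # vertical H2 relations between them).
    for sp, f, inten, fam in [
        ("TG 50:3", "C53H96O6", 5.0e9, "TG:3"),
        ("TG 52:3", "C55H100O6", 8.7e9, "TG:3"),
        ("TG 54:3", "C57H104O6", 2.6e9, "TG:3"),
        ("TG 50:2", "C53H98O6", 6.2e9, "TG:2"),
        ("TG 52:2", "C55H102O6", 7.8e9, "TG:2"),
    ]:
        out.append(SpeciesAssignment("cuticle", sp, f, na_major, inten, fam))
    # Ovary: PA species, K-weighted on the shell, Na-weighted in the core.
    for sp, f, inten, fam in [
        ("PA 36:2", "C39H73O8P", 3.2e10, "PA:2"),
        ("PA 38:2", "C41H77O8P", 3.0e9, "PA:2"),
        ("PA 36:3", "C39H71O8P", 2.0e10, "PA:3"),
        ("PA 38:3", "C41H75O8P", 5.8e9, "PA:3"),
    ]:
        out.append(SpeciesAssignment("ovary_shell", sp, f, k_shell, inten, fam))
        out.append(SpeciesAssignment("ovary_core", sp, f, na_core, inten, fam))
    # Ovary lysophospholipids.
    out.append(
        SpeciesAssignment(
            "ovary", "LPC O-16:0", "C24H52NO6P",
            {"[M+H]+": 0.2, "[M+Na]+": 1.0, "[M+K]+": 0.1}, 8.6e10, "LPC-O:0",
        )
    )
    out.append(SpeciesAssignment("ovary", "LPE O-19:2", "C24H48NO6P", h_major, 1.8e10, "LPE-O:2"))
    # Brain: PC series plus a polyunsaturated PA.
    for sp, f, inten in [
        ("PC 34:1", "C42H82NO8P", 7.7e10),
        ("PC 35:1", "C43H84NO8P", 2.3e9),
        ("PC 36:1", "C44H86NO8P", 1.8e9),
    ]:
        out.append(SpeciesAssignment("brain", sp, f, mixed, inten, "PC:1"))
    out.append(
        SpeciesAssignment(
            "brain", "PA 38:4", "C41H73O8P",
            {"[M+H]+": 0.05, "[M+Na]+": 0.8, "[M+K]+": 1.0}, 1.2e10, "PA:4",
        )
    )
    # Heart and digestive tubules share the PC :2 CH2 family.
    out.append(SpeciesAssignment("heart", "PC 34:2", "C42H80NO8P", mixed, 2.5e10, "PC:2"))
    out.append(SpeciesAssignment("digestive_tubules", "PC 36:2", "C44H84NO8P", mixed, 1.2e10, "PC:2"))
    # Chelicerae sterols.
    st = {"[M+H]+": 0.05, "[M+Na]+": 1.0, "[M+K]+": 0.1}
    out.append(SpeciesAssignment("chelicerae", "ST 26:2;O4", "C26H42O4", st, 5.4e8, "ST:2;O4"))
    out.append(SpeciesAssignment("chelicerae", "ST 28:2;O4", "C28H46O4", st, 7.7e8, "ST:2;O4"))
    # Silk glands: medium-chain acylcarnitine.
    out.append(SpeciesAssignment("silk_glands", "CAR 6:0", "C13H25NO4", h_major, 1.0e9, "CAR"))
    return out


@dataclass(frozen=True)
class InstrumentModel:
    """FT-ICR-like acquisition parameters.

    Resolving power is anchored at ``resolving_power`` FWHM at m/z 400
    and scales as R(m) = R0 * 400 / m, so peak FWHM grows quadratically
    with m/z.  ``ppm_sigma`` is the 1-sigma mass-accuracy jitter; the
    default of 1 ppm keeps 99.7% of centroids within a 3 ppm accuracy
    envelope.
    """

    mz_min: float = 200.0
    mz_max: float = 1400.0
    resolving_power: float = 300_000.0
    reference_mz: float = 400.0
    ppm_sigma: float = 1.0
    points_per_fwhm: int = 6
    noise_cv: float = 0.15
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz range must satisfy min < max")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")

    def fwhm(self, mz: float) -> float:
        """Peak FWHM (Da) at ``mz`` under the 1/m resolving-power law."""
        r = self.resolving_power * self.reference_mz / mz
        return mz / r


CHCA_FORMULA = "C10H7NO3"


def matrix_ion_set(matrix_formula: str = CHCA_FORMULA) -> List[float]:
    """m/z of the six matrix cluster ions injected into every pixel.

    [M+Na]+, [M+K]+, [2M+H]+, [2M+Na]+, [2M+K]+ and [3M+H]+ of the
    MALDI matrix (CHCA by default).  The protonated monomer is omitted
    because it sits below the 200-1400 acquisition window.  These mimic
    the recurrent, non-CH2-repeating background clusters that dominate
    the mean spectrum of a real acquisition.
    """
    comp = parse_composition(matrix_formula)
    dimer = {k: 2 * v for k, v in comp.items()}
    trimer = {k: 3 * v for k, v in comp.items()}
    return [
        ion_mz(comp, "[M+Na]+"),
        ion_mz(comp, "[M+K]+"),
        ion_mz(dimer, "[M+H]+"),
        ion_mz(dimer, "[M+Na]+"),
        ion_mz(dimer, "[M+K]+"),
        ion_mz(trimer, "[M+H]+"),
    ]


#: Apex heights of the matrix ions, order-matched to matrix_ion_set().
MATRIX_ION_INTENSITIES = (4.0e9, 2.5e9, 1.2e9, 1.5e9, 8.0e8, 6.0e8)

#: Isotopologues simulated per ion (monoisotopic + two heavy).
N_ISOTOPOLOGUES = 3


def _binomial_isotopes(n_carbon: int, n: int = N_ISOTOPOLOGUES) -> List[float]:
    from scipy.stats import binom

    p = C13_NATURAL_ABUNDANCE
    mono = binom.pmf(0, n_carbon, p)
    return [float(binom.pmf(k, n_carbon, p) / mono) for k in range(n)]


def _expand_ions(
    assignments: Sequence[SpeciesAssignment],
) -> List[Tuple[SpeciesAssignment, str, int, float, float]]:
    """Expand assignments into (assignment, adduct, isotopologue, mz, weight)."""
    rows = []
    for a in assignments:
        comp = parse_composition(a.formula)
        n_carbon = comp.get("C", 0) + comp.get("12C", 0)
        iso_ab = _binomial_isotopes(n_carbon)
        for adduct, w in a.adduct_weights.items():
            if w <= 0:
                continue
            base_mz = ion_mz(comp, adduct)
            for k, ab in enumerate(iso_ab):
                rows.append((a, get_adduct(adduct).name, k, base_mz + k * C13_MASS_SHIFT, w * ab))
    return rows


def _profile_from_peaks(
    peaks: Sequence[Tuple[float, float]],
    instrument: InstrumentModel,
    halfwidth_fwhm: float = 3.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render Gaussian peaks as a sparse profile (union of peak windows).

    Only windows of ±``halfwidth_fwhm`` FWHM around each centroid are
    sampled, at ``points_per_fwhm`` points per FWHM; overlapping
    windows are merged onto a common grid.  The gaps between windows
    carry no samples, which mirrors a reduced/processed profile export.
    """
    if not peaks:
        return np.array([]), np.array([])
    intervals = []
    for mz, _h in peaks:
        f = instrument.fwhm(mz)
        intervals.append((mz - halfwidth_fwhm * f, mz + halfwidth_fwhm * f, f))
    intervals.sort()
    merged: List[List[float]] = []
    for lo, hi, f in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = min(merged[-1][2], f)
        else:
            merged.append([lo, hi, f])
    grids = []
    for lo, hi, f in merged:
        step = f / instrument.points_per_fwhm
        n = max(2, int(math.ceil((hi - lo) / step)) + 1)
        grids.append(np.linspace(lo, hi, n))
    axis = np.concatenate(grids)
    signal = np.full_like(axis, float(instrument.baseline))
    for mz, h in peaks:
        f = instrument.fwhm(mz)
        sigma = f / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        lo, hi = mz - halfwidth_fwhm * f, mz + halfwidth_fwhm * f
        i0, i1 = np.searchsorted(axis, [lo, hi])
        window = axis[i0:i1]
        signal[i0:i1] += h * np.exp(-0.5 * ((window - mz) / sigma) ** 2)
    return axis, signal


def simulate_pixel_spectrum(
    assignments: Sequence[SpeciesAssignment],
    instrument: InstrumentModel,
    rng: np.random.Generator,
    matrix_ions: Optional[Sequence[float]] = None,
    matrix_intensities: Sequence[float] = MATRIX_ION_INTENSITIES,
) -> Tuple[np.ndarray, np.ndarray, List[dict]]:
    """Forward-model one pixel.

    Each (species, adduct, isotopologue) contributes one Gaussian peak
    centred at the theoretical m/z perturbed by Normal(0, ppm_sigma)
    jitter, with height = base x adduct weight x isotopologue abundance
    x log-normal noise.  Matrix ions are always added.  Returns the
    profile arrays and the list of ground-truth peak records.
    """
    if matrix_ions is None:
        matrix_ions = matrix_ion_set()
    log_sigma = math.sqrt(math.log(1.0 + instrument.noise_cv**2)) if instrument.noise_cv > 0 else 0.0

    peaks: List[Tuple[float, float]] = []
    truth: List[dict] = []

    def add(mz: float, height: float, species: str, adduct: str, iso: int, region: str, family):
        eps = rng.normal(0.0, instrument.ppm_sigma) if instrument.ppm_sigma > 0 else 0.0
        obs = mz * (1.0 + eps * 1e-6)
        noise = math.exp(rng.normal(0.0, log_sigma)) if log_sigma > 0 else 1.0
        h = height * noise
        if not (instrument.mz_min <= mz <= instrument.mz_max):
            logger.warning("ion %s %s at m/z %.4f outside instrument range; skipped", species, adduct, mz)
            return
        peaks.append((obs, h))
        truth.append(
            dict(mz_true=mz, mz_observed=obs, intensity=h, species=species,
                 adduct=adduct, isotopologue=iso, region=region, family=family)
        )

    for mz, h in zip(matrix_ions, matrix_intensities):
        add(mz, h, "matrix", "cluster", 0, "everywhere", None)
    for a, adduct, iso, mz, weight in _expand_ions(assignments):
        add(mz, a.base_intensity * weight, a.species, adduct, iso, a.region, a.family)

    axis, signal = _profile_from_peaks(peaks, instrument)
    return axis, signal, truth


def simulate_dataset(
    phantom: Phantom,
    assignments: Optional[Sequence[SpeciesAssignment]] = None,
    instrument: InstrumentModel = InstrumentModel(),
    seed: int = 0,
) -> Tuple[MSIDataset, pd.DataFrame]:
    """Simulate one spectrum per phantom pixel.

    Returns the dataset and a ground-truth table with one row per
    simulated peak (pixel x/y, true and observed m/z, intensity,
    species, adduct, isotopologue index, region, CH2 family).
    Reproducible: the same seed yields an identical dataset.
    """
    if assignments is None:
        assignments = default_assignments()
    for a in assignments:
        phantom.mask(a.region)  # validates region names up front

    h, w = phantom.labels.shape
    matrix_ions = matrix_ion_set()
    by_region: Dict[str, List[SpeciesAssignment]] = {}
    for a in assignments:
        by_region.setdefault(a.region, []).append(a)

    # Per-pixel assignment lists resolved through the (sub-)masks once.
    masks = {name: phantom.mask(name) for name in by_region}

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(h * w)

    mzs, intens, coords = [], [], []
    truth_rows: List[dict] = []
    for y in range(h):
        for x in range(w):
            pixel_assign = [a for name, m in masks.items() if m[y, x] for a in by_region[name]]
            rng = np.random.default_rng(children[y * w + x])
            axis, signal, truth = simulate_pixel_spectrum(
                pixel_assign, instrument, rng, matrix_ions=matrix_ions
            )
            mzs.append(axis)
            intens.append(signal)
            coords.append((x, y))
            for rec in truth:
                rec["x"] = x
                rec["y"] = y
            truth_rows.extend(truth)

    dataset = MSIDataset(
        mzs=mzs,
        intensities=intens,
        coordinates=coords,
        shape=(h, w),
        pixel_size_um=phantom.spec.pixel_size_um,
        metadata={"seed": seed, "generator": "kmdmsi.phantom"},
    )
    truth_df = pd.DataFrame(truth_rows)
    return dataset, truth_df
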