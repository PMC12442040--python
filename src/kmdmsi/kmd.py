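"""Kendrick mass defect space: projection, filtering and grouping.

Consensus ions are projected to (m/z, KM, KMD) points; the lipid
window keeps KMD in [0.10, 0.50] and m/z in [200, 1400].  Points are
then grouped three ways:

* horizontal CH2 series — homologous families whose members differ by
  integer multiples of 14.01565 Da (constant KMD);
* vertical series — nearly isobaric ions differing by H2
  (unsaturation) or O (oxidation) steps;
* adduct/isotopologue collapsing — Na/K adducts and heavy-carbon
  isotopologues of one species merged onto the protonated
  monoisotopic representative.

Matrix-cluster ions are flagged beforehand and excluded from series
building, mirroring the grey-dot removal of background clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import masses
from .masses import DEFAULT_KENDRICK, KendrickParams, kendrick_mass, kendrick_mass_defect
from .spectral import AlignedPeakMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KMDWindow",
    "compute_kmd_points",
    "filter_window",
    "SeriesGroup",
    "chain_ch2_series",
    "chain_vertical",
    "ADDUCT_ISOTOPE_SHIFTS",
    "collapse_adducts_isotopes",
    "CloudSelection",
    "select_cloud",
    "flag_matrix_points",
]

CH2_MASS = 14.01565

#: Exact step masses for vertical grouping.
VERTICAL_STEPS: Dict[str, float] = {
    "H2": 2 * masses.ATOMIC_MASSES["H"],
    "O": masses.ATOMIC_MASSES["O"],
}

#: m/z shifts removed when collapsing onto the protonated monoisotopic
#: species: metal-for-proton exchanges and the 13C substitution.
ADDUCT_ISOTOPE_SHIFTS: Dict[str, float] = {
    "Na-H": masses.ATOMIC_MASSES["Na"] - masses.ATOMIC_MASSES["H"],
    "K-H": masses.ATOMIC_MASSES["K"] - masses.ATOMIC_MASSES["H"],
    "13C": masses.C13_MASS_SHIFT,
}


@dataclass(frozen=True)
class KMDWindow:
    """Rectangular lipid-of-interest window in (m/z, KMD) space."""

    kmd_min: float = 0.10
    kmd_max: float = 0.50
    mz_min: float = 200.0
    mz_max: float = 1400.0

    def __post_init__(self) -> None:
        if self.kmd_min >= self.kmd_max or self.mz_min >= self.mz_max:
            raise ValueError("window bounds must satisfy min < max on both axes")


def compute_kmd_points(
    matrix: AlignedPeakMatrix, params: KendrickParams = DEFAULT_KENDRICK
) -> pd.DataFrame:
    """One Kendrick point per consensus bin.

    Columns: ``bin`` (index into the aligned matrix), ``mz``, ``km``,
    ``kmd``, ``intensity`` (summed over pixels).
    """
    if matrix.n_bins == 0:
        raise ValueError("aligned peak matrix is empty")
    mz = matrix.mz
    km = mz * params.nominal_mass / params.exact_mass
    kmd = np.array([kendrick_mass_defect(v, params.rounding) for v in km])
    return pd.DataFrame(
        {
            "bin": np.arange(matrix.n_bins),
            "mz": mz,
            "km": km,
            "kmd": kmd,
            "intensity": matrix.bin_total_intensity(),
        }
    )


def kmd_points_from_mz(
    mz_values: Sequence[float],
    intensities: Optional[Sequence[float]] = None,
    params: KendrickParams = DEFAULT_KENDRICK,
) -> pd.DataFrame:
    """Kendrick points straight from an m/z list (no imaging context)."""
    mz = np.asarray(mz_values, dtype=float)
    inten = np.ones_like(mz) if intensities is None else np.asarray(intensities, float)
    km = mz * params.nominal_mass / params.exact_mass
    kmd = np.array([kendrick_mass_defect(v, params.rounding) for v in km])
    return pd.DataFrame(
        {"bin": np.arange(mz.size), "mz": mz, "km": km, "kmd": kmd, "intensity": inten}
    )


def filter_window(points: pd.DataFrame, window: KMDWindow = KMDWindow()) -> pd.DataFrame:
    """Keep points inside the window (bounds inclusive); order preserved.

    Idempotent: filtering a filtered frame changes nothing.
    """
    keep = (
        (points["kmd"] >= window.kmd_min)
        & (points["kmd"] <= window.kmd_max)
        & (points["mz"] >= window.mz_min)
        & (points["mz"] <= window.mz_max)
    )
    return points.loc[keep]


@dataclass
class SeriesGroup:
    """A grouped set of Kendrick points.

    ``members`` are point-frame index labels sorted by m/z;
    ``orientation`` is one of horizontal-CH2, vertical-H2, vertical-O
    or adduct-collapsed; ``canonical`` is the lowest-m/z member.
    """

    members: List[int]
    orientation: str
    step_formula: str
    step_mass: float
    canonical: int


class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {i: i for i in items}

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller label wins as root
            lo, hi = (ri, rj) if ri < rj else (rj, ri)
            self.parent[hi] = lo


def _step_edges(
    mz: np.ndarray,
    step_mass: float,
    ppm_tolerance: float,
    k_max: int,
) -> List[Tuple[int, int, int, float]]:
    """All pairs (i, j, k, |ppm|) with mz[j] - mz[i] ~ k * step.

    ``mz`` must be ascending; the ppm deviation is measured against the
    heavier member of the pair.
    """
    edges = []
    n = mz.size
    reach = k_max * step_mass + 1.0
    for i in range(n):
        for j in range(i + 1, n):
            delta = mz[j] - mz[i]
            if delta > reach:
                break
            k = int(round(delta / step_mass))
            if k < 1 or k > k_max:
                continue
            dev_ppm = abs(delta - k * step_mass) / mz[j] * 1e6
            if dev_ppm <= ppm_tolerance:
                edges.append((i, j, k, dev_ppm))
    return edges


def _chain(
    points: pd.DataFrame,
    step_formula: str,
    step_mass: float,
    ppm_tolerance: float,
    k_max: int,
    orientation: str,
    span_limit: Optional[float] = None,
    exclude: Optional[pd.Series] = None,
) -> Tuple[List[SeriesGroup], List[int]]:
    sub = points if exclude is None else points.loc[~exclude.reindex(points.index, fill_value=False)]
    sub = sub.sort_values("mz")
    labels = list(sub.index)
    mz = sub["mz"].to_numpy()
    uf = _UnionFind(range(len(labels)))
    span_lo = {i: mz[i] for i in range(len(labels))}
    span_hi = {i: mz[i] for i in range(len(labels))}
    edges = _step_edges(mz, step_mass, ppm_tolerance, k_max)
    edges.sort(key=lambda e: (e[3], e[0], e[1]))  # best matches first; deterministic
    for i, j, _k, _ppm in edges:
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            continue
        if span_limit is not None:
            lo = min(span_lo[ri], span_lo[rj])
            hi = max(span_hi[ri], span_hi[rj])
            if hi - lo > span_limit:
                continue
        uf.union(i, j)
        r = uf.find(i)
        span_lo[r] = min(span_lo[ri], span_lo[rj])
        span_hi[r] = max(span_hi[ri], span_hi[rj])
    components: Dict[int, List[int]] = {}
    for i in range(len(labels)):
        components.setdefault(uf.find(i), []).append(i)
    groups, singletons = [], []
    for comp in components.values():
        members = sorted((labels[i] for i in comp), key=lambda lab: points.at[lab, "mz"])
        if len(members) >= 2:
            groups.append(
                SeriesGroup(
                    members=members,
                    orientation=orientation,
                    step_formula=step_formula,
                    step_mass=step_mass,
                    canonical=members[0],
                )
            )
        else:
            singletons.append(members[0])
    groups.sort(key=lambda g: points.at[g.canonical, "mz"])
    return groups, sorted(singletons)


def chain_ch2_series(
    points: pd.DataFrame,
    ppm_tolerance: float = 2.0,
    k_max: int = 6,
    exclude: Optional[pd.Series] = None,
) -> Tuple[List[SeriesGroup], List[int]]:
    """Horizontal CH2 homologous series.

    Connects points whose mass difference is an integer multiple (up to
    ``k_max``) of 14.01565 Da within ``ppm_tolerance`` (measured
    against the heavier member); series are the connected components
    with at least two members, singletons are returned separately.
    ``exclude`` is a boolean mask (e.g. matrix flags) of points barred
    from chaining.
    """
    return _chain(points, "CH2", CH2_MASS, ppm_tolerance, k_max, "horizontal-CH2", exclude=exclude)


def chain_vertical(
    points: pd.DataFrame,
    step_formula: str = "H2",
    ppm_tolerance: float = 2.0,
    span_steps: int = 3,
    exclude: Optional[pd.Series] = None,
) -> Tuple[List[SeriesGroup], List[int]]:
    """Vertical series: near-isobars differing by H2 or O steps.

    Components are kept within a total m/z span of ``span_steps`` step
    masses, reflecting that vertical groups collect close unsaturation/
    oxidation variants rather than long ladders.
    """
    if step_formula not in VERTICAL_STEPS:
        raise ValueError(
            f"unknown vertical step {step_formula!r}; expected one of {sorted(VERTICAL_STEPS)}"
        )
    step = VERTICAL_STEPS[step_formula]
    span_limit = span_steps * step * (1 + 1e-6)
    return _chain(
        points, step_formula, step, ppm_tolerance, span_steps,
        f"vertical-{step_formula}", span_limit=span_limit, exclude=exclude,
    )


def collapse_adducts_isotopes(
    points: pd.DataFrame,
    shifts: Mapping[str, float] = ADDUCT_ISOTOPE_SHIFTS,
    ppm_tolerance: float = 2.0,
) -> pd.DataFrame:
    """Collapse adduct/isotopologue families onto one canonical point.

    For each point a partner is sought at m/z minus each shift (within
    ``ppm_tolerance`` of the heavier member); links are merged with
    union-find and each family is represented by its lowest-m/z member,
    interpreted as the protonated monoisotopic species.  When two
    candidate partners fall inside the tolerance the smaller |ppm| wins
    (logged).  Total intensity is conserved: the canonical point
    carries the family's summed intensity.

    Returns a frame indexed like ``points`` with columns ``canonical``
    (index label of the family representative), ``canonical_mz`` and
    ``collapsed_intensity`` (family sum, repeated on every member).
    """
    order = points.sort_values("mz")
    labels = list(order.index)
    mz = order["mz"].to_numpy()
    uf = _UnionFind(range(len(labels)))
    for i in range(len(labels)):
        for name, shift in shifts.items():
            target = mz[i] - shift
            if target <= 0:
                continue
            j = int(np.searchsorted(mz, target))
            best, best_ppm = None, None
            for cand in (j - 1, j, j + 1):
                if 0 <= cand < len(labels) and cand != i:
                    dev = abs(mz[cand] - target) / mz[i] * 1e6
                    if dev <= ppm_tolerance and (best_ppm is None or dev < best_ppm):
                        best, best_ppm = cand, dev
            if best is not None:
                if best_ppm is not None and best_ppm > 0:
                    logger.debug(
                        "collapse: %.5f -[%s]-> partner %.5f (%.2f ppm)",
                        mz[i], name, mz[best], best_ppm,
                    )
                uf.union(i, best)
    roots: Dict[int, List[int]] = {}
    for i in range(len(labels)):
        roots.setdefault(uf.find(i), []).append(i)
    canonical = pd.Series(index=points.index, dtype=object)
    collapsed_int = pd.Series(index=points.index, dtype=float)
    canonical_mz = pd.Series(index=points.index, dtype=float)
    for comp in roots.values():
        members = [labels[i] for i in comp]
        canon = min(members, key=lambda lab: points.at[lab, "mz"])
        total = float(points.loc[members, "intensity"].sum())
        for lab in members:
            canonical.at[lab] = canon
            collapsed_int.at[lab] = total
            canonical_mz.at[lab] = float(points.at[canon, "mz"])
    return pd.DataFrame(
        {"canonical": canonical, "canonical_mz": canonical_mz, "collapsed_intensity": collapsed_int}
    )


@dataclass
class CloudSelection:
    """An analyst-drawn region of (m/z, KMD) space and its members."""

    name: str
    geometry: object  # (mz_min, mz_max, kmd_min, kmd_max) or [(mz, kmd), ...]
    members: List[int]


def select_cloud(points: pd.DataFrame, geometry, name: str = "cloud") -> CloudSelection:
    """Select the points inside a rectangle or polygon (boundary inclusive).

    ``geometry`` is either ``(mz_min, mz_max, kmd_min, kmd_max)`` or a
    polygon as a vertex list ``[(mz, kmd), ...]`` with at least three
    vertices.
    """
    if isinstance(geometry, (tuple, list)) and len(geometry) == 4 and np.isscalar(geometry[0]):
        mz_min, mz_max, kmd_min, kmd_max = map(float, geometry)
        if mz_min >= mz_max or kmd_min >= kmd_max:
            raise ValueError("degenerate rectangle")
        keep = (
            (points["mz"] >= mz_min)
            & (points["mz"] <= mz_max)
            & (points["kmd"] >= kmd_min)
            & (points["kmd"] <= kmd_max)
        )
        members = list(points.index[keep])
    else:
        from shapely.geometry import Point, Polygon

        poly = Polygon([(float(a), float(b)) for a, b in geometry])
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("degenerate polygon geometry")
        members = [
            lab
            for lab, row in points.iterrows()
            if poly.covers(Point(row["mz"], row["kmd"]))
        ]
    return CloudSelection(name=name, geometry=geometry, members=members)


def flag_matrix_points(
    points: pd.DataFrame,
    matrix_mzs: Sequence[float],
    ppm_tolerance: float = 3.0,
) -> pd.Series:
    """Boolean mask marking points that match a matrix-cluster m/z.

    With an empty matrix list nothing is flagged; with zero tolerance
    only exact matches are flagged.
    """
    flags = pd.Series(False, index=points.index)
    for target in matrix_mzs:
        dev = (points["mz"] - target).abs() / target * 1e6
        flags |= dev <= ppm_tolerance
    return flags
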