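"""Ground-truth scoring of pipeline stages on phantom datasets.

Given the species assignments that generated a phantom, these helpers
compute the theoretical ion lines (species x adduct x isotopologue),
map them onto consensus bins, and score series recovery, adduct/
isotopologue collapsing and spatial enrichment.  They exist so that
tests and reproduction scripts measure the same quantities the same
way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kmd import SeriesGroup
from .masses import C13_MASS_SHIFT, ion_mz, parse_composition
from .phantom import N_ISOTOPOLOGUES, Phantom, SpeciesAssignment

__all__ = [
    "theoretical_ions",
    "match_to_bins",
    "score_ch2_recovery",
    "score_collapse",
    "species_home_masks",
]


def theoretical_ions(assignments: Sequence[SpeciesAssignment]) -> pd.DataFrame:
    """Expand assignments into unique theoretical ion lines.

    One row per (species, adduct, isotopologue) with positive weight:
    columns species, family, adduct, isotopologue, mz.  Duplicate
    species entries (e.g. the same lipid assigned to two sub-regions)
    are collapsed.
    """
    rows = {}
    for a in assignments:
        comp = parse_composition(a.formula)
        for adduct, w in a.adduct_weights.items():
            if w <= 0:
                continue
            base = ion_mz(comp, adduct)
            for k in range(N_ISOTOPOLOGUES):
                key = (a.species, adduct, k)
                rows[key] = {
                    "species": a.species,
                    "family": a.family,
                    "adduct": adduct,
                    "isotopologue": k,
                    "mz": base + k * C13_MASS_SHIFT,
                }
    return pd.DataFrame(list(rows.values()))


def match_to_bins(
    ions: pd.DataFrame, points: pd.DataFrame, tolerance_ppm: float = 3.0
) -> pd.Series:
    """Map each theoretical ion to the nearest consensus point label.

    Returns a Series aligned with ``ions`` holding the point index
    label, or NA when no point lies within ``tolerance_ppm``.
    """
    mz_pts = points["mz"].to_numpy()
    labels = np.asarray(points.index)
    order = np.argsort(mz_pts)
    mz_sorted = mz_pts[order]
    out = []
    for mz in ions["mz"].to_numpy():
        j = int(np.searchsorted(mz_sorted, mz))
        best, best_dev = None, None
        for cand in (j - 1, j):
            if 0 <= cand < mz_sorted.size:
                dev = abs(mz_sorted[cand] - mz) / mz * 1e6
                if dev <= tolerance_ppm and (best_dev is None or dev < best_dev):
                    best, best_dev = labels[order[cand]], dev
        out.append(best)
    return pd.Series(out, index=ions.index, dtype=object)


@dataclass
class SeriesScore:
    n_lines: int  # expected multi-member CH2 lines
    n_recovered: int  # lines found as exactly one component
    n_cross_family_merges: int  # components mixing distinct families

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_lines if self.n_lines else 1.0


def score_ch2_recovery(
    ions: pd.DataFrame,
    bin_of: pd.Series,
    series: Sequence[SeriesGroup],
) -> SeriesScore:
    """Score horizontal CH2 chaining against planted homologous lines.

    An expected line is a (family, adduct, isotopologue) group of two
    or more planted species; it is recovered when all its member bins
    fall in one connected component that contains no bin of a
    different family.
    """
    comp_of: Dict[object, int] = {}
    for i, g in enumerate(series):
        for m in g.members:
            comp_of[m] = i
    fam_of_bin: Dict[object, set] = {}
    for (_, ion), b in zip(ions.iterrows(), bin_of):
        if b is not None and ion["family"] is not None:
            fam_of_bin.setdefault(b, set()).add(ion["family"])

    n_lines = n_recovered = 0
    grouped = ions.groupby(["family", "adduct", "isotopologue"], dropna=True)
    for _key, grp in grouped:
        if len(grp) < 2:
            continue
        n_lines += 1
        bins = [bin_of[i] for i in grp.index]
        if any(b is None for b in bins):
            continue
        comps = {comp_of.get(b) for b in bins}
        if len(comps) == 1 and None not in comps:
            n_recovered += 1

    merges = 0
    for i, g in enumerate(series):
        fams = set()
        for m in g.members:
            fams |= fam_of_bin.get(m, set())
        if len(fams) > 1:
            merges += 1
    return SeriesScore(n_lines, n_recovered, merges)


@dataclass
class CollapseScore:
    n_species: int
    n_collapsed: int  # species whose every observed ion maps to one canonical
    n_shared_canonicals: int  # canonicals claimed by more than one species
    intensity_in: float
    intensity_out: float

    @property
    def recovery(self) -> float:
        return self.n_collapsed / self.n_species if self.n_species else 1.0


def score_collapse(
    ions: pd.DataFrame,
    bin_of: pd.Series,
    collapse: pd.DataFrame,
    points: pd.DataFrame,
) -> CollapseScore:
    """Score adduct/isotopologue collapsing against planted families."""
    canon_by_species: Dict[str, set] = {}
    for (idx, ion), b in zip(ions.iterrows(), bin_of):
        if b is None or b not in collapse.index:
            continue
        canon_by_species.setdefault(ion["species"], set()).add(collapse.at[b, "canonical"])
    n_species = len(canon_by_species)
    n_collapsed = sum(1 for s in canon_by_species.values() if len(s) == 1)
    claimed: Dict[object, int] = {}
    for s in canon_by_species.values():
        for c in s:
            claimed[c] = claimed.get(c, 0) + 1
    n_shared = sum(1 for v in claimed.values() if v > 1)
    total_in = float(points.loc[collapse.index, "intensity"].sum())
    per_canon = collapse.drop_duplicates("canonical")["collapsed_intensity"]
    return CollapseScore(
        n_species=n_species,
        n_collapsed=n_collapsed,
        n_shared_canonicals=n_shared,
        intensity_in=total_in,
        intensity_out=float(per_canon.sum()),
    )


def species_home_masks(
    assignments: Sequence[SpeciesAssignment], phantom: Phantom
) -> Dict[str, np.ndarray]:
    """Union of home-region masks per species (ovary sub-masks merge)."""
    masks: Dict[str, np.ndarray] = {}
    for a in assignments:
        m = phantom.mask(a.region)
        if a.species in masks:
            masks[a.species] = masks[a.species] | m
        else:
            masks[a.species] = m.copy()
    return masks
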