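"""Exact-mass lipid annotation against a bundled reference table.

Observed m/z values are matched to a curated offline table of lipid
and metabolite species (LIPID MAPS shorthand names with neutral
elemental compositions) over the H/Na/K adduct space.  Candidate
ranking follows the positive-mode MALDI reasoning used for the
workflow this package implements: lowest |ΔM| first, a class-priority
list for near-ties, and exclusion of implausibly oxidised
compositions.  Annotations can be propagated along horizontal CH2
series and validated against carbon isotopologue patterns.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kmd import CH2_MASS, SeriesGroup
from .masses import (
    ion_mz,
    isotope_pattern,
    parse_composition,
    ppm_error,
)

__all__ = [
    "LipidRecord",
    "load_lipid_table",
    "RankingPolicy",
    "AnnotationCandidate",
    "AnnotationResult",
    "annotate_mz",
    "rank_candidates",
    "propagate_series_annotation",
    "validate_isotope_pattern",
]

DEFAULT_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M+K]+")


@dataclass(frozen=True)
class LipidRecord:
    """A reference species: shorthand name plus neutral composition."""

    name: str
    lipid_class: str
    formula: str
    double_bonds: Optional[int]
    oxygens: int
    notes: str = ""

    @property
    def composition(self) -> Dict[str, int]:
        return parse_composition(self.formula)


_SHORTHAND = re.compile(
    r"^(?P<cls>[A-Za-z]+)\s+(?P<ether>O-)?(?P<c>\d+):(?P<d>\d+)(?P<ox>;O\d*)?$"
)

# Hydrogen count as a function of total acyl carbons c and double bonds d,
# per class: H = slope*c + intercept - 2*d.  Carbon offset is the backbone
# contribution (glycerol or headgroup).  Used to cross-check the bundled
# table; classes absent here are accepted as-is.
_CLASS_FORMULA = {
    # class: (carbon offset, H intercept, O count, N count, P count)
    "TG": (3, -4, 6, 0, 0),
    "DG": (3, -2, 5, 0, 0),
    "MG": (3, 0, 4, 0, 0),
    "PC": (8, 0, 8, 1, 1),
    "PE": (5, 0, 8, 1, 1),
    "PA": (3, -1, 8, 0, 1),
    "LPC O": (8, 4, 6, 1, 1),
    "LPE O": (5, 4, 6, 1, 1),
}


def parse_shorthand(name: str) -> Optional[dict]:
    """Parse one LIPID MAPS shorthand name; None when not shorthand."""
    m = _SHORTHAND.match(name.strip())
    if not m:
        return None
    return {
        "class": m.group("cls"),
        "ether": bool(m.group("ether")),
        "carbons": int(m.group("c")),
        "double_bonds": int(m.group("d")),
        "oxygen_suffix": m.group("ox") or "",
    }


def _check_shorthand_formula(name: str, comp: Mapping[str, int]) -> Optional[str]:
    """Return an error message when a shorthand disagrees with its formula."""
    info = parse_shorthand(name)
    if info is None or info["oxygen_suffix"]:
        return None
    key = f"{info['class']} O" if info["ether"] else info["class"]
    if key not in _CLASS_FORMULA:
        return None
    c_off, h_int, n_o, n_n, n_p = _CLASS_FORMULA[key]
    c = info["carbons"] + c_off
    h = 2 * c + h_int - 2 * info["double_bonds"]
    expected = {"C": c, "H": h, "O": n_o}
    if n_n:
        expected["N"] = n_n
    if n_p:
        expected["P"] = n_p
    actual = {k: v for k, v in comp.items() if v}
    if actual != expected:
        return f"{name}: formula {actual} does not match class formula {expected}"
    return None


def load_lipid_table(path: Optional[str] = None) -> List[LipidRecord]:
    """Load the reference table (bundled CSV when ``path`` is None).

    Columns: name, lipid_class, formula, double_bonds, oxygens, notes.
    Every formula is parsed and, for the classes with a defined
    composition rule, cross-checked against the shorthand; duplicate
    names are rejected.  Errors carry the 1-based data row number.
    """
    if path is None:
        ref = resources.files("kmdmsi").joinpath("data/lipid_reference.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "lipid_class", "formula", "double_bonds", "oxygens"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference table must have columns {sorted(required)}")
    records: List[LipidRecord] = []
    seen = set()
    for i, row in df.iterrows():
        line = i + 1
        name = str(row["name"]).strip()
        if name in seen:
            raise ValueError(f"row {line}: duplicate species name {name!r}")
        seen.add(name)
        try:
            comp = parse_composition(str(row["formula"]))
        except ValueError as exc:
            raise ValueError(f"row {line}: {exc}") from None
        for part in name.split(" or "):
            problem = _check_shorthand_formula(part, comp)
            if problem:
                raise ValueError(f"row {line}: {problem}")
        db = row["double_bonds"]
        records.append(
            LipidRecord(
                name=name,
                lipid_class=str(row["lipid_class"]).strip(),
                formula=str(row["formula"]).strip(),
                double_bonds=None if pd.isna(db) else int(db),
                oxygens=int(row["oxygens"]),
                notes="" if pd.isna(row.get("notes")) else str(row.get("notes")),
            )
        )
    return records


@dataclass(frozen=True)
class RankingPolicy:
    """Candidate acceptance and ordering rules.

    ``max_ppm`` is the acceptance window; matches beyond
    ``hypothetical_ppm`` are kept but flagged low-confidence, following
    the convention that annotations with ΔM above ~4 ppm are
    hypothetical.  Within ``tie_ppm`` of the best |ΔM| the class
    priority list (positive-mode ionizability) breaks ties; compositions
    exceeding the oxidation caps are excluded outright.

    The default priority places the glyceride classes DG/MG above TG:
    a sodiated DG and a potassiated TG are near-exact isobars (3C+Na
    vs 4H+O+K differ by ~0.15 mDa), so mass error alone cannot
    separate them and the published assignments resolve this tie
    toward the DG.
    """

    max_ppm: float = 6.0
    hypothetical_ppm: float = 4.0
    tie_ppm: float = 0.3
    class_priority: Tuple[str, ...] = (
        "PC/PE", "PC", "SM", "LPC", "DG", "MG", "TG", "LPE", "PE", "PA", "ST", "CAR",
    )
    max_double_bonds: int = 10
    max_oxygens: int = 10

    def __post_init__(self) -> None:
        if self.max_ppm <= 0:
            raise ValueError("max ppm must be positive")

    def class_rank(self, lipid_class: str) -> int:
        try:
            return self.class_priority.index(lipid_class)
        except ValueError:
            return len(self.class_priority)


DEFAULT_POLICY = RankingPolicy()


@dataclass(frozen=True)
class AnnotationCandidate:
    record: LipidRecord
    adduct: str
    mz_theoretical: float
    ppm: float  # signed
    low_confidence: bool
    rationale: str = ""


@dataclass
class AnnotationResult:
    query_mz: float
    candidates: List[AnnotationCandidate]

    @property
    def best(self) -> Optional[AnnotationCandidate]:
        return self.candidates[0] if self.candidates else None

    def to_row(self) -> dict:
        b = self.best
        return {
            "mz_exp": self.query_mz,
            "best_match": b.record.name if b else "",
            "ion": b.adduct if b else "",
            "mz_theoretical": b.mz_theoretical if b else np.nan,
            "delta_ppm": b.ppm if b else np.nan,
            "low_confidence": b.low_confidence if b else False,
            "n_candidates": len(self.candidates),
        }


def rank_candidates(
    candidates: Sequence[AnnotationCandidate],
    policy: RankingPolicy = DEFAULT_POLICY,
) -> List[AnnotationCandidate]:
    """Order candidates by the policy (a total, deterministic order).

    Oxidation-cap violators are removed first; remaining candidates are
    sorted by ascending |ΔM|, with the class-priority list applied
    inside near-tie groups (|ΔM| within ``tie_ppm`` of the group
    leader) and the name as the final tie-break.
    """
    kept = [
        c
        for c in candidates
        if (c.record.double_bonds is None or c.record.double_bonds <= policy.max_double_bonds)
        and c.record.oxygens <= policy.max_oxygens
    ]
    kept.sort(key=lambda c: (abs(c.ppm), c.record.name, c.adduct))
    ordered: List[AnnotationCandidate] = []
    i = 0
    while i < len(kept):
        leader = abs(kept[i].ppm)
        j = i
        while j < len(kept) and abs(kept[j].ppm) - leader <= policy.tie_ppm:
            j += 1
        group = sorted(
            kept[i:j],
            key=lambda c: (policy.class_rank(c.record.lipid_class), abs(c.ppm), c.record.name, c.adduct),
        )
        ordered.extend(group)
        i = j
    out = []
    for rank, c in enumerate(ordered):
        why = f"|ΔM|={abs(c.ppm):.2f} ppm"
        if rank > 0:
            why += f"; rank {rank + 1} by mass error/class priority"
        out.append(replace(c, rationale=why))
    return out


def annotate_mz(
    mz: float,
    table: Sequence[LipidRecord],
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    policy: RankingPolicy = DEFAULT_POLICY,
) -> AnnotationResult:
    """All (species, adduct) matches of ``mz`` within the policy window, ranked."""
    if not table:
        raise ValueError("reference table is empty")
    raw: List[AnnotationCandidate] = []
    for rec in table:
        comp = rec.composition
        for adduct in adducts:
            theo = ion_mz(comp, adduct)
            dppm = ppm_error(mz, theo)
            if abs(dppm) <= policy.max_ppm:
                raw.append(
                    AnnotationCandidate(
                        record=rec,
                        adduct=adduct,
                        mz_theoretical=theo,
                        ppm=dppm,
                        low_confidence=abs(dppm) > policy.hypothetical_ppm,
                    )
                )
    return AnnotationResult(query_mz=mz, candidates=rank_candidates(raw, policy))


def _shift_shorthand(name: str, k: int) -> Optional[str]:
    """Shift every shorthand part of ``name`` by k CH2 (carbons += k)."""
    parts = []
    for part in name.split(" or "):
        info = parse_shorthand(part)
        if info is None:
            return None
        c = info["carbons"] + k
        if c <= 0:
            return None
        prefix = "O-" if info["ether"] else ""
        parts.append(f"{info['class']} {prefix}{c}:{info['double_bonds']}{info['oxygen_suffix']}")
    return " or ".join(parts)


def propagate_series_annotation(
    series: SeriesGroup,
    anchor: int,
    anchor_name: str,
    points: pd.DataFrame,
    ppm_tolerance: float = 2.0,
) -> pd.DataFrame:
    """Propagate an anchor annotation along a horizontal CH2 series.

    Each member at an integer offset of k CH2 units from the anchor
    receives the anchor's class with the carbon count shifted by k
    (e.g. TG 50:3 two units up becomes TG 52:3), flagged "propagated";
    the anchor row is flagged "anchor".  Members at a non-integer
    offset (a corrupted series) stay unannotated with a warning status.
    Propagation is involutive: re-anchoring at any propagated member
    recovers the original annotations.
    """
    if series.orientation != "horizontal-CH2":
        raise ValueError("annotation propagation requires a horizontal CH2 series")
    if anchor not in series.members:
        raise ValueError(f"anchor {anchor!r} is not a member of the series")
    anchor_mz = float(points.at[anchor, "mz"])
    rows = []
    for member in series.members:
        mz = float(points.at[member, "mz"])
        delta = mz - anchor_mz
        k = int(round(delta / CH2_MASS))
        dev_ppm = abs(delta - k * CH2_MASS) / max(mz, anchor_mz) * 1e6
        if member == anchor:
            rows.append(dict(member=member, mz=mz, k=0, name=anchor_name, status="anchor"))
            continue
        name = _shift_shorthand(anchor_name, k) if dev_ppm <= ppm_tolerance else None
        if name is None:
            status = "warning: non-integer CH2 offset" if dev_ppm > ppm_tolerance else \
                "warning: name not propagatable"
            rows.append(dict(member=member, mz=mz, k=k, name="", status=status))
        else:
            rows.append(dict(member=member, mz=mz, k=k, name=name, status="propagated"))
    return pd.DataFrame(rows).set_index("member")


def validate_isotope_pattern(
    formula: str,
    observed: Sequence[Tuple[float, float]],
    query_mz: float,
    n_isotopologues: int = 3,
    ppm_tolerance: float = 2.0,
) -> float:
    """Cosine agreement between theoretical and observed isotope patterns.

    The theoretical carbon-binomial pattern of ``formula`` (first
    ``n_isotopologues`` peaks, monoisotopic = 1) is compared with the
    observed intensities found within ``ppm_tolerance`` of
    ``query_mz`` + each isotopologue offset; a missing observed
    isotopologue counts as 0.  Returns a score in [0, 1].
    """
    theo = isotope_pattern(formula, n=n_isotopologues)
    obs_mz = np.array([m for m, _ in observed], dtype=float)
    obs_int = np.array([h for _, h in observed], dtype=float)
    vec_t = np.array([ab for _off, ab in theo])
    vec_o = np.zeros_like(vec_t)
    for k, (off, _ab) in enumerate(theo):
        target = query_mz + off
        if obs_mz.size == 0:
            continue
        dev = np.abs(obs_mz - target) / target * 1e6
        j = int(np.argmin(dev))
        if dev[j] <= ppm_tolerance:
            vec_o[k] = obs_int[j]
    denom = float(np.linalg.norm(vec_t) * np.linalg.norm(vec_o))
    if denom == 0:
        return 0.0
    return float(np.dot(vec_t, vec_o) / denom)
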