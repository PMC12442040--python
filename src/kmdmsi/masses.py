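"""Exact-mass arithmetic for singly charged lipid ions.

This module is the numerical foundation of the package: elemental
compositions, monoisotopic and ion masses, ppm mass errors, Kendrick
mass / Kendrick mass defect, and a carbon-binomial isotopologue model.

All masses are monoisotopic, in daltons (Da).  Only singly charged
positive ions ([M+H]+, [M+Na]+, [M+K]+) are supported, which covers
positive-mode MALDI lipid imaging; for such ions the m/z equals the
ion mass.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

from scipy.stats import binom

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "C13_MASS_SHIFT",
    "C13_NATURAL_ABUNDANCE",
    "Composition",
    "parse_composition",
    "monoisotopic_mass",
    "AdductSpec",
    "ADDUCTS",
    "ion_mz",
    "ppm_error",
    "KendrickParams",
    "kendrick_mass",
    "kendrick_mass_defect",
    "isotope_pattern",
]

#: Monoisotopic atomic masses (Da).  Keys are element symbols; a leading
#: mass number selects a specific isotope ("13C", "12C").
ATOMIC_MASSES: Dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
    "P": 30.97376163,
    "K": 38.96370649,
    "S": 31.97207100,
    "12C": 12.000000,
    "13C": 13.00335484,
}

ELECTRON_MASS = 0.00054858  # Da
PROTON_MASS = 1.00727646  # Da; equals H minus one electron

#: Mass added by one 12C -> 13C substitution (Da).
C13_MASS_SHIFT = ATOMIC_MASSES["13C"] - ATOMIC_MASSES["12C"]

#: Natural abundance of carbon-13.
C13_NATURAL_ABUNDANCE = 0.0107

Composition = Dict[str, int]

_TOKEN = re.compile(r"(\d+(?=[A-Z]))?([A-Z][a-z]?)(\d+)?")


def parse_composition(text: str) -> Composition:
    """Parse an elemental composition string into ``{symbol: count}``.

    Accepts both the spaced table notation (``"C53 H96 O6 Na"``,
    ``"12C38 13C H73 O8 P K"``) and compact formulas (``"C53H96O6Na"``).
    A leading mass number marks an explicit isotope and is kept as part
    of the symbol (``"13C"``).

    Raises
    ------
    ValueError
        If the string contains an unknown element symbol or stray text.
    """
    comp: Composition = {}
    pos = 0
    s = text.strip()
    while pos < len(s):
        if s[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(2):
            raise ValueError(f"cannot parse composition {text!r} at position {pos}")
        isotope, element, count = m.groups()
        symbol = (isotope or "") + element
        if symbol not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        comp[symbol] = comp.get(symbol, 0) + (int(count) if count else 1)
        pos = m.end()
    return comp


def format_composition(comp: Mapping[str, int]) -> str:
    """Render a composition in Hill-like order (C, H, then alphabetical)."""

    def key(sym: str) -> Tuple[int, str]:
        base = sym.lstrip("0123456789")
        order = {"C": 0, "H": 1}.get(base, 2)
        return (order, sym)

    parts = []
    for sym in sorted(comp, key=key):
        n = comp[sym]
        if n == 0:
            continue
        parts.append(f"{sym}{n if n != 1 else ''}")
    return " ".join(parts)


def monoisotopic_mass(comp: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental composition.

    ``comp`` may be a mapping or a composition string.  An empty
    composition has mass 0.
    """
    if isinstance(comp, str):
        comp = parse_composition(comp)
    total = 0.0
    for symbol, count in comp.items():
        if count < 0:
            raise ValueError(f"negative count for {symbol!r}")
        try:
            total += ATOMIC_MASSES[symbol] * count
        except KeyError:
            raise ValueError(f"unknown element symbol {symbol!r}") from None
    return total


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged positive cation adduct.

    ``cation`` is the attaching element; protonation is treated as
    adding a bare proton while metal adducts add the neutral atom and
    remove one electron (the two conventions agree because
    proton = H − e⁻).
    """

    name: str
    cation: str
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged (+1) adducts are supported")

    @property
    def mass_shift(self) -> float:
        """Mass added to the neutral molecule to form the ion (Da)."""
        if self.cation == "H":
            return PROTON_MASS
        return ATOMIC_MASSES[self.cation] - ELECTRON_MASS


ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", "H"),
    "[M+Na]+": AdductSpec("[M+Na]+", "Na"),
    "[M+K]+": AdductSpec("[M+K]+", "K"),
}


def get_adduct(adduct: str | AdductSpec) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    key = adduct.replace(" ", "").replace("^", "")
    if key not in ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )
    return ADDUCTS[key]


def ion_mz(neutral: Mapping[str, int] | str, adduct: str | AdductSpec) -> float:
    """Theoretical m/z of a singly charged adduct ion of a neutral molecule.

    [M+H]+ adds one proton; [M+Na]+ / [M+K]+ add the metal atom and
    subtract one electron.  Because the charge is +1 the returned value
    is both the ion mass and its m/z.
    """
    if isinstance(neutral, str):
        neutral = parse_composition(neutral)
    if not neutral:
        raise ValueError("neutral composition is empty")
    return monoisotopic_mass(neutral) + get_adduct(adduct).mass_shift


def ion_mz_from_ion_composition(ion_comp: Mapping[str, int] | str) -> float:
    """m/z of a +1 cation given the full ion composition (cation included)."""
    if isinstance(ion_comp, str):
        ion_comp = parse_composition(ion_comp)
    if not ion_comp:
        raise ValueError("ion composition is empty")
    return monoisotopic_mass(ion_comp) - ELECTRON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error (observed − theoretical) in ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


ROUNDING_MODES = ("down", "up", "nearest")


@dataclass(frozen=True)
class KendrickParams:
    """Kendrick rescaling parameters.

    The default base unit is the methylene repeat CH2 with nominal mass
    14 and exact mass 14.01565 Da, the standard choice for lipid
    homologous series.  ``rounding`` selects the integer-rounding
    convention for the mass defect: "up" (ceiling, KMD in [0, 1)),
    "down" (floor, KMD in (−1, 0]) or "nearest" (KMD in [−0.5, 0.5]).
    """

    base_composition: Mapping[str, int] = field(
        default_factory=lambda: {"C": 1, "H": 2}
    )
    nominal_mass: float = 14.00000
    exact_mass: float = 14.01565
    rounding: str = "up"

    def __post_init__(self) -> None:
        if self.rounding not in ROUNDING_MODES:
            raise ValueError(
                f"unknown rounding mode {self.rounding!r}; expected one of {ROUNDING_MODES}"
            )
        if self.exact_mass <= 0 or self.nominal_mass <= 0:
            raise ValueError("base-unit masses must be positive")
        if abs(self.nominal_mass - round(self.nominal_mass)) > 1e-9:
            raise ValueError("nominal mass must be integer-valued")
        ref = monoisotopic_mass(self.base_composition)
        if abs(ref - self.exact_mass) > 5e-6:
            raise ValueError(
                f"exact mass {self.exact_mass} does not match base composition "
                f"mass {ref:.5f}"
            )


DEFAULT_KENDRICK = KendrickParams()


def kendrick_mass(mz: float, params: KendrickParams = DEFAULT_KENDRICK) -> float:
    """Kendrick mass: m/z rescaled by nominal/exact mass of the base unit."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return mz * params.nominal_mass / params.exact_mass


def kendrick_mass_defect(km: float, rounding: str = "up") -> float:
    """Kendrick mass defect: rounded KM minus KM.

    With ceiling rounding ("up") the KMD of any non-integer KM lies in
    (0, 1); homologous CH2 series share the same KMD.  KM values within
    1e-9 of an integer are treated as integers (KMD exactly 0) so that
    exact multiples of the base unit are stable under float rounding.
    """
    if abs(km - round(km)) < 1e-9:
        return 0.0
    if rounding == "down":
        return math.floor(km) - km
    if rounding == "up":
        return math.ceil(km) - km
    if rounding == "nearest":
        return round(km) - km
    raise ValueError(f"unknown rounding mode {rounding!r}")


def kmd_of_mz(mz: float, params: KendrickParams = DEFAULT_KENDRICK) -> float:
    """Convenience: KMD of an m/z under ``params`` (KM computed internally)."""
    return kendrick_mass_defect(kendrick_mass(mz, params), params.rounding)


def isotope_pattern(
    comp: Mapping[str, int] | str,
    n: int = 3,
    p13: float = C13_NATURAL_ABUNDANCE,
) -> List[Tuple[float, float]]:
    """Carbon-binomial isotopologue pattern of a composition.

    Returns ``n`` entries ``(mass offset in Da, relative abundance)``
    for 0..n−1 heavy-carbon substitutions, normalised so the
    monoisotopic (all-12C) peak has abundance 1.  Heavier elements'
    minor isotopes are ignored; for CHNOPK lipids carbon dominates the
    A+1/A+2 envelope, which is all the validation step needs.
    """
    if isinstance(comp, str):
        comp = parse_composition(comp)
    if n < 1:
        raise ValueError("n must be >= 1")
    n_carbon = comp.get("C", 0) + comp.get("12C", 0)
    if n_carbon < 1:
        raise ValueError("composition contains no carbon")
    mono = binom.pmf(0, n_carbon, p13)
    out = []
    for k in range(n):
        ab = binom.pmf(k, n_carbon, p13) / mono if k <= n_carbon else 0.0
        out.append((k * C13_MASS_SHIFT, float(ab)))
    return out
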