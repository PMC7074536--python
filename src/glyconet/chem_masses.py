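"""Exact monoisotopic mass arithmetic for glycosylated natural products.

Implements elemental-formula parsing, ion m/z computation, glycan residue and
oxocarbenium-ion masses, and the table of characteristic modification mass
deltas (hydroxylation, methylation, dehydrogenation, ...) used to annotate
edges of a molecular network.

All masses are monoisotopic (most abundant isotope), in daltons. Ion m/z
values account for the electron mass, so a singly protonated species is
``M + 1.007276`` rather than ``M + 1.007825``. Display helpers support both
two-decimal truncation (the convention used for observed fragment values in
the literature this package targets) and ordinary rounding.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

# CODATA/NIST monoisotopic atomic masses, Da.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "F": 18.99840322,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS  # [M+H]+ adduct increment
ISOTOPE_SPACING = 1.00336  # average 13C isotopologue spacing, Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition with an integer charge.

    ``element_counts`` maps element symbols to non-negative counts;
    ``charge`` is in units of elementary charge (positive for cations).
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for elem, count in self.element_counts.items():
            if elem not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            if count < 0:
                raise FormulaError(f"negative count for {elem}: {count}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for elem, n in other.element_counts.items():
            counts[elem] = counts.get(elem, 0) + n
        return ElementalFormula(counts, self.charge + other.charge)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string with an optional trailing charge.

    Examples: ``"C6H10O5"``, ``"C30H47O2+"``, ``""`` (the empty formula).
    Charge is given as trailing ``+``/``-`` marks (``"++"`` for 2+).
    """
    text = text.strip()
    charge = 0
    while text.endswith(("+", "-")):
        charge += 1 if text[-1] == "+" else -1
        text = text[:-1]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        elem = m.group(1)
        if elem not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol: {elem!r}")
        counts[elem] = counts.get(elem, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    return ElementalFormula(counts, charge)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass (Da) or, for charged species, m/z.

    Sum of most-abundant-isotope masses minus ``charge`` electron masses,
    divided by ``|charge|`` when multiply charged.
    """
    mass = sum(ELEMENT_MASSES[e] * n for e, n in f.element_counts.items())
    mass -= f.charge * ELECTRON_MASS
    if abs(f.charge) > 1:
        mass /= abs(f.charge)
    return mass


def _signed_formula_mass(element_change: Mapping[str, int]) -> float:
    """Mass of a signed element-count map (counts may be negative)."""
    return sum(ELEMENT_MASSES[e] * n for e, n in element_change.items())


@dataclass(frozen=True)
class ModificationDelta:
    """A characteristic chemical modification and its monoisotopic mass delta."""

    name: str
    element_change: Mapping[str, int]
    delta_mass: float

    def __post_init__(self) -> None:
        expected = _signed_formula_mass(self.element_change)
        if abs(expected - self.delta_mass) > 1e-6:
            raise ValueError(
                f"{self.name}: delta_mass {self.delta_mass} inconsistent with "
                f"element change (expected {expected:.6f})"
            )


def _delta(name: str, change: Mapping[str, int]) -> ModificationDelta:
    return ModificationDelta(name, change, _signed_formula_mass(change))


#: Default modification table used for delta-mass edge traversal.
DEFAULT_DELTAS: tuple[ModificationDelta, ...] = (
    _delta("hydroxylation", {"O": 1}),                       # +15.9949
    _delta("methylation", {"C": 1, "H": 2}),                 # +14.0157
    _delta("dehydrogenation", {"H": -2}),                    # -2.0157
    _delta("reduction", {"H": 2}),                           # +2.0157
    _delta("methoxylation-dehydrogenation", {"C": 1, "O": 1}),  # net +CO, +27.9949
    _delta("bromination", {"Br": 1, "H": -1}),               # +77.9105
)


@dataclass(frozen=True)
class GlycanResidue:
    """A dehydrated glycosyl residue (the mass added per glycosidic bond)."""

    name: str
    residue_formula: ElementalFormula
    residue_mass: float

    def __post_init__(self) -> None:
        if abs(self.residue_formula.mass - self.residue_mass) > 1e-6:
            raise ValueError(f"{self.name}: residue mass/formula mismatch")


def _residue(name: str, formula: str) -> GlycanResidue:
    f = parse_formula(formula)
    return GlycanResidue(name, f, f.mass)


PENTOSE = _residue("pentose", "C5H8O4")        # 132.0423  e.g. xylose
HEXOSE = _residue("hexose", "C6H10O5")         # 162.0528  e.g. glucose
HEXNAC = _residue("HexNAc", "C8H13NO5")        # 203.0794  e.g. GlcNAc/GalNAc
DEOXYHEXOSE = _residue("deoxyhexose", "C6H10O4")  # 146.0579

#: Default glycan residue table, keyed by name.
DEFAULT_GLYCANS: dict[str, GlycanResidue] = {
    r.name: r for r in (PENTOSE, HEXOSE, HEXNAC, DEOXYHEXOSE)
}


def glycan_oxocarbenium_mz(residues: Sequence[GlycanResidue]) -> float:
    """m/z of the singly charged B-type (oxocarbenium) ion of a glycan chain.

    The B ion retains the glycan side of the glycosidic cleavage: the sum of
    the dehydrated residue masses plus a proton. The HexNAc oxocarbenium at
    204.0866 is the canonical example.
    """
    if not residues:
        raise ValueError("residue list must be non-empty")
    return sum(r.residue_mass for r in residues) + PROTON_MASS


def proton_adduct_mz(neutral_mass: float) -> float:
    """[M+H]+ m/z of a neutral of the given monoisotopic mass."""
    return neutral_mass + PROTON_MASS


def classify_delta(
    observed: float,
    table: Sequence[ModificationDelta] = DEFAULT_DELTAS,
    tolerance: float = 0.01,
) -> Optional[tuple[ModificationDelta, int]]:
    """Match an observed precursor mass difference against a delta table.

    Matching is on magnitudes: ``|observed|`` is compared to ``|delta_mass|``
    of every table entry and the closest entry within ``tolerance`` wins.
    Ties are broken by sign agreement (so +2.016 resolves to reduction, not
    reversed dehydrogenation), then table order. Returns the entry together
    with the direction (+1 when the observed difference has the same sign as
    the entry's delta, -1 otherwise), or None if nothing matches.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    best: Optional[tuple[ModificationDelta, int]] = None
    best_key: tuple = (math.inf, 1, math.inf)
    for order, entry in enumerate(table):
        err = abs(abs(observed) - abs(entry.delta_mass))
        if err > tolerance:
            continue
        sign_obs = 1 if observed >= 0 else -1
        sign_entry = 1 if entry.delta_mass >= 0 else -1
        direction = 1 if sign_obs == sign_entry else -1
        key = (round(err, 12), 0 if direction == 1 else 1, order)
        if key < best_key:
            best = (entry, direction)
            best_key = key
    return best


# ---------------------------------------------------------------------------
# display conventions


def format_mz(value: float, decimals: int = 2, mode: str = "truncate") -> float:
    """Report an m/z at a fixed number of decimals.

    ``mode="truncate"`` chops toward zero (the convention printed for observed
    fragment values in the source literature: 421.3465 -> 421.34);
    ``mode="round"`` is ordinary half-even rounding.
    """
    if mode == "truncate":
        factor = 10**decimals
        return math.trunc(value * factor) / factor
    if mode == "round":
        return round(value, decimals)
    raise ValueError(f"unknown mode {mode!r}")


def nominal_mass(value: float) -> int:
    """Integer-rounded (nominal) mass."""
    return int(round(value))


# ---------------------------------------------------------------------------
# CSV round-trip so users can extend the tables


def save_delta_table(table: Iterable[ModificationDelta], path: str | Path) -> None:
    rows = []
    for t in table:
        change = " ".join(f"{e}:{n}" for e, n in t.element_change.items())
        rows.append({"name": t.name, "formula_change": change, "delta_mass": t.delta_mass})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_delta_table(path: str | Path) -> list[ModificationDelta]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        change = {}
        for tok in str(row["formula_change"]).split():
            elem, n = tok.split(":")
            change[elem] = int(n)
        out.append(ModificationDelta(row["name"], change, float(row["delta_mass"])))
    return out


def save_glycan_table(table: Mapping[str, GlycanResidue], path: str | Path) -> None:
    rows = [
        {
            "name": r.name,
            "formula_change": "".join(
                f"{e}{n}" for e, n in sorted(r.residue_formula.element_counts.items())
            ),
            "delta_mass": r.residue_mass,
        }
        for r in table.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_glycan_table(path: str | Path) -> dict[str, GlycanResidue]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        f = parse_formula(str(row["formula_change"]))
        out[row["name"]] = GlycanResidue(row["name"], f, float(row["delta_mass"]))
    return out
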