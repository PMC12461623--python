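"""Exact monoisotopic mass arithmetic.

Every other layer of the pipeline routes its mass computations through this
module so that a single constants table governs all arithmetic: atomic
monoisotopic masses (lightest stable isotope, IUPAC/CODATA values), the 20
standard amino-acid residue compositions, the proton mass used for m/z
conversions, and the averagine isotope spacing used for isotope-envelope
targets and mis-pick correction.

The chemistry modelled here is Schiff-base formation between a carbonyl
ligand and a lysine side chain followed by reductive amination: the ligand
condenses with loss of water (−H2O) and the imine is then reduced (+H2), so
the net mass the cross-link adds to the peptide is the free-ligand mass minus
one oxygen atom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ELEMENT_MASSES",
    "RESIDUE_FORMULAS",
    "PROTON_MASS",
    "WATER_MASS",
    "OXYGEN_MASS",
    "NH3_MASS",
    "ISOTOPE_SPACING",
    "ElementalComposition",
    "Peptide",
    "AdductMass",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "formula_mass",
    "residue_mass",
    "peptide_mass",
    "adduct_from_ligand",
    "neutral_mass",
    "mz_from_neutral",
    "fragment_mz",
    "fragment_neutral",
    "isotope_targets",
]

# Monoisotopic atomic masses (Da) of the lightest stable isotope.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885271,
    "F": 18.99840316,
    "Br": 78.91833760,
    "I": 126.90447190,
    "Se": 79.91652130,
    "Fe": 55.93493633,
    "Mg": 23.98504170,
    "Ca": 39.96259086,
    "Zn": 63.92914201,
}

# Residue (i.e., dehydrated amino-acid) elemental compositions.
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

PROTON_MASS = 1.00727646688
ISOTOPE_SPACING = 1.003355  # averagine C13-C12 spacing, Da

STANDARD_RESIDUES = frozenset(RESIDUE_FORMULAS)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unrecognized elemental formulas."""


@dataclass(frozen=True)
class ElementalComposition:
    """Counts per chemical element symbol; the empty composition has mass 0."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symbol, count in self.counts.items():
            if symbol not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(
                    f"element count for {symbol!r} must be a non-negative "
                    f"integer, got {count!r}"
                )

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for symbol, count in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return ElementalComposition({s: c for s, c in merged.items() if c})

    def mass(self) -> float:
        return sum(ELEMENT_MASSES[s] * c for s, c in self.counts.items())


def parse_formula(formula: str) -> ElementalComposition:
    """Parse a Hill-style elemental formula ("C8H9NO3") into a composition.

    Raises :class:`FormulaError` naming the offending token on unknown
    element symbols or malformed counts.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula token at {formula[pos:]!r} in {formula!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        count = int(digits) if digits else 1
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass (Da) of a composition: sum of count x atomic mass."""
    return comp.mass()


def formula_mass(formula: str) -> float:
    """Convenience: monoisotopic mass of a formula string."""
    return monoisotopic_mass(parse_formula(formula))


WATER_MASS = formula_mass("H2O")
OXYGEN_MASS = ELEMENT_MASSES["O"]
NH3_MASS = formula_mass("NH3")

_RESIDUE_MASSES: dict[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class Peptide:
    """A peptide over the 20 standard one-letter codes.

    ``site_index`` is the 1-based position of the cross-linked residue within
    the peptide (e.g. 7 for the K of DSVTRQKEPRAPW, lysine 43 of the mature
    carrier protein). ``protein_span`` is the 1-based inclusive (start, end)
    within the mature carrier protein, when known.
    """

    sequence: str
    site_index: int | None = None
    protein_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"non-standard residue(s) {sorted(bad)} in {self.sequence!r}"
            )
        if self.site_index is not None and not (
            1 <= self.site_index <= len(self.sequence)
        ):
            raise ValueError(
                f"site_index {self.site_index} outside 1..{len(self.sequence)}"
            )
        if self.protein_span is not None:
            start, end = self.protein_span
            if end - start + 1 != len(self.sequence):
                raise ValueError("protein_span length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AdductMass:
    """Mass bookkeeping for a ligand attached by reductive amination.

    ``delta_mass`` is what the cross-link adds to the peptide;
    ``free_ligand_mass`` is the ligand before conjugation, exactly one oxygen
    heavier (Schiff base loses H2O, reduction adds H2; net -O).
    """

    delta_mass: float
    free_ligand_mass: float

    def __post_init__(self) -> None:
        if abs((self.free_ligand_mass - self.delta_mass) - OXYGEN_MASS) > 1e-9:
            raise ValueError(
                "free_ligand_mass - delta_mass must equal the oxygen "
                "monoisotopic mass"
            )


def residue_mass(aa: str) -> float:
    try:
        return _RESIDUE_MASSES[aa]
    except KeyError:
        raise ValueError(f"non-standard residue {aa!r}") from None


def peptide_mass(p: Peptide | str) -> float:
    """Neutral monoisotopic mass: sum of residue masses plus one water."""
    seq = p.sequence if isinstance(p, Peptide) else p
    if not seq:
        raise ValueError("empty peptide sequence")
    return sum(residue_mass(aa) for aa in seq) + WATER_MASS


def adduct_from_ligand(ligand_mass: float) -> AdductMass:
    """Adduct bookkeeping for a free ligand of the given monoisotopic mass."""
    if ligand_mass <= OXYGEN_MASS:
        raise ValueError(
            f"ligand mass {ligand_mass} Da must exceed one oxygen "
            f"({OXYGEN_MASS:.6f} Da)"
        )
    return AdductMass(delta_mass=ligand_mass - OXYGEN_MASS,
                      free_ligand_mass=ligand_mass)


def neutral_mass(mz: float, z: int) -> float:
    """Neutral mass M from m/z at positive charge z: M = z*mz - z*proton."""
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return z * mz - z * PROTON_MASS


def mz_from_neutral(neutral: float, z: int) -> float:
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return neutral / z + PROTON_MASS


def fragment_neutral(p: Peptide | str, series: str, index: int,
                     neutral_loss: str = "none") -> float:
    """Neutral mass of a b- or y-fragment (optionally minus NH3)."""
    seq = p.sequence if isinstance(p, Peptide) else p
    n = len(seq)
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} outside 1..{n - 1}")
    if series == "b":
        neutral = sum(residue_mass(aa) for aa in seq[:index])
    else:
        neutral = sum(residue_mass(aa) for aa in seq[n - index:]) + WATER_MASS
    if neutral_loss == "NH3":
        neutral -= NH3_MASS
    elif neutral_loss != "none":
        raise ValueError(f"unsupported neutral loss {neutral_loss!r}")
    return neutral


def fragment_mz(p: Peptide | str, series: str, index: int, z: int = 1,
                neutral_loss: str = "none") -> float:
    """Monoisotopic m/z of a b/y fragment at charge 1 or 2."""
    if z not in (1, 2):
        raise ValueError(f"fragment charge must be 1 or 2, got {z}")
    return mz_from_neutral(fragment_neutral(p, series, index, neutral_loss), z)


def isotope_targets(neutral: float, z: int, n_isotopes: int) -> list[float]:
    """m/z targets of isotopes M..M+(n-1) at charge z."""
    if n_isotopes < 1:
        raise ValueError("n_isotopes must be >= 1")
    return [mz_from_neutral(neutral + k * ISOTOPE_SPACING, z)
            for k in range(n_isotopes)]
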