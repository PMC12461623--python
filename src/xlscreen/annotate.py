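"""Compound annotation of Δ-mass values under a propagated-error tolerance.

The precursor's absolute mass error is set by the instrument accuracy on the
whole cross-linked peptide (e.g. 5 ppm of ~1786 Da for the 13-mer carrying
acetyl-6-formylpterin). Subtracting the exactly-known theoretical peptide
mass transfers that entire absolute error onto the small Δ-mass, so the
*relative* accuracy of the inferred ligand mass is much worse than the
instrument ppm — about 41 ppm for Ac-6-FP at 5 ppm precursor accuracy, and
worse still for lighter ligands. Annotation therefore matches the free-ligand
mass against a local compound table with a wide net (200 ppm) and flags which
matches survive the propagated tolerance (clamped to the practical 30-60 ppm
band used for shortlisting).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .masscalc import formula_mass

__all__ = [
    "ToleranceModel",
    "CompoundRecord",
    "CandidateMatch",
    "propagated_tolerance_ppm",
    "tolerance_curve",
    "load_compound_table",
    "bundled_compound_table",
    "match_compounds",
]

MAX_CANDIDATE_PPM = 200.0  # widest net for candidate generation
PRACTICAL_TOLERANCE_BAND = (30.0, 60.0)  # ppm clamp for shortlisting


@dataclass(frozen=True)
class ToleranceModel:
    """Error propagation from precursor accuracy to ligand-mass accuracy.

    ``denominator_convention`` selects what the propagated absolute error is
    expressed relative to: the free-ligand mass ("ligand") or the Δ-mass
    ("delta", default — reproduces the 40-45 ppm worked example for
    Ac-6-FP).
    """

    precursor_ppm: float = 5.0
    crosslinked_peptide_mass: float | None = None
    denominator_convention: str = "delta"

    def __post_init__(self) -> None:
        if self.precursor_ppm <= 0:
            raise ValueError("precursor_ppm must be positive")
        if self.denominator_convention not in ("ligand", "delta"):
            raise ValueError("denominator_convention must be 'ligand' or "
                             "'delta'")


def propagated_tolerance_ppm(tm: ToleranceModel, ligand_mass: float,
                             peptide_mass_da: float | None = None) -> float:
    """ppm tolerance on a ligand of the given free mass.

    absolute error = precursor_ppm x 1e-6 x (peptide + Δ) mass; returned ppm
    = absolute error / denominator mass x 1e6. Strictly decreasing in the
    ligand mass at fixed peptide.
    """
    from .masscalc import OXYGEN_MASS

    if ligand_mass <= 0:
        raise ValueError("ligand mass must be positive")
    delta = ligand_mass - OXYGEN_MASS
    if delta <= 0:
        raise ValueError(
            f"ligand mass {ligand_mass} Da leaves no positive delta mass")
    if tm.crosslinked_peptide_mass is not None:
        crosslinked = tm.crosslinked_peptide_mass
    elif peptide_mass_da is not None:
        crosslinked = peptide_mass_da + delta
    else:
        raise ValueError("crosslinked peptide mass unknown: set it on the "
                         "ToleranceModel or pass peptide_mass_da")
    absolute_error = tm.precursor_ppm * 1e-6 * crosslinked
    denominator = ligand_mass if tm.denominator_convention == "ligand" else delta
    return absolute_error / denominator * 1e6


def tolerance_curve(tm: ToleranceModel, mass_grid,
                    peptide_mass_da: float | None = None) -> list[dict]:
    """Propagated tolerance over a grid of ligand masses (monotone
    decreasing)."""
    grid = list(mass_grid)
    if not grid:
        raise ValueError("empty ligand-mass grid")
    return [{"ligand_mass": float(m),
             "tolerance_ppm": propagated_tolerance_ppm(tm, m, peptide_mass_da)}
            for m in grid]


@dataclass(frozen=True)
class CompoundRecord:
    """One compound-table entry; the mass is computed from the formula when
    absent, and when both are present they must agree to < 1e-4 Da."""

    name: str
    formula: str | None
    monoisotopic_mass: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if self.formula:
            computed = formula_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) >= 1e-4:
                raise ValueError(
                    f"{self.name}: formula {self.formula} computes to "
                    f"{computed:.5f} Da, stored mass is "
                    f"{self.monoisotopic_mass:.5f} Da")


@dataclass(frozen=True)
class CandidateMatch:
    compound: CompoundRecord
    free_ligand_mass: float
    ppm_error: float  # signed: (compound - observed)/observed
    applied_tolerance_ppm: float
    within_propagated_tolerance: bool


def load_compound_table(path) -> list[CompoundRecord]:
    """Read a compound TSV with columns name, formula, monoisotopic_mass
    (either of the last two may be blank, not both)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"compound table {path} must have a 'name' column")
        for row in reader:
            name = (row.get("name") or "").strip()
            formula = (row.get("formula") or "").strip() or None
            mass_str = (row.get("monoisotopic_mass") or "").strip()
            if not name:
                continue
            if mass_str:
                mass = float(mass_str)
            elif formula:
                mass = formula_mass(formula)
            else:
                raise ValueError(
                    f"compound {name!r}: need a formula or a mass")
            records.append(CompoundRecord(
                name, formula, mass, (row.get("source") or "").strip()))
    if not records:
        raise ValueError(f"no compounds in {path}")
    return records


def bundled_compound_table() -> list[CompoundRecord]:
    """The small bundled table of B-vitamin vitamers, pterins and
    riboflavin-pathway compounds."""
    ref = importlib.resources.files("xlscreen").joinpath("data/compounds.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_compound_table(Path(path))


def match_compounds(free_ligand_mass: float,
                    table: list[CompoundRecord],
                    tm: ToleranceModel,
                    peptide_mass_da: float | None = None,
                    max_ppm: float = MAX_CANDIDATE_PPM,
                    ) -> list[CandidateMatch]:
    """Rank compounds against an observed free-ligand mass.

    Every compound within ``max_ppm`` (default 200) is emitted, ranked by
    |ppm error| with ties alphabetical; each match is flagged by whether it
    survives the propagated tolerance, clamped to the practical 30-60 ppm
    shortlisting band.
    """
    if free_ligand_mass <= 0:
        raise ValueError("free ligand mass must be positive")
    tol = propagated_tolerance_ppm(tm, free_ligand_mass, peptide_mass_da)
    lo, hi = PRACTICAL_TOLERANCE_BAND
    applied = float(np.clip(tol, lo, hi))
    matches = []
    for comp in table:
        ppm = (comp.monoisotopic_mass - free_ligand_mass) \
            / free_ligand_mass * 1e6
        if abs(ppm) > max_ppm:
            continue
        matches.append(CandidateMatch(
            compound=comp, free_ligand_mass=free_ligand_mass,
            ppm_error=ppm, applied_tolerance_ppm=applied,
            within_propagated_tolerance=abs(ppm) <= applied))
    matches.sort(key=lambda m: (abs(m.ppm_error), m.compound.name))
    return matches
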