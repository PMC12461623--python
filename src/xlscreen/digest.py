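"""In silico proteolysis and reporter-peptide selection.

The screen needs one proteolytic peptide that contains the cross-linking site
(lysine 43 of the mature carrier protein) and behaves well on LC-MS. This
module digests the carrier sequence under a cleavage rule and ranks the
site-covering products; for MR1 under chymotrypsin the winner is the 13-mer
DSVTRQKEPRAPW (mature residues 37-49, site at peptide position 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .masscalc import Peptide, STANDARD_RESIDUES

__all__ = [
    "EnzymeRule",
    "DigestProduct",
    "CHYMOTRYPSIN",
    "CHYMOTRYPSIN_HIGH_SPECIFICITY",
    "TRYPSIN",
    "ENZYMES",
    "digest",
    "select_reporter_peptide",
    "read_protein_fasta",
]


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity: cut C-terminal of ``cleave_after`` residues,
    blocked when the next residue is in ``blocked_by_next`` (classically
    proline)."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = field(default_factory=frozenset)
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def with_missed(self, n: int) -> "EnzymeRule":
        return EnzymeRule(self.name, self.cleave_after, self.blocked_by_next, n)


CHYMOTRYPSIN = EnzymeRule("chymotrypsin", frozenset("FWYLM"), frozenset("P"))
CHYMOTRYPSIN_HIGH_SPECIFICITY = EnzymeRule(
    "chymotrypsin-high-specificity", frozenset("FWY"), frozenset("P"))
TRYPSIN = EnzymeRule("trypsin", frozenset("KR"), frozenset("P"))

ENZYMES: dict[str, EnzymeRule] = {
    e.name: e for e in (CHYMOTRYPSIN, CHYMOTRYPSIN_HIGH_SPECIFICITY, TRYPSIN)
}


@dataclass(frozen=True)
class DigestProduct:
    peptide: Peptide
    start: int  # 1-based inclusive in the protein
    end: int
    n_missed: int


def _cleavage_points(protein: str, rule: EnzymeRule) -> list[int]:
    """0-based indices after which the backbone is cut; termini are always
    boundaries (0 and len are implicit)."""
    points = []
    for i, aa in enumerate(protein[:-1]):
        if aa in rule.cleave_after and protein[i + 1] not in rule.blocked_by_next:
            points.append(i + 1)
    return points


def digest(protein: str, rule: EnzymeRule) -> list[DigestProduct]:
    """All cleavage-consistent products with up to ``rule.missed_cleavages``
    missed cleavages, ordered by (start, end).

    The zero-missed-cleavage products partition the protein.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in protein")
    boundaries = [0] + _cleavage_points(protein, rule) + [len(protein)]
    products = []
    for i in range(len(boundaries) - 1):
        for missed in range(rule.missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(boundaries):
                break
            start, end = boundaries[i], boundaries[j]
            products.append(
                DigestProduct(
                    peptide=Peptide(protein[start:end],
                                    protein_span=(start + 1, end)),
                    start=start + 1,
                    end=end,
                    n_missed=missed,
                )
            )
    products.sort(key=lambda p: (p.start, p.end))
    return products


def select_reporter_peptide(
    products: list[DigestProduct],
    site: int,
    ideal_length: tuple[int, int] = (8, 20),
) -> list[DigestProduct]:
    """Rank the digestion products that cover the 1-based protein ``site``.

    Ranking: distance of the peptide length to the ideal range (0 when the
    length falls inside it), then fewer missed cleavages, then alphabetical
    sequence. Each returned product carries its ``site_index`` relative to
    the peptide. Returns an empty list (with a warning) when nothing covers
    the site.
    """
    if products and not all(isinstance(p, DigestProduct) for p in products):
        raise TypeError("products must be DigestProduct instances")
    if site < 1 or (products and site > max(p.end for p in products)):
        raise ValueError(f"site {site} outside the digested protein")
    lo, hi = ideal_length
    covering = []
    for prod in products:
        if prod.start <= site <= prod.end:
            pep = Peptide(
                prod.peptide.sequence,
                site_index=site - prod.start + 1,
                protein_span=(prod.start, prod.end),
            )
            covering.append(DigestProduct(pep, prod.start, prod.end, prod.n_missed))

    def length_penalty(p: DigestProduct) -> int:
        n = len(p.peptide)
        if n < lo:
            return lo - n
        if n > hi:
            return n - hi
        return 0

    covering.sort(key=lambda p: (length_penalty(p), p.n_missed,
                                 p.peptide.sequence))
    if not covering:
        warnings.warn(f"no digestion product covers protein position {site}")
    return covering


def read_protein_fasta(path, identifier: str | None = None) -> str:
    """Read a protein sequence from FASTA; first record unless an identifier
    is given."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if identifier is None:
        return str(records[0].seq).upper()
    for rec in records:
        if rec.id == identifier:
            return str(rec.seq).upper()
    raise KeyError(f"identifier {identifier!r} not found in {path}")
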