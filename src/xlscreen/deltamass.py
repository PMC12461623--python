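"""Reporter-ion Δ-mass screen.

The screen exploits one fact: whatever unknown ligand is attached to the
cross-linking site, every fragment of the reporter peptide that does NOT
contain that site keeps its theoretical m/z. Those ligand-unaffected b- and
y-ions (at charges 1-2), plus precursor-survivor ions derived from each
spectrum's own observed precursor (charges 2-3, with and without NH3 loss),
form a reporter set whose presence evidences the peptide backbone regardless
of the modification. Spectra rich in reporters are retained, and the ligand
mass is read off as

    Δ-mass = observed precursor neutral mass − theoretical peptide mass,

corrected to the free-ligand mass by adding one oxygen (the mass lost in
Schiff-base formation plus reductive amination).

Shortlisting applies three criteria: (A) retention time within a window of
the unmodified peptide's reference RT (±15 min on a 2 h gradient, scaled
proportionally for other gradient lengths), (B) a minimum number of matched
reporter ions (default 10; a permissive benchmarking mode uses 4), and
(C) a Δ-mass window — candidates above 40 Da, unmodified controls within
−0.05..4.05 Da (covering M..M+4 monoisotopic mis-picks).

The by-eye spectral vetting of the original workflow is replaced by three
deterministic quality scores (matched-TIC fraction, ladder continuity,
similarity to the control consensus) that annotate but never delete hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .masscalc import (
    ISOTOPE_SPACING,
    NH3_MASS,
    OXYGEN_MASS,
    Peptide,
    fragment_mz,
    mz_from_neutral,
    neutral_mass,
    peptide_mass,
)
from .spectra_io import Run, SpectrumRecord

__all__ = [
    "Reporter",
    "ReporterSet",
    "ReporterMatch",
    "MatchResult",
    "QualityScores",
    "DeltaMassHit",
    "LigandCluster",
    "ScreenConfig",
    "build_reporter_set",
    "match_reporters",
    "compute_delta_mass",
    "reference_rt",
    "quality_scores",
    "screen_spectra",
    "cluster_hits",
]


@dataclass(frozen=True)
class Reporter:
    """One reporter-ion target. Ladder reporters have a fixed theoretical
    m/z; precursor reporters are derived per spectrum from the observed
    precursor neutral mass (``mz`` is None until then)."""

    label: str
    kind: str  # "ladder" | "precursor"
    series: str | None  # "b" | "y" for ladder reporters
    index: int | None
    charge: int
    neutral_loss: str = "none"
    mz: float | None = None


@dataclass(frozen=True)
class ScreenConfig:
    """All screen thresholds in one place (YAML-configurable via the CLI)."""

    frag_tol: float = 0.03  # fragment match tolerance
    frag_tol_unit: str = "Da"  # "Da" | "ppm"
    precursor_ppm: float = 5.0
    min_reporters: int = 10  # benchmarking mode: 4
    rt_window: float = 15.0  # minutes at the 120-min reference gradient
    reference_gradient: float = 120.0
    control_window: tuple[float, float] = (-0.05, 4.05)
    candidate_min_delta: float = 40.0
    charges: tuple[int, ...] = (2, 3, 4, 5)  # enumerated when z unknown
    reference_rt: float | None = None  # override when no control hits exist
    cluster_tol_ppm: float = 50.0  # matches the propagated-error band on delta
    # report-time quality flags; annotate, never delete
    min_tic_fraction: float = 0.1
    min_ladder_continuity: int = 3
    min_control_similarity: float = 0.5

    def rt_window_for(self, gradient_length: float) -> float:
        """RT criterion scales proportionally with gradient length."""
        return self.rt_window * gradient_length / self.reference_gradient

    def frag_tol_da(self, mz: float) -> float:
        if self.frag_tol_unit == "Da":
            return self.frag_tol
        if self.frag_tol_unit == "ppm":
            return self.frag_tol * 1e-6 * mz
        raise ValueError(f"unknown tolerance unit {self.frag_tol_unit!r}")


@dataclass(frozen=True)
class ReporterSet:
    """Ligand-unaffected ladder reporters plus the per-spectrum precursor
    survivor rule. For DSVTRQKEPRAPW with the site at position 7 the ladder
    holds 24 entries (b1-b6, y1-y6 at charges 1-2) and each spectrum adds 4
    precursor reporters (2+/3+, each with and without NH3 loss)."""

    peptide: Peptide
    ladder: tuple[Reporter, ...]
    precursor_rules: tuple[Reporter, ...]

    @property
    def size(self) -> int:
        return len(self.ladder) + len(self.precursor_rules)

    def reporters_for(self, observed_neutral: float) -> list[Reporter]:
        """Full reporter list for one spectrum: ladder plus survivor ions at
        the spectrum's own observed precursor neutral mass."""
        out = list(self.ladder)
        for rule in self.precursor_rules:
            loss = NH3_MASS if rule.neutral_loss == "NH3" else 0.0
            out.append(replace(
                rule, mz=mz_from_neutral(observed_neutral - loss, rule.charge)))
        return out


def build_reporter_set(p: Peptide) -> ReporterSet:
    """Enumerate the ligand-unaffected reporters of a site-bearing peptide:
    b_i for i < site_index and y_j for j <= len - site_index, at charges 1
    and 2, plus the four precursor-survivor rules."""
    if p.site_index is None:
        raise ValueError("peptide must carry a site_index")
    k, n = p.site_index, len(p)
    ladder = []
    for z in (1, 2):
        for i in range(1, k):
            ladder.append(Reporter(f"b{i}^{z}", "ladder", "b", i, z,
                                   mz=fragment_mz(p, "b", i, z)))
        for j in range(1, n - k + 1):
            ladder.append(Reporter(f"y{j}^{z}", "ladder", "y", j, z,
                                   mz=fragment_mz(p, "y", j, z)))
    precursor_rules = tuple(
        Reporter(f"p^{z}" + ("-NH3" if loss == "NH3" else ""),
                 "precursor", None, None, z, neutral_loss=loss)
        for z in (2, 3) for loss in ("none", "NH3"))
    return ReporterSet(p, tuple(ladder), precursor_rules)


@dataclass(frozen=True)
class ReporterMatch:
    reporter: Reporter
    peak_index: int
    peak_mz: float
    peak_intensity: float
    mz_error: float  # observed - theoretical, Da


@dataclass(frozen=True)
class MatchResult:
    n_reporters: int
    matches: tuple[ReporterMatch, ...]

    @property
    def matched_intensity(self) -> float:
        return float(sum(m.peak_intensity for m in self.matches))


def match_reporters(s: SpectrumRecord, rs: ReporterSet,
                    cfg: ScreenConfig | None = None,
                    observed_neutral: float | None = None) -> MatchResult:
    """Match reporters to the spectrum's most intense peaks within tolerance.

    A peak may satisfy at most one reporter: reporters are processed
    greedily in order of their best candidate-peak intensity (ties broken by
    smaller |m/z error|) and each takes its most intense still-unassigned
    peak within tolerance.

    ``observed_neutral`` fixes the precursor-survivor targets; by default it
    is derived from the spectrum's own precursor m/z and charge (survivors
    are skipped when the charge is unknown and no neutral is supplied).
    """
    cfg = cfg or ScreenConfig()
    if observed_neutral is None and s.precursor_mz is not None \
            and s.precursor_z is not None:
        observed_neutral = neutral_mass(s.precursor_mz, s.precursor_z)
    reporters = (rs.reporters_for(observed_neutral)
                 if observed_neutral is not None else list(rs.ladder))
    if s.n_peaks == 0:
        return MatchResult(0, ())

    mz, inten = s.mz, s.intensity
    candidates = []  # (reporter, [peak indices within tol sorted by intensity])
    for rep in reporters:
        tol = cfg.frag_tol_da(rep.mz)
        lo = np.searchsorted(mz, rep.mz - tol, side="left")
        hi = np.searchsorted(mz, rep.mz + tol, side="right")
        if hi <= lo:
            continue
        idx = np.arange(lo, hi)
        order = sorted(idx, key=lambda i: (-inten[i], abs(mz[i] - rep.mz)))
        candidates.append((rep, order))
    # greedy by best candidate intensity, ties by |error|
    candidates.sort(key=lambda c: (-inten[c[1][0]],
                                   abs(mz[c[1][0]] - c[0].mz)))
    used: set[int] = set()
    matches = []
    for rep, order in candidates:
        for i in order:
            if i not in used:
                used.add(i)
                matches.append(ReporterMatch(rep, int(i), float(mz[i]),
                                             float(inten[i]),
                                             float(mz[i] - rep.mz)))
                break
    return MatchResult(len(matches), tuple(matches))


@dataclass(frozen=True)
class DeltaMassResult:
    charge: int
    observed_neutral: float
    delta_mass: float
    free_ligand_mass: float
    isotope_k: int
    isotope_corrected_delta: float
    charge_enumerated: bool = False


def _isotope_correct(delta: float, k_max: int = 4) -> tuple[int, float]:
    """k in 0..k_max minimizing |delta - k*spacing|; meaningful for deltas in
    the control window (monoisotopic mis-picks), reported alongside the raw
    value elsewhere."""
    ks = np.arange(k_max + 1)
    residuals = delta - ks * ISOTOPE_SPACING
    k = int(ks[np.argmin(np.abs(residuals))])
    return k, float(delta - k * ISOTOPE_SPACING)


def compute_delta_mass(s: SpectrumRecord, p: Peptide | str,
                       charges: tuple[int, ...] = (2, 3, 4, 5),
                       ) -> list[DeltaMassResult]:
    """Δ-mass of one MS2 spectrum against the theoretical peptide mass.

    Returns a single result when the precursor charge is known; otherwise
    one flagged result per enumerated charge.
    """
    if s.precursor_mz is None:
        raise ValueError(f"spectrum {s.scan_id!r} has no precursor m/z")
    theo = peptide_mass(p)
    zs = [s.precursor_z] if s.precursor_z is not None else list(charges)
    enumerated = s.precursor_z is None
    results = []
    for z in zs:
        observed = neutral_mass(s.precursor_mz, z)
        delta = observed - theo
        k, corrected = _isotope_correct(delta)
        results.append(DeltaMassResult(
            charge=z, observed_neutral=observed, delta_mass=delta,
            free_ligand_mass=delta + OXYGEN_MASS, isotope_k=k,
            isotope_corrected_delta=corrected, charge_enumerated=enumerated))
    return results


@dataclass(frozen=True)
class QualityScores:
    matched_tic_fraction: float
    ladder_continuity: int
    control_similarity: float

    def flags(self, cfg: ScreenConfig) -> dict[str, bool]:
        return {
            "tic_ok": self.matched_tic_fraction >= cfg.min_tic_fraction,
            "ladder_ok": self.ladder_continuity >= cfg.min_ladder_continuity,
            "similarity_ok":
                self.control_similarity >= cfg.min_control_similarity,
        }


@dataclass
class DeltaMassHit:
    scan_id: str
    rt: float
    precursor_z: int
    observed_neutral: float
    delta_mass: float
    free_ligand_mass: float
    isotope_k: int
    isotope_corrected_delta: float
    n_reporters: int
    matched_intensity: float
    hit_class: str  # "candidate" | "control"
    charge_enumerated: bool = False
    quality: QualityScores | None = None
    match: MatchResult | None = None


def _reporter_vector(rs: ReporterSet, match: MatchResult) -> np.ndarray:
    """Intensity vector over the reporter universe (ladder + survivor
    labels), L2-normalized; used for control-consensus similarity."""
    labels = [r.label for r in rs.ladder] + [r.label for r in rs.precursor_rules]
    pos = {lab: i for i, lab in enumerate(labels)}
    v = np.zeros(len(labels))
    for m in match.matches:
        v[pos[m.reporter.label]] = m.peak_intensity
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _ladder_continuity(match: MatchResult) -> int:
    best = 0
    for series in ("b", "y"):
        idx = sorted({m.reporter.index for m in match.matches
                      if m.reporter.kind == "ladder"
                      and m.reporter.series == series})
        run = longest = 0
        prev = None
        for i in idx:
            run = run + 1 if prev is not None and i == prev + 1 else 1
            longest = max(longest, run)
            prev = i
        best = max(best, longest)
    return best


def quality_scores(s: SpectrumRecord, rs: ReporterSet, match: MatchResult,
                   control_consensus: np.ndarray | None) -> QualityScores:
    tic = s.tic
    frac = match.matched_intensity / tic if tic > 0 else 0.0
    sim = 0.0
    if control_consensus is not None and np.linalg.norm(control_consensus) > 0:
        v = _reporter_vector(rs, match)
        sim = float(np.dot(v, control_consensus)
                    / max(np.linalg.norm(control_consensus), 1e-30))
        sim = float(np.clip(sim, 0.0, 1.0))
    return QualityScores(min(frac, 1.0), _ladder_continuity(match), sim)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    cutoff = 0.5 * cum[-1]
    return float(values[np.searchsorted(cum, cutoff)])


def reference_rt(control_hits: list[DeltaMassHit],
                 cfg: ScreenConfig | None = None) -> float:
    """Intensity-weighted median RT of control-class (unmodified) hits; the
    anchor of the RT-window criterion."""
    cfg = cfg or ScreenConfig()
    if not control_hits:
        if cfg.reference_rt is not None:
            return cfg.reference_rt
        raise ValueError(
            "no control-class hits found; supply reference_rt in the config")
    rts = np.array([h.rt for h in control_hits])
    weights = np.array([max(h.matched_intensity, 1e-30) for h in control_hits])
    return _weighted_median(rts, weights)


def screen_spectra(run: Run, p: Peptide,
                   cfg: ScreenConfig | None = None,
                   ) -> tuple[list[DeltaMassHit], list[DeltaMassHit]]:
    """Apply the full A/B/C screen to a run.

    Returns ``(candidate_hits, control_hits)`` — disjoint lists. Every hit
    carries at least ``min_reporters`` matched reporters. Controls fall in
    the control Δ-mass window; candidates exceed the candidate Δ-mass
    threshold and lie within the RT window around the control reference RT.
    Quality scores (including similarity to the control consensus) annotate
    every hit.
    """
    cfg = cfg or ScreenConfig()
    rs = build_reporter_set(p)
    lo, hi = cfg.control_window

    provisional: list[DeltaMassHit] = []
    for s in run.ms2:
        for res in compute_delta_mass(s, p, cfg.charges):
            match = match_reporters(s, rs, cfg,
                                    observed_neutral=res.observed_neutral)
            if match.n_reporters < cfg.min_reporters:
                continue
            if lo <= res.delta_mass <= hi:
                hclass = "control"
            elif res.delta_mass > cfg.candidate_min_delta:
                hclass = "candidate"
            else:
                continue
            provisional.append(DeltaMassHit(
                scan_id=s.scan_id, rt=s.rt, precursor_z=res.charge,
                observed_neutral=res.observed_neutral,
                delta_mass=res.delta_mass,
                free_ligand_mass=res.free_ligand_mass,
                isotope_k=res.isotope_k,
                isotope_corrected_delta=res.isotope_corrected_delta,
                n_reporters=match.n_reporters,
                matched_intensity=match.matched_intensity,
                hit_class=hclass, charge_enumerated=res.charge_enumerated,
                match=match))

    controls = [h for h in provisional if h.hit_class == "control"]
    candidates = [h for h in provisional if h.hit_class == "candidate"]
    if candidates:
        ref = reference_rt(controls, cfg)
        window = cfg.rt_window_for(run.gradient_length)
        candidates = [h for h in candidates if abs(h.rt - ref) <= window]

    # control consensus for the similarity score
    consensus = None
    if controls:
        vecs = [_reporter_vector(rs, h.match) for h in controls]
        consensus = np.mean(vecs, axis=0)
        norm = np.linalg.norm(consensus)
        if norm > 0:
            consensus = consensus / norm
    spectra_by_id = {s.scan_id: s for s in run.ms2}
    for h in controls + candidates:
        h.quality = quality_scores(spectra_by_id[h.scan_id], rs, h.match,
                                   consensus)
    return candidates, controls


@dataclass
class LigandCluster:
    """Candidate hits agreeing on one Δ-mass, single-linkage at the
    clustering tolerance; the representative is the intensity-weighted mean
    Δ-mass."""

    delta_mass: float
    free_ligand_mass: float
    hits: list[DeltaMassHit] = field(default_factory=list)

    @property
    def n_spectra(self) -> int:
        return len(self.hits)

    @property
    def total_reporters(self) -> int:
        return sum(h.n_reporters for h in self.hits)

    @property
    def best_hit(self) -> DeltaMassHit:
        return max(self.hits, key=lambda h: (
            h.n_reporters,
            h.quality.matched_tic_fraction if h.quality else 0.0))


def _weighted_mean_delta(hits: list[DeltaMassHit]) -> float:
    w = np.array([max(h.matched_intensity, 1e-30) for h in hits])
    d = np.array([h.delta_mass for h in hits])
    return float(np.average(d, weights=w))


def _split_to_tolerance(hits: list[DeltaMassHit],
                        tol_ppm: float) -> list[list[DeltaMassHit]]:
    """Recursively split a sorted chain at its widest gap until every member
    lies within tolerance of the group's weighted-mean representative."""
    rep = _weighted_mean_delta(hits)
    tol = tol_ppm * 1e-6 * max(abs(rep), 1.0)
    if all(abs(h.delta_mass - rep) <= tol for h in hits) or len(hits) == 1:
        return [hits]
    gaps = [hits[i + 1].delta_mass - hits[i].delta_mass
            for i in range(len(hits) - 1)]
    cut = int(np.argmax(gaps)) + 1
    return (_split_to_tolerance(hits[:cut], tol_ppm)
            + _split_to_tolerance(hits[cut:], tol_ppm))


def cluster_hits(candidates: list[DeltaMassHit],
                 tol_ppm: float = 50.0) -> list[LigandCluster]:
    """Aggregate per-spectrum candidate hits into ligand-mass clusters.

    Single-linkage at ``tol_ppm`` on Δ-mass, sorted by spectrum count then
    summed reporter count (both descending).
    """
    if not candidates:
        return []
    hits = sorted(candidates, key=lambda h: h.delta_mass)
    chains: list[list[DeltaMassHit]] = [[hits[0]]]
    for h in hits[1:]:
        prev = chains[-1][-1]
        tol = tol_ppm * 1e-6 * max(abs(prev.delta_mass), 1.0)
        if h.delta_mass - prev.delta_mass <= tol:
            chains[-1].append(h)
        else:
            chains.append([h])
    groups: list[list[DeltaMassHit]] = []
    for chain in chains:
        groups.extend(_split_to_tolerance(chain, tol_ppm))
    clusters = []
    for grp in groups:
        rep = _weighted_mean_delta(grp)
        clusters.append(LigandCluster(rep, rep + OXYGEN_MASS, grp))
    clusters.sort(key=lambda c: (-c.n_spectra, -c.total_reporters))
    return clusters
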