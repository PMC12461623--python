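"""XIC extraction and AUC-ratio cross-linking-yield estimation.

The cross-linking yield is reported as the ratio of chromatographic areas:
the XIC of the ligand-bound peptide over the XIC of the unmodified peptide,
each summing the three most abundant isotopes ([M], [M+1], [M+2]). Yields
are nominal ratios — no ionization-efficiency correction is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .masscalc import AdductMass, Peptide, isotope_targets, peptide_mass
from .spectra_io import Run

__all__ = ["XICTrace", "YieldEstimate", "extract_xic", "auc",
           "crosslink_yield"]


@dataclass
class XICTrace:
    """Summed-isotope extracted-ion chromatogram of one neutral species."""

    neutral: float
    charge: int
    n_isotopes: int
    mz_tol_ppm: float
    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("XIC retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("XIC intensities must be non-negative")


def extract_xic(run: Run, neutral: float, z: int, n_isotopes: int = 3,
                mz_tol_ppm: float = 10.0,
                rt_range: tuple[float, float] | None = None) -> XICTrace:
    """Per-MS1-scan summed intensity within ``mz_tol_ppm`` of each isotope
    target of the species; one trace point per scan in range."""
    if not run.has_ms1:
        raise ValueError(
            "run has no MS1 scans (MGF input?); XIC quantification needs "
            "mzML with survey scans")
    targets = np.asarray(isotope_targets(neutral, z, n_isotopes))
    tols = mz_tol_ppm * 1e-6 * targets
    rts, sums = [], []
    for scan in run.ms1:
        if rt_range is not None and not (rt_range[0] <= scan.rt <= rt_range[1]):
            continue
        total = 0.0
        if scan.n_peaks:
            lo = np.searchsorted(scan.mz, targets - tols, side="left")
            hi = np.searchsorted(scan.mz, targets + tols, side="right")
            for a, b in zip(lo, hi):
                if b > a:
                    total += float(scan.intensity[a:b].sum())
        rts.append(scan.rt)
        sums.append(total)
    return XICTrace(neutral, z, n_isotopes, mz_tol_ppm,
                    np.asarray(rts), np.asarray(sums))


def auc(trace: XICTrace) -> float:
    """Trapezoidal area under the XIC, in intensity·min."""
    if trace.rt.size < 2:
        warnings.warn("XIC has fewer than 2 points; AUC reported as 0")
        return 0.0
    return float(np.trapezoid(trace.intensity, trace.rt))


@dataclass
class YieldEstimate:
    auc_modified: float
    auc_unmodified: float
    charge: int

    @property
    def defined(self) -> bool:
        return self.auc_unmodified > 0

    @property
    def yield_percent(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.auc_modified / self.auc_unmodified


def crosslink_yield(run: Run, p: Peptide | str, adduct: AdductMass,
                    z: int, n_isotopes: int = 3, mz_tol_ppm: float = 10.0,
                    rt_range: tuple[float, float] | None = None,
                    ) -> tuple[YieldEstimate, XICTrace, XICTrace]:
    """AUC-ratio yield of the ligand-bound versus unmodified peptide.

    Returns the estimate plus both traces (modified, unmodified) for
    plotting. A zero unmodified AUC leaves the yield undefined (flagged via
    ``YieldEstimate.defined``).
    """
    base = peptide_mass(p)
    unmod = extract_xic(run, base, z, n_isotopes, mz_tol_ppm, rt_range)
    mod = extract_xic(run, base + adduct.delta_mass, z, n_isotopes,
                      mz_tol_ppm, rt_range)
    est = YieldEstimate(auc(mod), auc(unmod), z)
    if not est.defined:
        warnings.warn("unmodified-peptide AUC is zero; yield undefined")
    return est, mod, unmod
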