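"""Deterministic synthetic LC-MS/MS runs with planted ground truth.

The generator emulates the acquisition the screen is built for: a carrier
peptide (by default the chymotryptic 13-mer DSVTRQKEPRAPW, site at position
7) eluting as a Gaussian peak on a 2 h gradient, observed as MS1 isotope
envelopes ([M], [M+1], [M+2]) and data-dependent MS2 spectra with b/y
fragment ladders, precursor-survivor ions (with and without NH3 loss) and
ppm-scale Gaussian mass error, at precursor charge states 2-5. Ligand-bound
species are planted with their fragments C-terminal/N-terminal of the site
shifted by the adduct Δ-mass and their MS1 amplitude set by the planted
AUC ratio. Decoy spectra — shuffled-sequence peptide ladders at random
precursor masses — provide a conservative false-positive challenge.

Every generated MS2 spectrum appears exactly once in the ground-truth
manifest; the run is byte-reproducible from the (mandatory) seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .masscalc import (
    ISOTOPE_SPACING,
    NH3_MASS,
    OXYGEN_MASS,
    Peptide,
    adduct_from_ligand,
    formula_mass,
    fragment_mz,
    mz_from_neutral,
    neutral_mass,
    peptide_mass,
)
from .spectra_io import Run, SpectrumRecord, write_run_mgf, write_run_mzml

__all__ = [
    "PlantedLigand",
    "SimulationConfig",
    "GroundTruthManifest",
    "simulate_run",
    "write_run",
    "write_manifest",
]

# MS1 isotope envelope ([M], [M+1], [M+2]) relative abundances for a
# ~1.6-1.8 kDa peptide; identical for all species so planted AUC ratios are
# exact amplitude ratios.
_ENVELOPE = (1.0, 0.85, 0.45)


@dataclass(frozen=True)
class PlantedLigand:
    """A ligand planted onto the site: identified by formula or free mass."""

    name: str
    formula: str | None = None
    mass: float | None = None
    n_spectra: int = 3
    auc_ratio: float = 0.08  # modified:unmodified MS1 amplitude ratio

    def free_mass(self) -> float:
        if self.mass is not None:
            return self.mass
        if self.formula is not None:
            return formula_mass(self.formula)
        raise ValueError(f"ligand {self.name!r}: need a formula or a mass")

    def delta_mass(self) -> float:
        return adduct_from_ligand(self.free_mass()).delta_mass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic run; the seed is mandatory."""

    seed: int
    peptide: str = "DSVTRQKEPRAPW"
    site_index: int = 7
    ligands: tuple[PlantedLigand, ...] = (
        PlantedLigand("acetyl-6-formylpterin", formula="C9H7N5O3"),)
    n_unmodified_spectra: int = 5
    apex_rt: float = 42.0  # minutes; unmodified elution apex
    modified_rt_offset: float = 1.5  # modified species elutes nearby (<2 min)
    elution_sigma: float = 0.15  # minutes
    base_amplitude: float = 1.0e6
    charges: tuple[int, ...] = (2, 3, 4, 5)
    charge_weights: tuple[float, ...] = (0.2, 0.6, 0.15, 0.05)
    ms1_charge: int = 3
    precursor_ppm_sd: float = 5.0 / 3.0  # so ~99.7% within the 5 ppm spec
    fragment_ppm_sd: float = 3.0
    ladder_completeness: float = 1.0
    noise_peaks: int = 30
    n_decoys: int = 100
    isotope_mispick_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    intensity_noise: float = 0.0  # multiplicative sd on MS1 points
    ms1_interval: float = 0.05  # minutes between survey scans
    gradient_length: float = 120.0
    include_ms1: bool = True

    def __post_init__(self) -> None:
        if self.elution_sigma <= 0:
            raise ValueError("elution_sigma must be positive")
        if not 0.0 <= self.ladder_completeness <= 1.0:
            raise ValueError("ladder_completeness must be in [0, 1]")
        if len(self.charges) != len(self.charge_weights):
            raise ValueError("charges and charge_weights must align")
        if abs(sum(self.isotope_mispick_probs) - 1.0) > 1e-9:
            raise ValueError("isotope_mispick_probs must sum to 1")
        if self.gradient_length <= 0 or self.ms1_interval <= 0:
            raise ValueError("gradient_length and ms1_interval must be "
                             "positive")
        if self.intensity_noise < 0:
            raise ValueError("intensity_noise must be >= 0")


@dataclass
class GroundTruthManifest:
    seed: int
    config: dict
    spectra: dict[str, dict]  # scan_id -> truth
    auc_ratios: dict[str, float]
    apex_rt: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _gaussian(t: np.ndarray, apex: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - apex) / sigma) ** 2)


def _ms1_scans(cfg: SimulationConfig, species: list[tuple[str, float, float,
                                                          float]],
               rng: np.random.Generator) -> list[SpectrumRecord]:
    """species: (name, neutral mass, amplitude, apex rt)."""
    times = np.arange(0.0, cfg.gradient_length + 1e-9, cfg.ms1_interval)
    scans = []
    for i, t in enumerate(times):
        mzs, intens = [], []
        for _name, neutral, amp, apex in species:
            height = amp * float(_gaussian(np.array([t]), apex,
                                           cfg.elution_sigma)[0])
            if height < amp * 1e-6:
                continue
            for k, rel in enumerate(_ENVELOPE):
                mz = mz_from_neutral(neutral + k * ISOTOPE_SPACING,
                                     cfg.ms1_charge)
                value = height * rel
                if cfg.intensity_noise > 0:
                    value *= max(0.0, 1.0 + cfg.intensity_noise * rng.normal())
                mzs.append(mz)
                intens.append(value)
        scans.append(SpectrumRecord(f"ms1_scan={i}", 1, float(t),
                                    np.asarray(mzs), np.asarray(intens)))
    return scans


def _ladder_peaks(seq: str, delta: float, site: int, cfg: SimulationConfig,
                  rng: np.random.Generator) -> tuple[list[float], list[float]]:
    """b/y ladder of ``seq`` with fragments containing the site shifted by
    ``delta``; each ion present with probability ladder_completeness."""
    n = len(seq)
    mzs, intens = [], []
    for series in ("b", "y"):
        for idx in range(1, n):
            contains_site = (idx >= site) if series == "b" \
                else (idx >= n - site + 1)
            shift = delta if contains_site else 0.0
            for z in (1, 2):
                if rng.random() > cfg.ladder_completeness:
                    continue
                mz = fragment_mz(seq, series, idx, z) + shift / z
                mz *= 1.0 + cfg.fragment_ppm_sd * 1e-6 * rng.normal()
                mzs.append(mz)
                intens.append(float(rng.lognormal(np.log(1.0e4), 0.5)))
    return mzs, intens


def _noise_peaks(cfg: SimulationConfig,
                 rng: np.random.Generator) -> tuple[list[float], list[float]]:
    mzs = rng.uniform(100.0, 2000.0, size=cfg.noise_peaks)
    intens = rng.lognormal(np.log(1.0e3), 0.7, size=cfg.noise_peaks)
    return list(mzs), list(intens)


def _ms2_spectrum(scan_id: str, seq: str, site: int, delta: float,
                  true_neutral: float, rt: float, cfg: SimulationConfig,
                  rng: np.random.Generator, with_survivors: bool = True,
                  ) -> tuple[SpectrumRecord, dict]:
    z = int(rng.choice(cfg.charges, p=np.asarray(cfg.charge_weights)
                       / sum(cfg.charge_weights)))
    k_iso = int(rng.choice(np.arange(len(cfg.isotope_mispick_probs)),
                           p=cfg.isotope_mispick_probs))
    picked_neutral = true_neutral + k_iso * ISOTOPE_SPACING
    prec_mz = mz_from_neutral(picked_neutral, z) \
        * (1.0 + cfg.precursor_ppm_sd * 1e-6 * rng.normal())
    mzs, intens = _ladder_peaks(seq, delta, site, cfg, rng)
    if with_survivors:
        observed_neutral = neutral_mass(prec_mz, z)
        for sz in (2, 3):
            for loss in (0.0, NH3_MASS):
                if rng.random() > cfg.ladder_completeness:
                    continue
                mz = mz_from_neutral(observed_neutral - loss, sz)
                mz *= 1.0 + cfg.fragment_ppm_sd * 1e-6 * rng.normal()
                mzs.append(mz)
                intens.append(float(rng.lognormal(np.log(3.0e4), 0.4)))
    nmz, nint = _noise_peaks(cfg, rng)
    spec = SpectrumRecord(scan_id, 2, rt, np.asarray(mzs + nmz),
                          np.asarray(intens + nint), precursor_mz=prec_mz,
                          precursor_z=z)
    truth = {"charge": z, "isotope_offset": k_iso, "rt": rt,
             "true_delta_mass": delta}
    return spec, truth


def _decoy_sequence(target: str, letters: list[str],
                    rng: np.random.Generator) -> str:
    """Shuffled-sequence decoy differing from the target at both termini.

    A permutation that conserves the target's terminal residues produces
    fragment ions identical to reporter ions, i.e. a half-target rather
    than a negative; as in standard decoy construction such shuffles are
    rejected and redrawn.
    """
    for _ in range(100):
        shuffled = "".join(rng.permutation(letters))
        if len(target) < 2 or (shuffled[0] != target[0]
                               and shuffled[-1] != target[-1]):
            return shuffled
    raise RuntimeError("could not draw a terminal-distinct decoy shuffle")


def simulate_run(cfg: SimulationConfig) -> tuple[Run, GroundTruthManifest]:
    """Generate one synthetic run plus its complete ground-truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    pep = Peptide(cfg.peptide, site_index=cfg.site_index)
    base = peptide_mass(pep)

    species = [("unmodified", base, cfg.base_amplitude, cfg.apex_rt)]
    for lig in cfg.ligands:
        species.append((lig.name, base + lig.delta_mass(),
                        cfg.base_amplitude * lig.auc_ratio,
                        cfg.apex_rt + cfg.modified_rt_offset))

    ms1 = _ms1_scans(cfg, species, rng) if cfg.include_ms1 else []

    ms2: list[SpectrumRecord] = []
    truth: dict[str, dict] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"ms2_scan={counter}"

    for _ in range(cfg.n_unmodified_spectra):
        rt = float(rng.uniform(cfg.apex_rt - cfg.elution_sigma,
                               cfg.apex_rt + cfg.elution_sigma))
        sid = next_id()
        spec, t = _ms2_spectrum(sid, cfg.peptide, cfg.site_index, 0.0, base,
                                rt, cfg, rng)
        ms2.append(spec)
        truth[sid] = {"class": "unmodified", "ligand": None, **t}

    for lig in cfg.ligands:
        delta = lig.delta_mass()
        apex = cfg.apex_rt + cfg.modified_rt_offset
        for _ in range(lig.n_spectra):
            rt = float(rng.uniform(apex - cfg.elution_sigma,
                                   apex + cfg.elution_sigma))
            sid = next_id()
            spec, t = _ms2_spectrum(sid, cfg.peptide, cfg.site_index, delta,
                                    base + delta, rt, cfg, rng)
            ms2.append(spec)
            truth[sid] = {"class": "modified", "ligand": lig.name, **t}

    letters = list(cfg.peptide)
    for _ in range(cfg.n_decoys):
        shuffled = _decoy_sequence(cfg.peptide, letters, rng)
        neutral = float(rng.uniform(900.0, 2200.0))
        rt = float(rng.uniform(0.0, cfg.gradient_length))
        sid = next_id()
        spec, t = _ms2_spectrum(sid, shuffled, cfg.site_index, 0.0, neutral,
                                rt, cfg, rng, with_survivors=False)
        ms2.append(spec)
        truth[sid] = {"class": "decoy", "ligand": None, **t,
                      "true_delta_mass": None}

    run = Run(ms1=ms1, ms2=sorted(ms2, key=lambda s: s.rt),
              gradient_length=cfg.gradient_length)
    manifest = GroundTruthManifest(
        seed=cfg.seed, config=asdict(cfg), spectra=truth,
        auc_ratios={lig.name: lig.auc_ratio for lig in cfg.ligands},
        apex_rt=cfg.apex_rt)
    return run, manifest


def write_run(run: Run, path, format: str = "mzML") -> None:
    """Serialize a run as mzML (MS1+MS2) or MGF (MS2 only, by format)."""
    if format.lower() == "mzml":
        write_run_mzml(run, path)
    elif format.lower() == "mgf":
        write_run_mgf(run, path)
    else:
        raise ValueError(f"unknown run format {format!r}")


def write_manifest(manifest: GroundTruthManifest, path) -> None:
    with open(path, "w") as fh:
        fh.write(manifest.to_json())
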