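"""The reporter-ion Δ-mass screen: reporter sets, matching, criteria."""

import numpy as np
import pytest

from xlscreen.deltamass import (
    DeltaMassHit,
    ScreenConfig,
    build_reporter_set,
    cluster_hits,
    compute_delta_mass,
    match_reporters,
    quality_scores,
    reference_rt,
    screen_spectra,
)
from xlscreen.masscalc import (
    ISOTOPE_SPACING,
    OXYGEN_MASS,
    Peptide,
    mz_from_neutral,
    peptide_mass,
)
from xlscreen.spectra_io import SpectrumRecord
from xlscreen.synthdata import PlantedLigand, SimulationConfig, simulate_run

AC6FP_DELTA = 217.059974
PEPTIDE_MASS = peptide_mass("DSVTRQKEPRAPW")


class TestReporterSet:
    def test_size_for_reporter_peptide(self, reporter_set):
        assert len(reporter_set.ladder) == 24
        assert len(reporter_set.precursor_rules) == 4
        assert reporter_set.size == 28

    def test_site_at_nterm_has_no_b_reporters(self):
        rs = build_reporter_set(Peptide("DSVTRQKEPRAPW", site_index=1))
        assert not any(r.series == "b" for r in rs.ladder)
        assert sum(r.series == "y" for r in rs.ladder) == 24

    def test_ladder_fragments_exclude_site(self, peptide, reporter_set):
        k, n = peptide.site_index, len(peptide)
        for r in reporter_set.ladder:
            if r.series == "b":
                assert r.index < k
            else:
                assert r.index <= n - k

    def test_requires_site_index(self):
        with pytest.raises(ValueError):
            build_reporter_set(Peptide("DSVTRQKEPRAPW"))


def _full_reporter_spectrum(reporter_set, neutral, z=3, extra=()):
    """Spectrum containing every reporter target exactly plus extras."""
    mzs = [r.mz for r in reporter_set.reporters_for(neutral)]
    mzs += [m for m, _ in extra]
    intens = [1000.0] * (len(mzs) - len(extra)) + [i for _, i in extra]
    return SpectrumRecord("t", 2, 42.0, np.array(mzs), np.array(intens),
                          precursor_mz=mz_from_neutral(neutral, z),
                          precursor_z=z)


class TestMatchReporters:
    def test_full_ladder_and_survivors_match_28(self, reporter_set):
        s = _full_reporter_spectrum(reporter_set, PEPTIDE_MASS + AC6FP_DELTA)
        res = match_reporters(s, reporter_set)
        assert res.n_reporters == 28

    def test_empty_spectrum_matches_zero(self, reporter_set):
        s = SpectrumRecord("e", 2, 0.0, [], [], precursor_mz=500.0,
                           precursor_z=2)
        assert match_reporters(s, reporter_set).n_reporters == 0

    def test_peak_used_at_most_once(self, reporter_set):
        s = _full_reporter_spectrum(reporter_set, PEPTIDE_MASS)
        res = match_reporters(s, reporter_set)
        peak_ids = [m.peak_index for m in res.matches]
        assert len(peak_ids) == len(set(peak_ids))

    def test_count_anti_monotone_in_tolerance(self, peptide, reporter_set):
        """Tightening the fragment tolerance never increases the count."""
        cfg = SimulationConfig(seed=5, include_ms1=False, noise_peaks=200,
                               fragment_ppm_sd=20.0, ladder_completeness=0.7)
        run, _ = simulate_run(cfg)
        for s in run.ms2[:30]:
            previous = None
            for tol in (0.1, 0.05, 0.03, 0.01, 0.005, 0.001):
                n = match_reporters(
                    s, reporter_set, ScreenConfig(frag_tol=tol)).n_reporters
                if previous is not None:
                    assert n <= previous
                previous = n


class TestComputeDeltaMass:
    def test_planted_ac6fp_delta(self):
        neutral = PEPTIDE_MASS + AC6FP_DELTA
        s = SpectrumRecord("a", 2, 42.0, [200.0], [1.0],
                           precursor_mz=mz_from_neutral(neutral, 3),
                           precursor_z=3)
        [res] = compute_delta_mass(s, "DSVTRQKEPRAPW")
        assert res.delta_mass == pytest.approx(AC6FP_DELTA, abs=1e-6)
        assert res.free_ligand_mass == pytest.approx(
            AC6FP_DELTA + OXYGEN_MASS, abs=1e-6)

    def test_unmodified_delta_zero(self):
        s = SpectrumRecord("u", 2, 42.0, [200.0], [1.0],
                           precursor_mz=mz_from_neutral(PEPTIDE_MASS, 2),
                           precursor_z=2)
        [res] = compute_delta_mass(s, "DSVTRQKEPRAPW")
        assert res.delta_mass == pytest.approx(0.0, abs=1e-9)
        assert res.isotope_k == 0

    def test_unknown_charge_enumerates_flagged(self):
        s = SpectrumRecord("q", 2, 42.0, [200.0], [1.0],
                           precursor_mz=800.0, precursor_z=None)
        results = compute_delta_mass(s, "DSVTRQKEPRAPW", charges=(2, 3, 4))
        assert [r.charge for r in results] == [2, 3, 4]
        assert all(r.charge_enumerated for r in results)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_isotope_mispick_corrected(self, k):
        neutral = PEPTIDE_MASS + k * ISOTOPE_SPACING
        s = SpectrumRecord("i", 2, 42.0, [200.0], [1.0],
                           precursor_mz=mz_from_neutral(neutral, 3),
                           precursor_z=3)
        [res] = compute_delta_mass(s, "DSVTRQKEPRAPW")
        assert res.isotope_k == k
        assert abs(res.isotope_corrected_delta) < 1e-9


def _hit(scan_id="s", rt=42.0, delta=0.0, intensity=1.0, n_rep=10):
    return DeltaMassHit(
        scan_id=scan_id, rt=rt, precursor_z=3,
        observed_neutral=PEPTIDE_MASS + delta, delta_mass=delta,
        free_ligand_mass=delta + OXYGEN_MASS, isotope_k=0,
        isotope_corrected_delta=delta, n_reporters=n_rep,
        matched_intensity=intensity, hit_class="control")


class TestReferenceRT:
    def test_single_control(self):
        assert reference_rt([_hit(rt=42.0)]) == 42.0

    def test_equal_weight_median(self):
        hits = [_hit(rt=r) for r in (40.0, 41.0, 43.0)]
        assert reference_rt(hits) == 41.0

    def test_no_controls_needs_config(self):
        with pytest.raises(ValueError, match="reference_rt"):
            reference_rt([])
        assert reference_rt([], ScreenConfig(reference_rt=37.5)) == 37.5


class TestQualityScores:
    def test_all_matched_tic_fraction_is_one(self, peptide, reporter_set):
        s = _full_reporter_spectrum(reporter_set, PEPTIDE_MASS)
        res = match_reporters(s, reporter_set)
        q = quality_scores(s, reporter_set, res, None)
        assert q.matched_tic_fraction == pytest.approx(1.0)
        assert q.ladder_continuity == 6

    def test_self_consensus_similarity_is_one(self, peptide, reporter_set):
        from xlscreen.deltamass import _reporter_vector

        s = _full_reporter_spectrum(reporter_set, PEPTIDE_MASS)
        res = match_reporters(s, reporter_set)
        consensus = _reporter_vector(reporter_set, res)
        q = quality_scores(s, reporter_set, res, consensus)
        assert q.control_similarity == pytest.approx(1.0)

    def test_no_matches_scores_zero(self, reporter_set):
        s = SpectrumRecord("n", 2, 0.0, [150.0], [5.0],
                           precursor_mz=500.0, precursor_z=2)
        cfg = ScreenConfig(frag_tol=1e-6)
        res = match_reporters(s, reporter_set, cfg)
        q = quality_scores(s, reporter_set, res, None)
        assert q.matched_tic_fraction == 0.0
        assert q.ladder_continuity <= 1


class TestScreen:
    def test_planted_run_fully_recovered(self, peptide, small_run):
        run, manifest = small_run
        candidates, controls = screen_spectra(run, peptide, ScreenConfig())
        truth = manifest.spectra
        mod = {sid for sid, t in truth.items() if t["class"] == "modified"}
        unmod = {sid for sid, t in truth.items()
                 if t["class"] == "unmodified"}
        decoys = {sid for sid, t in truth.items() if t["class"] == "decoy"}
        cand_ids = {h.scan_id for h in candidates}
        ctrl_ids = {h.scan_id for h in controls}
        assert cand_ids == mod
        assert ctrl_ids == unmod
        assert not (cand_ids | ctrl_ids) & decoys
        assert all(h.n_reporters >= 10 for h in candidates + controls)

    def test_only_unmodified_gives_no_candidates(self, peptide):
        cfg = SimulationConfig(seed=3, ligands=(), n_decoys=0,
                               include_ms1=False)
        run, _ = simulate_run(cfg)
        candidates, controls = screen_spectra(run, peptide, ScreenConfig())
        assert candidates == []
        assert len(controls) == cfg.n_unmodified_spectra

    def test_rt_window_excludes_distant_candidates(self, peptide):
        cfg = SimulationConfig(seed=4, modified_rt_offset=20.0, n_decoys=0,
                               include_ms1=False)
        run, _ = simulate_run(cfg)
        candidates, controls = screen_spectra(run, peptide, ScreenConfig())
        assert candidates == []  # criterion A: beyond +/-15 min of reference
        assert controls

    def test_control_window_bounds_hold(self, peptide, small_run):
        run, _ = small_run
        candidates, controls = screen_spectra(run, peptide, ScreenConfig())
        for h in controls:
            assert -0.05 <= h.delta_mass <= 4.05
        for h in candidates:
            assert h.delta_mass > 40.0
        assert not {h.scan_id for h in candidates} \
            & {h.scan_id for h in controls}


class TestClusterHits:
    def test_nearby_masses_merge(self):
        hits = [_hit("a", delta=217.0600), _hit("b", delta=217.0608)]
        [cluster] = cluster_hits(hits, tol_ppm=10.0)
        assert cluster.n_spectra == 2

    def test_distinct_masses_split(self):
        hits = [_hit("a", delta=151.06), _hit("b", delta=217.06)]
        clusters = cluster_hits(hits, tol_ppm=10.0)
        assert len(clusters) == 2

    def test_members_within_tolerance_of_representative(self):
        rng = np.random.default_rng(8)
        hits = [_hit(str(i), delta=float(d), intensity=float(w))
                for i, (d, w) in enumerate(zip(
                    rng.uniform(50, 400, 60), rng.uniform(0.1, 10, 60)))]
        tol_ppm = 200.0
        for cluster in cluster_hits(hits, tol_ppm=tol_ppm):
            tol = tol_ppm * 1e-6 * max(abs(cluster.delta_mass), 1.0)
            for h in cluster.hits:
                assert abs(h.delta_mass - cluster.delta_mass) <= tol + 1e-12

    def test_sorted_by_spectrum_count(self):
        hits = ([_hit(f"a{i}", delta=217.06) for i in range(3)]
                + [_hit("b", delta=151.06)])
        clusters = cluster_hits(hits, tol_ppm=10.0)
        assert [c.n_spectra for c in clusters] == [3, 1]

    def test_empty_input(self):
        assert cluster_hits([]) == []


def test_shifted_ladder_still_matches_unaffected_reporters(peptide,
                                                           reporter_set):
    """A planted adduct shifts only site-containing fragments; the reporter
    count from ligand-free ions stays complete."""
    cfg = SimulationConfig(
        seed=9, include_ms1=False, noise_peaks=0, n_decoys=0,
        n_unmodified_spectra=0,
        ligands=(PlantedLigand("pyridoxal", formula="C8H9NO3", n_spectra=5),))
    run, _ = simulate_run(cfg)
    for s in run.ms2:
        res = match_reporters(s, reporter_set)
        assert res.n_reporters == 28
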