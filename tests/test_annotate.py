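"""Error-propagation tolerances and local compound matching."""

import numpy as np
import pytest

from xlscreen.annotate import (
    CompoundRecord,
    ToleranceModel,
    bundled_compound_table,
    load_compound_table,
    match_compounds,
    propagated_tolerance_ppm,
    tolerance_curve,
)
from xlscreen.masscalc import formula_mass, peptide_mass

PEPTIDE_MASS = peptide_mass("DSVTRQKEPRAPW")
AC6FP_MASS = formula_mass("C9H7N5O3")


class TestPropagatedTolerance:
    def test_ac6fp_on_reporter_peptide(self):
        tm = ToleranceModel(precursor_ppm=5.0)
        tol = propagated_tolerance_ppm(tm, AC6FP_MASS,
                                       peptide_mass_da=PEPTIDE_MASS)
        assert tol == pytest.approx(41.1, abs=0.1)
        assert 40.0 <= tol <= 45.0

    def test_twenty_ppm_is_four_times_five(self):
        kwargs = dict(peptide_mass_da=PEPTIDE_MASS)
        t5 = propagated_tolerance_ppm(ToleranceModel(5.0), AC6FP_MASS,
                                      **kwargs)
        t20 = propagated_tolerance_ppm(ToleranceModel(20.0), AC6FP_MASS,
                                       **kwargs)
        assert t20 == pytest.approx(4.0 * t5, rel=1e-12)

    def test_strictly_decreasing_in_ligand_mass(self):
        tm = ToleranceModel(5.0)
        tols = [propagated_tolerance_ppm(tm, m, peptide_mass_da=PEPTIDE_MASS)
                for m in np.linspace(60, 500, 40)]
        assert all(b < a for a, b in zip(tols, tols[1:]))

    def test_ligand_convention_differs(self):
        delta_tol = propagated_tolerance_ppm(
            ToleranceModel(5.0, denominator_convention="delta"), AC6FP_MASS,
            peptide_mass_da=PEPTIDE_MASS)
        ligand_tol = propagated_tolerance_ppm(
            ToleranceModel(5.0, denominator_convention="ligand"), AC6FP_MASS,
            peptide_mass_da=PEPTIDE_MASS)
        assert ligand_tol < delta_tol

    def test_nonpositive_ligand_rejected(self):
        with pytest.raises(ValueError):
            propagated_tolerance_ppm(ToleranceModel(5.0), 0.0,
                                     peptide_mass_da=PEPTIDE_MASS)


class TestToleranceCurve:
    def test_monotone_decreasing_grid(self):
        tm = ToleranceModel(5.0)
        rows = tolerance_curve(tm, [100.0, 200.0, 400.0],
                               peptide_mass_da=PEPTIDE_MASS)
        tols = [r["tolerance_ppm"] for r in rows]
        assert tols[0] > tols[1] > tols[2]

    def test_5ppm_below_20ppm_everywhere(self):
        grid = np.linspace(60, 400, 20)
        lo = tolerance_curve(ToleranceModel(5.0), grid,
                             peptide_mass_da=PEPTIDE_MASS)
        hi = tolerance_curve(ToleranceModel(20.0), grid,
                             peptide_mass_da=PEPTIDE_MASS)
        assert all(a["tolerance_ppm"] < b["tolerance_ppm"]
                   for a, b in zip(lo, hi))

    def test_point_consistency(self):
        tm = ToleranceModel(5.0)
        [row] = tolerance_curve(tm, [AC6FP_MASS],
                                peptide_mass_da=PEPTIDE_MASS)
        assert row["tolerance_ppm"] == propagated_tolerance_ppm(
            tm, AC6FP_MASS, peptide_mass_da=PEPTIDE_MASS)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tolerance_curve(ToleranceModel(5.0), [],
                            peptide_mass_da=PEPTIDE_MASS)


class TestCompoundRecord:
    def test_formula_mass_consistency_enforced(self):
        with pytest.raises(ValueError):
            CompoundRecord("bogus", "C8H9NO3", 200.0)

    def test_table_loader_computes_missing_masses(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("name\tformula\tmonoisotopic_mass\n"
                     "pyridoxal\tC8H9NO3\t\n"
                     "massonly\t\t123.4567\n")
        table = load_compound_table(p)
        assert table[0].monoisotopic_mass == pytest.approx(167.05824,
                                                           abs=1e-4)
        assert table[1].monoisotopic_mass == 123.4567

    def test_loader_rejects_empty_entries(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("name\tformula\tmonoisotopic_mass\nghost\t\t\n")
        with pytest.raises(ValueError):
            load_compound_table(p)


class TestMatchCompounds:
    def test_pyridoxal_rank_one(self):
        table = bundled_compound_table()
        matches = match_compounds(formula_mass("C8H9NO3"), table,
                                  ToleranceModel(5.0),
                                  peptide_mass_da=PEPTIDE_MASS)
        assert matches[0].compound.name == "pyridoxal"
        assert abs(matches[0].ppm_error) < 0.01
        assert matches[0].within_propagated_tolerance

    def test_ac6fp_within_tolerance(self):
        table = bundled_compound_table()
        matches = match_compounds(AC6FP_MASS * (1 + 20e-6), table,
                                  ToleranceModel(5.0),
                                  peptide_mass_da=PEPTIDE_MASS)
        top = matches[0]
        assert top.compound.name == "acetyl-6-formylpterin"
        assert top.within_propagated_tolerance

    def test_empty_table(self):
        assert match_compounds(167.0582, [], ToleranceModel(5.0),
                               peptide_mass_da=PEPTIDE_MASS) == []

    def test_flag_consistent_with_applied_tolerance(self):
        table = bundled_compound_table()
        rng = np.random.default_rng(13)
        for _ in range(50):
            free = float(rng.uniform(50, 500))
            for m in match_compounds(free, table, ToleranceModel(5.0),
                                     peptide_mass_da=PEPTIDE_MASS):
                assert abs(m.ppm_error) <= 200.0
                assert m.within_propagated_tolerance \
                    == (abs(m.ppm_error) <= m.applied_tolerance_ppm)
                assert 30.0 <= m.applied_tolerance_ppm <= 60.0

    def test_planted_compound_always_rank_one(self):
        """Free masses perturbed within instrument accuracy recover the
        planted table compound at rank 1 (100 random trials)."""
        table = bundled_compound_table()
        rng = np.random.default_rng(99)
        for _ in range(100):
            comp = table[int(rng.integers(len(table)))]
            if comp.monoisotopic_mass < 40.0:
                continue
            observed = comp.monoisotopic_mass * (1 + 5e-6 * rng.normal())
            matches = match_compounds(observed, table, ToleranceModel(5.0),
                                      peptide_mass_da=PEPTIDE_MASS)
            assert matches[0].compound.name == comp.name
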