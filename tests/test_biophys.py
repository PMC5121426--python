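import numpy as np
import pytest

from poreform.biophys import (
    PoreGeometryModel,
    TitrationCurve,
    apply_mutations,
    cuvette_setting,
    cuvette_temperature,
    dye_radius,
    fraction_folded,
    leakage_percent,
    min_oligomer_for_dye,
    partition_dG,
    partition_isotherm,
    peptide_average_mass,
)
from poreform.core import R_KCAL
from poreform.synthgen import MACULATIN_SEQUENCE

ANTS_MW = 427.33
DPX_MW = 422.16


class TestPeptideMass:
    def test_wild_type_amidated(self):
        """Amidated 21-residue maculatin matches its measured 2145.55 g/mol."""
        assert peptide_average_mass(MACULATIN_SEQUENCE, "amide") == pytest.approx(
            2145.55, abs=0.1
        )

    def test_p15a_mutant(self):
        seq = apply_mutations(MACULATIN_SEQUENCE, "P15A")
        assert peptide_average_mass(seq, "amide") == pytest.approx(2119.51, abs=0.1)

    def test_double_mutant(self):
        seq = apply_mutations(MACULATIN_SEQUENCE, "P15A", "E19Q")
        assert peptide_average_mass(seq, "amide") == pytest.approx(2118.53, abs=0.1)

    def test_single_glycine_free_acid(self):
        assert peptide_average_mass("G", "acid") == pytest.approx(75.07, abs=0.01)

    def test_amide_correction(self):
        for seq in ("GLFG", "KAVE", MACULATIN_SEQUENCE):
            diff = peptide_average_mass(seq, "amide") - peptide_average_mass(seq, "acid")
            # masses are reported at 2 decimals, so the -0.9847 Da correction
            # shows up as -0.98 or -0.99
            assert diff == pytest.approx(-0.985, abs=0.006)

    def test_additive_up_to_one_water(self):
        a, b = "GLFGV", "LAKVA"
        joined = peptide_average_mass(a + b, "acid")
        parts = peptide_average_mass(a, "acid") + peptide_average_mass(b, "acid")
        assert joined == pytest.approx(parts - 18.02, abs=0.02)

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            peptide_average_mass("GLX1", "acid")

    def test_mutation_validation(self):
        with pytest.raises(ValueError, match="position"):
            apply_mutations(MACULATIN_SEQUENCE, "P14A")


class TestFractionFolded:
    def test_endpoints_and_midpoint(self):
        assert fraction_folded(-30000.0, -30000.0, -2000.0) == 1.0
        assert fraction_folded(-2000.0, -30000.0, -2000.0) == 0.0
        assert fraction_folded(-16000.0, -30000.0, -2000.0) == pytest.approx(0.5)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert fraction_folded(-35000.0, -30000.0, -2000.0) == 1.0

    def test_equal_references_rejected(self):
        with pytest.raises(ValueError):
            fraction_folded(-5.0, -1.0, -1.0)


class TestPartition:
    #: the experimental lipid titration series, in M
    LIPIDS = np.array([200e-6, 400e-6, 4000e-6, 10000e-6])

    def _curve(self, k_x, temperature=298.15):
        theta_u, theta_f = -2000.0, -30000.0
        f = partition_isotherm(self.LIPIDS, k_x)
        theta = theta_u + f * (theta_f - theta_u)
        return TitrationCurve(self.LIPIDS, theta, theta_f, theta_u,
                              temperature=temperature)

    def test_unit_partition_zero_dG(self):
        # Kx = 1 means no preference; dG = 0 at any temperature
        for t in (280.0, 298.15, 320.0):
            k, dg = partition_dG(self._curve(1.0, t))
            assert k == pytest.approx(1.0, rel=1e-6)
            assert dg == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_roundtrip_exact(self):
        for k_true in (50.0, 2.35e3, 1e5):
            k, _ = partition_dG(self._curve(k_true))
            assert k == pytest.approx(k_true, rel=1e-6)

    def test_strong_binder_free_energy(self):
        """Kx = 2.35e3 at 25 °C gives the measured -4.6 kcal/mol regime."""
        k, dg = partition_dG(self._curve(2.35e3))
        assert dg == pytest.approx(-4.6, abs=0.05)
        assert -4.6 - 0.8 <= dg <= -4.6 + 0.8

    def test_dG_formula(self):
        k, dg = partition_dG(self._curve(100.0))
        assert dg == pytest.approx(-R_KCAL * 298.15 * np.log(100.0), rel=1e-6)

    def test_flat_curve_rejected(self):
        theta = np.full(4, -2000.0)
        curve = TitrationCurve(self.LIPIDS, theta, -30000.0, -2000.0)
        with pytest.raises(ValueError):
            partition_dG(curve)

    def test_nonincreasing_lipids_rejected(self):
        with pytest.raises(ValueError):
            TitrationCurve([1e-4, 1e-4], [-3.0, -4.0], -30.0, -2.0)


class TestLeakage:
    def test_reference_points(self):
        assert leakage_percent(10.0, 10.0, 110.0) == 0.0
        assert leakage_percent(110.0, 10.0, 110.0) == 100.0
        assert leakage_percent(60.0, 10.0, 110.0) == pytest.approx(50.0)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert leakage_percent(120.0, 10.0, 110.0) == 100.0

    def test_equal_references_rejected(self):
        with pytest.raises(ValueError):
            leakage_percent(5.0, 7.0, 7.0)


class TestPoreGeometry:
    def test_ants_radius(self):
        r = dye_radius(PoreGeometryModel(ANTS_MW))
        assert r == pytest.approx(5.0, abs=0.05)

    def test_dpx_nearly_equal(self):
        r_ants = dye_radius(PoreGeometryModel(ANTS_MW))
        r_dpx = dye_radius(PoreGeometryModel(DPX_MW))
        # r scales as M^(1/3): a 5.2 Da mass difference moves r by ~0.02 Å
        assert abs(r_ants - r_dpx) == pytest.approx(0.020, abs=0.005)
        # both dyes therefore require the same minimum pore order
        assert min_oligomer_for_dye(PoreGeometryModel(ANTS_MW)) == \
            min_oligomer_for_dye(PoreGeometryModel(DPX_MW))

    def test_cube_root_scaling(self):
        r1 = dye_radius(PoreGeometryModel(ANTS_MW))
        r8 = dye_radius(PoreGeometryModel(8 * ANTS_MW))
        assert r8 == pytest.approx(2 * r1, rel=1e-9)

    def test_ants_needs_heptamer(self):
        """A ~5 Å dye through a ring of 10 Å helices needs n >= 7."""
        assert min_oligomer_for_dye(PoreGeometryModel(ANTS_MW)) == 7

    def test_vanishing_dye_needs_tetramer(self):
        assert min_oligomer_for_dye(PoreGeometryModel(1e-6)) == 4

    def test_monotone_in_dye_radius(self):
        ns = [min_oligomer_for_dye(PoreGeometryModel(mw))
              for mw in (1.0, 100.0, 427.33, 4000.0, 40000.0)]
        assert ns == sorted(ns)

    def test_wider_helices_need_fewer(self):
        narrow = min_oligomer_for_dye(PoreGeometryModel(ANTS_MW, helix_diameter=10.0))
        wide = min_oligomer_for_dye(PoreGeometryModel(ANTS_MW, helix_diameter=20.0))
        assert wide <= narrow


class TestCuvetteCalibration:
    def test_intercept(self):
        assert cuvette_temperature(0.0) == pytest.approx(4.715)

    def test_high_setting(self):
        assert cuvette_temperature(90.0) == pytest.approx(73.655)

    def test_inverse_roundtrip(self):
        for t in (0.0, 37.0, 95.0):
            assert cuvette_temperature(cuvette_setting(t)) == pytest.approx(t)
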