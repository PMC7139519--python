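"""Descriptor arithmetic, thermodynamic-cycle consistency, and table I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsrr import descriptors as d

enthalpies = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestSolvationEnergy:
    @pytest.mark.parametrize(
        "e_solv, e_vac, expected",
        [
            (-100.0, -100.0, 0.0),
            (-27.785 - 630.0, -630.0, -27.785),
            (-12.34, -2.30, -10.04),
        ],
    )
    def test_difference(self, e_solv, e_vac, expected):
        assert d.solvation_energy(e_solv, e_vac) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            d.solvation_energy(float("nan"), 0.0)


class TestHatSpletEnthalpies:
    def test_bde_cancellation(self, flavonoid_record, smd_ref):
        rec = flavonoid_record
        rec.H_radical_per_site = {"OH1": rec.H_parent - smd_ref.H_hydrogen_radical}
        rec.H_anion_per_site = {"OH1": -520.0}
        rec.n_OH = 1
        per_site, bde_min = d.bond_dissociation_enthalpies(rec, smd_ref)
        assert bde_min == pytest.approx(0.0, abs=1e-12)

    def test_bde_min_is_sitewise_minimum(self, flavonoid_record, smd_ref):
        per_site, bde_min = d.bond_dissociation_enthalpies(flavonoid_record, smd_ref)
        assert bde_min == pytest.approx(min(per_site.values()))
        # exhaustive site scan oracle
        expected = min(
            h + smd_ref.H_hydrogen_radical - flavonoid_record.H_parent
            for h in flavonoid_record.H_radical_per_site.values()
        )
        assert bde_min == pytest.approx(expected)

    def test_no_hydroxyls_returns_missing(self, smd_ref):
        rec = d.QMSpeciesRecord(
            "bare", -500.0, {}, {}, -490.0, -500.0, -8.0, -1.0, 3.0, -0.5, 0
        )
        per_site, bde_min = d.bond_dissociation_enthalpies(rec, smd_ref)
        assert per_site == {} and math.isnan(bde_min)

    def test_ete_hand_value(self, flavonoid_record, smd_ref):
        # H_rad=-500, H_anion=-520, H_e=-17.816 -> 2.184
        assert d.electron_transfer_enthalpy(
            flavonoid_record, smd_ref, "OH1"
        ) == pytest.approx(2.184)

    def test_pa_hand_value(self, flavonoid_record, smd_ref):
        # H_anion=-520 ... use OH1 with H_parent=-740, H_proton=-250.574
        rec = flavonoid_record
        rec.H_anion_per_site = {"OH1": -480.0, "OH2": -511.0}
        assert d.proton_affinity(rec, smd_ref, "OH1") == pytest.approx(9.426)

    def test_missing_site_errors(self, flavonoid_record, smd_ref):
        with pytest.raises(ValueError):
            d.electron_transfer_enthalpy(flavonoid_record, smd_ref, "OH9")
        with pytest.raises(ValueError):
            d.proton_affinity(flavonoid_record, smd_ref, "OH9")

    @settings(max_examples=50, derandomize=True)
    @given(
        h_parent=enthalpies,
        h_rad=enthalpies,
        h_anion=enthalpies,
    )
    def test_thermodynamic_cycle_identity(self, h_parent, h_rad, h_anion):
        """BDE - (PA + ETE) depends only on the reference enthalpies."""
        ref = d.ReferenceEnthalpies.smd_water()
        rec = d.QMSpeciesRecord(
            "x", h_parent, {"OH1": h_rad}, {"OH1": h_anion},
            -10.0, -20.0, -8.0, -1.0, 1.0, -0.5, 1,
        )
        _, bde = d.bond_dissociation_enthalpies(rec, ref)
        pa = d.proton_affinity(rec, ref, "OH1")
        ete = d.electron_transfer_enthalpy(rec, ref, "OH1")
        assert bde - (pa + ete) == pytest.approx(ref.cycle_constant, abs=1e-9)


class TestFrontierOrbitalDescriptors:
    def test_koopmans_signs(self):
        ip, ea, gap = d.koopmans_ip_ea(-0.25, 0.05)
        assert (ip, ea, gap) == pytest.approx((0.25, -0.05, 0.30))

    def test_gap_equals_ip_minus_ea(self):
        ip, ea, gap = d.koopmans_ip_ea(-7.9, -1.3)
        assert gap == pytest.approx(ip - ea)

    def test_negative_gap_warns_but_proceeds(self):
        with pytest.warns(UserWarning):
            ip, ea, gap = d.koopmans_ip_ea(-1.0, -2.0)
        assert gap == pytest.approx(-1.0)

    def test_global_reactivity_hand_values(self):
        eta, mu, omega = d.global_reactivity(9.0, 1.0)
        assert (eta, mu, omega) == pytest.approx((4.0, -5.0, 3.125))

    def test_degenerate_hardness_gives_missing_omega(self):
        eta, mu, omega = d.global_reactivity(3.0, 3.0)
        assert eta == 0.0 and math.isnan(omega)

    def test_omega_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ip = rng.uniform(5, 10)
            ea = rng.uniform(-1, ip - 0.01)
            *_, omega = d.global_reactivity(ip, ea)
            assert omega >= 0

    def test_electronegativity_is_negated_mu(self):
        _, mu, _ = d.global_reactivity(8.0, 1.0)
        assert d.electronegativity(8.0, 1.0) == pytest.approx(-mu)


class TestAssembly:
    def test_single_record_gives_1x13(self, flavonoid_record):
        out = d.assemble_descriptors([flavonoid_record])
        assert out.shape == (1, 13)
        assert list(out.columns) == list(d.DESCRIPTOR_NAMES)

    def test_duplicate_ids_rejected(self, flavonoid_record):
        with pytest.raises(ValueError, match="duplicate"):
            d.assemble_descriptors([flavonoid_record, flavonoid_record])

    def test_site_policy_uses_bde_min_site(self, flavonoid_record, smd_ref):
        vec = d.compute_descriptors(flavonoid_record, smd_ref)
        per_site, _ = d.bond_dissociation_enthalpies(flavonoid_record, smd_ref)
        site = min(per_site, key=per_site.get)
        assert vec.ETE == pytest.approx(
            d.electron_transfer_enthalpy(flavonoid_record, smd_ref, site)
        )
        assert vec.PA == pytest.approx(
            d.proton_affinity(flavonoid_record, smd_ref, site)
        )

    def test_csv_round_trip(self, flavonoid_record, tmp_path):
        out = d.assemble_descriptors([flavonoid_record])
        path = tmp_path / "descriptors.csv"
        d.write_descriptors(out, path)
        back = d.read_descriptors(path)
        pd.testing.assert_frame_equal(out, back, atol=1e-6, rtol=0)

    def test_qm_records_csv_round_trip(self, flavonoid_record, tmp_path):
        path = tmp_path / "qm_records.csv"
        d.write_qm_records([flavonoid_record], path)
        (rec,) = d.read_qm_records(path)
        assert rec.H_radical_per_site == flavonoid_record.H_radical_per_site
        assert rec.n_OH == flavonoid_record.n_OH
        assert rec.E_HOMO == flavonoid_record.E_HOMO

    def test_hartree_input_matches_kcal_pipeline(self, flavonoid_record, smd_ref, tmp_path):
        """Hartree-unit energies reproduce the kcal/mol path to 1e-6 relative."""
        path = tmp_path / "qm_records.csv"
        d.write_qm_records([flavonoid_record], path)
        table = pd.read_csv(path, keep_default_na=False)
        energy = table["quantity"].isin(["H", "E"])
        table.loc[energy, "value"] /= d.HARTREE_TO_KCAL
        table.loc[energy, "unit"] = "hartree"
        path2 = tmp_path / "qm_records_hartree.csv"
        table.to_csv(path2, index=False)
        a = d.assemble_descriptors(d.read_qm_records(path), smd_ref)
        b = d.assemble_descriptors(d.read_qm_records(path2), smd_ref)
        pd.testing.assert_frame_equal(a, b, rtol=1e-6)
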