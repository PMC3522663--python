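"""Drug-profile, occupancy and binding-kinetics behaviour."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psyqsp.pharmacology import (
    BindingKinetics,
    DrugProfile,
    approximate_ki,
    kinetics_from_affinity,
    load_drug_table,
    mixture,
    moiety_concentrations,
    occupancy,
    registry,
)


class TestDrugTable:
    def test_table_fixture_loads_expected_affinities(self, ref_drugs):
        jnj = ref_drugs["JNJ37822681"]
        assert jnj.ki("D2") == 220.0
        assert jnj.ki("5-HT2A") == 1632.0
        # ">10000" and "N/A" cells mean no binding
        assert jnj.ki("D1") is None
        assert jnj.ki("alpha1") is None
        ocap = ref_drugs["ocaperidone"]
        assert ocap.ki("D2") == 1.22
        assert ocap.ki("5-HT1C") == 28.0   # legacy label kept distinct from 5-HT2C
        assert ocap.ki("5-HT2C") == 27.0
        assert ocap.ki("M2") is None
        assert ref_drugs["ND8295"].ki("D2") == 1.3

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("drug,receptor,ki_nM\n")
        assert load_drug_table(p) == []

    def test_censored_cells_can_be_kept_at_bound(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("drug,receptor,ki_nM\nX,D2,>10000\n")
        assert load_drug_table(p)[0].ki("D2") is None
        assert load_drug_table(p, censored_ki=10000)[0].ki("D2") == 10000.0

    def test_unknown_receptor_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("drug,receptor,ki_nM\nX,NOT-A-RECEPTOR,5\n")
        with pytest.raises(KeyError):
            load_drug_table(p)

    def test_non_positive_ki_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("drug,receptor,ki_nM\nX,D2,-3\n")
        with pytest.raises(ValueError):
            load_drug_table(p)

    def test_registry_is_extensible(self):
        registry.register("NMDA-GluN2B")
        assert "NMDA-GluN2B" in registry


class TestOccupancy:
    @pytest.mark.parametrize(
        "dose,ki,expected",
        [(220.0, 220.0, 0.5), (0.0, 220.0, 0.0), (700.0, 220.0, 700.0 / 920.0)],
    )
    def test_hill_formula(self, dose, ki, expected):
        assert occupancy(dose, ki) == pytest.approx(expected, abs=1e-9)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            occupancy(-1.0, 220.0)

    @settings(deadline=None, max_examples=50)
    @given(
        dose=st.floats(0.01, 1e5),
        factor=st.floats(1.01, 10.0),
        ki=st.floats(0.01, 1e5),
    )
    def test_monotone_in_dose_and_ki(self, dose, factor, ki):
        assert occupancy(dose * factor, ki) > occupancy(dose, ki)
        assert occupancy(dose, ki * factor) < occupancy(dose, ki)

    def test_saturates_toward_one(self):
        assert occupancy(1e12, 220.0) > 0.999999


class TestApproximateKi:
    @pytest.mark.parametrize(
        "k_d2,aff_x,aff_d2,expected",
        [
            (100.0, 50.0, 50.0, 100.0),
            (100.0, 100.0, 50.0, 200.0),
            # ocaperidone 5-HT2A scaled from its D2 potency
            (1.0, 0.58, 1.22, 0.58 / 1.22),
        ],
    )
    def test_affinity_ratio_scaling(self, k_d2, aff_x, aff_d2, expected):
        assert approximate_ki(k_d2, aff_x, aff_d2) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(
        k=st.floats(0.1, 1e4), ax=st.floats(0.1, 1e4),
        ad=st.floats(0.1, 1e4), s=st.floats(0.01, 100.0),
    )
    def test_homogeneous_in_affinity_scale(self, k, ax, ad, s):
        assert approximate_ki(k, ax * s, ad * s) == pytest.approx(
            approximate_ki(k, ax, ad), rel=1e-9
        )

    def test_zero_affinity_rejected(self):
        with pytest.raises(ValueError):
            approximate_ki(100.0, 0.0, 50.0)


class TestKinetics:
    def test_koff_scales_with_ki(self):
        kin = kinetics_from_affinity(220.0, kon_ref=1e-3)
        assert kin.koff == pytest.approx(0.22)
        kin2 = kinetics_from_affinity(1.22, kon_ref=1e-3)
        assert kin2.koff == pytest.approx(1.22e-3)
        # shared kon: koff ratio equals Ki ratio
        assert kin.koff / kin2.koff == pytest.approx(220.0 / 1.22)

    def test_kd_consistency(self):
        kin = kinetics_from_affinity(37.5)
        assert kin.kd == pytest.approx(37.5, rel=1e-12)
        assert isinstance(kin, BindingKinetics)


class TestMoieties:
    def test_ocaperidone_mixture_split(self, ref_drugs):
        moiety = ref_drugs["ocaperidone-moiety"]
        conc = moiety_concentrations(moiety, 4.3)
        assert conc["ocaperidone"] == pytest.approx(3.225)
        assert conc["ND8295"] == pytest.approx(1.075)

    def test_single_component_identity(self, ref_drugs):
        conc = moiety_concentrations(ref_drugs["JNJ37822681"], 700.0)
        assert conc == {"JNJ37822681": 700.0}

    @settings(deadline=None, max_examples=30)
    @given(total=st.floats(0.0, 1e6), frac=st.floats(0.01, 0.99))
    def test_mass_conservation(self, total, frac):
        a = DrugProfile("a", affinities={"D2": 1.0})
        b = DrugProfile("b", affinities={"D2": 2.0})
        m = mixture("m", [(a, frac), (b, 1.0 - frac)])
        conc = moiety_concentrations(m, total)
        assert sum(conc.values()) == pytest.approx(total, rel=1e-12, abs=1e-12)

    def test_bad_fractions_rejected(self):
        a = DrugProfile("a", affinities={"D2": 1.0})
        with pytest.raises(ValueError):
            mixture("m", [(a, 0.6), (a, 0.6)])


class TestEfficacy:
    def test_default_full_antagonist_weight_zero(self):
        d = DrugProfile("d", affinities={"D2": 10.0})
        assert d.efficacy_at("D2") == -1.0
        assert d.activation_weight("D2") == 0.0

    def test_partial_agonist_weight(self):
        d = DrugProfile("d", affinities={"5-HT1A": 10.0}, efficacy={"5-HT1A": 0.5})
        assert d.activation_weight("5-HT1A") == pytest.approx(0.75)

    def test_out_of_range_efficacy_rejected(self):
        with pytest.raises(ValueError):
            DrugProfile("d", affinities={"D2": 10.0}, efficacy={"D2": 1.5})
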