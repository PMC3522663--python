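"""Synapse competition model: oracle equivalence, displacement, inversion."""

import numpy as np
import pytest

from psyqsp.pharmacology import DrugProfile, kinetics_from_affinity
from psyqsp.receptor_competition import (
    InversionError,
    SynapseConfig,
    _build,
    _run_cycle,
    invert_functional_concentration,
    periodic_steady_state,
    simulate_synapse,
    steady_state_occupancy,
    time_averaged_activation,
    tracer_displacement,
)


def constant_synapse(**kw):
    base = dict(
        pulsatile=False, autoreceptor_receptor=None, release_per_spike=50.0,
        tonic_rate=3.0, clearance_rate=25.0, receptor_kd=(("D2", 1600.0),),
    )
    base.update(kw)
    return SynapseConfig(**base)


class TestOracle:
    def test_single_ligand_half_occupancy(self):
        assert steady_state_occupancy([(220.0, 220.0)]) == [pytest.approx(0.5)]

    def test_symmetric_ligands_equal(self):
        occ = steady_state_occupancy([(100.0, 30.0), (100.0, 30.0)])
        assert occ[0] == pytest.approx(occ[1])

    def test_ode_steady_state_matches_closed_form(self):
        # three-way competition: NT at its simulated level + drug + tracer
        cfg = constant_synapse()
        drug = DrugProfile("d", affinities={"D2": 220.0})
        prob = _build(cfg, drug, 400.0, (1.5, 1.0))
        state = periodic_steady_state(prob)
        _, b_avg, c_avg, _, _ = _run_cycle(prob, state, False)
        oracle = steady_state_occupancy(
            [(1600.0, c_avg[1]), (220.0, 400.0), (1.5, 1.0)]
        )
        for sim, ref in zip(b_avg[0], oracle):
            assert sim == pytest.approx(ref, rel=1e-6)

    def test_free_nt_settles_at_release_over_clearance(self):
        cfg = constant_synapse(release_per_spike=100.0, tonic_rate=3.0,
                               clearance_rate=25.0)
        ts = simulate_synapse(cfg, [], duration=20.0)
        assert ts.free_nt[-1] == pytest.approx(3.0 * 100.0 / 25.0, rel=1e-6)

    def test_single_drug_approaches_langmuir(self):
        cfg = constant_synapse(release_per_spike=0.0, tonic_rate=0.0)
        kin = kinetics_from_affinity(220.0)
        ts = simulate_synapse(cfg, [(kin, 220.0)], duration=100.0)
        assert ts.bound["ligand_1"][-1] == pytest.approx(0.5, rel=1e-4)

    def test_zero_duration_returns_empty_series(self):
        ts = simulate_synapse(constant_synapse(), [], duration=0.0)
        assert len(ts.times) == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_synapse(constant_synapse(), [], duration=-1.0)


class TestDisplacement:
    def test_zero_concentration_zero_displacement(self, da_ventral, ref_drugs):
        assert tracer_displacement(da_ventral, ref_drugs["JNJ37822681"], 0.0) == 0.0

    def test_saturating_concentration_approaches_full(self, da_ventral, ref_drugs):
        d = tracer_displacement(da_ventral, ref_drugs["JNJ37822681"], 1e6)
        assert d > 99.0

    def test_monotone_in_concentration(self, da_ventral, ref_drugs):
        jnj = ref_drugs["JNJ37822681"]
        concs = np.geomspace(10.0, 5000.0, 8)
        disps = [tracer_displacement(da_ventral, jnj, c) for c in concs]
        assert np.all(np.diff(disps) > 0)

    def test_reference_calibration_reproduces_pet_pairs(self, da_ventral, ref_drugs):
        # the shipped synapse is a stored fit to these three pairs (<=3 pp)
        jnj = ref_drugs["JNJ37822681"]
        for conc, disp in [(400.0, 55.0), (700.0, 75.0), (840.0, 80.0)]:
            assert tracer_displacement(da_ventral, jnj, conc) == pytest.approx(
                disp, abs=3.0
            )


class TestInversion:
    def test_round_trip(self, da_ventral, ref_drugs):
        jnj = ref_drugs["JNJ37822681"]
        c0 = 700.0
        d = tracer_displacement(da_ventral, jnj, c0)
        c1 = invert_functional_concentration(da_ventral, jnj, d)
        assert c1 == pytest.approx(c0, rel=0.01)

    def test_target_out_of_range_rejected(self, da_ventral, ref_drugs):
        with pytest.raises(InversionError):
            invert_functional_concentration(da_ventral, ref_drugs["JNJ37822681"], 0.0)
        with pytest.raises(InversionError):
            invert_functional_concentration(da_ventral, ref_drugs["JNJ37822681"], 100.0)

    def test_unreachable_target_within_bounds_rejected(self, da_ventral, ref_drugs):
        with pytest.raises(InversionError):
            invert_functional_concentration(
                da_ventral, ref_drugs["JNJ37822681"], 95.0, conc_bounds=(1.0, 10.0)
            )


class TestActivation:
    def test_zero_concentration_zero_delta(self, da_ventral, ref_drugs):
        a = time_averaged_activation(da_ventral, ref_drugs["JNJ37822681"], "D2", 0.0)
        assert a.delta == 0.0
        assert a.averaging_window == pytest.approx(10.0)

    def test_saturating_antagonist_abolishes_activation(self, da_ventral, ref_drugs):
        a = time_averaged_activation(da_ventral, ref_drugs["JNJ37822681"], "D2", 1e7)
        assert a.drug_activation < 0.02
        assert a.delta == pytest.approx(-a.baseline_activation, abs=0.02)

    def test_blockade_monotone_in_concentration(self, da_ventral, ref_drugs):
        jnj = ref_drugs["JNJ37822681"]
        deltas = [
            time_averaged_activation(da_ventral, jnj, "D2", c).delta
            for c in (400.0, 700.0, 840.0)
        ]
        assert deltas[0] > deltas[1] > deltas[2]
        assert all(d < 0 for d in deltas)
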