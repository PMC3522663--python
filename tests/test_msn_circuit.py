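"""MSN circuit: Kir2 contract, spiking behaviour, firing -> PANSS link."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import curve_fit

from psyqsp.msn_circuit import (
    AfferentDrive,
    CouplingParams,
    MSNParams,
    PanssLink,
    PathologyConfig,
    circuit_firing,
    firing_to_panss,
    kir2_conductance,
    kir2_current,
    population_factors,
    simulate_msn,
)


class TestKir2:
    def test_saturates_at_gmax(self):
        v = np.linspace(-130.0, 60.0, 2000)
        g = np.array([kir2_conductance(vi) for vi in v])
        assert g.max() == pytest.approx(1.2, rel=1e-3)
        assert np.all(g > 0)

    def test_half_activation_at_vh(self):
        assert kir2_conductance(-111.0) == pytest.approx(0.6, rel=1e-12)

    def test_zero_current_at_reversal(self):
        assert kir2_current(-90.0) == 0.0

    def test_current_sign_follows_driving_force(self):
        assert kir2_current(-111.0) == pytest.approx(0.6 * (-21.0))
        assert kir2_current(-120.0) < 0  # inward below E_K
        assert kir2_current(-60.0) > 0

    def test_unmodulated_factor_is_exactly_one(self):
        c = CouplingParams(d1_kir=-2.0)
        assert kir2_conductance(-80.0, 0.0, coupling=c) == kir2_conductance(-80.0)

    def test_slope_parameter_recoverable_from_samples(self):
        v = np.linspace(-130.0, -80.0, 200)
        g = np.array([kir2_conductance(vi) for vi in v])

        def boltzmann(v, gmax, vh, vc):
            return gmax / (1.0 + np.exp((v - vh) / vc))

        popt, _ = curve_fit(boltzmann, v, g, p0=(1.0, -100.0, -5.0))
        assert popt[0] == pytest.approx(1.2, rel=1e-6)
        assert popt[1] == pytest.approx(-111.0, rel=1e-6)
        assert popt[2] == pytest.approx(-11.0, rel=1e-6)


class TestSimulateMSN:
    def test_no_drive_no_spikes(self):
        params = MSNParams.reference()
        drive = dataclasses.replace(AfferentDrive.reference(), cortical_rate=0.0)
        assert simulate_msn(params, drive, seed=0) == 0

    def test_deterministic_per_seed(self):
        params = MSNParams.reference()
        drive = AfferentDrive.reference()
        a = simulate_msn(params, drive, seed=5)
        b = simulate_msn(params, drive, seed=5)
        c = simulate_msn(params, drive, seed=6)
        assert a == b
        assert isinstance(a, int)
        assert a != c  # different realization (overwhelmingly likely)

    def test_count_non_increasing_when_weight_decreases(self):
        params = MSNParams.reference()
        drive = AfferentDrive.reference()
        weights = params.syn_weight * np.array([1.2, 1.0, 0.8, 0.6])
        counts = [
            simulate_msn(dataclasses.replace(params, syn_weight=w), drive, seed=3)
            for w in weights
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_shipped_placebo_reference_firing(self):
        res = circuit_firing(seed=1, pathology=PathologyConfig.reference())
        assert res.combined == pytest.approx(199.0, abs=3.0)


class TestCircuitFiring:
    def test_population_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            circuit_firing(weights={"d1": 0.5, "d2": 0.5, "mixed": 0.5})

    def test_combined_is_convex_combination(self):
        res = circuit_firing(seed=2, pathology=PathologyConfig.reference())
        lo, hi = min(res.counts.values()), max(res.counts.values())
        assert lo <= res.combined <= hi
        assert sum(res.weights.values()) == pytest.approx(1.0)

    def test_factors_identity_without_activations(self):
        fac = population_factors({}, CouplingParams.reference("panss"), "d1")
        assert all(v == 1.0 for v in fac.values())

    def test_d2_blockade_raises_indirect_pathway_firing(self):
        cp = CouplingParams.reference("panss")
        path = PathologyConfig.reference()
        base = circuit_firing({}, cp, pathology=path, seed=4)
        blocked = circuit_firing({"D2": -0.3}, cp, pathology=path, seed=4)
        assert blocked.counts["d2"] > base.counts["d2"]


class TestPanssLink:
    def test_anchor_reproduction(self):
        for firing, panss in [(245, 13.4), (286, 24.0), (297, 27.0), (199, 1.7)]:
            assert firing_to_panss(firing) == pytest.approx(panss, abs=1.0)

    def test_monotone_non_decreasing(self):
        xs = np.linspace(0, 400, 50)
        ys = [firing_to_panss(x) for x in xs]
        assert np.all(np.diff(ys) >= 0)

    def test_negative_firing_rejected(self):
        with pytest.raises(ValueError):
            firing_to_panss(-1.0)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            PanssLink.fit([200, 250, 300], [10.0, 5.0, 1.0])
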