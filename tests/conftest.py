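"""Shared fixtures.

The expensive fixtures (parameter-recovery experiment, reference-arm
predictions) are session-scoped and shared between the acceptance tests and
the module-level property tests so the heavy simulations run once.
"""

import numpy as np
import pytest

from psyqsp import config
from psyqsp.calibration import calibrate, objective_r2
from psyqsp.msn_circuit import CouplingParams
from psyqsp.synthetic_data import (
    SyntheticSpec,
    generate_drug_library,
    generate_synthetic_trials,
)

SEED = 11


@pytest.fixture(scope="session")
def ref_drugs():
    return config.reference_drugs()


@pytest.fixture(scope="session")
def da_ventral():
    return config.reference_synapses()["DA_ventral"]


@pytest.fixture(scope="session")
def recovery_experiment():
    """Calibrate on noise-free and noisy 43-point synthetic datasets.

    Returns everything the recovery, noise-monotonicity and
    mechanistic-vs-baseline checks need.
    """
    spec0 = SyntheticSpec(noise_sd_per_100=0.0, seed=SEED)
    library = generate_drug_library(spec0)
    ds0, ev0 = generate_synthetic_trials(library, spec=spec0)
    res0 = calibrate(ds0, evaluator=ev0, seed=SEED)

    spec2 = SyntheticSpec(noise_sd_per_100=2.0, seed=SEED)
    ds2, ev2 = generate_synthetic_trials(generate_drug_library(spec2), spec=spec2)
    res2 = calibrate(
        ds2, evaluator=ev2, seed=SEED,
        probe_schedule=(0.10,) * 3 + (0.05,) * 4, valley_rounds=0,
    )
    return {
        "library": library,
        "true_coupling": spec0.true_coupling,
        "noiseless": {"dataset": ds0, "evaluator": ev0, "result": res0},
        "noise2": {"dataset": ds2, "evaluator": ev2, "result": res2},
    }


@pytest.fixture(scope="session")
def reference_predictions(ref_drugs):
    """Shipped-calibration predictions for the reference trial arms."""
    from psyqsp.pipeline import predict_clinical_profile

    arms = [
        ("placebo", None, None),
        ("JNJ37822681_10", "JNJ37822681", 55.0),
        ("JNJ37822681_20", "JNJ37822681", 75.0),
        ("JNJ37822681_30", "JNJ37822681", 80.0),
        ("olanzapine_15", "olanzapine", 75.0),
    ]
    out = {}
    for key, drug, disp in arms:
        if drug is None:
            from psyqsp.eps_circuit import (
                eps_score,
                eps_to_anticholinergic_fraction,
                motor_msn_firing,
                pyramidal_threshold,
            )
            from psyqsp.msn_circuit import PathologyConfig, circuit_firing, firing_to_panss

            firing = circuit_firing(
                {}, CouplingParams.reference("panss"),
                pathology=PathologyConfig.reference(), seed=1,
            )
            thr = pyramidal_threshold({})
            score = eps_score(motor_msn_firing({}, seed=1).combined, thr)
            out[key] = {
                "panss": firing_to_panss(firing.combined),
                "threshold": thr,
                "eps_fraction": eps_to_anticholinergic_fraction(score, seed=1),
                "firing": firing.combined,
            }
        else:
            r = predict_clinical_profile(ref_drugs[drug], displacement_pct=disp, seed=1)
            out[key] = {
                "panss": r.panss_improvement,
                "threshold": r.threshold_factor,
                "eps_fraction": r.anticholinergic_fraction,
                "firing": r.accumbens_firing,
            }
    return out
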