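"""End-to-end prediction pipeline.

Drug profile + PET-derived D2 engagement -> functional brain concentration
-> receptor-activation changes -> accumbens circuit firing -> PANSS-total
improvement, and in parallel motor circuit x cortical threshold -> EPS
(anticholinergic-use) liability, with normal-theory 95% prediction
intervals.  Predictions are driven by displacement or concentration, never
by the milligram dose.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from . import config
from .activations import drug_activations
from .calibration import CalibrationResult
from .eps_circuit import (
    eps_score,
    eps_to_anticholinergic_fraction,
    motor_msn_firing,
    pyramidal_threshold,
)
from .msn_circuit import (
    CouplingParams,
    PathologyConfig,
    circuit_firing,
    firing_to_panss,
)
from .pharmacology import DrugProfile
from .receptor_competition import invert_functional_concentration

__all__ = ["PredictionReport", "predict_clinical_profile", "run_scenarios"]


@dataclass
class PredictionReport:
    """Full model prediction for one drug at one level of D2 engagement."""

    drug: str
    displacement_pct: float | None
    functional_concentration_nM: float
    accumbens_firing: float
    panss_improvement: float
    panss_interval: tuple[float, float]
    motor_firing: float
    threshold_factor: float
    eps_score: float
    anticholinergic_fraction: float
    anticholinergic_interval: tuple[float, float]
    seed: int = 0
    calibration: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.panss_interval
        if not (lo <= self.panss_improvement <= hi):
            raise ValueError("PANSS interval must contain the point estimate")
        if not (0.0 <= self.anticholinergic_fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panss_interval"] = list(self.panss_interval)
        d["anticholinergic_interval"] = list(self.anticholinergic_interval)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionReport":
        d = dict(d)
        d["panss_interval"] = tuple(d["panss_interval"])
        d["anticholinergic_interval"] = tuple(d["anticholinergic_interval"])
        return cls(**d)


def _interval_sds() -> tuple[float, float]:
    iv = config.reference_raw().get("reference_intervals", {})
    return iv.get("panss_residual_sd", 3.0), iv.get("eps_residual_sd", 0.04)


def predict_clinical_profile(
    drug: DrugProfile,
    displacement_pct: float | None = None,
    concentration_nM: float | None = None,
    calibration: CalibrationResult | None = None,
    coupling: CouplingParams | None = None,
    motor_coupling: CouplingParams | None = None,
    seed: int = 0,
) -> PredictionReport:
    """Predict PANSS-total improvement and EPS liability for one drug.

    Exactly one of ``displacement_pct`` (observed raclopride displacement,
    inverted through the reference striatal synapse) or ``concentration_nM``
    (functional brain concentration) must be given.  With ``calibration``
    the fitted couplings and residual spread are used; otherwise the
    shipped reference calibration.
    """
    if (displacement_pct is None) == (concentration_nM is None):
        raise ValueError("give exactly one of displacement_pct / concentration_nM")
    syn = config.reference_synapses()["DA_ventral"]
    if displacement_pct is not None:
        conc = invert_functional_concentration(syn, drug, displacement_pct)
    else:
        conc = float(concentration_nM)
    if coupling is None:
        coupling = (
            calibration.coupling if calibration is not None
            else CouplingParams.reference("panss")
        )
    motor_coupling = motor_coupling or CouplingParams.reference("motor")

    acts_v = drug_activations(drug, conc, region="ventral")
    firing = circuit_firing(
        acts_v, coupling, pathology=PathologyConfig.reference(), seed=seed
    )
    if calibration is not None:
        panss = calibration.predict_outcome(firing.combined)
        panss_sd = calibration.residual_sd
        _, eps_sd = _interval_sds()
        cal_meta = {"r2": calibration.r2, "residual_sd": calibration.residual_sd}
    else:
        panss = firing_to_panss(firing.combined)
        panss_sd, eps_sd = _interval_sds()
        cal_meta = {"source": "shipped-reference"}

    acts_d = drug_activations(drug, conc, region="dorsal")
    motor = motor_msn_firing(acts_d, motor_coupling, seed=seed)
    thr = pyramidal_threshold(acts_d)
    score = eps_score(motor.combined, thr)
    frac = eps_to_anticholinergic_fraction(score, seed=seed)

    panss_iv = _normal_interval(panss, panss_sd)
    eps_iv = _normal_interval(frac, eps_sd, clip=(0.0, 1.0))
    return PredictionReport(
        drug=drug.name,
        displacement_pct=displacement_pct,
        functional_concentration_nM=conc,
        accumbens_firing=firing.combined,
        panss_improvement=panss,
        panss_interval=panss_iv,
        motor_firing=motor.combined,
        threshold_factor=thr,
        eps_score=score,
        anticholinergic_fraction=frac,
        anticholinergic_interval=eps_iv,
        seed=seed,
        calibration=cal_meta,
    )


def _normal_interval(x: float, sd: float, clip=None) -> tuple[float, float]:
    lo, hi = x - 1.96 * sd, x + 1.96 * sd
    if clip is not None:
        lo, hi = max(lo, clip[0]), min(hi, clip[1])
    return (lo, hi)


def run_scenarios(
    drug: DrugProfile,
    occupancies: list[float],
    calibration: CalibrationResult | None = None,
    seed: int = 0,
) -> list[PredictionReport]:
    """One prediction report per assumed D2 occupancy (percent).

    Used to explore whether higher-than-measured target engagement would
    reconcile model and clinical outcomes.
    """
    for occ in occupancies:
        if not (0 < occ < 100):
            raise ValueError(f"occupancy {occ} outside (0, 100)%")
    return [
        predict_clinical_profile(
            drug, displacement_pct=occ, calibration=calibration, seed=seed
        )
        for occ in occupancies
    ]
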