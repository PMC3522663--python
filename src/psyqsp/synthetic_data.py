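"""Synthetic drug libraries and clinical trial datasets with known truth.

The retrospective antipsychotic trial database the platform was originally
calibrated on is not redistributable, so testing the calibration machinery
requires datasets whose generating mechanism is known exactly.  This module
builds (a) drug libraries spanning the pharmacological archetypes of the
antipsychotic class -- a selective low-affinity D2 antagonist, a
rich-off-target olanzapine-like profile, a weak-D2 clozapine-like profile,
plus randomized sparse profiles -- and (b) drug-dose clinical datasets whose
outcomes are the mechanistic circuit model evaluated at a known "true"
coupling vector, aggregated over patient arms with Gaussian noise whose
standard deviation shrinks as 1/sqrt(arm size).

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ClinicalDataset, ClinicalPoint, CircuitEvaluator, weighted_average_outcome
from .msn_circuit import CouplingParams, reference_panss_link
from .pharmacology import DrugProfile

__all__ = [
    "SyntheticSpec",
    "recovery_coupling",
    "generate_drug_library",
    "generate_synthetic_trials",
    "write_clinical_csv",
]

#: Receptors sampled for off-target binding (the circuit-coupled set plus
#: the serotonergic receptors relevant to the EPS side).
OFFTARGET_RECEPTORS = ("D1", "M1", "M2", "alpha1", "5-HT3", "5-HT2A", "5-HT1A", "5-HT2C")


def recovery_coupling() -> CouplingParams:
    """Ground-truth coupling vector for recovery experiments.

    Magnitudes are chosen so every coupling channel has a clearly resolvable
    effect on the integer spike counts (a 10% change moves at least a couple
    of spikes on strongly-binding drugs), i.e. the recovery problem is
    identifiable at the stated precision.
    """
    return CouplingParams(
        d1_kir=-0.4, d1_syn=0.2, d2_gk=0.4, d2_presyn=-0.15,
        m1_leak=0.8, m2_gk=0.25, m2_presyn=-0.15,
        a1_syn=0.15, a1_bg=1.0, ht3_bg=-2.5,
    )


@dataclass
class SyntheticSpec:
    """Study-design parameters of a synthetic trial programme."""

    n_drugs: int = 9
    doses_per_drug: tuple[int, ...] = (5, 5, 5, 5, 5, 5, 5, 4, 4)  # -> 43 points
    occupancy_range: tuple[float, float] = (0.30, 0.85)
    d2_ki_range: tuple[float, float] = (30.0, 400.0)     # nM, log-uniform
    offtarget_rel_range: tuple[float, float] = (0.3, 30.0)  # Ki relative to D2
    offtarget_prob: float = 0.5
    true_coupling: CouplingParams = field(default_factory=recovery_coupling)
    noise_sd_per_100: float = 2.0     # outcome sd at arm size 100
    arm_n_range: tuple[int, int] = (50, 400)
    arms_per_point: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_per_100 < 0:
            raise ValueError("noise sd must be >= 0")
        if len(self.doses_per_drug) != self.n_drugs:
            raise ValueError("doses_per_drug must have n_drugs entries")


def generate_drug_library(spec: SyntheticSpec) -> list[DrugProfile]:
    """Synthetic antipsychotic library; deterministic per ``spec.seed``.

    The first three drugs are fixed archetypes (selective-D2,
    olanzapine-like, clozapine-like); the rest have log-uniform D2 affinity
    and random sparse off-target profiles.
    """
    rng = np.random.default_rng(spec.seed)
    lib: list[DrugProfile] = []
    if spec.n_drugs == 0:
        return lib
    archetypes = [
        DrugProfile("syn-selective-d2", affinities={"D2": 220.0}),
        DrugProfile("syn-olanzapine-like", affinities={
            "D2": 31.0, "D1": 70.0, "5-HT2A": 4.0, "5-HT2C": 11.0,
            "5-HT3": 202.0, "M1": 26.0, "M2": 48.0, "alpha1": 19.0,
        }),
        DrugProfile("syn-clozapine-like", affinities={
            "D2": 157.0, "D1": 270.0, "5-HT2A": 8.0, "5-HT1A": 124.0,
            "5-HT3": 241.0, "M1": 1.9, "M2": 72.0, "alpha1": 7.0,
        }),
        # archetypes that probe single off-target channels strongly, making
        # each coupling parameter identifiable from the library
        DrugProfile("syn-d1-rich", affinities={"D2": 120.0, "D1": 25.0}),
        DrugProfile("syn-m2-rich", affinities={"D2": 150.0, "M2": 20.0}),
        DrugProfile("syn-a1-rich", affinities={"D2": 150.0, "alpha1": 15.0}),
        DrugProfile("syn-ht3-rich", affinities={"D2": 150.0, "5-HT3": 20.0}),
    ]
    lib.extend(archetypes[: spec.n_drugs])
    lo, hi = spec.d2_ki_range
    rlo, rhi = spec.offtarget_rel_range
    for i in range(len(lib), spec.n_drugs):
        ki_d2 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        aff = {"D2": ki_d2}
        for rec in OFFTARGET_RECEPTORS:
            if rng.random() < spec.offtarget_prob:
                rel = float(np.exp(rng.uniform(np.log(rlo), np.log(rhi))))
                aff[rec] = ki_d2 * rel
        lib.append(DrugProfile(f"syn-drug-{i}", affinities=aff))
    return lib


def generate_synthetic_trials(
    library: list[DrugProfile],
    true_coupling: CouplingParams | None = None,
    spec: SyntheticSpec | None = None,
    evaluator: CircuitEvaluator | None = None,
) -> tuple[ClinicalDataset, CircuitEvaluator]:
    """Drug-dose clinical dataset generated by the mechanistic model.

    For each drug, doses are concentrations spanning the naive D2 occupancy
    range; the noise-free outcome is the reference firing->PANSS link applied
    to the circuit firing at ``true_coupling``; per-arm Gaussian noise has sd
    ``noise_sd_per_100 * sqrt(100 / n)`` and arms are aggregated by
    patient-weighted averaging.  Returns the dataset and the evaluator
    (reusable for calibration, guaranteeing the same afferent trains).
    """
    spec = spec or SyntheticSpec()
    true_coupling = true_coupling or spec.true_coupling
    rng = np.random.default_rng(spec.seed + 1)
    drugs = {d.name: d for d in library}
    points = []
    occ_lo, occ_hi = spec.occupancy_range
    for d, n_doses in zip(library, spec.doses_per_drug):
        ki = d.ki("D2")
        if ki is None:
            raise ValueError(f"{d.name}: library drugs must bind D2")
        for occ in np.linspace(occ_lo, occ_hi, n_doses):
            conc = ki * occ / (1.0 - occ)
            points.append(
                ClinicalPoint(drug=d.name, dose=round(float(conc), 4),
                              concentration=float(conc), outcome=0.0, n=1)
            )
    dataset = ClinicalDataset(points=points, scale="PANSS-total")
    if evaluator is None:
        evaluator = CircuitEvaluator(dataset, drugs=drugs, seed=spec.seed)
    link = reference_panss_link()
    firing = evaluator(true_coupling)
    n_lo, n_hi = spec.arm_n_range
    a_lo, a_hi = spec.arms_per_point
    for pt, f in zip(dataset.points, firing):
        clean = link(f)
        n_arms = int(rng.integers(a_lo, a_hi + 1))
        arms = []
        for _ in range(n_arms):
            n = int(rng.integers(n_lo, n_hi + 1))
            sd = spec.noise_sd_per_100 * np.sqrt(100.0 / n)
            arms.append((clean + rng.normal(0.0, sd) if sd > 0 else clean, n))
        pt.outcome = weighted_average_outcome(arms)
        pt.n = sum(n for _, n in arms)
    return dataset, evaluator


def write_clinical_csv(dataset: ClinicalDataset, path) -> None:
    """Write the calibration module's clinical CSV dialect."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drug", "dose_mg", "concentration_nM", "outcome", "scale", "n"])
        for p in dataset.points:
            w.writerow([p.drug, p.dose, p.concentration, p.outcome, dataset.scale, p.n])
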