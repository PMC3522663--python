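"""Drug -> receptor-activation-change vectors under the reference synapses.

Bridges the receptor-competition model and the circuit models: given a drug
and its functional brain concentration, returns the change in time-averaged
activation for each receptor the circuits couple to, using the shipped
reference synapse configurations (ventral/accumbens or dorsal/motor DA,
plus the ACh, NE and 5-HT systems).
"""

from __future__ import annotations

from . import config
from .pharmacology import DrugProfile
from .receptor_competition import time_averaged_activation

__all__ = ["drug_activations", "CIRCUIT_RECEPTORS", "EPS_RECEPTORS"]

CIRCUIT_RECEPTORS = ("D1", "D2", "M1", "M2", "alpha1", "5-HT3")
EPS_RECEPTORS = CIRCUIT_RECEPTORS + ("5-HT2A", "5-HT1A")


def _binds(drug: DrugProfile, receptor: str) -> bool:
    return any(p.binds(receptor) for p, _ in drug.species())


def drug_activations(
    drug: DrugProfile | None,
    conc: float,
    region: str = "ventral",
    receptors: tuple[str, ...] = EPS_RECEPTORS,
) -> dict[str, float]:
    """Activation deltas for ``receptors`` at functional concentration ``conc``.

    ``region`` selects the DA synapse variant ("ventral" = accumbens with
    schizophrenia pathology, "dorsal" = motor striatum).  Receptors of
    non-dopamine systems that the drug does not bind are returned as exact
    zeros without simulation (the drug cannot perturb those synapses).
    """
    if region not in ("ventral", "dorsal"):
        raise ValueError("region must be 'ventral' or 'dorsal'")
    synapses = config.reference_synapses()
    da_key = "DA_ventral" if region == "ventral" else "DA_dorsal"
    out: dict[str, float] = {}
    for rec in receptors:
        system = config.receptor_system(rec)
        cfg = synapses[da_key] if system == "DA" else synapses[system]
        if drug is None or conc == 0.0:
            out[rec] = 0.0
            continue
        if system != "DA" and not _binds(drug, rec):
            # no binding at this receptor and no feedback path into its
            # synapse -> no activation change
            out[rec] = 0.0
            continue
        out[rec] = time_averaged_activation(cfg, drug, rec, conc).delta
    return out
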