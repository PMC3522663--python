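"""Reference-configuration loading.

The package ships, as plain data files, (a) the binding table of the two
experimental compounds and the metabolite, (b) consensus receptor-screening
affinities for three comparator antipsychotics, and (c) a YAML file with the
calibrated reference model: synapse parameters anchored to the published PET
displacement pairs, circuit parameters, coupling values and outcome-link
anchors.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .pharmacology import DrugProfile, load_drug_table, mixture
from .receptor_competition import SynapseConfig

__all__ = [
    "reference_raw",
    "reference_synapses",
    "reference_drugs",
    "reference_arms",
    "receptor_system",
    "tracer_params",
]


def _data_path(name: str):
    return resources.files("psyqsp.data").joinpath(name)


@lru_cache(maxsize=1)
def reference_raw() -> dict:
    with resources.as_file(_data_path("reference.yaml")) as p:
        return yaml.safe_load(p.read_text())


_SYNAPSE_FIELDS = {
    "transmitter", "tonic_rate", "burst_rate", "burst_schedule", "period",
    "release_per_spike", "clearance_rate", "clearance_km",
    "cleft_release_scale", "cleft_clearance_rate",
    "autoreceptor_gain", "autoreceptor_half", "autoreceptor_width",
    "autoreceptor_kd", "autoreceptor_receptor",
    "primary_receptor", "receptor_kd", "cleft_receptor_kd",
}


@lru_cache(maxsize=1)
def reference_synapses() -> dict[str, SynapseConfig]:
    raw = reference_raw()
    out = {}
    for name, section in raw["synapses"].items():
        kw = {k: v for k, v in section.items() if k in _SYNAPSE_FIELDS}
        if "burst_schedule" in kw:
            kw["burst_schedule"] = tuple(tuple(b) for b in kw["burst_schedule"])
        for key in ("receptor_kd", "cleft_receptor_kd"):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = tuple(kw[key].items())
        out[name] = SynapseConfig(**kw)
    return out


@lru_cache(maxsize=1)
def reference_drugs() -> dict[str, DrugProfile]:
    """All shipped drug profiles, including the active-moiety mixture."""
    drugs: dict[str, DrugProfile] = {}
    with resources.as_file(_data_path("table1_affinities.csv")) as p:
        for d in load_drug_table(p):
            drugs[d.name] = d
    with resources.as_file(_data_path("reference_drugs.csv")) as p:
        for d in load_drug_table(p):
            drugs[d.name] = d
    for name, parts in reference_raw().get("mixtures", {}).items():
        drugs[name] = mixture(name, [(drugs[p], f) for p, f in parts])
    return drugs


def reference_arms() -> list[dict]:
    """Reference drug-dose arms with their PET displacement."""
    return list(reference_raw()["reference_arms"])


def receptor_system(receptor: str) -> str:
    """Transmitter system whose synapse carries ``receptor``."""
    return reference_raw()["receptor_systems"][receptor]


def tracer_params() -> tuple[float, float]:
    t = reference_raw()["tracer"]
    return float(t["kd_nM"]), float(t["conc_nM"])
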