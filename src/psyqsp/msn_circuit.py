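"""Biophysical medium spiny neuron (MSN) circuit model.

A single-compartment Hodgkin-Huxley MSN with an inward-rectifier (Kir2)
conductance is driven by Poisson cortical afferents gated by periodic
hippocampal/amygdala envelopes.  The Kir2 conductance follows a Boltzmann
voltage dependence

    g(V) = gmax / (1 + exp((V - Vh) / Vc)),   gmax = 1.2 mS/cm^2,
    Vh = -111 mV (half activation), Vc = -11 mV (slope),

with reversal at E_K = -90 mV, and is multiplicatively modulated by the
dopamine D1 activation change ``u``.

The circuit readout is the number of action potentials over a fixed 21 s
window, computed for a direct-pathway (D1) population, an indirect-pathway
(D2) population and a small mixed D1+D2 population, combined by fixed
weights.  Ten coupling parameters scale how receptor-activation changes
(from the synapse competition model) modulate circuit conductances and
synaptic drive; their shipped values are a reference calibration anchored to
published firing/outcome pairs, and the firing -> PANSS-improvement link is
a least-squares fit to those anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels, config

__all__ = [
    "MSNParams",
    "CouplingParams",
    "PathologyConfig",
    "AfferentDrive",
    "CircuitResult",
    "kir2_conductance",
    "kir2_current",
    "simulate_msn",
    "circuit_firing",
    "firing_to_panss",
    "PanssLink",
    "POPULATIONS",
]

POPULATIONS = ("d1", "d2", "mixed")

#: Receptors entering the ten coupling parameters.
COUPLED_RECEPTORS = ("D1", "D2", "M1", "M2", "alpha1", "5-HT3")


@dataclass(frozen=True)
class MSNParams:
    """Membrane and synaptic parameters (conductances mS/cm^2, potentials mV)."""

    cm: float = 1.0
    g_na: float = 100.0
    e_na: float = 50.0
    g_kdr: float = 80.0
    e_k: float = -90.0
    g_leak: float = 0.1
    e_leak: float = -67.0
    kir2_gmax: float = 1.2
    kir2_vh: float = -111.0
    kir2_vc: float = -11.0
    tau_syn_ms: float = 3.0
    e_syn: float = 0.0
    syn_weight: float = 0.9
    i_bg: float = 0.5
    dt_ms: float = 0.2
    spike_threshold_mv: float = 0.0
    refractory_ms: float = 2.0
    v0: float = -85.0

    def __post_init__(self):
        if self.kir2_vc == 0:
            raise ValueError("kir2_vc must be nonzero")
        for f in ("g_na", "g_kdr", "g_leak", "kir2_gmax", "syn_weight", "cm"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @classmethod
    def reference(cls) -> "MSNParams":
        m = config.reference_raw()["msn"]
        return cls(
            cm=m["cm"], g_na=m["g_na"], e_na=m["e_na"], g_kdr=m["g_kdr"],
            e_k=m["e_k"], g_leak=m["g_leak"], e_leak=m["e_leak"],
            kir2_gmax=m["kir2_gmax"], kir2_vh=m["kir2_vh"], kir2_vc=m["kir2_vc"],
            tau_syn_ms=m["tau_syn_ms"], e_syn=m["e_syn"],
            syn_weight=m["syn_weight"], i_bg=m["i_bg"], dt_ms=m["dt_ms"],
            spike_threshold_mv=m["spike_threshold_mv"],
            refractory_ms=m["refractory_ms"], v0=m["v0"],
        )


@dataclass
class CouplingParams:
    """The ten biological coupling parameters.

    Each scales a multiplicative modulation ``factor = 1 + c * u`` applied to
    a circuit quantity, where ``u`` is the drug-induced change in the
    receptor's time-averaged activation.  Two couplings each for D1, D2, M2
    and alpha1; one each for M1 and 5-HT3.
    """

    d1_kir: float = 0.0     # D1 -> Kir2 conductance (direct + mixed MSN)
    d1_syn: float = 0.0     # D1 -> afferent synaptic weight (direct + mixed)
    d2_gk: float = 0.0      # D2 -> resting K conductance (indirect + mixed)
    d2_presyn: float = 0.0  # presynaptic D2 -> glutamate weight (all MSN)
    m1_leak: float = 0.0    # M1 -> leak conductance (all)
    m2_gk: float = 0.0      # M2 -> resting K conductance (all)
    m2_presyn: float = 0.0  # presynaptic M2 -> glutamate weight (all)
    a1_syn: float = 0.0     # alpha1 -> afferent synaptic weight (all)
    a1_bg: float = 0.0      # alpha1 -> background current (all)
    ht3_bg: float = 0.0     # 5-HT3 -> background current (all)

    NAMES = (
        "d1_kir", "d1_syn", "d2_gk", "d2_presyn", "m1_leak",
        "m2_gk", "m2_presyn", "a1_syn", "a1_bg", "ht3_bg",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES])

    @classmethod
    def from_array(cls, x) -> "CouplingParams":
        return cls(**dict(zip(cls.NAMES, map(float, x))))

    @classmethod
    def reference(cls, which: str = "panss") -> "CouplingParams":
        key = {"panss": "couplings_panss", "motor": "couplings_motor"}[which]
        return cls(**config.reference_raw()[key])

    @classmethod
    def reference_bounds(cls) -> dict[str, tuple[float, float]]:
        raw = config.reference_raw()["coupling_bounds"]
        return {k: tuple(v) for k, v in raw.items()}


@dataclass(frozen=True)
class PathologyConfig:
    """Disease-state modifiers (applied to the accumbens/PANSS circuit)."""

    da_release_multiplier: float = 2.0
    d1_high_affinity_factor: float = 1.0
    d2_bp_factor: float = 0.7
    dat_factor: float = 0.7
    ht2c_factor: float = 1.0
    cortical_drive_factor: float = 0.85

    def __post_init__(self):
        for f in ("da_release_multiplier", "d1_high_affinity_factor",
                  "d2_bp_factor", "dat_factor", "ht2c_factor",
                  "cortical_drive_factor"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @classmethod
    def reference(cls) -> "PathologyConfig":
        p = config.reference_raw()["pathology"]
        return cls(
            da_release_multiplier=p["da_release_multiplier"],
            d2_bp_factor=p["d2_bp_factor"],
            dat_factor=p["dat_factor"],
            cortical_drive_factor=p["cortical_drive_factor"],
        )


@dataclass(frozen=True)
class AfferentDrive:
    """Cortical afferent statistics and limbic gating envelopes.

    Gates are periodic on/off envelopes: within each period the rate factor
    is 1 for ``duty`` of the period and ``off_level`` otherwise.
    """

    cortical_rate: float = 32.0                    # Hz (volley rate)
    hippocampal_gate: tuple[float, float, float] = (2.0, 0.6, 0.25)
    amygdala_gate: tuple[float, float, float] = (3.7, 0.5, 0.4)
    presyn_attenuation: float = 1.0                # extra weight multiplier

    def __post_init__(self):
        if self.cortical_rate < 0:
            raise ValueError("cortical_rate must be >= 0")
        if not (0 <= self.presyn_attenuation <= 1.0 + 1e-9):
            raise ValueError("presyn_attenuation must be in [0, 1]")

    @classmethod
    def reference(cls) -> "AfferentDrive":
        m = config.reference_raw()["msn"]
        h = m["hippocampal_gate"]
        a = m["amygdala_gate"]
        return cls(
            cortical_rate=m["afferent_rate"],
            hippocampal_gate=(h["period_s"], h["duty"], h["off_level"]),
            amygdala_gate=(a["period_s"], a["duty"], a["off_level"]),
        )


@dataclass
class CircuitResult:
    """Spike counts per population and their weighted combination."""

    counts: dict[str, int]
    combined: float
    weights: dict[str, float]
    seed: int


# ---------------------------------------------------------------------------
# Kir2 (Eq.-level contract)
# ---------------------------------------------------------------------------


def kir2_conductance(
    v: float, u: float = 0.0,
    params: MSNParams | None = None,
    coupling: CouplingParams | None = None,
) -> float:
    """Kir2 conductance (mS/cm^2) at membrane potential ``v`` (mV).

    Boltzmann voltage dependence with half-activation at ``kir2_vh`` and
    saturation at ``kir2_gmax``, times the D1 modulation factor
    ``1 + d1_kir * u`` (exactly 1 at ``u = 0``).
    """
    p = params or MSNParams()
    c = coupling or CouplingParams()
    mod = max(1.0 + c.d1_kir * u, 0.0)
    return p.kir2_gmax * mod / (1.0 + math.exp((v - p.kir2_vh) / p.kir2_vc))


def kir2_current(
    v: float, u: float = 0.0,
    params: MSNParams | None = None,
    coupling: CouplingParams | None = None,
) -> float:
    """Kir2 current (uA/cm^2): ``g(V, u) * (V - E_K)``; zero at E_K."""
    p = params or MSNParams()
    return kir2_conductance(v, u, params, coupling) * (v - p.e_k)


# ---------------------------------------------------------------------------
# population modulation factors
# ---------------------------------------------------------------------------


def _g(activations: dict[str, float], receptor: str) -> float:
    return activations.get(receptor, 0.0)


def population_factors(
    activations: dict[str, float],
    coupling: CouplingParams,
    population: str,
) -> dict[str, float]:
    """Multiplicative circuit modulations for one MSN population.

    Returns factors for Kir2 gmax, delayed-rectifier gmax, afferent weight,
    leak, and background current, each ``1 + c*u`` clipped at 0.05.
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    uD1 = _g(activations, "D1")
    uD2 = _g(activations, "D2")
    uM1 = _g(activations, "M1")
    uM2 = _g(activations, "M2")
    uA1 = _g(activations, "alpha1")
    uH3 = _g(activations, "5-HT3")
    has_d1 = population in ("d1", "mixed")
    has_d2 = population in ("d2", "mixed")
    clip = lambda x: max(x, 0.05)
    # D1, D2 and M2 all modulate the resting K (Kir2-type) conductance: the
    # single-compartment reduction folds the different K channel types the
    # receptors target into this one stabilising conductance.
    kir = clip(1.0 + coupling.m2_gk * uM2)
    if has_d1:
        kir *= clip(1.0 + coupling.d1_kir * uD1)
    if has_d2:
        kir *= clip(1.0 + coupling.d2_gk * uD2)
    gk = 1.0
    w = clip(1.0 + coupling.d2_presyn * uD2) * clip(1.0 + coupling.m2_presyn * uM2)
    w *= clip(1.0 + coupling.a1_syn * uA1)
    if has_d1:
        w *= clip(1.0 + coupling.d1_syn * uD1)
    leak = clip(1.0 + coupling.m1_leak * uM1)
    bg = clip(1.0 + coupling.a1_bg * uA1) * clip(1.0 + coupling.ht3_bg * uH3)
    return {"kir": kir, "gk": gk, "weight": w, "leak": leak, "bg": bg}


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _gate_envelope(t: np.ndarray, gate: tuple[float, float, float]) -> np.ndarray:
    period, duty, off = gate
    if period <= 0:
        return np.ones_like(t)
    phase = np.mod(t, period) / period
    return np.where(phase < duty, 1.0, off)


def afferent_impulses(
    params: MSNParams,
    drive: AfferentDrive,
    duration: float,
    seed: int,
    cortical_factor: float = 1.0,
) -> np.ndarray:
    """Per-step synaptic conductance increments from the afferent train.

    Poisson volleys at the gated cortical rate; deterministic per seed.
    The returned array is the *unit-weight* train times ``syn_weight``;
    presynaptic modulations scale it multiplicatively afterwards.
    """
    dt_s = params.dt_ms * 1e-3
    n = int(round(duration / dt_s))
    t = np.arange(n) * dt_s
    rate = drive.cortical_rate * cortical_factor
    lam = rate * dt_s * _gate_envelope(t, drive.hippocampal_gate)
    lam *= _gate_envelope(t, drive.amygdala_gate)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return counts * (params.syn_weight * drive.presyn_attenuation)


def simulate_msn(
    params: MSNParams,
    drive: AfferentDrive,
    activations: dict[str, float] | None = None,
    coupling: CouplingParams | None = None,
    duration: float = 21.0,
    seed: int = 0,
    population: str = "d1",
    cortical_factor: float = 1.0,
    record: bool = False,
    _impulses: np.ndarray | None = None,
):
    """Spike count of one MSN over ``duration`` seconds (default 21 s).

    Deterministic given ``seed``.  With ``record=True`` returns
    ``(count, v_trace)``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    activations = activations or {}
    coupling = coupling or CouplingParams()
    fac = population_factors(activations, coupling, population)
    g_imp = (
        _impulses
        if _impulses is not None
        else afferent_impulses(params, drive, duration, seed, cortical_factor)
    )
    g_imp = g_imp * fac["weight"]
    n = len(g_imp)
    v_series = np.zeros(n if record else 1)
    tabs = _msn_tables(params.dt_ms, params.kir2_vh, params.kir2_vc)
    count = _kernels.msn_table_run(
        n, params.dt_ms, g_imp, params.i_bg * fac["bg"], params.cm,
        params.g_na, params.e_na,
        params.g_kdr * fac["gk"], params.e_k,
        params.g_leak * fac["leak"], params.e_leak,
        params.kir2_gmax * fac["kir"],
        params.tau_syn_ms, params.e_syn,
        params.v0, params.spike_threshold_mv, params.refractory_ms,
        *tabs, v_series, record,
    )
    if record:
        return int(count), v_series
    return int(count)


@lru_cache(maxsize=8)
def _msn_tables(dt_ms: float, kir_vh: float, kir_vc: float):
    return _kernels.build_msn_tables(dt_ms, kir_vh, kir_vc)


def circuit_firing(
    activations: dict[str, float] | None = None,
    coupling: CouplingParams | None = None,
    pathology: PathologyConfig | None = None,
    seed: int = 0,
    params: MSNParams | None = None,
    drive: AfferentDrive | None = None,
    weights: dict[str, float] | None = None,
    duration: float = 21.0,
) -> CircuitResult:
    """Weighted D1/D2/mixed population firing number.

    ``pathology`` (when given) attenuates the cortical rate by its
    hypofrontality factor; the dopaminergic pathology itself lives in the
    synapse configuration that produced ``activations``.
    """
    params = params or MSNParams.reference()
    drive = drive or AfferentDrive.reference()
    if weights is None:
        weights = dict(config.reference_raw()["msn"]["population_weights"])
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population weights must sum to 1, got {total}")
    cortical = pathology.cortical_drive_factor if pathology is not None else 1.0
    counts = {}
    for i, pop in enumerate(POPULATIONS):
        counts[pop] = simulate_msn(
            params, drive, activations, coupling,
            duration=duration, seed=seed + i, population=pop,
            cortical_factor=cortical,
        )
    combined = sum(weights[p] * counts[p] for p in POPULATIONS)
    return CircuitResult(counts=counts, combined=combined, weights=weights, seed=seed)


# ---------------------------------------------------------------------------
# firing -> PANSS link
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanssLink:
    """Monotone linear map from MSN firing number to PANSS-total improvement.

    Least-squares fit to the published anchor pairs; slope is constrained
    positive (monotone by construction).
    """

    slope: float
    intercept: float

    def __call__(self, firing: float) -> float:
        if firing < 0:
            raise ValueError("firing must be >= 0")
        return self.slope * firing + self.intercept

    @classmethod
    def fit(cls, firing, panss) -> "PanssLink":
        firing = np.asarray(firing, dtype=float)
        panss = np.asarray(panss, dtype=float)
        slope, intercept = np.polyfit(firing, panss, 1)
        if slope <= 0:
            raise ValueError("anchor pairs do not define a monotone link")
        return cls(slope=float(slope), intercept=float(intercept))


@lru_cache(maxsize=1)
def reference_panss_link() -> PanssLink:
    a = config.reference_raw()["panss_anchors"]
    return PanssLink.fit(a["firing"], a["panss"])


def firing_to_panss(firing: float, link: PanssLink | None = None) -> float:
    """PANSS-total improvement (points) predicted from a firing number."""
    return (link or reference_panss_link())(firing)
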