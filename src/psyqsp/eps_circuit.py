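"""Extra-pyramidal symptom (EPS) liability model.

Motor-side counterpart of the accumbens circuit: a dorsal-striatum MSN
circuit (no accumbens pathology, lower D3 autoreceptor level in its DA
synapse) provides a motor firing number, which is multiplied by a cortical
*threshold factor* derived from a 12-compartment passive pyramidal cell in
the supplementary motor area.  The threshold factor is the minimal apical
input rate whose steady depolarization reaches the soma spiking threshold,
normalized so the drug-free value equals the calibrated 0.70 anchor;
5-HT2A blockade (and 5-HT1A activation) increase apical synaptic efficacy
respectively lower membrane leak, reducing the required rate and therefore
the factor.

The product ``firing x threshold`` is mapped to the fraction of patients
requiring anticholinergic co-medication through a two-parameter logistic
solved exactly on the placebo/olanzapine calibration anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import config
from .activations import drug_activations
from .msn_circuit import CircuitResult, CouplingParams, MSNParams, AfferentDrive, circuit_firing

__all__ = [
    "PyramidalParams",
    "EPSResult",
    "pyramidal_threshold",
    "motor_msn_firing",
    "eps_score",
    "eps_to_anticholinergic_fraction",
    "reference_eps_link",
    "EpsLink",
    "ThresholdError",
]


class ThresholdError(RuntimeError):
    """Soma threshold not bracketed by the allowed apical input rates."""


@dataclass(frozen=True)
class PyramidalParams:
    """Passive 12-compartment pyramidal cable (soma = compartment 0).

    5-HT2A receptors sit on the apical compartments (synaptic-gain
    coupling ``ht2a_gain``); 5-HT1A receptors sit on all compartments
    (leak coupling ``ht1a_gain``).
    """

    n_compartments: int = 12
    apical_compartments: tuple[int, ...] = (8, 9, 10, 11)
    g_leak: float = 0.1        # mS/cm^2
    e_leak: float = -70.0      # mV
    g_axial: float = 1.0       # mS/cm^2
    e_syn: float = 0.0         # mV
    tau_syn_ms: float = 5.0
    syn_weight: float = 0.004  # mS/cm^2 per input spike
    soma_threshold_mv: float = -55.0
    ht2a_gain: float = -0.8
    ht1a_gain: float = -0.3
    rate_bounds: tuple[float, float] = (0.0, 5000.0)  # Hz

    def __post_init__(self):
        if self.n_compartments < 2:
            raise ValueError("need at least 2 compartments")
        if not self.apical_compartments:
            raise ValueError("apical compartment set must be non-empty")
        if max(self.apical_compartments) >= self.n_compartments:
            raise ValueError("apical index out of range")

    @classmethod
    def reference(cls) -> "PyramidalParams":
        p = config.reference_raw()["pyramidal"]
        return cls(
            n_compartments=p["n_compartments"],
            apical_compartments=tuple(p["apical_compartments"]),
            g_leak=p["g_leak"], e_leak=p["e_leak"], g_axial=p["g_axial"],
            e_syn=p["e_syn"], tau_syn_ms=p["tau_syn_ms"],
            syn_weight=p["syn_weight"],
            soma_threshold_mv=p["soma_threshold_mv"],
            ht2a_gain=p["ht2a_gain"], ht1a_gain=p["ht1a_gain"],
        )


@dataclass
class EPSResult:
    """EPS prediction for one drug-dose condition."""

    motor_msn_firing: float
    threshold_factor: float
    anticholinergic_fraction: float

    @property
    def eps_score(self) -> float:
        return self.motor_msn_firing * self.threshold_factor


def _soma_depolarization(
    rate: float, params: PyramidalParams, activations: dict[str, float]
) -> float:
    """Steady-state soma potential under Poisson apical drive at ``rate``.

    The mean synaptic conductance of a Poisson train is rate * weight * tau;
    the passive cable steady state is a tridiagonal linear solve.
    """
    n = params.n_compartments
    u2a = activations.get("5-HT2A", 0.0)
    u1a = activations.get("5-HT1A", 0.0)
    syn_gain = max(1.0 + params.ht2a_gain * u2a, 0.05)
    leak_gain = max(1.0 + params.ht1a_gain * u1a, 0.05)
    g_l = params.g_leak * leak_gain
    g_syn = rate * params.syn_weight * (params.tau_syn_ms * 1e-3) * syn_gain
    G = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        G[i, i] += g_l
        b[i] += g_l * params.e_leak
        if i + 1 < n:
            G[i, i] += params.g_axial
            G[i, i + 1] -= params.g_axial
            G[i + 1, i + 1] += params.g_axial
            G[i + 1, i] -= params.g_axial
        if i in params.apical_compartments:
            G[i, i] += g_syn
            b[i] += g_syn * params.e_syn
    v = np.linalg.solve(G, b)
    return float(v[0])


def threshold_rate(
    activations: dict[str, float] | None = None,
    params: PyramidalParams | None = None,
) -> float:
    """Minimal apical input rate (Hz) that depolarizes the soma to threshold."""
    params = params or PyramidalParams.reference()
    activations = activations or {}
    lo, hi = params.rate_bounds
    v_lo = _soma_depolarization(lo, params, activations)
    v_hi = _soma_depolarization(hi, params, activations)
    thr = params.soma_threshold_mv
    if not (v_lo < thr <= v_hi):
        raise ThresholdError(
            f"soma threshold {thr} mV not bracketed: V({lo})={v_lo:.2f}, "
            f"V({hi})={v_hi:.2f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _soma_depolarization(mid, params, activations) >= thr:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@lru_cache(maxsize=1)
def _reference_rate() -> float:
    """Fixed normalization rate: drug-free threshold factor = 0.70 anchor."""
    p = config.reference_raw()["pyramidal"]
    return threshold_rate({}, PyramidalParams.reference()) / p["placebo_threshold_factor"]


def pyramidal_threshold(
    activations: dict[str, float] | None = None,
    params: PyramidalParams | None = None,
) -> float:
    """Cortical threshold factor in (0, 1]: threshold rate / reference rate.

    5-HT2A blockade and 5-HT1A activation lower the factor (signals pass to
    the soma at lower input rates); the drug-free reference value is the
    calibrated 0.70.
    """
    r = threshold_rate(activations, params)
    return min(r / _reference_rate(), 1.0)


def motor_msn_firing(
    activations: dict[str, float] | None = None,
    coupling: CouplingParams | None = None,
    seed: int = 0,
    params: MSNParams | None = None,
    drive: AfferentDrive | None = None,
) -> CircuitResult:
    """Dorsal-striatum MSN circuit firing (no accumbens pathology).

    ``activations`` must be computed under the dorsal DA synapse
    (:func:`psyqsp.activations.drug_activations` with ``region='dorsal'``).
    """
    coupling = coupling if coupling is not None else CouplingParams.reference("motor")
    return circuit_firing(
        activations, coupling, pathology=None, seed=seed,
        params=params, drive=drive,
    )


def eps_score(firing: float, threshold_factor: float) -> float:
    """EPS score: motor firing number times the cortical threshold factor."""
    if firing < 0:
        raise ValueError("firing must be >= 0")
    if not (0 < threshold_factor <= 1.0):
        raise ValueError("threshold factor must be in (0, 1]")
    return firing * threshold_factor


@dataclass(frozen=True)
class EpsLink:
    """Logistic map from EPS score to anticholinergic-medication fraction."""

    s0: float      # score at 50% fraction
    width: float   # logistic width (score units)

    def __call__(self, score: float) -> float:
        if score < 0:
            raise ValueError("score must be >= 0")
        return 1.0 / (1.0 + math.exp(-(score - self.s0) / self.width))

    @classmethod
    def from_anchors(cls, s1: float, f1: float, s2: float, f2: float) -> "EpsLink":
        """Exact two-point logistic solve (monotone requires s2>s1, f2>f1)."""
        l1 = math.log(f1 / (1 - f1))
        l2 = math.log(f2 / (1 - f2))
        if l2 == l1:
            raise ValueError("anchor fractions must differ")
        width = (s2 - s1) / (l2 - l1)
        if width <= 0:
            raise ValueError("anchors do not define an increasing logistic")
        s0 = s1 - l1 * width
        return cls(s0=s0, width=width)


@lru_cache(maxsize=None)
def reference_eps_link(seed: int = 0) -> EpsLink:
    """Logistic solved on the placebo / olanzapine calibration anchors.

    The anchor scores are computed from the shipped reference model (placebo
    and the 15 mg olanzapine arm at 75% D2 engagement) using the given
    circuit seed, the anchor fractions are the published calibration values
    (16% and 23%); anchoring per seed keeps the calibrated fractions exact
    for any choice of afferent-train realization.
    """
    from .receptor_competition import invert_functional_concentration

    raw = config.reference_raw()
    anchors = raw["eps_anchors"]["fraction"]
    syn = config.reference_synapses()["DA_ventral"]
    drugs = config.reference_drugs()
    arm = next(
        a for a in raw["reference_arms"]
        if a["drug"] == "olanzapine" and a["dose_mg"] == 15
    )
    conc = invert_functional_concentration(syn, drugs["olanzapine"], arm["displacement_pct"])
    acts = drug_activations(drugs["olanzapine"], conc, region="dorsal")
    s_placebo = eps_score(
        motor_msn_firing({}, seed=seed).combined, pyramidal_threshold({})
    )
    s_olz = eps_score(
        motor_msn_firing(acts, seed=seed).combined, pyramidal_threshold(acts)
    )
    return EpsLink.from_anchors(
        s_placebo, anchors["placebo"], s_olz, anchors["olanzapine_15mg"]
    )


def eps_to_anticholinergic_fraction(
    score: float, link: EpsLink | None = None, seed: int = 0
) -> float:
    """Fraction of patients requiring anticholinergic medication, in [0, 1]."""
    return (link or reference_eps_link(seed))(score)
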