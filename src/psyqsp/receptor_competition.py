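"""Kinetic receptor-competition model of a central synapse.

Neurotransmitter (NT), drug species and a PET tracer compete by mass action
for receptor pools fed by two well-stirred NT compartments sharing one
spike-driven release process (tonic firing interrupted by scheduled bursts):

* an *extrasynaptic* compartment cleared by a saturable transporter and
  carrying the autoreceptor pool and the PET tracer's target pool --
  volume-transmission NT, whose level can surge several-fold when an
  antagonist blocks autoreceptors (release disinhibition through a
  descending sigmoid of autoreceptor activation);
* an intrasynaptic *cleft* compartment cleared first-order (diffusion
  dominated), feeding the postsynaptic activation pools, so that
  postsynaptic activation genuinely falls under receptor blockade instead
  of being refilled by the extrasynaptic surge.

The model serves two purposes:

* converting an observed PET tracer displacement (e.g. raclopride at D2)
  into the *functional* intrasynaptic drug concentration that reproduces it
  (:func:`tracer_displacement`, :func:`invert_functional_concentration`);
* computing the drug-induced change in time-averaged receptor activation
  over the firing-pattern period (:func:`time_averaged_activation`), the
  quantity the circuit models consume.

Slow-dissociating ligands equilibrate over minutes-to-hours, far longer
than the 10 s firing period, so all summary operations evaluate the
*periodic steady state* of the cycle map (found with a quasi-Newton root
solve on the state after one period) rather than a transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .pharmacology import DEFAULT_KON, DrugProfile, kinetics_from_affinity

__all__ = [
    "SynapseConfig",
    "CompetitionState",
    "CompetitionTimeSeries",
    "ActivationSummary",
    "simulate_synapse",
    "steady_state_occupancy",
    "tracer_displacement",
    "invert_functional_concentration",
    "time_averaged_activation",
    "periodic_steady_state",
    "InversionError",
    "DegenerateConfigError",
]

_kernels.warmup()


class InversionError(RuntimeError):
    """Target displacement unreachable within concentration bounds."""


class DegenerateConfigError(RuntimeError):
    """Synapse configuration yields ~zero baseline tracer binding."""


@dataclass(frozen=True)
class SynapseConfig:
    """Release/clearance/firing parameters of one transmitter system.

    ``receptor_kd`` maps postsynaptic receptor subtypes to the NT's
    equilibrium dissociation constant there (nM).  ``primary_receptor``
    names the subtype that carries the tracer and is reported by the
    single-pool operations.  The autoreceptor pool binds the NT with
    ``autoreceptor_kd`` and binds drugs with their Ki at
    ``autoreceptor_receptor``.
    """

    transmitter: str = "DA"
    tonic_rate: float = 3.0              # Hz
    burst_rate: float = 60.0             # Hz
    burst_schedule: tuple[tuple[float, float], ...] = ((9.0, 0.5),)
    period: float = 10.0                 # s; firing pattern + averaging window
    release_per_spike: float = 100.0     # nM added per spike (extrasynaptic scale)
    clearance_rate: float = 25.0         # per s (extrasynaptic; low-conc limit)
    clearance_km: float = 0.0            # transporter Km, nM; 0 = first-order
    cleft_release_scale: float = 1.0     # per-spike release scale in the cleft
    cleft_clearance_rate: float | None = None  # per s; defaults to clearance_rate
    autoreceptor_gain: float = 0.0       # release disinhibition amplitude
    autoreceptor_half: float = 0.5       # activation at half-maximal feedback
    autoreceptor_width: float = 0.05     # sigmoid width
    autoreceptor_kd: float = 200.0       # NT Kd at the autoreceptor (nM)
    autoreceptor_receptor: str | None = "D2"
    primary_receptor: str = "D2"
    receptor_kd: tuple[tuple[str, float], ...] = (("D2", 1600.0),)
    #: NT Kd used for pools placed in the cleft compartment (the
    #: activation-relevant, typically high-affinity receptor state);
    #: falls back to ``receptor_kd`` when a receptor is not listed.
    cleft_receptor_kd: tuple[tuple[str, float], ...] = ()
    receptor_density: float = 1.0
    pulsatile: bool = True
    dt: float = 1e-3                     # s
    kon_nt: float = DEFAULT_KON          # per nM per s

    def __post_init__(self):
        if isinstance(self.receptor_kd, dict):
            object.__setattr__(self, "receptor_kd", tuple(self.receptor_kd.items()))
        if isinstance(self.cleft_receptor_kd, dict):
            object.__setattr__(
                self, "cleft_receptor_kd", tuple(self.cleft_receptor_kd.items())
            )
        if isinstance(self.burst_schedule, list):
            object.__setattr__(
                self, "burst_schedule", tuple(tuple(b) for b in self.burst_schedule)
            )
        if self.clearance_rate <= 0:
            raise ValueError("clearance_rate must be positive")
        if self.burst_rate < self.tonic_rate:
            raise ValueError("burst_rate must be >= tonic_rate")
        if not (0 <= self.tonic_rate):
            raise ValueError("tonic_rate must be non-negative")

    @property
    def cleft_clearance(self) -> float:
        return (
            self.cleft_clearance_rate
            if self.cleft_clearance_rate is not None
            else self.clearance_rate
        )

    def kd_at(self, receptor: str, compartment: str = "ext") -> float:
        if compartment == "cleft":
            for r, kd in self.cleft_receptor_kd:
                if r == receptor:
                    return kd
        for r, kd in self.receptor_kd:
            if r == receptor:
                return kd
        raise KeyError(f"{self.transmitter} synapse has no {receptor} pool")

    def with_receptor(self, receptor: str) -> "SynapseConfig":
        self.kd_at(receptor)
        return replace(self, primary_receptor=receptor)


@dataclass
class CompetitionState:
    """Snapshot of the cleft at one time point."""

    time: float
    free_nt: float
    bound: dict[str, float]

    def __post_init__(self):
        if self.free_nt < -1e-12:
            raise ValueError("free NT must be non-negative")
        tot = sum(self.bound.values())
        if tot > 1.0 + 1e-9 or any(v < -1e-12 for v in self.bound.values()):
            raise ValueError("bound fractions must be >= 0 and sum <= 1")


@dataclass
class CompetitionTimeSeries:
    times: np.ndarray                    # s
    free_nt: np.ndarray                  # nM
    bound: dict[str, np.ndarray]         # ligand -> occupancy fraction (primary pool)
    pools: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def states(self) -> list[CompetitionState]:
        return [
            CompetitionState(
                time=float(t),
                free_nt=float(self.free_nt[i]),
                bound={k: float(v[i]) for k, v in self.bound.items()},
            )
            for i, t in enumerate(self.times)
        ]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times, "free_nt": self.free_nt}
        for k, v in self.bound.items():
            data[f"bound_{k}"] = v
        return pd.DataFrame(data)


@dataclass
class ActivationSummary:
    """Drug-induced change in time-averaged receptor activation."""

    receptor: str
    baseline_activation: float
    drug_activation: float
    averaging_window: float

    @property
    def delta(self) -> float:
        return self.drug_activation - self.baseline_activation


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------


@dataclass
class _Problem:
    config: SynapseConfig
    pool_names: list[str]          # postsynaptic pools, then optionally "auto"
    ligand_names: list[str]        # "NT", drug species..., optionally "tracer"
    kon: np.ndarray                # (P, L)
    koff: np.ndarray
    conc: np.ndarray               # (L,)
    act_weight_post: np.ndarray    # (L,) per-ligand activation weight (post pools)
    auto_pool: int
    act_weight_auto: np.ndarray
    release_pulses: np.ndarray
    n_steps: int
    pool_comp: np.ndarray = None   # (P,) 0 = extrasynaptic, 1 = cleft


def _spike_pulses(config: SynapseConfig) -> np.ndarray:
    """Per-step NT release amounts over one period (deterministic trains)."""
    dt = config.dt
    n = int(round(config.period / dt))
    pulses = np.zeros(n)
    if not config.pulsatile:
        pulses[:] = config.tonic_rate * config.release_per_spike * dt
        return pulses
    in_burst = np.zeros(n, dtype=np.bool_)
    t = np.arange(n) * dt
    for start, dur in config.burst_schedule:
        in_burst |= (t >= start) & (t < start + dur)
    # regular spike trains: tonic spikes outside bursts, burst-rate inside
    for rate, mask in ((config.tonic_rate, ~in_burst), (config.burst_rate, in_burst)):
        if rate <= 0:
            continue
        interval = 1.0 / rate
        next_spike = 0.0
        for i in range(n):
            if not mask[i]:
                next_spike = t[i] + dt
                continue
            if t[i] + 1e-12 >= next_spike:
                pulses[i] += config.release_per_spike
                next_spike = t[i] + interval
    return pulses


def _build(
    config: SynapseConfig,
    drug: DrugProfile | None,
    conc: float,
    tracer: tuple[float, float] | None,
    pools: list[str] | None = None,
    compartment: str = "cleft",
) -> _Problem:
    """Assemble kernel arrays for NT + drug species + optional tracer.

    ``compartment`` places the postsynaptic pools: ``"cleft"`` (intrasynaptic
    NT; activation readouts) or ``"ext"`` (extrasynaptic NT; PET tracer
    competition).  The autoreceptor pool always sees extrasynaptic NT.
    """
    pool_names = list(pools) if pools is not None else [config.primary_receptor]
    has_auto = config.autoreceptor_receptor is not None
    ligand_names = ["NT"]
    species: list[tuple[DrugProfile, float]] = []
    if drug is not None and conc > 0:
        species = drug.species()
        ligand_names += [p.name for p, _ in species]
    if tracer is not None:
        ligand_names.append("tracer")
    P = len(pool_names) + (1 if has_auto else 0)
    L = len(ligand_names)
    kon = np.zeros((P, L))
    koff = np.zeros((P, L))
    conc_arr = np.zeros(L)
    w_post = np.zeros(L)
    w_auto = np.zeros(L)
    w_post[0] = 1.0
    w_auto[0] = 1.0
    for ip, rname in enumerate(pool_names):
        kd_nt = config.kd_at(rname, compartment)
        kon[ip, 0] = config.kon_nt
        koff[ip, 0] = kd_nt * config.kon_nt
    if has_auto:
        kon[-1, 0] = config.kon_nt
        koff[-1, 0] = config.autoreceptor_kd * config.kon_nt
    il = 1
    for prof, frac in species:
        conc_arr[il] = conc * frac
        for ip, rname in enumerate(pool_names):
            ki = prof.ki(rname)
            if ki is not None:
                kin = kinetics_from_affinity(ki)
                kon[ip, il] = kin.kon
                koff[ip, il] = kin.koff
        if has_auto:
            ki = prof.ki(config.autoreceptor_receptor)
            if ki is not None:
                kin = kinetics_from_affinity(ki)
                kon[-1, il] = kin.kon
                koff[-1, il] = kin.koff
                w_auto[il] = prof.activation_weight(config.autoreceptor_receptor)
        # activation weight at the primary postsynaptic pool
        w_post[il] = prof.activation_weight(pool_names[0])
        il += 1
    if tracer is not None:
        tr_kd, tr_conc = tracer
        conc_arr[-1] = tr_conc
        kin = kinetics_from_affinity(tr_kd)
        # tracer binds the primary pool only
        kon[0, -1] = kin.kon
        koff[0, -1] = kin.koff
    pulses = _spike_pulses(config)
    pool_comp = np.zeros(P, dtype=np.int64)
    if compartment == "cleft":
        pool_comp[: len(pool_names)] = 1
    return _Problem(
        config=config,
        pool_names=pool_names + (["auto"] if has_auto else []),
        ligand_names=ligand_names,
        kon=kon,
        koff=koff,
        conc=conc_arr,
        act_weight_post=w_post,
        auto_pool=P - 1 if has_auto else -1,
        act_weight_auto=w_auto,
        release_pulses=pulses,
        n_steps=len(pulses),
        pool_comp=pool_comp,
    )


def _run_cycle(problem: _Problem, state: np.ndarray, record: bool):
    cfg = problem.config
    n = problem.n_steps
    P, L = problem.kon.shape
    c_series = np.zeros((n if record else 1, 2))
    b_series = np.zeros((n if record else 1, P, L))
    out_state, b_avg, c_avg = _kernels.synapse_cycle(
        state, n, cfg.dt, problem.release_pulses, cfg.clearance_rate, cfg.clearance_km,
        cfg.cleft_release_scale, cfg.cleft_clearance,
        problem.kon, problem.koff, problem.conc, problem.pool_comp,
        problem.auto_pool, problem.act_weight_auto,
        cfg.autoreceptor_gain, cfg.autoreceptor_half, cfg.autoreceptor_width,
        not cfg.pulsatile, record, c_series, b_series,
    )
    return out_state, b_avg, c_avg, c_series, b_series


def periodic_steady_state(problem: _Problem) -> np.ndarray:
    """State at period start such that one cycle maps it onto itself.

    Solved with a quasi-Newton root find on the cycle-map drift, restricted
    to dynamically active coordinates (pool/ligand pairs with nonzero rates;
    inert pairs are pinned at zero occupancy).
    """
    state = np.zeros(2 + problem.kon.size)
    # relax fast modes first
    for _ in range(6):
        state, *_ = _run_cycle(problem, state, False)
    active = np.concatenate(
        ([True, True], ((problem.kon > 0) | (problem.koff > 0)).ravel())
    )
    scale = np.ones(active.sum())
    scale[:2] = max(1.0, abs(state[0]), abs(state[1]))  # concentrations vs fractions

    def drift(xa):
        x = np.zeros_like(state)
        x[active] = np.clip(xa, 0.0, None)
        out, *_ = _run_cycle(problem, x, False)
        return (out - x)[active]

    # damped Newton on the cycle-map drift.  Slow ligands contract by only
    # ~1e-4 per cycle, so the finite-difference step must be far above the
    # drift magnitude (generic root finders mis-estimate the Jacobian here).
    x = state[active].copy()
    F = drift(x)
    tol = 1e-10 * scale
    for _ in range(12):
        if np.all(np.abs(F) < tol):
            break
        d = len(x)
        J = np.empty((d, d))
        for j in range(d):
            eps = 1e-5 * scale[j] + 1e-4 * abs(x[j])
            xp = x.copy()
            xp[j] += eps
            J[:, j] = (drift(xp) - F) / eps
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        accepted = False
        for damp in (1.0, 0.5, 0.25, 0.1):
            xn = np.clip(x + damp * step, 0.0, None)
            Fn = drift(xn)
            if np.linalg.norm(Fn / scale) < np.linalg.norm(F / scale):
                x, F = xn, Fn
                accepted = True
                break
        if not accepted:
            break
    if not np.all(np.abs(F) < 1e3 * tol):
        # fallback: plain relaxation (geometric convergence, slow but sure)
        for _ in range(3000):
            xn = np.clip(x + F, 0.0, None)
            Fn = drift(xn)
            x, F = xn, Fn
            if np.all(np.abs(F) < tol):
                break
    state[active] = np.clip(x, 0.0, None)
    state[~active] = 0.0
    # polish: one more cycle keeps us on the orbit
    state, *_ = _run_cycle(problem, state, False)
    return state


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_synapse(
    config: SynapseConfig,
    ligands: list[tuple],
    duration: float,
    seed: int = 0,
    initial_state: np.ndarray | None = None,
) -> CompetitionTimeSeries:
    """Integrate the cleft from rest for ``duration`` seconds.

    ``ligands`` is a list of ``(BindingKinetics, concentration_nM)`` pairs
    binding the primary receptor pool (and the autoreceptor, with the same
    kinetics, when one is configured).  The integration is fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic circuit models.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    prob = _build(config, None, 0.0, None)
    # splice generic ligands into the problem arrays
    L = 1 + len(ligands)
    P = prob.kon.shape[0]
    kon = np.zeros((P, L))
    koff = np.zeros((P, L))
    conc = np.zeros(L)
    kon[:, 0] = prob.kon[:, 0]
    koff[:, 0] = prob.koff[:, 0]
    names = ["NT"]
    for i, (kin, c) in enumerate(ligands, start=1):
        if c < 0:
            raise ValueError("ligand concentrations must be >= 0")
        kon[:, i] = kin.kon
        koff[:, i] = kin.koff
        conc[i] = c
        names.append(f"ligand_{i}")
    prob.kon, prob.koff, prob.conc = kon, koff, conc
    prob.act_weight_auto = np.zeros(L)
    prob.act_weight_auto[0] = 1.0
    prob.ligand_names = names

    n_total = int(round(duration / config.dt))
    if n_total == 0:
        z = np.zeros(0)
        return CompetitionTimeSeries(times=z, free_nt=z, bound={n: z for n in names})
    state = (
        np.zeros(2 + kon.size) if initial_state is None else initial_state.copy()
    )
    n_cycle = prob.n_steps
    chunks_c, chunks_b = [], []
    done = 0
    while done < n_total:
        take = min(n_cycle, n_total - done)
        if take < n_cycle:
            # shorten the final cycle
            prob2 = replace_problem_steps(prob, take)
            state, _, _, c_s, b_s = _run_cycle(prob2, state, True)
        else:
            state, _, _, c_s, b_s = _run_cycle(prob, state, True)
        chunks_c.append(c_s[:take])
        chunks_b.append(b_s[:take])
        done += take
    c_all = np.concatenate(chunks_c)[:, 1]  # cleft NT drives the primary pool
    b_all = np.concatenate(chunks_b)
    times = (np.arange(n_total) + 1) * config.dt
    bound = {name: b_all[:, 0, i] for i, name in enumerate(names)}
    pools = {
        pname: {name: b_all[:, ip, i] for i, name in enumerate(names)}
        for ip, pname in enumerate(prob.pool_names)
    }
    return CompetitionTimeSeries(times=times, free_nt=c_all, bound=bound, pools=pools)


def replace_problem_steps(problem: _Problem, n: int) -> _Problem:
    import copy

    p = copy.copy(problem)
    p.release_pulses = problem.release_pulses[:n]
    p.n_steps = n
    return p


def steady_state_occupancy(ligands: list[tuple[float, float]]) -> list[float]:
    """Closed-form competitive-binding occupancies.

    ``ligands`` is a list of ``(Kd_nM, conc_nM)``; returns the equilibrium
    occupancy of each ligand on a shared receptor pool:
    ``occ_i = (c_i/Kd_i) / (1 + sum_j c_j/Kd_j)``.
    """
    loads = []
    for kd, c in ligands:
        if not (kd > 0):
            raise ValueError("Kd must be positive")
        loads.append(c / kd)
    denom = 1.0 + sum(loads)
    return [x / denom for x in loads]


_TRACER_KD = 1.5    # raclopride Kd, nM
_TRACER_CONC = 0.1  # trace dose, nM

_baseline_cache: dict = {}


def _baseline_tracer_binding(config: SynapseConfig, tracer: tuple[float, float]) -> float:
    key = (config, tracer)
    if key not in _baseline_cache:
        prob = _build(config, None, 0.0, tracer, compartment="ext")
        state = periodic_steady_state(prob)
        _, b_avg, _, _, _ = _run_cycle(prob, state, False)
        _baseline_cache[key] = float(b_avg[0, -1])
    return _baseline_cache[key]


def tracer_displacement(
    config: SynapseConfig,
    drug: DrugProfile,
    conc: float,
    tracer_kd: float = _TRACER_KD,
    tracer_conc: float = _TRACER_CONC,
) -> float:
    """Percent reduction in time-averaged specific tracer binding under drug."""
    if conc < 0:
        raise ValueError("conc must be >= 0")
    tracer = (tracer_kd, tracer_conc)
    bp0 = _baseline_tracer_binding(config, tracer)
    if bp0 < 1e-12:
        raise DegenerateConfigError("baseline tracer binding is ~0")
    if conc == 0:
        return 0.0
    prob = _build(config, drug, conc, tracer, compartment="ext")
    state = periodic_steady_state(prob)
    _, b_avg, _, _, _ = _run_cycle(prob, state, False)
    bp = float(b_avg[0, -1])
    return 100.0 * (1.0 - bp / bp0)


def invert_functional_concentration(
    config: SynapseConfig,
    drug: DrugProfile,
    target_displacement: float,
    conc_bounds: tuple[float, float] = (1e-4, 1e7),
    tol_pct: float = 0.1,
) -> float:
    """Concentration (nM) whose tracer displacement matches the target.

    Bisection on log-concentration; displacement is monotone in
    concentration.  Raises :class:`InversionError` if the target lies
    outside the displacement range achievable within ``conc_bounds``.
    """
    if not (0 < target_displacement < 100):
        raise InversionError("target displacement must be in (0, 100)%")
    lo, hi = conc_bounds
    d_lo = tracer_displacement(config, drug, lo)
    d_hi = tracer_displacement(config, drug, hi)
    if not (d_lo <= target_displacement <= d_hi):
        raise InversionError(
            f"target {target_displacement}% outside achievable "
            f"[{d_lo:.2f}, {d_hi:.2f}]% for bounds {conc_bounds}"
        )
    llo, lhi = math.log(lo), math.log(hi)
    d_mid = None
    for _ in range(60):
        lmid = 0.5 * (llo + lhi)
        mid = math.exp(lmid)
        d_mid = tracer_displacement(config, drug, mid)
        if abs(d_mid - target_displacement) < tol_pct * 0.25:
            return mid
        if d_mid < target_displacement:
            llo = lmid
        else:
            lhi = lmid
    return math.exp(0.5 * (llo + lhi))


def time_averaged_activation(
    config: SynapseConfig,
    drug: DrugProfile | None,
    receptor: str,
    conc: float,
) -> ActivationSummary:
    """Time-averaged activation of ``receptor`` with and without the drug.

    Activation is the NT-bound fraction plus the efficacy-weighted
    drug-bound fraction (weight ``(1+e)/2``), averaged over the firing
    period at periodic steady state.
    """
    if conc < 0:
        raise ValueError("conc must be >= 0")
    cfg = config.with_receptor(receptor)
    base = _activation_cache_get(cfg)
    if drug is None or conc == 0:
        return ActivationSummary(
            receptor=receptor,
            baseline_activation=base,
            drug_activation=base,
            averaging_window=cfg.period,
        )
    prob = _build(cfg, drug, conc, None)
    state = periodic_steady_state(prob)
    _, b_avg, _, _, _ = _run_cycle(prob, state, False)
    act = float(np.dot(b_avg[0], prob.act_weight_post))
    return ActivationSummary(
        receptor=receptor,
        baseline_activation=base,
        drug_activation=act,
        averaging_window=cfg.period,
    )


def _activation_cache_get(cfg: SynapseConfig) -> float:
    key = ("act0", cfg)
    if key not in _baseline_cache:
        prob = _build(cfg, None, 0.0, None)
        state = periodic_steady_state(prob)
        _, b_avg, _, _, _ = _run_cycle(prob, state, False)
        _baseline_cache[key] = float(b_avg[0, 0])
    return _baseline_cache[key]
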