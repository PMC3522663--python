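"""Calibration of the ten coupling parameters against clinical outcomes.

The model is fit exactly the way the platform's reference calibration was
produced: for each drug-dose point the receptor-activation changes are
computed once (they do not depend on the couplings), the circuit model maps
couplings to a firing number per point, and the squared Pearson correlation
(r^2) between firing numbers and the patient-weighted clinical outcomes is
maximized by a coarse search of the 10-dimensional coupling space (Latin
hypercube, or a full factorial grid when few dimensions are free) followed
by steepest ascent with a finite-difference gradient and backtracking line
search.

Because r^2 is affine-invariant, the outcome *scale* (PANSS points per
spike) is recovered afterwards by ordinary least squares of outcomes on
firing numbers; its residual standard deviation feeds the normal-theory
95% prediction intervals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .activations import drug_activations
from .msn_circuit import (
    AfferentDrive,
    CouplingParams,
    MSNParams,
    PathologyConfig,
    POPULATIONS,
    afferent_impulses,
    simulate_msn,
)
from . import config

__all__ = [
    "ClinicalPoint",
    "ClinicalDataset",
    "CalibrationResult",
    "weighted_average_outcome",
    "objective_r2",
    "coarse_grid_search",
    "steepest_descent_refine",
    "sensitivity_analysis",
    "prediction_interval",
    "CircuitEvaluator",
    "calibrate",
    "load_clinical_csv",
]


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass
class ClinicalPoint:
    """One aggregated drug-dose observation."""

    drug: str
    dose: float
    concentration: float          # functional brain concentration, nM
    outcome: float                # patient-weighted average outcome
    n: int                        # total patients across arms

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class ClinicalDataset:
    """Drug-dose points on one clinical scale."""

    points: list[ClinicalPoint]
    scale: str = "PANSS-total"

    def __post_init__(self):
        seen = set()
        for p in self.points:
            key = (p.drug, p.dose)
            if key in seen:
                raise ValueError(f"duplicate drug-dose point {key}")
            seen.add(key)

    def __len__(self):
        return len(self.points)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([p.outcome for p in self.points])


def weighted_average_outcome(arms: Sequence[tuple[float, int]]) -> float:
    """Patient-count-weighted average outcome over trial arms."""
    if not arms:
        raise ValueError("no arms given")
    num = den = 0.0
    for value, n in arms:
        if n <= 0:
            raise ValueError("arm sizes must be positive")
        num += value * n
        den += n
    return num / den


def load_clinical_csv(path: str | Path, scale: str | None = None) -> ClinicalDataset:
    """Read the clinical-dataset CSV dialect.

    Columns: ``drug,dose_mg,concentration_nM,outcome,scale,n`` (multiple rows
    per drug-dose are aggregated by patient-weighted averaging).
    """
    rows: dict[tuple[str, float], list] = {}
    detected = scale
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["drug"], float(row["dose_mg"]))
            rows.setdefault(key, []).append(row)
            detected = detected or row.get("scale")
    points = []
    for (drug, dose), arms in rows.items():
        outcome = weighted_average_outcome(
            [(float(a["outcome"]), int(a["n"])) for a in arms]
        )
        points.append(
            ClinicalPoint(
                drug=drug, dose=dose,
                concentration=float(arms[0]["concentration_nM"]),
                outcome=outcome, n=sum(int(a["n"]) for a in arms),
            )
        )
    return ClinicalDataset(points=points, scale=detected or "PANSS-total")


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def objective_r2(model_outputs: Sequence[float], clinical: Sequence[float]) -> float:
    """Squared Pearson correlation (sign-blind, affine-invariant)."""
    x = np.asarray(model_outputs, dtype=float)
    y = np.asarray(clinical, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate series: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# evaluator: couplings -> model outputs per dataset point
# ---------------------------------------------------------------------------


class CircuitEvaluator:
    """Maps a coupling vector to circuit firing numbers for a dataset.

    Receptor activations (per point) and afferent spike trains (per point x
    population) are precomputed once, so each evaluation costs only the
    Hodgkin-Huxley integrations.  Deterministic per ``seed``.

    ``n_trains`` averages the spike count over several afferent-train
    realizations per point and population.  This refines the integer
    quantization of the firing readout (steps of 1/n_trains spikes), which
    is what makes near-exact recovery of the couplings from noise-free
    synthetic outcomes a well-conditioned optimization problem.
    """

    def __init__(
        self,
        dataset: ClinicalDataset,
        drugs: dict | None = None,
        region: str = "ventral",
        pathology: PathologyConfig | None = None,
        params: MSNParams | None = None,
        drive: AfferentDrive | None = None,
        seed: int = 0,
        duration: float = 21.0,
        n_trains: int = 2,
    ):
        self.dataset = dataset
        self.params = params or MSNParams.reference()
        self.drive = drive or AfferentDrive.reference()
        self.seed = seed
        self.duration = duration
        drugs = drugs or config.reference_drugs()
        if pathology is None and region == "ventral":
            pathology = PathologyConfig.reference()
        cortical = pathology.cortical_drive_factor if pathology else 1.0
        raw_weights = config.reference_raw()["msn"]["population_weights"]
        self.weights = {p: raw_weights[p] for p in POPULATIONS}
        self.activations = []
        self._trains = []
        for i, pt in enumerate(dataset.points):
            drug = drugs[pt.drug] if pt.concentration > 0 else None
            self.activations.append(
                drug_activations(drug, pt.concentration, region=region)
            )
            trains = []
            for j in range(len(POPULATIONS)):
                reps = []
                for k in range(n_trains):
                    s = (seed + 9973 * i + 31 * j + 7919 * k) % (2**31 - 1)
                    reps.append(
                        afferent_impulses(self.params, self.drive, duration, s, cortical)
                    )
                trains.append(reps)
            self._trains.append(trains)

    def __call__(
        self, coupling: CouplingParams, n_trains: int | None = None
    ) -> np.ndarray:
        out = np.empty(len(self.dataset.points))
        for i, acts in enumerate(self.activations):
            total = 0.0
            for j, pop in enumerate(POPULATIONS):
                reps = self._trains[i][j]
                if n_trains is not None:
                    reps = reps[:n_trains]
                mean_count = 0.0
                for imp in reps:
                    mean_count += simulate_msn(
                        self.params, self.drive, acts, coupling,
                        duration=self.duration, seed=0, population=pop,
                        _impulses=imp,
                    )
                total += self.weights[pop] * (mean_count / len(reps))
            out[i] = total
        return out

    def subview(self, n_trains: int):
        """Cheap consistent surrogate using only the first ``n_trains`` trains."""
        return lambda coupling: self(coupling, n_trains=n_trains)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

Bounds = dict[str, tuple[float, float]]


def _bounds_arrays(bounds: Bounds) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = list(CouplingParams.NAMES)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    return lo, hi, names


def coarse_grid_search(
    dataset: ClinicalDataset,
    evaluator: Callable[[CouplingParams], np.ndarray],
    bounds: Bounds,
    n_samples: int = 2000,
    grid_points_per_dim: int = 4,
    seed: int = 0,
) -> tuple[CouplingParams, float]:
    """Best coupling over a coarse sample of the bounded parameter space.

    A full factorial grid is used when at most 4 dimensions are free
    (nonzero bound width); otherwise a seeded Latin-hypercube sample of
    ``n_samples`` points.  Returns the best point and its r^2.
    """
    lo, hi, names = _bounds_arrays(bounds)
    if np.any(hi < lo):
        raise ValueError("invalid bounds")
    free = hi > lo
    y = dataset.outcomes
    if free.sum() <= 4:
        axes = [
            np.linspace(lo[i], hi[i], grid_points_per_dim) if free[i] else [lo[i]]
            for i in range(len(names))
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        samples = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        sampler = qmc.LatinHypercube(d=int(free.sum()), seed=seed)
        unit = sampler.random(n_samples)
        samples = np.tile(lo, (n_samples, 1))
        samples[:, free] = lo[free] + unit * (hi[free] - lo[free])
    best, best_r2 = None, -np.inf
    for x in samples:
        cp = CouplingParams.from_array(x)
        try:
            r2 = objective_r2(evaluator(cp), y)
        except ValueError:
            continue
        if r2 > best_r2:
            best, best_r2 = x.copy(), r2
    if best is None:
        raise RuntimeError("no valid grid point (degenerate evaluator output)")
    return CouplingParams.from_array(best), float(best_r2)


@dataclass
class CalibrationResult:
    """Outcome of a coupling calibration."""

    coupling: CouplingParams
    r2: float
    residual_sd: float
    scale_slope: float            # outcome units per spike (OLS)
    scale_intercept: float
    trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must be in [0, 1]")

    def predict_outcome(self, firing: float) -> float:
        return self.scale_slope * firing + self.scale_intercept


def _fit_scale(outputs: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(outputs, y, 1)
    resid = y - (slope * outputs + intercept)
    dof = max(len(y) - 2, 1)
    return float(slope), float(intercept), float(np.sqrt(np.sum(resid**2) / dof))


def steepest_descent_refine(
    start: CouplingParams,
    dataset: ClinicalDataset,
    evaluator: Callable[[CouplingParams], np.ndarray],
    bounds: Bounds,
    max_iter: int = 40,
    fd_step: float = 0.02,
    tol: float = 1e-4,
    init_step: float = 0.1,
) -> CalibrationResult:
    """Gradient ascent on r^2 with backtracking; r^2 never decreases.

    The gradient is a central finite difference with a step of ``fd_step``
    times each bound width (the firing readout is integer-quantized, so the
    step must straddle several quantization plateaus).  Terminates when an
    iteration improves r^2 by less than ``tol`` or the gradient vanishes.
    """
    lo, hi, names = _bounds_arrays(bounds)
    width = hi - lo
    free = width > 0
    y = dataset.outcomes
    x = np.clip(start.as_array(), lo, hi)
    r2 = objective_r2(evaluator(CouplingParams.from_array(x)), y)
    trace = [r2]
    converged = False
    step = init_step
    for _ in range(max_iter):
        grad = np.zeros_like(x)
        for i in np.where(free)[0]:
            h = fd_step * width[i]
            xp = x.copy(); xp[i] = min(x[i] + h, hi[i])
            xm = x.copy(); xm[i] = max(x[i] - h, lo[i])
            rp = objective_r2(evaluator(CouplingParams.from_array(xp)), y)
            rm = objective_r2(evaluator(CouplingParams.from_array(xm)), y)
            grad[i] = (rp - rm) / (xp[i] - xm[i])
        gnorm = np.linalg.norm(grad * width)
        if gnorm == 0:
            converged = True
            break
        direction = grad * width**2 / gnorm  # scale-aware ascent direction
        improved = False
        s = step
        for _ in range(8):
            xn = np.clip(x + s * direction, lo, hi)
            r2n = objective_r2(evaluator(CouplingParams.from_array(xn)), y)
            if r2n > r2:
                x, r2 = xn, r2n
                trace.append(r2)
                improved = True
                step = min(s * 2.0, 1.0)
                break
            s *= 0.5
        if not improved:
            converged = True
            break
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    outputs = evaluator(CouplingParams.from_array(x))
    slope, intercept, sd = _fit_scale(outputs, y)
    return CalibrationResult(
        coupling=CouplingParams.from_array(x), r2=float(r2),
        residual_sd=sd, scale_slope=slope, scale_intercept=intercept,
        trace=trace, converged=converged,
    )


def _centered(y: np.ndarray) -> np.ndarray:
    return y - y.mean()


def gauss_newton_refine(
    start: np.ndarray,
    y: np.ndarray,
    ev_call: Callable[[CouplingParams], np.ndarray],
    lo: np.ndarray,
    hi: np.ndarray,
    probe_schedule: Sequence[float],
    noise_tol: float = 3e-5,
) -> tuple[np.ndarray, float]:
    """Scale-separable Gauss-Newton ascent of r^2.

    Each iteration linearizes the firing vector with central differences
    (probe = fraction of bound width) and solves the least-squares problem
    ``min |f + J d - gamma*(y - ybar)|`` jointly over the coupling step
    ``d`` and the free outcome scale ``gamma`` -- equivalent to maximizing
    the correlation on the linearized model.  Steps that reduce r^2 by less
    than ``noise_tol`` are still accepted (the integer-count staircase
    superimposes noise of that order on the smooth objective); the best
    point ever seen is returned.
    """
    width = hi - lo
    yt = _centered(y)
    x = start.copy()
    fx = ev_call(CouplingParams.from_array(x))
    r2 = objective_r2(fx, y)
    best = (r2, x.copy())
    n = len(y)
    for probe in probe_schedule:
        J = np.empty((n, len(x)))
        for j in range(len(x)):
            h = probe * width[j]
            xp = x.copy()
            xp[j] = min(x[j] + h, hi[j])
            xm = x.copy()
            xm[j] = max(x[j] - h, lo[j])
            J[:, j] = (ev_call(CouplingParams.from_array(xp))
                       - ev_call(CouplingParams.from_array(xm))) / (xp[j] - xm[j])
        A = np.column_stack([J - J.mean(axis=0), -yt])
        sol, *_ = np.linalg.lstsq(A, -_centered(fx), rcond=None)
        d = sol[: len(x)]
        tol = max(noise_tol, 0.02 * (1.0 - r2))
        stepped = False
        for s in (1.0, 0.5, 0.25, 0.1, 0.05):
            xn = np.clip(x + s * d, lo, hi)
            fn = ev_call(CouplingParams.from_array(xn))
            r2n = objective_r2(fn, y)
            if r2n > best[0]:
                best = (r2n, xn.copy())
            if r2n > r2 - tol:
                x, fx, r2 = xn, fn, r2n
                stepped = True
                break
        if not stepped:
            break
    return best[1], best[0]


def valley_polish(
    x: np.ndarray,
    y: np.ndarray,
    ev_call: Callable[[CouplingParams], np.ndarray],
    lo: np.ndarray,
    hi: np.ndarray,
    n_directions: int = 3,
    span: float = 0.06,
    probe: float = 0.03,
) -> tuple[np.ndarray, float]:
    """Line searches along the flattest curvature directions.

    Near-degenerate coupling pairs (two channels of the same receptor)
    create long shallow valleys; the smallest-eigenvalue directions of the
    scaled Gauss-Newton normal matrix track the valley floor.
    """
    width = hi - lo
    n = len(y)
    fx = ev_call(CouplingParams.from_array(x))
    r2 = objective_r2(fx, y)
    J = np.empty((n, len(x)))
    for j in range(len(x)):
        h = probe * width[j]
        xp = x.copy()
        xp[j] = min(x[j] + h, hi[j])
        xm = x.copy()
        xm[j] = max(x[j] - h, lo[j])
        J[:, j] = (ev_call(CouplingParams.from_array(xp))
                   - ev_call(CouplingParams.from_array(xm))) / (xp[j] - xm[j])
    Js = (J - J.mean(axis=0)) * width
    _, V = np.linalg.eigh(Js.T @ Js)
    for idx in range(n_directions):
        v = V[:, idx] * width
        grid = np.linspace(-span, span, 13)
        best_t, best_r2 = 0.0, r2
        for t in grid:
            if t == 0:
                continue
            r2n = objective_r2(ev_call(CouplingParams.from_array(np.clip(x + t * v, lo, hi))), y)
            if r2n > best_r2:
                best_t, best_r2 = t, r2n
        if best_t != 0.0:
            for t in np.linspace(best_t - span / 12, best_t + span / 12, 5):
                r2n = objective_r2(ev_call(CouplingParams.from_array(np.clip(x + t * v, lo, hi))), y)
                if r2n > best_r2:
                    best_t, best_r2 = t, r2n
            x = np.clip(x + best_t * v, lo, hi)
            r2 = best_r2
    return x, r2


def calibrate(
    dataset: ClinicalDataset,
    evaluator: CircuitEvaluator | None = None,
    bounds: Bounds | None = None,
    seed: int = 0,
    probe_schedule: Sequence[float] = (0.10,) * 3 + (0.05,) * 8 + (0.02,) * 5,
    valley_rounds: int = 1,
    use_grid_fallback: bool = True,
    n_grid: int = 32,
) -> CalibrationResult:
    """Full coupling calibration.

    Correlation-maximizing Gauss-Newton ascent from the zero-coupling start
    (coarse-to-fine probe schedule), followed by valley polish along the
    flattest curvature directions (which resolves the near-degenerate
    same-receptor coupling pairs).  If the zero start fails badly, a small
    Latin-hypercube screen supplies an alternative start.  The returned
    result carries the OLS outcome scale and residual sd.
    """
    evaluator = evaluator or CircuitEvaluator(dataset, seed=seed)
    bounds = bounds or CouplingParams.reference_bounds()
    lo, hi, names = _bounds_arrays(bounds)
    y = dataset.outcomes
    x, r2 = gauss_newton_refine(
        np.zeros(len(names)), y, evaluator, lo, hi, probe_schedule
    )
    if use_grid_fallback and r2 < 0.8:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        samples = lo + sampler.random(n_grid) * (hi - lo)
        scored = [
            (objective_r2(evaluator(CouplingParams.from_array(p)), y), p)
            for p in samples
        ]
        r2g, xg = max(scored, key=lambda t: t[0])
        xg2, r2g2 = gauss_newton_refine(xg, y, evaluator, lo, hi, probe_schedule)
        if r2g2 > r2:
            x, r2 = xg2, r2g2
    for _ in range(valley_rounds):
        xn, r2n = valley_polish(x, y, evaluator, lo, hi, span=0.06)
        if r2n <= r2 + 2e-6:   # ignore sub-noise movements
            if r2n > r2:
                x, r2 = xn, r2n
            break
        x, r2 = xn, r2n
    outputs = evaluator(CouplingParams.from_array(x))
    r2 = objective_r2(outputs, y)
    slope, intercept, sd = _fit_scale(outputs, y)
    return CalibrationResult(
        coupling=CouplingParams.from_array(x), r2=float(r2),
        residual_sd=sd, scale_slope=slope, scale_intercept=intercept,
        trace=[float(r2)], converged=True,
    )


# ---------------------------------------------------------------------------
# sensitivity / intervals
# ---------------------------------------------------------------------------


def sensitivity_analysis(
    coupling: CouplingParams,
    evaluator: Callable[[CouplingParams], np.ndarray],
    outcome_link: Callable[[float], float] | None = None,
    perturbation: float = 0.20,
) -> dict[str, dict[str, float]]:
    """Per-parameter output change under a +/- ``perturbation`` fraction.

    For each coupling parameter, all drug-dose predictions are re-evaluated
    with the parameter scaled by (1 +/- perturbation); reported are the
    min / max / mean change of the (optionally outcome-linked) predictions
    for each direction, plus an influence score (mean absolute change),
    sorted descending.
    """
    from .msn_circuit import firing_to_panss

    link = outcome_link or firing_to_panss
    base = np.array([link(v) for v in evaluator(coupling)])
    out = {}
    x0 = coupling.as_array()
    for i, name in enumerate(CouplingParams.NAMES):
        entry = {}
        for sign, key in ((1, "up"), (-1, "down")):
            x = x0.copy()
            x[i] = x0[i] * (1 + sign * perturbation)
            pred = np.array([link(v) for v in evaluator(CouplingParams.from_array(x))])
            d = pred - base
            entry[f"{key}_min"] = float(d.min())
            entry[f"{key}_max"] = float(d.max())
            entry[f"{key}_mean"] = float(d.mean())
        entry["influence"] = 0.5 * (
            abs(entry["up_mean"]) + abs(entry["down_mean"])
        )
        out[name] = entry
    return dict(sorted(out.items(), key=lambda kv: -kv[1]["influence"]))


def prediction_interval(
    result: CalibrationResult, prediction: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-theory prediction interval around a point prediction."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    half = z * result.residual_sd
    return (prediction - half, prediction + half)
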