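"""Multivariate occupancy-regression comparator.

The simple alternative to the mechanistic circuit model: regress clinical
outcomes linearly on per-receptor Hill occupancies.  Occupancies at
receptors without direct displacement data use the affinity-ratio
approximation ``Ki_x = K_D2 * Aff_x / Aff_D2`` anchored on the drug's D2
half-displacement dose.  Because the regression assumes independent, linear
receptor contributions, it under-fits outcomes produced by interacting
non-linear circuit physiology -- which is exactly the comparison the
mechanistic model is meant to win.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .pharmacology import DrugProfile, approximate_ki, occupancy

__all__ = [
    "DEFAULT_FEATURE_RECEPTORS",
    "OccupancyFeatures",
    "BaselineModel",
    "occupancy_features",
    "fit_baseline",
    "predict_baseline",
]

#: Receptor subset with known subcortical physiology (feature columns).
DEFAULT_FEATURE_RECEPTORS = (
    "D1", "D2", "5-HT2A", "5-HT2C", "5-HT3", "M1", "M2", "alpha1", "alpha2",
)


@dataclass
class OccupancyFeatures:
    """Drug-dose x receptor occupancy design matrix (entries in [0, 1])."""

    matrix: np.ndarray
    receptors: tuple[str, ...]
    index: list[tuple[str, float]]          # (drug name, dose)

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[1] != len(self.receptors):
            raise ValueError("matrix shape does not match receptor list")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")


def _profile_occupancy(drug: DrugProfile, dose: float, k_d2: float, receptor: str) -> float:
    """Mixture-aware approximate occupancy at one receptor."""
    total = 0.0
    for prof, frac in drug.species():
        aff_x = prof.ki(receptor)
        aff_d2 = prof.ki("D2")
        if aff_x is None or aff_d2 is None:
            continue
        ki_x = approximate_ki(k_d2, aff_x, aff_d2)
        total += frac * occupancy(dose, ki_x)
    return total


def occupancy_features(
    drugs: list[tuple[DrugProfile, float, float]],
    receptors: tuple[str, ...] = DEFAULT_FEATURE_RECEPTORS,
) -> OccupancyFeatures:
    """Build the occupancy design matrix.

    ``drugs`` is a list of ``(profile, dose, k_d2)`` where ``k_d2`` is the
    dose (same units as ``dose``) at which the drug displaces half the D2
    tracer.  Receptors the drug does not bind contribute 0.
    """
    rows = []
    index = []
    for drug, dose, k_d2 in drugs:
        if k_d2 is None or not (k_d2 > 0):
            raise ValueError(f"{drug.name}: k_d2 required and positive")
        if dose < 0:
            raise ValueError(f"{drug.name}: negative dose")
        rows.append([_profile_occupancy(drug, dose, k_d2, r) for r in receptors])
        index.append((drug.name, dose))
    return OccupancyFeatures(
        matrix=np.asarray(rows, dtype=float), receptors=tuple(receptors), index=index
    )


@dataclass
class BaselineModel:
    """Fitted linear occupancy-regression model."""

    params: np.ndarray                       # intercept first
    receptors: tuple[str, ...]
    r2: float
    results: object = None                   # statsmodels results (optional)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.receptors, self.params[1:]))


def fit_baseline(
    features: OccupancyFeatures,
    outcomes,
    ridge: float = 0.0,
) -> BaselineModel:
    """Ordinary least squares of outcomes on occupancies (in-sample r^2).

    ``ridge > 0`` switches to L2-regularized least squares for
    rank-deficient designs.
    """
    y = np.asarray(outcomes, dtype=float)
    X = sm.add_constant(features.matrix, has_constant="add")
    n, k = X.shape
    if n < k + 1:
        warnings.warn(
            f"only {n} rows for {k} parameters; fit is ill-determined",
            stacklevel=2,
        )
    if ridge > 0:
        model = sm.OLS(y, X)
        res = model.fit_regularized(alpha=ridge, L1_wt=0.0)
        params = np.asarray(res.params)
        fitted = X @ params
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        return BaselineModel(params=params, receptors=features.receptors, r2=r2)
    if np.linalg.matrix_rank(X) < k:
        warnings.warn("rank-deficient design; using pseudo-inverse", stacklevel=2)
    res = sm.OLS(y, X).fit()
    return BaselineModel(
        params=np.asarray(res.params), receptors=features.receptors,
        r2=float(res.rsquared), results=res,
    )


def predict_baseline(model: BaselineModel, features: OccupancyFeatures) -> np.ndarray:
    """Linear predictions for new drug-dose rows."""
    if features.receptors != model.receptors:
        raise ValueError(
            f"feature columns {features.receptors} do not match "
            f"training columns {model.receptors}"
        )
    X = sm.add_constant(features.matrix, has_constant="add")
    return X @ model.params
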