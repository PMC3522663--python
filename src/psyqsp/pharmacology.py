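"""Drug receptor pharmacology: profiles, occupancy, and binding kinetics.

Receptor affinities are equilibrium inhibition constants (Ki, nM) against a
fixed registry of CNS targets (dopamine, serotonin, acetylcholine,
norepinephrine, histamine, GABA and channel targets).  A drug's *active
moiety* may be a mixture of parent and metabolite(s), each with its own
profile; mixture fractions are molar fractions of the total functional
concentration.

Binding kinetics are derived from affinity under a shared, diffusion-limited
association rate: ``koff = Ki * kon``.  Affinity differences therefore appear
purely as dissociation-rate differences, which is the minimal kinetic scheme
that distinguishes fast-dissociating low-affinity D2 antagonists from
slow-dissociating high-affinity ones.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DEFAULT_RECEPTORS",
    "ReceptorRegistry",
    "registry",
    "DrugProfile",
    "BindingKinetics",
    "occupancy",
    "approximate_ki",
    "kinetics_from_affinity",
    "moiety_concentrations",
    "load_drug_table",
    "mixture",
    "DEFAULT_KON",
]

#: Shared association rate constant, per nM per second (1e7 M^-1 s^-1,
#: a typical near-diffusion-limited value for small-molecule CNS ligands).
DEFAULT_KON = 1e-2

#: Canonical receptor labels.  5-HT1C is retained as a historical label
#: distinct from 5-HT2C because legacy rodent binding tables report both.
DEFAULT_RECEPTORS = (
    "D1", "D2", "D3",
    "5-HT1A", "5-HT1B", "5-HT1C", "5-HT1D",
    "5-HT2A", "5-HT2C", "5-HT3", "5-HT6",
    "alpha1", "alpha2",
    "M1", "M2",
    "beta1", "beta2",
    "H1", "H2",
    "Ca-channel", "GABA",
)

_ALIASES = {
    "5HT1A": "5-HT1A", "5HT1B": "5-HT1B", "5HT1C": "5-HT1C",
    "5HT1D": "5-HT1D", "5HT2A": "5-HT2A", "5HT2C": "5-HT2C",
    "5HT3": "5-HT3", "5HT6": "5-HT6",
    "A1": "alpha1", "A2": "alpha2",
    "ALPHA-1": "alpha1", "ALPHA-2": "alpha2",
    "CA": "Ca-channel", "CA-CHANNEL": "Ca-channel",
    "M1 MACHR": "M1", "M2 MACHR": "M2",
    "B1": "beta1", "B2": "beta2",
}


class ReceptorRegistry:
    """Mutable registry of known receptor labels.

    The shipped default contains the targets of the reference binding table;
    additional targets (e.g. glutamate receptor subtypes) can be registered
    to extend the model.
    """

    def __init__(self, names=DEFAULT_RECEPTORS):
        self._names: dict[str, str] = {}
        for n in names:
            self.register(n)

    def register(self, name: str) -> str:
        canon = name.strip()
        self._names[canon.upper()] = canon
        return canon

    def resolve(self, name: str) -> str:
        """Return the canonical label for ``name`` or raise ``KeyError``."""
        key = name.strip().upper()
        key = _ALIASES.get(key, key)
        key = key.upper()
        if key not in self._names:
            raise KeyError(f"unknown receptor label: {name!r}")
        return self._names[key]

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except KeyError:
            return False

    def __iter__(self):
        return iter(self._names.values())

    def __len__(self):
        return len(self._names)


#: Process-wide default registry.
registry = ReceptorRegistry()


@dataclass(frozen=True)
class BindingKinetics:
    """Association/dissociation rate pair; ``kd`` must equal koff/kon."""

    kon: float  # per nM per s
    koff: float  # per s

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass
class DrugProfile:
    """Receptor binding profile of one molecular species or moiety mixture.

    Parameters
    ----------
    name
        Drug label.
    affinities
        Map receptor -> Ki in nM.  A receptor absent from the map is treated
        as unaffected by the drug (the convention used for ">10000" / "N/A"
        entries in binding tables).
    efficacy
        Map receptor -> intrinsic activity in [-1, +1]; -1 is a neutral full
        antagonist (the default for any receptor not listed), +1 a full
        agonist.  The activation weight applied to the drug-bound fraction is
        ``(1 + e) / 2`` so a full antagonist contributes no activation.
    components
        For active-moiety mixtures: list of ``(DrugProfile, fraction)`` with
        fractions summing to 1.  A plain drug has no components.
    """

    name: str
    affinities: dict[str, float] = field(default_factory=dict)
    efficacy: dict[str, float] = field(default_factory=dict)
    components: list[tuple["DrugProfile", float]] = field(default_factory=list)

    def __post_init__(self):
        reg = registry
        self.affinities = {reg.resolve(r): float(k) for r, k in self.affinities.items()}
        for r, k in self.affinities.items():
            if not (k > 0):
                raise ValueError(f"{self.name}: non-positive Ki for {r}: {k}")
        self.efficacy = {reg.resolve(r): float(e) for r, e in self.efficacy.items()}
        for r, e in self.efficacy.items():
            if not (-1.0 <= e <= 1.0):
                raise ValueError(f"{self.name}: efficacy out of [-1, 1] for {r}: {e}")
        if self.components:
            total = sum(f for _, f in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: mixture fractions sum to {total}, not 1")

    # -- queries ---------------------------------------------------------

    def ki(self, receptor: str) -> float | None:
        """Ki (nM) at ``receptor`` or None if the drug does not bind it."""
        return self.affinities.get(registry.resolve(receptor))

    def binds(self, receptor: str) -> bool:
        return self.ki(receptor) is not None

    def efficacy_at(self, receptor: str) -> float:
        return self.efficacy.get(registry.resolve(receptor), -1.0)

    def activation_weight(self, receptor: str) -> float:
        """Fraction of the drug-bound pool that counts as activated."""
        return (1.0 + self.efficacy_at(receptor)) / 2.0

    @property
    def is_mixture(self) -> bool:
        return bool(self.components)

    def species(self) -> list[tuple["DrugProfile", float]]:
        """Molecular species and molar fractions (identity for plain drugs)."""
        return list(self.components) if self.components else [(self, 1.0)]


def occupancy(dose: float, ki: float) -> float:
    """Hill (Langmuir) receptor occupancy, ``dose / (dose + ki)``.

    ``dose`` and ``ki`` must share units (nM concentration, or mg dose with a
    Ki expressed as the dose giving 50% occupancy).
    """
    if dose < 0:
        raise ValueError(f"negative dose: {dose}")
    if not (ki > 0):
        raise ValueError(f"Ki must be positive: {ki}")
    return dose / (dose + ki)


def approximate_ki(k_d2: float, aff_x: float, aff_d2: float) -> float:
    """Scale a drug's in-vivo D2 potency to another receptor by affinity ratio.

    ``k_d2`` is the dose (or concentration) at which half the D2 receptors
    are occupied (50% tracer displacement); the returned value is the
    corresponding half-occupancy dose at receptor X, ``k_d2 * aff_x / aff_d2``.
    """
    if not (k_d2 > 0 and aff_x > 0 and aff_d2 > 0):
        raise ValueError("k_d2 and affinities must be positive")
    return k_d2 * aff_x / aff_d2


def kinetics_from_affinity(ki: float, kon_ref: float = DEFAULT_KON) -> BindingKinetics:
    """Derive mass-action rates from affinity under a shared kon."""
    if not (ki > 0 and kon_ref > 0):
        raise ValueError("ki and kon_ref must be positive")
    return BindingKinetics(kon=kon_ref, koff=ki * kon_ref)


def moiety_concentrations(profile: DrugProfile, total_conc: float) -> dict[str, float]:
    """Split a total active-moiety concentration over molecular species."""
    if total_conc < 0:
        raise ValueError(f"negative concentration: {total_conc}")
    return {p.name: total_conc * f for p, f in profile.species()}


def mixture(name: str, parts: list[tuple[DrugProfile, float]]) -> DrugProfile:
    """Build an active-moiety mixture profile (e.g. parent + metabolite)."""
    return DrugProfile(name=name, components=parts)


_MISSING = {">10000", "N/A", "NA", ""}


def load_drug_table(
    path: str | Path,
    *,
    censored_ki: float | None = None,
) -> list[DrugProfile]:
    """Read a binding-table CSV into drug profiles.

    Expected columns: ``drug,receptor,ki_nM[,efficacy]``.  Cells reading
    ``>10000`` or ``N/A`` mean the table reports no measurable binding; by
    default such receptors are simply absent from the profile.  Passing
    ``censored_ki=10000`` instead assigns the censoring bound as the Ki
    (useful for sensitivity checks).
    """
    path = Path(path)
    drugs: dict[str, DrugProfile] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            if not row.get("drug"):
                continue
            name = row["drug"].strip()
            prof = drugs.setdefault(name, DrugProfile(name=name))
            receptor = registry.resolve(row["receptor"])
            cell = (row.get("ki_nM") or "").strip()
            if cell.upper() in {c.upper() for c in _MISSING} or cell.startswith(">"):
                if censored_ki is not None:
                    prof.affinities[receptor] = float(censored_ki)
                continue
            ki = float(cell)
            if not (ki > 0):
                raise ValueError(f"{name}/{receptor}: non-positive Ki {ki}")
            prof.affinities[receptor] = ki
            eff = (row.get("efficacy") or "").strip()
            if eff:
                e = float(eff)
                if not (-1.0 <= e <= 1.0):
                    raise ValueError(f"{name}/{receptor}: efficacy {e} out of range")
                prof.efficacy[receptor] = e
    return list(drugs.values())


def _is_close(a: float, b: float, rel: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=rel)
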