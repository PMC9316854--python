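"""Pharmacokinetic unit conversions and dosing protocols.

Chlorambucil enters the model as a molecule count: a dose in mg is
multiplied by ``sigma = Avogadro / molecular weight`` ~ 1.9796e18
molecules/mg.  Its blood concentration (mg/L over the 5 L blood volume)
drives the cytotoxicity law, and its 0.0625-day half-life gives the
first-order decay rate ``mu_C = ln2 / t_half ~ 11.090/day``.

Protocols are sequences of timed impulse doses of CAR-T cells and/or
chlorambucil.  The module ships the seven published in-silico scenarios as
presets (``build_preset``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .cytotoxicity import CHLORAMBUCIL_MOLECULAR_WEIGHT
from .model import SystemState

__all__ = [
    "AVOGADRO",
    "SIGMA_MOLECULES_PER_MG",
    "CHLORAMBUCIL_HALF_LIFE_DAYS",
    "CART_CHEMO_SENSITIVITY",
    "DrugConstants",
    "DoseEvent",
    "Protocol",
    "PRESET_NAMES",
    "mg_to_molecules",
    "molecules_to_mg",
    "blood_concentration",
    "half_life_to_decay_rate",
    "weight_based_dose",
    "build_preset",
]

AVOGADRO = 6.02214076e23  # molecules/mol
#: Molecules per mg of chlorambucil (Avogadro / molecular weight in mg/mol).
SIGMA_MOLECULES_PER_MG = AVOGADRO / (CHLORAMBUCIL_MOLECULAR_WEIGHT * 1e3)
CHLORAMBUCIL_HALF_LIFE_DAYS = 0.0625
#: Chemotherapy cytotoxicity on CAR-T cells as a fraction of that on cancer cells.
CART_CHEMO_SENSITIVITY = 0.054


@dataclass(frozen=True)
class DrugConstants:
    """Physical constants of the chemotherapy drug."""

    avogadro: float = AVOGADRO
    molecular_weight_mg_per_mol: float = CHLORAMBUCIL_MOLECULAR_WEIGHT * 1e3
    half_life_days: float = CHLORAMBUCIL_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half_life must be positive")

    @property
    def sigma(self) -> float:
        """Molecules per mg."""
        return self.avogadro / self.molecular_weight_mg_per_mol

    @property
    def decay_rate(self) -> float:
        """First-order decay rate mu_C (day^-1)."""
        return half_life_to_decay_rate(self.half_life_days)


def mg_to_molecules(dose_mg: float) -> float:
    """Number of drug molecules in a dose of ``dose_mg`` milligrams."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg * SIGMA_MOLECULES_PER_MG


def molecules_to_mg(molecules: float) -> float:
    if molecules < 0:
        raise ValueError("molecule count must be non-negative")
    return molecules / SIGMA_MOLECULES_PER_MG


def blood_concentration(dose_mg: float, blood_volume_L: float = 5.0) -> float:
    """Blood concentration (mg/L) of a dose distributed over the blood volume."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if blood_volume_L <= 0:
        raise ValueError("blood volume must be positive")
    return dose_mg / blood_volume_L


def half_life_to_decay_rate(t_half_days: float) -> float:
    """First-order decay rate (day^-1) from a biological half-life (days)."""
    if t_half_days <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / t_half_days


def weight_based_dose(weight_kg: float, dose_per_kg: float) -> float:
    """Total dose (mg) for a patient of ``weight_kg`` at ``dose_per_kg`` mg/kg."""
    if weight_kg < 0 or dose_per_kg < 0:
        raise ValueError("weight and per-kg dose must be non-negative")
    return weight_kg * dose_per_kg


@dataclass(frozen=True)
class DoseEvent:
    """One timed dose, delivered as a constant-rate pulse.

    ``agent`` is ``"car_t"`` (amount in cells) or ``"chlorambucil"``
    (amount in mg).  ``resolved_amount`` is the total state increment
    actually delivered: cells for CAR-T, molecules for the drug.
    ``duration`` (days) is the pulse width; the infusion rate is
    ``resolved_amount / duration``, and a duration of 0 requests an
    instantaneous impulse instead.  A CAR-T dose at day 0 is applied
    through the initial condition (protocol convention).
    """

    time: float
    agent: str
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration < 0:
            raise ValueError("dose duration must be non-negative")
        if self.agent not in ("car_t", "chlorambucil"):
            raise ValueError(f"unknown agent {self.agent!r}")

    @property
    def resolved_amount(self) -> float:
        if self.agent == "chlorambucil":
            return mg_to_molecules(self.amount)
        return self.amount

    def to_dict(self) -> dict:
        unit = "mg" if self.agent == "chlorambucil" else "cells"
        return {"day": self.time, "agent": self.agent, "amount": self.amount,
                "unit": unit, "duration": self.duration}


@dataclass
class Protocol:
    """A named treatment schedule with initial conditions and overrides.

    Doses at day 0 are applied through the initial condition by the
    simulator; later doses are impulses.  ``overrides`` are model-parameter
    overrides applied on top of the defaults for the run.
    """

    name: str
    doses: list[DoseEvent] = field(default_factory=list)
    initial_state: SystemState = field(default_factory=lambda: SystemState(A=1e10, Ad=5e8))
    overrides: dict = field(default_factory=dict)
    horizon: float = 100.0

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.time)
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def total(self, agent: str) -> float:
        """Total amount scheduled for ``agent`` (cells or mg)."""
        return sum(d.amount for d in self.doses if d.agent == agent)

    @property
    def total_cart_cells(self) -> float:
        return self.total("car_t")

    @property
    def total_chlorambucil_mg(self) -> float:
        return self.total("chlorambucil")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        s = self.initial_state
        return {
            "name": self.name,
            "doses": [d.to_dict() for d in self.doses],
            "initial_conditions": {"A": s.A, "Ad": s.Ad, "C": s.C, "T": s.T},
            "overrides": dict(self.overrides),
            "horizon_days": self.horizon,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Protocol":
        ic = doc.get("initial_conditions", {})
        doses = [
            DoseEvent(time=d["day"], agent=d["agent"], amount=d["amount"],
                      duration=d.get("duration", 1.0))
            for d in doc.get("doses", [])
        ]
        return cls(
            name=doc["name"],
            doses=doses,
            initial_state=SystemState(
                A=ic.get("A", 0.0), Ad=ic.get("Ad", 0.0),
                C=ic.get("C", 0.0), T=ic.get("T", 0.0),
            ),
            overrides=dict(doc.get("overrides", {})),
            horizon=doc.get("horizon_days", 100.0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Published scenario presets
# ---------------------------------------------------------------------------

# Shared figure-level parameterization: growth at 10% of the in-vitro rate,
# CAR-T exhaustion at 1/14 per day, efficacy from the fitted law.
_FIG_OVERRIDES = {"rho_A": 0.1680, "mu_T": 1.0 / 14.0, "alpha_T": 1.2560e-7,
                  "rho_T": 2.9409e-13}

_WEEKLY_DOSE = 202_079_012.0
_FORTNIGHT_DOSE = 245_633_284.0

PRESET_NAMES = (
    "no_treatment",
    "cart_depletion",
    "cart_persistence",
    "weekly_cart",
    "fortnight_cart",
    "constant_chemoimmuno",
    "increasing_chemoimmuno",
)


def build_preset(name: str) -> Protocol:
    """Return one of the seven published in-silico scenarios.

    All start from 1e10 live leukemia cells with 5% of that as dead cells.
    ``cart_depletion`` / ``cart_persistence`` differ only in the CAR-T
    mitosis rate, which straddles the depletion/persistence threshold
    ``mu_A*mu_T/mu_d``.
    """
    ic = SystemState(A=1e10, Ad=0.05 * 1e10)
    if name == "no_treatment":
        return Protocol(name=name, doses=[], initial_state=ic,
                        overrides=dict(_FIG_OVERRIDES), horizon=500.0)
    if name == "cart_depletion":
        ov = dict(_FIG_OVERRIDES, rho_T=2.5714e-13)
        return Protocol(name=name, doses=[DoseEvent(0.0, "car_t", 2.4e8)],
                        initial_state=ic, overrides=ov, horizon=500.0)
    if name == "cart_persistence":
        return Protocol(name=name, doses=[DoseEvent(0.0, "car_t", 2.4e8)],
                        initial_state=ic, overrides=dict(_FIG_OVERRIDES), horizon=500.0)
    if name == "weekly_cart":
        doses = [DoseEvent(t, "car_t", _WEEKLY_DOSE) for t in (0.0, 7.0, 14.0, 21.0)]
        return Protocol(name=name, doses=doses, initial_state=ic,
                        overrides=dict(_FIG_OVERRIDES), horizon=250.0)
    if name == "fortnight_cart":
        doses = [DoseEvent(t, "car_t", _FORTNIGHT_DOSE) for t in (0.0, 14.0, 28.0, 42.0)]
        return Protocol(name=name, doses=doses, initial_state=ic,
                        overrides=dict(_FIG_OVERRIDES), horizon=250.0)
    if name == "constant_chemoimmuno":
        doses = [DoseEvent(t, "car_t", _FORTNIGHT_DOSE) for t in (0.0, 14.0, 28.0)]
        doses += [DoseEvent(t, "chlorambucil", 56.0)
                  for t in (6.0, 10.0, 20.0, 24.0, 34.0, 38.0)]
        return Protocol(name=name, doses=doses, initial_state=ic,
                        overrides=dict(_FIG_OVERRIDES), horizon=60.0)
    if name == "increasing_chemoimmuno":
        doses = [DoseEvent(t, "car_t", _FORTNIGHT_DOSE) for t in (0.0, 14.0, 28.0)]
        schedule = [(6.0, 40.0), (10.0, 48.0), (20.0, 48.0),
                    (24.0, 56.0), (34.0, 56.0), (38.0, 64.0)]
        doses += [DoseEvent(t, "chlorambucil", mg) for t, mg in schedule]
        return Protocol(name=name, doses=doses, initial_state=ic,
                        overrides=dict(_FIG_OVERRIDES), horizon=60.0)
    raise KeyError(
        f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
    )
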