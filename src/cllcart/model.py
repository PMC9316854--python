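"""Core state/parameter types and vector fields of the leukemia chemoimmunotherapy model.

The model tracks four coupled populations in the blood circulatory system of
an adult patient (assumed 5 L of blood):

* ``A``  -- live chronic lymphocytic leukemia (CLL) cells,
* ``Ad`` -- dead leukemia cells awaiting dissolution,
* ``C``  -- molecules of the chemotherapy drug chlorambucil,
* ``T``  -- chimeric antigen receptor (CAR) T cells.

Live cells grow logistically toward the carrying capacity ``b``, die by
necrosis on contact with dead cells (mass action), and are killed by the
drug (Michaelis-Menten saturation in ``C``) and by CAR-T cells (mass
action).  Dead cells accumulate every kill and dissolve at rate ``mu_d``.
The drug decays with first-order kinetics and is consumed by its own kill
events; CAR-T cells are activated by antigen encounters, die or exhaust at
rate ``mu_T``, self-inhibit quadratically (fratricide) and are also damaged
by the drug.

All state components are absolute counts (cells or molecules) in the full
blood volume; per-microlitre readouts are derived views (count / 5e6 uL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ModelParameters",
    "SystemState",
    "rhs_full",
    "rhs_immunotherapy",
    "rhs_post_eradication",
    "apply_eradication_clamp",
    "ERADICATION_THRESHOLD",
]

#: A population whose solution falls below one cell (or one molecule) is
#: treated as extinct and set to zero.
ERADICATION_THRESHOLD = 1.0

# Growth rates above 1.68/day exceed the in-vitro estimate the model is
# scaled from; CAR-T death rates outside [1/30, 1/14]/day fall outside the
# clinically reported exhaustion range.  Both are soft limits.
_RHO_A_MAX = 1.68
_MU_T_RANGE = (1.0 / 30.0, 1.0 / 14.0)


@dataclass
class ModelParameters:
    """Rate constants and capacities of the chemoimmunotherapy model.

    Defaults reproduce the published parameterization of the model: the
    carrying capacity ``b`` estimates lymphocytes as 1.6% of ~4.5e13 total
    cells in an adult, the growth rate ``rho_A`` is 10% of the in-vitro
    value (in-vivo conditions are not ideal), and the CAR-T efficacy
    ``alpha_T`` comes from the fitted three-rate efficacy law.

    Parameters
    ----------
    rho_A : float
        Leukemia growth rate (day^-1).
    b : float
        Leukemia carrying capacity (cells).
    mu_A : float
        Death rate of leukemia cells by necrosis on contact with dead
        cells (cells^-1 day^-1).
    a : float
        Drug amount producing half the maximum kill effect (molecules).
    mu_AC : float
        Chemotherapy cytotoxicity on cancer cells (day^-1); 0 when no
        chemotherapy is modelled.
    alpha_T : float
        CAR-T killing efficacy (cells^-1 day^-1); must exceed ``rho_T``.
    mu_d : float
        Dissolution rate of dead leukemia cells (day^-1).
    mu_C : float
        First-order decay rate of the drug (day^-1), ln2 / half-life.
    mu_CA, mu_CT : float, optional
        Drug deactivation per cancer-cell / CAR-T kill
        (molecules cells^-1 day^-1).  Default to ``10 * mu_AC`` and
        ``10 * mu_TC`` when not given.
    rho_T : float
        CAR-T mitosis/activation rate (cells^-1 day^-1).
    mu_T : float
        CAR-T death/exhaustion rate (day^-1).
    mu_TC : float
        Chemotherapy cytotoxicity on CAR-T cells (day^-1).
    phi_C : float
        Constant chemotherapy infusion rate (molecules day^-1).
    phi_T : float
        Constant CAR-T infusion rate (cells day^-1).
    blood_volume : float
        Blood volume of the patient (litres).
    """

    rho_A: float = 0.1680
    b: float = 7.2e11
    mu_A: float = 1.63199e-12
    a: float = 1e7
    mu_AC: float = 0.0
    alpha_T: float = 1.2560e-7
    mu_d: float = 0.408
    mu_C: float = 11.090
    mu_CA: float | None = None
    mu_CT: float | None = None
    rho_T: float = 2.9409e-13
    mu_T: float = 1.0 / 14.0
    mu_TC: float = 0.0
    phi_C: float = 0.0
    phi_T: float = 0.0
    blood_volume: float = 5.0

    def __post_init__(self) -> None:
        if self.mu_CA is None:
            self.mu_CA = 10.0 * self.mu_AC
        if self.mu_CT is None:
            self.mu_CT = 10.0 * self.mu_TC
        self.validate()

    def validate(self) -> None:
        """Check invariants; raise ``ValueError`` on hard violations.

        Soft range deviations (``rho_A`` above the in-vitro ceiling,
        ``mu_T`` outside the reported exhaustion range) only warn, since
        those are plausibility ranges rather than structural constraints.
        """
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"parameter {f.name} must be non-negative, got {value}")
        if self.b <= 0:
            raise ValueError("carrying capacity b must be positive")
        if self.blood_volume <= 0:
            raise ValueError("blood_volume must be positive")
        if self.alpha_T <= self.rho_T:
            raise ValueError(
                "CAR-T killing efficacy alpha_T must exceed the mitosis rate "
                f"rho_T (alpha_T={self.alpha_T}, rho_T={self.rho_T}); the "
                "boundedness and eradication thresholds divide by (alpha_T - rho_T)"
            )
        if self.rho_A > _RHO_A_MAX:
            warnings.warn(
                f"rho_A={self.rho_A} exceeds the in-vitro ceiling {_RHO_A_MAX}/day",
                stacklevel=3,
            )
        lo, hi = _MU_T_RANGE
        if self.mu_T and not (lo <= self.mu_T <= hi):
            warnings.warn(
                f"mu_T={self.mu_T} outside the reported range [1/30, 1/14]/day",
                stacklevel=3,
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        """Flat key-value mapping, keys named exactly as the field names."""
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**mapping)

    def evolve(self, **changes: float) -> "ModelParameters":
        """Return a copy with ``changes`` applied.

        The derived couplings ``mu_CA = 10*mu_AC`` and ``mu_CT = 10*mu_TC``
        are recomputed when the underlying cytotoxicity changes unless an
        explicit override is part of ``changes``.
        """
        d = self.to_dict()
        d.update(changes)
        if "mu_AC" in changes and "mu_CA" not in changes:
            d["mu_CA"] = 10.0 * d["mu_AC"]
        if "mu_TC" in changes and "mu_CT" not in changes:
            d["mu_CT"] = 10.0 * d["mu_TC"]
        return ModelParameters(**d)


@dataclass
class SystemState:
    """State of the four populations at time ``t`` (days).

    Components are absolute counts: ``A`` live leukemia cells, ``Ad`` dead
    leukemia cells, ``C`` drug molecules, ``T`` CAR-T cells.  All must be
    non-negative (the model lives in the non-negative orthant).
    """

    A: float
    Ad: float = 0.0
    C: float = 0.0
    T: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.A, self.Ad, self.C, self.T) < 0:
            raise ValueError(f"state components must be non-negative: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.Ad, self.C, self.T], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "SystemState":
        return cls(A=float(y[0]), Ad=float(y[1]), C=float(y[2]), T=float(y[3]), t=t)

    def per_microlitre(self, blood_volume_L: float = 5.0) -> dict[str, float]:
        """Concentration view (counts per uL of blood)."""
        v_uL = blood_volume_L * 1e6
        return {"A": self.A / v_uL, "Ad": self.Ad / v_uL, "C": self.C / v_uL, "T": self.T / v_uL}


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------

def _rhs_array(
    y: np.ndarray,
    p: ModelParameters,
    phi_C: float,
    phi_T: float,
) -> np.ndarray:
    """Unchecked right-hand side on a raw state array (A, Ad, C, T)."""
    A, Ad, C, T = y
    mm = C / (p.a + C)  # Michaelis-Menten drug saturation
    kill_chemo = p.mu_AC * A * mm
    kill_cart = p.alpha_T * A * T
    necrosis = p.mu_A * A * Ad
    dA = p.rho_A * A * (1.0 - A / p.b) - necrosis - kill_chemo - kill_cart
    dAd = -p.mu_d * Ad + necrosis + kill_chemo + kill_cart
    dC = -p.mu_C * C - p.mu_CA * A * mm - p.mu_CT * T * mm + phi_C
    dT = (
        p.rho_T * (A + T) * T
        - p.mu_T * T
        - p.alpha_T * T * T
        - p.mu_TC * T * mm
        + phi_T
    )
    return np.array([dA, dAd, dC, dT])


def rhs_full(
    state: SystemState,
    params: ModelParameters,
    phi_C_rate: float | None = None,
    phi_T_rate: float | None = None,
) -> tuple[float, float, float, float]:
    """Time derivative (dA, dAd, dC, dT) of the full four-state system.

    ``phi_C_rate`` / ``phi_T_rate`` override the constant infusion rates
    stored in ``params`` when given (molecules/day and cells/day).
    """
    phi_C = params.phi_C if phi_C_rate is None else phi_C_rate
    phi_T = params.phi_T if phi_T_rate is None else phi_T_rate
    if phi_C < 0 or phi_T < 0:
        raise ValueError("infusion rates must be non-negative")
    d = _rhs_array(state.as_array(), params, phi_C, phi_T)
    return tuple(float(v) for v in d)


def rhs_immunotherapy(
    state: tuple[float, float, float],
    params: ModelParameters,
    phi_T_rate: float | None = None,
) -> tuple[float, float, float]:
    """Derivative of the drug-free reduction (A, Ad, T).

    Chlorambucil has a half-life of 0.0625 days, so over immunotherapy
    timescales the drug pool is empty and the system reduces to three
    equations; this is exactly ``rhs_full`` restricted to C = 0, phi_C = 0.
    """
    A, Ad, T = state
    full = rhs_full(SystemState(A=A, Ad=Ad, C=0.0, T=T), params, phi_C_rate=0.0,
                    phi_T_rate=phi_T_rate)
    return (full[0], full[1], full[3])


def rhs_post_eradication(
    state: tuple[float, float, float],
    params: ModelParameters,
) -> tuple[float, float, float]:
    """Derivative of (Ad, C, T) after the tumor is eradicated and therapy stops.

    With A = 0 and both infusions off, dead cells decay linearly, the drug
    decays and is consumed by residual CAR-T kills, and CAR-T cells shrink
    under exhaustion plus net fratricide ``(alpha_T - rho_T) T^2``.
    """
    Ad, C, T = state
    full = rhs_full(SystemState(A=0.0, Ad=Ad, C=C, T=T), params, phi_C_rate=0.0,
                    phi_T_rate=0.0)
    return (full[1], full[2], full[3])


def apply_eradication_clamp(
    state: SystemState, threshold: float = ERADICATION_THRESHOLD
) -> SystemState:
    """Set every component strictly below ``threshold`` to exactly zero.

    Encodes the eradication-threshold assumption: a population described by
    an ODE solution below one cell (or molecule) is extinct.  The rule is
    applied to all four components.  Applied as a post-step/event rule so
    the vector field itself stays smooth.
    """
    vals = [state.A, state.Ad, state.C, state.T]
    clamped = [0.0 if v < threshold else v for v in vals]
    return SystemState(A=clamped[0], Ad=clamped[1], C=clamped[2], T=clamped[3], t=state.t)
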