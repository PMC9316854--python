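"""Closed-form stability and boundedness analysis of the chemoimmunotherapy model.

Everything here is analytic (or a scalar root-solve): ultimate bounds on
all compact invariant sets of the system, the CAR-T infusion-rate
thresholds for leukemia eradication and persistence, the CAR-T
depletion/persistence threshold on the mitosis rate, the equilibria of the
drug-free reduction, and the Jacobian eigenvalues at those equilibria.

Threshold doses
---------------
With ``r = rho_A / alpha_T``, the eradication threshold is::

    phi_CART   = r * ( r * (alpha_T - rho_T) + mu_T + mu_TC )

and the persistence threshold ``phi_prstnc`` is the same expression with
``mu_TC = 0``.  A constant CAR-T infusion above ``phi_CART`` guarantees
global eradication of the leukemia population; below ``phi_prstnc`` the
tumor persists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import ModelParameters, rhs_immunotherapy

__all__ = [
    "LocalizingBounds",
    "StabilityReport",
    "eradication_dose_threshold",
    "persistence_dose_threshold",
    "cart_fate_threshold",
    "localizing_domain",
    "equilibria",
    "immunotherapy_cart_level",
    "jacobian_eigenvalues",
    "coexistence_equilibrium",
    "stability_report",
]

#: Eigenvalue real parts within this tolerance of zero are "boundary".
_STABILITY_TOL = 1e-12


@dataclass(frozen=True)
class LocalizingBounds:
    """Ultimate bounds containing all compact invariant sets.

    ``A_sup`` is returned signed: a negative value is precisely the
    nonexistence condition (no invariant set with a living tumor), so it
    is not clamped here.
    """

    A_sup: float
    Ad_sup: float
    T_inf: float
    T_sup: float
    C_inf: float
    C_sup: float
    A_max: float
    condition13_holds: bool


def _require_condition5(p: ModelParameters) -> None:
    if p.alpha_T <= p.rho_T:
        raise ValueError(
            "alpha_T must exceed rho_T (CAR-T efficacy above mitosis rate); "
            f"got alpha_T={p.alpha_T}, rho_T={p.rho_T}"
        )


def eradication_dose_threshold(params: ModelParameters) -> float:
    """Constant CAR-T infusion rate (cells/day) above which leukemia is eradicated.

    phi_CART = (rho_A/alpha_T) * [ (rho_A/alpha_T)(alpha_T - rho_T) + mu_T + mu_TC ].
    Chemotherapy pressure on the CAR-T cells (mu_TC > 0) raises the bar.
    """
    _require_condition5(params)
    r = params.rho_A / params.alpha_T
    return r * (r * (params.alpha_T - params.rho_T) + params.mu_T + params.mu_TC)


def persistence_dose_threshold(params: ModelParameters) -> float:
    """Constant CAR-T infusion rate below which the leukemia population persists.

    Identical to the eradication threshold without the chemotherapy term.
    """
    _require_condition5(params)
    r = params.rho_A / params.alpha_T
    return r * (r * (params.alpha_T - params.rho_T) + params.mu_T)


def cart_fate_threshold(params: ModelParameters) -> tuple[float, str]:
    """Threshold ``mu_A*mu_T/mu_d`` on the CAR-T mitosis rate, with the fate label.

    Returns ``(threshold, label)`` where the label classifies ``rho_T`` as
    ``"depletion"`` (below), ``"persistence"`` (above) or ``"boundary"``.
    """
    thr = params.mu_A * params.mu_T / params.mu_d
    if params.rho_T < thr:
        label = "depletion"
    elif params.rho_T > thr:
        label = "persistence"
    else:
        label = "boundary"
    return thr, label


def localizing_domain(
    params: ModelParameters,
    phi_C_rate: float | None = None,
    phi_T_rate: float | None = None,
) -> LocalizingBounds:
    """Localizing-domain bounds for constant infusion rates.

    Rates default to ``params.phi_C`` / ``params.phi_T``.  ``C_inf`` is
    floored at zero (a negative lower drug bound has no biological
    meaning); ``condition13_holds`` reports whether the un-floored bound
    was positive.
    """
    _require_condition5(params)
    p = params
    phi_C = p.phi_C if phi_C_rate is None else phi_C_rate
    phi_T = p.phi_T if phi_T_rate is None else phi_T_rate
    if phi_C < 0 or phi_T < 0:
        raise ValueError("infusion rates must be non-negative")

    Ad_sup = p.b * (p.rho_A + p.mu_d) ** 2 / (4.0 * p.mu_d * p.rho_A)
    gap = p.alpha_T - p.rho_T
    theta = (p.mu_T + p.mu_TC) / (2.0 * gap)
    T_inf = math.sqrt(theta * theta + phi_T / gap) - theta
    T_sup = phi_T / p.mu_T + p.b * (p.rho_A + p.mu_T) ** 2 / (4.0 * p.rho_A * p.mu_T)
    A_max = min(p.b, Ad_sup, T_sup)
    C_sup = phi_C / p.mu_C
    raw_C_inf = (phi_C - p.mu_CA * A_max - p.mu_CT * T_sup) / p.mu_C
    condition13 = phi_C > p.mu_CA * A_max + p.mu_CT * T_sup
    A_sup = p.b - (p.alpha_T * p.b / p.rho_A) * T_inf
    return LocalizingBounds(
        A_sup=A_sup, Ad_sup=Ad_sup, T_inf=T_inf, T_sup=T_sup,
        C_inf=max(0.0, raw_C_inf), C_sup=C_sup, A_max=A_max,
        condition13_holds=condition13,
    )


# ---------------------------------------------------------------------------
# Equilibria of the drug-free reduction (A, Ad, T)
# ---------------------------------------------------------------------------

def immunotherapy_cart_level(params: ModelParameters, phi_T_rate: float) -> float:
    """CAR-T level T1* of the tumor-free equilibrium under constant infusion.

    T1* = ( sqrt(mu_T^2 + 4 phi_T (alpha_T - rho_T)) - mu_T ) / (2 (alpha_T - rho_T)).
    """
    _require_condition5(params)
    gap = params.alpha_T - params.rho_T
    return (math.sqrt(params.mu_T**2 + 4.0 * phi_T_rate * gap) - params.mu_T) / (2.0 * gap)


def equilibria(params: ModelParameters, phi_T_rate: float = 0.0) -> list[dict]:
    """Named equilibria of the drug-free (A, Ad, T) reduction.

    Always returns the origin and the tumor-free immunotherapy point
    ``(0, 0, T1*)``; adds the untreated tumor equilibrium
    ``(mu_d/mu_A, rho_A (b mu_A - mu_d)/(b mu_A^2), 0)`` when it is
    positive (``b mu_A > mu_d``).
    """
    p = params
    out = [{"name": "origin", "A": 0.0, "Ad": 0.0, "T": 0.0}]
    T1 = immunotherapy_cart_level(p, phi_T_rate)
    out.append({"name": "tumor_free", "A": 0.0, "Ad": 0.0, "T": T1})
    if p.b * p.mu_A - p.mu_d > 0 and p.mu_A > 0:
        A_star = p.mu_d / p.mu_A
        Ad_star = p.rho_A * (p.b * p.mu_A - p.mu_d) / (p.b * p.mu_A**2)
        out.append({"name": "no_treatment", "A": A_star, "Ad": Ad_star, "T": 0.0})
    return out


def jacobian_eigenvalues(
    params: ModelParameters,
    equilibrium: str,
    phi_T_rate: float = 0.0,
) -> tuple[complex, ...]:
    """Closed-form eigenvalues of the reduced-system Jacobian at a named point.

    ``equilibrium="no_treatment"`` returns (lambda1, lambda2, lambda3) at
    the untreated tumor point: the conjugate pair of the (A, Ad) block and
    lambda3 = -(mu_A*mu_T - mu_d*rho_T)/mu_A, whose sign flip at
    rho_T = mu_A*mu_T/mu_d is the CAR-T depletion/persistence boundary.

    ``equilibrium="tumor_free"`` returns (lambda4, lambda5, lambda6) at the
    immunotherapy-only point: lambda4 = rho_A - alpha_T*T1* changes sign
    exactly at phi_T = phi_prstnc.
    """
    p = params
    if equilibrium == "no_treatment":
        if p.b * p.mu_A - p.mu_d <= 0:
            raise ValueError("untreated equilibrium requires b*mu_A > mu_d")
        disc = complex(
            p.mu_d**2 * p.rho_A**2
            - 4.0 * p.mu_A * p.mu_d * p.rho_A * p.b * (p.mu_A * p.b - p.mu_d)
        )
        root = np.sqrt(disc)
        denom = 2.0 * p.mu_A * p.b
        lam1 = (-p.mu_d * p.rho_A - root) / denom
        lam2 = (-p.mu_d * p.rho_A + root) / denom
        lam3 = complex(-(p.mu_A * p.mu_T - p.mu_d * p.rho_T) / p.mu_A)
        return (lam1, lam2, lam3)
    if equilibrium == "tumor_free":
        _require_condition5(p)
        T1 = immunotherapy_cart_level(p, phi_T_rate)
        lam4 = complex(p.rho_A - p.alpha_T * T1)
        lam5 = complex(-p.mu_d)
        lam6 = complex(-math.sqrt(p.mu_T**2 + 4.0 * phi_T_rate * (p.alpha_T - p.rho_T)))
        return (lam4, lam5, lam6)
    raise ValueError(
        f"unsupported equilibrium {equilibrium!r}; use 'no_treatment' or 'tumor_free'"
    )


def coexistence_equilibrium(params: ModelParameters) -> tuple[float, float, float] | None:
    """Positive steady state (A*, Ad*, T*) of the drug-free system without infusion.

    Exists only in the CAR-T persistence regime (rho_T > mu_A*mu_T/mu_d):
    the T-nullcline ``T = (rho_T A - mu_T)/(alpha_T - rho_T)`` needs
    ``A > mu_T/rho_T`` while the Ad-nullcline needs ``A < mu_d/mu_A``.
    Returns ``None`` when no positive root exists.
    """
    p = params
    _require_condition5(p)
    gap = p.alpha_T - p.rho_T
    if p.rho_T <= 0:
        return None
    lo = p.mu_T / p.rho_T          # T > 0 above this
    hi = p.mu_d / p.mu_A           # Ad > 0 below this
    if lo >= hi:
        return None

    def t_of(A):
        return (p.rho_T * A - p.mu_T) / gap

    def ad_of(A):
        T = t_of(A)
        return p.alpha_T * A * T / (p.mu_d - p.mu_A * A)

    def resid(A):
        # A-nullcline after dividing by A > 0
        return p.rho_A * (1.0 - A / p.b) - p.mu_A * ad_of(A) - p.alpha_T * t_of(A)

    eps = 1e-9 * (hi - lo)
    a, b_ = lo + eps, hi - eps
    fa, fb = resid(a), resid(b_)
    if not np.isfinite(fa) or not np.isfinite(fb) or fa * fb > 0:
        return None
    A_star = optimize.brentq(resid, a, b_, xtol=1e-6, rtol=1e-14)
    T_star = t_of(A_star)
    Ad_star = ad_of(A_star)
    # polish the full 3-D root; also guards against spurious brackets
    sol = optimize.root(
        lambda y: rhs_immunotherapy((y[0], y[1], y[2]), p, phi_T_rate=0.0),
        x0=[A_star, Ad_star, T_star], tol=1e-12,
    )
    if sol.success and (sol.x > 0).all():
        A_star, Ad_star, T_star = map(float, sol.x)
    return (A_star, Ad_star, T_star)


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Everything the analytic layer can say about one parameterization."""

    phi_CART: float
    phi_prstnc: float
    cart_persistence_threshold: float
    cart_fate: str
    bounds: LocalizingBounds
    equilibria: list[dict]
    eigenvalues_no_treatment: tuple[complex, ...] | None
    eigenvalues_tumor_free: tuple[complex, ...]
    coexistence: tuple[float, float, float] | None
    conditions: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def cplx(seq):
            if seq is None:
                return None
            return [{"re": z.real, "im": z.imag} for z in seq]

        b = self.bounds
        return {
            "phi_CART": self.phi_CART,
            "phi_prstnc": self.phi_prstnc,
            "cart_persistence_threshold": self.cart_persistence_threshold,
            "cart_fate": self.cart_fate,
            "bounds": {
                "A_sup": b.A_sup, "Ad_sup": b.Ad_sup, "T_inf": b.T_inf,
                "T_sup": b.T_sup, "C_inf": b.C_inf, "C_sup": b.C_sup,
                "A_max": b.A_max, "condition13_holds": b.condition13_holds,
            },
            "equilibria": self.equilibria,
            "eigenvalues_no_treatment": cplx(self.eigenvalues_no_treatment),
            "eigenvalues_tumor_free": cplx(self.eigenvalues_tumor_free),
            "coexistence": list(self.coexistence) if self.coexistence else None,
            "conditions": dict(self.conditions),
        }


def stability_report(
    params: ModelParameters,
    phi_C_rate: float | None = None,
    phi_T_rate: float | None = None,
) -> StabilityReport:
    """Compute thresholds, bounds, equilibria and eigenvalues in one pass."""
    p = params
    phi_C = p.phi_C if phi_C_rate is None else phi_C_rate
    phi_T = p.phi_T if phi_T_rate is None else phi_T_rate
    phi_cart = eradication_dose_threshold(p)
    phi_pr = persistence_dose_threshold(p)
    fate_thr, fate = cart_fate_threshold(p)
    bounds = localizing_domain(p, phi_C, phi_T)
    eq = equilibria(p, phi_T)
    has_untreated = any(e["name"] == "no_treatment" for e in eq)
    eig_nt = jacobian_eigenvalues(p, "no_treatment", phi_T) if has_untreated else None
    eig_tf = jacobian_eigenvalues(p, "tumor_free", phi_T)
    conditions = {
        "condition5_alphaT_gt_rhoT": p.alpha_T > p.rho_T,
        "condition7_cart_persistence": p.rho_T > fate_thr,
        "condition13_drug_floor": bounds.condition13_holds,
        "condition14_eradication": phi_T > phi_cart,
        "condition24_untreated_equilibrium": p.b * p.mu_A - p.mu_d > 0,
        "condition28_leukemia_persistence": phi_T < phi_pr,
    }
    return StabilityReport(
        phi_CART=phi_cart, phi_prstnc=phi_pr,
        cart_persistence_threshold=fate_thr, cart_fate=fate,
        bounds=bounds, equilibria=eq,
        eigenvalues_no_treatment=eig_nt, eigenvalues_tumor_free=eig_tf,
        coexistence=coexistence_equilibrium(p), conditions=conditions,
    )
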