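"""Analytic thresholds, bounds, equilibria and eigenvalues."""

import numpy as np
import pytest

from cllcart import (
    ModelParameters,
    cart_fate_threshold,
    coexistence_equilibrium,
    equilibria,
    eradication_dose_threshold,
    immunotherapy_cart_level,
    jacobian_eigenvalues,
    localizing_domain,
    persistence_dose_threshold,
    rhs_immunotherapy,
    stability_report,
)


class TestDoseThresholds:
    @pytest.mark.parametrize(
        "mu_TC, expected",
        [
            (0.0, 320_252.0),
            (0.0170, 342_971.0),
            (0.0186, 345_131.0),
            (0.0200, 347_066.0),
            (0.0214, 348_821.0),
        ],
    )
    def test_published_eradication_thresholds(self, mu_TC, expected, default_params):
        phi = eradication_dose_threshold(default_params.evolve(mu_TC=mu_TC))
        assert phi == pytest.approx(expected, rel=1e-3)

    def test_persistence_equals_eradication_without_chemo(self, default_params):
        assert persistence_dose_threshold(default_params) == eradication_dose_threshold(
            default_params.evolve(mu_TC=0.0)
        )

    def test_monotone_in_growth_rate(self, default_params):
        values = [
            persistence_dose_threshold(default_params.evolve(rho_A=r))
            for r in (0.05, 0.1, 0.168, 0.3)
        ]
        assert values == sorted(values)

    def test_requires_efficacy_above_mitosis(self):
        bad = ModelParameters().to_dict()
        bad.update(alpha_T=1e-13, rho_T=2e-13)
        with pytest.raises(ValueError, match="alpha_T"):
            ModelParameters(**bad)


class TestCartFate:
    def test_threshold_value_and_classification(self, default_params):
        thr, fate = cart_fate_threshold(default_params)
        assert thr == pytest.approx(2.857e-13, rel=1e-3)
        assert fate == "persistence"  # default rho_T = 2.9409e-13
        assert cart_fate_threshold(default_params.evolve(rho_T=2.5714e-13))[1] == "depletion"
        assert cart_fate_threshold(default_params.evolve(rho_T=thr))[1] == "boundary"

    def test_fast_dissolution_limit(self, default_params):
        thr, fate = cart_fate_threshold(default_params.evolve(mu_d=1e6))
        assert thr < 1e-18
        assert fate == "persistence"


class TestLocalizingDomain:
    def test_dead_cell_bound_plug_in_oracle(self, default_params):
        p = default_params
        bounds = localizing_domain(p)
        expected = p.b * (p.rho_A + p.mu_d) ** 2 / (4 * p.mu_d * p.rho_A)
        assert bounds.Ad_sup == pytest.approx(expected, rel=1e-12)
        assert bounds.Ad_sup == pytest.approx(8.7126e11, rel=1e-4)

    def test_no_infusion_limits(self, default_params):
        bounds = localizing_domain(default_params, phi_C_rate=0.0, phi_T_rate=0.0)
        assert bounds.T_inf == 0.0
        assert bounds.C_inf == 0.0 and bounds.C_sup == 0.0
        assert not bounds.condition13_holds
        assert bounds.A_sup == default_params.b  # no CAR-T pressure

    def test_infusion_tightens_tumor_bound(self, default_params):
        b0 = localizing_domain(default_params, phi_T_rate=0.0)
        b1 = localizing_domain(default_params, phi_T_rate=3e5)
        assert b1.T_inf > 0
        assert b1.A_sup < b0.A_sup
        # beyond the eradication threshold the signed bound goes negative
        phi = eradication_dose_threshold(default_params)
        assert localizing_domain(default_params, phi_T_rate=2 * phi).A_sup < 0
        assert localizing_domain(default_params, phi_T_rate=0.5 * phi).A_sup > 0

    def test_drug_floor_condition(self, default_params):
        p = default_params.evolve(mu_AC=0.3712, mu_TC=0.02)
        big = 1e25
        bounds = localizing_domain(p, phi_C_rate=big, phi_T_rate=0.0)
        assert bounds.condition13_holds
        assert 0 < bounds.C_inf <= bounds.C_sup == pytest.approx(big / p.mu_C)


class TestEquilibria:
    def test_untreated_tumor_burden(self, default_params):
        eq = {e["name"]: e for e in equilibria(default_params)}
        A_star = eq["no_treatment"]["A"]
        Ad_star = eq["no_treatment"]["Ad"]
        assert A_star == pytest.approx(2.500e11, rel=1e-4)
        assert Ad_star / A_star == pytest.approx(0.2688, rel=1e-3)

    def test_tumor_free_cart_level(self, default_params):
        assert immunotherapy_cart_level(default_params, 0.0) == 0.0
        eq = {e["name"]: e for e in equilibria(default_params, phi_T_rate=0.0)}
        assert eq["tumor_free"]["T"] == 0.0
        assert eq["origin"] == {"name": "origin", "A": 0.0, "Ad": 0.0, "T": 0.0}


class TestEigenvalues:
    def test_untreated_point_is_stable_node_or_focus(self, default_params):
        lam1, lam2, lam3 = jacobian_eigenvalues(default_params, "no_treatment")
        assert lam1.real < 0 and lam2.real < 0
        # persistence regime: the CAR-T direction is unstable
        assert lam3.real > 0

    def test_cart_direction_flips_at_fate_threshold(self, default_params):
        thr, _ = cart_fate_threshold(default_params)
        at = jacobian_eigenvalues(default_params.evolve(rho_T=thr), "no_treatment")[2]
        assert at.real == pytest.approx(0.0, abs=1e-18)
        below = jacobian_eigenvalues(default_params.evolve(rho_T=0.9 * thr), "no_treatment")[2]
        above = jacobian_eigenvalues(default_params.evolve(rho_T=1.1 * thr), "no_treatment")[2]
        assert below.real < 0 < above.real

    def test_tumor_free_leading_eigenvalue_flips_at_persistence_threshold(
        self, default_params
    ):
        phi_star = persistence_dose_threshold(default_params)
        for factor in (0.5, 0.9, 0.99):
            lam4 = jacobian_eigenvalues(default_params, "tumor_free",
                                        phi_T_rate=factor * phi_star)[0]
            assert lam4.real > 0
        for factor in (1.01, 1.1, 2.0):
            lam4 = jacobian_eigenvalues(default_params, "tumor_free",
                                        phi_T_rate=factor * phi_star)[0]
            assert lam4.real < 0
        at = jacobian_eigenvalues(default_params, "tumor_free", phi_T_rate=phi_star)[0]
        assert at.real == pytest.approx(0.0, abs=1e-9)

    def test_unknown_equilibrium_rejected(self, default_params):
        with pytest.raises(ValueError):
            jacobian_eigenvalues(default_params, "coexistence")

    def test_agreement_with_numerical_jacobian(self):
        # 50 random valid parameter draws: closed-form eigenvalues match a
        # finite-difference Jacobian of the reduced vector field to 1e-6
        rng = np.random.default_rng(2024)
        base = ModelParameters()
        checked = 0
        while checked < 50:
            scale = rng.uniform(0.5, 2.0, size=7)
            try:
                p = base.evolve(
                    rho_A=base.rho_A * scale[0], b=base.b * scale[1],
                    mu_A=base.mu_A * scale[2], mu_d=base.mu_d * scale[3],
                    alpha_T=base.alpha_T * scale[4], rho_T=base.rho_T * scale[5],
                    mu_T=np.clip(base.mu_T * scale[6], 1 / 30, 1 / 14),
                )
            except ValueError:
                continue
            if p.b * p.mu_A - p.mu_d <= 0:
                continue
            checked += 1
            phi_T = float(rng.uniform(0, 5e5))
            for name, point in [
                ("no_treatment", None),
                ("tumor_free", None),
            ]:
                eq = {e["name"]: e for e in equilibria(p, phi_T)}[name]
                x0 = np.array([eq["A"], eq["Ad"], eq["T"]])
                J = _numerical_jacobian(p, x0, phi_T)
                num = np.sort_complex(np.linalg.eigvals(J))
                ana = np.sort_complex(np.array(jacobian_eigenvalues(p, name, phi_T)))
                np.testing.assert_allclose(num, ana, rtol=1e-6,
                                           atol=1e-6 * max(1.0, np.abs(ana).max()))


def _numerical_jacobian(p, x0, phi_T):
    """Central finite differences of the reduced (A, Ad, T) vector field."""
    J = np.zeros((3, 3))
    for j in range(3):
        h = max(1e-7 * abs(x0[j]), 1e-3)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        fp = np.array(rhs_immunotherapy(tuple(xp), p, phi_T_rate=phi_T))
        fm = np.array(rhs_immunotherapy(tuple(xm), p, phi_T_rate=phi_T))
        J[:, j] = (fp - fm) / (xp[j] - xm[j])
    return J


class TestCoexistence:
    def test_persistence_regime_point(self, default_params):
        point = coexistence_equilibrium(default_params)
        assert point is not None
        A, Ad, T = point
        assert A == pytest.approx(2.4716e11, rel=1e-2)
        assert Ad == pytest.approx(6.6835e10, rel=1e-2)
        assert T == pytest.approx(1.0001e4, rel=1e-2)
        # it is a genuine steady state of the reduced vector field
        resid = np.array(rhs_immunotherapy((A, Ad, T), default_params, 0.0))
        scale = np.array([default_params.rho_A * A, default_params.mu_d * Ad,
                          default_params.mu_T * T])
        assert np.all(np.abs(resid) <= 1e-6 * scale)

    def test_depletion_regime_has_no_positive_point(self, default_params):
        assert coexistence_equilibrium(default_params.evolve(rho_T=2.5714e-13)) is None


def test_stability_report_aggregates_consistently(default_params):
    report = stability_report(default_params, phi_T_rate=4e5)
    assert report.phi_CART == pytest.approx(320_252, rel=1e-3)
    assert report.conditions["condition14_eradication"]  # 4e5 > phi_CART
    assert not report.conditions["condition28_leukemia_persistence"]
    assert report.cart_fate == "persistence"
    doc = report.to_dict()
    assert doc["bounds"]["Ad_sup"] == report.bounds.Ad_sup
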