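"""Well-mixed RhoA-NMIIA kinetics: rates, fixed points, phase-plane objects.

Fixed-point expectations come from an independent polynomial-root oracle:
with kappa1 = kappa2 = kappa and Hill coefficient n, diagonal steady states
solve c^(n+1) - c^n + kappa^n * c = 0, i.e. c = 0 or c^n - c^(n-1) +
kappa^n = 0.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

import rhozone as rz
from rhozone.kinetics import (
    NonBistableError,
    classify_basin,
    hill,
    nullclines,
    separatrix,
    unstable_manifold,
    export_phase_portrait,
)


def clipped_rates(p):
    """Rate field for ODE oracles: solver trial steps may graze tiny negative
    values, which the domain-checked public API rejects by design."""
    return lambda t, y: rz.reaction_rates(max(y[0], 0.0), max(y[1], 0.0), p)


def diagonal_roots(kappa: float, n: int = 4) -> np.ndarray:
    """Oracle: positive real roots of c^n - c^(n-1) + kappa^n = 0."""
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    coeffs[1] = -1.0
    coeffs[-1] = kappa**n
    r = np.roots(coeffs)
    real = np.sort(r[np.abs(r.imag) < 1e-12].real)
    return real[real > 1e-12]


class TestReactionRates:
    def test_origin_is_fixed_point(self):
        d_rho, d_m = rz.reaction_rates(0.0, 0.0, rz.KineticParams())
        assert d_rho == 0.0 and d_m == 0.0

    def test_half_saturation_gives_half_rate(self):
        # m at kappa1 activates rho production at exactly half the maximum
        d_rho, _ = rz.reaction_rates(0.0, 0.2, rz.KineticParams(alpha=1.0, kappa1=0.2))
        assert d_rho == pytest.approx(0.5)

    def test_unit_concentrations(self):
        # hand-checked: 1/(1 + 0.2^4) - 1 = -0.0015974...
        d_rho, d_m = rz.reaction_rates(1.0, 1.0, rz.KineticParams())
        expected = 1.0 / (1.0 + 0.2**4) - 1.0
        assert d_rho == pytest.approx(expected, rel=1e-12)
        assert d_m == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            rz.reaction_rates(-0.1, 0.0, rz.KineticParams())

    def test_decay_factor_scales_dissociation_only(self):
        # the factor must multiply the -alpha*c term, not the recruitment term
        p = rz.KineticParams(alpha=0.5)
        rho, m = 0.3, 0.7
        d_rho, d_m = rz.reaction_rates(rho, m, p, m_decay=2.0)
        assert d_m == pytest.approx(p.alpha * (hill(rho, p.kappa2, p.n) - 2.0 * m))
        assert d_rho == pytest.approx(p.alpha * (hill(m, p.kappa1, p.n) - rho))


class TestFixedPoints:
    @pytest.mark.parametrize("kappa", [0.2, 0.4])
    def test_bistable_points_match_polynomial_oracle(self, kappa):
        fps = rz.find_fixed_points(rz.KineticParams(kappa1=kappa, kappa2=kappa))
        roots = diagonal_roots(kappa)
        assert len(roots) == 2
        assert len(fps.points) == 3
        expected = np.concatenate([[0.0], roots])
        np.testing.assert_allclose(np.sort(fps.points[:, 0]), expected, atol=1e-8)
        # symmetric kappas put every fixed point on the diagonal
        np.testing.assert_allclose(fps.points[:, 0], fps.points[:, 1], atol=1e-8)
        assert sorted(fps.stability) == ["saddle", "stable", "stable"]
        assert fps.is_bistable

    def test_rates_vanish_at_fixed_points(self):
        p = rz.KineticParams(kappa1=0.4, kappa2=0.4)
        for rho, m in rz.find_fixed_points(p).points:
            d_rho, d_m = rz.reaction_rates(rho, m, p)
            assert abs(d_rho) < 1e-10 and abs(d_m) < 1e-10

    def test_saddle_closer_to_origin_than_to_high_state(self):
        fps = rz.find_fixed_points(rz.KineticParams(kappa1=0.4, kappa2=0.4))
        d_low = np.linalg.norm(fps.saddle - fps.low)
        d_high = np.linalg.norm(fps.saddle - fps.high)
        assert d_low < d_high

    def test_large_kappa_monostable(self):
        # c^4 - c^3 + 1 has no positive real roots
        assert diagonal_roots(1.0).size == 0
        assert not rz.bistability_check(rz.KineticParams(kappa1=1.0, kappa2=1.0))

    def test_small_kappa_limit_bistable(self):
        assert rz.bistability_check(rz.KineticParams(kappa1=0.01, kappa2=0.01))

    def test_stability_labels_agree_with_forward_integration(self):
        p = rz.KineticParams(kappa1=0.4, kappa2=0.4)
        fps = rz.find_fixed_points(p)

        def flow_to(y0, t=200.0):
            sol = solve_ivp(clipped_rates(p), (0, t), y0, rtol=1e-9, atol=1e-12)
            return sol.y[:, -1]

        for (rho, m), label in zip(fps.points, fps.stability):
            for delta in ([1e-3, 1.3e-3], [-1e-3, -0.7e-3]):
                y0 = np.clip([rho + delta[0], m + delta[1]], 0, None)
                end = flow_to(y0)
                if label == "stable":
                    assert np.linalg.norm(end - [rho, m]) < 1e-6
                else:  # saddle: generic perturbations leave
                    assert np.linalg.norm(end - [rho, m]) > 0.05

    def test_alpha_zero_rejected_for_fixed_point_analysis(self):
        with pytest.raises(ValueError):
            rz.find_fixed_points(rz.KineticParams(alpha=0.0))


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(alpha=-1.0), dict(kappa1=0.0), dict(kappa2=-0.2), dict(n=0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rz.KineticParams(**kwargs)


class TestDiagonalDynamics:
    @given(c0=st.floats(0.01, 1.2))
    def test_symmetric_system_stays_on_diagonal(self, c0):
        p = rz.KineticParams()
        sol = solve_ivp(clipped_rates(p), (0, 20.0), [c0, c0], rtol=1e-9, atol=1e-12)
        assert np.abs(sol.y[0] - sol.y[1]).max() < 1e-8

    def test_threshold_separates_decay_from_ignition(self, saddle_value):
        p = rz.KineticParams()
        for c0, target in [(saddle_value * 0.5, 0.0), (saddle_value * 1.5, None)]:
            sol = solve_ivp(clipped_rates(p), (0, 300.0), [c0, c0],
                            rtol=1e-9, atol=1e-12)
            end = sol.y[0, -1]
            if target == 0.0:
                assert end < 1e-6
            else:
                high = rz.find_fixed_points(p).high[0]
                assert end == pytest.approx(high, abs=1e-6)


class TestSeparatrix:
    def test_requires_bistability(self):
        with pytest.raises(NonBistableError):
            separatrix(rz.KineticParams(kappa1=1.0, kappa2=1.0))

    def test_symmetric_under_species_exchange(self):
        sep = separatrix(rz.KineticParams(kappa1=0.4, kappa2=0.4), arc_points=200)
        swapped = sep[:, ::-1][::-1]
        # same curve traced from the other end; compare by nearest distance
        d = np.array([np.linalg.norm(sep - q, axis=1).min() for q in swapped])
        assert d.max() < 5e-3

    def test_points_flow_back_to_saddle(self):
        p = rz.KineticParams(kappa1=0.4, kappa2=0.4)
        fps = rz.find_fixed_points(p)
        sep = separatrix(p, arc_points=100)
        rng = np.random.default_rng(0)
        for q in sep[rng.choice(len(sep), 5, replace=False)]:
            if np.any(q < 0) or np.any(q > 1.4):
                continue
            sol = solve_ivp(
                lambda t, y: rz.reaction_rates(np.clip(y[0], 0, None),
                                               np.clip(y[1], 0, None), p),
                (0, 60.0), q, rtol=1e-10, atol=1e-13, dense_output=True,
            )
            dist = np.linalg.norm(sol.y - fps.saddle[:, None], axis=0)
            assert dist.min() < 1e-3

    def test_basin_classification_matches_forward_integration(self):
        p = rz.KineticParams(kappa1=0.4, kappa2=0.4)
        fps = rz.find_fixed_points(p)
        sep = separatrix(p)
        grid = np.linspace(0.0, 1.2, 10)
        pts = [(r, m) for r in grid for m in grid]
        labels = classify_basin(p, pts, sep=sep)

        def oracle(pt):
            sol = solve_ivp(clipped_rates(p), (0, 400.0), pt, rtol=1e-9, atol=1e-12)
            end = sol.y[:, -1]
            return "high" if np.linalg.norm(end - fps.high) < 0.1 else "low"

        mismatch = sum(lab != oracle(pt) for pt, lab in zip(pts, labels))
        assert mismatch == 0


def test_phase_portrait_export_is_plain_csv(tmp_path):
    paths = export_phase_portrait(rz.KineticParams(kappa1=0.4, kappa2=0.4), tmp_path)
    assert {"nullcline_rho", "nullcline_m", "fixed_points", "separatrix",
            "unstable_manifold"} <= set(paths)
    import pandas as pd

    fp = pd.read_csv(paths["fixed_points"])
    assert list(fp.columns) == ["rho", "m", "stability"]
    assert len(fp) == 3


def test_nullclines_pass_through_fixed_points():
    p = rz.KineticParams(kappa1=0.4, kappa2=0.4)
    rho_nc, m_nc = nullclines(p, samples=2000)
    for pt in rz.find_fixed_points(p).points:
        assert np.linalg.norm(rho_nc - pt, axis=1).min() < 2e-3
        assert np.linalg.norm(m_nc - pt, axis=1).min() < 2e-3


def test_unstable_manifold_connects_to_stable_states():
    p = rz.KineticParams(kappa1=0.4, kappa2=0.4)
    fps = rz.find_fixed_points(p)
    man = unstable_manifold(p, arc_points=200)
    # the two heteroclinic branches end near the low and high states
    d_low = np.linalg.norm(man - fps.low, axis=1).min()
    d_high = np.linalg.norm(man - fps.high, axis=1).min()
    assert d_low < 1e-3 and d_high < 1e-3
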