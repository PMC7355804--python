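"""Cosolvency model fitting against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from cosolvency.dataset import SolubilityDataset
from cosolvency.models import (
    fit_apelblat,
    fit_ja_vant_hoff,
    fit_jouyban_acree,
    fit_vant_hoff,
    predict_vant_hoff,
    r_squared,
    rmsd_percent,
    yalkowsky_roseman,
)
from cosolvency.simulate import GeneratorConfig, generate, perturb_fixture

T5 = np.array([298.2, 303.2, 308.2, 313.2, 318.2])


class TestDiagnostics:
    def test_rmsd_zero_for_perfect_predictions(self):
        x = np.array([1e-5, 2e-4, 0.03])
        assert rmsd_percent(x, x) == 0.0

    def test_rmsd_single_point_ten_percent(self):
        assert rmsd_percent([1.0], [0.9]) == pytest.approx(10.0, rel=1e-12)

    def test_rmsd_errors(self):
        with pytest.raises(ValueError):
            rmsd_percent([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            rmsd_percent([0.0, 1.0], [0.1, 1.0])

    def test_r_squared_perfect(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_r_squared_hand_computed(self):
        # y = (1, 2, 4), yhat = (1.5, 2, 3.5): SS_res = 0.5, SS_tot = 14/3
        assert r_squared([1, 2, 4], [1.5, 2, 3.5]) == pytest.approx(
            1 - 0.5 / (14 / 3), rel=1e-12
        )

    def test_r_squared_zero_variance_error(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestVantHoff:
    def test_noiseless_recovery(self):
        x = np.exp(1.0 - 100.0 / T5)
        fit = fit_vant_hoff(T5, x)
        assert fit.a == pytest.approx(1.0, abs=1e-10)
        assert fit.b == pytest.approx(-100.0, abs=1e-7)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmsd_pct == pytest.approx(0.0, abs=1e-8)

    def test_grid_search_oracle(self):
        # dense (a, b) grid search with two refinement passes on a 5-point toy set
        rng = np.random.default_rng(7)
        y = -2.0 - 900.0 / T5 + rng.normal(0, 0.01, 5)
        x = np.exp(y)
        fit = fit_vant_hoff(T5, x)

        def sse(a, b):
            return np.sum((y - a - b / T5) ** 2)

        a0, b0, wa, wb = -2.0, -900.0, 1.0, 400.0
        for _ in range(12):
            A = np.linspace(a0 - wa, a0 + wa, 81)
            B = np.linspace(b0 - wb, b0 + wb, 81)
            S = np.array([[sse(a, b) for b in B] for a in A])
            ia, ib = np.unravel_index(np.argmin(S), S.shape)
            a0, b0 = A[ia], B[ib]
            wa, wb = wa / 4, wb / 4
        assert fit.a == pytest.approx(a0, abs=1e-6)
        assert fit.b == pytest.approx(b0, abs=1e-3)

    def test_predict_closed_form(self):
        fit = fit_vant_hoff(T5, np.exp(-4.45 - 2093.60 / T5))
        assert predict_vant_hoff(fit, 308.2) == pytest.approx(
            math.exp(-4.45 - 2093.60 / 308.2), rel=1e-9
        )

    def test_zero_slope_is_temperature_independent(self):
        from cosolvency.models import VantHoffFit

        fit = VantHoffFit(m=0.5, a=-3.0, b=0.0, r2=1.0, rmsd_pct=0.0)
        assert np.allclose(fit.predict(T5), math.exp(-3.0))

    def test_degenerate_temperatures_rejected(self):
        with pytest.raises(ValueError):
            fit_vant_hoff([300.0, 300.0, 300.0], [1e-4, 1e-4, 1e-4])


class TestApelblat:
    def test_nested_vant_hoff_recovery(self):
        # data generated with C = 0 must reduce to the Van't Hoff fit
        x = np.exp(-3.0 - 1200.0 / T5)
        fit = fit_apelblat(T5, x)
        assert fit.A == pytest.approx(-3.0, abs=1e-5)
        assert fit.B == pytest.approx(-1200.0, abs=1e-2)
        assert fit.C == pytest.approx(0.0, abs=1e-5)

    def test_normal_equations_oracle_exact_arithmetic(self):
        # solve the 3x3 normal equations with sympy rationals on a toy set
        rng = np.random.default_rng(3)
        y = 5.0 - 2000.0 / T5 - 0.5 * np.log(T5) + rng.normal(0, 0.01, 5)
        fit = fit_apelblat(T5, np.exp(y))
        Ts = [sympy.Rational(str(t)) for t in T5]
        X = sympy.Matrix([[1, 1 / t, sympy.log(t)] for t in Ts])
        yv = sympy.Matrix([sympy.Float(v, 30) for v in y])
        coef = (X.T * X).evalf(40).solve((X.T * yv).evalf(40))
        assert fit.A == pytest.approx(float(coef[0]), rel=1e-8)
        assert fit.B == pytest.approx(float(coef[1]), rel=1e-8)
        assert fit.C == pytest.approx(float(coef[2]), rel=1e-8)

    def test_condition_number_reported(self):
        fit = fit_apelblat(T5, np.exp(-3.0 - 1200.0 / T5))
        assert fit.condition_number > 1e6  # {1, 1/T, ln T} over 20 K is near-collinear

    def test_rmsd_never_worse_than_vant_hoff(self, ppn):
        # nested models fit by exact least squares on the same response
        for m in ppn.m_levels:
            T, x = ppn.level(m)
            assert fit_apelblat(T, x).rmsd_pct <= fit_vant_hoff(T, x).rmsd_pct + 1e-12


class TestYalkowsky:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [(8.44e-2, 1.31e-5, -4.12), (8.12e-2, 1.17e-5, -4.16)],
    )
    def test_printed_row_values(self, x1, x2, expected):
        # m = 0.2 row of the study's log-linear table
        pred = yalkowsky_roseman(0.2, x1, x2)
        assert round(pred.log10_x, 2) == expected

    def test_endpoint_identity(self):
        assert yalkowsky_roseman(1.0, 0.08, 1e-5).log10_x == math.log10(0.08)

    @given(m1=st.floats(0, 1), lx1=st.floats(-6, -1), lx2=st.floats(-6, -1))
    def test_bounded_by_pure_solvents(self, m1, lx1, lx2):
        pred = yalkowsky_roseman(m1, 10.0**lx1, 10.0**lx2)
        assert min(lx1, lx2) - 1e-12 <= pred.log10_x <= max(lx1, lx2) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            yalkowsky_roseman(0.5, -0.1, 1e-5)
        with pytest.raises(ValueError):
            yalkowsky_roseman(1.5, 0.1, 1e-5)


class TestJouybanAcree:
    def test_noiseless_recovery(self):
        cfg = GeneratorConfig(J=(50.0, 10.0, 0.0), noise_sigma=0.0)
        fit = fit_jouyban_acree(generate(cfg))
        assert fit.J[0] == pytest.approx(50.0, rel=1e-8)
        assert fit.J[1] == pytest.approx(10.0, rel=1e-8)
        assert fit.J[2] == 0.0
        assert set(fit.retained_terms) == {0, 1}
        assert fit.rmsd_pct == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_interaction_reduces_to_log_linear(self):
        cfg = GeneratorConfig(J=(0.0, 0.0, 0.0), noise_sigma=0.0)
        ds = generate(cfg)
        fit = fit_jouyban_acree(ds)
        assert fit.J == (0.0, 0.0, 0.0)
        grid = ds.pivot()
        for m in ds.m_levels:
            for T in ds.temperatures:
                yal = yalkowsky_roseman(m, grid.loc[1.0, T], grid.loc[0.0, T])
                assert fit.predict(m, T) == pytest.approx(yal.x, rel=1e-12)

    def test_single_term_equals_projection_oracle(self, ppn):
        # when only the i = 0 power survives, the no-intercept estimate is
        # the closed-form projection sum(w y) / sum(w^2), w = m1 m2 / T
        fit = fit_jouyban_acree(ppn)
        assert fit.retained_terms == (0,)
        grid = ppn.pivot()
        ws, ys = [], []
        for m in ppn.m_levels:
            if m in (0.0, 1.0):
                continue
            for T in ppn.temperatures:
                ws.append(m * (1 - m) / T)
                ys.append(
                    math.log(grid.loc[m, T])
                    - m * math.log(grid.loc[1.0, T])
                    - (1 - m) * math.log(grid.loc[0.0, T])
                )
        w, y = np.array(ws), np.array(ys)
        assert fit.J[0] == pytest.approx(float(w @ y / (w @ w)), rel=1e-8)

    def test_missing_pure_rows_rejected(self, ppn, masses):
        ds = SolubilityDataset(tuple(r for r in ppn.records if r.m < 1.0), masses)
        with pytest.raises(Exception, match="m = 0 and m = 1"):
            fit_jouyban_acree(ds)


class TestJAVantHoff:
    def test_stage_one_equals_pure_solvent_fits(self, ppn):
        fit = fit_ja_vant_hoff(ppn)
        T1, x1 = ppn.level(1.0)
        T2, x2 = ppn.level(0.0)
        vh1, vh2 = fit_vant_hoff(T1, x1), fit_vant_hoff(T2, x2)
        assert (fit.A1, fit.B1) == (vh1.a, vh1.b)
        assert (fit.A2, fit.B2) == (vh2.a, vh2.b)

    def test_noiseless_full_recovery(self):
        cfg = GeneratorConfig(
            A1=-0.3, B1=-700.0, A2=-4.0, B2=-2000.0, J=(30.0, -8.0, 5.0), noise_sigma=0.0
        )
        fit = fit_ja_vant_hoff(generate(cfg))
        assert fit.A1 == pytest.approx(-0.3, abs=1e-8)
        assert fit.B1 == pytest.approx(-700.0, rel=1e-8)
        assert fit.A2 == pytest.approx(-4.0, rel=1e-8)
        assert fit.B2 == pytest.approx(-2000.0, rel=1e-8)
        assert fit.J[0] == pytest.approx(30.0, rel=1e-7)
        assert fit.J[1] == pytest.approx(-8.0, rel=1e-7)
        assert fit.J[2] == pytest.approx(5.0, rel=1e-6)
        assert fit.rmsd_pct == pytest.approx(0.0, abs=1e-7)

    def test_zero_interaction_reduces_to_blended_vant_hoff(self):
        cfg = GeneratorConfig(J=(0.0,), noise_sigma=0.0)
        fit = fit_ja_vant_hoff(generate(cfg))
        assert fit.J == (0.0, 0.0, 0.0)
        for m in (0.25, 0.5, 0.75):
            for T in (300.0, 315.0):
                x1 = math.exp(fit.A1 + fit.B1 / T)
                x2 = math.exp(fit.A2 + fit.B2 / T)
                yal = yalkowsky_roseman(m, x1, x2)
                assert fit.predict(m, T) == pytest.approx(yal.x, rel=1e-12)

    def test_parameter_recovery_under_noise(self):
        # J0 estimates from replicated noisy grids scatter around the truth
        cfg0 = GeneratorConfig(J=(-16.42,), noise_sigma=0.01)
        est = []
        for seed in range(100):
            ds = generate(GeneratorConfig(J=(-16.42,), noise_sigma=0.01, seed=seed))
            est.append(fit_ja_vant_hoff(ds).J[0])
        est = np.array(est)
        se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - (-16.42)) < 3 * se
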