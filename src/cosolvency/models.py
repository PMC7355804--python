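"""Cosolvency models: Van't Hoff, Apelblat, Yalkowsky-Roseman,
Jouyban-Acree and Jouyban-Acree-Van't Hoff, with %RMSD / R^2 diagnostics.

All temperature fits regress ln x; the two mixture models add binary
interaction terms J_i * m1 * m2 * (m1 - m2)^i / T estimated by no-intercept
least squares, with insignificant powers (p > 0.05) eliminated.  R^2 is
reported on the regression (ln x) scale and %RMSD on the mole-fraction
scale, as

    %RMSD = 100 * sqrt( mean_i [ (x_obs,i - x_pred,i) / x_obs,i ]^2 ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .dataset import DatasetError, SolubilityDataset

__all__ = [
    "VantHoffFit",
    "ApelblatFit",
    "YalkowskyPrediction",
    "JouybanAcreeFit",
    "JAVantHoffFit",
    "fit_vant_hoff",
    "predict_vant_hoff",
    "fit_apelblat",
    "yalkowsky_roseman",
    "fit_jouyban_acree",
    "fit_ja_vant_hoff",
    "rmsd_percent",
    "r_squared",
]

P_DROP = 0.05  # significance threshold for interaction-term elimination


def rmsd_percent(x_obs: Sequence[float], x_pred: Sequence[float]) -> float:
    """Percent root-mean-square relative deviation between observations and predictions."""
    x_obs = np.asarray(x_obs, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    if x_obs.shape != x_pred.shape:
        raise ValueError(f"length mismatch: {x_obs.shape} vs {x_pred.shape}")
    if x_obs.size == 0:
        raise ValueError("empty series")
    if np.any(x_obs <= 0):
        raise ValueError("observed solubilities must be positive")
    return 100.0 * float(np.sqrt(np.mean(((x_obs - x_pred) / x_obs) ** 2)))


def r_squared(y_obs: Sequence[float], y_fit: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the given scale."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_obs.size < 2:
        raise ValueError("need at least two points")
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in observations")
    ss_res = float(np.sum((y_obs - y_fit) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# single-composition temperature models


@dataclass(frozen=True)
class VantHoffFit:
    """ln x = a + b/T at one solvent composition."""

    m: float
    a: float
    b: float
    r2: float
    rmsd_pct: float

    @property
    def n_coefficients(self) -> int:
        return 2

    def predict(self, T):
        return np.exp(self.a + self.b / np.asarray(T, dtype=float))


def fit_vant_hoff(T_series, x_series, m: float = math.nan) -> VantHoffFit:
    """Least-squares Van't Hoff fit of ln x on 1/T.

    Needs three or more points at distinct temperatures; R^2 is computed on
    ln x and %RMSD on back-transformed mole fractions.
    """
    T = np.asarray(T_series, dtype=float)
    x = np.asarray(x_series, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(T)) < 2:
        raise ValueError("temperatures are degenerate")
    y = np.log(x)
    b, a = np.polyfit(1.0 / T, y, 1)
    yhat = a + b / T
    return VantHoffFit(
        m=m,
        a=float(a),
        b=float(b),
        r2=r_squared(y, yhat),
        rmsd_pct=rmsd_percent(x, np.exp(yhat)),
    )


def predict_vant_hoff(fit: VantHoffFit, T):
    """Evaluate exp(a + b/T)."""
    return fit.predict(T)


@dataclass(frozen=True)
class ApelblatFit:
    """ln x = A + B/T + C ln T at one solvent composition.

    The model is linear in (A, B, C); over a narrow temperature window the
    regressors {1, 1/T, ln T} are nearly collinear, so individual
    coefficients are poorly determined even when predictions are excellent —
    ``condition_number`` records how severe this is.
    """

    m: float
    A: float
    B: float
    C: float
    r2: float
    rmsd_pct: float
    condition_number: float

    @property
    def n_coefficients(self) -> int:
        return 3

    def predict(self, T):
        T = np.asarray(T, dtype=float)
        return np.exp(self.A + self.B / T + self.C * np.log(T))


def fit_apelblat(T_series, x_series, m: float = math.nan) -> ApelblatFit:
    """Least squares of ln x on {1, 1/T, ln T} (exact for this linear-in-
    parameters model, no iterative optimisation needed)."""
    T = np.asarray(T_series, dtype=float)
    x = np.asarray(x_series, dtype=float)
    if T.size < 4:
        raise ValueError("need at least 4 points")
    X = np.column_stack([np.ones_like(T), 1.0 / T, np.log(T)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (degenerate temperatures)")
    y = np.log(x)
    # column equilibration tames the collinearity of {1, 1/T, ln T}
    norms = np.linalg.norm(X, axis=0)
    coef = np.linalg.lstsq(X / norms, y, rcond=None)[0] / norms
    yhat = X @ coef
    return ApelblatFit(
        m=m,
        A=float(coef[0]),
        B=float(coef[1]),
        C=float(coef[2]),
        r2=r_squared(y, yhat),
        rmsd_pct=rmsd_percent(x, np.exp(yhat)),
        condition_number=float(np.linalg.cond(X)),
    )


# ---------------------------------------------------------------------------
# mixture models


@dataclass(frozen=True)
class YalkowskyPrediction:
    """Log-linear blend of the two pure-solvent solubilities (no fitting)."""

    m: float
    T: float
    log10_x: float

    @property
    def x(self) -> float:
        return 10.0**self.log10_x


def yalkowsky_roseman(
    m1: float, x1: float, x2: float, T: float = math.nan
) -> YalkowskyPrediction:
    """log10 x = m1 log10 x1 + (1 - m1) log10 x2.

    ``x1``/``x2`` are the pure-cosolvent and pure-water solubilities at the
    same temperature.
    """
    if not 0.0 <= m1 <= 1.0:
        raise ValueError(f"mass fraction m1={m1} outside [0, 1]")
    if x1 <= 0 or x2 <= 0:
        raise ValueError("pure-solvent solubilities must be positive")
    return YalkowskyPrediction(
        m=m1, T=T, log10_x=m1 * math.log10(x1) + (1.0 - m1) * math.log10(x2)
    )


def _interaction_design(m1: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Columns m1 m2 (m1 - m2)^i / T for i = 0, 1, 2 (m2 = 1 - m1)."""
    m2 = 1.0 - m1
    w = m1 * m2 / T
    d = m1 - m2
    return np.column_stack([w, w * d, w * d**2])


def _fit_interaction_terms(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """No-intercept least squares of residual log-solubilities on the
    interaction columns, with backward elimination at p > 0.05.

    Returns a length-3 coefficient vector (zeros for dropped powers) and the
    retained powers.  At least one power is always retained; a perfect
    (zero-residual) fit skips the p-value screen and instead prunes powers
    whose coefficients are numerically zero.
    """
    terms = [0, 1, 2]
    scale = max(1.0, float(np.max(np.abs(y))) if y.size else 1.0)
    while True:
        res = sm.OLS(y, X[:, terms]).fit()
        if res.ssr <= 1e-20 * max(1.0, float(y @ y)):
            # exact fit: keep only numerically nonzero coefficients
            mag = np.abs(res.params)
            keep = [t for t, c in zip(terms, mag) if c > 1e-9 * max(1.0, mag.max())]
            if not keep:
                # interaction numerically zero: the log-linear limit
                return np.zeros(3), (0,)
            if keep != terms:
                terms = keep
                res = sm.OLS(y, X[:, terms]).fit()
            break
        pvals = np.asarray(res.pvalues)
        worst = int(np.argmax(pvals))
        if pvals[worst] > P_DROP and len(terms) > 1:
            terms.pop(worst)
            continue
        break
    J = np.zeros(3)
    J[terms] = res.params
    return J, tuple(terms)


def _grid_arrays(dataset: SolubilityDataset):
    dataset.require_grid(pure_endpoints=True)
    grid = dataset.to_frame().pivot(index="m", columns="T_K", values="x_e")
    Ts = np.array(grid.columns, dtype=float)
    ms = np.array(grid.index, dtype=float)
    return grid, ms, Ts


@dataclass(frozen=True)
class JouybanAcreeFit:
    """Binary interaction terms on top of measured pure-solvent solubilities.

    ln x(m, T) = m1 ln x1(T) + m2 ln x2(T) + (m1 m2 / T) sum_i J_i (m1 - m2)^i

    ``pure_lnx`` stores the measured pure-solvent log-solubilities by
    temperature so the fit can predict at any grid composition.
    """

    J: tuple[float, float, float]
    retained_terms: tuple[int, ...]
    rmsd_pct: float
    pure_lnx: Mapping[float, tuple[float, float]] = field(default_factory=dict, repr=False)

    @property
    def n_coefficients(self) -> int:
        return len(self.retained_terms)

    def predict(self, m1: float, T: float) -> float:
        if T not in self.pure_lnx:
            raise ValueError(f"no pure-solvent anchors at T={T}")
        ln1, ln2 = self.pure_lnx[T]
        m2 = 1.0 - m1
        inter = (m1 * m2 / T) * sum(J * (m1 - m2) ** i for i, J in enumerate(self.J))
        return math.exp(m1 * ln1 + m2 * ln2 + inter)


def fit_jouyban_acree(dataset: SolubilityDataset) -> JouybanAcreeFit:
    """Fit the interaction coefficients on a complete solubility grid.

    Per mixture point the residual y = ln x(m,T) - m1 ln x1(T) - m2 ln x2(T)
    is regressed (no intercept) on m1 m2 (m1-m2)^i / T for i = 0, 1, 2;
    insignificant powers are dropped and the model refit.  %RMSD is over the
    mixture points (pure rows are reproduced exactly by construction).
    """
    grid, ms, Ts = _grid_arrays(dataset)
    pure_lnx = {float(T): (math.log(grid.loc[1.0, T]), math.log(grid.loc[0.0, T])) for T in Ts}
    mix = [(m, T) for m in ms if 0.0 < m < 1.0 for T in Ts]
    if not mix:
        raise DatasetError("no mixture compositions to fit")
    m_arr = np.array([m for m, _ in mix])
    T_arr = np.array([T for _, T in mix])
    x_obs = np.array([grid.loc[m, T] for m, T in mix])
    ln_base = np.array([m * pure_lnx[T][0] + (1 - m) * pure_lnx[T][1] for m, T in mix])
    y = np.log(x_obs) - ln_base
    J, retained = _fit_interaction_terms(y, _interaction_design(m_arr, T_arr))
    fit = JouybanAcreeFit(tuple(J), retained, 0.0, pure_lnx)
    x_pred = np.array([fit.predict(m, T) for m, T in mix])
    return JouybanAcreeFit(tuple(J), retained, rmsd_percent(x_obs, x_pred), pure_lnx)


@dataclass(frozen=True)
class JAVantHoffFit:
    """Jouyban-Acree with Van't Hoff-smoothed pure-solvent terms.

    ln x(m, T) = m1 (A1 + B1/T) + m2 (A2 + B2/T)
                 + (m1 m2 / T) sum_i J_i (m1 - m2)^i

    Fully parametric in (m, T) — unlike :class:`JouybanAcreeFit` it does not
    need measured pure-solvent values at prediction time.
    """

    A1: float
    B1: float
    A2: float
    B2: float
    J: tuple[float, float, float]
    retained_terms: tuple[int, ...]
    rmsd_pct: float

    @property
    def n_coefficients(self) -> int:
        return 4 + len(self.retained_terms)

    def predict(self, m1: float, T: float) -> float:
        m2 = 1.0 - m1
        inter = (m1 * m2 / T) * sum(J * (m1 - m2) ** i for i, J in enumerate(self.J))
        return math.exp(m1 * (self.A1 + self.B1 / T) + m2 * (self.A2 + self.B2 / T) + inter)


def fit_ja_vant_hoff(dataset: SolubilityDataset) -> JAVantHoffFit:
    """Two-stage fit: pure-solvent Van't Hoff curves, then interaction terms.

    Stage 1 fits ln x = A + B/T separately on the m = 1 (cosolvent) and
    m = 0 (water) rows.  Stage 2 regresses the mixture residuals about the
    blended Van't Hoff baseline on the interaction columns exactly as in
    :func:`fit_jouyban_acree`.  %RMSD spans the whole grid, pure rows
    included, since those are now modeled rather than reproduced.
    """
    grid, ms, Ts = _grid_arrays(dataset)
    vh1 = fit_vant_hoff(Ts, grid.loc[1.0].to_numpy(), m=1.0)
    vh2 = fit_vant_hoff(Ts, grid.loc[0.0].to_numpy(), m=0.0)
    mix = [(m, T) for m in ms if 0.0 < m < 1.0 for T in Ts]
    m_arr = np.array([m for m, _ in mix])
    T_arr = np.array([T for _, T in mix])
    x_mix = np.array([grid.loc[m, T] for m, T in mix])
    base = m_arr * (vh1.a + vh1.b / T_arr) + (1 - m_arr) * (vh2.a + vh2.b / T_arr)
    y = np.log(x_mix) - base
    J, retained = _fit_interaction_terms(y, _interaction_design(m_arr, T_arr))
    fit = JAVantHoffFit(vh1.a, vh1.b, vh2.a, vh2.b, tuple(J), retained, 0.0)
    all_pts = [(m, T) for m in ms for T in Ts]
    x_obs = np.array([grid.loc[m, T] for m, T in all_pts])
    x_pred = np.array([fit.predict(m, T) for m, T in all_pts])
    return JAVantHoffFit(
        vh1.a, vh1.b, vh2.a, vh2.b, tuple(J), retained, rmsd_percent(x_obs, x_pred)
    )
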