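"""Ideal solubility, activity coefficients and mixing thermodynamics.

The ideal mole-fraction solubility of a crystalline solute follows from its
fusion properties alone:

    ln x_idl = -dH_fus (T_fus - T) / (R T_fus T)
               + (dC_p / R) [ (T_fus - T)/T + ln(T / T_fus) ]

and the solute activity coefficient is the ratio gamma_i = x_idl / x_e.
Mixing quantities for the saturated ternary solution combine the ideal
(Lewis-Randall) terms with excess terms driven by the solute's non-ideality:
G_E = R T x1 ln gamma_i, and H_E from G_E via Gibbs-Helmholtz.  Since only
the solute's activity coefficient is measurable from a solubility grid, the
solvent species are treated as ideal in the excess terms.

Entropy of mixing is recovered from the exact identity
S_mix = (H_mix - G_mix) / T, so every record satisfies G = H - T S by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .dataset import CompositionRecord, SolubilityDataset, saturated_composition

__all__ = [
    "GAS_CONSTANT",
    "FusionProperties",
    "ThermoRecord",
    "IdealMixing",
    "ideal_solubility",
    "activity_coefficient",
    "ideal_mixing",
    "excess_gibbs",
    "excess_enthalpy",
    "excess_enthalpy_fd",
    "mixing_thermo",
    "thermo_frame",
]

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class FusionProperties:
    """Fusion (melting) properties of the solute.

    Attributes
    ----------
    T_fus : float
        Fusion temperature, K.
    dH_fus : float
        Fusion enthalpy, J/mol.
    dC_p : float
        Molar heat-capacity difference between the hypothetical supercooled
        liquid and the solid, J/(mol K).
    """

    T_fus: float
    dH_fus: float
    dC_p: float

    def __post_init__(self) -> None:
        for name in ("T_fus", "dH_fus", "dC_p"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"fusion property '{name}' must be positive, got {v!r}")


class IdealMixing(NamedTuple):
    """Ideal mixing Gibbs energy (J/mol), entropy (J/(mol K)), enthalpy (J/mol)."""

    gibbs: float
    entropy: float
    enthalpy: float


@dataclass(frozen=True)
class ThermoRecord:
    """Mixing thermodynamics of one saturated (m, T) point.

    Energies in J/mol, entropies in J/(mol K).  ``H_mix_id`` is identically
    zero for an ideal solution; net terms are ideal + excess.
    """

    m: float
    T: float
    x_idl: float
    gamma_i: float
    G_mix_id: float
    H_mix_id: float
    S_mix_id: float
    G_excess: float
    H_excess: float
    G_mix: float
    H_mix: float
    S_mix: float


def ideal_solubility(T: float, fp: FusionProperties) -> float:
    """Ideal mole-fraction solubility at temperature ``T`` (K).

    Valid for 0 < T <= T_fus; equals 1 at the fusion temperature.
    """
    T = float(T)
    if not 0 < T <= fp.T_fus:
        raise ValueError(f"T={T} K outside (0, T_fus={fp.T_fus} K]")
    R = GAS_CONSTANT
    term1 = -fp.dH_fus * (fp.T_fus - T) / (R * fp.T_fus * T)
    term2 = (fp.dC_p / R) * ((fp.T_fus - T) / T + math.log(T / fp.T_fus))
    return math.exp(term1 + term2)


def activity_coefficient(x_idl: float, x_e: float) -> float:
    """Solute activity coefficient gamma_i = x_idl / x_e."""
    if not 0 < x_idl <= 1 or not 0 < x_e <= 1:
        raise ValueError(f"mole fractions must lie in (0, 1]; got {x_idl}, {x_e}")
    return x_idl / x_e


def _xlogx(x: float) -> float:
    # 0 ln 0 := 0 (limit convention)
    return 0.0 if x == 0.0 else x * math.log(x)


def ideal_mixing(comp: CompositionRecord, T: float) -> IdealMixing:
    """Ideal mixing Gibbs energy, entropy and enthalpy of a ternary composition.

    G_id = R T sum x ln x <= 0;  S_id = -R sum x ln x >= 0;  H_id = 0.
    """
    s = _xlogx(comp.x1) + _xlogx(comp.x2) + _xlogx(comp.x3)
    return IdealMixing(GAS_CONSTANT * T * s, -GAS_CONSTANT * s, 0.0)


def excess_gibbs(comp: CompositionRecord, gamma_i: float, T: float) -> float:
    """Excess Gibbs energy R T x1 ln gamma_i (solute contribution only).

    The solvent species carry no measurable activity coefficient in a
    solubility experiment and are treated as ideal.
    """
    if not gamma_i > 0:
        raise ValueError(f"gamma_i must be positive, got {gamma_i}")
    return GAS_CONSTANT * T * comp.x1 * math.log(gamma_i)


def excess_enthalpy(GE_series: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Excess enthalpy from a G_E(T) series via Gibbs-Helmholtz.

    Fits G_E/T as a linear function of 1/T over the series; under that form
    H_E = -T^2 d(G_E/T)/dT equals the fitted slope, constant in T.  Returns
    ``[(T, H_E), ...]`` aligned with the input.
    """
    if len(GE_series) < 2:
        raise ValueError("need G_E at two or more temperatures")
    T = np.array([t for t, _ in GE_series], dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("temperatures must be distinct")
    g_over_t = np.array([g for _, g in GE_series], dtype=float) / T
    slope, _ = np.polyfit(1.0 / T, g_over_t, 1)
    return [(t, float(slope)) for t in T]


def excess_enthalpy_fd(GE_series: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Finite-difference cross-check of :func:`excess_enthalpy`.

    Differentiates G_E/T against T with ``numpy.gradient`` (central
    differences in the interior) and applies H_E = -T^2 d(G_E/T)/dT
    pointwise.
    """
    if len(GE_series) < 2:
        raise ValueError("need G_E at two or more temperatures")
    pairs = sorted(GE_series)
    T = np.array([t for t, _ in pairs], dtype=float)
    g_over_t = np.array([g for _, g in pairs], dtype=float) / T
    dgdT = np.gradient(g_over_t, T)
    return list(zip(T.tolist(), (-(T**2) * dgdT).tolist()))


def mixing_thermo(dataset: SolubilityDataset, fp: FusionProperties) -> list[ThermoRecord]:
    """Full mixing-thermodynamics table for every (m, T) point of a dataset.

    Per point: saturated composition, ideal solubility, activity coefficient,
    ideal mixing terms and excess Gibbs energy; per m-level the excess
    enthalpy from the Gibbs-Helmholtz fit across that level's temperatures
    (hence at least two temperatures per level are required).  Net terms:
    G_mix = G_id + G_E, H_mix = H_E, S_mix = (H_mix - G_mix)/T.
    """
    out: list[ThermoRecord] = []
    for m in dataset.m_levels:
        T_arr, x_arr = dataset.level(m)
        if len(T_arr) < 2:
            raise ValueError(f"m={m}: need at least two temperatures per level")
        comps, gammas, xidls, ge = [], [], [], []
        for T, x_e in zip(T_arr, x_arr):
            rec = next(r for r in dataset.records if r.m == m and r.T == T)
            comp = saturated_composition(rec, dataset.molar_masses)
            x_idl = ideal_solubility(T, fp)
            gam = activity_coefficient(x_idl, x_e)
            comps.append(comp)
            xidls.append(x_idl)
            gammas.append(gam)
            ge.append(excess_gibbs(comp, gam, T))
        he = dict(excess_enthalpy(list(zip(T_arr, ge))))
        for T, comp, x_idl, gam, G_E in zip(T_arr, comps, xidls, gammas, ge):
            ideal = ideal_mixing(comp, T)
            H_E = he[T]
            G = ideal.gibbs + G_E
            H = ideal.enthalpy + H_E
            out.append(
                ThermoRecord(
                    m=m,
                    T=float(T),
                    x_idl=x_idl,
                    gamma_i=gam,
                    G_mix_id=ideal.gibbs,
                    H_mix_id=ideal.enthalpy,
                    S_mix_id=ideal.entropy,
                    G_excess=G_E,
                    H_excess=H_E,
                    G_mix=G,
                    H_mix=H,
                    S_mix=(H - G) / T,
                )
            )
    return out


def thermo_frame(records: Iterable[ThermoRecord]):
    """Thermodynamics records as a tidy DataFrame (CSV-ready)."""
    import pandas as pd

    cols = [
        "m",
        "T_K",
        "x_idl",
        "gamma_i",
        "G_mix_id",
        "S_mix_id",
        "G_excess",
        "H_excess",
        "G_mix",
        "H_mix",
        "S_mix",
    ]
    rows = [
        [
            r.m,
            r.T,
            r.x_idl,
            r.gamma_i,
            r.G_mix_id,
            r.S_mix_id,
            r.G_excess,
            r.H_excess,
            r.G_mix,
            r.H_mix,
            r.S_mix,
        ]
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)
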