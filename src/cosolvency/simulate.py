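"""Synthetic solubility grids with the statistical structure the analysis assumes.

Grids are generated from the Jouyban-Acree-Van't Hoff law

    ln x(m, T) = m1 (A1 + B1/T) + m2 (A2 + B2/T)
                 + (m1 m2 / T) sum_i J_i (m1 - m2)^i  + eps,

with eps ~ Normal(0, sigma^2) on ln x, i.e. multiplicative lognormal noise
on x — matching the relative-error structure that the percent-RMSD metric
of the downstream fits assumes.  The default configuration mirrors the
piperine / Transcutol-HP study: an 11 x 5 grid (m = 0.0-1.0 by 0.1,
T = 298.2-318.2 K by 5 K) around the study's trained coefficients, with a
1% noise scale consistent with the sub-2% model RMSDs seen on such data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .dataset import MolarMasses, SolubilityDataset, SolubilityRecord

__all__ = ["GeneratorConfig", "generate", "perturb_fixture", "load_config"]

_DEFAULT_M = tuple(round(0.1 * i, 1) for i in range(11))
_DEFAULT_T = (298.2, 303.2, 308.2, 313.2, 318.2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the generative law and the sampling grid.

    A1, B1 (A2, B2) are the Van't Hoff intercept/slope of the pure cosolvent
    (water); J holds up to three interaction coefficients (K);
    ``noise_sigma`` is the standard deviation of the Gaussian noise on ln x.
    """

    m_levels: tuple[float, ...] = _DEFAULT_M
    T_levels: tuple[float, ...] = _DEFAULT_T
    A1: float = -0.21
    B1: float = -696.21
    A2: float = -4.45
    B2: float = -2093.60
    J: tuple[float, ...] = (-16.42,)
    noise_sigma: float = 0.01
    seed: int = 0
    molar_masses: MolarMasses = field(
        default_factory=lambda: MolarMasses(285.34, 134.17, 18.07)
    )

    def __post_init__(self) -> None:
        if 0.0 not in self.m_levels or 1.0 not in self.m_levels:
            raise ValueError("m_levels must include the pure solvents 0 and 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if len(self.J) > 3:
            raise ValueError("at most three interaction coefficients")

    def log_solubility(self, m1: float, T: float) -> float:
        """Noise-free ln x at one grid point."""
        m2 = 1.0 - m1
        inter = (m1 * m2 / T) * sum(J * (m1 - m2) ** i for i, J in enumerate(self.J))
        return m1 * (self.A1 + self.B1 / T) + m2 * (self.A2 + self.B2 / T) + inter


def generate(cfg: GeneratorConfig) -> SolubilityDataset:
    """Draw one synthetic solubility grid; deterministic for a fixed seed.

    Raises if any generated mole fraction reaches 1 (the parameters then do
    not describe a dilute solubility grid), naming the offending cell.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for m in cfg.m_levels:
        for T in cfg.T_levels:
            lnx = cfg.log_solubility(m, T) + (
                rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0
            )
            x = float(np.exp(lnx))
            if x >= 1.0:
                raise ValueError(f"generated x >= 1 at (m={m}, T={T}): {x}")
            records.append(SolubilityRecord(m=m, T=T, x_e=x))
    return SolubilityDataset(tuple(records), cfg.molar_masses, ("solute", "cosolvent", "water"))


def perturb_fixture(dataset: SolubilityDataset, sigma: float, seed: int) -> SolubilityDataset:
    """Multiply each x_e by exp(eps), eps ~ Normal(0, sigma^2).

    Used for robustness checks of the fitters around a real grid; sigma = 0
    returns an identical dataset.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return dataset
    rng = np.random.default_rng(seed)
    records = []
    for r in dataset.records:
        x = float(r.x_e * np.exp(rng.normal(0.0, sigma)))
        if x >= 1.0:
            raise ValueError(f"perturbed x >= 1 at (m={r.m}, T={r.T})")
        records.append(SolubilityRecord(r.m, r.T, x, r.raw_solubility))
    return SolubilityDataset(tuple(records), dataset.molar_masses, dataset.labels)


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a GeneratorConfig from YAML or JSON."""
    path = Path(path)
    raw = (
        json.loads(path.read_text())
        if path.suffix.lower() == ".json"
        else yaml.safe_load(path.read_text())
    )
    if "m_levels" in raw:
        raw["m_levels"] = tuple(raw["m_levels"])
    if "T_levels" in raw:
        raw["T_levels"] = tuple(raw["T_levels"])
    if "J" in raw:
        raw["J"] = tuple(raw["J"])
    if "molar_masses" in raw:
        raw["molar_masses"] = MolarMasses(**raw["molar_masses"])
    return GeneratorConfig(**raw)
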