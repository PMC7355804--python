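"""Solubility data model, unit conversions and CSV I/O.

A solubility study of a solute in a binary aqueous cosolvent blend is a grid
of equilibrium measurements indexed by the cosolvent mass fraction ``m`` of
the solute-free solvent (m = 0 pure water, m = 1 pure cosolvent) and the
absolute temperature ``T``.  Measurements arrive either directly as mole
fractions or as mg of dissolved solute per gram of solvent; the conversion
between the two is plain mole bookkeeping over the three species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "MolarMasses",
    "SolubilityRecord",
    "CompositionRecord",
    "SolubilityDataset",
    "to_mole_fraction",
    "to_raw_solubility",
    "saturated_composition",
    "load_dataset",
    "save_dataset",
    "ppn_fixture",
]


class DatasetError(ValueError):
    """Raised for invalid solubility data (units, duplicates, missing cells)."""


@dataclass(frozen=True)
class MolarMasses:
    """Molar masses of the three species, g/mol.

    Attributes
    ----------
    solute, cosolvent, water : float
        Molar masses of the dissolved solute, the organic cosolvent and
        water, all in g/mol and strictly positive.
    """

    solute: float
    cosolvent: float
    water: float

    def __post_init__(self) -> None:
        for name in ("solute", "cosolvent", "water"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise DatasetError(f"molar mass '{name}' must be positive, got {v!r}")


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium measurement: mass fraction, temperature, mole fraction.

    ``raw_solubility`` optionally keeps the as-measured value in mg solute
    per g of solute-free solvent.
    """

    m: float
    T: float
    x_e: float
    raw_solubility: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise DatasetError(f"mass fraction m={self.m} outside [0, 1]")
        if not self.T > 0:
            raise DatasetError(f"temperature T={self.T} K must be positive")
        if not 0.0 < self.x_e < 1.0:
            raise DatasetError(f"mole fraction x_e={self.x_e} outside (0, 1)")
        if self.raw_solubility is not None and self.raw_solubility < 0:
            raise DatasetError("raw solubility must be nonnegative")


@dataclass(frozen=True)
class CompositionRecord:
    """Mole fractions (solute, cosolvent, water) of a saturated solution."""

    x1: float
    x2: float
    x3: float

    def __post_init__(self) -> None:
        for name, v in (("x1", self.x1), ("x2", self.x2), ("x3", self.x3)):
            if not 0.0 <= v <= 1.0:
                raise DatasetError(f"mole fraction {name}={v} outside [0, 1]")
        if abs(self.x1 + self.x2 + self.x3 - 1.0) > 1e-12:
            raise DatasetError("mole fractions must sum to 1 within 1e-12")


def to_mole_fraction(raw_mg_per_g: float, m: float, masses: MolarMasses) -> float:
    """Convert mg solute per g solvent into a mole-fraction solubility.

    The basis is 1 g of solute-free solvent split into ``m`` g cosolvent and
    ``1 - m`` g water, holding ``raw_mg_per_g`` mg of dissolved solute:

        x_e = (m1/M1) / (m1/M1 + m2/M2 + m3/M3)

    with m1 = raw/1000 g, m2 = m g, m3 = (1 - m) g.  At m = 0 or m = 1 this
    reduces to the two-species (binary) form.
    """
    if raw_mg_per_g < 0:
        raise DatasetError(f"raw solubility must be nonnegative, got {raw_mg_per_g}")
    if not 0.0 <= m <= 1.0:
        raise DatasetError(f"mass fraction m={m} outside [0, 1]")
    n1 = raw_mg_per_g * 1e-3 / masses.solute
    n2 = m / masses.cosolvent
    n3 = (1.0 - m) / masses.water
    return n1 / (n1 + n2 + n3)


def to_raw_solubility(x_e: float, m: float, masses: MolarMasses) -> float:
    """Inverse of :func:`to_mole_fraction`: mole fraction -> mg per g solvent."""
    if not 0.0 <= x_e < 1.0:
        raise DatasetError(f"mole fraction x_e={x_e} outside [0, 1)")
    if not 0.0 <= m <= 1.0:
        raise DatasetError(f"mass fraction m={m} outside [0, 1]")
    n_solvent = m / masses.cosolvent + (1.0 - m) / masses.water
    n1 = x_e / (1.0 - x_e) * n_solvent
    return n1 * masses.solute * 1e3


def saturated_composition(record: SolubilityRecord, masses: MolarMasses) -> CompositionRecord:
    """Mole fractions of all three species in the saturated solution.

    The solute takes ``x_e``; the remaining ``1 - x_e`` is split between
    cosolvent and water in their solute-free mole ratio (m/M2) : ((1-m)/M3).
    """
    n2 = record.m / masses.cosolvent
    n3 = (1.0 - record.m) / masses.water
    frac2 = n2 / (n2 + n3)
    x1 = record.x_e
    x2 = (1.0 - x1) * frac2
    x3 = (1.0 - x1) - x2
    return CompositionRecord(x1, x2, x3)


@dataclass(frozen=True)
class SolubilityDataset:
    """A collection of solubility records over (m, T) with shared molar masses."""

    records: tuple[SolubilityRecord, ...]
    molar_masses: MolarMasses
    labels: tuple[str, str, str] = ("solute", "cosolvent", "water")

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[float, float]] = set()
        for r in self.records:
            key = (r.m, r.T)
            if key in seen:
                raise DatasetError(f"duplicate record at (m={r.m}, T={r.T})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def m_levels(self) -> tuple[float, ...]:
        return tuple(sorted({r.m for r in self.records}))

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted({r.T for r in self.records}))

    def x(self, m: float, T: float) -> float:
        """Mole-fraction solubility at one grid point."""
        for r in self.records:
            if r.m == m and r.T == T:
                return r.x_e
        raise DatasetError(f"no record at (m={m}, T={T})")

    def level(self, m: float) -> tuple[np.ndarray, np.ndarray]:
        """(T, x_e) arrays at fixed mass fraction, sorted by temperature."""
        recs = sorted((r for r in self.records if r.m == m), key=lambda r: r.T)
        if not recs:
            raise DatasetError(f"no records at m={m}")
        return np.array([r.T for r in recs]), np.array([r.x_e for r in recs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": [r.m for r in self.records],
                "T_K": [r.T for r in self.records],
                "x_e": [r.x_e for r in self.records],
            }
        ).sort_values(["m", "T_K"], ignore_index=True)

    def pivot(self) -> pd.DataFrame:
        """m-by-T grid of mole fractions (requires a complete grid)."""
        self.require_grid(pure_endpoints=False)
        return self.to_frame().pivot(index="m", columns="T_K", values="x_e")

    def require_grid(self, pure_endpoints: bool = True) -> None:
        """Validate that records form a complete rectangular (m, T) grid.

        ``pure_endpoints`` additionally demands the m = 0 and m = 1 rows that
        binary mixture models need.
        """
        ms, Ts = self.m_levels, self.temperatures
        have = {(r.m, r.T) for r in self.records}
        missing = [(m, T) for m in ms for T in Ts if (m, T) not in have]
        if missing:
            raise DatasetError(f"incomplete grid; missing cells: {missing[:5]}")
        if pure_endpoints and (0.0 not in ms or 1.0 not in ms):
            raise DatasetError("mixture-model fitting needs m = 0 and m = 1 rows")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        masses: MolarMasses,
        labels: tuple[str, str, str] = ("solute", "cosolvent", "water"),
    ) -> "SolubilityDataset":
        """Build a dataset from a DataFrame with columns m, T_K and x_e or mg_per_g."""
        cols = set(df.columns)
        if not {"m", "T_K"} <= cols or not ({"x_e"} <= cols or {"mg_per_g"} <= cols):
            raise DatasetError(
                f"need columns {{m, T_K}} plus x_e or mg_per_g; got {sorted(cols)}"
            )
        records = []
        for i, row in df.iterrows():
            try:
                m = float(row["m"])
                T = float(row["T_K"])
                if "x_e" in cols and not pd.isna(row["x_e"]):
                    raw = float(row["mg_per_g"]) if "mg_per_g" in cols and not pd.isna(row.get("mg_per_g")) else None
                    x_e = float(row["x_e"])
                else:
                    raw = float(row["mg_per_g"])
                    x_e = to_mole_fraction(raw, m, masses)
                records.append(SolubilityRecord(m, T, x_e, raw))
            except (TypeError, ValueError, KeyError) as exc:
                raise DatasetError(f"row {i}: {exc}") from exc
        return cls(tuple(records), masses, labels)


def load_dataset(
    path: str | Path,
    masses: MolarMasses | None = None,
    labels: tuple[str, str, str] = ("solute", "cosolvent", "water"),
) -> SolubilityDataset:
    """Read a solubility CSV (columns ``m, T_K, x_e`` or ``m, T_K, mg_per_g``).

    Lines starting with ``#`` are comments.  When only raw mg-per-g values
    are present they are converted with ``masses`` (Table-of-materials values
    for the piperine study when not given).
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if masses is None:
        from .piperine import PIPERINE_MASSES

        masses = PIPERINE_MASSES
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DatasetError(f"could not parse {path}: {exc}") from exc
    return SolubilityDataset.from_frame(df, masses, labels)


def save_dataset(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write the dataset as a ``m, T_K, x_e`` CSV (repr precision)."""
    df = dataset.to_frame()
    with open(path, "w") as fh:
        fh.write("m,T_K,x_e\n")
        for _, row in df.iterrows():
            fh.write(f"{row['m']:g},{row['T_K']:g},{float(row['x_e'])!r}\n")


def ppn_fixture() -> SolubilityDataset:
    """The packaged piperine / Transcutol-HP / water solubility grid.

    55 records: THP mass fractions 0.0-1.0 in steps of 0.1 by temperatures
    298.2-318.2 K in steps of 5 K, as mole fractions, with the study's
    molar masses (285.34, 134.17, 18.07 g/mol).
    """
    from .piperine import PIPERINE_MASSES

    ref = resources.files("cosolvency").joinpath("data/piperine_thp_water_xe.csv")
    with resources.as_file(ref) as p:
        return load_dataset(p, PIPERINE_MASSES, ("piperine", "Transcutol-HP", "water"))
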