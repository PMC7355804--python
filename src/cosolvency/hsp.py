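"""Hansen solubility parameter (HSP) arithmetic.

The total solubility parameter of a substance combines its dispersion,
polar and hydrogen-bonding components as delta^2 = delta_d^2 + delta_p^2 +
delta_h^2 (all MPa^1/2).  A binary solvent blend takes the linear mix
delta_mix = alpha * delta_1 + (1 - alpha) * delta_2, and a solute dissolves
best in the solvent whose delta lies closest to its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = ["HSPComponents", "total_hsp", "mixture_hsp", "proximity_rank", "load_hsp_table"]


@dataclass(frozen=True)
class HSPComponents:
    """Hansen components (MPa^1/2) of a pure substance; total optional.

    Either the three components, the total, or both may be given; when both
    are present they must be Pythagorean-consistent.
    """

    delta_d: float | None = None
    delta_p: float | None = None
    delta_h: float | None = None
    delta_total: float | None = None

    def __post_init__(self) -> None:
        comps = (self.delta_d, self.delta_p, self.delta_h)
        present = [c for c in comps if c is not None]
        if len(present) not in (0, 3):
            raise ValueError("give all three Hansen components or none")
        if any(c < 0 for c in present):
            raise ValueError("Hansen components must be nonnegative")
        if self.delta_total is not None and self.delta_total < 0:
            raise ValueError("total HSP must be nonnegative")
        if len(present) == 3 and self.delta_total is not None:
            ss = sum(c * c for c in present)
            if not math.isclose(self.delta_total**2, ss, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"delta_total={self.delta_total} inconsistent with components {present}"
                )

    @property
    def total(self) -> float:
        """Total HSP: stored value, or derived from components."""
        if self.delta_total is not None:
            return self.delta_total
        return total_hsp(self)


def total_hsp(c: HSPComponents) -> float:
    """Total HSP sqrt(delta_d^2 + delta_p^2 + delta_h^2), MPa^1/2."""
    if c.delta_d is None:
        raise ValueError("Hansen components are missing; cannot derive a total")
    return math.sqrt(c.delta_d**2 + c.delta_p**2 + c.delta_h**2)


def mixture_hsp(alpha: float, delta1: float, delta2: float) -> float:
    """Linear blend of two solvent HSPs, weighted by cosolvent fraction alpha.

    ``alpha`` is nominally the cosolvent volume fraction; for water-miscible
    glycol-ether cosolvents the mass fraction is routinely used instead and
    is the convention adopted by callers in this package.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    return alpha * delta1 + (1.0 - alpha) * delta2


def proximity_rank(
    solute_delta: float, candidates: list[tuple[str, float]]
) -> list[tuple[str, float, float]]:
    """Rank candidate solvents by |delta - delta_solute|, closest first.

    Returns ``(label, delta, distance)`` triples; ties keep input order.
    """
    if not candidates:
        raise ValueError("no candidate solvents given")
    ranked = sorted(
        ((label, d, abs(d - solute_delta)) for label, d in candidates),
        key=lambda t: t[2],
    )
    return ranked


def load_hsp_table(path: str | Path) -> dict[str, HSPComponents]:
    """Read a substance -> HSP table from CSV or JSON.

    CSV columns: ``substance, delta_d, delta_p, delta_h, delta_total`` (any
    subset from which a total is derivable; blanks allowed).  JSON: a mapping
    from substance to an object with the same keys.
    """
    path = Path(path)
    table: dict[str, HSPComponents] = {}
    if path.suffix.lower() == ".json":
        for name, rec in json.loads(path.read_text()).items():
            table[name] = HSPComponents(
                rec.get("delta_d"), rec.get("delta_p"), rec.get("delta_h"), rec.get("delta_total")
            )
        return table
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if "substance" not in df.columns:
        raise ValueError("HSP CSV needs a 'substance' column")
    for _, row in df.iterrows():
        vals = {
            k: (None if k not in df.columns or pd.isna(row[k]) else float(row[k]))
            for k in ("delta_d", "delta_p", "delta_h", "delta_total")
        }
        table[str(row["substance"])] = HSPComponents(**vals)
    return table
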