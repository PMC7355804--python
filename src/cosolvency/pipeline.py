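"""End-to-end solubility analysis: conversion, thermodynamics, HSP, model
fits and model ranking, with report tables written to disk.

Report tables mirror the layout conventions of published cosolvency
studies: solubilities to 3 significant figures, log-solubilities and %RMSD
to 2 decimals, so diffs against printed tables are meaningful.  Reruns on
identical inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import models as mdl
from .dataset import SolubilityDataset
from .hsp import mixture_hsp, proximity_rank
from .thermo import FusionProperties, ThermoRecord, ideal_solubility, mixing_thermo, thermo_frame

__all__ = ["AnalysisError", "AnalysisReport", "ModelSummary", "run_analysis", "rank_models"]

MODEL_NAMES = ("vant-hoff", "apelblat", "yalkowsky-roseman", "jouyban-acree", "ja-vant-hoff")


class AnalysisError(RuntimeError):
    """A pipeline stage failed; the message names the stage and grid point."""


@dataclass(frozen=True)
class ModelSummary:
    name: str
    avg_rmsd_pct: float
    n_coefficients: int


@dataclass
class AnalysisReport:
    """All computed artifacts of one analysis run."""

    dataset_summary: dict
    ideal_solubility: dict[float, float]
    activity_coefficients: pd.DataFrame
    hsp_table: pd.DataFrame | None
    vant_hoff: list[mdl.VantHoffFit]
    apelblat: list[mdl.ApelblatFit]
    yalkowsky: pd.DataFrame
    jouyban_acree: mdl.JouybanAcreeFit | None
    ja_vant_hoff: mdl.JAVantHoffFit | None
    thermo: list[ThermoRecord]
    summaries: list[ModelSummary]
    ranking: list[str]
    warnings: list[str] = field(default_factory=list)


def rank_models(summaries: Sequence[ModelSummary]) -> list[str]:
    """Order models by average %RMSD, ties by fewer coefficients, then name."""
    if not summaries:
        raise ValueError("no models to rank")
    return [
        s.name
        for s in sorted(summaries, key=lambda s: (s.avg_rmsd_pct, s.n_coefficients, s.name))
    ]


def _sig3(x: float) -> str:
    return f"{x:.3g}" if x == 0 else f"{x:.2e}"


def run_analysis(
    dataset: SolubilityDataset,
    fusion_props: FusionProperties,
    hsp_totals: dict[str, float] | None = None,
    outdir: str | Path | None = None,
    model_names: Sequence[str] = MODEL_NAMES,
    strict: bool = False,
    checks: Sequence[str] = (),
) -> AnalysisReport:
    """Run every analysis stage in order and optionally write artifacts.

    ``hsp_totals`` maps substance labels to total Hansen parameters; the
    dataset's solute/cosolvent/water labels select which entries are used
    for blending and proximity ranking.  ``checks`` enables optional data
    cross-checks ("monotonic-T", "monotonic-m": solubility should increase
    with temperature / cosolvent fraction); violations become warnings, or
    errors under ``strict``.
    """
    if len(dataset) == 0:
        raise AnalysisError("validation: dataset is empty")
    unknown = set(model_names) - set(MODEL_NAMES)
    if unknown:
        raise AnalysisError(f"validation: unknown models {sorted(unknown)}")
    warnings: list[str] = []

    # optional data cross-checks
    grid_ok = True
    try:
        dataset.require_grid(pure_endpoints=True)
    except Exception:
        grid_ok = False
    if "monotonic-T" in checks:
        for m in dataset.m_levels:
            _, x = dataset.level(m)
            if not all(a < b for a, b in zip(x, x[1:])):
                warnings.append(f"data: x_e not increasing in T at m={m}")
    if "monotonic-m" in checks and grid_ok:
        grid = dataset.pivot()
        for T in grid.columns:
            col = grid[T].to_numpy()
            if not all(a < b for a, b in zip(col, col[1:])):
                warnings.append(f"data: x_e not increasing in m at T={T}")

    # ideal solubility and activity coefficients
    try:
        x_idl = {T: ideal_solubility(T, fusion_props) for T in dataset.temperatures}
    except ValueError as exc:
        raise AnalysisError(f"ideal-solubility: {exc}") from exc
    gamma_rows = [
        {"m": r.m, "T_K": r.T, "gamma_i": x_idl[r.T] / r.x_e}
        for r in sorted(dataset.records, key=lambda r: (r.m, r.T))
    ]
    gamma = pd.DataFrame(gamma_rows)

    # HSP stage
    hsp_df = None
    solute_lbl, cos_lbl, water_lbl = dataset.labels
    if hsp_totals is not None:
        try:
            d_solute = hsp_totals[solute_lbl]
            d1, d2 = hsp_totals[cos_lbl], hsp_totals[water_lbl]
        except KeyError as exc:
            raise AnalysisError(f"hsp: missing total HSP for {exc}") from exc
        rows = [
            {"m": m, "delta_mix": mixture_hsp(m, d1, d2)}
            for m in dataset.m_levels
        ]
        hsp_df = pd.DataFrame(rows)
        ranked = proximity_rank(
            d_solute, list(zip(hsp_df["m"].astype(str), hsp_df["delta_mix"]))
        )
        hsp_df.attrs["closest_m"] = ranked[0][0]

    # thermodynamics
    try:
        thermo = mixing_thermo(dataset, fusion_props)
    except ValueError as exc:
        raise AnalysisError(f"thermodynamics: {exc}") from exc

    # model fits
    vh_fits: list[mdl.VantHoffFit] = []
    ap_fits: list[mdl.ApelblatFit] = []
    yal = pd.DataFrame()
    ja = javh = None
    summaries: list[ModelSummary] = []
    if "vant-hoff" in model_names:
        for m in dataset.m_levels:
            T, x = dataset.level(m)
            try:
                vh_fits.append(mdl.fit_vant_hoff(T, x, m=m))
            except ValueError as exc:
                raise AnalysisError(f"vant-hoff at m={m}: {exc}") from exc
        summaries.append(
            ModelSummary(
                "vant-hoff",
                sum(f.rmsd_pct for f in vh_fits) / len(vh_fits),
                sum(f.n_coefficients for f in vh_fits),
            )
        )
    if "apelblat" in model_names:
        for m in dataset.m_levels:
            T, x = dataset.level(m)
            try:
                ap_fits.append(mdl.fit_apelblat(T, x, m=m))
            except ValueError as exc:
                raise AnalysisError(f"apelblat at m={m}: {exc}") from exc
        summaries.append(
            ModelSummary(
                "apelblat",
                sum(f.rmsd_pct for f in ap_fits) / len(ap_fits),
                sum(f.n_coefficients for f in ap_fits),
            )
        )
    mixture_models = {"yalkowsky-roseman", "jouyban-acree", "ja-vant-hoff"} & set(model_names)
    if mixture_models and not grid_ok:
        raise AnalysisError("mixture-models: dataset is not a complete grid with m=0 and m=1")
    if "yalkowsky-roseman" in model_names:
        grid = dataset.pivot()
        rows = []
        for m in dataset.m_levels:
            if m in (0.0, 1.0):
                continue
            preds = [
                mdl.yalkowsky_roseman(m, grid.loc[1.0, T], grid.loc[0.0, T], T)
                for T in dataset.temperatures
            ]
            x_obs = [grid.loc[m, T] for T in dataset.temperatures]
            rmsd = mdl.rmsd_percent(x_obs, [p.x for p in preds])
            row = {"m": m, **{f"log10_x_{p.T:g}K": p.log10_x for p in preds}, "rmsd_pct": rmsd}
            rows.append(row)
        yal = pd.DataFrame(rows)
        summaries.append(ModelSummary("yalkowsky-roseman", float(yal["rmsd_pct"].mean()), 0))
    if "jouyban-acree" in model_names:
        ja = mdl.fit_jouyban_acree(dataset)
        if ja.retained_terms != (0, 1, 2):
            warnings.append(
                f"jouyban-acree: retained interaction powers {ja.retained_terms} "
                "(insignificant terms dropped)"
            )
        summaries.append(ModelSummary("jouyban-acree", ja.rmsd_pct, ja.n_coefficients))
    if "ja-vant-hoff" in model_names:
        javh = mdl.fit_ja_vant_hoff(dataset)
        if javh.retained_terms != (0, 1, 2):
            warnings.append(
                f"ja-vant-hoff: retained interaction powers {javh.retained_terms} "
                "(insignificant terms dropped)"
            )
        summaries.append(ModelSummary("ja-vant-hoff", javh.rmsd_pct, javh.n_coefficients))

    if strict and warnings:
        raise AnalysisError("strict mode: " + "; ".join(warnings))

    report = AnalysisReport(
        dataset_summary={
            "n_records": len(dataset),
            "m_levels": list(dataset.m_levels),
            "temperatures": list(dataset.temperatures),
            "labels": list(dataset.labels),
        },
        ideal_solubility=x_idl,
        activity_coefficients=gamma,
        hsp_table=hsp_df,
        vant_hoff=vh_fits,
        apelblat=ap_fits,
        yalkowsky=yal,
        jouyban_acree=ja,
        ja_vant_hoff=javh,
        thermo=thermo,
        summaries=summaries,
        ranking=rank_models(summaries) if summaries else [],
        warnings=warnings,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Write all report artifacts (CSV tables + JSON summary) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "ideal_solubility.csv", "w") as fh:
        fh.write("T_K,x_idl\n")
        for T, x in sorted(report.ideal_solubility.items()):
            fh.write(f"{T:g},{_sig3(x)}\n")

    with open(out / "activity_coefficients.csv", "w") as fh:
        fh.write("m,T_K,gamma_i\n")
        for _, r in report.activity_coefficients.iterrows():
            fh.write(f"{r['m']:g},{r['T_K']:g},{r['gamma_i']:.4g}\n")

    if report.hsp_table is not None:
        with open(out / "hsp.csv", "w") as fh:
            fh.write("m,delta_mix\n")
            for _, r in report.hsp_table.iterrows():
                fh.write(f"{r['m']:g},{r['delta_mix']:.2f}\n")

    if report.vant_hoff:
        with open(out / "vant_hoff.csv", "w") as fh:
            fh.write("m,a,b,R2,RMSD_pct\n")
            for f in report.vant_hoff:
                fh.write(f"{f.m:g},{f.a:.4f},{f.b:.2f},{f.r2:.4f},{f.rmsd_pct:.2f}\n")

    if report.apelblat:
        with open(out / "apelblat.csv", "w") as fh:
            fh.write("m,A,B,C,R2,RMSD_pct\n")
            for f in report.apelblat:
                fh.write(
                    f"{f.m:g},{f.A:.2f},{f.B:.2f},{f.C:.2f},{f.r2:.4f},{f.rmsd_pct:.2f}\n"
                )

    if len(report.yalkowsky):
        cols = [c for c in report.yalkowsky.columns if c.startswith("log10_x_")]
        with open(out / "yalkowsky.csv", "w") as fh:
            fh.write("m," + ",".join(cols) + ",RMSD_pct\n")
            for _, r in report.yalkowsky.iterrows():
                vals = ",".join(f"{r[c]:.2f}" for c in cols)
                fh.write(f"{r['m']:g},{vals},{r['rmsd_pct']:.2f}\n")

    thermo_df = thermo_frame(report.thermo)
    thermo_df.to_csv(out / "thermodynamics.csv", index=False, float_format="%.6g")

    summary = {
        "dataset": report.dataset_summary,
        "models": {
            s.name: {"avg_rmsd_pct": round(s.avg_rmsd_pct, 2), "n_coefficients": s.n_coefficients}
            for s in report.summaries
        },
        "ranking": report.ranking,
        "warnings": report.warnings,
    }
    if report.jouyban_acree is not None:
        f = report.jouyban_acree
        summary["jouyban_acree"] = {
            "J": list(f.J),
            "retained_terms": list(f.retained_terms),
            "rmsd_pct": round(f.rmsd_pct, 2),
        }
    if report.ja_vant_hoff is not None:
        f = report.ja_vant_hoff
        summary["ja_vant_hoff"] = {
            "A1": f.A1,
            "B1": f.B1,
            "A2": f.A2,
            "B2": f.B2,
            "J": list(f.J),
            "retained_terms": list(f.retained_terms),
            "rmsd_pct": round(f.rmsd_pct, 2),
        }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
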