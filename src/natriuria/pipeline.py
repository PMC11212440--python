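"""End-to-end analysis workflow on a cohort file.

Reproduces the study's analysis tables on a real or synthetic cohort:
correlation of AM / PM / (AM+PM)/2 spot sodium with the 24h collection
(as total excretion, as concentration, and creatinine-adjusted), with
stratification by CKD stage (G1-3a vs G3b-5) and diuretic use and Fisher-Z
comparisons between strata and between sample timings; Bland-Altman
agreement, Spearman correlation and P30 for each prediction equation and
eligible timing; and sensitivity/specificity/PPV/NPV grids at the 2 and
4 g/d sodium thresholds.

All statistics are pairwise-complete: a participant enters each cell only
if every quantity the cell needs is present.  Cells with fewer than 4
complete pairs are reported as missing rather than failing, so small
cohorts still run.  The report is deterministic and invariant to the row
order of the input file (rows are sorted by participant id internally).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import (
    Participant,
    average_spot,
    creatinine_adjust,
    normalize_to_24h,
    participants_from_frame,
    read_cohort_csv,
    validate_collection,
)
from .equations import (
    IneligibleTimingError,
    estimate_intersalt,
    estimate_kawasaki,
    estimate_tanaka,
)

__all__ = ["run_analysis", "write_report", "DEFAULT_THRESHOLDS", "DEFAULT_FORMULAS"]

DEFAULT_THRESHOLDS = (2.0, 4.0)
DEFAULT_FORMULAS = ("kawasaki", "tanaka", "intersalt")
DEFAULT_STRATA = ("ckd", "diuretics")
MIN_CELL_N = 4

_ESTIMATORS = {
    "kawasaki": lambda spot, anthro: estimate_kawasaki(spot, anthro),
    "tanaka": estimate_tanaka,
    "intersalt": estimate_intersalt,
}
#: Eligible sample timings per formula (Kawasaki is AM-only by design).
_FORMULA_TIMINGS = {
    "kawasaki": ("AM",),
    "tanaka": ("AM", "PM"),
    "intersalt": ("AM", "PM"),
}

_MILD_STAGES = frozenset({"G1", "G2", "G3a"})


def _corr_cell(x: Sequence[float], y: Sequence[float]) -> Optional[dict]:
    pairs = [(a, b) for a, b in zip(x, y) if a is not None and b is not None]
    if len(pairs) < MIN_CELL_N:
        return None
    xs, ys = zip(*pairs)
    res = st.spearman_rho(xs, ys)
    if math.isnan(res.rho):
        return None
    return {"r": res.rho, "p": res.p, "n": res.n}


def _z_cell(c1: Optional[dict], c2: Optional[dict], labels) -> Optional[dict]:
    if c1 is None or c2 is None:
        return None
    try:
        z = st.fisher_z_compare(c1["r"], c1["n"], c2["r"], c2["n"], labels=labels)
    except ValueError:
        return None
    return {"z": z.z, "p": z.p, "ordering": list(z.ordering)}


def _spot_value(p: Participant, timing: str, kind: str) -> Optional[float]:
    spot = {"AM": p.am, "PM": p.pm, "AVG": average_spot(p.am, p.pm)}[timing]
    if spot is None:
        return None
    if kind == "creatinine_adjusted":
        return creatinine_adjust(spot)
    return spot.una


def run_analysis(
    cohort,
    *,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    formulas: Sequence[str] = DEFAULT_FORMULAS,
    strata: Sequence[str] = DEFAULT_STRATA,
) -> dict:
    """Run the full analysis on a cohort and return the report as a dict.

    ``cohort`` may be a path to a cohort CSV, a cohort dataframe, or a list
    of Participant records.
    """
    if isinstance(cohort, (str, Path)):
        participants = participants_from_frame(read_cohort_csv(cohort))
    elif isinstance(cohort, pd.DataFrame):
        participants = participants_from_frame(cohort)
    else:
        participants = list(cohort)
    participants = sorted(participants, key=lambda p: p.id)

    kept, excluded = [], []
    for p in participants:
        res = validate_collection(p.collection)
        if res:
            kept.append(p)
        else:
            excluded.append({"id": p.id, "reason": res.reason})

    measured = {p.id: normalize_to_24h(p.collection) for p in kept}

    report: dict = {
        "n_input": len(participants),
        "n_analyzed": len(kept),
        "excluded": excluded,
        "correlations": _correlation_tables(kept, measured, strata),
        "agreement": {},
        "classification": {},
    }

    # -- estimation-based sections ----------------------------------------
    ba_data: dict = {}
    for formula in formulas:
        report["agreement"][formula] = {}
        report["classification"][formula] = {}
        for timing in ("AM", "PM"):
            if timing not in _FORMULA_TIMINGS[formula]:
                # intentionally empty cell (e.g. Kawasaki-PM is ineligible)
                report["agreement"][formula][timing] = None
                report["classification"][formula][timing] = None
                continue
            pairs = []
            for p in kept:
                spot = p.am if timing == "AM" else p.pm
                if spot is None:
                    continue
                try:
                    est = _ESTIMATORS[formula](spot, p.anthro)
                except (ValueError, IneligibleTimingError):
                    continue
                pairs.append((measured[p.id].na_mg_d, est.na_mg_per_day))
            cell, cls_cell, ba = _agreement_cell(pairs, thresholds)
            report["agreement"][formula][timing] = cell
            report["classification"][formula][timing] = cls_cell
            if ba is not None:
                ba_data[(formula, timing)] = ba
    report["_bland_altman_data"] = ba_data  # stripped before JSON output
    return report


def _agreement_cell(pairs, thresholds):
    if len(pairs) < MIN_CELL_N:
        return None, None, None
    m = np.array([a for a, _ in pairs])
    e = np.array([b for _, b in pairs])
    ba = st.bland_altman(m, e)
    rho = st.spearman_rho(m, e)
    cell = {
        "n": ba.n,
        "mean_bias_mg_d": ba.mean_bias,
        "sd_diff_mg_d": ba.sd_diff,
        "loa_low_mg_d": ba.loa_low,
        "loa_high_mg_d": ba.loa_high,
        "bias_p": ba.bias_p,
        "rho": rho.rho,
        "rho_p": rho.p,
        "p30_pct": st.p30_precision(m, e) if np.all(m > 0) else None,
    }
    cls_cell = {}
    for t in thresholds:
        c = st.classification_metrics(m / 1000.0, e / 1000.0, t)
        cls_cell[f"{t:g}"] = {
            "threshold_g_d": t,
            "tp": c.tp,
            "fp": c.fp,
            "tn": c.tn,
            "fn": c.fn,
            "sensitivity_pct": c.sensitivity,
            "specificity_pct": c.specificity,
            "ppv_pct": c.ppv,
            "npv_pct": c.npv,
        }
    return cell, cls_cell, ba


def _correlation_tables(kept, measured, strata):
    targets = {
        "vs_24h_excretion_mmol_d": lambda p: measured[p.id].na_mmol_d,
        "vs_24h_concentration_mmol_l": lambda p: p.collection.una,
        "creatinine_adjusted_vs_24h_excretion": lambda p: measured[p.id].na_mmol_d,
    }
    tables: dict = {}
    for tname, target_of in targets.items():
        kind = "creatinine_adjusted" if tname.startswith("creatinine") else "una"
        table: dict = {}
        for timing in ("AM", "PM", "AVG"):
            xs = [_spot_value(p, timing, kind) for p in kept]
            ys = [target_of(p) for p in kept]
            col = {"all": _corr_cell(xs, ys)}
            for stratum in strata:
                groups = _split(kept, stratum)
                cells = {}
                for gname, members in groups.items():
                    gx = [_spot_value(p, timing, kind) for p in members]
                    gy = [target_of(p) for p in members]
                    cells[gname] = _corr_cell(gx, gy)
                names = list(groups)
                cells["z_between"] = _z_cell(
                    cells[names[0]], cells[names[1]], (names[0], names[1])
                )
                col[stratum] = cells
            table[timing] = col
        # Fisher-Z comparisons between sample timings on the whole cohort
        table["timing_comparisons"] = {
            "AM_vs_PM": _z_cell(table["AM"]["all"], table["PM"]["all"], ("AM", "PM")),
            "AM_vs_AVG": _z_cell(table["AM"]["all"], table["AVG"]["all"], ("AM", "AVG")),
            "AVG_vs_PM": _z_cell(table["AVG"]["all"], table["PM"]["all"], ("AVG", "PM")),
        }
        tables[tname] = table
    return tables


def _split(participants, stratum):
    if stratum == "ckd":
        return {
            "G1-3a": [p for p in participants if p.ckd_stage in _MILD_STAGES],
            "G3b-5": [p for p in participants if p.ckd_stage not in _MILD_STAGES],
        }
    if stratum == "diuretics":
        return {
            "no_diuretics": [p for p in participants if not p.diuretic_use],
            "diuretics": [p for p in participants if p.diuretic_use],
        }
    raise ValueError(f"unknown stratum {stratum!r} (expected 'ckd' or 'diuretics')")


# ---------------------------------------------------------------------------
# Report serialization


def report_json(report: dict) -> str:
    """Deterministic JSON rendering of a report (Bland-Altman arrays omitted)."""
    slim = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(slim, sort_keys=True, indent=2, allow_nan=True)


def write_report(report: dict, outdir) -> None:
    """Write report.json, flat TSV tables, and Bland-Altman plot data CSVs."""
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "blandaltman").mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_json(report) + "\n")

    rows = []
    for tname, table in report["correlations"].items():
        for timing in ("AM", "PM", "AVG"):
            col = table[timing]
            rows.append(_corr_row(tname, timing, "all", col["all"]))
            for stratum, cells in col.items():
                if stratum == "all":
                    continue
                for gname, cell in cells.items():
                    if gname == "z_between":
                        continue
                    rows.append(_corr_row(tname, timing, f"{stratum}:{gname}", cell))
    pd.DataFrame(rows).to_csv(outdir / "tables" / "correlations.tsv", sep="\t", index=False)

    agr_rows, cls_rows = [], []
    for formula, timings in report["agreement"].items():
        for timing, cell in timings.items():
            if cell is None:
                continue
            agr_rows.append({"formula": formula, "timing": timing, **cell})
            for tkey, ccell in report["classification"][formula][timing].items():
                cls_rows.append({"formula": formula, "timing": timing, **ccell})
    pd.DataFrame(agr_rows).to_csv(outdir / "tables" / "agreement.tsv", sep="\t", index=False)
    pd.DataFrame(cls_rows).to_csv(
        outdir / "tables" / "classification.tsv", sep="\t", index=False
    )

    for (formula, timing), ba in report.get("_bland_altman_data", {}).items():
        df = pd.DataFrame({"mean_mg_d": ba.means, "diff_mg_d": ba.diffs})
        df["mean_bias_mg_d"] = ba.mean_bias
        df["loa_low_mg_d"] = ba.loa_low
        df["loa_high_mg_d"] = ba.loa_high
        df.to_csv(outdir / "blandaltman" / f"{formula}_{timing}.csv", index=False)


def _corr_row(table, timing, group, cell):
    row = {"table": table, "timing": timing, "group": group}
    if cell is None:
        row.update({"r": np.nan, "p": np.nan, "n": 0})
    else:
        row.update(cell)
    return row
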