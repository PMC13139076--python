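"""Chi-square comparisons of zonated vs non-zonated cell-state counts.

For every (patient, hypothesis, nonzero level) the grid supplies two
simulated lobules — the non-zonated baseline and the zonated variant —
whose discrete cell-state counts form a contingency table.  Two table
modes mirror the published report structure:

* *overall*: 2 conditions x {healthy, necrotic, regenerated}; cells that
  are damaged but neither lysed nor regenerated count with the healthy
  (non-necrosed viable) column.
* *zonal*: 2 conditions x {necrosed, not necrosed} restricted to one zone
  (pericentral zone 3 by default), or alternatively a zone-1 vs zone-3
  necrosed comparison within the zonated run.

The Pearson statistic is computed from the margins directly; the p-value
comes from the chi-square upper tail.  No continuity correction and no
multiple-testing adjustment are applied by default, matching the raw
per-test significance stars of the publication-style tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cell_model import DAMAGED, HEALTHY, NECROSED, REGENERATED
from .errors import DegenerateTableError, InvalidParameterError
from .experiment import GridRun

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p: float
    stars: str


def significance_stars(p: float) -> str:
    """Star string per the printed legend; thresholds are strict (<)."""
    if not 0 <= p <= 1:
        raise InvalidParameterError(f"p must be in [0, 1], got {p}")
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return ""


def chi_square(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence on a counts table.

    Expected counts come from the row/column margins; zero margins make
    the test undefined and raise :class:`DegenerateTableError`.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("table must be at least 2x2")
    if np.any(obs < 0):
        raise InvalidParameterError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2.sf(stat, dof))
    return ChiSquareResult(statistic=stat, dof=dof, p=p,
                           stars=significance_stars(p))


def _test_or_blank(table: np.ndarray) -> ChiSquareResult:
    """Chi-square after dropping all-zero columns; identical or degenerate
    tables yield statistic 0 / p 1 (a blank star cell)."""
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=0) > 0
    trimmed = table[:, keep]
    if trimmed.shape[1] < 2 or np.any(trimmed.sum(axis=1) == 0):
        return ChiSquareResult(statistic=0.0, dof=1, p=1.0, stars="")
    return chi_square(trimmed)


def overall_table(baseline: GridRun, zonated: GridRun) -> np.ndarray:
    """2x3 condition x {healthy, necrotic, regenerated} counts."""
    rows = []
    for run in (baseline, zonated):
        lab = run.tally.label_totals()
        rows.append([lab[HEALTHY] + lab[DAMAGED], lab[NECROSED],
                     lab[REGENERATED]])
    return np.array(rows)


def zonal_table(baseline: GridRun, zonated: GridRun, zone: int = 3,
                contrast: str = "condition") -> np.ndarray:
    """2x2 necrosed-vs-not table.

    ``contrast='condition'`` compares baseline vs zonated within ``zone``;
    ``contrast='zone'`` compares zone 1 vs zone 3 within the zonated run.
    """
    if contrast == "condition":
        rows = []
        for run in (baseline, zonated):
            counts = run.tally.counts[zone - 1]
            nec = counts[NECROSED]
            rows.append([nec, counts.sum() - nec])
        return np.array(rows)
    if contrast == "zone":
        rows = []
        for z in (1, 3):
            counts = zonated.tally.counts[z - 1]
            nec = counts[NECROSED]
            rows.append([nec, counts.sum() - nec])
        return np.array(rows)
    raise InvalidParameterError(f"unknown contrast {contrast!r}")


def _index_runs(runs: list[GridRun]) -> dict[tuple[str, str, float], GridRun]:
    return {(r.patient.id, r.hypothesis, r.level): r for r in runs}


def build_comparison_tables(runs: list[GridRun], zone: int = 3,
                            zonal_contrast: str = "condition"):
    """Star matrices for the overall and zonal chi-square comparisons.

    Returns ``(overall, zonal, detail)``: two DataFrames of star strings
    (rows = hypotheses, columns = patient/level pairs) and a tidy detail
    frame carrying every statistic, dof, p and the underlying counts so
    each star is auditable.
    """
    index = _index_runs(runs)
    hyps = sorted({r.hypothesis for r in runs})
    pats = sorted({r.patient.id for r in runs})
    levels = sorted({r.level for r in runs if r.level > 0})
    cols = [(p, lv) for p in pats for lv in levels]

    star_overall = pd.DataFrame("", index=hyps,
                                columns=[f"{p}-{int(lv*100)}" for p, lv in cols])
    star_zonal = star_overall.copy()
    detail_rows = []
    for hyp in hyps:
        for p, lv in cols:
            base = index.get((p, hyp, 0.0))
            zon = index.get((p, hyp, lv))
            if base is None:
                raise InvalidParameterError(
                    f"missing level-0 baseline for patient {p}, {hyp}")
            if zon is None:
                continue
            col = f"{p}-{int(lv*100)}"
            t_overall = overall_table(base, zon)
            r_overall = _test_or_blank(t_overall)
            star_overall.loc[hyp, col] = r_overall.stars
            t_zonal = zonal_table(base, zon, zone=zone,
                                  contrast=zonal_contrast)
            r_zonal = _test_or_blank(t_zonal)
            star_zonal.loc[hyp, col] = r_zonal.stars
            for mode, tab, res in (("overall", t_overall, r_overall),
                                   ("zonal", t_zonal, r_zonal)):
                detail_rows.append({
                    "patient": p, "hypothesis": hyp, "level": lv,
                    "mode": mode, "statistic": res.statistic,
                    "dof": res.dof, "p": res.p, "stars": res.stars,
                    "counts": json.dumps(np.asarray(tab).astype(int).tolist()),
                })
    return star_overall, star_zonal, pd.DataFrame(detail_rows)


def export_report(runs: list[GridRun], out_dir, config=None,
                  zone: int = 3, zonal_contrast: str = "condition") -> dict:
    """CSV/JSON bundle: star tables, per-run necrosis data, manifest.

    ``fig4_overall_necrosis.csv`` holds the overall necrosed percentage
    per run (necrosed / lattice size * 100); ``fig5_zonal_necrosis.csv``
    the per-zone necrosed counts.  The manifest records the config hash so
    re-running from the same config reproduces identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    master_rows = []
    for r in runs:
        nz = r.tally.necrosed_by_zone()
        total = r.tally.total
        master_rows.append({
            "key": r.key, "patient": r.patient.id, "dose_g": r.patient.dose_g,
            "hypothesis": r.hypothesis, "level": r.level,
            "t_star_s": r.tally.t_star,
            "necrosed_total": int(nz.sum()),
            "necrosed_pct": 100.0 * nz.sum() / total if total else 0.0,
            "necrosed_z1": int(nz[0]), "necrosed_z2": int(nz[1]),
            "necrosed_z3": int(nz[2]),
            "healthy_total": int(r.tally.label_totals()[HEALTHY]),
            "damaged_total": int(r.tally.label_totals()[DAMAGED]),
            "regenerated_total": int(r.tally.label_totals()[REGENERATED]),
        })
    master_cols = ["key", "patient", "dose_g", "hypothesis", "level",
                   "t_star_s", "necrosed_total", "necrosed_pct",
                   "necrosed_z1", "necrosed_z2", "necrosed_z3",
                   "healthy_total", "damaged_total", "regenerated_total"]
    master = pd.DataFrame(master_rows, columns=master_cols)
    master.to_csv(out / "master.csv", index=False)

    if runs:
        star_overall, star_zonal, detail = build_comparison_tables(
            runs, zone=zone, zonal_contrast=zonal_contrast)
    else:
        star_overall = pd.DataFrame()
        star_zonal = pd.DataFrame()
        detail = pd.DataFrame(columns=["patient", "hypothesis", "level",
                                       "mode", "statistic", "dof", "p",
                                       "stars", "counts"])
    star_overall.to_csv(out / "table4_overall_stars.csv")
    star_zonal.to_csv(out / "table5_zonal_stars.csv")
    detail.to_csv(out / "chi_square_detail.csv", index=False)

    fig4 = master[["key", "patient", "hypothesis", "level", "necrosed_pct"]]
    fig4.to_csv(out / "fig4_overall_necrosis.csv", index=False)
    fig5 = master[["key", "patient", "hypothesis", "level",
                   "necrosed_z1", "necrosed_z2", "necrosed_z3"]]
    fig5.to_csv(out / "fig5_zonal_necrosis.csv", index=False)

    manifest = {
        "n_runs": len(runs),
        "zone": zone,
        "zonal_contrast": zonal_contrast,
        "config_hash": config.hash() if config is not None else None,
        "files": ["master.csv", "table4_overall_stars.csv",
                  "table5_zonal_stars.csv", "chi_square_detail.csv",
                  "fig4_overall_necrosis.csv", "fig5_zonal_necrosis.csv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
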