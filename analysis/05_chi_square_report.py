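#!/usr/bin/env python
"""Chi-square comparison of zonated vs non-zonated cell-state distributions.

Reconstructs the grid tallies written by 04_run_grid.py, tests every
(patient, hypothesis, level>0) cell against its level-0 baseline in both
report modes (overall state distribution; necrosed-vs-not within the
pericentral zone), and writes the star tables and figure-ready CSVs to
results/report/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import zonetox as zt
from zonetox.config import RunConfig
from zonetox.experiment import GridRun, ZoneTally
from zonetox.pbpk import patient_fixtures

RESULTS = Path(__file__).resolve().parents[1] / "results"
tallies = pd.read_csv(RESULTS / "grid_tallies.csv")
cfg = RunConfig.from_yaml(RESULTS / "grid_config.yaml")
patients = {p.id: p for p in patient_fixtures()}

runs = []
for _, row in tallies.iterrows():
    counts = np.array([[row[f"{z}_{lab}"] for lab in
                        ("healthy", "damaged", "necrosed", "regenerated")]
                       for z in ("z1", "z2", "z3")])
    runs.append(GridRun(key=row["key"], patient=patients[row["patient"]],
                        hypothesis=row["hypothesis"], level=row["level"],
                        tally=ZoneTally(counts=counts,
                                        t_star=row["t_star_h"] * 3600.0)))

manifest = zt.export_report(runs, RESULTS / "report", config=cfg)
print(f"report for {manifest['n_runs']} runs -> {RESULTS / 'report'}")

overall, zonal, _ = zt.build_comparison_tables(runs)
print("\noverall cell-state distribution, zonated vs non-zonated "
      "(columns: patient-level%):")
print(overall.to_string())
print("\npericentral (zone 3) necrosed-vs-not, zonated vs non-zonated:")
print(zonal.to_string())
print("\nblank cells: distribution indistinguishable from the non-zonated "
      "baseline; *, **, *** mark p < 0.05, 0.01, 0.001.")
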