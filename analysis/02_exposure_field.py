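#!/usr/bin/env python
"""Lobule lattice and the portal->central exposure gradient.

Builds the default 5,114-cell lattice, runs the 1-D transport surrogate
on patient D's liver input, and summarizes how peak per-cell exposure
attenuates from the periportal to the pericentral end.  Writes the zone
layout and a 21-point exposure profile to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import zonetox as zt
from zonetox.config import RunConfig

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = RunConfig()
lattice = zt.build_lattice()
sizes = lattice.zone_sizes()
print(f"lattice: {lattice.n_cells} cells, zones {sizes}")
pd.DataFrame({"zone": [1, 2, 3], "n_cells": sizes,
              "x_min": [lattice.x[lattice.zone == z].min() for z in (1, 2, 3)],
              "x_max": [lattice.x[lattice.zone == z].max() for z in (1, 2, 3)],
              }).to_csv(OUT / "lattice_zones.csv", index=False)

pat = zt.patient_fixtures()[3]
series = zt.simulate_pbpk(pat, cfg.pbpk, cfg.pbpk_dt)
field = zt.transport_exposure(series, lattice, cfg.transport,
                              scale=cfg.exposure_scale)
idx = np.linspace(0, lattice.n_cells - 1, 21).astype(int)
peaks = field.c[idx].max(axis=1)
profile = pd.DataFrame({"x": lattice.x[idx], "zone": lattice.zone[idx],
                        "peak_exposure_mol": peaks})
profile.to_csv(OUT / "exposure_profile_D.csv", index=False)
print(profile.to_string(index=False))
print(f"\nperiportal/pericentral peak-exposure ratio: "
      f"{peaks[0] / peaks[-1]:.2f} (attenuation factor "
      f"e^(uptake_loss*transit) = "
      f"{np.exp(cfg.transport.uptake_loss * cfg.transport.transit_time):.2f})")
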