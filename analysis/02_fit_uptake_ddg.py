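#!/usr/bin/env python
"""Fit HDX uptake kinetics and map the opening free-energy difference.

Reads the two simulated states, fits each peptide's %D time course,
computes the differential deuteration map with Welch tests, and converts
the slow exchange-rate ratio of matched peptides into ddG_open.  The
planted contrast (k_A = 2e-3/s vs k_B = 6e-3/s at 310.15 K) corresponds
to ddG_open(A-B) = -RT ln(k_A/k_B) = +0.68 kcal/mol: state A is the more
protected one.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from domaincoupling import hdx_uptake as hdx, io_formats as io
from domaincoupling.constants import R_KCAL, T_37C

BASE = Path(__file__).resolve().parent.parent / "results"
state_a = io.read_uptake_table(BASE / "data" / "uptake_state_A.csv")
state_b = io.read_uptake_table(BASE / "data" / "uptake_state_B.csv")

rows = []
fits_a = {s.peptide.key: hdx.fit_uptake(s, order=1) for s in state_a}
fits_b = {s.peptide.key: hdx.fit_uptake(s, order=1) for s in state_b}
for key in sorted(fits_a):
    fa, fb = fits_a[key], fits_b[key]
    dd = hdx.ddG_from_rates(fa, fb, temperature=T_37C)
    rows.append({"start": key[0], "end": key[1],
                 "k_HX_A": fa.slow_rate, "k_HX_B": fb.slow_rate,
                 "ddG_open_kcal_mol": dd.ddG_open})
fit_df = pd.DataFrame(rows)
fit_df.to_csv(BASE / "uptake_ddG.csv", index=False, float_format="%.6g")

diff = hdx.differential_map(state_a, state_b)
diff.to_csv(BASE / "differential_map.csv", index=False, float_format="%.6g")

planted = -R_KCAL * T_37C * np.log(2e-3 / 6e-3)
print(fit_df.to_string(index=False))
print(f"\nplanted ddG_open(A-B) = {planted:+.3f} kcal/mol; "
      f"recovered mean = {fit_df['ddG_open_kcal_mol'].mean():+.3f}")
sig = (diff["p_value"] < 0.05).mean()
print(f"differential map: {len(diff)} peptide-timepoints, "
      f"{100 * sig:.0f}% significant at p < 0.05 "
      f"(B deuterates faster everywhere)")
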