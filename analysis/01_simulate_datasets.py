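#!/usr/bin/env python
"""Simulate the synthetic study: two protein states across every assay.

State A stands in for a well-packed (protected) transporter and state B
for an interface-destabilized variant: B exchanges faster (larger k_HX),
unfolds faster in the EX1 regime (larger k_u), and is thermodynamically
less stable.  Writes every dataset in the CSV/PDB formats the readers
accept, under results/data/.
"""

from pathlib import Path

import numpy as np

from domaincoupling import io_formats as io, synthetic_data as sim
from domaincoupling.constants import celsius_to_kelvin

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# --- HDX uptake: 4 peptides per state, state B exchanges ~3x faster ------
for state, rate, seed in (("A", 2e-3, SEED), ("B", 6e-3, SEED + 50)):
    series = []
    for p in range(4):
        spec = sim.UptakeSimSpec(rates=(rate,), seed=seed + p)
        start = 1 + 12 * p
        series.append(sim.simulate_uptake(spec, state=state,
                                          start=start, end=start + 9))
    io.write_uptake_table(series, OUT / f"uptake_state_{state}.csv")
    print(f"uptake state {state}: 4 peptides, k_HX = {rate:g}/s")

# --- EX1 envelopes: state B unfolds ~3x faster ---------------------------
for state, k_u, seed in (("A", 1e-3, SEED + 100), ("B", 3e-3, SEED + 101)):
    spec = sim.EX1SimSpec(k_u=k_u, seed=seed)
    env = sim.simulate_ex1_envelopes(spec, state=state)
    io.write_envelope_series(env, OUT / f"envelopes_{state}",
                             manifest_name="manifest.csv")
    print(f"EX1 envelopes state {state}: k_u = {k_u:g}/s")

# --- equilibrium: urea titrations at 20-32 degC, state B destabilized ----
for state, dg0 in (("A", 3.0), ("B", 2.0)):
    for i, t_c in enumerate((20.0, 22.0, 23.0, 28.0, 32.0)):
        spec = sim.StabilitySimSpec(dG0=dg0, m_value=1.5, dG_slope_T=-0.1,
                                    noise_sd=0.005, seed=SEED + 200 + i)
        curve = sim.simulate_unfolding_curve(
            spec, np.linspace(0, 6, 13),
            temperature=celsius_to_kelvin(t_c))
        np.savetxt(OUT / f"urea_{state}_{t_c:g}C.csv",
                   np.column_stack([curve.axis_values, curve.mean_signal]),
                   delimiter=",", header="axis_value,signal", comments="")
    print(f"urea titrations state {state}: dG0(20C) = {dg0:g} kcal/mol")

# --- trajectory with two planted communities and a bridge ----------------
# frame data is bulky, so it goes under scratch/ and is regenerated on
# demand rather than versioned
TRAJ_OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
TRAJ_OUT.mkdir(parents=True, exist_ok=True)
comms = (tuple(range(30)), tuple(range(30, 60)))
spec = sim.TrajectorySimSpec(n_residues=60, n_frames=1500, communities=comms,
                             intra_corr=0.8, inter_corr=0.1,
                             bridge_pairs=((29, 30),), bridge_corr=0.6,
                             fluctuation_sd=0.5, seed=SEED + 300)
traj = sim.simulate_trajectory(spec)
io.write_trajectory_csv(traj, TRAJ_OUT / "trajectory.csv")
io.write_reference_structure(traj.residue_ids, traj.reference,
                             TRAJ_OUT / "trajectory_reference.pdb")
np.savetxt(TRAJ_OUT / "trajectory_planted_labels.csv",
           traj.meta["planted_labels"], fmt="%d",
           header="community", comments="")
print("trajectory: 60 residues x 1500 frames, 2 planted communities, "
      "bridge pair (30, 31) [1-based]")
print(f"all datasets under {OUT}")
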