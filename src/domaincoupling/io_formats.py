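"""Readers and writers for every external representation the pipeline uses.

Formats
-------
* HDX uptake CSV: columns ``state, start, end, sequence, time_s, replicate,
  percentD`` (optional ``charge``, ``temperature_k``), one row per
  replicate measurement.  Rows may alternatively carry pre-averaged means
  (``replicate_means=True``), since exported tables are sometimes means.
* Envelope manifest CSV (``state, start, end, sequence, time_s, path``)
  binding two-column (mass_offset_Da, intensity) text files to
  peptide/timepoint pairs.
* PDB for reference structures (single model, one C-alpha per residue) and
  per-residue scalar projections written to the B-factor column; multi-model
  PDB or a plain per-frame coordinate CSV (``frame, residue_id, x, y, z``)
  for trajectories.

Readers validate and reject out-of-range values with row-indexed
diagnostics; they never silently repair.
"""

from __future__ import annotations

import math
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Structure import Structure
from Bio.PDB.Model import Model
from Bio.PDB.Chain import Chain
from Bio.PDB.Residue import Residue
from Bio.PDB.Atom import Atom

from .types import (
    EnvelopeSeries,
    FormatError,
    PeptideRecord,
    TrajectoryEnsemble,
    UptakeSeries,
    ValidationError,
)

UPTAKE_COLUMNS = ["state", "start", "end", "sequence", "time_s",
                  "replicate", "percentD"]


# ---------------------------------------------------------------------------
# HDX uptake tables
# ---------------------------------------------------------------------------

def read_uptake_table(path, replicate_means: bool = False) -> list[UptakeSeries]:
    """Read an HDX uptake CSV into validated :class:`UptakeSeries`.

    Rows are grouped by (state, start, end, sequence); the per-timepoint
    replicate matrix keeps missing replicates as NaN.  With
    ``replicate_means=True`` each row is a replicate-mean export and the
    ``replicate`` column is ignored (single pseudo-replicate).
    """
    df = pd.read_csv(path)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns
               and not (replicate_means and c == "replicate")]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    bad = df.index[(df["percentD"] < 0) | (df["percentD"] > 100)].tolist()
    if bad:
        raise ValidationError(
            f"{path}: %D outside [0, 100] at row(s) {[i + 2 for i in bad]} "
            "(1-based line numbers incl. header)")
    bad_t = df.index[df["time_s"] <= 0].tolist()
    if bad_t:
        raise ValidationError(
            f"{path}: non-positive time_s at row(s) {[i + 2 for i in bad_t]}")

    out: list[UptakeSeries] = []
    for (state, start, end, seq), grp in df.groupby(
            ["state", "start", "end", "sequence"], sort=True, dropna=False):
        seq = "" if (isinstance(seq, float) and math.isnan(seq)) else str(seq)
        peptide = PeptideRecord(protein_state=str(state), start=int(start),
                                end=int(end), sequence=seq)
        times = np.sort(grp["time_s"].unique())
        if replicate_means:
            mat = np.full((times.size, 1), np.nan)
            for ti, t in enumerate(times):
                mat[ti, 0] = grp.loc[grp["time_s"] == t, "percentD"].mean()
        else:
            reps = np.sort(grp["replicate"].unique())
            rep_idx = {r: i for i, r in enumerate(reps)}
            mat = np.full((times.size, reps.size), np.nan)
            for _, row in grp.iterrows():
                ti = int(np.searchsorted(times, row["time_s"]))
                mat[ti, rep_idx[row["replicate"]]] = row["percentD"]
        temp = float(grp["temperature_k"].iloc[0]) \
            if "temperature_k" in grp.columns else 310.15
        out.append(UptakeSeries(peptide=peptide, timepoints=times,
                                percent_d=mat, temperature=temp))
    return out


def write_uptake_table(series_list: list[UptakeSeries], path) -> None:
    """Inverse of :func:`read_uptake_table` (up to float formatting)."""
    rows = []
    for s in series_list:
        for ti, t in enumerate(s.timepoints):
            for ri in range(s.percent_d.shape[1]):
                v = s.percent_d[ti, ri]
                if np.isfinite(v):
                    rows.append({"state": s.peptide.protein_state,
                                 "start": s.peptide.start,
                                 "end": s.peptide.end,
                                 "sequence": s.peptide.sequence,
                                 "time_s": t, "replicate": ri + 1,
                                 "percentD": v, "temperature_k": s.temperature})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

def read_envelope_manifest(manifest_path) -> list[EnvelopeSeries]:
    """Read a manifest CSV binding envelope text files to peptides/timepoints.

    Each referenced file holds two whitespace- or comma-separated columns
    (mass offset in Da, intensity); paths are resolved relative to the
    manifest.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = ["state", "start", "end", "sequence", "time_s", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{manifest_path}: missing column(s) {missing}")
    out = []
    for (state, start, end, seq), grp in df.groupby(
            ["state", "start", "end", "sequence"], sort=True, dropna=False):
        seq = "" if (isinstance(seq, float) and math.isnan(seq)) else str(seq)
        peptide = PeptideRecord(protein_state=str(state), start=int(start),
                                end=int(end), sequence=seq)
        grp = grp.sort_values("time_s")
        envs = []
        for _, row in grp.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = manifest_path.parent / p
            env = np.loadtxt(p, delimiter="," if p.suffix == ".csv" else None)
            envs.append(env)
        out.append(EnvelopeSeries(peptide=peptide,
                                  timepoints=grp["time_s"].to_numpy(float),
                                  envelopes=envs))
    return out


def write_envelope_series(series: EnvelopeSeries, directory,
                          manifest_name: str = "manifest.csv") -> Path:
    """Write per-timepoint envelope text files plus the binding manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    pep = series.peptide
    for t, env in zip(series.timepoints, series.envelopes):
        fname = f"{pep.protein_state}_{pep.start}_{pep.end}_t{t:g}.txt"
        np.savetxt(directory / fname, env, fmt="%.6f")
        rows.append({"state": pep.protein_state, "start": pep.start,
                     "end": pep.end, "sequence": pep.sequence,
                     "time_s": t, "path": fname})
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# PDB structures and trajectories
# ---------------------------------------------------------------------------

def _ca_coords(model) -> tuple[list[int], np.ndarray]:
    ids, xyz, missing = [], [], []
    for chain in model:
        for res in chain:
            if res.id[0] != " ":
                continue
            if "CA" in res:
                ids.append(res.id[1])
                xyz.append(res["CA"].get_coord())
            else:
                missing.append(f"{chain.id}:{res.get_resname()}{res.id[1]}")
    if missing:
        raise FormatError(f"residue(s) lacking a C-alpha atom: {missing}")
    return ids, np.asarray(xyz, dtype=float)


def read_reference_structure(path) -> tuple[list[int], np.ndarray]:
    """Read a single-model PDB into (residue_ids, C-alpha coordinates).

    Residue file order is preserved.  Multi-model files are rejected with a
    pointer to :func:`read_trajectory_pdb`.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ref", str(path))
    models = list(structure)
    if len(models) != 1:
        raise FormatError(
            f"{path}: {len(models)} models found; use read_trajectory_pdb "
            "for multi-model trajectories")
    return _ca_coords(models[0])


def read_trajectory_pdb(path, reference_path=None) -> TrajectoryEnsemble:
    """Read a multi-model PDB as a trajectory (one frame per model).

    The reference is the first model unless ``reference_path`` names a
    separate single-model PDB.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    frames, ids = [], None
    for model in structure:
        mids, xyz = _ca_coords(model)
        if ids is None:
            ids = mids
        elif mids != ids:
            raise FormatError(f"{path}: model residue sets differ")
        frames.append(xyz)
    if not frames:
        raise FormatError(f"{path}: no models found")
    if reference_path is not None:
        rids, ref = read_reference_structure(reference_path)
        if rids != ids:
            raise FormatError("reference residues differ from trajectory")
    else:
        ref = frames[0]
    return TrajectoryEnsemble(residue_ids=ids, frames=np.asarray(frames),
                              reference=ref)


def read_trajectory_csv(path, reference_path=None) -> TrajectoryEnsemble:
    """Read a plain per-frame coordinate CSV
    (columns ``frame, residue_id, x, y, z``)."""
    df = pd.read_csv(path)
    required = ["frame", "residue_id", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    frames_idx = np.sort(df["frame"].unique())
    ids = df.loc[df["frame"] == frames_idx[0], "residue_id"].tolist()
    frames = np.empty((frames_idx.size, len(ids), 3))
    for fi, f in enumerate(frames_idx):
        sub = df[df["frame"] == f].sort_index()
        if sub["residue_id"].tolist() != ids:
            raise FormatError(f"{path}: frame {f} residue set differs")
        frames[fi] = sub[["x", "y", "z"]].to_numpy(float)
    if reference_path is not None:
        rids, ref = read_reference_structure(reference_path)
        if rids != [int(i) for i in ids]:
            raise FormatError("reference residues differ from trajectory")
    else:
        ref = frames[0]
    return TrajectoryEnsemble(residue_ids=[int(i) for i in ids],
                              frames=frames, reference=ref)


def write_trajectory_csv(traj: TrajectoryEnsemble, path) -> None:
    rows = []
    for fi in range(traj.n_frames):
        for ri, rid in enumerate(traj.residue_ids):
            x, y, z = traj.frames[fi, ri]
            rows.append({"frame": fi, "residue_id": rid,
                         "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")


def _build_structure(residue_ids, coords_list, bfactors=None) -> Structure:
    structure = Structure("synthetic")
    for mi, coords in enumerate(coords_list):
        model = Model(mi)
        chain = Chain("A")
        for ri, rid in enumerate(residue_ids):
            res = Residue((" ", int(rid), " "), "GLY", "")
            b = 0.0 if bfactors is None else float(bfactors[ri])
            atom = Atom("CA", np.asarray(coords[ri], dtype=float), b, 1.0,
                        " ", " CA ", ri + 1, element="C")
            res.add(atom)
            chain.add(res)
        model.add(chain)
        structure.add(model)
    return structure


def write_reference_structure(residue_ids, coords, path) -> None:
    """Write C-alpha coordinates as a single-model synthetic PDB."""
    io = PDBIO()
    io.set_structure(_build_structure(residue_ids, [coords]))
    io.save(str(path))


def write_trajectory_pdb(traj: TrajectoryEnsemble, path) -> None:
    """Write a trajectory as a multi-model synthetic PDB."""
    io = PDBIO()
    io.set_structure(_build_structure(traj.residue_ids, list(traj.frames)))
    io.save(str(path), write_end=True)


def write_residue_projection(residue_ids, coords, values, path,
                             missing_sentinel: float = -1.0,
                             clip: tuple[float, float] = (-99.99, 999.99)) -> None:
    """Project per-residue scalars onto a structure via the B-factor column.

    ``values`` must provide one number per residue (NaN allowed for
    missing); missing values become ``missing_sentinel`` in the PDB and NaN
    in the sidecar CSV (same path with ``.csv`` appended), which keeps the
    unclipped values.  B-factors are clipped to the fixed-width PDB field.
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(residue_ids):
        raise ValidationError(
            f"{values.size} values for {len(residue_ids)} residues")
    b = np.where(np.isfinite(values),
                 np.clip(values, clip[0], clip[1]), missing_sentinel)
    io = PDBIO()
    io.set_structure(_build_structure(residue_ids, [coords], bfactors=b))
    io.save(str(path))
    pd.DataFrame({"residue_id": list(residue_ids), "value": values}) \
        .to_csv(str(path) + ".csv", index=False, float_format="%.6f")
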