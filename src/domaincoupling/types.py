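"""Validated domain containers shared by all analysis stages.

Every container checks its own invariants at construction time so the
analysis modules can assume well-formed inputs.  Residue and peptide
indexing is 1-based inclusive throughout (e.g. a peptide "a.a. 1033-1043"
has start=1033, end=1043).  Percent deuteration (%D) is stored uncorrected
for back-exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


class FormatError(ValueError):
    """An external file does not match the expected layout."""


@dataclass(frozen=True)
class PeptideRecord:
    """Identity of one proteolytic peptide within a protein state."""

    protein_state: str
    start: int
    end: int
    sequence: str = ""
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"peptide start {self.start} > end {self.end}")
        if self.sequence and len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != {self.end - self.start + 1}")
        if self.charge is not None and self.charge <= 0:
            raise ValidationError("charge must be a positive integer")

    @property
    def key(self) -> tuple[int, int, str]:
        """Match key used to pair peptides across protein states."""
        return (self.start, self.end, self.sequence)

    def label(self) -> str:
        return f"{self.protein_state}:{self.start}-{self.end}"


@dataclass
class UptakeSeries:
    """Per-peptide %D time course with replicates for one protein state.

    ``percent_d`` is a (timepoint x replicate) matrix; missing replicates
    are NaN and downstream statistics use the per-timepoint n.
    """

    peptide: PeptideRecord
    timepoints: np.ndarray          # seconds, strictly increasing
    percent_d: np.ndarray           # [timepoint, replicate], %D
    temperature: float = 310.15     # kelvin

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.percent_d = np.atleast_2d(np.asarray(self.percent_d, dtype=float))
        if self.timepoints.ndim != 1 or self.timepoints.size < 1:
            raise ValidationError("need at least one timepoint")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if self.percent_d.shape[0] != self.timepoints.size:
            raise ValidationError(
                f"percent_d has {self.percent_d.shape[0]} rows for "
                f"{self.timepoints.size} timepoints")
        finite = self.percent_d[np.isfinite(self.percent_d)]
        if np.any(finite < 0) or np.any(finite > 100):
            raise ValidationError("%D values must lie in [0, 100]")
        if np.any(np.sum(np.isfinite(self.percent_d), axis=1) < 1):
            raise ValidationError("every timepoint needs >=1 replicate")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (kelvin)")

    @property
    def n_replicates(self) -> np.ndarray:
        """Number of finite replicates per timepoint."""
        return np.sum(np.isfinite(self.percent_d), axis=1)

    @property
    def mean_d(self) -> np.ndarray:
        return np.nanmean(self.percent_d, axis=1)

    @property
    def sem_d(self) -> np.ndarray:
        n = self.n_replicates
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(self.percent_d, axis=1, ddof=1)
        return np.where(n >= 2, sd / np.sqrt(n), np.nan)


@dataclass
class EnvelopeSeries:
    """Isotope-envelope intensity distributions over labeling time.

    Each envelope is an (n_points, 2) array of (mass offset in Da,
    intensity >= 0) with strictly increasing mass offsets.
    """

    peptide: PeptideRecord
    timepoints: np.ndarray
    envelopes: list[np.ndarray]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(self.envelopes) != self.timepoints.size:
            raise ValidationError("one envelope required per timepoint")
        self.envelopes = [np.asarray(e, dtype=float) for e in self.envelopes]
        for i, env in enumerate(self.envelopes):
            if env.ndim != 2 or env.shape[1] != 2 or env.shape[0] < 5:
                raise ValidationError(
                    f"envelope {i}: need >=5 (mass_offset, intensity) rows")
            if np.any(np.diff(env[:, 0]) <= 0):
                raise ValidationError(
                    f"envelope {i}: mass offsets must be strictly increasing")
            if np.any(env[:, 1] < 0):
                raise ValidationError(f"envelope {i}: negative intensity")


DENATURANT_MOLAR = "denaturant_molar"
TEMPERATURE_KELVIN = "temperature_kelvin"


@dataclass
class UnfoldingCurve:
    """Equilibrium signal versus denaturant concentration or temperature.

    ``signal`` is (axis x replicate); for a denaturant curve ``temperature``
    records the kelvin temperature the titration was measured at.
    """

    axis_kind: str
    axis_values: np.ndarray
    signal: np.ndarray
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if self.axis_kind not in (DENATURANT_MOLAR, TEMPERATURE_KELVIN):
            raise ValidationError(f"unknown axis_kind {self.axis_kind!r}")
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] == 1 and self.axis_values.size > 1:
            self.signal = self.signal.T
        if self.axis_values.size < 6:
            raise ValidationError("need >=6 axis points")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValidationError("axis values must be strictly increasing")
        if self.signal.shape[0] != self.axis_values.size:
            raise ValidationError("signal rows must match axis points")

    @property
    def mean_signal(self) -> np.ndarray:
        return np.nanmean(self.signal, axis=1)


@dataclass
class TrajectoryEnsemble:
    """Per-frame residue (C-alpha) coordinates plus a reference structure.

    ``frames`` has shape (n_frames, n_residues, 3) in angstrom;
    ``reference`` is (n_residues, 3).  ``frame_spacing`` is metadata only
    (e.g. ns between saved frames) and never enters any computation.
    """

    residue_ids: Sequence[int]
    frames: np.ndarray
    reference: np.ndarray
    frame_spacing: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_ids = list(self.residue_ids)
        self.frames = np.asarray(self.frames, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (len(self.residue_ids), 3):
            raise ValidationError(
                f"reference shape {self.reference.shape} != "
                f"({len(self.residue_ids)}, 3)")
        if self.frames.ndim != 3 or self.frames.shape[1:] != self.reference.shape:
            raise ValidationError(
                "frames must be (n_frames, n_residues, 3) matching reference")
        if self.frames.shape[0] < 2:
            raise ValidationError("need >=2 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.reference.shape[0]
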