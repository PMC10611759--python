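"""Synthetic-data generators with planted ground truth.

Each generator is the documented inverse of the model its consumer fits:

* :func:`simulate_uptake` inverts the mono/bi-exponential HDX uptake model
  fitted by :mod:`domaincoupling.hdx_uptake`;
* :func:`simulate_ex1_envelopes` inverts the two-population (folded /
  unfolded) bimodal envelope model deconvoluted by
  :mod:`domaincoupling.ex1_kinetics`, with folded fraction
  ``F_f(t) = exp(-k_u t)``;
* :func:`simulate_unfolding_curve` inverts the two-state linear-extrapolation
  model fitted by :mod:`domaincoupling.equilibrium_stability`;
* :func:`simulate_trajectory` plants a block correlation (community)
  structure and optional native-contact loss for
  :mod:`domaincoupling.trajectory_network`.

Defaults encode the study conditions the pipeline targets: D2O labeling at
10, 240, and 1200 s at 37 degC with 3 technical replicates, Gaussian %D
noise, and urea titrations measured in the 16-32 degC range.  All
randomness flows through the explicit ``seed`` on each spec; the same seed
always reproduces the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL
from .types import (
    DENATURANT_MOLAR,
    TEMPERATURE_KELVIN,
    EnvelopeSeries,
    PeptideRecord,
    TrajectoryEnsemble,
    UnfoldingCurve,
    UptakeSeries,
    ValidationError,
)

#: D2O labeling schedule (seconds) used for full-length transporter HDX.
DEFAULT_TIMEPOINTS = (10.0, 240.0, 1200.0)

#: Extended schedule used when resolving biexponential or EX1 kinetics.
EXTENDED_TIMEPOINTS = (10.0, 60.0, 240.0, 600.0, 1200.0)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# HDX uptake
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UptakeSimSpec:
    """Planted parameters for a %D time course.

    ``amplitudes``/``rates`` hold one entry (mono-exponential: A, k_HX) or
    two (biexponential: A1, A2 with k_HX1 > k_HX2).  ``a0`` is the
    burst-phase %D labeled before the first timepoint.
    """

    a0: float = 5.0
    amplitudes: tuple[float, ...] = (70.0,)
    rates: tuple[float, ...] = (5e-3,)
    noise_sd: float = 1.5
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    temperature: float = 310.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.rates) or not 1 <= len(self.rates) <= 2:
            raise ValidationError("need 1 or 2 (amplitude, rate) pairs")
        if self.a0 + sum(self.amplitudes) > 100 + 1e-9:
            raise ValidationError("A0 + sum(amplitudes) must be <= 100 %D")
        if any(k <= 0 for k in self.rates):
            raise ValidationError("rates must be positive")
        if len(self.rates) == 2 and self.rates[0] <= self.rates[1]:
            raise ValidationError("biexponential requires k_HX1 > k_HX2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("need >=1 replicate")

    def model(self, t: np.ndarray) -> np.ndarray:
        """Noise-free %D at times ``t`` (the generative model)."""
        t = np.asarray(t, dtype=float)
        d = np.full_like(t, float(self.a0))
        for a, k in zip(self.amplitudes, self.rates):
            d = d + a * (1.0 - np.exp(-k * t))
        return d


def simulate_uptake(spec: UptakeSimSpec, state: str = "sim",
                    start: int = 1, end: int = 10) -> UptakeSeries:
    """Draw a replicated uptake series from the planted exponential model.

    %D = model(t) + N(0, noise_sd), clipped to [0, 100].
    """
    rng = _rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    clean = spec.model(t)[:, None]
    noise = rng.normal(0.0, spec.noise_sd, size=(t.size, spec.n_replicates)) \
        if spec.noise_sd > 0 else 0.0
    percent_d = np.clip(clean + noise, 0.0, 100.0)
    peptide = PeptideRecord(protein_state=state, start=start, end=end)
    return UptakeSeries(peptide=peptide, timepoints=t, percent_d=percent_d,
                        temperature=spec.temperature)


# ---------------------------------------------------------------------------
# EX1 bimodal envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EX1SimSpec:
    """Planted EX1 unfolding kinetics behind a bimodal envelope series.

    The folded population decays as F_f(t) = exp(-k_u t); each envelope is
    F_f * N(centroid_folded, width) + (1 - F_f) * N(centroid_unfolded, width)
    sampled on a regular mass-offset grid with multiplicative intensity
    noise (keeps intensities naturally non-negative at small noise; any
    residual negatives are clipped to 0).
    """

    k_u: float = 1e-3
    centroid_folded: float = 2.0
    centroid_unfolded: float = 8.0
    width: float = 1.0
    n_points: int = 81
    timepoints: tuple[float, ...] = EXTENDED_TIMEPOINTS
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.centroid_unfolded <= self.centroid_folded:
            raise ValidationError("centroid_unfolded must exceed centroid_folded")
        if self.width <= 0 or self.k_u <= 0:
            raise ValidationError("width and k_u must be positive")
        if self.n_points < 5:
            raise ValidationError("need >=5 grid points")

    def folded_fraction(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-self.k_u * np.asarray(t, dtype=float))


def _gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def simulate_ex1_envelopes(spec: EX1SimSpec, state: str = "sim",
                           start: int = 1, end: int = 10) -> EnvelopeSeries:
    rng = _rng(spec.seed)
    lo = spec.centroid_folded - 4.0 * spec.width
    hi = spec.centroid_unfolded + 4.0 * spec.width
    grid = np.linspace(lo, hi, spec.n_points)
    envelopes = []
    for t in spec.timepoints:
        ff = float(np.exp(-spec.k_u * t))
        clean = ff * _gaussian(grid, spec.centroid_folded, spec.width) \
            + (1.0 - ff) * _gaussian(grid, spec.centroid_unfolded, spec.width)
        if spec.noise_sd > 0:
            clean = clean * (1.0 + rng.normal(0.0, spec.noise_sd, grid.size))
        envelopes.append(np.column_stack([grid, np.clip(clean, 0.0, None)]))
    peptide = PeptideRecord(protein_state=state, start=start, end=end)
    return EnvelopeSeries(peptide=peptide,
                          timepoints=np.asarray(spec.timepoints, float),
                          envelopes=envelopes)


# ---------------------------------------------------------------------------
# Equilibrium unfolding curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilitySimSpec:
    """Two-state stability model with linear urea and temperature terms.

    ``dG(urea, T) = dG0 - m_value*[urea] + dG_slope_T*(T - T_ref)`` in
    kcal/mol with T in kelvin (slope per kelvin equals slope per degC).
    Baselines are (intercept, slope-per-axis-unit) pairs for the folded and
    unfolded signals.
    """

    dG0: float = 3.0                    # kcal/mol at T_ref, zero urea
    m_value: float = 1.5                # kcal/mol/M
    dG_slope_T: float = -0.2            # kcal/mol/degC
    t_ref: float = 293.15               # kelvin
    baseline_folded: tuple[float, float] = (1.0, 0.0)
    baseline_unfolded: tuple[float, float] = (0.1, 0.0)
    noise_sd: float = 0.0               # signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_value <= 0:
            raise ValidationError("m_value must be positive")

    def delta_g(self, urea: np.ndarray, temperature: float) -> np.ndarray:
        return (self.dG0 - self.m_value * np.asarray(urea, float)
                + self.dG_slope_T * (temperature - self.t_ref))

    @property
    def midpoint_urea(self) -> float:
        """Denaturant midpoint C_m = dG0/m at T_ref (f_u = 0.5)."""
        return self.dG0 / self.m_value

    @property
    def melting_temperature(self) -> float:
        """Kelvin temperature where dG crosses 0 at zero urea."""
        return self.t_ref - self.dG0 / self.dG_slope_T


def fraction_unfolded(dg: np.ndarray, temperature: float) -> np.ndarray:
    """Two-state f_u = 1 / (1 + exp(dG / RT)); dG in kcal/mol."""
    return 1.0 / (1.0 + np.exp(np.asarray(dg, float) / (R_KCAL * temperature)))


def simulate_unfolding_curve(spec: StabilitySimSpec, axis_values,
                             temperature: float = 293.15,
                             axis_kind: str = DENATURANT_MOLAR,
                             n_replicates: int = 1) -> UnfoldingCurve:
    """Simulate a urea titration or a thermal melt.

    For a denaturant axis the curve is measured at fixed ``temperature``;
    for a temperature axis (kelvin values) urea is zero and the transition
    midpoint sits at ``spec.melting_temperature``.
    """
    rng = _rng(spec.seed)
    axis = np.asarray(axis_values, dtype=float)
    if axis_kind == DENATURANT_MOLAR:
        dg = spec.delta_g(axis, temperature)
        f_u = fraction_unfolded(dg, temperature)
        base_f = spec.baseline_folded[0] + spec.baseline_folded[1] * axis
        base_u = spec.baseline_unfolded[0] + spec.baseline_unfolded[1] * axis
    elif axis_kind == TEMPERATURE_KELVIN:
        dg = spec.dG0 + spec.dG_slope_T * (axis - spec.t_ref)
        f_u = np.array([float(fraction_unfolded(g, t)) for g, t in zip(dg, axis)])
        base_f = spec.baseline_folded[0] + spec.baseline_folded[1] * axis
        base_u = spec.baseline_unfolded[0] + spec.baseline_unfolded[1] * axis
        temperature = float(np.mean(axis))
    else:
        raise ValidationError(f"unknown axis_kind {axis_kind!r}")
    clean = base_f + f_u * (base_u - base_f)
    signal = np.repeat(clean[:, None], n_replicates, axis=1)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    return UnfoldingCurve(axis_kind=axis_kind, axis_values=axis,
                          signal=signal, temperature=temperature)


# ---------------------------------------------------------------------------
# Residue trajectories with planted community structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactLoss:
    """Break native contacts by displacing ``residues`` (0-based indices
    into the trajectory) by ``displacement`` angstrom along +z for every
    frame index >= ``after_frame``."""

    residues: tuple[int, ...]
    after_frame: int = 0
    displacement: float = 100.0


@dataclass(frozen=True)
class TrajectorySimSpec:
    """Planted correlated-motion structure for a residue trajectory.

    Residue displacements are drawn, independently per cartesian axis, from
    a zero-mean Gaussian whose residue-residue correlation matrix is
    ``intra_corr`` within each community block, ``inter_corr`` between
    blocks, and ``bridge_corr`` on the listed bridge pairs.  The reference
    structure lays residues along a compact 3-D lattice walk (consecutive
    residues adjacent), so contiguous communities occupy contiguous space.
    """

    n_residues: int = 60
    n_frames: int = 2000
    communities: tuple[tuple[int, ...], ...] = ()
    intra_corr: float = 0.8
    inter_corr: float = 0.1
    bridge_pairs: tuple[tuple[int, int], ...] = ()
    bridge_corr: float = 0.6
    fluctuation_sd: float = 0.5          # angstrom per axis
    lattice_spacing: float = 3.8         # angstrom, C-alpha like
    contact_loss: ContactLoss | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.inter_corr < self.intra_corr < 1):
            raise ValidationError("need 0 <= inter_corr < intra_corr < 1")
        if self.communities:
            flat = sorted(r for c in self.communities for r in c)
            if flat != list(range(self.n_residues)):
                raise ValidationError(
                    "communities must partition residues 0..n_residues-1")
        if self.fluctuation_sd <= 0:
            raise ValidationError("fluctuation_sd must be positive")

    def community_labels(self) -> np.ndarray:
        """Planted community id per residue (all zeros when unpartitioned)."""
        labels = np.zeros(self.n_residues, dtype=int)
        for cid, members in enumerate(self.communities):
            labels[list(members)] = cid
        return labels


def _lattice_walk(n: int, spacing: float) -> np.ndarray:
    """Boustrophedon walk through a near-cubic grid; consecutive points are
    one lattice spacing apart so index-contiguous blocks are compact."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    coords = []
    for z in range(side):
        for yy in range(side):
            y = yy if z % 2 == 0 else side - 1 - yy
            for xx in range(side):
                fwd = (z * side + yy) % 2 == 0
                x = xx if fwd else side - 1 - xx
                coords.append((x, y, z))
                if len(coords) == n:
                    return np.asarray(coords, dtype=float) * spacing
    return np.asarray(coords[:n], dtype=float) * spacing


def planted_correlation_matrix(spec: TrajectorySimSpec) -> tuple[np.ndarray, dict]:
    """Target residue-residue correlation matrix, made positive definite by
    eigenvalue clipping and diagonal renormalization when needed."""
    n = spec.n_residues
    if spec.communities:
        labels = spec.community_labels()
        same = labels[:, None] == labels[None, :]
        corr = np.where(same, spec.intra_corr, spec.inter_corr)
    else:
        # no planted blocks: residues share only the background correlation
        corr = np.full((n, n), spec.inter_corr)
    for i, j in spec.bridge_pairs:
        corr[i, j] = corr[j, i] = spec.bridge_corr
    np.fill_diagonal(corr, 1.0)

    eigvals = np.linalg.eigvalsh(corr)
    report = {"min_eigenvalue": float(eigvals.min()), "clipped": False,
              "max_adjustment": 0.0}
    if eigvals.min() < -0.5:
        raise ValidationError(
            f"planted correlation matrix is severely indefinite (min "
            f"eigenvalue {eigvals.min():.3g}); reduce intra/inter/bridge "
            "contrasts")
    if eigvals.min() < 1e-8:
        target = corr
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 1e-6, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        report["clipped"] = True
        report["max_adjustment"] = float(np.max(np.abs(corr - target)))
    return corr, report


def simulate_trajectory(spec: TrajectorySimSpec) -> TrajectoryEnsemble:
    """Draw a trajectory with planted correlation-block structure.

    Returns a :class:`TrajectoryEnsemble` whose ``meta`` carries the
    planted community labels and the positive-definiteness report so
    recovery tests can compare against ground truth.
    """
    rng = _rng(spec.seed)
    corr, report = planted_correlation_matrix(spec)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(spec.n_residues))
    reference = _lattice_walk(spec.n_residues, spec.lattice_spacing)
    frames = np.empty((spec.n_frames, spec.n_residues, 3))
    for axis in range(3):
        z = rng.standard_normal((spec.n_frames, spec.n_residues))
        frames[:, :, axis] = reference[None, :, axis] \
            + spec.fluctuation_sd * (z @ chol.T)
    if spec.contact_loss is not None:
        cl = spec.contact_loss
        frames[cl.after_frame:, list(cl.residues), 2] += cl.displacement
    return TrajectoryEnsemble(
        residue_ids=list(range(1, spec.n_residues + 1)),
        frames=frames,
        reference=reference,
        meta={"planted_labels": spec.community_labels(),
              "planted_correlation": corr,
              "correlation_report": report,
              "spec": spec},
    )
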