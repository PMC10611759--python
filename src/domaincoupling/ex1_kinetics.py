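"""EX1 kinetics: bimodal envelope deconvolution and Eyring energetics.

In the EX1 exchange regime a cooperative unfolding event labels all amides
of a segment at once, so the isotope envelope of a peptide splits into a
low-mass (folded, protected) and a high-mass (unfolded, exchanged)
population whose relative areas interconvert with labeling time.  The
folded fraction decays as

    ln F_f(t) = -k_u * t           (fit through the origin)

and the unfolding rate maps to an activation free energy through the
Eyring relation

    k_u = (k_B*T/h) * exp(-dG_act / (R*T)).

Differences between two states use ddG_act(B-A) = -R*T*ln(k_u(B)/k_u(A)),
positive when state B unfolds slower (higher barrier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import H_PLANCK, K_B, R_KCAL
from .types import EnvelopeSeries, PeptideRecord, ValidationError

#: F_f below this is treated as fully unfolded when fitting ln F_f
#: (log blow-up guard).
FF_FLOOR = 0.02


class DeconvolutionError(RuntimeError):
    """Joint bimodal fit failed to converge."""


@dataclass
class BimodalFit:
    """Two-Gaussian mixture deconvolution of an envelope series.

    Centroids and widths are shared across timepoints (joint fit); the
    per-timepoint mixing fraction ``folded_fraction`` is the area share of
    the low-mass (folded) component.
    """

    peptide: PeptideRecord
    timepoints: np.ndarray
    folded_fraction: np.ndarray
    centroid_folded: float
    centroid_unfolded: float
    width_folded: float
    width_unfolded: float
    residual: float
    per_timepoint: bool = False

    def __post_init__(self) -> None:
        self.folded_fraction = np.asarray(self.folded_fraction, dtype=float)
        if np.any(self.folded_fraction < -1e-9) or np.any(self.folded_fraction > 1 + 1e-9):
            raise ValidationError("F_f must lie in [0, 1]")
        if self.centroid_unfolded <= self.centroid_folded:
            raise ValidationError("centroid_unfolded must exceed centroid_folded")


@dataclass
class UnfoldingKineticsFit:
    """Origin-constrained ln F_f decay and its Eyring activation energy."""

    peptide: PeptideRecord
    k_u: float                  # 1/s
    dG_act: float               # kcal/mol
    temperature: float          # kelvin
    n_points: int
    rss: float
    k_B: float = K_B
    h: float = H_PLANCK
    R: float = R_KCAL


@dataclass
class ActivationDifference:
    """Unfolding activation-energy difference between two states."""

    ddG_act: float              # kcal/mol, -R*T*ln(k_u_B / k_u_A)
    k_u_a: float
    k_u_b: float
    temperature: float


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def _normalize(env: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y = env[:, 0], env[:, 1]
    area = np.trapezoid(y, x)
    if area <= 0:
        raise ValidationError("envelope has zero total intensity")
    return x, y / area


def _moments(env: np.ndarray) -> tuple[float, float]:
    x, y = _normalize(env)
    w = y / np.trapezoid(y, x)
    mu = np.trapezoid(w * x, x)
    var = max(np.trapezoid(w * (x - mu) ** 2, x), 1e-6)
    return float(mu), float(np.sqrt(var))


def deconvolute_envelope(env: EnvelopeSeries,
                         shared_shapes: bool = True) -> BimodalFit:
    """Deconvolute a bimodal envelope series into folded fractions.

    Fits a two-Gaussian mixture to every (area-normalized) envelope with
    centroids and widths shared across timepoints, which stabilizes the fit
    when individual spectra are nearly unimodal.  ``shared_shapes=False``
    fits each timepoint independently and reports median shapes
    (diagnostic mode).  Unimodal series resolve with the absent component's
    weight at the 0/1 bound.
    """
    if env.timepoints.size < 2:
        raise ValidationError("need >=2 timepoints for EX1 deconvolution")
    grids, ys = zip(*(_normalize(e) for e in env.envelopes))
    mu_first, sd_first = _moments(env.envelopes[0])
    mu_last, sd_last = _moments(env.envelopes[-1])
    lo = min(g.min() for g in grids)
    hi = max(g.max() for g in grids)
    span = hi - lo
    sd0 = float(np.clip(0.5 * (sd_first + sd_last), 1e-3, span))

    n_t = env.timepoints.size

    def unpack(p):
        cf, gap, wf, wu = p[:4]
        ff = p[4:]
        return cf, cf + gap, wf, wu, ff

    def resid(p):
        cf, cu, wf, wu, ff = unpack(p)
        out = []
        for f, x, y in zip(ff, grids, ys):
            model = f * _gauss(x, cf, wf) + (1 - f) * _gauss(x, cu, wu)
            out.append(model - y)
        return np.concatenate(out)

    # mixture-moment initial folded fractions from per-envelope centroids
    denom = max(mu_last - mu_first, 1e-6)
    ff0 = np.clip([(mu_last - _moments(e)[0]) / denom for e in env.envelopes],
                  0.02, 0.98)
    starts = []
    for frac in (0.25, 0.5):
        cf0 = lo + frac * 0.5 * span
        cu0 = hi - frac * 0.5 * span
        starts.append(np.concatenate([[cf0, max(cu0 - cf0, 1e-3), sd0, sd0], ff0]))
    starts.append(np.concatenate([[mu_first, max(mu_last - mu_first, 1e-3),
                                   sd0, sd0], ff0]))

    lb = np.concatenate([[lo, 1e-4, 1e-4, 1e-4], np.zeros(n_t)])
    ub = np.concatenate([[hi, span, span, span], np.ones(n_t)])
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb + 1e-9, ub - 1e-9)
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lb, ub),
                                         xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DeconvolutionError(
            f"joint bimodal fit failed for {env.peptide.label()}")

    cf, cu, wf, wu, ff = unpack(best.x)
    ff = np.clip(np.asarray(ff), 0.0, 1.0)
    # label canonicalization: with an (effectively) unimodal series the
    # optimizer may park all weight on the "unfolded" component.  When the
    # folded component is essentially absent and the envelope centroid does
    # not drift up-mass over time (no EX1 conversion), the single static
    # population is the protected/folded one.
    drift = _moments(env.envelopes[-1])[0] - mu_first
    if np.mean(ff) < 0.05 and abs(cu - mu_first) < abs(cf - mu_first) \
            and drift < 0.5 * wu:
        ff = 1.0 - ff
        cf, cu = cu, cf
        wf, wu = wu, wf
        if cu <= cf:  # the absent component's position is unidentifiable
            cu = cf + 4.0 * wf
            wu = wf
    if not shared_shapes:
        # per-timepoint refit, seeded from the joint solution
        ffs, cfs, cus, wfs, wus = [], [], [], [], []
        for x, y in zip(grids, ys):
            def r1(p):
                return p[4] * _gauss(x, p[0], p[2]) \
                    + (1 - p[4]) * _gauss(x, p[0] + p[1], p[3]) - y
            s = optimize.least_squares(
                r1, [cf, cu - cf, wf, wu, 0.5],
                bounds=([lo, 1e-4, 1e-4, 1e-4, 0], [hi, span, span, span, 1]))
            cfs.append(s.x[0]); cus.append(s.x[0] + s.x[1])
            wfs.append(s.x[2]); wus.append(s.x[3]); ffs.append(s.x[4])
        return BimodalFit(env.peptide, env.timepoints, np.asarray(ffs),
                          float(np.median(cfs)), float(np.median(cus)),
                          float(np.median(wfs)), float(np.median(wus)),
                          float(best.cost), per_timepoint=True)
    return BimodalFit(env.peptide, env.timepoints, ff, float(cf), float(cu),
                      float(wf), float(wu), float(best.cost))


def is_bimodal(env: np.ndarray, dip_fraction: float = 0.1) -> bool:
    """Convention-flagged bimodality call: True when the intensity between
    the two largest well-separated local maxima dips below
    ``(1 - dip_fraction)`` of the smaller maximum.  The threshold is a
    convention, not a measured property of any instrument."""
    x, y = _normalize(env)
    peaks = [i for i in range(1, len(y) - 1)
             if y[i] >= y[i - 1] and y[i] >= y[i + 1]]
    if len(peaks) < 2:
        return False
    peaks = sorted(peaks, key=lambda i: y[i], reverse=True)[:2]
    i, j = sorted(peaks)
    valley = y[i:j + 1].min()
    return valley < (1.0 - dip_fraction) * min(y[i], y[j])


def eyring_dG(k_u: float, temperature: float) -> float:
    """Activation free energy (kcal/mol) from a rate via Eyring."""
    return R_KCAL * temperature * np.log(K_B * temperature / (H_PLANCK * k_u))


def eyring_rate(dG_act: float, temperature: float) -> float:
    """Inverse of :func:`eyring_dG` (exact bijection)."""
    return K_B * temperature / H_PLANCK * np.exp(-dG_act / (R_KCAL * temperature))


def fit_unfolding_rate(fit: BimodalFit,
                       temperature: float = 310.15,
                       through_origin: bool = True) -> UnfoldingKineticsFit:
    """Unfolding rate from the folded-fraction decay.

    Least-squares fit of ln F_f = -k_u * t constrained through the origin
    (the decay law has no intercept).  Points with F_f <= 0.02 are excluded
    (log blow-up guard); an unconstrained variant is available for
    diagnostics only.  Raises when no usable points remain ("no EX1
    signal").
    """
    t = np.asarray(fit.timepoints, dtype=float)
    ff = np.asarray(fit.folded_fraction, dtype=float)
    keep = ff > FF_FLOOR
    t, ff = t[keep], ff[keep]
    if t.size < 2 or np.all(ff >= 1.0 - 1e-12):
        raise ValidationError("no EX1 signal: folded fractions at bounds")
    ln_ff = np.log(ff)
    if through_origin:
        denom = float(np.sum(t * t))
        if denom == 0:
            raise ValidationError("need a nonzero timepoint")
        k_u = float(-np.sum(t * ln_ff) / denom)
        rss = float(np.sum((ln_ff + k_u * t) ** 2))
    else:
        slope, intercept = np.polyfit(t, ln_ff, 1)
        k_u = float(-slope)
        rss = float(np.sum((ln_ff - (slope * t + intercept)) ** 2))
    if k_u <= 0:
        raise ValidationError("fitted unfolding rate is non-positive")
    return UnfoldingKineticsFit(peptide=fit.peptide, k_u=k_u,
                                dG_act=float(eyring_dG(k_u, temperature)),
                                temperature=temperature, n_points=int(t.size),
                                rss=rss)


def ddG_activation(fit_a: UnfoldingKineticsFit,
                   fit_b: UnfoldingKineticsFit) -> ActivationDifference:
    """Activation-energy difference; positive when state B unfolds slower."""
    if not np.isclose(fit_a.temperature, fit_b.temperature):
        raise ValidationError(
            f"temperature mismatch: {fit_a.temperature} K vs "
            f"{fit_b.temperature} K")
    ddg = -R_KCAL * fit_a.temperature * np.log(fit_b.k_u / fit_a.k_u)
    return ActivationDifference(ddG_act=float(ddg), k_u_a=fit_a.k_u,
                                k_u_b=fit_b.k_u,
                                temperature=fit_a.temperature)
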