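"""Two-state equilibrium stability analysis.

Urea titrations are analyzed with the linear extrapolation method: the
fraction unfolded at each denaturant concentration gives an equilibrium
constant K = f_u / (1 - f_u) and a pointwise free energy

    dG([urea]) = -R*T*ln(K) = dG0 - m * [urea]

whose zero-urea intercept is the folding free energy at the measurement
temperature.  Per-temperature dG0 values (20-32 degC range) are then
extrapolated linearly to 37 degC.  Unfolding kinetics follow the same
pattern in log-rate space, log k_u = log k_u^H2O + m_ku * [urea], with the
water-extrapolated rates themselves extrapolated to 37 degC and converted
to an activation energy both via dG_act = -R*T*ln(k_u) (the convention
used in the source analyses, lacking the transmission prefactor) and via
the full Eyring relation; the two differ by exactly R*T*ln(k_B*T/h).
Thermal melts are fitted to a four-parameter Boltzmann sigmoid with T_m at
the inflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import H_PLANCK, K_B, R_KCAL, T_37C, celsius_to_kelvin, kelvin_to_celsius
from .types import DENATURANT_MOLAR, TEMPERATURE_KELVIN, UnfoldingCurve, ValidationError

#: fraction-unfolded window admitted to the pointwise dG fit
#: (log-odds blow-up guard outside it).
FU_WINDOW = (0.05, 0.95)


@dataclass
class UreaFit:
    """Linear-extrapolation fit of one urea titration."""

    dG0: float                   # kcal/mol, zero-urea intercept
    m_value: float               # kcal/mol/M
    temperature: float           # kelvin
    baselines: tuple[tuple[float, float], tuple[float, float]]
    urea: np.ndarray             # points admitted to the dG fit
    dG_points: np.ndarray        # pointwise -RT ln K at those points
    rss: float


@dataclass
class StabilityEstimate:
    """dG0 extrapolated to a target temperature from per-temperature fits."""

    dG0_target: float
    target_temperature: float    # kelvin
    slope: float                 # kcal/mol per degC
    intercept: float             # kcal/mol at 0 degC
    temperatures: np.ndarray     # kelvin
    dG0_values: np.ndarray
    prediction_interval: tuple[float, float]
    confidence: float = 0.95


@dataclass
class RateExtrapolation:
    """Unfolding rates extrapolated to water and to a target temperature."""

    log10_ku_water: dict         # temperature (K) -> log10 k_u^H2O
    m_ku: dict                   # temperature (K) -> log10-slope per M
    k_u_target: float            # 1/s at target temperature
    target_temperature: float
    dG_act_simple: float         # -R*T*ln(k_u), kcal/mol
    dG_act_eyring: float         # R*T*ln(kB*T/(h*k_u)), kcal/mol
    slope: float                 # log10 k_u^H2O per degC
    intercept: float
    warnings: list = field(default_factory=list)


@dataclass
class MeltCurveFit:
    """Four-parameter Boltzmann sigmoid fit of a thermal melt."""

    t_m: float                   # degC (inflection)
    slope: float                 # degC transition width parameter
    baseline_pre: float
    baseline_post: float
    rss: float

    def model(self, t_c: np.ndarray) -> np.ndarray:
        t_c = np.asarray(t_c, dtype=float)
        return self.baseline_pre + (self.baseline_post - self.baseline_pre) \
            / (1.0 + np.exp((self.t_m - t_c) / self.slope))


def _two_state_model(x, bf0, bf1, bu0, bu1, dg0, m, rt):
    fu = 1.0 / (1.0 + np.exp((dg0 - m * x) / rt))
    return (bf0 + bf1 * x) + fu * ((bu0 + bu1 * x) - (bf0 + bf1 * x))


def fit_urea_unfolding(curve: UnfoldingCurve,
                       linear_baselines: bool = False,
                       fixed_m: float | None = None) -> UreaFit:
    """Fit one urea titration by linear extrapolation.

    A global two-state fit supplies the folded/unfolded baselines
    (constant by default; ``linear_baselines`` adds slopes for drifting
    signals); the fraction unfolded is then computed pointwise, converted
    to dG = -R*T*ln(f_u/(1-f_u)), and fitted linearly in [urea] with
    delta-method weights.  Points with f_u outside [0.05, 0.95] are
    excluded from the linear fit.  With ``fixed_m`` the slope is
    constrained and only the intercept fitted.  Raises when the curve
    shows no transition inside the sampled range.
    """
    if curve.axis_kind != DENATURANT_MOLAR:
        raise ValidationError("fit_urea_unfolding needs a denaturant-axis curve")
    x = curve.axis_values
    y = curve.mean_signal
    rt = R_KCAL * curve.temperature
    span = y.max() - y.min()
    if span <= 0:
        raise ValidationError("flat curve: no transition")

    mid = 0.5 * (x.min() + x.max())
    if linear_baselines:
        p0 = [y[0], 0.0, y[-1], 0.0, 1.5 * mid, 1.5]
        lb = [-np.inf, -np.inf, -np.inf, -np.inf, -50.0, 1e-3]
        ub = [np.inf, np.inf, np.inf, np.inf, 50.0, 50.0]

        def resid(p):
            return _two_state_model(x, *p, rt) - y
    else:
        p0 = [y[0], y[-1], 1.5 * mid, 1.5]
        lb = [-np.inf, -np.inf, -50.0, 1e-3]
        ub = [np.inf, np.inf, 50.0, 50.0]

        def resid(p):
            return _two_state_model(x, p[0], 0.0, p[1], 0.0, p[2], p[3], rt) - y

    best = None
    for dg0_start in (0.5, 1.5, 3.0, 6.0):
        q0 = list(p0)
        q0[-2] = dg0_start
        sol = optimize.least_squares(resid, q0, bounds=(lb, ub),
                                     xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if linear_baselines:
        bf0, bf1, bu0, bu1, dg0_g, m_g = best.x
    else:
        bf0, bu0, dg0_g, m_g = best.x
        bf1 = bu1 = 0.0

    # no transition: a straight line explains the curve as well as the
    # two-state model does
    rss_two = 2.0 * float(best.cost)
    lin = np.polyfit(x, y, 1)
    rss_line = float(np.sum((np.polyval(lin, x) - y) ** 2))
    if rss_line <= 2.0 * rss_two + 1e-12 * span ** 2:
        raise ValidationError(
            "no transition: curve is indistinguishable from a monotone "
            "baseline")

    base_f = bf0 + bf1 * x
    base_u = bu0 + bu1 * x
    with np.errstate(divide="ignore", invalid="ignore"):
        f_u = (y - base_f) / (base_u - base_f)
    keep = np.isfinite(f_u) & (f_u >= FU_WINDOW[0]) & (f_u <= FU_WINDOW[1])
    if keep.sum() < 2:
        raise ValidationError(
            "no transition: fewer than 2 points with f_u in [0.05, 0.95]")
    fu = f_u[keep]
    dg = -rt * np.log(fu / (1.0 - fu))
    # delta-method weights: sd(dG) ~ RT/(f_u (1-f_u)) * sd(f_u), so points
    # near the baselines carry little information
    w = fu * (1.0 - fu)
    if fixed_m is not None:
        m = float(fixed_m)
        dg0 = float(np.average(dg + m * x[keep], weights=w ** 2))
    else:
        slope, dg0 = np.polyfit(x[keep], dg, 1, w=w)
        m = float(-slope)
        dg0 = float(dg0)
    rss = float(np.sum((dg - (dg0 - m * x[keep])) ** 2))
    return UreaFit(dG0=dg0, m_value=m, temperature=curve.temperature,
                   baselines=((bf0, bf1), (bu0, bu1)),
                   urea=x[keep], dG_points=dg, rss=rss)


def extrapolate_dG_to_temperature(temperatures_k, dG0_values,
                                  target_k: float = T_37C,
                                  confidence: float = 0.95) -> StabilityEstimate:
    """Ordinary least squares of dG0 versus temperature (degC), evaluated at
    the target temperature with a prediction interval.

    Needs >=3 temperatures (the underlying design used 4-5 between 20 and
    32 degC).
    """
    t_k = np.asarray(temperatures_k, dtype=float)
    g = np.asarray(dG0_values, dtype=float)
    if t_k.size < 3 or t_k.size != g.size:
        raise ValidationError("need >=3 (temperature, dG0) pairs")
    t_c = kelvin_to_celsius(t_k)
    target_c = kelvin_to_celsius(target_k)
    slope, intercept = np.polyfit(t_c, g, 1)
    pred = slope * target_c + intercept

    n = t_c.size
    resid = g - (slope * t_c + intercept)
    dof = n - 2
    if dof > 0 and np.sum(resid ** 2) > 0:
        s2 = np.sum(resid ** 2) / dof
        se = np.sqrt(s2 * (1 + 1 / n + (target_c - t_c.mean()) ** 2
                           / np.sum((t_c - t_c.mean()) ** 2)))
        tcrit = stats.t.ppf(0.5 + confidence / 2, dof)
        pi = (float(pred - tcrit * se), float(pred + tcrit * se))
    else:
        pi = (float(pred), float(pred))
    return StabilityEstimate(dG0_target=float(pred), target_temperature=target_k,
                             slope=float(slope), intercept=float(intercept),
                             temperatures=t_k, dG0_values=g,
                             prediction_interval=pi, confidence=confidence)


def extrapolate_rate(rate_table, target_k: float = T_37C) -> RateExtrapolation:
    """Extrapolate unfolding rates to water, then to a target temperature.

    ``rate_table`` maps temperature (kelvin) to a sequence of
    ``([urea], k_u)`` pairs (>=3 concentrations per temperature, >=2
    temperatures).  Per temperature, log10(k_u) is fitted linearly in
    [urea]; the zero-urea intercepts are then fitted linearly in
    temperature (degC) and evaluated at the target.  The activation energy
    is reported both as -R*T*ln(k_u) and via the Eyring relation.  A
    negative denaturant slope m_ku yields a warning, not an error.
    """
    warnings: list[str] = []
    log_kw: dict[float, float] = {}
    m_ku: dict[float, float] = {}
    if len(rate_table) < 2:
        raise ValidationError("need rates at >=2 temperatures")
    for t_k, pairs in rate_table.items():
        pairs = np.asarray(pairs, dtype=float)
        if pairs.shape[0] < 3:
            raise ValidationError(
                f"need >=3 urea concentrations at {t_k} K")
        slope, intercept = np.polyfit(pairs[:, 0], np.log10(pairs[:, 1]), 1)
        if slope < 0:
            warnings.append(
                f"negative m_ku ({slope:.3g} /M) at {t_k} K: unfolding rate "
                "decreases with denaturant")
        log_kw[float(t_k)] = float(intercept)
        m_ku[float(t_k)] = float(slope)

    t_keys = sorted(log_kw)
    t_c = kelvin_to_celsius(np.array(t_keys))
    lw = np.array([log_kw[t] for t in t_keys])
    slope, intercept = np.polyfit(t_c, lw, 1)
    target_c = kelvin_to_celsius(target_k)
    k_target = float(10.0 ** (slope * target_c + intercept))
    dg_simple = float(-R_KCAL * target_k * np.log(k_target))
    dg_eyring = float(R_KCAL * target_k
                      * np.log(K_B * target_k / (H_PLANCK * k_target)))
    return RateExtrapolation(log10_ku_water=log_kw, m_ku=m_ku,
                             k_u_target=k_target, target_temperature=target_k,
                             dG_act_simple=dg_simple, dG_act_eyring=dg_eyring,
                             slope=float(slope), intercept=float(intercept),
                             warnings=warnings)


def fit_melt(curve: UnfoldingCurve) -> MeltCurveFit:
    """Boltzmann sigmoid fit of a thermal melt; T_m is the inflection.

    The curve's kelvin axis is converted to degC for reporting.  Raises
    when the fitted inflection falls outside the sampled temperature range
    (no transition observed).
    """
    if curve.axis_kind != TEMPERATURE_KELVIN:
        raise ValidationError("fit_melt needs a temperature-axis curve")
    t_c = kelvin_to_celsius(curve.axis_values)
    y = curve.mean_signal
    if y.max() - y.min() <= 0:
        raise ValidationError("flat melt curve: no transition")

    def model(t, pre, post, tm, slope):
        return pre + (post - pre) / (1.0 + np.exp((tm - t) / slope))

    p0 = [y[0], y[-1], float(t_c[np.argmin(np.abs(y - 0.5 * (y[0] + y[-1])))]),
          max((t_c.max() - t_c.min()) / 20.0, 0.1)]
    popt, _ = optimize.curve_fit(model, t_c, y, p0=p0, maxfev=20000)
    pre, post, tm, slope = popt
    if slope < 0:  # canonicalize: slope > 0, swap baselines
        pre, post, slope = post, pre, -slope
    if not (t_c.min() - 1e-9 <= tm <= t_c.max() + 1e-9):
        raise ValidationError(
            f"no inflection in sampled range: fitted T_m {tm:.1f} degC")
    rss = float(np.sum((model(t_c, pre, post, tm, slope) - y) ** 2))
    return MeltCurveFit(t_m=float(tm), slope=float(slope),
                        baseline_pre=float(pre), baseline_post=float(post),
                        rss=rss)
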