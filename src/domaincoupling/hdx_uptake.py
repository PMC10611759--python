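"""HDX uptake kinetics: exponential fits, differential maps, opening dG.

The deuteration time course of a peptide is fitted to

    mono:  D(t) = A0 + A*(1 - exp(-k_HX * t))
    bi:    D(t) = A0 + A1*(1 - exp(-k_HX1 * t)) + A2*(1 - exp(-k_HX2 * t))

where A0 is the burst-phase %D and, for the biexponential, k_HX1 > k_HX2
(fast exchange in loosely structured regions, slow exchange in structured
regions).  Under EX2 conditions the ratio of exchange rates between two
protein states reports the difference in the free energy of the local
opening event that permits exchange:

    ddG_open(A-B) = -R*T*ln(k_HX(A) / k_HX(B))

so a positive value means state A exchanges slower (is more protected).
Because the underlying experiments use a temperature-jump protocol, these
ddG values are approximate and are labeled as EX2-assumed estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import R_KCAL
from .types import PeptideRecord, UptakeSeries, ValidationError

RATE_BOUNDS = (1e-7, 10.0)

#: Fixed grid of rate initializations (1/s) for the deterministic multistart.
RATE_STARTS = tuple(float(10.0 ** e) for e in range(-6, 1))


class FitFailure(RuntimeError):
    """Raised when no multistart converges; the peptide is excluded
    downstream (peptides without quantifiable kinetics are removed)."""


@dataclass
class UptakeFit:
    """Result of a mono- or biexponential uptake fit."""

    peptide: PeptideRecord
    model_order: int
    a0: float
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]                # descending for order 2
    rss: float
    aicc: float
    n_points: int
    rate_identifiable: tuple[bool, ...] = ()
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if any(a < -1e-9 for a in (self.a0, *self.amplitudes)):
            raise ValidationError("amplitudes must be >= 0")
        if any(k <= 0 for k in self.rates):
            raise ValidationError("rates must be positive")
        if self.model_order == 2 and self.rates[0] <= self.rates[1]:
            raise ValidationError("order-2 fit requires k_HX1 > k_HX2")

    @property
    def slow_rate(self) -> float:
        """k_HX (order 1) or k_HX2 (order 2): the structured-region rate
        used for opening free-energy differences."""
        return self.rates[-1]

    @property
    def slow_rate_identifiable(self) -> bool:
        return bool(self.rate_identifiable[-1]) if self.rate_identifiable else True

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        d = np.full_like(t, self.a0)
        for a, k in zip(self.amplitudes, self.rates):
            d = d + a * (1.0 - np.exp(-k * t))
        return d


def _uptake_model(t: np.ndarray, a0: float, amps, rates) -> np.ndarray:
    d = np.full_like(t, a0)
    for a, k in zip(amps, rates):
        d = d + a * (1.0 - np.exp(-k * t))
    return d


def _identifiable(rate: float, t: np.ndarray) -> bool:
    """A rate is identifiable when the exponential decays between 5% and
    99% across the observed window; outside that the data carry no rate
    information."""
    total = 1.0 - np.exp(-rate * t.max())
    before = 1.0 - np.exp(-rate * t.min())
    return (total >= 0.05) and (before <= 0.99)


def _aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample-corrected Akaike criterion for least-squares fits."""
    rss = max(rss, 1e-12)
    aic = n * np.log(rss / n) + 2 * n_params
    denom = n - n_params - 1
    if denom <= 0:
        return np.inf
    return aic + 2 * n_params * (n_params + 1) / denom


def _fit_order(t: np.ndarray, y: np.ndarray, w: np.ndarray, order: int):
    """Weighted least squares for one model order over the rate-start grid.

    Returns (params, rss) for the best start or None if nothing converged.
    """
    span = float(np.clip(y.max() - y.min(), 1.0, 100.0))
    a0_init = float(np.clip(y.min(), 0.0, 100.0))
    best = None
    if order == 1:
        starts = [(a0_init, span, k) for k in RATE_STARTS]
        lb = [0.0, 0.0, RATE_BOUNDS[0]]
        ub = [100.0, 100.0, RATE_BOUNDS[1]]

        def resid(p):
            return w * (_uptake_model(t, p[0], [p[1]], [p[2]]) - y)
    else:
        pairs = [(k1, k2) for k1, k2 in itertools.product(RATE_STARTS, RATE_STARTS)
                 if k1 > k2]
        starts = [(a0_init, span / 2, k1, span / 2, k2) for k1, k2 in pairs]
        lb = [0.0, 0.0, RATE_BOUNDS[0], 0.0, RATE_BOUNDS[0]]
        ub = [100.0, 100.0, RATE_BOUNDS[1], 100.0, RATE_BOUNDS[1]]

        def resid(p):
            return w * (_uptake_model(t, p[0], [p[1], p[3]], [p[2], p[4]]) - y)

    for p0 in starts:
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lb, ub),
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum((resid(sol.x) / np.where(w > 0, w, 1.0) * w) ** 2))
        rss_unw = float(np.sum((_uptake_model(t, sol.x[0],
                                              sol.x[1::2], sol.x[2::2]) - y) ** 2))
        if best is None or rss_unw < best[1] - 1e-15:
            best = (sol.x, rss_unw, rss)
    return best


def fit_uptake(series: UptakeSeries, order: int | str = "auto") -> UptakeFit:
    """Fit a deuteration time course to a mono- or biexponential model.

    Fits replicate means (weighted by 1/SEM when every timepoint has >=3
    replicates) with a deterministic multistart over a fixed grid of rate
    initializations.  ``order='auto'`` selects between orders by the
    small-sample-corrected Akaike criterion.

    Raises :class:`FitFailure` if no start converges, and
    :class:`ValidationError` when there are too few distinct timepoints
    (>=3 for order 1, >=5 for order 2).
    """
    t = series.timepoints
    y = series.mean_d
    if order in (1, "1"):
        orders = [1]
    elif order in (2, "2"):
        orders = [2]
    elif order == "auto":
        orders = [1, 2] if t.size >= 5 else [1]
    else:
        raise ValidationError(f"order must be 1, 2 or 'auto', got {order!r}")
    if 1 in orders and t.size < 3:
        raise ValidationError("order-1 fit needs >=3 distinct timepoints")
    if orders == [2] and t.size < 5:
        raise ValidationError("order-2 fit needs >=5 distinct timepoints")

    sem = series.sem_d
    if np.all(series.n_replicates >= 3) and np.all(np.nan_to_num(sem) > 0):
        w = 1.0 / sem
        w = w / w.mean()
    else:
        w = np.ones_like(y)

    candidates = []
    for m in orders:
        if m == 2 and t.size < 5:
            continue
        best = _fit_order(t, y, w, m)
        if best is None:
            continue
        x, rss, _ = best
        n_params = 3 if m == 1 else 5
        candidates.append((m, x, rss, _aicc(rss, t.size, n_params)))
    if not candidates:
        raise FitFailure(
            f"uptake fit failed for peptide {series.peptide.label()}: "
            "no multistart converged")

    m, x, rss, aicc = min(candidates, key=lambda c: c[3])
    if m == 1:
        amps, rates = (float(x[1]),), (float(x[2]),)
    else:
        pairs = sorted(zip((float(x[2]), float(x[4])),
                           (float(x[1]), float(x[3]))), reverse=True)
        rates = (pairs[0][0], pairs[1][0])
        amps = (pairs[0][1], pairs[1][1])
        if rates[0] <= rates[1]:  # merged rates: collapse to order 1 instead
            return fit_uptake(series, order=1)
    # a vanishing amplitude leaves its rate unconstrained by the data
    ident = tuple(_identifiable(k, t) and a > 1e-3
                  for a, k in zip(amps, rates))
    return UptakeFit(peptide=series.peptide, model_order=m, a0=float(x[0]),
                     amplitudes=amps, rates=rates, rss=rss, aicc=aicc,
                     n_points=int(t.size), rate_identifiable=ident,
                     temperature=series.temperature)


# ---------------------------------------------------------------------------
# Differential deuteration maps
# ---------------------------------------------------------------------------

def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Welch t-test p-value with the degenerate-variance
    convention: identical constant replicates give p = 1 when the means
    agree and p = 0 when they differ (never NaN)."""
    if np.nanstd(a) == 0.0 and np.nanstd(b) == 0.0:
        return 1.0 if np.isclose(np.nanmean(a), np.nanmean(b)) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False, nan_policy="omit").pvalue)


def differential_map(state_a: list[UptakeSeries], state_b: list[UptakeSeries],
                     adjust: bool = False) -> pd.DataFrame:
    """Per-peptide, per-timepoint differential deuteration (B - A).

    Peptides are matched across states by (start, end, sequence).  Returns a
    tidy frame with columns ``start, end, sequence, time_s, delta_percentD,
    p_value, n_A, n_B`` (plus ``p_adjusted`` when ``adjust`` is set, using
    Benjamini-Hochberg; off by default since the source analyses apply no
    multiplicity correction).  Unmatched peptides are listed in
    ``df.attrs['unmatched_A' / 'unmatched_B']`` rather than silently
    dropped.  p-values require >=2 replicates in both states; otherwise the
    delta is still reported with p = NaN.
    """
    index_a = {s.peptide.key: s for s in state_a}
    index_b = {s.peptide.key: s for s in state_b}
    common = [k for k in index_a if k in index_b]
    if not common:
        raise ValidationError("no common peptides between states")

    rows = []
    for key in sorted(common):
        sa, sb = index_a[key], index_b[key]
        times = np.intersect1d(sa.timepoints, sb.timepoints)
        for t in times:
            ia = int(np.where(sa.timepoints == t)[0][0])
            ib = int(np.where(sb.timepoints == t)[0][0])
            ra = sa.percent_d[ia][np.isfinite(sa.percent_d[ia])]
            rb = sb.percent_d[ib][np.isfinite(sb.percent_d[ib])]
            delta = float(np.mean(rb) - np.mean(ra))
            p = _welch_p(ra, rb) if (ra.size >= 2 and rb.size >= 2) else np.nan
            rows.append({"start": key[0], "end": key[1], "sequence": key[2],
                         "time_s": float(t), "delta_percentD": delta,
                         "p_value": p, "n_A": int(ra.size), "n_B": int(rb.size)})
    df = pd.DataFrame(rows)
    if adjust:
        df["p_adjusted"] = _benjamini_hochberg(df["p_value"].to_numpy())
    df.attrs["unmatched_A"] = sorted(k for k in index_a if k not in index_b)
    df.attrs["unmatched_B"] = sorted(k for k in index_b if k not in index_a)
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    n = pm.size
    order = np.argsort(pm)
    ranked = pm[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.clip(ranked, 0, 1)
    out[mask] = adj
    return out


def project_deltas_to_residues(df: pd.DataFrame, time_s: float,
                               n_residues: int) -> np.ndarray:
    """Per-residue mean delta %D over all peptides covering each residue.

    Overlapping-peptide projection convention for structure coloring;
    residues covered by no peptide are NaN.  ``n_residues`` is the length
    of the 1-based residue range.
    """
    sums = np.zeros(n_residues)
    counts = np.zeros(n_residues)
    sel = df[np.isclose(df["time_s"], time_s)]
    for _, row in sel.iterrows():
        lo, hi = int(row["start"]) - 1, int(row["end"])
        sums[lo:hi] += row["delta_percentD"]
        counts[lo:hi] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# ---------------------------------------------------------------------------
# Opening free-energy differences
# ---------------------------------------------------------------------------

@dataclass
class DifferentialEnergetics:
    """Opening free-energy difference between two states for one peptide.

    ``ddG_open = -R*T*ln(rate_A / rate_B)`` in kcal/mol; positive when
    state A exchanges slower (is more protected).  Values assume EX2
    exchange under a temperature-jump protocol and are therefore
    approximate, as noted in ``kinetics_regime_note``.
    """

    peptide: PeptideRecord
    ddG_open: float
    rate_a: float
    rate_b: float
    temperature: float
    kinetics_regime_note: str = (
        "approximate (EX2 assumed; temperature-jump protocol)")


def ddG_from_rates(fit_a: UptakeFit, fit_b: UptakeFit,
                   temperature: float = 310.15,
                   component: str = "slow") -> DifferentialEnergetics:
    """Opening free-energy difference from an exchange-rate ratio.

    Uses k_HX for order-1 fits and the slower k_HX2 for order-2 fits
    (``component='slow'``); ``component='single'`` additionally requires
    both fits to be mono-exponential.
    """
    if component not in ("slow", "single"):
        raise ValidationError("component must be 'slow' or 'single'")
    if component == "single" and (fit_a.model_order != 1 or fit_b.model_order != 1):
        raise ValidationError("component='single' requires order-1 fits")
    if not (fit_a.slow_rate_identifiable and fit_b.slow_rate_identifiable):
        raise ValidationError(
            "exchange rate unidentifiable over the observed window for "
            f"{fit_a.peptide.label()} / {fit_b.peptide.label()}")
    ka, kb = fit_a.slow_rate, fit_b.slow_rate
    ddg = -R_KCAL * temperature * np.log(ka / kb)
    return DifferentialEnergetics(peptide=fit_a.peptide, ddG_open=float(ddg),
                                  rate_a=ka, rate_b=kb, temperature=temperature)
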