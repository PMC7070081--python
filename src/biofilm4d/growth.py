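"""Per-colonizer growth-law fitting and population summaries.

Actively growing colonizers expand as V(t) = V(0) + a·t^b (t in minutes,
V in µm³), with "a" a normalization constant and "b" the growth-law
exponent; when V(t) ≫ V(0) this reduces to the pure power law
V(t) = a·t^b.  Both model variants are fitted by nonlinear least squares
on the untransformed model, initialized from a log–log linear regression
of the above-baseline volume, which makes convergence robust over the
5–6 decades that "a" spans in practice.

Population summaries report median and quartiles (linear-interpolation
quantile rule) of the fitted coefficients, overall and stratified by the
colonizer's initial cell-count class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tracking import Track


@dataclass
class GrowthFit:
    """Fitted growth law for one track."""

    track_id: int
    model: str                    # offset_power | pure_power
    a: float | None = None        # µm³·min^(−b)
    b: float | None = None        # dimensionless
    v0: float | None = None       # µm³ (offset model only)
    sd_a: float | None = None
    sd_b: float | None = None
    rss: float | None = None
    r_squared: float | None = None
    n_points: int = 0
    converged: bool = False
    static: bool = False          # flat series, growth law not identifiable


def _loglog_init(t: np.ndarray, v_excess: np.ndarray) -> tuple[float, float]:
    """Initial (a, b) from a log–log regression of positive excess volumes."""
    ok = (t > 0) & (v_excess > 0)
    if ok.sum() < 2:
        return 1e-5, 2.0
    slope, intercept = np.polyfit(np.log(t[ok]), np.log(v_excess[ok]), 1)
    b0 = float(np.clip(slope, 0.05, 10.0))
    a0 = float(np.exp(np.clip(intercept, -50, 50)))
    return a0, b0


def fit_growth(track: Track, model: str = "offset_power",
               static_rtol: float = 0.05) -> GrowthFit:
    """Fit V(t) = V(0) + a·t^b (or a·t^b) to one track's volume series.

    Times are measured from the track's origin frame (t = 0 at first
    observation).  Series whose total relative excursion is below
    ``static_rtol`` are flagged static and not fitted.  Standard errors
    come from the fit covariance.
    """
    if model not in ("offset_power", "pure_power"):
        raise ValueError(f"unknown model {model!r}")
    t = np.asarray(track.times, dtype=float)
    t = t - t[0]
    v = track.volumes
    fit = GrowthFit(track_id=track.track_id, model=model, n_points=len(t))
    if len(t) < 5:
        return fit
    if np.ptp(v) <= static_rtol * v[0]:
        fit.static = True
        return fit

    if model == "offset_power":
        def f(tt, a, b, v0):
            return v0 + a * np.power(tt, b)
        a0, b0 = _loglog_init(t, v - v[0])
        p0, bounds = [a0, b0, v[0]], ([0, 0, 0], [np.inf, 10, np.inf])
    else:
        def f(tt, a, b):
            return a * np.power(tt, b)
        a0, b0 = _loglog_init(t, v)
        p0, bounds = [a0, b0], ([0, 0], [np.inf, 10])

    try:
        popt, pcov = curve_fit(f, t, v, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return fit
    resid = v - f(t, *popt)
    sd = np.sqrt(np.diag(pcov))
    fit.a, fit.b = float(popt[0]), float(popt[1])
    fit.sd_a, fit.sd_b = float(sd[0]), float(sd[1])
    if model == "offset_power":
        fit.v0 = float(popt[2])
    fit.rss = float(resid @ resid)
    tss = float(((v - v.mean()) ** 2).sum())
    fit.r_squared = 1.0 - fit.rss / tss if tss > 0 else None
    fit.converged = bool(np.isfinite(sd).all())
    return fit


def growth_rate(track: Track, smoothing: int | None = None) -> np.ndarray:
    """dV/dt series (µm³/min) by central finite differences.

    One-sided differences at the ends; optional centered moving average
    of window ``smoothing`` afterwards.  Requires ≥ 3 points.
    """
    t = np.asarray(track.times, dtype=float)
    v = track.volumes
    if len(t) < 3:
        raise ValueError("growth_rate requires at least 3 time points")
    rate = np.gradient(v, t)
    if smoothing is not None and smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        rate = np.convolve(rate, kernel, mode="same")
    return rate


def is_usable(fit: GrowthFit, max_sd_b: float = 1.0, min_r2: float = 0.5) -> bool:
    """Quality gate for population summaries.

    Converged fits with sd_b ≤ ``max_sd_b`` and R² ≥ ``min_r2``; looser
    or failed fits are tallied as "unfit" rather than silently dropped.
    """
    return (fit.converged and fit.sd_b is not None and fit.sd_b <= max_sd_b
            and fit.r_squared is not None and fit.r_squared >= min_r2)


def population_summary(fits: list[GrowthFit], tracks: list[Track] | None = None,
                       max_sd_b: float = 1.0, min_r2: float = 0.5) -> dict:
    """Median and quartiles of fitted (a, b) across the population.

    Quantiles use the linear-interpolation rule.  When ``tracks`` is
    given, coefficients are additionally stratified by the colonizer's
    initial cell-count class, and SC/DC/unfit counts are included.
    """
    if not fits:
        raise ValueError("population_summary needs at least one fit")
    usable = [f for f in fits if is_usable(f, max_sd_b, min_r2)]

    def q(vals):
        vals = np.asarray(vals, dtype=float)
        return dict(median=float(np.quantile(vals, 0.5)),
                    q1=float(np.quantile(vals, 0.25)),
                    q3=float(np.quantile(vals, 0.75)),
                    n=int(len(vals)))

    out: dict = {
        "n_fits": len(fits),
        "n_usable": len(usable),
        "n_static": sum(f.static for f in fits),
        "a": q([f.a for f in usable]) if usable else None,
        "b": q([f.b for f in usable]) if usable else None,
    }
    if tracks is not None:
        by_id = {tr.track_id: tr for tr in tracks}
        strat: dict[str, dict] = {}
        for f in usable:
            tr = by_id.get(f.track_id)
            cls = tr.elements[0].colonizer_class if tr is not None else None
            if cls is None:
                continue
            strat.setdefault(cls, []).append(f)
        out["by_p0_class"] = {cls: {"a": q([f.a for f in fl]),
                                    "b": q([f.b for f in fl])}
                              for cls, fl in sorted(strat.items())}
        counts = {"SC": 0, "DC": 0, "unfit": 0}
        for tr in tracks:
            if tr.dynamics_class in counts:
                counts[tr.dynamics_class] += 1
        out["dynamics_counts"] = counts
    return out


def fits_table(fits: list[GrowthFit]) -> pd.DataFrame:
    """Tabular view of fitted coefficients (one row per track)."""
    rows = [dict(track_id=f.track_id, model=f.model, a=f.a, b=f.b, v0=f.v0,
                 sd_a=f.sd_a, sd_b=f.sd_b, r_squared=f.r_squared,
                 n_points=f.n_points, converged=f.converged, static=f.static)
            for f in fits]
    return pd.DataFrame(rows, columns=["track_id", "model", "a", "b", "v0",
                                       "sd_a", "sd_b", "r_squared", "n_points",
                                       "converged", "static"])
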