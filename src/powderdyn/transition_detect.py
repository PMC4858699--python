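"""Detection of the two dynamical-transition temperatures from T-series.

Two distinct transitions are located:

* ``T_low``: a change of slope between two harmonic (linear) regimes of the
  average MSF, found by an exhaustive two-segment breakpoint search (in
  semi-log space by default) over the data below a temperature cap;
* ``T_D`` (the protein dynamical transition): either the intersection of the
  two free lines of a bilinear enthalpy fit (the calorimetric signature, a
  heat-capacity jump ΔC_p), or the onset of persistent excess of the MSF
  over the extrapolated upper harmonic segment.

Breakpoint candidates are midpoints between consecutive data temperatures;
each segment keeps at least three points and the two lines are fit
independently (no continuity constraint).  Significance of the two-regime
model is a single-vs-two-line F-test, Bonferroni-corrected for the number of
candidate breakpoints searched, so the reported p-value controls the
family-wise error of the search.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .core_model import EnthalpyFit, SegmentedFit, TemperatureSeries


@dataclass
class LineFit:
    slope: float
    intercept: float
    sigma: float            # residual standard deviation
    slope_se: float
    n: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class MethylFit:
    """Methyl-hydrogen MSF(T): exponential below t_low, linear above."""
    log_intercept: float    # a in value ≈ exp(a + b T)
    rate: float             # b, 1/K
    sigma_log: float
    slope: float            # linear regime above t_low
    intercept: float
    sigma_linear: float


@dataclass
class ResidueTransitionReport:
    residue_index: int
    has_tlow_slope_change: bool
    has_td_deviation: bool
    slope_mid: float                    # Å²/K on t_low <= T <= t_d
    amplitude_above_td: float           # Å², mean excess over mid-fit; NaN if no deviation
    p_slope_change: float = float("nan")

    def __post_init__(self) -> None:
        if not self.has_td_deviation and math.isfinite(self.amplitude_above_td):
            raise ValueError("amplitude_above_td defined only with a T_D deviation")


def _ols(t: np.ndarray, y: np.ndarray) -> LineFit:
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    dof = max(len(t) - 2, 1)
    sigma = float(np.sqrt((resid ** 2).sum() / dof))
    return LineFit(float(res.slope), float(res.intercept), sigma,
                   float(res.stderr) if np.isfinite(res.stderr) else 0.0, len(t))


def _sse_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, sse) of the least-squares line."""
    A = np.column_stack([t, np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float((resid ** 2).sum())


def fit_harmonic_low(series: TemperatureSeries, t_min: float = 100.0,
                     t_max: float = 150.0) -> LineFit:
    """OLS line on the low-temperature harmonic window (default 100–150 K)."""
    sub = series.restrict(t_min, t_max)
    if len(sub) < 3:
        raise ValueError(f"need >= 3 points in [{t_min}, {t_max}] K, "
                         f"got {len(sub)}")
    return _ols(sub.temperatures, sub.values)


def _two_regime_p(sse_single: float, sse_two: float, n: int,
                  n_candidates: int, scale: float) -> float:
    """Bonferroni-corrected single-vs-two-line F-test p-value."""
    atol = n * (1e-8 * max(scale, 1e-300)) ** 2
    if sse_single <= atol:
        return 1.0     # single line already exact
    if n <= 4:
        return 1.0
    if sse_two <= atol:
        return 0.0
    f_stat = ((sse_single - sse_two) / 2.0) / (sse_two / (n - 4))
    if f_stat <= 0:
        return 1.0
    p = float(stats.f.sf(f_stat, 2, n - 4))
    return min(1.0, p * max(n_candidates, 1))


def _segmented_search(t: np.ndarray, y: np.ndarray, fit_space: str,
                      min_seg: int = 3) -> SegmentedFit:
    n = len(t)
    candidates = [(t[i] + t[i + 1]) / 2.0 for i in range(min_seg - 1, n - min_seg)]
    if not candidates:
        raise ValueError("too few points for a two-segment fit")
    best = None
    for c in candidates:
        left = t < c
        s1, a1, sse1 = _sse_line(t[left], y[left])
        s2, a2, sse2 = _sse_line(t[~left], y[~left])
        sse = sse1 + sse2
        # strict inequality: ties break toward the lowest candidate
        if best is None or sse < best[0] - 1e-15 * max(abs(best[0]), 1.0):
            best = (sse, c, s1, a1, s2, a2, left.sum())
    sse, c, s1, a1, s2, a2, n_left = best
    _, _, sse_single = _sse_line(t, y)
    p = _two_regime_p(sse_single, sse, n, len(candidates), np.abs(y).max())
    left = t < c
    resid_low = y[left] - (a1 + s1 * t[left])
    resid_high = y[~left] - (a2 + s2 * t[~left])
    return SegmentedFit(
        breakpoint=float(c), slope_low=s1, intercept_low=a1,
        slope_high=s2, intercept_high=a2, sse=float(sse),
        sse_single=float(sse_single), p_two_regime=p, fit_space=fit_space,
        resid_sigma_low=float(np.sqrt((resid_low ** 2).sum() / max(left.sum() - 2, 1))),
        resid_sigma_high=float(np.sqrt((resid_high ** 2).sum() / max((~left).sum() - 2, 1))),
        n_candidates=len(candidates), t_min=float(t[0]), t_max=float(t[-1]))


def detect_tlow(series: TemperatureSeries, t_cap: float = 210.0,
                fit_space: str = "log") -> SegmentedFit:
    """Locate the harmonic slope change T_low below ``t_cap``.

    Fits two independent lines (to log MSF by default, matching the
    semi-logarithmic convention for the sub-210 K regimes) at every
    admissible breakpoint and returns the SSE-minimizing fit.
    """
    if fit_space not in ("linear", "log"):
        raise ValueError("fit_space must be 'linear' or 'log'")
    sub = series.restrict(t_max=t_cap)
    if len(sub) < 6:
        raise ValueError(f"need >= 6 points at T <= {t_cap} K, got {len(sub)}")
    y = sub.values
    if fit_space == "log":
        if (y <= 0).any():
            raise ValueError("nonpositive values cannot be fit in log space")
        y = np.log(y)
    return _segmented_search(sub.temperatures, y, fit_space)


def detect_td_enthalpy(h_series: TemperatureSeries, alpha: float = 0.01) -> EnthalpyFit:
    """Calorimetric T_D: intersection of the two free lines of a bilinear
    enthalpy fit, with ΔC_p the difference of the segment slopes.

    Reports ``transition_detected=False`` (single-regime behaviour) when the
    two-line model is not significant at ``alpha`` or the intersection falls
    outside the data range.
    """
    if len(h_series) < 8:
        raise ValueError("need >= 8 enthalpy points")
    t = h_series.temperatures
    if t[-1] - t[0] < 80.0:
        raise ValueError("enthalpy series must span >= 80 K")
    seg = _segmented_search(t, h_series.values, "linear")
    single_slope, _, _ = _sse_line(t, h_series.values)

    diagnostic = ""
    detected = seg.p_two_regime < alpha
    t_d = float("nan")
    if detected:
        dslope = seg.slope_high - seg.slope_low
        scale = max(abs(seg.slope_high), abs(seg.slope_low), 1e-300)
        if abs(dslope) < 1e-10 * scale:
            detected = False
            diagnostic = "parallel-segments"
        else:
            t_d = (seg.intercept_low - seg.intercept_high) / dslope
            if not (t[0] < t_d < t[-1]):
                detected = False
                diagnostic = "intersection-outside-range"
                t_d = float("nan")
    if detected:
        return EnthalpyFit(t_d=float(t_d), cp_low=seg.slope_low,
                           cp_high=seg.slope_high,
                           delta_cp=seg.slope_high - seg.slope_low,
                           transition_detected=True,
                           p_two_regime=seg.p_two_regime, fit=seg)
    return EnthalpyFit(t_d=float("nan"), cp_low=single_slope,
                       cp_high=single_slope, delta_cp=0.0,
                       transition_detected=False,
                       p_two_regime=seg.p_two_regime,
                       diagnostic=diagnostic, fit=seg)


def _persistent_onset(t: np.ndarray, excess: np.ndarray,
                      threshold: np.ndarray) -> float | None:
    """Smallest temperature from which the excess exceeds the threshold at
    every remaining point (single noisy spikes do not qualify)."""
    above = excess > threshold
    for j in range(len(t)):
        if above[j:].all() and above[j]:
            return float(t[j])
    return None


def detect_td_msf(series: TemperatureSeries, seg: SegmentedFit,
                  k_sigma: float = 3.0, t_cap: float = 210.0) -> float | None:
    """Onset T_D from the MSF curve itself.

    Extrapolates the upper harmonic segment of ``seg`` beyond ``t_cap`` and
    returns the smallest data temperature at which the observation exceeds
    the extrapolation by more than ``k_sigma`` times the larger of the fit
    residual σ and the point error, persistently (all hotter points must
    exceed too).  ``None`` when the curve never leaves the harmonic line.
    """
    mask = series.temperatures > t_cap
    if not mask.any():
        return None
    t = series.temperatures[mask]
    obs = series.values[mask]
    err = series.errors[mask] if series.errors is not None else np.zeros_like(obs)
    if seg.fit_space == "log":
        pred = seg.predict_high(t)
        obs_fs = np.log(obs)
        err_fs = np.where(obs > 0, err / np.maximum(obs, 1e-300), 0.0)
    else:
        pred = seg.predict_high(t)
        obs_fs = obs
        err_fs = err
    floor = 1e-9 * max(np.abs(obs_fs).max(), 1e-300)  # exact-data noise floor
    threshold = k_sigma * np.maximum(seg.resid_sigma_high, err_fs) + floor
    return _persistent_onset(t, obs_fs - pred, threshold)


def detect_residue_transitions(per_residue: Mapping[int, TemperatureSeries],
                               t_low: float, t_d: float,
                               alpha: float = 0.05,
                               k_sigma: float = 3.0) -> list[ResidueTransitionReport]:
    """Check every residue for the two whole-protein transitions.

    ``t_low`` and ``t_d`` come from the independent whole-protein analysis.
    Per residue: a line is fit on t_low <= T <= t_d; a slope change at t_low
    is declared by a two-sample slope test against the fit on T <= t_low;
    anharmonic deviation at t_d by the persistence rule applied to the
    mid-fit extrapolation.
    """
    reports = []
    for idx in sorted(per_residue):
        series = per_residue[idx]
        low = series.restrict(t_max=t_low)
        mid = series.restrict(t_low, t_d)
        if len(low) < 3 or len(mid) < 3:
            warnings.warn(f"residue {idx}: too few points around [{t_low}, {t_d}] K; skipped")
            continue
        fit_low = _ols(low.temperatures, low.values)
        fit_mid = _ols(mid.temperatures, mid.values)
        se = math.hypot(fit_low.slope_se, fit_mid.slope_se)
        slope_scale = max(abs(fit_low.slope), abs(fit_mid.slope), 1e-300)
        if abs(fit_mid.slope - fit_low.slope) <= 1e-8 * slope_scale:
            p_slope = 1.0      # numerically identical slopes (exact data)
        elif se > 0:
            t_stat = (fit_mid.slope - fit_low.slope) / se
            dof = fit_low.n + fit_mid.n - 4
            p_slope = float(2 * stats.t.sf(abs(t_stat), dof))
        else:
            p_slope = 0.0

        above = series.restrict(t_min=np.nextafter(t_d, np.inf))
        onset = None
        if len(above) > 0:
            pred = fit_mid.predict(above.temperatures)
            err = (above.errors if above.errors is not None
                   else np.zeros_like(above.values))
            floor = 1e-9 * max(np.abs(above.values).max(), 1e-300)
            threshold = k_sigma * np.maximum(fit_mid.sigma, err) + floor
            onset = _persistent_onset(above.temperatures, above.values - pred,
                                      threshold)
        has_dev = onset is not None
        if has_dev:
            amplitude = float(np.mean(above.values - fit_mid.predict(above.temperatures)))
        else:
            amplitude = float("nan")
        reports.append(ResidueTransitionReport(
            residue_index=idx,
            has_tlow_slope_change=p_slope < alpha,
            has_td_deviation=has_dev,
            slope_mid=fit_mid.slope,
            amplitude_above_td=amplitude,
            p_slope_change=p_slope))
    return reports


def fit_methyl(series: TemperatureSeries, t_low: float) -> MethylFit:
    """Two-regime fit of methyl-hydrogen MSF(T).

    Below ``t_low`` the MSF grows exponentially with temperature, so a line
    is fit to log(MSF) vs T; at and above ``t_low`` an ordinary line is fit
    in linear space.
    """
    if (series.values <= 0).any():
        raise ValueError("methyl MSF values must be positive")
    low = series.restrict(t_max=np.nextafter(t_low, -np.inf))
    high = series.restrict(t_min=t_low)
    if len(low) < 3 or len(high) < 3:
        raise ValueError("need >= 3 points on each side of t_low")
    f_log = _ols(low.temperatures, np.log(low.values))
    f_lin = _ols(high.temperatures, high.values)
    return MethylFit(log_intercept=f_log.intercept, rate=f_log.slope,
                     sigma_log=f_log.sigma, slope=f_lin.slope,
                     intercept=f_lin.intercept, sigma_linear=f_lin.sigma)
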