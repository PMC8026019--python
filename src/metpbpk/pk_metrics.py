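"""Non-compartmental PK summaries of simulated or observed curves.

Implements the standard NCA quantities: AUC by linear trapezoid, Cmax/Tmax,
terminal half-life by best-adjusted-R² log-linear regression over suffixes of
post-Tmax points, steady-state metrics for repeated dosing, and per-tissue
amount/fraction-of-dose curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import nmol_to_mg
from .ode_engine import SimulationResult


class HalfLifeUndefinedError(ValueError):
    """No terminal window with a negative log-linear slope exists."""


@dataclass
class PKSummary:
    """Summary metrics for one tissue curve; Cmean is multi-dose only."""

    auc24: float  # nmol*h/mL
    cmax: float  # nmol/mL
    tmax: float  # h
    t_half: float  # h
    amount_at_cmax_mg: float | None = None
    cmean: float | None = None  # nmol/mL, final dosing interval
    steady_state_reached: bool | None = None


def auc(time, conc, t_end: float | None = None) -> float:
    """Linear-trapezoid area under the curve from the first time to ``t_end``."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(time) < 2:
        raise ValueError("AUC needs at least two points")
    if t_end is None:
        t_end = time[-1]
    if t_end > time[-1] + 1e-12:
        raise ValueError(f"t_end={t_end} beyond last observation {time[-1]}")
    mask = time <= t_end
    t, c = time[mask], conc[mask]
    if t[-1] < t_end:  # close the interval by interpolation
        t = np.append(t, t_end)
        c = np.append(c, np.interp(t_end, time, conc))
    return float(np.trapezoid(c, t))


def cmax_tmax(time, conc) -> tuple[float, float]:
    """Global maximum and its time; ties resolved to the earliest time."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(time) == 0:
        raise ValueError("empty series")
    i = int(np.argmax(conc))  # argmax returns the first maximum
    return float(conc[i]), float(time[i])


def _refined_peak(time, conc) -> tuple[float, float]:
    """Cmax/Tmax with parabolic interpolation through the discrete maximum.

    On densely sampled smooth curves this removes the output-grid
    quantization of Tmax (error O(h^2) instead of O(h)); at a boundary
    maximum it falls back to the discrete value. Raw sparse datasets should
    use :func:`cmax_tmax` instead, which never interpolates.
    """
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    i = int(np.argmax(conc))
    if i == 0 or i == len(conc) - 1:
        return float(conc[i]), float(time[i])
    t0, t1, t2 = time[i - 1:i + 2]
    y0, y1, y2 = conc[i - 1:i + 2]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    if a >= 0:  # degenerate/flat neighborhood: keep the grid point
        return float(y1), float(t1)
    b = (t2 ** 2 * (y0 - y1) + t1 ** 2 * (y2 - y0) + t0 ** 2 * (y1 - y2)) / denom
    tv = -b / (2 * a)
    c0 = y1 - a * t1 ** 2 - b * t1
    return float(a * tv ** 2 + b * tv + c0), float(tv)


def terminal_half_life(time, conc, min_points: int = 3) -> float:
    """Terminal half-life ln(2)/λz.

    λz is the negative slope of ln(conc) vs time over the terminal window;
    the window is the suffix of >= ``min_points`` strictly-post-Tmax points
    that maximizes the adjusted R² of the log-linear regression (the usual
    NCA best-fit convention).
    """
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    _, tmax = cmax_tmax(time, conc)
    mask = (time > tmax) & (conc > 0)
    t, y = time[mask], np.log(conc[mask])
    n_all = len(t)
    if n_all < min_points:
        raise HalfLifeUndefinedError(
            f"need >= {min_points} positive points after Tmax, have {n_all}")

    # suffix regression statistics via reversed cumulative sums
    def rcum(v):
        return np.cumsum(v[::-1])[::-1]

    n = np.arange(n_all, 0, -1, dtype=float)
    sx, sy = rcum(t), rcum(y)
    sxx, sxy, syy = rcum(t * t), rcum(t * y), rcum(y * y)
    den_x = n * sxx - sx ** 2
    den_y = n * syy - sy ** 2
    cov = n * sxy - sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / den_x
        r2 = cov ** 2 / (den_x * den_y)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    valid = (n >= min_points) & (slope < 0) & np.isfinite(adj)
    # a perfectly flat-in-noise den_y==0 suffix is not a usable window
    valid &= den_y > 0
    if not valid.any():
        raise HalfLifeUndefinedError("no terminal window with negative slope")
    best = int(np.argmax(np.where(valid, adj, -np.inf)))
    lam = -slope[best]
    return float(np.log(2.0) / lam)


def amount_at_cmax(result: SimulationResult, tissue: str) -> float:
    """Amount of metformin (mg free base) in a tissue at its own Cmax."""
    a = result.amount(tissue)
    return nmol_to_mg(float(a.max()))


def summarize(result: SimulationResult, tissue: str,
              t_end: float = 24.0) -> PKSummary:
    """Single-dose NCA summary of one simulated tissue curve."""
    t = result.time
    c = result.concentration(tissue)
    cmax, tmax = _refined_peak(t, c)
    return PKSummary(
        auc24=auc(t, c, min(t_end, t[-1])),
        cmax=cmax, tmax=tmax,
        t_half=terminal_half_life(t[t <= t_end], c[t <= t_end]),
        amount_at_cmax_mg=amount_at_cmax(result, tissue),
    )


def _interval_bounds(dose_times, tau: float, t_last: float):
    starts = list(np.asarray(dose_times, dtype=float))
    bounds = [(s, min(s + tau, t_last)) for s in starts]
    return [b for b in bounds if b[1] > b[0]]


def steady_state_time(result: SimulationResult, tissue: str, tau: float,
                      dose_times=None, tolerance: float = 0.01) -> float:
    """Time at which the per-interval Cmax stabilizes.

    Returns the Tmax of the first dosing interval whose Cmax differs from
    the previous interval's by less than ``tolerance`` (relative). For a
    compartment that accumulates monotonically through the whole course
    (e.g. red blood cells on short courses) the time of the global maximum
    is returned. Returns NaN if neither applies.
    """
    if dose_times is None:
        dose_times = [e.time for e in result.schedule.events]
    if len(dose_times) < 2:
        raise ValueError("steady-state time needs a multi-dose result")
    t, c = result.time, result.concentration(tissue)
    peaks = []
    for t0, t1 in _interval_bounds(dose_times, tau, t[-1]):
        m = (t >= t0) & (t <= t1)
        peaks.append(_refined_peak(t[m], c[m]))
    for prev, cur in zip(peaks, peaks[1:]):
        if prev[0] > 0 and abs(cur[0] - prev[0]) / prev[0] < tolerance:
            return cur[1]
    if all(b[0] > a[0] for a, b in zip(peaks, peaks[1:])):
        return _refined_peak(t, c)[1]
    return float("nan")


def multidose_summary(result: SimulationResult, tissue: str, tau: float,
                      dose_times=None, ss_tolerance: float = 0.01) -> PKSummary:
    """Repeated-dosing summary: course-wide Cmax/Tmax, Cmean over the final
    complete dosing interval, AUC24 over the first 24 h, terminal half-life
    after the last dose."""
    if dose_times is None:
        dose_times = [e.time for e in result.schedule.events]
    if len(dose_times) < 2:
        raise ValueError("multidose summary needs >= 2 dosing intervals")
    t, c = result.time, result.concentration(tissue)
    cmax, tmax = _refined_peak(t, c)
    last_start = max(dose_times)
    last_end = last_start + tau
    if last_end > t[-1]:
        raise ValueError("simulation must cover the final dosing interval")
    m = (t >= last_start) & (t <= last_end)
    cmean = auc(t[m], c[m]) / tau
    t_ss = steady_state_time(result, tissue, tau, dose_times, ss_tolerance)
    reached = np.isfinite(t_ss)
    if not reached:
        warnings.warn(f"steady state not reached for {tissue!r}", stacklevel=2)
    post = t >= last_start
    return PKSummary(
        auc24=auc(t, c, min(24.0, t[-1])),
        cmax=cmax, tmax=tmax,
        t_half=terminal_half_life(t[post], c[post]),
        amount_at_cmax_mg=amount_at_cmax(result, tissue),
        cmean=cmean, steady_state_reached=bool(reached),
    )


def amount_metrics(result: SimulationResult,
                   absorbed_nmol: float | None = None) -> pd.DataFrame:
    """Per-tissue peak amounts (mg) and fractions of the absorbed dose.

    The absorbed amount defaults to the cumulative urinary excretion at the
    end of the run: metformin is not metabolized, so on a long single-dose
    simulation everything absorbed ends up in urine.
    """
    if absorbed_nmol is None:
        absorbed_nmol = float(result.cumulative_urine[-1])
    rows = []
    for comp in result.model.compartments:
        if comp.name in (result.model.urine, result.model.feces):
            continue
        a = result.amount(comp.name)
        i = int(np.argmax(a))
        rows.append({
            "tissue": comp.name,
            "peak_amount_mg": nmol_to_mg(float(a[i])),
            "peak_time_h": float(result.time[i]),
            "peak_fraction_of_absorbed": float(a[i]) / absorbed_nmol
            if absorbed_nmol > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def oscillation_metrics(result: SimulationResult, tissue: str, tau: float,
                        dose_times=None) -> tuple[float, float]:
    """(amplitude, mean) of a tissue curve over the final dosing interval.

    Amplitude is Cmax - Cmin over the interval; mean is the interval-average
    concentration. Used for the tissue-proportion scenarios.
    """
    if dose_times is None:
        dose_times = [e.time for e in result.schedule.events]
    last_start = max(dose_times)
    last_end = last_start + tau
    t, c = result.time, result.concentration(tissue)
    if last_end > t[-1]:
        raise ValueError("simulation must cover the final dosing interval")
    m = (t >= last_start) & (t <= last_end)
    amp = float(c[m].max() - c[m].min())
    mean = auc(t[m], c[m]) / tau
    return amp, mean


#: Tissues reported in the human summary tables, in printing order.
REPORT_TISSUES = ("venous_plasma", "rbc", "adipose", "brain", "remainder",
                  "muscle", "enterocytes", "lungs", "stomach", "heart",
                  "liver", "kidney")


def summary_table(result: SimulationResult, dose_mg: float,
                  tissues=None, multidose_tau: float | None = None) -> pd.DataFrame:
    """Table of PK metrics per tissue (single or repeated dosing)."""
    if tissues is None:
        tissues = [t for t in REPORT_TISSUES
                   if t in result.model.names]
    rows = []
    for tissue in tissues:
        if multidose_tau is None:
            s = summarize(result, tissue)
        else:
            s = multidose_summary(result, tissue, multidose_tau)
        row = {"tissue": tissue, "dose_mg": dose_mg, "auc24_nmol_h_per_mL": s.auc24,
               "cmax_nmol_per_mL": s.cmax, "tmax_h": s.tmax,
               "amount_at_cmax_mg": s.amount_at_cmax_mg, "t_half_h": s.t_half}
        if multidose_tau is not None:
            row["cmean_nmol_per_mL"] = s.cmean
            row["steady_state_reached"] = s.steady_state_reached
        rows.append(row)
    return pd.DataFrame(rows)
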