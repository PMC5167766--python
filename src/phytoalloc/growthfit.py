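"""Turbidostat growth-rate estimation from OD680 logs.

A turbidostat holds culture biomass near a set point by repeated fractional
dilutions (here 10 % volumetric additions to a 450 mL cuvette, so each event
multiplies optical density by 1/1.1).  Between dilutions the culture regrows
exponentially; the specific growth rate mu (d^-1) is the log-linear slope of
OD680 within each dilution cycle, and the per-run estimate is the mean over
the final ten cycles.

Dilution events are detected as relative drops of at least ``drop_threshold``
between consecutive samples of a median-filtered copy of the series (the
filter suppresses isolated noise spikes; detection never alters the data used
for fitting).  First and last partial cycles are excluded from fitting by
default.  The estimator works on log OD, so it is invariant to any uniform
rescaling of the sensor gain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import median_filter

__all__ = [
    "GrowthFitError",
    "TurbidostatLog",
    "CycleFit",
    "GrowthEstimate",
    "detect_dilutions",
    "fit_cycle",
    "summarize_growth",
    "estimate_growth",
    "read_od_log",
    "write_od_log",
]

HOURS_PER_DAY = 24.0


class GrowthFitError(ValueError):
    """Raised for invalid OD logs or unusable cycle segments."""


@dataclass
class TurbidostatLog:
    """OD680 time series; ``annotated_dilutions`` (hours) are ground-truth
    event times carried by the synthetic generator, never used for fitting."""

    time_h: np.ndarray
    od680: np.ndarray
    annotated_dilutions: np.ndarray | None = None
    flags: tuple = ()

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od680 = np.asarray(self.od680, dtype=float)
        if self.time_h.ndim != 1 or len(self.time_h) != len(self.od680):
            raise GrowthFitError("time and OD must be 1-D and equal length")
        if len(self.time_h) > 1 and not np.all(np.diff(self.time_h) > 0):
            raise GrowthFitError("times must be strictly increasing")
        if np.any(~np.isfinite(self.od680)) or np.any(self.od680 <= 0):
            raise GrowthFitError("OD680 must be finite and > 0")
        if self.annotated_dilutions is not None:
            self.annotated_dilutions = np.asarray(self.annotated_dilutions, dtype=float)


@dataclass
class CycleFit:
    start_h: float
    end_h: float
    n_points: int
    mu_day: float
    r2: float


@dataclass
class GrowthEstimate:
    cycles: list[CycleFit]
    mu_mean: float
    mu_sd: float
    n_cycles_used: int
    flags: tuple = ()


def _adaptive_window(log_od: np.ndarray, threshold_log: float) -> int:
    """Median-filter window that keeps false dilution detections negligible.

    The noise sd of log OD is estimated robustly from first differences (the
    rare dilution drops barely move the MAD); the window is sized so that the
    difference of two disjoint window medians has sd <= threshold/5, i.e. a
    ~5-sigma detection criterion.  Noise-free logs collapse to window 1
    (plain sample-to-sample differencing).
    """
    d = np.diff(log_od)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / math.sqrt(2.0)
    if sigma <= 0:
        return 1
    # sd of a window median ~ sigma * sqrt(pi/2) / sqrt(w); difference of two
    # disjoint medians multiplies by sqrt(2)
    w = math.ceil((math.sqrt(math.pi) * 5.0 * sigma / threshold_log) ** 2)
    return int(np.clip(w, 1, max(1, len(log_od) // 20)))


def detect_dilutions(
    log: TurbidostatLog,
    drop_threshold: float = 0.05,
    smooth_window: int | None = None,
) -> np.ndarray:
    """Indices of the first sample of each new cycle (one per dilution event).

    A boundary is declared where log OD, median-filtered over ``smooth_window``
    samples (sized automatically from the estimated noise when None), falls by
    at least ``drop_threshold`` across a window-length gap; runs of adjacent
    detections are merged into one event, localized at the largest raw
    single-sample drop.  An event-free log returns an empty boundary array —
    callers see the single-cycle condition through the empty result.
    """
    if len(log.od680) < 2:
        raise GrowthFitError("need at least 2 samples to detect dilutions")
    if not 0.0 < drop_threshold < 1.0:
        raise GrowthFitError("drop_threshold must be in (0, 1)")
    y = np.log(log.od680)
    thr = -math.log1p(-drop_threshold)
    w = _adaptive_window(y, thr) if smooth_window is None else max(1, int(smooth_window))
    if w == 1:
        yf, gap = y, 1
    else:
        yf, gap = median_filter(y, size=w, mode="nearest"), w + 1
    if len(y) <= gap:
        return np.asarray([], dtype=int)
    score = yf[gap:] - yf[:-gap]
    idxs = np.flatnonzero(score <= -thr)
    raw_diff = np.diff(y)

    def localize(lo: int, hi: int) -> int:
        hi = min(hi, len(raw_diff) - 1)
        return lo + int(np.argmin(raw_diff[lo : hi + 1])) + 1

    boundaries: list[int] = []
    start = prev = None
    for i in idxs:
        if start is None:
            start = prev = i
        elif i - prev > gap:
            boundaries.append(localize(start, prev + gap))
            start = prev = i
        else:
            prev = i
    if start is not None:
        boundaries.append(localize(start, prev + gap))
    return np.asarray(boundaries, dtype=int)


def fit_cycle(time_h, od680) -> CycleFit:
    """Exponential fit of one regrowth segment, performed in log space.

    OD(t) = OD0 exp(mu t) implies ln OD linear in t; mu is the slope with
    time in days.  The reported r^2 is that of the log-linear regression.
    """
    time_h = np.asarray(time_h, dtype=float)
    od680 = np.asarray(od680, dtype=float)
    if len(time_h) < 4:
        raise GrowthFitError(f"cycle needs >= 4 points, got {len(time_h)}")
    if time_h[-1] <= time_h[0]:
        raise GrowthFitError("cycle must span positive time")
    if np.any(od680 <= 0):
        raise GrowthFitError("cycle OD must be > 0")
    t_days = time_h / HOURS_PER_DAY
    y = np.log(od680)
    res = stats.linregress(t_days, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0  # constant OD
    return CycleFit(
        start_h=float(time_h[0]),
        end_h=float(time_h[-1]),
        n_points=len(time_h),
        mu_day=float(res.slope),
        r2=r2,
    )


def summarize_growth(cycles: list[CycleFit], n_last: int = 10) -> GrowthEstimate:
    """Mean +/- SD of mu over the final ``n_last`` fitted cycles."""
    if not cycles:
        raise GrowthFitError("no usable cycles to summarize")
    flags: list[str] = []
    used = cycles[-n_last:]
    if len(used) < n_last:
        flags.append("short_series")
    mu = np.array([c.mu_day for c in used])
    mu_sd = float(np.std(mu, ddof=1)) if len(mu) > 1 else float("nan")
    if len(mu) == 1:
        flags.append("single_cycle")
    return GrowthEstimate(
        cycles=list(cycles),
        mu_mean=float(np.mean(mu)),
        mu_sd=mu_sd,
        n_cycles_used=len(used),
        flags=tuple(flags),
    )


def estimate_growth(
    log: TurbidostatLog,
    drop_threshold: float = 0.05,
    n_last: int = 10,
    exclude_first: bool = True,
    exclude_last: bool = True,
    min_points: int = 4,
    smooth_window: int | None = None,
) -> GrowthEstimate:
    """Segment a turbidostat log into dilution cycles and estimate mu.

    First and last (partial) segments are dropped by default; each segment is
    trimmed by the detection window on both ends (boundary positions are only
    certain to that resolution, and a stray pre/post-dilution sample is a
    large-leverage outlier); segments left with fewer than ``min_points``
    samples are skipped with a flag.
    """
    y = np.log(log.od680)
    thr = -math.log1p(-drop_threshold)
    w = _adaptive_window(y, thr) if smooth_window is None else max(1, int(smooth_window))
    boundaries = detect_dilutions(log, drop_threshold, w)
    flags: list[str] = list(log.flags)
    if len(boundaries) == 0:
        flags.append("no_dilutions_detected")
    trim = w // 2 + 1 if w > 1 else 0
    edges = [0, *boundaries.tolist(), len(log.od680)]
    segments = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    if exclude_first and len(segments) > 1:
        segments = segments[1:]
    if exclude_last and len(segments) > 1:
        segments = segments[:-1]
    cycles = []
    skipped = 0
    for a, b in segments:
        a, b = a + trim, b - trim
        if b - a < min_points:
            skipped += 1
            continue
        cycles.append(fit_cycle(log.time_h[a:b], log.od680[a:b]))
    if skipped:
        flags.append(f"skipped_{skipped}_short_segments")
    if not cycles:
        raise GrowthFitError("no segment had enough points for an exponential fit")
    est = summarize_growth(cycles, n_last=n_last)
    return GrowthEstimate(
        cycles=est.cycles,
        mu_mean=est.mu_mean,
        mu_sd=est.mu_sd,
        n_cycles_used=est.n_cycles_used,
        flags=tuple(dict.fromkeys([*flags, *est.flags])),
    )


def read_od_log(path) -> TurbidostatLog:
    df = pd.read_csv(path)
    if not {"time_h", "od680"} <= set(df.columns):
        raise GrowthFitError(f"OD log {path} must have columns time_h, od680")
    return TurbidostatLog(df["time_h"].to_numpy(), df["od680"].to_numpy())


def write_od_log(log: TurbidostatLog, path) -> None:
    pd.DataFrame({"time_h": log.time_h, "od680": log.od680}).to_csv(
        path, index=False, float_format="%.12g"
    )
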