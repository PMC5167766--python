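"""Fast repetition rate (FRR) chlorophyll fluorescence: model and fitting.

A fast repetition rate fluorometer delivers a train of microsecond blue
flashlets whose cumulative photon dose progressively closes photosystem II
(PSII) reaction centers within a single photochemical turnover.  Fluorescence
yield rises from the open-center baseline ``F0`` toward the all-closed maximum
``FM``; the rise rate is set by the effective absorption cross section serving
PSII photochemistry, ``sigma_PSII`` (reported in 1e-20 m^2 quanta^-1), and by
excitonic connectivity ``p`` between PSII units.  After the saturating train,
fluorescence relaxes biphasically with lifetimes ``tau1`` (QA- reoxidation,
hundreds of microseconds) and ``tau2`` (milliseconds).

The closure fraction ``C`` evolves with cumulative dose ``E`` (quanta m^-2) as

    dC/dE = sigma * (1 - C) * (1 - p) / (1 - p C)

which integrates to the monotone potential

    g(C) = p C - (1 - p) ln(1 - C) = (1 - p) sigma E + g(C0)

and reduces to the Poisson single-hit form ``C = 1 - exp(-sigma E)`` when
``p = 0``.  Fluorescence during the train is ``F = F0 + (FM - F0) C``.

Fitting an induction trace recovers ``(F0, FM, sigma_PSII, p)``; for a trace
recorded under actinic light the baseline sits at the steady-state closure
``C0 > 0``, which can be fitted as an extra parameter (the fitted baseline
fluorescence is then the light-acclimated steady state ``FS``).

Derived photophysiology follows the standard definitions:
``FV/FM = (FM - F0)/FM``; the post-actinic baseline ``F'_02s`` is corrected to
``F'_0`` in proportion to any ``F'_M`` to ``F'_M2s`` recovery;
``qP = (F'_M - FS)/(F'_M - F'_0)``; and PSII electron transport is
``sigma'_PSII * I * qP`` with irradiance converted to quanta m^-2 s^-1.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.constants import Avogadro

__all__ = [
    "SIGMA_SCALE",
    "FrrFitError",
    "FlashletTrace",
    "FrrRecording",
    "FrrFit",
    "PhotoPhysiology",
    "quanta_per_m2",
    "closure_fraction",
    "induction_fluorescence",
    "relaxation_fluorescence",
    "fit_induction",
    "fit_relaxation",
    "compute_fv_fm",
    "correct_f0_prime",
    "compute_qp",
    "compute_etr",
    "derive_photophysiology",
    "read_recording",
    "write_recording",
]

#: sigma_PSII is conventionally reported in units of 1e-20 m^2 quanta^-1.
SIGMA_SCALE = 1e-20

_MIN_INDUCTION_POINTS = 10


class FrrFitError(ValueError):
    """Raised for invalid traces or contract violations in FRR fitting."""


def quanta_per_m2(intensity_umol_m2_s, duration_s):
    """Photon dose (quanta m^-2) of a flashlet of given intensity and length.

    Intensity is in umol photons m^-2 s^-1; the factor 1e-6 * N_A converts
    micromoles of photons to quanta.
    """
    return np.asarray(intensity_umol_m2_s, dtype=float) * 1e-6 * Avogadro * duration_s


# ---------------------------------------------------------------------------
# trace containers


@dataclass
class FlashletTrace:
    """One phase of an FRR record: induction flashlets or relaxation samples.

    ``time_s`` is seconds from the start of the flashlet train for induction
    phases and seconds *after the end of the train* for relaxation phases.
    ``excitation_umol_m2_s`` is zero during relaxation.
    """

    phase: str  # "induction" | "relaxation"
    time_s: np.ndarray
    excitation_umol_m2_s: np.ndarray
    fluorescence: np.ndarray
    flashlet_duration_s: float = 1.2e-6
    light_state: str = "dark_adapted"  # "dark_adapted" | "actinic"
    actinic_umol_m2_s: float = 0.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.excitation_umol_m2_s = np.asarray(self.excitation_umol_m2_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.phase not in ("induction", "relaxation"):
            raise FrrFitError(f"unknown phase {self.phase!r}")
        if self.time_s.ndim != 1 or len(self.time_s) != len(self.fluorescence):
            raise FrrFitError("time and fluorescence must be 1-D and equal length")
        if len(self.excitation_umol_m2_s) != len(self.time_s):
            raise FrrFitError("excitation must match trace length")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise FrrFitError("times must be strictly increasing")
        if np.any(~np.isfinite(self.fluorescence)) or np.any(self.fluorescence <= 0):
            raise FrrFitError("fluorescence must be finite and > 0")

    @property
    def doses_quanta_m2(self) -> np.ndarray:
        return quanta_per_m2(self.excitation_umol_m2_s, self.flashlet_duration_s)

    @property
    def cumulative_dose(self) -> np.ndarray:
        return np.cumsum(self.doses_quanta_m2)


@dataclass
class FrrRecording:
    """A full FRR measurement: induction, optional relaxation, optional
    second induction taken after a 2-s dark gap (perturbation / F0' check)."""

    induction: FlashletTrace
    relaxation: FlashletTrace | None = None
    induction_2s: FlashletTrace | None = None


# ---------------------------------------------------------------------------
# model


def _closure_potential(c, p):
    return p * c - (1.0 - p) * np.log1p(-c)


def closure_fraction(cum_dose, sigma_m2, p=0.0, c0=0.0):
    """Closed-PSII fraction after cumulative excitation ``cum_dose``.

    ``sigma_m2`` is the cross section in m^2 quanta^-1 (SI, not 1e-20 units);
    ``p`` is connectivity in [0, 1); ``c0`` the closure at zero dose.
    """
    cum_dose = np.asarray(cum_dose, dtype=float)
    if not 0.0 <= p < 1.0:
        raise FrrFitError("connectivity p must be in [0, 1)")
    if not 0.0 <= c0 < 1.0:
        raise FrrFitError("initial closure must be in [0, 1)")
    if p == 0.0:
        # Poisson single-hit closed form
        return 1.0 - (1.0 - c0) * np.exp(-sigma_m2 * cum_dose)
    t = (1.0 - p) * sigma_m2 * cum_dose + _closure_potential(c0, p)
    # Newton solve of g(C) = t; start from the p=0 solution, which lies below
    # the root (so the convex g keeps iterates monotone and inside (0, 1)).
    c = -np.expm1(-np.maximum(t, 0.0))
    c = np.clip(c, 0.0, 1.0 - 1e-15)
    for _ in range(60):
        f = p * c - (1.0 - p) * np.log1p(-c) - t
        df = p + (1.0 - p) / (1.0 - c)
        step = f / df
        c = np.clip(c - step, 0.0, 1.0 - 1e-15)
        if np.max(np.abs(step)) < 1e-15:
            break
    return c


def induction_fluorescence(cum_dose, f0, fm, sigma_1e20, p=0.0, c0=0.0):
    """Model fluorescence during the flashlet train.

    ``f0`` is the fluorescence at zero closure (the dark baseline, or the
    light-acclimated F0' when ``c0 > 0``); ``sigma_1e20`` in 1e-20 m^2.
    """
    c = closure_fraction(cum_dose, sigma_1e20 * SIGMA_SCALE, p, c0)
    return f0 + (fm - f0) * c


def relaxation_fluorescence(t, f0, f_peak, tau1, tau2, amp1):
    """Biphasic post-train relaxation toward the baseline ``f0``."""
    t = np.asarray(t, dtype=float)
    decay = amp1 * np.exp(-t / tau1) + (1.0 - amp1) * np.exp(-t / tau2)
    return f0 + (f_peak - f0) * decay


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FrrFit:
    """Fitted single-turnover parameters and (optionally) relaxation kinetics.

    ``sigma_psii`` is in 1e-20 m^2 quanta^-1.  ``initial_closure`` is the
    fitted baseline closure C0 (0 for dark-adapted fits); the steady-state
    fluorescence ``fs`` is the model value at C0.
    """

    f0: float
    fm: float
    sigma_psii: float
    connectivity_p: float
    initial_closure: float = 0.0
    tau1: float = float("nan")
    tau2: float = float("nan")
    amp1: float = float("nan")
    amp2: float = float("nan")
    rss: float = float("nan")
    rss_relaxation: float = float("nan")
    converged: bool = True
    n_points: int = 0
    flags: tuple = ()

    @property
    def fv_fm(self) -> float:
        return compute_fv_fm(self.f0, self.fm)

    @property
    def fs(self) -> float:
        return self.f0 + (self.fm - self.f0) * self.initial_closure

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


def _run_ls(resid, x0, bounds, x_scale):
    return optimize.least_squares(
        resid,
        x0,
        bounds=bounds,
        method="trf",
        x_scale=x_scale,
        ftol=1e-13,
        xtol=1e-13,
        gtol=1e-13,
        max_nfev=5000,
    )


def fit_induction(
    trace: FlashletTrace,
    *,
    fix_p: float | None = None,
    fit_initial_closure: bool = False,
    p_init: float = 0.1,
) -> FrrFit:
    """Fit ``(F0, FM, sigma_PSII[, p][, C0])`` to an induction trace.

    ``fix_p`` freezes connectivity at a given value (0 gives the pure Poisson
    model).  ``fit_initial_closure`` adds the baseline closure C0 as a free
    parameter — use this for traces recorded under actinic light, where the
    first flashlet already sees partially closed centers.

    Raises :class:`FrrFitError` for non-induction traces or fewer than 10
    flashlets.  A fit whose optimum has FM <= F0 is returned flagged
    ``failed_fm_le_f0`` with ``converged=False`` (no silent defaults).
    """
    if trace.phase != "induction":
        raise FrrFitError("fit_induction requires an induction-phase trace")
    F = trace.fluorescence
    n = len(F)
    if n < _MIN_INDUCTION_POINTS:
        raise FrrFitError(f"induction trace needs >= {_MIN_INDUCTION_POINTS} points, got {n}")
    cum = trace.cumulative_dose
    if np.any(cum <= 0):
        raise FrrFitError("induction flashlets must carry positive excitation")

    f0g = float(F[0])
    fmg = float(np.max(F))
    span = max(fmg - f0g, 1e-9 * fmg)
    k = min(5, n)
    norm = np.clip((F[:k] - f0g) / span, 1e-4, 0.999)
    with np.errstate(divide="ignore"):
        sg = float(np.median(-np.log1p(-norm) / (SIGMA_SCALE * cum[:k])))
    sg = float(np.clip(sg, 10.0, 3000.0))

    free = ["f0", "fm", "sigma"]
    lo, hi = [1e-9, 1e-9, 10.0], [np.inf, np.inf, 3000.0]
    if fix_p is None:
        free.append("p")
        lo.append(0.0)
        hi.append(0.6)
    if fit_initial_closure:
        free.append("c0")
        lo.append(0.0)
        hi.append(0.95)

    def unpack(x):
        vals = dict(zip(free, x))
        return (
            vals["f0"],
            vals["fm"],
            vals["sigma"],
            vals.get("p", fix_p if fix_p is not None else 0.0),
            vals.get("c0", 0.0),
        )

    # residuals on log fluorescence: flashlet noise is multiplicative, so the
    # log scale is homoscedastic and keeps the plateau from dominating the fit
    logF = np.log(F)

    def resid(x):
        f0, fm, sig, p, c0 = unpack(x)
        return np.log(induction_fluorescence(cum, f0, fm, sig, p, c0)) - logF

    def start(sig, p, c0):
        x0 = {"f0": f0g if not fit_initial_closure else max(f0g * (1.0 - c0), 1e-6),
              "fm": fmg, "sigma": sig, "p": p, "c0": c0}
        return [x0[name] for name in free]

    starts = [
        start(sg, p_init, 0.05 if fit_initial_closure else 0.0),
        start(min(sg * 3.0, 3000.0), 0.0, 0.3 if fit_initial_closure else 0.0),
        start(max(sg * 0.3, 10.0), 0.3, 0.1 if fit_initial_closure else 0.0),
    ]

    best = None
    scale = [max(abs(v), 1e-3) for v in starts[0]]
    for x0 in starts:
        try:
            res = _run_ls(resid, x0, (lo, hi), scale)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
        # good enough: converged with rms log-residual below 20 % — later
        # starts only matter when the first lands in a bad local optimum
        if best.status > 0 and best.cost < 0.5 * n * 0.2**2:
            break
    if best is None:
        raise FrrFitError("induction fit failed to run")

    f0, fm, sig, p, c0 = unpack(best.x)
    flags: list[str] = []
    converged = bool(best.status > 0)
    if fm <= f0:
        flags.append("failed_fm_le_f0")
        converged = False
    if not converged and "failed_fm_le_f0" not in flags:
        flags.append("not_converged")
    return FrrFit(
        f0=float(f0),
        fm=float(fm),
        sigma_psii=float(sig),
        connectivity_p=float(p),
        initial_closure=float(c0),
        rss=float(2.0 * best.cost),
        converged=converged,
        n_points=n,
        flags=tuple(flags),
    )


def fit_relaxation(trace: FlashletTrace, induction_fit: FrrFit) -> FrrFit:
    """Fit biphasic relaxation lifetimes to a post-train trace.

    Both the baseline and the peak amplitude are free parameters (the
    baseline is seeded from the induction fit's F0; freeing it keeps the
    noisy induction estimate from biasing the lifetimes, and the peak absorbs
    the slightly sub-unity closure reached by the train).  Lifetimes are
    ordered so that ``tau1 < tau2``; near-degenerate or single-phase optima
    collapse to a single exponential with ``amp2 = 0`` and a
    ``single_exponential`` flag.
    """
    if trace.phase != "relaxation":
        raise FrrFitError("fit_relaxation requires a relaxation-phase trace")
    t = trace.time_s
    F = trace.fluorescence
    if len(t) < 6:
        raise FrrFitError("relaxation trace needs >= 6 samples")
    f0g = min(induction_fit.f0, float(np.min(F)))
    fpk0 = float(np.max(F))
    if fpk0 <= f0g:
        raise FrrFitError("relaxation trace never exceeds the baseline F0")

    logF = np.log(F)

    def resid(x):
        f0, fpk, tau1, tau2, a1 = x
        return np.log(relaxation_fluorescence(t, f0, fpk, tau1, tau2, a1)) - logF

    lo = [1e-9, 1e-9, 1e-6, 1e-6, 0.0]
    hi = [np.inf, np.inf, 10.0, 10.0, 1.0]
    scale = [max(f0g, 1e-3), fpk0, 1e-3, 1e-2, 1.0]
    starts = [
        [f0g, fpk0, 3e-4, 5e-3, 0.7],
        [f0g, fpk0, 1e-4, 2e-3, 0.5],
        [f0g, fpk0, 1e-3, 2e-2, 0.5],
    ]
    best = None
    for x0 in starts:
        res = _run_ls(resid, x0, (lo, hi), scale)
        if best is None or res.cost < best.cost:
            best = res
        if best.status > 0 and best.cost < 0.5 * len(t) * 0.2**2:
            break

    f0r, fpk, tau_a, tau_b, a1 = best.x
    if tau_a <= tau_b:
        tau1, tau2, amp1 = tau_a, tau_b, a1
    else:
        tau1, tau2, amp1 = tau_b, tau_a, 1.0 - a1
    amp2 = 1.0 - amp1
    flags: list[str] = []
    if fpk <= f0r:
        flags.append("failed_fpk_le_f0")

    degenerate = amp2 < 0.02 or amp1 < 0.02 or tau2 / tau1 < 1.2
    if degenerate:
        # single-exponential refit
        def resid1(x):
            f0_, fpk_, tau_ = x
            return np.log(relaxation_fluorescence(t, f0_, fpk_, tau_, tau_, 1.0)) - logF

        res1 = _run_ls(resid1, [f0g, fpk0, max(tau1, 1e-5)],
                       ([1e-9, 1e-9, 1e-6], [np.inf, np.inf, 10.0]),
                       [max(f0g, 1e-3), fpk0, 1e-3])
        f0r, fpk, tau1 = res1.x
        tau2, amp1, amp2 = tau1, 1.0, 0.0
        best = res1
        flags.append("single_exponential")

    return replace(
        induction_fit,
        tau1=float(tau1),
        tau2=float(tau2),
        amp1=float(amp1),
        amp2=float(amp2),
        rss_relaxation=float(2.0 * best.cost),
        flags=induction_fit.flags + tuple(flags),
    )


# ---------------------------------------------------------------------------
# derived photophysiology


def compute_fv_fm(f0: float, fm: float) -> float:
    """Maximum PSII photochemical quantum yield, (FM - F0)/FM."""
    if not fm > 0:
        raise FrrFitError(f"FM must be > 0, got {fm}")
    if f0 < 0:
        raise FrrFitError(f"F0 must be >= 0, got {f0}")
    if f0 > fm:
        raise FrrFitError(f"F0 ({f0:g}) exceeds FM ({fm:g}): no variable fluorescence")
    return (fm - f0) / fm


def correct_f0_prime(f0_2s_prime: float, fm_prime: float, fm_2s_prime: float) -> float:
    """Proportional correction of the post-actinic baseline to F0'.

    Any recovery of maximal fluorescence from FM' to FM2s' during the 2-s dark
    gap is assumed to scale the baseline equally:
    F0' = F0_2s' * {1 - [(FM2s' - FM')/FM2s']}.
    """
    if not fm_2s_prime > 0:
        raise FrrFitError(f"FM_2s' must be > 0, got {fm_2s_prime}")
    result = f0_2s_prime * (1.0 - (fm_2s_prime - fm_prime) / fm_2s_prime)
    if result < 0:
        raise FrrFitError(
            f"corrected F0' is negative ({result:g}); inputs F0_2s'={f0_2s_prime:g}, "
            f"FM'={fm_prime:g}, FM_2s'={fm_2s_prime:g}"
        )
    return result


def compute_qp(fs: float, fm_prime: float, f0_prime: float) -> float:
    """Photochemical quenching qP = (FM' - FS)/(FM' - F0').

    Values outside [0, 1] (possible under noise) are returned as-is with a
    warning; callers decide whether to flag them.
    """
    if not fm_prime > f0_prime:
        raise FrrFitError(f"FM' ({fm_prime:g}) must exceed F0' ({f0_prime:g})")
    qp = (fm_prime - fs) / (fm_prime - f0_prime)
    if not 0.0 <= qp <= 1.0:
        warnings.warn(f"qP = {qp:.4f} outside [0, 1]; retained unclipped", stacklevel=2)
    return qp


def compute_etr(sigma_prime_1e20: float, irradiance_umol_m2_s: float, qp: float) -> float:
    """PSII electron transport rate, e- PSII^-1 s^-1.

    ETR = sigma'_PSII * I * qP with sigma' converted from 1e-20 m^2 quanta^-1
    and I from umol photons m^-2 s^-1 to quanta m^-2 s^-1.
    """
    if sigma_prime_1e20 < 0 or irradiance_umol_m2_s < 0:
        raise FrrFitError("sigma' and irradiance must be >= 0")
    quanta = irradiance_umol_m2_s * 1e-6 * Avogadro
    return sigma_prime_1e20 * SIGMA_SCALE * quanta * qp


@dataclass
class PhotoPhysiology:
    """Per-culture photophysiology derived from the dark and actinic fits."""

    fv_fm: float
    f0: float
    fm: float
    sigma_psii: float
    connectivity_p: float
    fs: float
    fm_prime: float
    sigma_psii_prime: float
    f0_2s_prime: float
    fm_2s_prime: float
    f0_prime: float
    qp: float
    etr: float
    tau1: float
    tau2: float
    inv_tau1: float
    flags: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


def derive_photophysiology(
    dark_fit: FrrFit,
    light_fit: FrrFit,
    light_2s_fit: FrrFit,
    actinic_umol_m2_s: float,
    fm_change_warn: float = 0.05,
) -> PhotoPhysiology:
    """Assemble the derived parameter set from the three induction fits.

    ``dark_fit`` must carry relaxation lifetimes (see :func:`fit_relaxation`).
    ``light_fit`` is the actinic-state fit (baseline = FS via its fitted C0);
    ``light_2s_fit`` the post-actinic fit after the 2-s dark gap.  A change of
    more than ``fm_change_warn`` between FM' and FM2s' raises a quality flag
    beyond the proportional F0' correction itself.
    """
    flags: list[str] = []
    fv_fm = dark_fit.fv_fm
    fs = light_fit.fs
    fm_prime = light_fit.fm
    f0_2s = light_2s_fit.f0
    fm_2s = light_2s_fit.fm
    f0_prime = correct_f0_prime(f0_2s, fm_prime, fm_2s)
    if abs(fm_2s - fm_prime) / fm_2s > fm_change_warn:
        flags.append("fm_2s_change_gt_5pct")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qp = compute_qp(fs, fm_prime, f0_prime)
    if not 0.0 <= qp <= 1.0:
        flags.append("qp_outside_unit_interval")
    etr = compute_etr(light_fit.sigma_psii, actinic_umol_m2_s, qp)
    return PhotoPhysiology(
        fv_fm=fv_fm,
        f0=dark_fit.f0,
        fm=dark_fit.fm,
        sigma_psii=dark_fit.sigma_psii,
        connectivity_p=dark_fit.connectivity_p,
        fs=fs,
        fm_prime=fm_prime,
        sigma_psii_prime=light_fit.sigma_psii,
        f0_2s_prime=f0_2s,
        fm_2s_prime=fm_2s,
        f0_prime=f0_prime,
        qp=qp,
        etr=etr,
        tau1=dark_fit.tau1,
        tau2=dark_fit.tau2,
        inv_tau1=1.0 / dark_fit.tau1 if dark_fit.tau1 > 0 else float("nan"),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# I/O


_TRACE_COLUMNS = [
    "phase",
    "time_s",
    "excitation_umol_m2_s",
    "fluorescence",
    "flashlet_duration_s",
    "light_state",
    "actinic_umol_m2_s",
]


def _trace_frame(trace: FlashletTrace, phase_label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phase": phase_label,
            "time_s": trace.time_s,
            "excitation_umol_m2_s": trace.excitation_umol_m2_s,
            "fluorescence": trace.fluorescence,
            "flashlet_duration_s": trace.flashlet_duration_s,
            "light_state": trace.light_state,
            "actinic_umol_m2_s": trace.actinic_umol_m2_s,
        }
    )


def write_recording(rec: FrrRecording, path) -> None:
    """Write an FRR recording as a tidy CSV (one row per flashlet/sample)."""
    frames = [_trace_frame(rec.induction, "induction")]
    if rec.relaxation is not None:
        frames.append(_trace_frame(rec.relaxation, "relaxation"))
    if rec.induction_2s is not None:
        frames.append(_trace_frame(rec.induction_2s, "induction_2s"))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def _trace_from_frame(df: pd.DataFrame, phase_label: str) -> FlashletTrace:
    sub = df[df["phase"] == phase_label]
    phase = "relaxation" if phase_label == "relaxation" else "induction"
    return FlashletTrace(
        phase=phase,
        time_s=sub["time_s"].to_numpy(),
        excitation_umol_m2_s=sub["excitation_umol_m2_s"].to_numpy(),
        fluorescence=sub["fluorescence"].to_numpy(),
        flashlet_duration_s=float(sub["flashlet_duration_s"].iloc[0]),
        light_state=str(sub["light_state"].iloc[0]),
        actinic_umol_m2_s=float(sub["actinic_umol_m2_s"].iloc[0]),
    )


def read_recording(path) -> FrrRecording:
    """Read an FRR recording CSV written by :func:`write_recording`."""
    df = pd.read_csv(path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise FrrFitError(f"trace file {path} missing columns {sorted(missing)}")
    phases = set(df["phase"].unique())
    if "induction" not in phases:
        raise FrrFitError(f"trace file {path} has no induction phase")
    rec = FrrRecording(induction=_trace_from_frame(df, "induction"))
    if "relaxation" in phases:
        rec.relaxation = _trace_from_frame(df, "relaxation")
    if "induction_2s" in phases:
        rec.induction_2s = _trace_from_frame(df, "induction_2s")
    return rec


def write_fit_json(fit: FrrFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
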