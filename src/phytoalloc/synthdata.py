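"""Synthetic instrument emulator: every input the analysis pipeline consumes,
generated from known ground truth so each stage is verifiable by parameter
recovery.

The generator emulates a two-species turbidostat study on marine centric
diatoms — a small species (``T_pseudonana``-like, ~40 um^3) and a large one
(``T_punctigera``-like, ~300,000 um^3) — grown under high- (~550 umol L^-1
NO3-) and low-nitrogen (~55 umol L^-1) media across three continuous growth
lights per species (30/180/380 and 30/90/180 umol photons m^-2 s^-1), with
3-4 replicate turbidostat runs per condition.  Five instrument channels are
emulated per replicate:

1. FRR fluorescence: 40 x 1.2 us flashlets over 128 us at ~1e5 umol photons
   m^-2 s^-1, dark-adapted and under actinic light, plus a biphasic
   relaxation record and a second induction after a 2-s dark gap.
2. Turbidostat OD680 logs with instantaneous 10 % dilutions of a 450 mL
   culture (each event multiplies OD by exactly 1/1.1).
3. Immunoblot tables with the standard ladders (RbcL 1500/750/375/187.5 fmol;
   PsbA 125/62.5/31.25/15.625 fmol) and sample lanes whose amounts follow
   from the per-cell ground truth and protein load.
4. Absorbance triplets (A664, A630, A750) consistent with the chlorophyll
   equation inverted through the 10x acetone dilution of the extract.
5. A per-culture composition table (C, C:N, protein, cell density).

Noise is multiplicative log-normal for fluorescence/OD/blot signals (always
positive) and additive Gaussian for absorbances; every channel inverts its
analysis stage exactly at zero noise.  All randomness descends from a single
seed through ``numpy.random.SeedSequence`` so manifests are byte-identical
across reruns.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from . import allocation, frrf, quantify
from .frrf import FlashletTrace, FrrRecording, SIGMA_SCALE
from .growthfit import TurbidostatLog, write_od_log
from .lightresponse import eilers_peeters_mu

__all__ = [
    "SynthError",
    "FrrProtocol",
    "Composition",
    "GroundTruth",
    "NoiseModel",
    "ScenarioConfig",
    "StudyConfig",
    "StudyBundle",
    "SMALL_DIATOM",
    "LARGE_DIATOM",
    "SPECIES_LIGHTS",
    "CELL_DENSITY_PER_ML",
    "COMPOSITION_TRUTH",
    "growth_curve_coefficients",
    "mu_truth",
    "frr_truth",
    "make_truth",
    "gen_frr_trace",
    "gen_turbidostat_log",
    "gen_blot_table",
    "gen_absorbance",
    "gen_study",
    "default_study_config",
]


class SynthError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# protocol and ground-truth containers


@dataclass
class FrrProtocol:
    """Flashlet-train geometry and relaxation sampling schedule.

    40 flashlets of 1.2 us at ~1e5 umol photons m^-2 s^-1 spread uniformly
    over a 128 us train; relaxation is sampled at ``n_relaxation`` log-spaced
    times bracketing typical tau1 (~hundreds of us) and tau2 (~ms).
    """

    n_flashlets: int = 40
    flashlet_duration_s: float = 1.2e-6
    flashlet_intensity_umol: float = 1e5
    train_span_s: float = 128e-6
    relaxation_start_s: float = 50e-6
    relaxation_window_s: float = 50e-3
    n_relaxation: int = 24
    dark_gap_s: float = 2.0

    def __post_init__(self):
        if self.n_flashlets < 1 or self.flashlet_duration_s <= 0:
            raise SynthError("flashlet count and duration must be positive")
        if self.n_flashlets * self.flashlet_duration_s > self.train_span_s:
            raise SynthError("flashlets do not fit in the train span")
        times = self.relaxation_times_s
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise SynthError("relaxation sampling times must be strictly increasing")

    @property
    def flashlet_times_s(self) -> np.ndarray:
        spacing = self.train_span_s / self.n_flashlets
        return spacing * np.arange(1, self.n_flashlets + 1)

    @property
    def relaxation_times_s(self) -> np.ndarray:
        return np.geomspace(self.relaxation_start_s, self.relaxation_window_s,
                            self.n_relaxation)

    @property
    def flashlet_dose_quanta_m2(self) -> float:
        return self.flashlet_intensity_umol * 1e-6 * Avogadro * self.flashlet_duration_s


@dataclass
class Composition:
    """Per-cell contents used as generating truth."""

    c_pg: float
    cn_mass: float
    chla_pg: float
    protein_pg: float
    psba_amol: float
    rbcl_amol: float

    @property
    def n_pg(self) -> float:
        return self.c_pg / self.cn_mass


@dataclass
class GroundTruth:
    """Generating parameters of one replicate culture.

    Fluorescence parameters describe the dark-adapted state; the light-
    acclimated state is derived through the primed-state factors (quenching
    of FM and sigma, the baseline quench of F0 and the 2-s recovery factor)
    and the steady-state closure model C_ss = sR/(1+sR) with s = sigma' I in
    quanta hits s^-1 and R = tau_ss the effective PSII turnover time under
    continuous light.
    """

    f0: float
    fm: float
    sigma_psii: float  # 1e-20 m^2 quanta^-1
    connectivity_p: float
    tau1_s: float
    tau2_s: float
    amp1: float
    amp2: float
    mu_day: float
    composition: Composition
    cell_density_per_ml: float
    filtered_volume_ml: float = 50.0
    tau_ss_s: float = 1e-3
    sigma_prime_factor: float = 0.95
    fm_prime_factor: float = 0.90
    f0_prime_factor: float = 0.95
    fm_recovery_2s: float = 1.05

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (self.fm >= self.f0 > 0):
            raise SynthError(f"need FM >= F0 > 0, got F0={self.f0}, FM={self.fm}")
        if not 0.0 <= self.connectivity_p < 1.0:
            raise SynthError("connectivity must be in [0, 1)")
        if not self.tau1_s < self.tau2_s:
            raise SynthError("tau1 must be < tau2")
        if abs(self.amp1 + self.amp2 - 1.0) > 1e-9:
            raise SynthError("relaxation amplitudes must sum to 1")
        if self.mu_day < 0:
            raise SynthError("growth rate must be >= 0")
        if self.sigma_psii <= 0:
            raise SynthError("sigma_PSII must be > 0")

    # -- light-acclimated state -------------------------------------------
    @property
    def fm_prime(self) -> float:
        return self.fm * self.fm_prime_factor

    @property
    def f0_prime(self) -> float:
        return self.f0 * self.f0_prime_factor

    @property
    def sigma_prime(self) -> float:
        return self.sigma_psii * self.sigma_prime_factor

    def steady_state_closure(self, actinic_umol: float) -> float:
        rate = self.sigma_prime * SIGMA_SCALE * actinic_umol * 1e-6 * Avogadro
        x = rate * self.tau_ss_s
        return x / (1.0 + x)

    def qp_true(self, actinic_umol: float) -> float:
        return 1.0 - self.steady_state_closure(actinic_umol)

    def etr_true(self, actinic_umol: float) -> float:
        return frrf.compute_etr(self.sigma_prime, actinic_umol, self.qp_true(actinic_umol))


@dataclass
class NoiseModel:
    """Measurement and between-replicate variability of the emulated study.

    CVs act as the log-sd of multiplicative log-normal factors (median-
    unbiased, always positive); absorbance noise is additive Gaussian.
    ``biological_cv`` spreads per-cell contents across replicate cultures,
    ``density_cv`` the cell density (the study accepted 20-50 % SD across
    treatments) and ``light_jitter_cv`` the small bioreactor-to-bioreactor
    differences in delivered light.
    """

    fluorescence_cv: float = 0.01
    od_cv: float = 0.02
    blot_cv: float = 0.05
    absorbance_sd: float = 0.005
    elemental_cv: float = 0.02
    biological_cv: float = 0.10
    density_cv: float = 0.30
    light_jitter_cv: float = 0.03

    def __post_init__(self):
        for name, val in asdict(self).items():
            if val < 0:
                raise SynthError(f"noise parameter {name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(cv * rng.standard_normal(size))


# ---------------------------------------------------------------------------
# study design constants

SMALL_DIATOM = "T_pseudonana"
LARGE_DIATOM = "T_punctigera"

SPECIES_LIGHTS = {SMALL_DIATOM: (30.0, 180.0, 380.0), LARGE_DIATOM: (30.0, 90.0, 180.0)}
CELL_DENSITY_PER_ML = {SMALL_DIATOM: 3.6e5, LARGE_DIATOM: 650.0}

#: treatment-mean per-cell contents, keyed (species, N level, nominal light):
#: C pg, mass C:N, Chl a pg, protein pg, PsbA amol, RbcL amol
COMPOSITION_TRUTH = {
    (SMALL_DIATOM, "LN", 30.0): Composition(10.5, 6.25, 0.25, 7.12, 0.73, 21.2),
    (SMALL_DIATOM, "HN", 30.0): Composition(8.29, 5.89, 0.27, 4.88, 0.30, 7.23),
    (SMALL_DIATOM, "LN", 180.0): Composition(9.25, 6.41, 0.20, 4.49, 0.43, 8.68),
    (SMALL_DIATOM, "HN", 180.0): Composition(8.09, 6.42, 0.13, 4.61, 0.33, 8.30),
    (SMALL_DIATOM, "LN", 380.0): Composition(8.91, 7.67, 0.08, 4.31, 0.40, 8.25),
    (SMALL_DIATOM, "HN", 380.0): Composition(8.71, 6.34, 0.09, 4.64, 0.34, 10.0),
    (LARGE_DIATOM, "LN", 30.0): Composition(5669.0, 5.30, 142.0, 4424.0, 246.0, 9578.0),
    (LARGE_DIATOM, "HN", 30.0): Composition(7675.0, 4.82, 115.0, 5703.0, 230.0, 3524.0),
    (LARGE_DIATOM, "LN", 90.0): Composition(6752.0, 7.61, 83.5, 3992.0, 215.0, 5178.0),
    (LARGE_DIATOM, "HN", 90.0): Composition(6921.0, 5.24, 79.1, 4475.0, 208.0, 3138.0),
    (LARGE_DIATOM, "LN", 180.0): Composition(8281.0, 9.28, 59.4, 4225.0, 206.0, 6977.0),
    (LARGE_DIATOM, "HN", 180.0): Composition(7160.0, 5.20, 58.3, 3503.0, 168.0, 2657.0),
}


def growth_curve_coefficients(species: str, nitrogen: str) -> tuple[float, float, float]:
    """Eilers-Peeters (a, b, c) of the generating growth-light response.

    High-N responses rise then fall (mu_max 1.5 d^-1 at I_opt 180 for the
    small species, 0.39 d^-1 at I_opt 90 for the large one); low-N responses
    saturate by 30 umol photons m^-2 s^-1 (a = 0) at a lower (small sp.) or
    higher (large sp.) plateau, matching the qualitative study outcome.
    """
    if (species, nitrogen) == (SMALL_DIATOM, "HN"):
        a, i_opt, mu_max = 1.2e-3, 180.0, 1.5
        return a, 1.0 / mu_max - 2.0 * a * i_opt, a * i_opt**2
    if (species, nitrogen) == (SMALL_DIATOM, "LN"):
        return 0.0, 1.0 / 1.05, 3.0
    if (species, nitrogen) == (LARGE_DIATOM, "HN"):
        a, i_opt, mu_max = 73.0769 / 3600.0, 90.0, 0.39
        return a, 1.0 / mu_max - 2.0 * a * i_opt, a * i_opt**2
    if (species, nitrogen) == (LARGE_DIATOM, "LN"):
        return 0.0, 1.0 / 0.55, 8.0
    raise SynthError(f"no growth-curve truth for {(species, nitrogen)}")


def mu_truth(species: str, nitrogen: str, irradiance_umol: float) -> float:
    a, b, c = growth_curve_coefficients(species, nitrogen)
    return float(eilers_peeters_mu(irradiance_umol, a, b, c))


def frr_truth(species: str, nitrogen: str, irradiance_umol: float) -> dict:
    """Dark-adapted photophysiology truth for one treatment.

    The small species holds FV/FM ~ 0.58 across treatments with sigma_PSII
    declining with growth light; the large species shows FV/FM falling from
    0.44 to 0.32 with light under HN (sustained PSII down-regulation), a
    higher FV/FM under LN, a large constant sigma_PSII and faster QA-
    reoxidation (smaller tau1) under LN.
    """
    if species == SMALL_DIATOM:
        fv_fm = 0.58
        sigma = max(550.0 - 0.5 * irradiance_umol, 200.0)
        tau1 = 400e-6
    elif species == LARGE_DIATOM:
        sigma = 700.0
        if nitrogen == "HN":
            fv_fm = max(0.44 - 0.0008 * (irradiance_umol - 30.0), 0.25)
            tau1 = 600e-6
        else:
            fv_fm = 0.50
            tau1 = 350e-6
    else:
        raise SynthError(f"unknown species {species!r}")
    return {
        "f0": 1.0 - fv_fm,
        "fm": 1.0,
        "sigma_psii": sigma,
        "connectivity_p": 0.3,
        "tau1_s": tau1,
        "tau2_s": 5e-3,
        "amp1": 0.7,
        "amp2": 0.3,
    }


def make_truth(
    species: str,
    nitrogen: str,
    light_nominal: float,
    light_actual: float | None = None,
    rng: np.random.Generator | None = None,
    noise: NoiseModel | None = None,
) -> GroundTruth:
    """Ground truth for one replicate of one treatment.

    Per-cell contents and cell density get independent log-normal replicate
    spreads (``biological_cv`` / ``density_cv``); the growth rate and the
    light-dependent photophysiology are evaluated at the replicate's actual
    delivered light.
    """
    noise = noise or NoiseModel.zero()
    rng = rng or np.random.default_rng(0)
    if light_actual is None:
        light_actual = light_nominal
    base = COMPOSITION_TRUTH[(species, nitrogen, light_nominal)]
    bcv = noise.biological_cv
    comp = Composition(
        c_pg=base.c_pg * _lognormal(rng, bcv),
        cn_mass=base.cn_mass * _lognormal(rng, bcv / 2.0),
        chla_pg=base.chla_pg * _lognormal(rng, bcv),
        protein_pg=base.protein_pg * _lognormal(rng, bcv),
        psba_amol=base.psba_amol * _lognormal(rng, bcv),
        rbcl_amol=base.rbcl_amol * _lognormal(rng, bcv),
    )
    gain = _lognormal(rng, noise.fluorescence_cv)  # instrument gain, cancels in ratios
    frr = frr_truth(species, nitrogen, light_actual)
    return GroundTruth(
        f0=frr["f0"] * gain,
        fm=frr["fm"] * gain,
        sigma_psii=frr["sigma_psii"],
        connectivity_p=frr["connectivity_p"],
        tau1_s=frr["tau1_s"],
        tau2_s=frr["tau2_s"],
        amp1=frr["amp1"],
        amp2=frr["amp2"],
        mu_day=mu_truth(species, nitrogen, light_actual),
        composition=comp,
        cell_density_per_ml=CELL_DENSITY_PER_ML[species] * _lognormal(rng, noise.density_cv),
    )


# ---------------------------------------------------------------------------
# per-channel generators


def gen_frr_trace(
    protocol: FrrProtocol,
    truth: GroundTruth,
    light_state: str = "dark",
    actinic_umol: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> FrrRecording:
    """Generate one FRR recording.

    ``light_state="dark"`` yields the dark-adapted induction (closure rising
    from 0) followed by biphasic relaxation samples.  ``light_state="actinic"``
    yields the light-acclimated induction whose baseline sits at the steady-
    state closure for ``actinic_umol``, plus the second induction taken after
    the 2-s dark gap (baseline F'_02s, maximum F'_M2s).
    """
    if light_state not in ("dark", "actinic"):
        raise SynthError(f"light_state must be 'dark' or 'actinic', got {light_state!r}")
    rng = np.random.default_rng(seed)
    times = protocol.flashlet_times_s
    excitation = np.full(protocol.n_flashlets, protocol.flashlet_intensity_umol)
    cum = protocol.flashlet_dose_quanta_m2 * np.arange(1, protocol.n_flashlets + 1)

    def induction(f0, fm, sigma, c0, state, actinic):
        f = frrf.induction_fluorescence(cum, f0, fm, sigma, truth.connectivity_p, c0)
        f = f * _lognormal(rng, noise_cv, len(f))
        return FlashletTrace(
            phase="induction",
            time_s=times,
            excitation_umol_m2_s=excitation,
            fluorescence=f,
            flashlet_duration_s=protocol.flashlet_duration_s,
            light_state=state,
            actinic_umol_m2_s=actinic,
        )

    if light_state == "dark":
        ind = induction(truth.f0, truth.fm, truth.sigma_psii, 0.0, "dark_adapted", 0.0)
        c_end = float(
            frrf.closure_fraction(cum[-1], truth.sigma_psii * SIGMA_SCALE, truth.connectivity_p)
        )
        f_peak = truth.f0 + (truth.fm - truth.f0) * c_end
        t_rel = protocol.relaxation_times_s
        f_rel = frrf.relaxation_fluorescence(
            t_rel, truth.f0, f_peak, truth.tau1_s, truth.tau2_s, truth.amp1
        )
        f_rel = f_rel * _lognormal(rng, noise_cv, len(f_rel))
        rel = FlashletTrace(
            phase="relaxation",
            time_s=t_rel,
            excitation_umol_m2_s=np.zeros_like(t_rel),
            fluorescence=f_rel,
            flashlet_duration_s=protocol.flashlet_duration_s,
            light_state="dark_adapted",
            actinic_umol_m2_s=0.0,
        )
        return FrrRecording(induction=ind, relaxation=rel)

    css = truth.steady_state_closure(actinic_umol)
    ind = induction(truth.f0_prime, truth.fm_prime, truth.sigma_prime, css,
                    "actinic", actinic_umol)
    fm_2s = truth.fm_prime * truth.fm_recovery_2s
    f0_2s = truth.f0_prime * truth.fm_recovery_2s  # proportional-correction inverse
    ind_2s = induction(f0_2s, fm_2s, truth.sigma_prime, 0.0, "actinic", actinic_umol)
    ind_2s.phase = "induction"
    rec = FrrRecording(induction=ind, induction_2s=ind_2s)
    return rec


def gen_turbidostat_log(
    truth: GroundTruth,
    setpoint: float = 1.0,
    dilution_fraction: float = 0.10,
    duration_h: float | None = None,
    sampling_interval_s: float | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    target_cycles: float = 14.5,
    samples_per_cycle: float = 2000.0,
) -> TurbidostatLog:
    """Simulate an OD680 log with instantaneous fractional dilutions.

    The culture starts freshly diluted at ``setpoint/(1+f)`` and regrows
    exponentially at the true rate; each setpoint crossing triggers an
    instantaneous dilution multiplying OD by exactly ``1/(1+f)`` (a 10 %
    volumetric addition to 450 mL gives 450/495 = 1/1.1).  Event times are
    recorded as ground truth in ``annotated_dilutions``.

    Defaults resolve each cycle with ~2000 samples (period clamped to
    1-300 s) and run for ~14.5 cycles; both can be overridden.  Runs covering
    fewer than 12 cycles are flagged ``short_run``; a zero growth rate yields
    an event-free, ``no_growth``-flagged log.
    """
    if not 0.0 < dilution_fraction < 1.0:
        raise SynthError("dilution_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mu = truth.mu_day
    flags: list[str] = []
    factor = 1.0 / (1.0 + dilution_fraction)
    if mu <= 0:
        duration_h = duration_h or 48.0
        interval = sampling_interval_s or 300.0
        t_h = np.arange(0.0, duration_h, interval / 3600.0)
        od = np.full_like(t_h, setpoint * factor)
        od = od * _lognormal(rng, noise_cv, len(od))
        return TurbidostatLog(t_h, od, annotated_dilutions=np.array([]),
                              flags=("no_growth",))

    cycle_h = math.log(1.0 + dilution_fraction) / mu * 24.0
    if duration_h is None:
        duration_h = target_cycles * cycle_h
    if sampling_interval_s is None:
        sampling_interval_s = float(np.clip(cycle_h * 3600.0 / samples_per_cycle, 1.0, 300.0))
    n_cycles = duration_h / cycle_h
    if n_cycles < 12.0:
        flags.append("short_run")

    t_h = np.arange(0.0, duration_h, sampling_interval_s / 3600.0)
    events = np.arange(1, int(np.floor(duration_h / cycle_h)) + 1) * cycle_h
    # OD at each sample: regrowth from the most recent dilution
    idx = np.searchsorted(events, t_h, side="right")
    last_event = np.where(idx > 0, events[np.clip(idx - 1, 0, None)], 0.0)
    od = setpoint * factor * np.exp(mu * (t_h - last_event) / 24.0)
    od = od * _lognormal(rng, noise_cv, len(od))
    return TurbidostatLog(t_h, od, annotated_dilutions=events, flags=tuple(flags))


def gen_blot_table(
    truth: GroundTruth,
    target: str,
    gain: float = 1000.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_sample_lanes: int = 2,
) -> quantify.BlotTable:
    """Generate one immunoblot table (standard ladder + sample lanes).

    Sample-lane amounts follow from the per-cell truth:
    fmol = (content amol / protein pg) x load ug x 1000.  Signals are
    gain x fmol with multiplicative noise, clamped at zero (flag column on
    each lane records nothing here; lognormal noise keeps signals positive,
    the clamp is a guard for user-supplied additive pipelines).
    """
    if gain < 0:
        raise SynthError("gain must be >= 0")
    rng = np.random.default_rng(seed)
    if target == "RbcL":
        ladder = quantify.RBCL_LADDER_FMOL
        content = truth.composition.rbcl_amol
    elif target == "PsbA":
        ladder = quantify.PSBA_LADDER_FMOL
        content = truth.composition.psba_amol
    else:
        raise SynthError(f"unknown blot target {target!r}")
    load_ug = quantify.BLOT_LOAD_UG[target]
    sample_fmol = content / truth.composition.protein_pg * load_ug * 1e3

    rows = []
    for i, fmol in enumerate(ladder):
        rows.append(("std%d" % (i + 1), "standard", fmol, fmol))
    for j in range(n_sample_lanes):
        rows.append(("sample%d" % (j + 1), "sample", float("nan"), sample_fmol))
    df = pd.DataFrame(rows, columns=["lane_id", "kind", "amount_fmol", "true_fmol"])
    signal = gain * df["true_fmol"].to_numpy() * _lognormal(rng, noise_cv, len(df))
    df["signal"] = np.maximum(signal, 0.0)
    df["saturated"] = False
    return quantify.BlotTable(
        lanes=df[["lane_id", "kind", "amount_fmol", "signal", "saturated"]],
        target=target,
        load_ug=load_ug,
    )


def gen_absorbance(
    truth: GroundTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    a750_baseline: float = 0.05,
    accessory_ratio: float = 0.3,
    extract_dilution: float = 10.0,
    extract_volume_ml: float = 0.45,
) -> quantify.AbsorbanceReading:
    """Absorbance triplet consistent with the per-cell Chl a truth.

    The chlorophyll equation is inverted with the accessory-pigment band set
    to ``accessory_ratio`` of the Chl band above baseline; additive Gaussian
    noise of sd ``noise_sd`` is applied to each absorbance independently.
    """
    rng = np.random.default_rng(seed)
    cells = truth.cell_density_per_ml * truth.filtered_volume_ml
    total_ug = truth.composition.chla_pg * cells * 1e-6
    extract_conc = total_ug / (extract_dilution * extract_volume_ml)
    x = extract_conc / (quantify.CHL_A_COEF_664 - quantify.CHL_A_COEF_630 * accessory_ratio)
    a664 = a750_baseline + x
    a630 = a750_baseline + accessory_ratio * x
    a750 = a750_baseline
    if noise_sd > 0:
        a664, a630, a750 = (a + noise_sd * rng.standard_normal() for a in (a664, a630, a750))
    return quantify.AbsorbanceReading(
        a664=float(a664),
        a630=float(a630),
        a750=float(a750),
        extract_dilution=extract_dilution,
        extract_volume_ml=extract_volume_ml,
        filtered_volume_ml=truth.filtered_volume_ml,
        cell_density_per_ml=truth.cell_density_per_ml,
    )


def gen_composition_row(truth: GroundTruth, noise: NoiseModel, seed: int = 0) -> dict:
    """Measured composition table for one culture (elemental analysis, protein
    assay, cell count); multiplicative measurement noise on each entry."""
    rng = np.random.default_rng(seed)
    cv = noise.elemental_cv
    return {
        "c_pg_cell": truth.composition.c_pg * float(_lognormal(rng, cv)),
        "cn_mass": truth.composition.cn_mass * float(_lognormal(rng, cv)),
        "protein_pg_cell": truth.composition.protein_pg * float(_lognormal(rng, cv)),
        "cell_density_per_ml": truth.cell_density_per_ml * float(_lognormal(rng, cv)),
        "filtered_volume_ml": truth.filtered_volume_ml,
    }


# ---------------------------------------------------------------------------
# study bundles


@dataclass
class ScenarioConfig:
    """One species x nitrogen-level scenario of the study design."""

    species: str
    nitrogen_level: str  # "HN" (~550 umol L^-1 NO3-) | "LN" (~55 umol L^-1)
    growth_lights: tuple = ()
    n_replicates: int = 3

    def __post_init__(self):
        if self.nitrogen_level not in ("HN", "LN"):
            raise SynthError("nitrogen_level must be 'HN' or 'LN'")
        if not self.growth_lights:
            self.growth_lights = SPECIES_LIGHTS[self.species]
        if len(self.growth_lights) == 0:
            raise SynthError("growth_lights must be non-empty")
        if self.n_replicates < 1:
            raise SynthError("need at least one replicate")


@dataclass
class StudyConfig:
    scenarios: list
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    protocol: FrrProtocol = field(default_factory=FrrProtocol)


@dataclass
class StudyBundle:
    path: Path
    runs: pd.DataFrame
    manifest: dict


def default_study_config(seed: int = 0, noise: NoiseModel | None = None,
                         n_replicates: int = 3) -> StudyConfig:
    """The full 2 species x 2 N x 3 lights design (36 runs at 3 replicates)."""
    scenarios = [
        ScenarioConfig(species, nitrogen, n_replicates=n_replicates)
        for species in (SMALL_DIATOM, LARGE_DIATOM)
        for nitrogen in ("LN", "HN")
    ]
    return StudyConfig(scenarios=scenarios, noise=noise or NoiseModel(), seed=seed)


def _truth_manifest_entry(truth: GroundTruth, light_actual: float) -> dict:
    comp = truth.composition
    n_pg = comp.n_pg
    derived = {
        "fv_fm": (truth.fm - truth.f0) / truth.fm,
        "fs": truth.f0_prime
        + (truth.fm_prime - truth.f0_prime) * truth.steady_state_closure(light_actual),
        "qp": truth.qp_true(light_actual),
        "etr": truth.etr_true(light_actual),
        "inv_tau1": 1.0 / truth.tau1_s,
        "n_pg": n_pg,
        "chla_n_fraction": allocation.chla_n_fraction(comp.chla_pg, n_pg),
        "psii_n_fraction": allocation.psii_n_fraction(comp.psba_amol, n_pg),
        "rubisco_n_fraction": allocation.rubisco_n_fraction(comp.rbcl_amol, n_pg),
        "rbcl_psba": allocation.rbcl_psba_ratio(comp.rbcl_amol, comp.psba_amol),
        "turnover_c_per_rbcl_s": allocation.rubisco_turnover(
            comp.c_pg, truth.mu_day, comp.rbcl_amol
        ),
    }
    entry = asdict(truth)
    entry["derived"] = derived
    return entry


def gen_study(config: StudyConfig, out_dir) -> StudyBundle:
    """Generate a full study bundle under ``out_dir``.

    Layout: ``runs.csv`` (one row of metadata per replicate run),
    ``manifest.json`` (per-run ground truth, for verification only — the
    analysis pipeline never reads it) and one directory per run holding
    ``frr_dark.csv``, ``frr_light.csv``, ``od_log.csv``, ``blot_rbcl.csv``,
    ``blot_psba.csv``, ``absorbance.csv`` and ``composition.csv``.
    Deterministic: the same config and seed reproduce every byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    noise = config.noise
    protocol = config.protocol

    runs = []
    for sc in config.scenarios:
        for light in sc.growth_lights:
            for rep in range(1, sc.n_replicates + 1):
                run_id = f"{sc.species}_{sc.nitrogen_level}_I{int(round(light)):03d}_r{rep}"
                runs.append((run_id, sc.species, sc.nitrogen_level, float(light), rep))
    ids = [r[0] for r in runs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SynthError(f"duplicate replicate identifiers: {dupes}")

    children = np.random.SeedSequence(config.seed).spawn(len(runs))
    manifest_runs = {}
    run_rows = []
    for (run_id, species, nitrogen, light, rep), child in zip(runs, children):
        rng = np.random.default_rng(child)
        sub_seeds = rng.integers(0, 2**31 - 1, size=7)
        light_actual = light * float(_lognormal(rng, noise.light_jitter_cv))
        truth = make_truth(species, nitrogen, light, light_actual, rng, noise)

        run_dir = out / run_id
        run_dir.mkdir(exist_ok=True)
        dark = gen_frr_trace(protocol, truth, "dark",
                             noise_cv=noise.fluorescence_cv, seed=int(sub_seeds[0]))
        frrf.write_recording(dark, run_dir / "frr_dark.csv")
        light_rec = gen_frr_trace(protocol, truth, "actinic", actinic_umol=light_actual,
                                  noise_cv=noise.fluorescence_cv, seed=int(sub_seeds[1]))
        frrf.write_recording(light_rec, run_dir / "frr_light.csv")
        log = gen_turbidostat_log(truth, noise_cv=noise.od_cv, seed=int(sub_seeds[2]))
        write_od_log(log, run_dir / "od_log.csv")
        for target, fname, s in (("RbcL", "blot_rbcl.csv", 3), ("PsbA", "blot_psba.csv", 4)):
            table = gen_blot_table(truth, target, noise_cv=noise.blot_cv,
                                   seed=int(sub_seeds[s]))
            quantify.write_blot_table(table, run_dir / fname)
        reading = gen_absorbance(truth, noise_sd=noise.absorbance_sd, seed=int(sub_seeds[5]))
        quantify.write_absorbance(reading, run_dir / "absorbance.csv")
        comp_row = gen_composition_row(truth, noise, seed=int(sub_seeds[6]))
        pd.DataFrame([comp_row]).to_csv(run_dir / "composition.csv", index=False,
                                        float_format="%.12g")

        manifest_runs[run_id] = {
            "species": species,
            "nitrogen_level": nitrogen,
            "light_nominal": light,
            "light_actual": light_actual,
            "replicate": rep,
            "truth": _truth_manifest_entry(truth, light_actual),
        }
        run_rows.append(
            {
                "run_id": run_id,
                "species": species,
                "nitrogen_level": nitrogen,
                "light_nominal": light,
                "light_actual": light_actual,
                "replicate": rep,
            }
        )

    runs_df = pd.DataFrame(run_rows)
    runs_df.to_csv(out / "runs.csv", index=False, float_format="%.12g")
    manifest = {
        "seed": config.seed,
        "noise": asdict(noise),
        "protocol": asdict(protocol),
        "scenarios": [asdict(sc) for sc in config.scenarios],
        "runs": manifest_runs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return StudyBundle(path=out, runs=runs_df, manifest=manifest)
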