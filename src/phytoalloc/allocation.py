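"""Nitrogen-allocation accounting and apparent RUBISCO turnover.

Per-cell contents of chlorophyll a, the PSII core subunit PsbA and the
RUBISCO large subunit RbcL are extrapolated to complex-level nitrogen and
expressed as molar fractions of total cellular nitrogen:

* Chl a carries 4 N atoms per molecule (molar mass 893.5 g mol^-1).
* One PsbA per PSII monomer; the whole PSII complex with its antenna is
  assigned ``n_atoms_per_psii_per_psba`` N atoms (default 4000).
* Eight RbcL per L8S8 RUBISCO holoenzyme (~560 kDa, ~16 % N by mass) gives
  ``n_atoms_per_rbcl`` N atoms per RbcL (default 800).

The complex-level stoichiometries are extrapolation factors, not measured
here; they are configuration constants with documented provenance and every
derived fraction is linear in them.

Apparent RUBISCO turnover (C atoms fixed per RbcL per second) combines
cellular carbon, the specific growth rate and RbcL content:

    turnover = (mol C cell^-1) * (e^mu - 1) / (mol RbcL cell^-1) / 86400

with mu in d^-1; the e^mu - 1 factor is the per-day fractional biomass gain
of exponential growth, and division by 86 400 converts to per second.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .quantify import CellComposition

__all__ = [
    "AllocationError",
    "StoichiometryConfig",
    "DEFAULT_STOICHIOMETRY",
    "AllocationBudget",
    "chla_n_fraction",
    "psii_n_fraction",
    "rubisco_n_fraction",
    "rbcl_psba_ratio",
    "rubisco_turnover",
    "build_budget",
]

PG_TO_G = 1e-12
AMOL_TO_MOL = 1e-18


class AllocationError(ValueError):
    """Raised for invalid allocation inputs or violated sanity gates."""


@dataclass(frozen=True)
class StoichiometryConfig:
    """Molar-mass and complex-level N constants used in the extrapolations."""

    n_atoms_per_chla: float = 4.0
    chla_molar_mass: float = 893.5  # g mol^-1
    n_molar_mass: float = 14.007  # g mol^-1
    c_molar_mass: float = 12.011  # g mol^-1
    n_atoms_per_psii_per_psba: float = 4000.0
    n_atoms_per_rbcl: float = 800.0
    seconds_per_day: float = 86400.0

    def __post_init__(self):
        for name, val in asdict(self).items():
            if not val > 0:
                raise AllocationError(f"stoichiometry constant {name} must be > 0")


DEFAULT_STOICHIOMETRY = StoichiometryConfig()


def _n_mol(n_pg: float, cfg: StoichiometryConfig) -> float:
    if not n_pg > 0:
        raise AllocationError(f"total N per cell must be > 0, got {n_pg}")
    return n_pg * PG_TO_G / cfg.n_molar_mass


def chla_n_fraction(chla_pg: float, n_pg: float,
                    cfg: StoichiometryConfig = DEFAULT_STOICHIOMETRY) -> float:
    """Molar fraction of cellular N bound in chlorophyll a."""
    if chla_pg < 0:
        raise AllocationError("Chl a content must be >= 0")
    chla_mol = chla_pg * PG_TO_G / cfg.chla_molar_mass
    return chla_mol * cfg.n_atoms_per_chla / _n_mol(n_pg, cfg)


def psii_n_fraction(psba_amol: float, n_pg: float,
                    cfg: StoichiometryConfig = DEFAULT_STOICHIOMETRY) -> float:
    """Molar fraction of cellular N in PSII, extrapolated from PsbA content."""
    if psba_amol < 0:
        raise AllocationError("PsbA content must be >= 0")
    return psba_amol * AMOL_TO_MOL * cfg.n_atoms_per_psii_per_psba / _n_mol(n_pg, cfg)


def rubisco_n_fraction(rbcl_amol: float, n_pg: float,
                       cfg: StoichiometryConfig = DEFAULT_STOICHIOMETRY) -> float:
    """Molar fraction of cellular N in RUBISCO, extrapolated from RbcL.

    A fraction above 1 is physically impossible and raises (sanity gate).
    """
    if rbcl_amol < 0:
        raise AllocationError("RbcL content must be >= 0")
    frac = rbcl_amol * AMOL_TO_MOL * cfg.n_atoms_per_rbcl / _n_mol(n_pg, cfg)
    if frac > 1.0:
        raise AllocationError(
            f"RUBISCO N fraction {frac:.3f} exceeds 1: contents and stoichiometry inconsistent"
        )
    return frac


def rbcl_psba_ratio(rbcl_amol: float, psba_amol: float) -> float:
    """Molar RbcL:PsbA ratio (unit-free as long as both share units)."""
    if not psba_amol > 0:
        raise AllocationError("PsbA content must be > 0 for the RbcL:PsbA ratio")
    return rbcl_amol / psba_amol


def rubisco_turnover(c_pg: float, mu_day: float, rbcl_amol: float,
                     cfg: StoichiometryConfig = DEFAULT_STOICHIOMETRY) -> float:
    """Apparent carbon assimilation per RbcL subunit, C RbcL^-1 s^-1."""
    if not rbcl_amol > 0:
        raise AllocationError("RbcL content must be > 0 for turnover")
    if mu_day < 0:
        raise AllocationError("growth rate must be >= 0")
    c_mol = c_pg * PG_TO_G / cfg.c_molar_mass
    rbcl_mol = rbcl_amol * AMOL_TO_MOL
    per_day = c_mol * math.expm1(mu_day) / rbcl_mol
    return per_day / cfg.seconds_per_day


@dataclass
class AllocationBudget:
    chla_n_fraction: float
    psii_n_fraction: float
    rubisco_n_fraction: float
    rbcl_psba: float
    turnover_c_per_rbcl_s: float
    flags: tuple = ()


def build_budget(comp: CellComposition, mu_day: float,
                 cfg: StoichiometryConfig = DEFAULT_STOICHIOMETRY) -> AllocationBudget:
    """Assemble the full allocation budget for one culture.

    Any component failure propagates as :class:`AllocationError` naming the
    offending quantity; a fraction sum above 1 is recorded as a warning flag
    but the budget is still emitted.
    """
    n_pg = comp.n_pg
    pieces = {}
    for name, fn in (
        ("chla_n_fraction", lambda: chla_n_fraction(comp.chla_pg, n_pg, cfg)),
        ("psii_n_fraction", lambda: psii_n_fraction(comp.psba_amol, n_pg, cfg)),
        ("rubisco_n_fraction", lambda: rubisco_n_fraction(comp.rbcl_amol, n_pg, cfg)),
        ("rbcl_psba", lambda: rbcl_psba_ratio(comp.rbcl_amol, comp.psba_amol)),
        ("turnover", lambda: rubisco_turnover(comp.c_pg, mu_day, comp.rbcl_amol, cfg)),
    ):
        try:
            pieces[name] = fn()
        except AllocationError as exc:
            raise AllocationError(f"{name}: {exc}") from exc
    flags = ()
    total = pieces["chla_n_fraction"] + pieces["psii_n_fraction"] + pieces["rubisco_n_fraction"]
    if total > 1.0:
        flags = ("fraction_sum_gt_1",)
    return AllocationBudget(
        chla_n_fraction=pieces["chla_n_fraction"],
        psii_n_fraction=pieces["psii_n_fraction"],
        rubisco_n_fraction=pieces["rubisco_n_fraction"],
        rbcl_psba=pieces["rbcl_psba"],
        turnover_c_per_rbcl_s=pieces["turnover"],
        flags=flags,
    )
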