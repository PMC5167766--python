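"""Study orchestration: generate/ingest -> fit -> quantify -> allocate.

``run_study`` walks a study bundle (one directory per replicate turbidostat
run, see :mod:`phytoalloc.synthdata` for the layout), derives every per-
replicate quantity, aggregates treatment means, fits growth-irradiance
responses per species x nitrogen level, and fits the cross-treatment
relationships between growth, RUBISCO allocation, QA-reoxidation rate and
the RbcL:PsbA ratio.  Failed replicates are recorded and skipped; the study
only fails if every replicate fails.  All outputs are plain tidy tables with
no timestamps, so reruns on unchanged inputs are byte-identical.

Statistical comparisons between treatments are deliberately not performed;
the exported tables are ready for any external stats tool.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import allocation, frrf, growthfit, lightresponse, quantify

__all__ = [
    "PipelineError",
    "StudyResults",
    "process_replicate",
    "run_study",
    "report",
    "write_results",
]

#: replicate-table quantities aggregated into the treatment summary
SUMMARY_QUANTITIES = [
    "mu_day",
    "fv_fm",
    "sigma_psii",
    "sigma_psii_prime",
    "qp",
    "etr",
    "tau1_s",
    "inv_tau1",
    "c_pg",
    "cn_mass",
    "n_pg",
    "chla_pg",
    "protein_pg",
    "psba_amol",
    "rbcl_amol",
    "chla_n_fraction",
    "psii_n_fraction",
    "rubisco_n_fraction",
    "rbcl_psba",
    "turnover_c_per_rbcl_s",
]


class PipelineError(RuntimeError):
    """Raised when a study cannot be processed at all."""


@dataclass
class StudyResults:
    replicates: pd.DataFrame
    treatments: pd.DataFrame
    light_response: pd.DataFrame
    cross_fits: pd.DataFrame
    failures: pd.DataFrame
    warnings: list = field(default_factory=list)


def process_replicate(run_dir, meta: dict,
                      stoich: allocation.StoichiometryConfig = allocation.DEFAULT_STOICHIOMETRY,
                      n_last: int = 10) -> dict:
    """Derive every per-replicate quantity from one run directory.

    Individual assay failures (e.g. a blot sample outside the ladder range)
    are recorded as flags and leave NaN in the affected columns; hard errors
    (unreadable traces) propagate to the caller.
    """
    run_dir = Path(run_dir)
    flags: list[str] = []
    row: dict = dict(meta)

    # --- FRR photophysiology -------------------------------------------
    dark_rec = frrf.read_recording(run_dir / "frr_dark.csv")
    dark_fit = frrf.fit_induction(dark_rec.induction)
    if dark_rec.relaxation is not None:
        dark_fit = frrf.fit_relaxation(dark_rec.relaxation, dark_fit)
    light_rec = frrf.read_recording(run_dir / "frr_light.csv")
    light_fit = frrf.fit_induction(
        light_rec.induction, fix_p=dark_fit.connectivity_p, fit_initial_closure=True
    )
    if light_rec.induction_2s is None:
        raise PipelineError(f"{run_dir}: light recording lacks the post-2s induction")
    light_2s_fit = frrf.fit_induction(
        light_rec.induction_2s, fix_p=dark_fit.connectivity_p
    )
    photo = frrf.derive_photophysiology(
        dark_fit, light_fit, light_2s_fit, float(meta["light_actual"])
    )
    row.update(
        f0=photo.f0, fm=photo.fm, fv_fm=photo.fv_fm, sigma_psii=photo.sigma_psii,
        connectivity_p=photo.connectivity_p, fs=photo.fs, fm_prime=photo.fm_prime,
        sigma_psii_prime=photo.sigma_psii_prime, f0_prime=photo.f0_prime,
        qp=photo.qp, etr=photo.etr, tau1_s=photo.tau1, tau2_s=photo.tau2,
        inv_tau1=photo.inv_tau1,
    )
    flags.extend(photo.flags)
    if not dark_fit.converged:
        flags.append("dark_fit_failed")

    # --- growth rate -----------------------------------------------------
    log = growthfit.read_od_log(run_dir / "od_log.csv")
    growth = growthfit.estimate_growth(log, n_last=n_last)
    row.update(mu_day=growth.mu_mean, mu_sd=growth.mu_sd,
               n_cycles_used=growth.n_cycles_used)
    flags.extend(growth.flags)

    # --- composition -----------------------------------------------------
    comp_df = pd.read_csv(run_dir / "composition.csv")
    crow = comp_df.iloc[0]
    c_pg = float(crow["c_pg_cell"])
    cn = float(crow["cn_mass"])
    protein_pg = float(crow["protein_pg_cell"])
    n_pg = quantify.nitrogen_per_cell(c_pg, cn)
    row.update(c_pg=c_pg, cn_mass=cn, protein_pg=protein_pg, n_pg=n_pg)

    contents = {}
    for target, fname, col in (("RbcL", "blot_rbcl.csv", "rbcl_amol"),
                               ("PsbA", "blot_psba.csv", "psba_amol")):
        table = quantify.read_blot_table(run_dir / fname)
        try:
            result = quantify.quantify_blot(table, protein_pg)
            for lane, msg in result["errors"].items():
                flags.append(f"{target}:{lane}:{msg}")
            contents[col] = result["amol_per_cell"]
        except quantify.QuantifyError as exc:
            flags.append(f"{target}:{exc}")
            contents[col] = float("nan")
    row.update(contents)

    reading = quantify.read_absorbance(run_dir / "absorbance.csv")
    extract_conc = quantify.chl_a_concentration(reading)
    if extract_conc < 0:
        flags.append("negative_chla_concentration")
    chla_pg = quantify.chl_a_per_cell(extract_conc, reading)
    row.update(chla_pg=chla_pg)

    # --- allocation ------------------------------------------------------
    for name, fn in (
        ("chla_n_fraction", lambda: allocation.chla_n_fraction(chla_pg, n_pg, stoich)),
        ("psii_n_fraction", lambda: allocation.psii_n_fraction(contents["psba_amol"], n_pg, stoich)),
        ("rubisco_n_fraction", lambda: allocation.rubisco_n_fraction(contents["rbcl_amol"], n_pg, stoich)),
        ("rbcl_psba", lambda: allocation.rbcl_psba_ratio(contents["rbcl_amol"], contents["psba_amol"])),
        ("turnover_c_per_rbcl_s",
         lambda: allocation.rubisco_turnover(c_pg, growth.mu_mean, contents["rbcl_amol"], stoich)),
    ):
        try:
            val = fn() if not any(math.isnan(v) for v in contents.values()) else float("nan")
        except (allocation.AllocationError, ValueError) as exc:
            flags.append(f"{name}:{exc}")
            val = float("nan")
        row[name] = val

    row["flags"] = ";".join(flags)
    return row


def _half_saturation(fit: lightresponse.LightResponseFit) -> float:
    """x at which an Eilers-Peeters fit reaches half its maximum."""
    if fit.model != "eilers_peeters" or not math.isfinite(fit.mu_max):
        return float("nan")
    target = fit.mu_max / 2.0
    x_hi = fit.i_opt if math.isfinite(fit.i_opt) else 10.0 * fit.c
    try:
        return float(optimize.brentq(
            lambda x: fit.predict(x) - target, 1e-12, x_hi, xtol=1e-12, rtol=1e-12
        ))
    except ValueError:
        return float("nan")


def _cross_fit_row(name: str, x, y, kind: str, subset: str) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    row = {"relationship": name, "subset": subset, "n": len(x), "model": "none",
           "a": np.nan, "b": np.nan, "c": np.nan, "mu_max": np.nan,
           "half_saturation": np.nan, "slope": np.nan, "intercept": np.nan,
           "slope_p": np.nan, "r2": np.nan, "flags": ""}
    try:
        if kind == "saturating":
            fit = lightresponse.fit_eilers_peeters(x, y)
            row.update(model=fit.model, a=fit.a, b=fit.b, c=fit.c, mu_max=fit.mu_max,
                       half_saturation=_half_saturation(fit), r2=fit.r2,
                       flags=";".join(fit.flags))
        else:
            fit = lightresponse.fit_linear_gated(x, y)
            row.update(model=fit.model, slope=fit.slope, intercept=fit.intercept,
                       slope_p=fit.slope_p, r2=fit.r2, flags=";".join(fit.flags))
    except lightresponse.LightResponseError as exc:
        row["flags"] = str(exc)
    return row


def run_study(
    bundle_dir,
    stoich: allocation.StoichiometryConfig = allocation.DEFAULT_STOICHIOMETRY,
    n_last: int = 10,
    pooled_exclude: tuple = (("T_pseudonana", "HN"),),
) -> StudyResults:
    """Process every replicate of a study bundle and fit the study-level
    relationships.

    ``pooled_exclude`` lists (species, nitrogen) groups left out of the
    pooled growth-vs-allocation fits (the small-species high-N cultures sit
    systematically above the shared saturating curve and are fitted
    separately by design); they remain in all other tables.
    """
    bundle_dir = Path(bundle_dir)
    runs_path = bundle_dir / "runs.csv"
    if not runs_path.exists():
        raise PipelineError(f"{bundle_dir} is not a study bundle (no runs.csv)")
    runs = pd.read_csv(runs_path)

    rows, failures = [], []
    for meta in runs.to_dict("records"):
        run_dir = bundle_dir / str(meta["run_id"])
        try:
            rows.append(process_replicate(run_dir, meta, stoich=stoich, n_last=n_last))
        except Exception as exc:  # fault isolation: record and continue
            failures.append({"run_id": meta["run_id"], "error": f"{type(exc).__name__}: {exc}"})
    if not rows:
        raise PipelineError(
            f"all {len(runs)} replicates failed; first error: "
            f"{failures[0]['error'] if failures else 'none'}"
        )
    replicates = pd.DataFrame(rows)

    # --- treatment aggregation (mean +/- SD over replicates) --------------
    group_cols = ["species", "nitrogen_level", "light_nominal"]
    agg = replicates.groupby(group_cols, sort=True)
    pieces = {"n": agg.size()}
    for q in SUMMARY_QUANTITIES:
        pieces[f"{q}_mean"] = agg[q].mean()
        pieces[f"{q}_sd"] = agg[q].std(ddof=1)
    treatments = pd.DataFrame(pieces).reset_index()

    # --- growth vs irradiance per species x N -----------------------------
    lr_rows = []
    for (species, nitrogen), sub in replicates.groupby(["species", "nitrogen_level"]):
        try:
            fit = lightresponse.select_response_model(
                sub["light_actual"].to_numpy(), sub["mu_day"].to_numpy()
            )
        except lightresponse.LightResponseError as exc:
            fit = lightresponse.LightResponseFit(model="none", n=len(sub),
                                                 flags=(str(exc),))
        lr_rows.append({
            "species": species, "nitrogen_level": nitrogen, "model": fit.model,
            "a": fit.a, "b": fit.b, "c": fit.c, "mu_max": fit.mu_max,
            "i_opt": fit.i_opt, "slope": fit.slope, "intercept": fit.intercept,
            "slope_p": fit.slope_p, "r2": fit.r2, "n": fit.n,
            "flags": ";".join(fit.flags),
        })
    light_response = pd.DataFrame(lr_rows)

    # --- cross-treatment relationships ------------------------------------
    excluded = replicates.apply(
        lambda r: (r["species"], r["nitrogen_level"]) in set(pooled_exclude), axis=1
    )
    pooled = replicates[~excluded]
    label = "pooled_excl_" + "_".join(f"{s}-{n}" for s, n in pooled_exclude) \
        if len(pooled_exclude) else "pooled_all"
    cross = [
        _cross_fit_row("mu_vs_rubisco_n_fraction", pooled["rubisco_n_fraction"],
                       pooled["mu_day"], "saturating", label),
        _cross_fit_row("turnover_vs_rubisco_n_fraction", pooled["rubisco_n_fraction"],
                       pooled["turnover_c_per_rbcl_s"], "linear", label),
        _cross_fit_row("inv_tau1_vs_rubisco_n_fraction", replicates["rubisco_n_fraction"],
                       replicates["inv_tau1"], "saturating", "pooled_all"),
        _cross_fit_row("inv_tau1_vs_rbcl_psba", replicates["rbcl_psba"],
                       replicates["inv_tau1"], "saturating", "pooled_all"),
        _cross_fit_row("mu_vs_rbcl_psba", replicates["rbcl_psba"],
                       replicates["mu_day"], "linear", "pooled_all"),
    ]
    cross_fits = pd.DataFrame(cross)

    warnings = [
        f"{r['run_id']}: {r['flags']}" for r in rows if r.get("flags")
    ]
    return StudyResults(
        replicates=replicates,
        treatments=treatments,
        light_response=light_response,
        cross_fits=cross_fits,
        failures=pd.DataFrame(failures, columns=["run_id", "error"]),
        warnings=warnings,
    )


def report(results: StudyResults) -> str:
    """Human-readable summary: treatment means +/- SD and the study-level
    fits.  No hypothesis tests are performed or reported."""
    lines = ["Study summary (mean +/- SD by species x nitrogen x light)", ""]
    fmt_cols = [
        ("mu_day", "mu (d^-1)", "{:.3f}"),
        ("fv_fm", "FV/FM", "{:.3f}"),
        ("sigma_psii", "sigma_PSII", "{:.0f}"),
        ("rubisco_n_fraction", "RUBISCO N:N", "{:.4f}"),
        ("turnover_c_per_rbcl_s", "C RbcL^-1 s^-1", "{:.3f}"),
    ]
    for _, row in results.treatments.iterrows():
        head = f"{row['species']} {row['nitrogen_level']} @ {row['light_nominal']:g} umol"
        parts = []
        n = int(row["n"])
        for col, label, fmt in fmt_cols:
            mean = row[f"{col}_mean"]
            sd = row[f"{col}_sd"]
            if n > 1 and np.isfinite(sd):
                parts.append(f"{label} {fmt.format(mean)} +/- {fmt.format(sd)}")
            else:
                parts.append(f"{label} {fmt.format(mean)} (n=1, SD omitted)")
        lines.append(f"  {head} (n={n}): " + "; ".join(parts))
    lines.append("")
    lines.append("Growth-irradiance fits:")
    for _, row in results.light_response.iterrows():
        if row["model"] == "eilers_peeters":
            lines.append(
                f"  {row['species']} {row['nitrogen_level']}: Eilers-Peeters "
                f"mu_max={row['mu_max']:.3f} d^-1 at I_opt={row['i_opt']:.0f} umol "
                f"(r2={row['r2']:.3f})"
            )
        elif row["model"] == "linear":
            lines.append(
                f"  {row['species']} {row['nitrogen_level']}: linear slope="
                f"{row['slope']:.4g} (p={row['slope_p']:.3g}, r2={row['r2']:.3f})"
            )
        else:
            lines.append(f"  {row['species']} {row['nitrogen_level']}: no model reported")
    lines.append("")
    lines.append("Cross-treatment fits:")
    for _, row in results.cross_fits.iterrows():
        if row["model"] == "eilers_peeters":
            desc = (f"saturating, max={row['mu_max']:.3g}, "
                    f"half-saturation={row['half_saturation']:.3g}, r2={row['r2']:.2f}")
        elif row["model"] == "linear":
            desc = (f"linear, slope={row['slope']:.3g} (p={row['slope_p']:.2g}), "
                    f"r2={row['r2']:.2f}")
        else:
            desc = "not reported (" + str(row["flags"]) + ")"
        lines.append(f"  {row['relationship']} [{row['subset']}]: {desc}")
    if len(results.failures):
        lines.append("")
        lines.append("Failed replicates:")
        for _, row in results.failures.iterrows():
            lines.append(f"  {row['run_id']}: {row['error']}")
    return "\n".join(lines) + "\n"


def write_results(results: StudyResults, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format="%.10g")
    results.replicates.to_csv(out / "replicates.csv", **kw)
    results.treatments.to_csv(out / "treatments.csv", **kw)
    results.light_response.to_csv(out / "light_response.csv", **kw)
    results.cross_fits.to_csv(out / "cross_fits.csv", **kw)
    results.failures.to_csv(out / "failures.csv", **kw)
    with open(out / "report.txt", "w") as fh:
        fh.write(report(results))
    with open(out / "warnings.log", "w") as fh:
        fh.write("\n".join(results.warnings) + ("\n" if results.warnings else ""))
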