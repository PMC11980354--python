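"""Data ingestion, validation, reporting, and the pipeline driver.

Individual-level tables arrive as CSV with idiosyncratic headers, so columns
are resolved through a declared header mapping rather than by position. Rows
failing validation (ages under the 15-year inclusion floor, unknown period
labels, sex codes outside {0, 1}) are quarantined with a reason, never
silently dropped.

`run_pipeline` ties the stages together: obtain an individual table (read or
simulate), fit the PH mortality model on everyone and within each period
stratum, and emit a compact summary table (stratum, n, effect (s.e.), CI,
LRT (p)) plus a machine-readable report embedding the exact configuration
and seed needed to regenerate it.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import fit as fitmod
from .hazards import ENTRY_AGE, GompertzMakehamParams
from .synthetic import SimConfig, simulate_assemblage

__all__ = [
    "DEFAULT_MAPPING",
    "load_site_table",
    "site_period_totals",
    "read_individuals",
    "write_individuals",
    "format_summary_row",
    "run_pipeline",
]

logger = logging.getLogger("paleomort")

#: Default header mapping: role -> column name, plus the declared period set.
DEFAULT_MAPPING = {
    "id": "id",
    "site": "site",
    "period": "period",
    "age_years": "age_years",
    "sex_code": "sex_code",
    "periods": ["early", "late"],
}


def load_site_table() -> pd.DataFrame:
    """The packaged 10-site medieval Irish assemblage composition table."""
    ref = importlib.resources.files("paleomort.data") / "sites_medieval_ireland.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def site_period_totals(sites: pd.DataFrame) -> dict:
    """Totals by period and overall from a per-site counts table."""
    out = {"total": int(sites["total"].sum()),
           "female": int(sites["female"].sum()),
           "male": int(sites["male"].sum())}
    for period, grp in sites.groupby("period"):
        out[f"n_{period}"] = int(grp["total"].sum())
    return out


def read_individuals(path, mapping: dict | None = None,
                     rejects_path=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate an individual-level CSV.

    Returns (valid, rejects); rejects carries a ``reject_reason`` column and
    is optionally written to ``rejects_path``. Validation: age present and
    >= 15 (the adult inclusion rule), period within the declared set, sex
    code in {0, 1} when present.
    """
    m = {**DEFAULT_MAPPING, **(mapping or {})}
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    required = [m["id"], m["site"], m["period"]]
    missing = [c for c in required if c not in df.columns]
    if m["age_years"] not in df.columns:
        missing.append(m["age_years"])
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")

    df = df.rename(columns={m["id"]: "id", m["site"]: "site", m["period"]: "period",
                            m["age_years"]: "age_years"})
    if m["sex_code"] in df.columns:
        df = df.rename(columns={m["sex_code"]: "sex_code"})

    reasons = pd.Series("", index=df.index)
    age = pd.to_numeric(df["age_years"], errors="coerce")
    reasons[age.isna()] += "unparseable age;"
    reasons[age < ENTRY_AGE] += f"age below {ENTRY_AGE:g}-year inclusion rule;"
    reasons[~df["period"].isin(m["periods"])] += "unknown period label;"
    if "sex_code" in df.columns:
        sex = pd.to_numeric(df["sex_code"], errors="coerce")
        bad_sex = sex.notna() & ~sex.isin([0, 1])
        reasons[bad_sex] += "sex code not in {0,1};"

    ok = reasons == ""
    valid = df[ok].copy()
    valid["age_years"] = age[ok]
    rejects = df[~ok].copy()
    rejects["reject_reason"] = reasons[~ok].str.rstrip(";")
    if rejects_path is not None and len(rejects):
        rejects.to_csv(rejects_path, index=False)

    counts = (valid.groupby(["site", "period"]).size().rename("n").reset_index()
              if len(valid) else pd.DataFrame())
    logger.info("read %d valid individuals (%d quarantined) from %s\n%s",
                len(valid), len(rejects), path, counts)
    return valid, rejects


def write_individuals(df: pd.DataFrame, path) -> None:
    """Write an individual table; the lossless counterpart of read_individuals."""
    df.to_csv(path, index=False)


def _fmt_ci(ci) -> str:
    return f"{ci[0]:.2f}, {ci[1]:.2f}" if ci is not None else "—"


def format_summary_row(label: str, n: int, effect: float, se: float | None,
                       ci=None, lrt_stat: float | None = None,
                       p: float | None = None) -> str:
    """One summary line: ``label (n = N) | effect (s.e.) | CI | LRT (p)``."""
    se_s = f"{se:.2f}" if se is not None else "—"
    lrt_s = f"{lrt_stat:.2f} ({p:.2f})" if lrt_stat is not None else "—"
    return f"{label} (n = {n}) | {effect:.2f} ({se_s}) | {_fmt_ci(ci)} | {lrt_s}"


def _fit_block(fit, ci, test=None):
    block = {
        "n": fit.n_used,
        "family": fit.family,
        "converged": fit.converged,
        "loglik": fit.loglik,
        "params": {name: fit.parameter_value(name) for name in fit.free_parameters},
        "se": fit.se,
        "rho_ci": list(ci) if ci is not None else None,
    }
    if test is not None:
        block["lrt"] = {"stat": test.stat, "df": test.df, "p": test.p,
                        "significant": test.significant, "alpha": test.alpha}
    return block


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis and return a report bundle.

    ``config`` names either a ``simulate`` block (SimConfig fields) or an
    ``input`` block (path + header mapping), plus optional ``family``
    ("gm"/"gompertz"), ``alpha``, ``ci`` ("wald"/"profile"), ``ci_level``,
    ``n_starts``, ``seed`` and ``strata`` (list of period labels).
    """
    family = config.get("family", "gm")
    alpha = float(config.get("alpha", fitmod.DEFAULT_ALPHA))
    ci_method = config.get("ci", "wald")
    level = float(config.get("ci_level", 0.95))
    seed = int(config.get("seed", fitmod.DEFAULT_SEED))
    opts = fitmod.FitOptions(n_starts=int(config.get("n_starts", 10)),
                             seed=seed, ci_level=level)

    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", seed)
        if "baseline" in sim and isinstance(sim["baseline"], dict):
            sim["baseline"] = GompertzMakehamParams(**sim["baseline"])
        asm = simulate_assemblage(SimConfig(**sim), estimate_age=False, estimate_sex=False)
        df = asm.table.rename(columns={"age_true": "age_years", "sex_true": "sex_code"})
        provenance = asm.provenance
    elif "input" in config:
        df, _ = read_individuals(config["input"]["path"],
                                 mapping=config["input"].get("mapping"))
        provenance = {"input": str(config["input"]["path"])}
    else:
        raise ValueError("config must contain a 'simulate' or 'input' block")

    data = fitmod.individuals_from_frame(df)
    full = fitmod.fit_mle(data, family=family, covariate=True, options=opts)
    reduced = fitmod.fit_mle(data, family=family, covariate=False, options=opts)
    test = fitmod.lrt(full, reduced, alpha=alpha)
    if ci_method == "profile":
        ci_all = fitmod.profile_ci(data, full, level=level)
    else:
        ci_all = fitmod.wald_ci(full, level=level, parameter="rho")

    strata = config.get("strata", ["early", "late"])
    comp = fitmod.compare_strata(data, strata=strata, level=level, family=family,
                                 options=opts, ci_method=ci_method)

    lines = [format_summary_row("All individuals", full.n_used, full.params.rho,
                                full.se.get("rho"), ci_all, test.stat, test.p)]
    for label, f in comp.fits.items():
        lines.append(format_summary_row(f"{label.capitalize()} period", f.n_used,
                                        f.params.rho, f.se.get("rho"),
                                        comp.cis.get(label)))

    if test.significant:
        covariate_conclusion = (
            f"The covariate improved the fit of the baseline model "
            f"(LRT p = {test.p:.3f} < alpha = {alpha:g})."
        )
    else:
        covariate_conclusion = (
            f"The likelihood-ratio test failed to indicate an effect of the covariate "
            f"on mortality risks (LRT p = {test.p:.3f} at alpha = {alpha:g}); this is "
            "not evidence of no effect."
        )

    bundle = {
        "config": {k: v for k, v in config.items() if k != "input"},
        "seed": seed,
        "provenance": provenance,
        "all": _fit_block(full, ci_all, test),
        "reduced": {"loglik": reduced.loglik, "converged": reduced.converged,
                    "params": {n: reduced.parameter_value(n) for n in reduced.free_parameters}},
        "strata": {label: _fit_block(f, comp.cis.get(label))
                   for label, f in comp.fits.items()},
        "strata_skipped": comp.skipped,
        "strata_overlap": comp.overlap,
        "conclusions": [covariate_conclusion, comp.conclusion],
        "summary_lines": lines,
        "text": "\n".join(lines),
    }
    return bundle


def bundle_to_json(bundle: dict) -> str:
    """Serialise a report bundle to JSON (numpy scalars coerced)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return str(o)

    return json.dumps(bundle, indent=2, default=default)
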