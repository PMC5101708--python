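"""End-to-end study pipeline.

Order of stages mirrors the analysis plan: simulate (or load) the
cohort → NCA per subject-occasion → per-subject means → twin
variance-component models + pairwise correlations → repeated-measures
genetic component → genotype/covariate association → per-zygosity PK
summary.  Identical config + seed gives an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import association as assoc
from . import heritability as herit
from . import io as tio
from . import nca, rgc, simulate
from .config import RunConfig, SimulationConfig

__all__ = ["run_pipeline"]

log = logging.getLogger("twinpk")

RGC_COLUMNS = ["cl_f", "auc_inf", "cmax", "tmax"]
TWIN_MODELS = ["ACE", "ADE", "AE", "CE"]


def _fit_table(pairs: herit.TwinPairSet, config: RunConfig) -> pd.DataFrame:
    fits = [herit.fit_saturated(pairs)]
    for m in TWIN_MODELS:
        fit = herit.fit_twin_model(pairs, m)
        fit.ci_95 = herit.component_confidence_intervals(
            fit, pairs, n_boot=config.bootstrap_reps, seed=config.seed
        )
        fits.append(fit)
    best = herit.select_model(fits[1:])
    rows = []
    for f in fits:
        row = {
            "model": f.model,
            "A": f.a2,
            "D": f.d2,
            "C": f.c2,
            "E": f.e2,
            "chi2": f.chi2_vs_saturated,
            "p": f.p_vs_saturated,
            "AIC": f.aic,
            "log_likelihood": f.log_likelihood,
            "selected": f.model == best.model,
        }
        for comp, ci in f.ci_95.items():
            if not comp.startswith("_"):
                row[f"{comp}_ci_low"], row[f"{comp}_ci_high"] = ci
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all output tables plus report.json."""
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(config.out_dir, name)
        df.to_csv(path, index=False)
        written.append(path)

    stage = "input"
    try:
        if config.conc_path:
            conc = tio.read_concentrations(config.conc_path)
            geno = tio.read_genotypes(config.geno_path) if config.geno_path else None
            covar = tio.read_covariates(config.covar_path) if config.covar_path else None
        else:
            stage = "simulate"
            sim = config.simulation or SimulationConfig(seed=config.seed)
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
            cohort = simulate.simulate_cohort(sim)
            simulate.write_cohort(cohort, config.out_dir)
            conc = cohort.concentration_table
            geno = cohort.genotype_table
            covar = cohort.covariate_table
        log.info("concentration rows: %d", len(conc))

        stage = "nca"
        per_occ, per_subj = nca.nca_table(conc, dose_mg=config.dose_mg,
                                          auc7_interpolation=config.auc7_interpolation)
        meta = conc.drop_duplicates("subject_id").set_index("subject_id")[
            ["pair_id", "zygosity"]
        ]
        per_occ = per_occ.merge(meta, left_on="subject_id", right_index=True)
        per_subj = per_subj.merge(meta, left_on="subject_id", right_index=True)
        save(pd.concat([per_occ, per_subj]), "pk_parameters.csv")

        stage = "heritability"
        pheno = per_subj.copy()
        value_col = "cl_f"
        if config.log_scale:
            pheno["log_cl_f"] = np.log(pheno["cl_f"])
            value_col = "log_cl_f"
        pairs = herit.TwinPairSet.from_frame(pheno, value_col)
        model_table = _fit_table(pairs, config)
        save(model_table, "heritability.csv")
        correlations = {}
        for zyg in ("MZ", "DZ"):
            try:
                r, ci = herit.pairwise_correlation(pairs, zyg)
                correlations[zyg] = {"r": r, "ci_95": list(ci)}
            except ValueError as exc:
                correlations[zyg] = {"error": str(exc)}

        stage = "rgc"
        rgc_rows = []
        for col in RGC_COLUMNS:
            if per_occ.groupby("subject_id").size().max() < 2:
                break
            res = rgc.compute_rgc(
                per_occ, col, n_resamples=config.rgc_resamples, seed=config.seed
            )
            rgc_rows.append(
                {
                    "parameter": col,
                    "vb": res.vb,
                    "vw": res.vw,
                    "rgc": res.rgc,
                    "ci_low": res.ci_95[0],
                    "ci_high": res.ci_95[1],
                    "negative": res.rgc < 0,
                    "n_resamples": res.n_resamples,
                }
            )
        rgc_table = pd.DataFrame(rgc_rows)
        if len(rgc_table):
            save(rgc_table, "rgc.csv")

        stage = "association"
        assoc_table = regression_table = None
        overall = None
        if geno is not None:
            assoc_table = assoc.genotype_trend_table(per_subj, geno, "cl_f")
            save(assoc_table, "assoc.csv")
        if covar is not None and geno is not None:
            covar2 = assoc.diet_scores(covar)
            wide = geno.pivot_table(
                index="subject_id", columns="locus", values="allele_count",
                aggfunc="first",
            )
            test_loci = [c for c in wide.columns if not str(c).startswith("ZYG")][:2]
            factors = covar2.set_index("subject_id")[
                ["sex", "age", "bmi", "protein_score", "vegetable_score"]
            ].join(wide[test_loci])
            # constant factors (e.g. a monomorphic locus in a small cohort)
            # carry no information and would break the OLS design
            factors = factors.loc[:, factors.std(axis=0) > 0]
            merged = per_subj.set_index("subject_id").join(factors, how="inner")
            regression_table, overall = assoc.multiple_regression(
                merged["cl_f"], merged[factors.columns]
            )
            save(regression_table, "regression.csv")

        stage = "summary"
        summary = tio.summarize_pk(per_subj, meta["zygosity"])
        save(summary, "pk_summary.csv")

        report = {
            "provenance": {
                # hash covers the analysis-relevant settings, not filesystem
                # locations, so re-runs elsewhere compare equal
                "config_hash": tio.config_hash(
                    {
                        k: v
                        for k, v in config.to_dict().items()
                        if k not in ("out_dir", "conc_path", "geno_path", "covar_path")
                    }
                ),
                "seed": config.seed,
                "n_subjects": int(per_subj["subject_id"].nunique()),
            },
            "pk_summary": summary.to_dict(orient="records"),
            "heritability": json.loads(model_table.to_json(orient="records")),
            "pairwise_correlations": correlations,
            "rgc": rgc_table.to_dict(orient="records") if len(rgc_table) else [],
            "association": assoc_table.to_dict(orient="records")
            if assoc_table is not None
            else [],
            "regression": {
                "factors": regression_table.to_dict(orient="records"),
                "overall": overall,
            }
            if regression_table is not None
            else {},
        }
        path = os.path.join(config.out_dir, "report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report
    except Exception as exc:
        for p in written:  # remove partial outputs so failures are clean
            if os.path.exists(p):
                os.remove(p)
        log.error("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
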