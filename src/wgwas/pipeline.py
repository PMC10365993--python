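"""End-to-end orchestration: simulate -> weights -> scans -> LDSC -> MR.

A :class:`RunConfig` fully determines a run (every stochastic stage has an
explicit seed); each stage persists its artifacts as TSV under the output
directory, and the final report is written both as machine-readable JSON
and as human-readable text.  Stages communicate only through the documented
file formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from wgwas import gwas, io, ldsc, mr, weights as wmod
from wgwas import synthetic as syn

logger = logging.getLogger("wgwas.pipeline")

__all__ = ["RunConfig", "run_pipeline", "config_from_yaml", "config_to_yaml"]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run.

    Desk-scale defaults: a 50,000-individual target population, 5,000 SNPs,
    a 10% participation rate (~5,000 volunteers) and a 2,000-individual
    reference sample; the
    genome-wide significance threshold is relaxed to 1e-5 because discovery
    at 5e-8 requires hundreds of thousands of individuals.
    """

    scenario: str = "healthy_volunteer"
    n_population: int = 50_000
    n_snps: int = 5_000
    n_reference: int = 2_000
    target_fraction: float = 0.10
    seed: int = 0
    weights_source: str = "lasso"  # "lasso" or "oracle"
    n_folds: int = 5
    n_lambda: int = 30
    significance: float = 1e-5
    n_pcs: int = 5
    ld_window_kb: float = 1_000.0
    n_blocks: int = 200
    clump_window_kb: float = 250.0
    clump_r2: float = 0.1
    mr_window_kb: float = 10_000.0
    mr_r2: float = 0.001
    min_instruments: int = 10
    weight_cap_percentile: Optional[float] = None  # optional extreme-weight cap

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def config_to_yaml(config: RunConfig, path) -> None:
    io.write_yaml(asdict(config), path)


def config_from_yaml(path) -> RunConfig:
    return RunConfig(**io.read_yaml(path))


def _build_scenario(config: RunConfig) -> syn.Scenario:
    if config.scenario == "healthy_volunteer":
        return syn.healthy_volunteer_scenario(
            seed=config.seed,
            n_population=config.n_population,
            n_snps=config.n_snps,
            n_reference=config.n_reference,
            target_fraction=config.target_fraction,
        )
    if config.scenario == "null":
        # participation unrelated to anything: weighting should change nothing
        sc = syn.healthy_volunteer_scenario(
            seed=config.seed,
            n_population=config.n_population,
            n_snps=config.n_snps,
            n_reference=config.n_reference,
            target_fraction=config.target_fraction,
        )
        sc.participation = syn.ParticipationModel(
            logit_coefficients={}, target_fraction=config.target_fraction
        )
        return sc
    raise ValueError(f"unknown scenario {config.scenario!r}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                logger.error("stage %s: FAILED", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            logger.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full workflow and return the run report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_to_yaml(config, outdir / "config.yaml")
    report: dict = {"config": asdict(config), "config_hash": config.digest()}

    # ---- simulate -------------------------------------------------------
    scenario = _stage("scenario")(_build_scenario)(config)
    data = syn.generate_scenario(scenario)
    g_pop: syn.GenotypeSet = data["genotypes"]
    population = data["population"]
    selected = data["selected"]
    reference = data["reference"]
    sel_idx = data["selected_index"]

    stacked = syn.stack_cohorts(selected, reference)
    io.write_cohort_tsv(stacked, outdir / "cohort_stacked.tsv")

    g_sel = g_pop.subset(individuals=sel_idx)
    sel_ids = selected["id"].tolist()
    io.write_plink(g_sel, outdir / "genotypes_selected", ids=sel_ids)

    # ---- weights --------------------------------------------------------
    if config.weights_source == "oracle":
        P = selected["true_P"].to_numpy()
        fit_info = {"source": "oracle"}
    else:
        design = wmod.build_design(stacked)
        fit = wmod.fit_participation_model(
            design,
            stacked["participation"].to_numpy(),
            sample_weight=stacked["design_weight"].to_numpy(),
            n_folds=config.n_folds,
            seed=config.seed,
            n_lambda=config.n_lambda,
        )
        P = fit.P
        fit_info = {
            "source": "lasso",
            "lambda": fit.lambda_,
            "n_predictors": design.shape[1],
            "n_retained_predictors": fit.n_retained_predictors,
        }
    pw = wmod.compute_weights(P)
    w_in = pw.w_in
    if config.weight_cap_percentile is not None:
        cap = np.percentile(pw.w, config.weight_cap_percentile)
        w_capped = np.minimum(pw.w, cap)
        w_in = w_capped / w_capped.mean()
    io.write_weights_tsv(sel_ids, pw.P, pw.w, w_in, outdir / "weights.tsv")

    rep = wmod.bias_report(
        selected, reference, w_in,
        reference_weights=reference["design_weight"].to_numpy(),
    )
    rep.to_csv(outdir / "bias_report.tsv", sep="\t", index=False)
    br_summary = wmod.summarize_bias_reduction(rep)
    report["weights"] = {
        **fit_info,
        "n_selected": int(len(selected)),
        "n_reference": int(len(reference)),
        "n_effective": pw.n_effective,
        "w_in_quantiles": {
            q: float(np.quantile(w_in, float(q))) for q in ("0.01", "0.25", "0.5", "0.75", "0.99")
        },
        "bias_reduction": br_summary,
    }

    # ---- GWAS both arms per trait --------------------------------------
    g_qc, qc_report = gwas.qc_filter(g_sel)
    qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    pcs = gwas.compute_pcs(g_qc, n_components=config.n_pcs, seed=config.seed)
    sex01 = (selected["sex"].astype(str) == "female").to_numpy(dtype=float)
    age = selected["age"].to_numpy(dtype=float)
    covars = np.column_stack([pcs, sex01, age])

    scans: dict[str, dict[str, pd.DataFrame]] = {}
    comparisons = {}
    for trait in data["traits"].columns:
        y = data["traits"][trait].to_numpy()[sel_idx]
        ss = gwas.run_scan(g_qc, y, covariates=covars, weights=None)
        ss_w = gwas.run_scan(g_qc, y, covariates=covars, weights=w_in)
        io.write_summary_stats(ss, outdir / f"gwas_{trait}.tsv")
        io.write_summary_stats(ss_w, outdir / f"wgwas_{trait}.tsv")
        scans[trait] = {"standard": ss, "weighted": ss_w}
        hits, summary = gwas.compare_scans(ss, ss_w, threshold=config.significance)
        hits.to_csv(outdir / f"compare_{trait}.tsv", sep="\t", index=False)
        comparisons[trait] = summary
    report["gwas"] = comparisons

    # participation-liability scan (weighted only, by construction)
    ss_part = gwas.participation_liability_scan(
        g_qc, selected["true_P"].to_numpy() if config.weights_source == "oracle" else P,
        weights=w_in, covariates=covars,
    )
    io.write_summary_stats(ss_part, outdir / "wgwas_participation.tsv")
    part_leads = gwas.clump(
        ss_part, g_qc, window_kb=config.clump_window_kb,
        r2_max=config.clump_r2, threshold=config.significance,
    )
    report["participation_gwa"] = {"n_lead_snps": len(part_leads)}

    # sex scans
    ss_sex, ss_sex_w = gwas.sex_scan(g_qc, sex01, weights=w_in, covariates=pcs)
    io.write_summary_stats(ss_sex, outdir / "gwas_sex.tsv")
    io.write_summary_stats(ss_sex_w, outdir / "wgwas_sex.tsv")

    # ---- LDSC -----------------------------------------------------------
    ld = ldsc.compute_ld_scores(g_qc, window_kb=config.ld_window_kb)
    ld.table.to_csv(outdir / "ld_scores.tsv", sep="\t", index=False)
    h2_rows = []
    diffs_p = []
    fits = {}
    for trait, arms in {**scans, "sex": {"standard": ss_sex, "weighted": ss_sex_w}}.items():
        f = ldsc.estimate_h2(arms["standard"], ld, n_blocks=config.n_blocks)
        f_w = ldsc.estimate_h2(arms["weighted"], ld, n_blocks=config.n_blocks)
        r = ldsc.jackknife_correlation(f.blocks, f_w.blocks)
        dt = ldsc.difference_test(f.h2, f_w.h2, f.se, f_w.se, r)
        fits[trait] = (f, f_w)
        h2_rows.append(
            {
                "trait": trait, "h2": f.h2, "h2_se": f.se, "intercept": f.intercept,
                "h2_w": f_w.h2, "h2_w_se": f_w.se, "intercept_w": f_w.intercept,
                "h2_diff": dt.diff, "se_diff": dt.se_diff, "r": dt.r, "z": dt.z, "p": dt.p,
            }
        )
        diffs_p.append(dt.p)
    trait_names = list(scans) + ["sex"]
    rg_rows = []
    for i, t1 in enumerate(list(scans)):
        for t2 in list(scans)[i + 1:]:
            rgf = ldsc.estimate_rg(scans[t1]["standard"], scans[t2]["standard"], ld,
                                   n_blocks=config.n_blocks)
            rgf_w = ldsc.estimate_rg(scans[t1]["weighted"], scans[t2]["weighted"], ld,
                                     n_blocks=config.n_blocks)
            if np.isfinite(rgf.rg) and np.isfinite(rgf_w.rg):
                r = ldsc.jackknife_correlation(rgf.blocks, rgf_w.blocks)
                dt = ldsc.difference_test(rgf.rg, rgf_w.rg, rgf.se, rgf_w.se, r)
                rg_rows.append(
                    {
                        "trait_1": t1, "trait_2": t2, "rg": rgf.rg, "rg_se": rgf.se,
                        "rg_w": rgf_w.rg, "rg_w_se": rgf_w.se, "rg_diff": dt.diff,
                        "se_diff": dt.se_diff, "r": dt.r, "z": dt.z, "p": dt.p,
                    }
                )
                diffs_p.append(dt.p)
    h2_tbl = pd.DataFrame(h2_rows)
    rg_tbl = pd.DataFrame(rg_rows)

    # ---- MR -------------------------------------------------------------
    mr_rows = []
    traits = list(scans)
    for exp_t in traits:
        for out_t in traits:
            if exp_t == out_t:
                continue
            try:
                instr = mr.select_instruments(
                    scans[exp_t]["standard"], scans[exp_t]["weighted"], g_qc,
                    threshold=config.significance, window_kb=config.mr_window_kb,
                    r2_max=config.mr_r2, min_instruments=config.min_instruments,
                )
            except mr.InsufficientInstruments as exc:
                mr_rows.append({"exposure": exp_t, "outcome": out_t, "excluded": str(exc)})
                continue
            tbl = mr.harmonize_instruments(
                instr, scans[exp_t]["standard"], scans[out_t]["standard"],
                scans[exp_t]["weighted"], scans[out_t]["weighted"],
            )
            fit_std, fit_w, comp = mr.mr_difference(tbl, corrected=True)
            mr_rows.append(
                {
                    "exposure": exp_t, "outcome": out_t, "m": fit_std.m,
                    "alpha": comp.alpha, "alpha_se": fit_std.se_corrected,
                    "alpha_w": comp.alpha_w, "alpha_w_se": fit_w.se_corrected,
                    "alpha_diff": comp.diff, "se_diff": comp.se_diff,
                    "r": comp.r, "z": comp.z, "p": comp.p, "excluded": "",
                }
            )
            diffs_p.append(comp.p)
    mr_tbl = pd.DataFrame(mr_rows)

    # FDR across all difference tests of the invocation
    all_p = np.array(diffs_p, dtype=float)
    if all_p.size:
        adj = mr.fdr_adjust(all_p)
        k = 0
        for tbl in (h2_tbl, rg_tbl):
            if "p" in tbl.columns and len(tbl):
                n_t = len(tbl)
                tbl["p_fdr"] = adj[k : k + n_t]
                k += n_t
        if "p" in mr_tbl.columns and len(mr_tbl):
            mask = mr_tbl["p"].notna()
            mr_tbl.loc[mask, "p_fdr"] = adj[k : k + int(mask.sum())]

    h2_tbl.to_csv(outdir / "ldsc_h2.tsv", sep="\t", index=False)
    rg_tbl.to_csv(outdir / "ldsc_rg.tsv", sep="\t", index=False)
    mr_tbl.to_csv(outdir / "mr_report.tsv", sep="\t", index=False)
    report["ldsc_h2"] = h2_tbl.to_dict(orient="records")
    report["ldsc_rg"] = rg_tbl.to_dict(orient="records")
    report["mr"] = mr_tbl.to_dict(orient="records")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: dict, path) -> None:
    lines = [
        f"wgwas run report (config {report['config_hash']})",
        "",
        f"selected n = {report['weights']['n_selected']}, "
        f"reference n = {report['weights']['n_reference']}, "
        f"n_effective = {report['weights']['n_effective']:.1f}",
        f"bias reduction (median over biased pairs): "
        f"{report['weights']['bias_reduction'].get('median', float('nan')):.3f}",
        "",
        "GWAS discovery classes by trait:",
    ]
    for trait, s in report["gwas"].items():
        lines.append(
            f"  {trait}: both={s['n_both']} GWA-only={s['n_gwa_only']} "
            f"wGWA-only={s['n_wgwa_only']} reduced={s['n_reduced']} "
            f"increased={s['n_increased']}"
        )
    lines.append("")
    lines.append("LDSC heritability (standard vs weighted):")
    for row in report["ldsc_h2"]:
        lines.append(
            f"  {row['trait']}: h2={row['h2']:.4f} (se {row['h2_se']:.4f}), "
            f"h2_w={row['h2_w']:.4f} (se {row['h2_w_se']:.4f}), Z_diff={row['z']:.2f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
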