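"""End-to-end validation pipeline.

Runs the full anchor-based validation sequence on a visit + diary dataset
(real or synthetic): WPAI scoring, diary aggregation, anchor responder
classification, test-retest reliability, construct validity, responsiveness
ANCOVA, and meaningful-change threshold determination — for the overall
population and the EM/CM subpopulations — and writes one CSV per report
table plus a JSON run manifest recording the configuration, seed, and row
counts at every filtering step.

Absenteeism is carried through descriptive outputs but excluded from the
responsiveness and threshold stages by default: its scores and changes are
too small and too weakly anchored for a standalone responder analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchors as anchors_mod
from . import diary as diary_mod
from . import generate as gen_mod
from . import reliability, responsiveness, thresholds, validity
from .scoring import SCORE_COLS, score_visits

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("wpaimc")

#: domain key -> score column
DOMAINS = {
    "presenteeism": "presenteeism_pct",
    "owpl": "overall_work_productivity_loss_pct",
    "activity": "activity_impairment_pct",
    "absenteeism": "absenteeism_pct",
}
DESCRIPTIVE_ONLY = ("absenteeism",)


@dataclass
class PipelineConfig:
    visits_path: str | None = None
    diary_path: str | None = None
    generator: gen_mod.GeneratorConfig | None = None
    populations: tuple[str, ...] = ("overall", "EM", "CM")
    anchor_names: tuple[str, ...] = ("MSQ_RFR", "MSQ_RFP", "MHD50")
    domains: tuple[str, ...] = ("presenteeism", "owpl", "activity", "absenteeism")
    grid_step: float = 10.0
    output_dir: str = "wpaimc_out"
    seed: int = 0
    apply_missingness: bool = True

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        if not set(self.domains) - set(DESCRIPTIVE_ONLY):
            raise ValueError("at least one analyzable domain is required")
        unknown = set(self.domains) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains: {sorted(unknown)}")
        have_paths = self.visits_path is not None and self.diary_path is not None
        if not have_paths and self.generator is None:
            raise ValueError("provide input paths or a generator config")


def _subject_table(data: gen_mod.TrialData) -> pd.DataFrame:
    """One row per subject: arms, scores and anchors at both visits, changes."""
    scored = score_visits(data.visits)
    base = scored[scored["visit"] == "baseline"].set_index("subject_id")
    m3 = scored[scored["visit"] == "month3"].set_index("subject_id")

    subj = base[["arm", "employed"]].copy()
    for key, col in DOMAINS.items():
        subj[f"{key}_baseline"] = base[col]
        subj[f"{key}_month3"] = m3[col]
        subj[f"{key}_change"] = m3[col] - base[col]
    for msq in ("msq_rfr", "msq_rfp"):
        subj[f"{msq.upper()}_baseline"] = base[msq]
        subj[f"{msq.upper()}_month3"] = m3[msq]

    summary = diary_mod.summarize_diary(data.diary, gen_mod.ANCHOR_DATE)
    wide = summary[~summary["missing"]].pivot(
        index="subject_id", columns="period", values="mhd_adjusted")
    hd = summary[~summary["missing"]].pivot(
        index="subject_id", columns="period", values="headache_days_adjusted")
    subj["MHD50_baseline"] = wide.get("baseline")
    subj["MHD50_month3"] = wide.get("month3")

    subtypes = []
    fallback = base.get("subtype")
    for sid in subj.index:
        mhd = subj.loc[sid, "MHD50_baseline"]
        hdays = hd["baseline"].get(sid, np.nan) if "baseline" in hd else np.nan
        if pd.notna(mhd) and pd.notna(hdays) and mhd >= 4:
            s = diary_mod.classify_subtype(diary_mod.MonthlySummary(
                0, 0, 30, mhd_adjusted=float(mhd),
                headache_days_adjusted=float(hdays)))
        else:
            s = fallback.get(sid) if fallback is not None else np.nan
        subtypes.append(s)
    subj["subtype"] = subtypes
    return subj.reset_index(), summary


def _baseline_table(subj: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for key in DOMAINS:
        col = subj[f"{key}_baseline"]
        rows.append({"measure": key, "n": int(col.notna().sum()),
                     "mean": col.mean(), "sd": col.std()})
    for extra in ("MSQ_RFR_baseline", "MSQ_RFP_baseline", "MHD50_baseline"):
        col = subj[extra]
        rows.append({"measure": extra.replace("_baseline", ""),
                     "n": int(col.notna().sum()),
                     "mean": col.mean(), "sd": col.std()})
    return pd.DataFrame(rows)


def _select_population(subj: pd.DataFrame, population: str) -> pd.DataFrame:
    if population == "overall":
        return subj
    return subj[subj["subtype"] == population]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns it in memory.

    The returned dict maps table names to DataFrames (plus the manifest
    dict); the same tables are written under ``config.output_dir``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "counts": {}}

    if config.visits_path is not None:
        data = gen_mod.read_dataset(config.visits_path, config.diary_path)
        manifest["input"] = {"visits": str(config.visits_path),
                             "diary": str(config.diary_path)}
    else:
        gcfg = config.generator.with_seed(config.seed)
        data = gen_mod.generate_trial(gcfg)
        if config.apply_missingness:
            data = gen_mod.apply_missingness(
                data, gcfg.missing_item_rate, seed=gcfg.seed + 1,
                diary_rate=gcfg.missing_diary_rate)
        manifest["input"] = {"generator": gcfg.__dict__.copy()}
        gen_mod.write_dataset(data, outdir / "data")

    manifest["counts"]["visit_rows"] = len(data.visits)
    manifest["counts"]["diary_rows"] = len(data.diary)

    subj, summary = _subject_table(data)
    manifest["counts"]["subjects"] = len(subj)

    statuses = anchors_mod.anchor_status_table(
        subj, {k: anchors_mod.DEFAULT_ANCHORS[k] for k in config.anchor_names})
    anchor_vals = {"MSQ_RFR": "MSQ_RFR_baseline", "MSQ_RFP": "MSQ_RFP_baseline",
                   "MHD50": "MHD50_baseline"}

    bundle: dict = {"manifest": manifest}
    tables: dict[str, list[pd.DataFrame]] = {
        "baseline_characteristics": [], "icc": [], "correlations": [],
        "ancova": [], "roc_grids": [], "threshold_summary": [], "ecdf": [],
    }
    analysis_domains = [d for d in config.domains if d not in DESCRIPTIVE_ONLY]

    for pop in config.populations:
        ps = _select_population(subj, pop)
        manifest["counts"][f"subjects_{pop}"] = len(ps)
        if ps.empty:
            log.warning("population %s is empty; stages skipped", pop)
            continue

        bt = _baseline_table(ps)
        bt.insert(0, "population", pop)
        tables["baseline_characteristics"].append(bt)

        # reliability in the stable placebo subgroup
        stable = reliability.select_stable_subgroup(
            summary[summary["subject_id"].isin(ps["subject_id"])],
            ps[["subject_id", "arm"]])
        manifest["counts"][f"stable_subgroup_{pop}"] = len(stable)
        for key in config.domains:
            obs = pd.concat([
                ps.loc[ps["subject_id"].isin(stable),
                       ["subject_id", f"{key}_baseline"]]
                .rename(columns={f"{key}_baseline": "score"}),
                ps.loc[ps["subject_id"].isin(stable),
                       ["subject_id", f"{key}_month3"]]
                .rename(columns={f"{key}_month3": "score"}),
            ]).dropna(subset=["score"])
            try:
                fit = reliability.fit_random_intercept(obs)
            except ValueError as exc:
                log.warning("ICC %s/%s skipped: %s", pop, key, exc)
                continue
            tables["icc"].append(pd.DataFrame([{
                "population": pop, "domain": key,
                "n_subjects": fit.n_subjects,
                "n_observations": fit.n_observations,
                "sigma_u2": fit.sigma_u2, "sigma_e2": fit.sigma_e2,
                "icc": fit.icc, "band": fit.band,
            }]))

        # construct validity at baseline
        rho, bands = validity.correlation_matrix(
            ps, [f"{d}_baseline" for d in config.domains],
            list(anchor_vals.values()))
        eligible = validity.anchor_eligibility(rho)
        corr = rho.stack().rename("rho").reset_index()
        corr.columns = ["domain", "anchor", "rho"]
        corr["band"] = bands.stack().to_numpy()
        corr["eligible_anchor"] = eligible.stack().to_numpy()
        corr.insert(0, "population", pop)
        tables["correlations"].append(corr)

        pop_status = statuses[statuses["subject_id"].isin(ps["subject_id"])]

        anc = responsiveness.responsiveness_table(ps, pop_status, analysis_domains)
        if not anc.empty:
            anc.insert(0, "population", pop)
            tables["ancova"].append(anc)

        # thresholds per domain
        for key in analysis_domains:
            grids = {}
            for anchor in config.anchor_names:
                merged = pop_status[pop_status["anchor"] == anchor].merge(
                    ps[["subject_id", f"{key}_change"]], on="subject_id"
                ).dropna(subset=[f"{key}_change"])
                if merged.empty or merged["responder"].nunique() < 2:
                    continue
                resp = merged["responder"].to_numpy()
                chg = merged[f"{key}_change"].to_numpy()
                g = thresholds.roc_grid(resp, chg)
                g.insert(0, "anchor", anchor)
                g.insert(0, "domain", key)
                g.insert(0, "population", pop)
                tables["roc_grids"].append(g)
                grids[anchor] = g
                try:
                    ic, sl, auc, band, conv = thresholds.fit_logistic_auc(resp, chg)
                except ValueError as exc:
                    log.warning("logistic %s/%s/%s skipped: %s",
                                pop, key, anchor, exc)
                    continue
                opt = thresholds.optimal_cutoff(g)
                curves = thresholds.ecdf_by_group(chg, resp)
                for flag, curve in curves.items():
                    c = curve.copy()
                    c.insert(0, "responder", flag)
                    c.insert(0, "anchor", anchor)
                    c.insert(0, "domain", key)
                    c.insert(0, "population", pop)
                    tables["ecdf"].append(c)
                tables["threshold_summary"].append(pd.DataFrame([{
                    "population": pop, "domain": key, "anchor": anchor,
                    "n": len(merged),
                    "optimal_cutoff": opt, "auc": auc, "auc_band": band,
                    "logit_intercept": ic, "logit_slope": sl,
                    "logit_converged": conv,
                    "consensus_threshold": np.nan,
                    "misclassification": np.nan,
                }]))
            if grids:
                consensus, _detail = thresholds.consensus_threshold(
                    grids, config.grid_step)
                for t in tables["threshold_summary"]:
                    sel = ((t["population"] == pop) & (t["domain"] == key))
                    if sel.any():
                        t.loc[sel, "consensus_threshold"] = consensus
                        anchor = t.loc[sel, "anchor"].iloc[0]
                        if anchor in grids:
                            t.loc[sel, "misclassification"] = (
                                thresholds.misclassification_rate(
                                    grids[anchor], consensus))

    _ROUND = {"mean": 2, "sd": 2, "rho": 4, "icc": 4, "sigma_u2": 2,
              "sigma_e2": 2, "sensitivity": 4, "specificity": 4, "ppv": 4,
              "npv": 4, "youden": 4, "phi": 4, "auc": 4, "F": 4,
              "misclassification": 4, "pct_nonresponder": 1,
              "pct_responder": 1}
    for name, parts in tables.items():
        if not parts:
            continue
        table = pd.concat(parts, ignore_index=True)
        bundle[name] = table
        out = table.copy()
        for col, nd in _ROUND.items():
            if col in out.columns:
                out[col] = out[col].round(nd)
        out.to_csv(outdir / f"{name}.csv", index=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
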