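"""End-to-end orchestration of the mouse and human analyses.

Mouse: per stratum (therapy arm x age group), select IMPs associated with
the pathophenotype, scan selected IMPs (ipQTLs) and the pathophenotype
(cdaQTLs), consolidate peaks, then build additive multi-QTL models (basal
cdaQTL plus ipQTL subsets) retained under the drop-one p < 0.05 rule.

Human: imputation-quality filter, CDA case labeling, stratified 80/20
train/test split, bootstrap SNV selection on training only, LASSO fit,
Youden cutoff, held-out evaluation.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genetics_core import BackcrossGenotypes, calc_genotype_probs
from .human_genetics import (
    HumanCohort,
    bootstrap_select_snvs,
    evaluate_on_test,
    filter_by_imputation,
    fit_lasso_risk_model,
    label_cda_cases,
    stratified_split,
)
from .imp_association import IMPPanel, assign_age_groups, select_imps
from .multiqtl import QTLModelSpec, compare_models, drop_one_analysis, fit_qtl_model
from .qtl_mapping import classify_peaks, consolidate_qtls, peaks_to_frame, scan_hk, scan_em

logger = logging.getLogger("ipqtl")

__all__ = ["AnalysisConfig", "ReportBundle", "run_mouse_pipeline", "run_human_pipeline"]


@dataclass
class AnalysisConfig:
    seed: int
    significant_lod: float = 3.0
    suggestive_lod: float = 1.5
    alpha: float = 0.05
    r2_min: float = 0.7
    drop_threshold: float = 5.0
    n_iter: int = 100
    min_hits: int = 5
    eval_frac: float = 0.8
    test_frac: float = 0.2
    max_extra_loci: int = 2
    min_stratum_n: int = 20
    scan_method: str = "hk"  # "hk" or "em"
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("significant_lod", "suggestive_lod", "alpha", "r2_min", "drop_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scan_method not in ("hk", "em"):
            raise ValueError("scan_method must be 'hk' or 'em'")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"tables": {}, "log": self.log}
        for name, df in self.tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            manifest["tables"][name] = path.name
            if name == "qtl_registry":  # registry is exported as CSV and JSON
                df.to_json(out / f"{name}.json", orient="records", indent=2)
        for name, model in self.models.items():
            path = out / f"{name}.json"
            model.to_json(path)
            manifest["tables"][name] = path.name
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return out


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(vars(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _run_log(config: AnalysisConfig) -> dict:
    return {"version": __version__, "seed": config.seed, "config_hash": _config_hash(config)}


def run_mouse_pipeline(
    geno: BackcrossGenotypes,
    imps: IMPPanel,
    phenotypes: pd.DataFrame,
    config: AnalysisConfig,
    pathophenotype: str = "fibrosis",
) -> ReportBundle:
    """IMP selection, ipQTL/cdaQTL scans and model integration per stratum."""
    config.validate()
    scan = scan_hk if config.scan_method == "hk" else scan_em
    probs = calc_genotype_probs(geno.map, geno)

    ages = phenotypes["age_weeks"].to_numpy(float)
    age_group, age_median = assign_age_groups(ages)
    arms = phenotypes["therapy_arm"].to_numpy()

    scan_frames, all_peaks, comparison_rows, imp_rows = [], [], [], []
    for arm in pd.unique(arms):
        for grp in ("young", "old"):
            stratum = f"{arm}|{grp}"
            rows = (arms == arm) & (age_group == grp)
            n_strat = int(rows.sum())
            if n_strat < config.min_stratum_n:
                logger.warning("stratum %s skipped: n=%d below minimum", stratum, n_strat)
                continue
            y = np.where(rows, phenotypes[pathophenotype].to_numpy(float), np.nan)

            if imps.molecules:
                sub_panel = IMPPanel(
                    levels=imps.levels.where(pd.Series(rows, index=imps.levels.index), np.nan),
                    molecule_class=imps.molecule_class,
                )
                selected = select_imps(sub_panel, y, alpha_entry=config.alpha)
            else:
                selected = pd.DataFrame(columns=["molecule"])
            for _, r in selected.iterrows():
                imp_rows.append({"stratum": stratum, **r.to_dict()})

            cda_scan = scan(probs, y, trait=pathophenotype, stratum=stratum)
            scan_frames.append(cda_scan.to_frame())
            cda_peaks = classify_peaks(
                cda_scan, significant=config.significant_lod, suggestive=config.suggestive_lod
            )
            all_peaks.extend(cda_peaks)

            ip_peaks = []
            for m in selected["molecule"]:
                x = np.where(rows, imps.levels[m].to_numpy(float), np.nan)
                s = scan(probs, x, trait=m, stratum=stratum)
                scan_frames.append(s.to_frame())
                pk = classify_peaks(
                    s, significant=config.significant_lod, suggestive=config.suggestive_lod
                )
                all_peaks.extend(pk)
                ip_peaks.extend(pk)

            if not cda_peaks:
                continue
            basal_peak = max(cda_peaks, key=lambda p: p.lod)
            basal_locus = (basal_peak.chromosome, basal_peak.position)
            basal = fit_qtl_model(
                probs, y, QTLModelSpec(loci=(basal_locus,), model_id="basal"),
                phenotype_name=pathophenotype, stratum=stratum,
            )
            ip_loci = []
            for p in sorted(ip_peaks, key=lambda p: -p.lod):
                loc = (p.chromosome, p.position)
                if loc != basal_locus and loc not in ip_loci:
                    ip_loci.append(loc)
            extended = []
            for k in range(1, config.max_extra_loci + 1):
                for combo in itertools.combinations(ip_loci, k):
                    spec = QTLModelSpec(
                        loci=(basal_locus,) + combo,
                        model_id="+".join(f"{c}@{p:g}" for c, p in combo),
                    )
                    try:
                        fit = fit_qtl_model(probs, y, spec, phenotype_name=pathophenotype, stratum=stratum)
                    except ValueError:
                        continue
                    drop_one_analysis(fit, probs, y)
                    extended.append(fit)
            table = compare_models(basal, extended)
            table.insert(0, "stratum", stratum)
            comparison_rows.append(table)

    registry = consolidate_qtls(all_peaks)
    registry_df = pd.DataFrame(
        [
            {
                "qtl_id": e.qtl_id,
                "chromosome": e.chromosome,
                "position_cM": e.position,
                "max_lod": e.max_lod,
                "support_lo": e.support_lo,
                "support_hi": e.support_hi,
                "n_conditions": len(e.members),
                "conditions": "; ".join(e.conditions),
            }
            for e in registry
        ]
    )

    chrom_idx = {c: i for i, c in enumerate(geno.map.chromosomes)}
    scans_df = (
        pd.concat(scan_frames, ignore_index=True) if scan_frames
        else pd.DataFrame(columns=["chromosome", "position_cM", "lod", "trait", "method", "stratum"])
    )
    heatmap = (
        scans_df.groupby(["chromosome", "trait", "stratum"], as_index=False)["lod"].max()
        .sort_values(["stratum", "trait", "chromosome"],
                     key=lambda s: s.map(chrom_idx) if s.name == "chromosome" else s)
        if len(scans_df) else scans_df
    )

    bundle = ReportBundle(
        tables={
            "scans": scans_df,
            "peaks": peaks_to_frame(all_peaks),
            "qtl_registry": registry_df,
            "heatmap_summary": heatmap,
            "model_comparison": (
                pd.concat(comparison_rows, ignore_index=True) if comparison_rows
                else pd.DataFrame(columns=["stratum", "model_id", "components", "lod",
                                           "percent_var", "delta_percent_var", "improvement",
                                           "worst_added_term_p"])
            ),
            "selected_imps": pd.DataFrame(imp_rows),
        },
        log={**_run_log(config), "age_median": age_median},
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def run_human_pipeline(cohort: HumanCohort, config: AnalysisConfig) -> ReportBundle:
    """Filter, label, split, bootstrap-select, LASSO-fit and evaluate."""
    config.validate()
    if cohort.imputation_r2 is not None:
        cohort = filter_by_imputation(cohort, r2_min=config.r2_min)
        if cohort.dosages.shape[1] == 0:
            raise ValueError("no SNVs remain after the imputation-quality filter")

    if cohort.outcome is None:
        if cohort.baseline is None or cohort.followup is None:
            raise ValueError("need either an outcome or baseline/follow-up measurements")
        labels, valid = label_cda_cases(cohort.baseline, cohort.followup, config.drop_threshold)
        cohort = cohort.subset(np.flatnonzero(valid))
        cohort.outcome = labels[valid]
    y = np.asarray(cohort.outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("fewer than two outcome classes after labeling")

    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = stratified_split(y, 1.0 - config.test_frac, rng)
    train = cohort.subset(train_idx)
    test = cohort.subset(test_idx)

    hits = bootstrap_select_snvs(
        train, n_iter=config.n_iter, eval_frac=config.eval_frac,
        min_hits=config.min_hits, alpha=config.alpha, seed=config.seed,
    )
    tables: dict[str, pd.DataFrame] = {
        "bootstrap_hits": hits.rename_axis("snv").reset_index(),
    }
    models = {}
    if len(hits):
        model = fit_lasso_risk_model(
            train, list(hits.index), hit_counts=hits.to_dict(), seed=config.seed
        )
        metrics_test = evaluate_on_test(model, test)
        tables["risk_metrics"] = pd.DataFrame(
            [
                {"split": "training", **model.training_metrics},
                {"split": "testing", **metrics_test},
            ]
        )
        models["risk_model"] = model
    else:
        logger.warning("no SNV reached min_hits; no risk model fitted")

    bundle = ReportBundle(
        tables=tables,
        models=models,
        log={
            **_run_log(config),
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
            "n_cases": int(y.sum()),
        },
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
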