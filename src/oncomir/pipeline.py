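"""End-to-end orchestration: matrices in, oncofetal report out.

Stage order: depth filter → replicate averaging → RPM normalization →
per-group expression calls → cross-cohort detection filter → differential
expression (ANOVA scheme on the discovery cohort, Welch-t + BH on the
validation cohort) → three-criterion oncofetal classification → LUAD↔FL
congruence test → genomic-cluster localization → optional linear-SVM panel
classifier (trained on discovery ANL+LUAD, evaluated on the validation
cohort) → optional per-miRNA survival screen.

Everything is driven by one strictly validated YAML config; a run writes
TSV/JSON stage outputs plus a machine-readable manifest into the output
directory and is byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_matrix as iom
from . import simulate as sim
from .classifier import fit_linear_svm, panel_features, roc_auc, score_samples
from .diffexp import de_anova_scheme, de_ttest_scheme, write_de_results
from .discovery import (classify_oncofetal, congruence_table, congruence_test,
                        count_in_region, oncofetal_frame, shared_targets)
from .io_matrix import parse_locus
from .reference import C14MC_REGION
from .survival import survival_screen

logger = logging.getLogger("oncomir")


class PipelineConfigError(ValueError):
    """Config fails validation (unknown key, threshold out of domain...)."""


_SIM_KEYS = {
    "discovery_sizes", "validation_sizes", "class_counts", "nb_dispersion",
    "expressed_mean_rpm", "silent_mean_rpm", "mean_scatter_sigma",
    "library_size_range", "cluster_fraction", "baseline_hazard",
    "hazard_ratio", "censoring_rate",
}
_INPUT_KEYS = {
    "discovery_matrix", "discovery_meta", "validation_matrix",
    "validation_meta", "annotation", "survival", "targets",
}


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one auditable place."""

    out_dir: str = "oncomir_out"
    seed: int = 0
    simulate: dict | None = None  # SimConfig overrides; None = read inputs
    inputs: dict | None = None  # paths, see _INPUT_KEYS
    min_reads: float = iom.MIN_TOTAL_READS
    detect_fraction: float = iom.DETECTION_FRACTION
    rpm_positive: float = iom.RPM_POSITIVE_THRESHOLD
    fc_threshold: float = 2.0
    fc_epsilon: float = 0.01
    alpha: float = 0.05
    pseudocount: float = 1.0
    posthoc: str = "lsd"
    congruence_collapse: bool = False
    cluster_region: str = (
        f"{C14MC_REGION.chrom}+:{C14MC_REGION.start}-{C14MC_REGION.end}"
    )
    min_shared_mirnas: int = 3
    svm_C: float = 1.0
    svm_tol: float = 1e-6
    run_classifier: bool = True
    run_survival: bool = True
    survival_bh: bool = False

    def validate(self) -> None:
        if self.min_reads < 0 or self.fc_epsilon < 0 or self.pseudocount < 0:
            raise PipelineConfigError("negative threshold")
        if not 0 <= self.detect_fraction <= 1:
            raise PipelineConfigError("detect_fraction must lie in [0, 1]")
        if self.fc_threshold <= 1:
            raise PipelineConfigError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise PipelineConfigError("alpha must lie in (0, 1)")
        if self.rpm_positive < 0:
            raise PipelineConfigError("rpm_positive must be non-negative")
        if self.posthoc not in ("lsd", "tukey"):
            raise PipelineConfigError(f"unknown posthoc {self.posthoc!r}")
        if self.svm_C <= 0 or self.svm_tol <= 0:
            raise PipelineConfigError("SVM settings must be positive")
        if self.min_shared_mirnas < 1:
            raise PipelineConfigError("min_shared_mirnas must be ≥ 1")
        if self.simulate is None and self.inputs is None:
            raise PipelineConfigError("need either a simulate block or inputs")
        if self.simulate is not None:
            unknown = set(self.simulate) - _SIM_KEYS
            if unknown:
                raise PipelineConfigError(f"unknown simulate keys: {sorted(unknown)}")
        if self.inputs is not None:
            unknown = set(self.inputs) - _INPUT_KEYS
            if unknown:
                raise PipelineConfigError(f"unknown input keys: {sorted(unknown)}")
        parse_locus(self.cluster_region)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise PipelineConfigError("config must be a YAML mapping")
        return cls.from_dict(d)

    def sim_config(self) -> sim.SimConfig:
        overrides = dict(self.simulate or {})
        if "library_size_range" in overrides:
            overrides["library_size_range"] = tuple(overrides["library_size_range"])
        return sim.SimConfig(seed=self.seed, **overrides)


def _preprocess(m: iom.ExpressionMatrix, cfg: PipelineConfig) -> iom.ExpressionMatrix:
    m = iom.filter_low_depth(m, min_reads=cfg.min_reads)
    m = iom.average_replicates(m)
    return iom.normalize_rpm(m)


def _expression_calls(m: iom.ExpressionMatrix, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    groups = sorted(m.meta["group"].unique())
    return {
        g: iom.calls_to_frame(
            iom.detect_expressed(m, g, rpm_threshold=cfg.rpm_positive,
                                 fraction=cfg.detect_fraction)
        )
        for g in groups
    }


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write outputs + manifest to the out directory.

    Returns the run report (also written as ``manifest.json``). Any stage
    error propagates with its stage name in the log.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    # -- inputs ---------------------------------------------------------------
    logger.info("stage: inputs")
    truth = None
    surv_table = None
    annotation: dict[str, iom.GenomicLocus] = {}
    if cfg.simulate is not None:
        sim_cfg = cfg.sim_config()
        discovery, validation, truth = sim.generate_cohorts(sim_cfg)
        annotation = truth.loci
        truth.to_frame().to_csv(out / "planted_truth.tsv", sep="\t",
                                lineterminator="\n")
    else:
        paths = cfg.inputs or {}
        discovery = iom.read_count_matrix(paths["discovery_matrix"],
                                          paths["discovery_meta"])
        validation = iom.read_count_matrix(paths["validation_matrix"],
                                           paths["validation_meta"])
        if paths.get("annotation"):
            annotation = iom.read_annotation(paths["annotation"])
        if paths.get("survival"):
            surv_table = pd.read_csv(paths["survival"], sep="\t",
                                     index_col="sample_id")

    iom.write_matrix(discovery, out / "discovery_counts.tsv",
                     out / "discovery_meta.tsv")
    iom.write_matrix(validation, out / "validation_counts.tsv",
                     out / "validation_meta.tsv")

    # -- preprocessing --------------------------------------------------------
    logger.info("stage: preprocessing")
    disc = _preprocess(discovery, cfg)
    valid = _preprocess(validation, cfg)
    report["stages"]["preprocessing"] = {
        "discovery_samples": disc.n_samples,
        "validation_samples": valid.n_samples,
        "mirnas": len(disc.mirna_ids),
    }

    # -- detection ------------------------------------------------------------
    logger.info("stage: detection")
    calls_disc = _expression_calls(disc, cfg)
    calls_valid = _expression_calls(valid, cfg)
    detected_disc = pd.concat(calls_disc.values())["expressed"].groupby(level=0).any()
    detected_valid = pd.concat(calls_valid.values())["expressed"].groupby(level=0).any()
    detected = sorted(detected_disc.index[detected_disc]
                      .intersection(detected_valid.index[detected_valid]))
    if not detected:
        raise iom.EmptyCohortError("no miRNA detected in both cohorts")
    disc = iom.ExpressionMatrix(disc.values.loc[detected], disc.meta, unit="rpm")
    valid = iom.ExpressionMatrix(valid.values.loc[detected], valid.meta, unit="rpm")
    calls_disc = _expression_calls(disc, cfg)
    calls_valid = _expression_calls(valid, cfg)
    for cohort, calls in (("discovery", calls_disc), ("validation", calls_valid)):
        pd.concat(calls.values(), keys=calls.keys(), names=["group"]).to_csv(
            out / f"expression_calls_{cohort}.tsv", sep="\t", lineterminator="\n"
        )
    report["stages"]["detection"] = {"detected_mirnas": len(detected)}

    # -- differential expression ---------------------------------------------
    logger.info("stage: differential expression")
    de_disc = de_anova_scheme(
        disc, comparisons=[("LUAD", "ANL"), ("FL", "ANL")],
        groups=["FL", "ANL", "LUAD"], posthoc=cfg.posthoc, alpha=cfg.alpha,
        fc_threshold=cfg.fc_threshold, fc_epsilon=cfg.fc_epsilon,
        pseudocount=cfg.pseudocount,
    )
    de_valid = de_ttest_scheme(
        valid, comparison=("LUAD", "ANL"), alpha=cfg.alpha,
        fc_threshold=cfg.fc_threshold, fc_epsilon=cfg.fc_epsilon,
        pseudocount=cfg.pseudocount,
    )
    write_de_results(de_disc, out / "de_discovery.tsv")
    write_de_results(de_valid, out / "de_validation.tsv")

    def _n(df, comparison, status):
        s = df[df["comparison"] == comparison]["status"]
        return int((s == status).sum())

    report["stages"]["diffexp"] = {
        "discovery_LUAD_vs_ANL_over": _n(de_disc, "LUAD_vs_ANL", "over"),
        "discovery_LUAD_vs_ANL_under": _n(de_disc, "LUAD_vs_ANL", "under"),
        "discovery_FL_vs_ANL_over": _n(de_disc, "FL_vs_ANL", "over"),
        "validation_LUAD_vs_ANL_over": _n(de_valid, "LUAD_vs_ANL", "over"),
        "validation_LUAD_vs_ANL_under": _n(de_valid, "LUAD_vs_ANL", "under"),
    }

    # -- oncofetal classification ---------------------------------------------
    logger.info("stage: oncofetal classification")
    calls = classify_oncofetal(de_disc, de_valid,
                               calls_disc["ANL"], calls_valid["ANL"])
    calls_df = oncofetal_frame(calls)
    calls_df.to_csv(out / "oncofetal_calls.tsv", sep="\t", lineterminator="\n")
    hits = sorted(calls_df.index[calls_df["oncofetal"]])
    report["stages"]["oncofetal"] = {"n_oncofetal": len(hits), "hits": hits}
    if truth is not None:
        planted = set(truth.oncofetal_ids)
        recovered = planted & set(hits)
        false_pos = set(hits) - planted
        report["stages"]["oncofetal"]["planted_comparison"] = {
            "planted": len(planted),
            "recovered": len(recovered),
            "false_positives": sorted(false_pos),
        }

    # -- congruence -----------------------------------------------------------
    logger.info("stage: congruence")
    table = congruence_table(de_disc, de_disc, "LUAD_vs_ANL", "FL_vs_ANL",
                             collapse=cfg.congruence_collapse)
    cong = congruence_test(table.to_numpy(), seed=cfg.seed)
    cong_out = {"rows": list(table.index), "columns": list(table.columns), **cong}
    (out / "congruence.json").write_text(json.dumps(cong_out, indent=2) + "\n")
    report["stages"]["congruence"] = {"p": cong["p"], "method": cong["method"]}

    # -- cluster localization --------------------------------------------------
    logger.info("stage: cluster localization")
    region = parse_locus(cfg.cluster_region)
    known = [h for h in hits if h in annotation]
    n_cluster = count_in_region(known, annotation, region) if known else 0
    report["stages"]["cluster"] = {
        "region": cfg.cluster_region,
        "hits_with_annotation": len(known),
        "in_region": n_cluster,
    }

    # -- shared predicted targets ---------------------------------------------
    if cfg.inputs and (cfg.inputs or {}).get("targets"):
        targets = pd.read_csv(cfg.inputs["targets"], sep="\t")
        panel_rows = targets[targets["mirna_id"].isin(hits)]
        genes = shared_targets(panel_rows, min_mirnas=cfg.min_shared_mirnas)
        pd.Series(genes, name="gene_symbol").to_csv(
            out / "shared_targets.tsv", sep="\t", index=False, lineterminator="\n"
        )
        report["stages"]["targets"] = {"n_shared_genes": len(genes)}

    # -- panel classifier ------------------------------------------------------
    if cfg.run_classifier and hits:
        logger.info("stage: classifier")
        train = disc.subset_groups(["ANL", "LUAD"])  # FL never a classifier input
        X_train = panel_features(train, hits, pseudocount=cfg.pseudocount)
        y_train = (train.meta["group"] == "LUAD").to_numpy()
        scorer = fit_linear_svm(X_train, y_train, C=cfg.svm_C, tol=cfg.svm_tol,
                                seed=cfg.seed)
        (out / "scorer.json").write_text(scorer.to_json() + "\n")
        X_test = panel_features(valid.subset_groups(["ANL", "LUAD"]), hits,
                                pseudocount=cfg.pseudocount)
        scores = score_samples(scorer, X_test)
        y_test = (valid.meta.loc[X_test.index, "group"] == "LUAD").to_numpy()
        roc = roc_auc(scores.to_numpy(), y_test)
        roc.to_frame().to_csv(out / "roc_validation.tsv", sep="\t", index=False,
                              lineterminator="\n")
        (out / "roc_summary.json").write_text(json.dumps(
            {"auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg}, indent=2
        ) + "\n")
        report["stages"]["classifier"] = {"auc": roc.auc, "panel_size": len(hits)}

    # -- survival --------------------------------------------------------------
    if cfg.run_survival and hits:
        logger.info("stage: survival")
        if surv_table is None and cfg.simulate is not None:
            # hazard tied to positivity of the first planted oncofetal miRNA
            designated = truth.oncofetal_ids[:1] if truth else hits[:1]
            surv_table = sim.generate_survival(cfg.sim_config(), valid, designated)
            surv_table.to_csv(out / "survival_input.tsv", sep="\t",
                              lineterminator="\n")
        if surv_table is not None:
            screen = survival_screen(valid, surv_table, hits, alpha=cfg.alpha,
                                     bh=cfg.survival_bh)
            screen.to_csv(out / "survival_screen.tsv", sep="\t",
                          lineterminator="\n")
            flagged = sorted(screen.index[screen["flagged"]])
            report["stages"]["survival"] = {
                "n_tested": int(screen["testable"].sum()),
                "flagged": flagged,
            }

    # -- manifest --------------------------------------------------------------
    cfg_dict = asdict(cfg)
    report["config"] = cfg_dict
    report["config_sha256"] = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True)
                                       + "\n")
    logger.info("pipeline complete: %s", out)
    return report
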