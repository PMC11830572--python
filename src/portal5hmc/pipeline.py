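"""End-to-end orchestration: simulate -> regions -> differential ->
markers -> evaluate, driven by one config, producing disk artifacts and a
machine-readable run report that is byte-identical across runs with the
same seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import differential, evaluate, markers, regions as regions_mod, synthetic
from .io import (CountMatrix, write_bed, write_bedgraph, write_count_matrix,
                 write_gene_models, write_sample_table)
from .markers import SplitSpec
from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    contrast: tuple[str, str] = ("PC", "MLM")
    lfc_min: float = 0.5
    p_max: float = 0.01
    min_samples: int = 10
    max_width: int = 1000
    rounds: int = 5
    repeats: int = 100
    min_rounds: int = 3
    within_round_rule: float = 0.3
    round_fraction: float = 0.8
    train_fraction: float = 2.0 / 3.0
    lambda_grid: tuple[float, ...] = (0.01, 1.0, 100.0)
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        for g in self.contrast:
            if g not in self.sim.group_sizes:
                raise ValueError(f"contrast group {g!r} not in group_sizes")
        if self.lfc_min <= 0 or self.p_max <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimulationConfig(**d.pop("sim", {}))
        if "contrast" in d:
            d["contrast"] = tuple(d["contrast"])
        if "lambda_grid" in d:
            d["lambda_grid"] = tuple(d["lambda_grid"])
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the full synthetic pipeline and write artifacts + report.

    Stages: simulate cohort; per-sample peaks; 0-gap merge; support/width
    filter; differential calling on the training cohort of the configured
    contrast; stability-consensus marker selection; final model training;
    validation metrics; survival stratification by the top marker. Returns
    the report dict (also written to ``report.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.sim.seed = int(config.sim.seed)

    def stage(name):
        return _StageContext(name)

    with stage("simulate"):
        genes, cand_regions = synthetic.simulate_genome(config.sim)
        counts, truth = synthetic.simulate_counts(config.sim, cand_regions)
        coverage = synthetic.simulate_coverage(genes, config.sim)
        peaks = synthetic.simulate_peaks(counts, cand_regions,
                                         config.sim.peak_presence_threshold)

        group_of = {sid: sid.split("_")[0] for sid in counts.sample_ids}
        samples = pd.DataFrame(
            {"group": [group_of[s] for s in counts.sample_ids],
             "compartment": "PVB"},
            index=pd.Index(counts.sample_ids, name="sample"),
        )

    with stage("regions"):
        merged = regions_mod.merge_peaks(peaks)
        retained = regions_mod.filter_regions(merged, config.min_samples,
                                              config.max_width)
        # candidate regions are disjoint by construction, so each retained
        # merged interval corresponds to >=1 whole candidate region
        keep_ids = []
        retained_sorted = sorted(retained, key=lambda m: (m.region.chrom, m.region.start))
        by_chrom: dict[str, list] = {}
        for m in retained_sorted:
            by_chrom.setdefault(m.region.chrom, []).append(m.region)
        for r in cand_regions:
            spans = by_chrom.get(r.chrom, [])
            import bisect
            starts = [x.start for x in spans]
            i = bisect.bisect_right(starts, r.start) - 1
            if i >= 0 and spans[i].end >= r.end:
                keep_ids.append(synthetic.region_id(r))
        analysis_counts = counts.subset_regions(keep_ids)
        annotated = regions_mod.annotate_regions(cand_regions, genes)
        feat_dist = regions_mod.feature_distribution(annotated)

    with stage("differential"):
        a, b = config.contrast
        contrast_ids = [s for s in analysis_counts.sample_ids if group_of[s] in (a, b)]
        split = SplitSpec(train_fraction=config.train_fraction, stratified=True,
                          seed=config.seed)
        train_ids, valid_ids = markers.split_cohort(samples.loc[contrast_ids], split)
        train_counts = analysis_counts.subset_samples(train_ids)
        sf_train = differential.size_factors(train_counts, fallback=True)
        groups_train = samples.loc[train_ids, "group"]
        disp = differential.estimate_dispersion(train_counts, sf_train, groups_train)
        results = differential.nb_wald_test(train_counts, sf_train, groups_train, disp,
                                            contrast=(a, b))
        up, down = differential.call_dhmrs(results, config.lfc_min, config.p_max)
        dhmr_ids = sorted(up + down)

    with stage("markers"):
        panel_size = 0
        model = None
        metrics = {}
        if dhmr_ids:
            sf_all = differential.size_factors(analysis_counts, fallback=True)
            X_all = markers.marker_features(analysis_counts, sf_all)[dhmr_ids]
            y_all = pd.Series(
                (samples.loc[contrast_ids, "group"] == b).astype(float),
                index=contrast_ids)
            panel = markers.stability_select(
                X_all.loc[train_ids], y_all.loc[train_ids],
                n_rounds=config.rounds, round_fraction=config.round_fraction,
                n_repeats=config.repeats, within_round_rule=config.within_round_rule,
                min_rounds=config.min_rounds, lambda_grid=config.lambda_grid,
                seed=config.seed)
            panel_size = len(panel.marker_ids)
            if panel_size:
                model = markers.train_final_model(
                    X_all.loc[train_ids, panel.marker_ids],
                    y_all.loc[train_ids].to_numpy(),
                    lambda_grid=config.lambda_grid, seed=config.seed)

    with stage("evaluate"):
        if model is not None:
            for split_name, ids in (("training", train_ids), ("validation", valid_ids)):
                scores = model.predict_proba(X_all.loc[ids])
                labels = y_all.loc[ids].to_numpy().astype(int)
                rr = evaluate.roc(scores, labels)
                conf = evaluate.confusion_at(scores, labels, 0.5)
                metrics[f"{split_name}_auc"] = rr.auc
                metrics[f"{split_name}_sensitivity"] = conf["sensitivity"]
                metrics[f"{split_name}_specificity"] = conf["specificity"]
            pm = evaluate.per_feature_auc(
                X_all.loc[valid_ids, model.marker_ids],
                y_all.loc[valid_ids].to_numpy().astype(int))
            metrics["per_marker_auc"] = {m: float(v) for m, v in pm["auc"].items()}

        # survival stratified by the strongest planted marker's level
        surv = {}
        if truth.predictive_marker_ids:
            top = max(truth.predictive_marker_ids,
                      key=lambda m: (abs(truth.true_log2fc[m]), m))
            sf_all2 = differential.size_factors(analysis_counts, fallback=True) \
                if not dhmr_ids else sf_all
            level = (counts.counts.loc[top] /
                     sf_all2.reindex(counts.sample_ids)).to_numpy()
            surv_tbl = synthetic.simulate_survival(level, config.sim)
            surv_tbl.index = pd.Index(counts.sample_ids, name="sample")
            samples = samples.join(surv_tbl)
            high = evaluate.dichotomize(level)
            for prefix in ("os", "efs"):
                fit = evaluate.km_logrank(surv_tbl[f"{prefix}_months"],
                                          surv_tbl[f"{prefix}_event"], high)
                surv[f"{prefix}_logrank_chi2"] = fit.logrank_chi2
                surv[f"{prefix}_logrank_p"] = fit.pvalue
            surv["marker"] = top

    with stage("write"):
        write_gene_models(genes, outdir / "genes.bed12")
        write_bed(cand_regions, outdir / "regions.bed")
        write_bed([m.region for m in retained], outdir / "regions_retained.bed")
        write_count_matrix(analysis_counts, outdir / "counts.tsv",
                           outdir / "library_sizes.tsv")
        write_sample_table(samples, outdir / "samples.tsv")
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", lineterminator="\n")
        write_bedgraph(coverage, outdir / "coverage.bedGraph")
        results.to_csv(outdir / "differential.tsv", sep="\t", lineterminator="\n",
                       index_label="region")
        feat_dist.to_csv(outdir / "feature_distribution.tsv", sep="\t",
                         lineterminator="\n")
        if model is not None:
            (outdir / "model.json").write_text(model.to_json() + "\n")
        if dhmr_ids and panel_size:
            panel.frequencies.assign(rounds_observed=panel.rounds_observed).to_csv(
                outdir / "panel.tsv", sep="\t", lineterminator="\n",
                index_label="marker")

        report = {
            "counts": {
                "regions_simulated": len(cand_regions),
                "regions_merged": len(merged),
                "regions_retained": len(retained),
                "regions_analyzed": len(keep_ids),
                "dhmr_up": len(up),
                "dhmr_down": len(down),
                "panel_size": panel_size,
                "n_train": len(train_ids),
                "n_validation": len(valid_ids),
            },
            "metrics": metrics,
            "survival": surv,
            "provenance": {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "version": __version__,
            },
        }
        _check_report(report, outdir)
        with open(outdir / "report.json", "w", newline="\n") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _check_report(report: dict, outdir: Path) -> None:
    """Report/artifact consistency: every reported count matches the
    corresponding artifact's row count."""
    c = report["counts"]
    n_retained = sum(1 for _ in open(outdir / "regions_retained.bed"))
    if n_retained != c["regions_retained"]:
        raise RuntimeError("report inconsistency: regions_retained")
    n_rows = sum(1 for _ in open(outdir / "counts.tsv")) - 1
    if n_rows != c["regions_analyzed"]:
        raise RuntimeError("report inconsistency: regions_analyzed")


class _StageContext:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        return False
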