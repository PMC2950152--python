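"""End-to-end orchestration: simulate → quantify → call → cluster → classify →
genomics → targets, driven by a single YAML config, with a machine-readable
run report.

Every stage writes a TSV/JSON artefact stamped with the config hash; the
report's headline numbers are all recomputable from those artefacts.  The
same config and seed always reproduce the same report (timestamps excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .classify import knn_loocv, score_markers, select_markers
from .containers import DISEASE_CONDITIONS, SampleTable
from .coregulation import comembership, kmeans_cluster
from .dysregulation import (
    call_dysregulation,
    derive_cutoff,
    dispersion_summary,
    venn_partition,
)
from .errors import ConfigError
from .genomics import chance_expectation, colocalize_with_loci, group_by_band
from .quantify import delta_ct, detection_filter, relative_expression
from .simulate import (
    AnnotationConfig,
    CohortConfig,
    TargetConfig,
    generate_annotation,
    generate_cohort,
    generate_target_catalog,
)
from .targets import function_summary, strictly_downregulated, target_genes

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # CohortConfig overrides; omit and provide "inputs" for real data
    "inputs": None,  # {"ct": path, "samples": path, ...}
    "quantify": {"ct_cutoff": 35.0, "detection_policy": "median", "baseline": "mean"},
    "call": {"alpha": 0.05, "multiplier": 0.5, "cutoff_override": None, "bh": False},
    "cluster": {"k": 20, "restarts": 10, "standardize": False},
    "classify": {"k": 3, "weighting": "distance", "n_additional": 9, "forced": []},
    "genomics": {"window_bp": 250000, "mc_draws": 0},
}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    headline: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_pipeline(
    config: dict | str | Path | None = None, outdir: str | Path = "."
) -> RunReport:
    """Execute every stage in order and write a report.json in ``outdir``."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    report = RunReport(config_hash=chash, seed=seed, version=__version__)

    # --- inputs: simulate or load -----------------------------------------
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        for key in ("ct", "samples"):
            if key not in paths:
                raise ConfigError(f"inputs block lacks {key!r}")
        ct = io.read_ct_table(paths["ct"])
        samples = io.read_sample_metadata(paths["samples"])
        annotation = (
            io.read_mirna_annotation(paths["annotation"]) if paths.get("annotation") else None
        )
        loci = io.read_locus_bed(paths["loci"]) if paths.get("loci") else None
        catalog = (
            io.read_target_catalog(paths["catalog"]) if paths.get("catalog") else None
        )
        process_table = (
            io.read_process_table(paths["processes"]) if paths.get("processes") else None
        )
        genome_sizes = None
        truth = ann_truth = None
    else:
        sim = dict(cfg.get("simulate") or {})
        sim.setdefault("seed", seed)
        if "planted_up" in sim or "planted_down" in sim:
            from .simulate import PlantedEffect

            for key in ("planted_up", "planted_down"):
                if sim.get(key) is not None:
                    sim[key] = [
                        PlantedEffect(**e) if isinstance(e, dict) else e
                        for e in sim[key]
                    ]
        ann_over = sim.pop("annotation", {})
        tgt_over = sim.pop("targets", {})
        cohort_cfg = CohortConfig(**sim)
        ct, samples, truth = generate_cohort(cohort_cfg)
        ann_cfg = AnnotationConfig(
            mirna_ids=cohort_cfg.mirna_ids(), seed=seed, **ann_over
        )
        annotation, loci, ann_truth = generate_annotation(ann_cfg)
        tgt_cfg = TargetConfig(mirna_ids=cohort_cfg.mirna_ids(), seed=seed, **tgt_over)
        catalog, process_table, _ = generate_target_catalog(tgt_cfg)
        genome_sizes = ann_truth.genome_sizes
        io.write_ct_table(outdir / "ct.tsv", ct, config_hash=chash)
        io.write_sample_metadata(outdir / "samples.tsv", samples, config_hash=chash)
        io.write_annotation_gff3(outdir / "annotation.gff3", annotation, config_hash=chash)
        io.write_locus_bed(outdir / "loci.bed", loci)
        io.write_target_catalog(outdir / "catalog.tsv", catalog, config_hash=chash)
        report.outputs.update(
            {
                "ct": "ct.tsv",
                "samples": "samples.tsv",
                "annotation": "annotation.gff3",
                "loci": "loci.bed",
                "catalog": "catalog.tsv",
            }
        )

    # --- quantification ----------------------------------------------------
    q = cfg["quantify"]
    detection = detection_filter(
        ct, samples, ct_cutoff=float(q["ct_cutoff"]), policy=q["detection_policy"]
    )
    dct = delta_ct(ct)
    rel = relative_expression(dct, samples, baseline=q["baseline"])
    rel_out = outdir / "rel_expr.tsv"
    with open(rel_out, "w") as fh:
        fh.write(f"# mirquiescent v{__version__} config={chash}\n")
        long = rel.log_fold.stack(future_stack=True).rename("log_fold").reset_index()
        long.columns = ["mirna_id", "sample_id", "log_fold"]
        long["delta_ct"] = rel.delta_ct.stack(future_stack=True).to_numpy()
        long["delta_delta_ct"] = rel.delta_delta_ct.stack(future_stack=True).to_numpy()
        long["fold"] = rel.fold.stack(future_stack=True).to_numpy()
        long.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    report.outputs["rel_expr"] = "rel_expr.tsv"

    conditions = [c for c in DISEASE_CONDITIONS if samples.samples_in_condition(c)]
    report.headline["n_panel"] = len(ct.mirna_ids)
    report.headline["n_samples"] = len(ct.sample_ids)
    report.headline["detected_per_condition"] = {
        c: int(detection.detected(c).sum()) for c in conditions
    }

    # --- dysregulation ------------------------------------------------------
    call_cfg = cfg["call"]
    disp = dispersion_summary(rel, samples, conditions=conditions, detection=detection)
    cutoff = derive_cutoff(
        disp.mean_disp, disp.sd_disp, multiplier=float(call_cfg["multiplier"])
    )
    if call_cfg.get("cutoff_override") is not None:
        cutoff = derive_cutoff(float(call_cfg["cutoff_override"]), 0.0, 0.0)
    calls = call_dysregulation(
        rel,
        samples,
        cutoff,
        alpha=float(call_cfg["alpha"]),
        detection=detection,
        conditions=conditions,
        bh_correct=bool(call_cfg["bh"]),
    )
    io.write_calls(outdir / "calls.tsv", calls, config_hash=chash)
    disp.sd_mirna.to_csv(outdir / "dispersion.tsv", sep="\t")
    report.outputs.update({"calls": "calls.tsv", "dispersion": "dispersion.tsv"})
    report.headline.update(
        {
            "mean_disp": disp.mean_disp,
            "sd_disp": disp.sd_disp,
            "cutoff": cutoff.cutoff,
            "fold_upper_bound": cutoff.fold_upper,
            "fold_lower_bound": cutoff.fold_lower,
            "dysregulated_per_condition": {
                c: sum(1 for x in calls if x.condition == c and x.significant)
                for c in conditions
            },
        }
    )
    venn = None
    if len(conditions) >= 2:
        venn = venn_partition(calls)
        venn_dict = {
            "per_disease": {
                d: {k: sorted(v) for k, v in sets.items()}
                for d, sets in venn.per_disease.items()
            },
            "common_quiescent": sorted(venn.common_quiescent),
        }
        with open(outdir / "venn.json", "w") as fh:
            json.dump(venn_dict, fh, indent=2, sort_keys=True)
        report.outputs["venn"] = "venn.json"
        report.headline["venn_sizes"] = venn.summary_sizes()

    # --- co-regulation clustering ------------------------------------------
    cl = cfg["cluster"]
    assignments = []
    for cond in conditions:
        a = kmeans_cluster(
            rel,
            samples,
            cond,
            k=int(cl["k"]),
            seed=seed,
            restarts=int(cl["restarts"]),
            standardize=bool(cl["standardize"]),
        )
        assignments.append(a)
        a.labels.to_csv(outdir / f"clusters_{cond}.tsv", sep="\t")
        report.outputs[f"clusters_{cond}"] = f"clusters_{cond}.tsv"
    report.headline["clusters_nonempty"] = {
        a.condition: int(a.labels.nunique()) for a in assignments
    }
    if venn is not None and venn.common_quiescent and assignments:
        com = comembership(assignments, venn.common_quiescent)
        with open(outdir / "comembership.json", "w") as fh:
            json.dump(
                {
                    "query": sorted(com.query),
                    "intersection": sorted(com.intersection),
                    "largest_shared": {
                        c: sorted(s) for c, s in com.largest_shared.items()
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        report.outputs["comembership"] = "comembership.json"
        report.headline["comembership_intersection"] = len(com.intersection)

    # --- classification -----------------------------------------------------
    clf = cfg["classify"]
    uc_q = samples.samples_in_condition("UC_quiescent")
    cd_q = samples.samples_in_condition("CD_quiescent")
    if len(uc_q) >= 2 and len(cd_q) >= 2:
        scores = score_markers(rel, samples)
        forced = [m for m in clf.get("forced", []) if m]
        panel = select_markers(scores, forced, n_additional=int(clf["n_additional"]))
        result = knn_loocv(
            rel, samples, panel, k=int(clf["k"]), weighting=clf["weighting"]
        )
        pred_rows = [
            {
                "sample_id": p.sample_id,
                "true_class": p.true_class,
                "predicted_class": p.predicted_class,
                "confidence": round(p.confidence, 6),
                "correct": p.correct,
            }
            for p in result.predictions
        ]
        pd.DataFrame(pred_rows).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        report.outputs["predictions"] = "predictions.tsv"
        report.headline["loocv_accuracy"] = result.accuracy
        report.headline["loocv_correct"] = (
            f"{sum(p.correct for p in result.predictions)}/{len(result.predictions)}"
        )
        report.headline["panel_size"] = len(panel)

    # --- genomics ------------------------------------------------------------
    if annotation is not None and loci is not None:
        dysregulated = {
            c.mirna_id for c in calls if c.significant and c.condition.endswith("_quiescent")
        }
        groups = group_by_band(annotation, restrict_to=dysregulated or None)
        pd.DataFrame(
            [
                {
                    "chromosome": g.chromosome,
                    "band": g.band,
                    "category": g.category,
                    "n_genes": len(g.gene_ids),
                    "gene_ids": ",".join(g.gene_ids),
                }
                for g in groups
            ]
        ).to_csv(outdir / "band_groups.tsv", sep="\t", index=False)
        report.outputs["band_groups"] = "band_groups.tsv"
        report.headline["band_duplexes"] = sum(1 for g in groups if g.category == "duplex")
        report.headline["band_clusters"] = sum(1 for g in groups if g.category == "cluster")
        gcfg = cfg["genomics"]
        overlap = colocalize_with_loci(
            annotation, loci, window_bp=int(gcfg["window_bp"])
        )
        overlap.to_csv(outdir / "locus_overlap.tsv", sep="\t", index=False)
        report.outputs["locus_overlap"] = "locus_overlap.tsv"
        if genome_sizes:
            enr = chance_expectation(
                n_genes=len(annotation),
                loci=loci,
                window_bp=int(gcfg["window_bp"]),
                genome_sizes=genome_sizes,
                observed=int(overlap["gene_id"].nunique()),
                mc_draws=int(gcfg["mc_draws"]),
                seed=seed,
            )
            with open(outdir / "enrichment.json", "w") as fh:
                json.dump(
                    {
                        "observed": enr.observed,
                        "expected": enr.expected,
                        "fold_enrichment": enr.fold_enrichment,
                        "p_value": enr.p_value,
                        "covered_fraction": enr.covered_fraction,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            report.outputs["enrichment"] = "enrichment.json"
            report.headline["locus_overlap_observed"] = enr.observed
            report.headline["locus_overlap_expected"] = enr.expected
            report.headline["enrichment_fold"] = enr.fold_enrichment

    # --- targets --------------------------------------------------------------
    if catalog is not None and venn is not None:
        common_up = {
            m
            for m in venn.common_quiescent
            if any(
                c.mirna_id == m and c.condition == "UC_quiescent" and c.direction == "up"
                for c in calls
            )
        }
        gene_set = target_genes(catalog, common_up)
        strict = strictly_downregulated(catalog, common_up, universe=set(ct.mirna_ids))
        report.headline["n_target_genes"] = len(gene_set)
        report.headline["n_strict_down_genes"] = len(strict)
        if process_table is not None:
            summary = function_summary(gene_set, strict, process_table)
            summary.counts.to_csv(outdir / "target_summary.tsv", sep="\t")
            report.outputs["target_summary"] = "target_summary.tsv"

    report.to_json(outdir / "report.json")
    report.outputs["report"] = "report.json"
    return report
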