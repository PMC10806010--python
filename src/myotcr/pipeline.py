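"""End-to-end orchestration: simulate -> ingest -> subsample -> metrics ->
overlap -> features -> cluster -> associate, with a run manifest.

Stages hand data to each other as plain TSV files in the run directory,
so every intermediate is inspectable and any stage can be re-run in
isolation. The manifest records the configuration hash, seeds, package
versions and per-stage row counts; a run is idempotent for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, diversity, features, io, overlap, simulate, stats
from .model import Compartment, RepertoireSample

log = logging.getLogger(__name__)

STAGES = ["simulate", "ingest", "subsample", "metrics", "overlap",
          "features", "cluster", "associate"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    depth: int = diversity.DEFAULT_DEPTH
    dominance_pct: float = diversity.DEFAULT_DOMINANCE_PCT
    threshold_floor: int = clustering.THRESHOLD_FLOOR
    edge_rule: str = "lt"
    hydrophobicity_scale: str = "kyte-doolittle"
    keep_all_if_shallow: bool = False
    # either point at existing tables ...
    clone_table: Optional[str] = None
    meta_table: Optional[str] = None
    # ... or simulate a cohort
    simulate: Optional[simulate.CohortConfig] = None

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = simulate.CohortConfig(**sim)
        return cfg

    def validate(self) -> None:
        if self.simulate is None and (self.clone_table is None or self.meta_table is None):
            raise ValueError(
                "config must provide either a simulate block or both "
                "clone_table and meta_table"
            )


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all outputs under ``out_dir``.

    Returns the run directory. Every stochastic stage derives its seed
    from ``config.seed`` and the seeds are recorded in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "stages": {}, "versions": _versions()}
    rows = manifest["stages"]

    # -- simulate / ingest ----------------------------------------------------
    if config.simulate is not None:
        samples, meta, truth = simulate.generate_cohort(config.simulate, seed=config.seed)
        io.write_clone_table(samples, out / "clones.tsv")
        io.write_subject_meta(meta, out / "meta.tsv")
        truth.clones.to_csv(out / "truth_clones.tsv", sep="\t", index=False)
        truth.subjects.to_csv(out / "truth_subjects.tsv", sep="\t", index=False)
        rows["simulate"] = {"n_samples": len(samples), "n_subjects": len(meta)}
        clone_path, meta_path = out / "clones.tsv", out / "meta.tsv"
    else:
        clone_path, meta_path = Path(config.clone_table), Path(config.meta_table)
        rows["simulate"] = {"skipped": True}

    samples = io.read_clone_table(clone_path)
    meta = io.read_subject_meta(meta_path)
    meta_df = io.meta_frame(meta)
    known = set(meta_df.index)
    unknown = sorted({s.subject_id for s in samples} - known)
    if unknown:
        raise ValueError(f"clone table references subjects without metadata: {unknown}")
    rows["ingest"] = {"n_samples": len(samples),
                      "n_clones": int(sum(s.n_clones for s in samples))}

    # -- subsample ------------------------------------------------------------
    sub: "list[RepertoireSample]" = []
    for k, s in enumerate(sorted(samples, key=lambda s: s.sample_id)):
        sub.append(
            diversity.subsample_reads(
                s, depth=config.depth, seed=config.seed + 1000 + k,
                keep_all_if_shallow=config.keep_all_if_shallow,
            )
        )
    io.write_clone_table(sub, out / "clones_subsampled.tsv")
    rows["subsample"] = {"n_samples": len(sub), "depth": config.depth}

    # -- metrics --------------------------------------------------------------
    profiles = diversity.profile_frame(
        [diversity.diversity_profile(s, config.dominance_pct) for s in sub]
    )
    profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    rows["metrics"] = {"n_rows": len(profiles)}

    # -- overlap --------------------------------------------------------------
    by_subject: "dict[str, dict[str, RepertoireSample]]" = {}
    for s in sub:
        by_subject.setdefault(s.subject_id, {})[s.compartment.value] = s
    classifications = []
    for subject_id in sorted(by_subject):
        pair = by_subject[subject_id]
        if "muscle" in pair and "blood" in pair:
            classifications.append(
                overlap.classify_overlap(pair["muscle"], pair["blood"],
                                         dominance_pct=config.dominance_pct,
                                         force=config.keep_all_if_shallow)
            )
    if classifications:
        summary, per_subject = overlap.cohort_overlap_summary(classifications)
        summary.to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
        per_subject.to_csv(out / "overlap_subjects.tsv", sep="\t", index=False)
        per_clone = pd.concat(
            [c.table.assign(subject_id=c.subject_id).reset_index() for c in classifications],
            ignore_index=True,
        )
        per_clone.to_csv(out / "overlap_clones.tsv", sep="\t", index=False)
    else:
        per_clone = pd.DataFrame()
    rows["overlap"] = {"n_subject_pairs": len(classifications)}

    # -- features -------------------------------------------------------------
    feats = _feature_stage(sub, classifications, config, out)
    rows["features"] = {"n_clones": len(feats)}

    # -- cluster (pooled dominant muscle clones across patients) --------------
    rows["cluster"] = _cluster_stage(sub, config, out)

    # -- associate ------------------------------------------------------------
    panel = stats.association_panel(profiles, meta_df.reset_index())
    panel.to_csv(out / "associations.tsv", sep="\t", index=False)
    rows["associate"] = {"n_cells": len(panel)}

    manifest["n_stages"] = len(STAGES)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _feature_stage(sub, classifications, config, out) -> pd.DataFrame:
    frames = []
    for s in sub:
        t = features.feature_table(s.table["cdr3_aa"], scale=config.hydrophobicity_scale)
        t.insert(0, "sample_id", s.sample_id)
        t.insert(1, "subject_id", s.subject_id)
        t.insert(2, "compartment", s.compartment.value)
        t["v_gene"] = s.table["v_gene"].to_numpy()
        frames.append(t)
    feats = pd.concat(frames, ignore_index=True)
    feats.to_csv(out / "features.tsv", sep="\t", index=False)
    summary, comparisons = features.feature_summary(feats, "compartment")
    summary.to_csv(out / "feature_summary.tsv", sep="\t", index=False)
    comparisons.to_csv(out / "feature_comparisons.tsv", sep="\t", index=False)
    usage = []
    for compartment, chunk in feats.groupby("compartment"):
        u = features.vgene_usage(chunk.assign(umi_count=1), weighting="by_clone")
        usage.append(u.assign(group=compartment))
    pd.concat(usage, ignore_index=True).to_csv(out / "vgene_usage.tsv", sep="\t", index=False)
    return feats


def _cluster_stage(sub, config, out) -> dict:
    pooled_cdr3: "list[str]" = []
    pooled_subjects: "list[str]" = []
    for s in sub:
        if s.compartment is not Compartment.MUSCLE:
            continue
        freqs = diversity.clone_frequencies(s, config.dominance_pct)
        dom = freqs[freqs["is_dominant"]]
        pooled_cdr3.extend(dom["cdr3_aa"])
        pooled_subjects.extend([s.subject_id] * len(dom))
    if len(pooled_cdr3) < 2:
        return {"skipped": "fewer than 2 pooled dominant muscle clones"}
    clusters, edges, result = clustering.cross_patient_sharing(
        pooled_cdr3, pooled_subjects, edge_rule=config.edge_rule
    )
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    edges.to_csv(out / "cluster_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"scope": "pooled_dominant_muscle", "threshold": result.threshold,
          "edge_rule": result.edge_rule}]
    ).to_csv(out / "thresholds.tsv", sep="\t", index=False)
    return {
        "n_clones": len(pooled_cdr3),
        "n_clusters": result.n_clusters,
        "n_multi_patient_clusters": int((clusters["n_patients"] >= 2).sum()),
        "threshold": result.threshold,
    }


def _versions() -> dict:
    import networkx
    import scipy

    return {
        "myotcr": _package_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
    }


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("myotcr")
    except Exception:  # pragma: no cover
        return "unknown"
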