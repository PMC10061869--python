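"""End-to-end orchestration of the EV analysis.

``run_all`` executes the full pipeline on a counts + metadata pair:
per-dose bimodality exclusion, EV computation, reference-anchored
classification with split-half cross-validation, metric comparison,
exclusive set intersections, and (with a GMT collection) over-
representation analysis.  All artifacts are TSV/JSON files under the
output directory, and a manifest records the configuration, seed and
library versions needed to reproduce the run exactly.

Stratified sensitivity re-runs (by sex, or excluding donor triplets with
heavy smoking or alcohol consumption) reduce the sample size; following
the recommendation for small designs, such runs raise the bimodality
threshold from 1.1 to 1.3 unless the threshold was set explicitly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bimodality import BimodalityConfig, filter_bimodal
from .classify import LABEL_CODES, classify_whole, crossvalidate
from .enrichment import read_gmt, run_enrichment
from .ev import EVConfig, compute_ev
from .io import compute_size_factors, normalize, read_counts, read_metadata
from .metrics import (
    classification_sets,
    exclusive_intersections,
    metric_vs_expression,
    variability_metrics,
)

__all__ = ["PipelineConfig", "apply_strata", "run_all"]


@dataclass
class PipelineConfig:
    counts: str = ""
    metadata: str = ""
    gene_sets: str | None = None
    out_dir: str = "evarseq_out"
    reference_group: str = "N0"
    bi_threshold: float | None = None  # None -> 1.1, or 1.3 under strata filters
    eps: float = 10.0
    zero_percent_thr: float = 0.2
    B: int = 1000
    R: int = 10
    k: float = 3.0
    alpha: float = 0.05
    mad_constant: float = 1.4826
    loess_span: float = 0.75
    loess_degree: int = 2
    seed: int = 0
    sex: str | None = None
    exclude_smoking_over: float | None = None
    exclude_alcohol_over: float | None = None
    by_triplet: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    @property
    def stratified(self) -> bool:
        return (
            self.sex is not None
            or self.exclude_smoking_over is not None
            or self.exclude_alcohol_over is not None
        )

    @property
    def effective_bi_threshold(self) -> float:
        if self.bi_threshold is not None:
            return self.bi_threshold
        return 1.3 if self.stratified else 1.1

    def validate(self) -> "PipelineConfig":
        for name in ("eps", "B", "R", "k", "alpha", "mad_constant", "loess_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bi_threshold is not None and self.bi_threshold <= 0:
            raise ValueError("bi_threshold must be positive")
        return self


def apply_strata(
    metadata: pd.DataFrame,
    sex: str | None = None,
    exclude_smoking_over: float | None = None,
    exclude_alcohol_over: float | None = None,
) -> pd.DataFrame:
    """Sample subset for a stratified sensitivity run.

    Lifestyle exclusions act at the matched-triplet level: a triplet is
    dropped entirely if any of its donors exceeds the smoking or alcohol
    limit.  Sex stratification then selects samples by donor sex.
    """
    needed = {"triplet_id", "sex", "smoking_pack_years", "alcohol_per_day"}
    missing = needed - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    keep = metadata.copy()
    bad_triplets: set = set()
    if exclude_smoking_over is not None:
        bad_triplets |= set(keep.loc[keep["smoking_pack_years"] > exclude_smoking_over, "triplet_id"])
    if exclude_alcohol_over is not None:
        bad_triplets |= set(keep.loc[keep["alcohol_per_day"] > exclude_alcohol_over, "triplet_id"])
    if bad_triplets:
        keep = keep[~keep["triplet_id"].isin(bad_triplets)]
    if sex is not None:
        keep = keep[keep["sex"] == sex]
    return keep


def _check_strata_sizes(metadata: pd.DataFrame, minimum: int = 8) -> None:
    sizes = metadata.groupby(["donor_group", "dose"]).size()
    too_small = sizes[sizes < minimum]
    if len(too_small):
        raise ValueError(
            f"strata too small after filtering (need >= {minimum} samples): "
            + ", ".join(f"{g}@{d}={n}" for (g, d), n in too_small.items())
        )


def run_all(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Run every stage and write all artifacts to ``config.out_dir``.

    ``counts`` and ``metadata`` may be passed in memory; otherwise they
    are read from the configured paths.  Returns a dict of the in-memory
    results keyed by stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    with stage("load"):
        if counts is None:
            counts = read_counts(config.counts)
        if metadata is None:
            metadata = read_metadata(config.metadata)
        metadata = metadata.loc[[s for s in counts.columns if s in metadata.index]]
        if config.stratified:
            metadata = apply_strata(
                metadata,
                sex=config.sex,
                exclude_smoking_over=config.exclude_smoking_over,
                exclude_alcohol_over=config.exclude_alcohol_over,
            )
            counts = counts[metadata.index]
        _check_strata_sizes(metadata)

    with stage("size_factors"):
        s = compute_size_factors(counts)
        s.to_frame().to_csv(out / "size_factors.tsv", sep="\t", index_label="sample_id")
        results["size_factors"] = s

    doses = sorted(metadata["dose"].unique())
    groups = sorted(metadata["donor_group"].unique())

    with stage("bimodality"):
        bi_cfg = BimodalityConfig(
            bi_threshold=config.effective_bi_threshold,
            zero_percent_thr=config.zero_percent_thr,
            eps=config.eps,
            seed=config.seed,
        )
        retained: dict[str, list] = {}
        for dose in doses:
            cols = metadata.index[metadata["dose"] == dose]
            ret, _exc, report = filter_bimodal(counts[list(cols)], s, bi_cfg)
            retained[dose] = ret
            report.to_csv(out / f"bimodality_{dose}Gy.tsv", sep="\t", index=False)
        results["retained"] = retained

    ev_cfg = EVConfig(
        B=config.B,
        mad_constant=config.mad_constant,
        loess_span=config.loess_span,
        loess_degree=config.loess_degree,
        seed=config.seed,
    )

    with stage("ev"):
        ev_table = compute_ev(counts, metadata, s, retained, ev_cfg, groups=groups, doses=doses)
        ev_table.to_csv(out / "ev.tsv", sep="\t", index=False)
        results["ev"] = ev_table

    with stage("classification"):
        whole, thresholds = classify_whole(
            ev_table, config.reference_group, B=config.B,
            constant=config.mad_constant, k=config.k, seed=config.seed,
        )
        results["thresholds"] = thresholds
        cls = crossvalidate(
            counts, metadata, s, retained, ev_cfg,
            reference_group=config.reference_group,
            R=config.R, k=config.k, alpha=config.alpha,
            seed=config.seed, by_triplet=config.by_triplet, whole=whole,
        )
        for dose in doses:
            sub = cls[cls["dose"] == dose].copy()
            sub["label_whole_code"] = sub["label_whole"].map(LABEL_CODES)
            sub["label_confirmed_code"] = sub["label_confirmed"].map(LABEL_CODES)
            sub.to_csv(out / f"classification_{dose}Gy.tsv", sep="\t", index=False)
        results["classification"] = cls

    with stage("metrics"):
        norm = normalize(counts, s)
        frames = []
        for dose in doses:
            for grp in groups:
                cols = metadata.index[(metadata["dose"] == dose) & (metadata["donor_group"] == grp)]
                m = variability_metrics(norm.loc[retained[dose], list(cols)], config.mad_constant)
                m.insert(1, "group", grp)
                m.insert(2, "dose", dose)
                frames.append(m)
        metric_table = pd.concat(frames, ignore_index=True)
        metric_table = metric_table.merge(
            ev_table[["gene_id", "group", "dose", "ev"]], on=["gene_id", "group", "dose"]
        )
        metric_table.to_csv(out / "metrics.tsv", sep="\t", index=False)
        tau = metric_vs_expression(metric_table)
        tau.to_csv(out / "tau.tsv", sep="\t", index=False)
        results["metrics"] = metric_table
        results["tau"] = tau

    with stage("intersections"):
        inter = {}
        for label in ("hypo", "hyper"):
            sets = classification_sets(cls, label)
            report = exclusive_intersections(sets)
            report.to_csv(out / f"intersections_{label}.tsv", sep="\t", index=False)
            inter[label] = report
        results["intersections"] = inter

    if config.gene_sets:
        with stage("enrichment"):
            collection = read_gmt(config.gene_sets)
            backgrounds = {dose: set(retained[dose]) for dose in doses}
            queries: dict[str, set] = {}
            query_bg: dict[str, str] = {}
            for label in ("hypo", "hyper"):
                for (grp, dose), sub in cls.groupby(["group", "dose"], sort=True):
                    genes = set(sub.loc[sub["label_confirmed"] == label, "gene_id"])
                    qid = f"{label}|{grp}|{dose}Gy"
                    queries[qid] = genes
                    query_bg[qid] = dose
                # unique (single-set) cells of the intersection analysis
                report = inter[label]
                set_cols = [c for c in report.columns if c not in ("count", "gene_ids")]
                for _, row in report.iterrows():
                    flags = [c for c in set_cols if row[c]]
                    if len(flags) == 1:
                        grp, dose = flags[0].split("@")
                        qid = f"{label}|unique:{flags[0]}"
                        queries[qid] = set(row["gene_ids"].split(",")) if row["gene_ids"] else set()
                        query_bg[qid] = dose
            enr = run_enrichment(queries, collection, backgrounds, query_bg, alpha=config.alpha)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enr

    manifest = {
        "package": "evarseq",
        "version": __version__,
        "config": asdict(config),
        "effective_bi_threshold": config.effective_bi_threshold,
        "seed": config.seed,
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "doses": list(doses),
        "groups": list(groups),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
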