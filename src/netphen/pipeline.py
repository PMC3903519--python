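"""End-to-end pipeline orchestration.

Runs build -> decompose -> distances -> deltas -> discrimination (and the
survival analysis when survival data are present), writing every module's
report plus a JSON run manifest into an output directory.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decompose import (
    decomposition_report,
    greedy_decompose,
    reference_set_from_file,
)
from .distance import (
    classify_cohort,
    cohort_mean_deltas,
    delta_differences,
    distance_vectors,
    select_discriminating_pairs,
)
from .genotype import GenotypeRecord, read_genotype_table
from .graph import build_dosage_graph, build_personal_cycle, build_study_graph
from .loci import LocusSpec, read_loci_config
from .survival import scan_report, survival_logistic, threshold_scan

logger = logging.getLogger("netphen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    loci_path: str
    genotype_paths: list[str]
    out_dir: str
    coding: str = "two_state"
    graph_mode: str = "subject"            # subject | dosage
    reference_source: str = "combined"     # combined | case | control | FILE
    alpha: float = 0.05
    scan: tuple[float, float, float] = (800.0, 1900.0, 10.0)
    min_abs: float = 0.5
    seed: int = 0
    folds: int = 10
    run_survival: bool | None = None       # None: run iff survival data present


def _references(
    config: RunConfig,
    records: Sequence[GenotypeRecord],
    loci: Sequence[LocusSpec],
):
    source = config.reference_source
    if source in ("combined", "case", "control"):
        subset = (
            records
            if source == "combined"
            else [r for r in records if r.cohort == source]
        )
        if not subset:
            raise ValueError(f"reference source {source!r}: no such subjects")
        if config.graph_mode == "dosage":
            graph = build_dosage_graph(subset, loci)
        else:
            cycles = [
                build_personal_cycle(r, loci, config.coding) for r in subset
            ]
            graph = build_study_graph(cycles, loci)
        return greedy_decompose(graph), graph
    # otherwise a file of injected reference cycles
    return reference_set_from_file(source, loci, config.coding), None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: load")
    loci = read_loci_config(config.loci_path)
    records: list[GenotypeRecord] = []
    for path in config.genotype_paths:
        records.extend(read_genotype_table(path, loci))
    labels = [r.cohort for r in records]

    logger.info("stage: build")
    cycles = [build_personal_cycle(r, loci, config.coding) for r in records]
    if config.graph_mode == "dosage":
        if config.coding != "two_state":
            raise ValueError("dosage graphs are defined for two_state coding")
        graph = build_dosage_graph(records, loci)
    else:
        graph = build_study_graph(cycles, loci)
    graph.to_json(out / "study_graph.json")

    logger.info("stage: decompose")
    rrps, ref_graph = _references(config, records, loci)
    if ref_graph is None:
        ref_graph = graph
    decomposition_report(rrps, loci).to_csv(
        out / "decomposition.csv", index=False
    )

    logger.info("stage: distances")
    vectors = distance_vectors(cycles, rrps)
    dist_df = pd.DataFrame(
        [v.distances for v in vectors],
        index=pd.Index([v.sample_id for v in vectors], name="sample_id"),
        columns=[f"d{r.rank}" for r in rrps],
    )
    dist_df.to_csv(out / "distances.csv")

    if len(rrps) >= 2:
        table = delta_differences(vectors)
        table.to_frame().to_csv(out / "deltas.csv")
    else:
        table = None

    manifest: dict = {
        "seed": config.seed,
        "coding": config.coding,
        "graph_mode": config.graph_mode,
        "reference_source": config.reference_source,
        "n_subjects": len(records),
        "n_references": len(rrps),
        "inputs": {
            "loci": str(config.loci_path),
            "genotypes": [str(p) for p in config.genotype_paths],
        },
        "python": platform.python_version(),
        "netphen_version": _pkg_version(),
        "artifacts": ["study_graph.json", "decomposition.csv", "distances.csv"],
    }

    logger.info("stage: discriminate")
    have_both = {"case", "control"} <= set(labels)
    if table is not None and have_both:
        means = cohort_mean_deltas(table, labels)
        means.to_csv(out / "cohort_means.csv", index=False)
        selected = select_discriminating_pairs(means, min_abs=config.min_abs)
        selected.to_csv(out / "discriminating_pairs.csv", index=False)
        result = classify_cohort(
            vectors, labels, folds=min(config.folds, _min_class(labels)),
            seed=config.seed,
        )
        manifest["classification"] = {
            "accuracy": result.accuracy,
            "roc_auc": result.roc_auc,
            "confusion": result.confusion.tolist(),
        }
        manifest["artifacts"] += [
            "deltas.csv", "cohort_means.csv", "discriminating_pairs.csv",
        ]

    survival_requested = config.run_survival
    have_survival = [r for r in records if r.survival_days is not None]
    if survival_requested is None:
        survival_requested = len(have_survival) >= 4
    if survival_requested:
        logger.info("stage: survival")
        if not have_survival:
            raise ValueError(
                "survival stage requested but the genotype table has no "
                "survival_days/event columns"
            )
        if table is None:
            raise ValueError("survival stage needs >= 2 reference profiles")
        idx = [
            i for i, r in enumerate(records) if r.survival_days is not None
        ]
        sub_table = type(table)(
            sample_ids=[table.sample_ids[i] for i in idx],
            pairs=table.pairs,
            values=table.values[np.asarray(idx)],
        )
        days = [records[i].survival_days for i in idx]
        lo, hi, step = config.scan
        splits, best = threshold_scan(
            days, sub_table, lo=lo, hi=hi, step=step, alpha=config.alpha
        )
        scan_report(splits).to_csv(out / "threshold_scan.csv", index=False)
        groups = [
            "short" if d <= best.threshold_days else "long" for d in days
        ]
        best.tests.to_csv(out / "survival_tests.csv", index=False)
        sig = best.tests[best.tests["significant"]]
        if len(sig) > 0:
            pairs = list(zip(sig["i"], sig["j"]))
            model = survival_logistic(sub_table, pairs, groups)
            model.to_json(out / "survival_model.json")
            manifest["artifacts"].append("survival_model.json")
        manifest["survival"] = {
            "best_threshold_days": best.threshold_days,
            "n_short": best.n_short,
            "n_long": best.n_long,
            "n_significant": best.n_significant,
        }
        manifest["artifacts"] += ["threshold_scan.csv", "survival_tests.csv"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _min_class(labels: Sequence[str]) -> int:
    labels = np.asarray(labels)
    return int(min(np.sum(labels == c) for c in set(labels)))


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("netphen")
    except PackageNotFoundError:
        return "unknown"
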