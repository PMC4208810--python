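"""End-to-end orchestration of the integrative-clustering pipeline.

Stage order: aberration profiling -> driver selection -> consensus
clustering of samples on driver-gene expression -> SAM subtype signature ->
ssGSEA pathway enrichment and subtype-specific pathway calls -> per-drug
differential sensitivity.  ``run_all`` is exactly the composition of the
stage functions; each stage derives its own RNG stream from
``config.rng_seed`` with a fixed offset, so running stages separately with
the same seed reproduces ``run_all`` bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .aberrations import ABERRATION_TYPES, count_aberrations, recurrence_table
from .config import PipelineConfig
from .consensus import ConsensusResult, consensus_cluster, name_clusters
from .drivers import select_drivers
from .drugs import compare_all_drugs
from .sam import SamResult, class_centroids, sam_analyze, select_signature
from .ssgsea import EnrichmentMatrix, enrichment_matrix, rank_normalize, subtype_pathways
from .types import CopyNumberCalls, ExpressionMatrix, GeneSetCollection, Ic50Table

__all__ = ["PipelineResult", "run_all", "SEED_OFFSETS"]

log = logging.getLogger("icpipe")

# fixed per-stage seed offsets keep stage-wise runs identical to run_all
SEED_OFFSETS = {"consensus": 0, "signature_sam": 101, "pathway_sam": 202}


def stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.rng_seed + SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineResult:
    burden: pd.DataFrame
    recurrence: dict[str, pd.DataFrame]
    drivers: pd.DataFrame
    driver_genes: list[str]
    consensus: ConsensusResult
    labels: pd.Series            # sample -> raw cluster number (1..k)
    cluster_names: dict[int, str]  # raw cluster -> "IC1"/"IC2"/...
    sam: SamResult
    signature: pd.DataFrame
    centroids: pd.DataFrame
    enrichment: EnrichmentMatrix
    pathway_calls: pd.DataFrame
    drug_comparison: pd.DataFrame

    @property
    def ic_labels(self) -> pd.Series:
        return self.labels.map(self.cluster_names)


def run_all(
    calls: CopyNumberCalls,
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    ic50: Ic50Table,
    config: PipelineConfig | None = None,
    k_range: Sequence[int] = (2, 3, 4, 5),
    reference_sets: Sequence[str] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all stage outputs.

    ``reference_sets`` optionally names gene sets (e.g. oxidative
    phosphorylation / mitochondrial sets) whose mean enrichment anchors the
    IC1 label; otherwise IC1 is anchored to the alphabetically first sample.
    """
    config = config or PipelineConfig()
    config.log_effective()
    t0 = time.perf_counter()

    burden = count_aberrations(calls)
    recurrence = {t: recurrence_table(calls, t, top_n=15) for t in ABERRATION_TYPES}
    log.info("stage aberrations done (%.1fs)", time.perf_counter() - t0)

    drivers = select_drivers(calls, expr, config)
    driver_genes = drivers.loc[drivers["selected"], "gene"].tolist()
    log.info("stage drivers done: %d drivers (%.1fs)", len(driver_genes),
             time.perf_counter() - t0)

    cons = consensus_cluster(
        expr, driver_genes or None,
        k_range=sorted(set(list(k_range) + [config.n_clusters])),
        config=config.replace(rng_seed=stage_seed(config, "consensus")),
    )
    labels = cons.labels[config.n_clusters]
    log.info("stage consensus done (%.1fs)", time.perf_counter() - t0)

    sig_genes = driver_genes or list(expr.values.index)
    sam = sam_analyze(
        expr.values.loc[expr.values.index.intersection(pd.Index(sig_genes)),
                        labels.index],
        labels.to_numpy(),
        n_permutations=config.sam_n_permutations,
        seed=stage_seed(config, "signature_sam"),
        s0_percentiles=config.sam_s0_percentiles,
    )
    signature = select_signature(sam, config.signature_q_threshold)
    centroids = (
        class_centroids(expr.values.loc[:, labels.index], labels.to_numpy(),
                        signature["feature"].tolist())
        if not signature.empty
        else pd.DataFrame()
    )
    log.info("stage signature done: %d features (%.1fs)", len(signature),
             time.perf_counter() - t0)

    es = rank_normalize(enrichment_matrix(expr, gene_sets, alpha=config.ssgsea_alpha))
    cluster_names = name_clusters(labels, es.scores, reference_sets)
    pathway_calls = subtype_pathways(
        EnrichmentMatrix(es.scores.loc[:, labels.index], es.alpha, True, es.variant),
        labels.loc[labels.index].to_numpy(),
        config,
        seed=stage_seed(config, "pathway_sam"),
    )
    log.info("stage ssgsea done (%.1fs)", time.perf_counter() - t0)

    drug_comparison = compare_all_drugs(ic50, labels, config.min_group_size)
    log.info("stage drugs done (%.1fs)", time.perf_counter() - t0)

    return PipelineResult(
        burden=burden,
        recurrence=recurrence,
        drivers=drivers,
        driver_genes=driver_genes,
        consensus=cons,
        labels=labels,
        cluster_names=cluster_names,
        sam=sam,
        signature=signature,
        centroids=centroids,
        enrichment=es,
        pathway_calls=pathway_calls,
        drug_comparison=drug_comparison,
    )


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every stage output as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.burden.to_csv(out / "burden.tsv", sep="\t")
    for t, tab in result.recurrence.items():
        tab.to_csv(out / f"recurrence_{t.lower()}.tsv", sep="\t", index=False)
    result.drivers.to_csv(out / "drivers.tsv", sep="\t", index=False)
    for kk, cm in result.consensus.consensus.items():
        cm.to_csv(out / f"consensus_k{kk}.tsv", sep="\t")
    result.consensus.per_k_stats.to_json(out / "per_k_stats.json", orient="records")
    labels = pd.DataFrame(
        {"sample": result.labels.index, "cluster": result.labels.to_numpy(),
         "ic": result.ic_labels.to_numpy()}
    )
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    result.sam.table.to_csv(out / "sam.tsv", sep="\t", index=False)
    result.signature.to_csv(out / "signature.tsv", sep="\t", index=False)
    if not result.centroids.empty:
        result.centroids.to_json(out / "centroids.json", orient="index")
    result.enrichment.scores.to_csv(out / "ssgsea_scores.tsv", sep="\t")
    result.pathway_calls.to_csv(out / "pathway_calls.tsv", sep="\t", index=False)
    result.drug_comparison.to_csv(out / "drug_comparison.tsv", sep="\t", index=False)
    summary = {
        "n_driver_genes": len(result.driver_genes),
        "k_selected_advisory": int(result.consensus.k_selected),
        "cluster_sizes": result.ic_labels.value_counts().to_dict(),
        "n_signature_features": int(len(result.signature)),
        "n_pathways_up": int((result.pathway_calls["call"] == "UP").sum()),
        "n_pathways_down": int((result.pathway_calls["call"] == "DOWN").sum()),
        "n_drugs_p_below_0.05": int((result.drug_comparison["p_value"] < 0.05).sum()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
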