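"""Synthetic paired copy-number / expression / gene-set / IC50 cohorts.

The generator plants exactly the statistical structure the analysis
pipeline assumes, so that every stage can be exercised and its recovery
measured without any external download:

* two latent sample clusters drawn from ``cluster_proportions``;
* *driver* genes whose copy state is enriched for one aberration
  (gain in one cluster, loss in the other, at ``driver_purity``) and whose
  log2 expression is ``baseline + dose_effect * dose + noise``;
* *cluster-marker* genes, copy-neutral but shifted by
  ``+/- cluster_shift / 2`` between the clusters (these are what the
  differential gene sets are built from);
* *null* genes with cluster-independent random copy states and expression
  independent of both dose and cluster — the false-positive floor for the
  driver-selection stage;
* an LOH mask independent of everything else (copy-neutral LOH included);
* gene sets: differential sets drawn mostly from one cluster's markers,
  null sets drawn uniformly;
* log-normal IC50s (median 1 µM) with ``ic50_fold`` between clusters for
  the differential drugs.

Everything is reproducible from ``spec.seed`` alone, and every generated
object passes its own container invariants and round-trips through the
readers/writers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GAIN,
    LOSS,
    CopyNumberCalls,
    ExpressionMatrix,
    GeneSetCollection,
    Ic50Table,
)

__all__ = ["CohortSpec", "CohortTruth", "SyntheticCohort", "generate_cohort",
           "generate_null_cohort", "write_cohort"]


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults describe a cohort this pipeline is intended for: 60 cell
    lines, 2000 genes of which 100 are copy-number drivers
    (``dose_effect`` = 1 log2 unit per copy-dose unit) and 400 are cluster
    markers separated by ``cluster_shift`` = 2.0 log2 units (4 noise SDs at
    ``noise_sd`` = 0.5); the differential drugs differ 8-fold in IC50,
    inside the 2-10 fold range typical of subtype-level chemosensitivity
    differences.
    """

    n_samples: int = 60
    n_genes: int = 2000
    n_driver_genes: int = 100
    n_null_genes: int = 1500
    cluster_proportions: tuple[float, float] = (0.5, 0.5)
    dose_effect: float = 1.0
    cluster_shift: float = 2.0
    noise_sd: float = 0.5
    driver_purity: float = 0.9
    null_gain_rate: float = 0.15
    null_loss_rate: float = 0.15
    loh_rate: float = 0.05
    n_gene_sets: int = 50
    n_differential_sets: int = 10
    set_size_range: tuple[int, int] = (15, 40)
    n_drugs: int = 20
    n_differential_drugs: int = 5
    ic50_fold: float = 8.0
    ic50_cv: float = 0.25  # SD of log10 IC50 within a cluster
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_gene_sets, self.n_drugs) < 1:
            raise ValueError("all counts must be positive")
        if self.n_driver_genes + self.n_null_genes > self.n_genes:
            raise ValueError("driver + null genes exceed n_genes")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9 or min(self.cluster_proportions) <= 0:
            raise ValueError("cluster_proportions must be positive and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_differential_sets > self.n_gene_sets:
            raise ValueError("more differential sets than gene sets")
        if self.n_differential_drugs > self.n_drugs:
            raise ValueError("more differential drugs than drugs")
        if not 0.5 <= self.driver_purity <= 1.0:
            raise ValueError("driver_purity must be in [0.5, 1]")
        if self.ic50_fold <= 0 or self.ic50_cv <= 0:
            raise ValueError("ic50_fold and ic50_cv must be positive")

    @property
    def n_marker_genes(self) -> int:
        return self.n_genes - self.n_driver_genes - self.n_null_genes

    def replace(self, **changes) -> "CohortSpec":
        return dataclasses.replace(self, **changes)


@dataclass
class CohortTruth:
    """Ground truth planted by the generator."""

    cluster_labels: pd.Series  # sample -> 1 or 2
    driver_genes: list[str]
    marker_genes: list[str]
    differential_sets: dict[str, int]  # set name -> cluster it is up in
    differential_drugs: dict[str, int]  # drug name -> sensitive cluster

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_labels": {s: int(c) for s, c in self.cluster_labels.items()},
            "driver_genes": self.driver_genes,
            "marker_genes": self.marker_genes,
            "differential_sets": {k: int(v) for k, v in self.differential_sets.items()},
            "differential_drugs": {k: int(v) for k, v in self.differential_drugs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            cluster_labels=pd.Series(payload["cluster_labels"]),
            driver_genes=payload["driver_genes"],
            marker_genes=payload["marker_genes"],
            differential_sets=payload["differential_sets"],
            differential_drugs=payload["differential_drugs"],
        )


@dataclass
class SyntheticCohort:
    calls: CopyNumberCalls
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    ic50: Ic50Table
    truth: CohortTruth

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.calls, self.expression, self.gene_sets, self.ic50, self.truth))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one cohort from the spec (deterministic per ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    clusters = rng.choice([1, 2], size=spec.n_samples, p=list(spec.cluster_proportions))
    labels = pd.Series(clusters, index=samples, name="cluster")

    n_drv, n_mrk = spec.n_driver_genes, spec.n_marker_genes
    driver_genes = genes[:n_drv]
    marker_genes = genes[n_drv:n_drv + n_mrk]
    null_genes = genes[n_drv + n_mrk:]

    state = np.zeros((spec.n_genes, spec.n_samples), dtype=np.int8)
    baseline = rng.uniform(4.0, 10.0, size=spec.n_genes)
    expr = np.tile(baseline[:, None], (1, spec.n_samples))

    in_c1 = clusters == 1
    # drivers: gain enriched in one cluster, loss in the other (alternating),
    # expression follows the numeric copy dose
    for g in range(n_drv):
        dir_state = GAIN if g % 2 == 0 else LOSS
        active_c1 = (g // 2) % 2 == 0  # active cluster alternates too
        active = in_c1 if active_c1 else ~in_c1
        carry = rng.random(spec.n_samples) < np.where(
            active, spec.driver_purity, 1.0 - spec.driver_purity
        )
        state[g, carry] = dir_state
        expr[g] += spec.dose_effect * state[g]
    # markers: copy-neutral expression shift between clusters
    for j, g in enumerate(range(n_drv, n_drv + n_mrk)):
        up_c1 = j % 2 == 0
        shift = np.where(in_c1 == up_c1, spec.cluster_shift / 2, -spec.cluster_shift / 2)
        expr[g] += shift
    # null genes: random states independent of everything
    n_null = len(null_genes)
    if n_null:
        u = rng.random((n_null, spec.n_samples))
        block = np.zeros((n_null, spec.n_samples), dtype=np.int8)
        block[u < spec.null_gain_rate] = GAIN
        block[(u >= spec.null_gain_rate)
              & (u < spec.null_gain_rate + spec.null_loss_rate)] = LOSS
        state[n_drv + n_mrk:] = block
    if spec.noise_sd > 0:
        expr += rng.normal(0.0, spec.noise_sd, size=expr.shape)
    loh = rng.random(state.shape) < spec.loh_rate

    calls = CopyNumberCalls(
        pd.DataFrame(state, index=genes, columns=samples),
        pd.DataFrame(loh, index=genes, columns=samples),
    )
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))

    # gene sets: differential sets mostly from one cluster's markers
    c1_markers = [g for j, g in enumerate(marker_genes) if j % 2 == 0]
    c2_markers = [g for j, g in enumerate(marker_genes) if j % 2 == 1]
    sets: dict[str, tuple[str, list[str]]] = {}
    differential_sets: dict[str, int] = {}
    lo, hi = spec.set_size_range
    for i in range(spec.n_gene_sets):
        name = f"SET{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < spec.n_differential_sets:
            up_cluster = 1 if i % 2 == 0 else 2
            pool = c1_markers if up_cluster == 1 else c2_markers
            n_marker_members = min(len(pool), max(1, int(round(0.8 * size))))
            members = list(rng.choice(pool, size=n_marker_members, replace=False))
            others = rng.choice(null_genes if null_genes else genes,
                                size=size - n_marker_members, replace=False)
            members += list(others)
            differential_sets[name] = up_cluster
            desc = f"synthetic differential set (up in cluster {up_cluster})"
        else:
            members = list(rng.choice(null_genes if null_genes else genes,
                                      size=min(size, max(n_null, 1)), replace=False))
            desc = "synthetic null set"
        sets[name] = (desc, members)
    gene_sets = GeneSetCollection(sets)

    # IC50s: log-normal around 1 uM; differential drugs shift half a fold
    # up in the resistant cluster and half a fold down in the sensitive one
    rows = []
    differential_drugs: dict[str, int] = {}
    half_shift = np.log10(spec.ic50_fold) / 2.0
    for i in range(spec.n_drugs):
        drug = f"DRUG{i + 1:02d}"
        log_ic50 = rng.normal(0.0, spec.ic50_cv, size=spec.n_samples)
        if i < spec.n_differential_drugs and spec.ic50_fold != 1.0:
            sensitive = 1 if i % 2 == 0 else 2
            differential_drugs[drug] = sensitive
            log_ic50 += np.where(clusters == sensitive, -half_shift, half_shift)
        for s, v in zip(samples, 10.0**log_ic50):
            rows.append({"drug": drug, "sample": s, "ic50_uM": float(v),
                         "censored": False})
    ic50 = Ic50Table(pd.DataFrame(rows))

    truth = CohortTruth(
        cluster_labels=labels,
        driver_genes=list(driver_genes),
        marker_genes=list(marker_genes),
        differential_sets=differential_sets,
        differential_drugs=differential_drugs,
    )
    return SyntheticCohort(calls, expression, gene_sets, ic50, truth)


def generate_null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Cohort with no planted structure anywhere.

    Copy states keep their marginal rates but are independent of cluster
    and expression (``dose_effect=0``, ``driver_purity=0.5``); there is no
    cluster expression shift and no differential drug.  Truth lists are
    empty (the cluster labels remain as arbitrary, signal-free draws).
    """
    null_spec = spec.replace(dose_effect=0.0, cluster_shift=0.0, ic50_fold=1.0,
                             driver_purity=0.5)
    cohort = generate_cohort(null_spec)
    cohort.truth.driver_genes = []
    cohort.truth.marker_genes = []
    cohort.truth.differential_sets = {}
    cohort.truth.differential_drugs = {}
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four standard input files plus the truth JSON."""
    from . import io as icio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out / "cn_calls.tsv",
        "expression": out / "expression.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "ic50": out / "ic50.tsv",
        "truth": out / "truth.json",
    }
    icio.write_cn_calls(cohort.calls, paths["calls"])
    icio.write_expression(cohort.expression, paths["expression"])
    icio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    icio.write_ic50(cohort.ic50, paths["ic50"])
    cohort.truth.to_json(paths["truth"])
    return paths
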