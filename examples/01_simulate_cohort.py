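"""Generate a synthetic paired copy-number / expression cohort.

The generator plants two latent sample clusters, copy-number-driven genes,
cluster-marker genes, differential gene sets and differential drugs, and
returns the ground truth alongside the four standard input files.
"""

from icpipe import CohortSpec, generate_cohort, write_cohort

spec = CohortSpec(seed=1)
cohort = generate_cohort(spec)
paths = write_cohort(cohort, "scratch/example_cohort")

t = cohort.truth
print(f"samples: {spec.n_samples} ({(t.cluster_labels == 1).sum()} in cluster 1, "
      f"{(t.cluster_labels == 2).sum()} in cluster 2)")
print(f"genes: {spec.n_genes} = {len(t.driver_genes)} drivers "
      f"+ {len(t.marker_genes)} cluster markers + {spec.n_null_genes} nulls")
print(f"gene sets: {len(cohort.gene_sets)} ({len(t.differential_sets)} differential)")
print(f"drugs: {len(cohort.ic50.drugs)} ({len(t.differential_drugs)} differential, "
      f"{spec.ic50_fold:g}-fold IC50 shift)")
print("files written:", ", ".join(str(p) for p in paths.values()))
# The truth JSON is what downstream examples compare their recoveries against.
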