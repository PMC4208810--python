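"""Per-sample aberration burden and per-gene recurrence.

Burden counts gains, losses and LOH calls per sample (a gene with loss plus
LOH counts in both columns, so the total is the exact row sum); recurrence
ranks genes by how many samples carry one aberration type, reported as a
rounded percent of the cohort.
"""

from icpipe import CohortSpec, count_aberrations, generate_cohort, recurrence_table

cohort = generate_cohort(CohortSpec(seed=1))

burden = count_aberrations(cohort.calls)
print("burden (first 4 samples):")
print(burden.head(4).to_string())
print("-> total = gain + loss + loh for every sample:",
      bool((burden["total"] == burden[["gain", "loss", "loh"]].sum(axis=1)).all()))

# restrict to a gene list, as one would to a kinome
subset = cohort.calls.genes[:200]
print("\nburden restricted to a 200-gene list (first 2 samples):")
print(count_aberrations(cohort.calls, subset).head(2).to_string())

gains = recurrence_table(cohort.calls, "GAIN", top_n=5)
print("\nmost recurrently gained genes:")
print(gains.to_string(index=False))
print("-> 'frequency' is the percent of the cohort carrying the gain,")
print("   rounded to the integer a published recurrence table would print.")
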