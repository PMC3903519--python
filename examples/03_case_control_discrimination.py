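"""Discriminate cohorts by graph distances from reference profiles.

Builds a cohort in which 77% of cases are forced to carry genotype cycles
sharing no vertex with a designated reference cycle (the "absence marker"
scenario: cases are recognised by the complete lack of a pattern, not by
the presence of one). Then:

* counts the maximal-distance subset among cases and controls,
* averages the pairwise distance differences per cohort (the 2D plot
  coordinates whose off-diagonal points mark discriminating reference
  pairs), and
* cross-validates a pruned decision tree on the distance vectors.
"""

from netphen import (
    PersonalCycle,
    SimulationConfig,
    build_personal_cycle,
    build_study_graph,
    classify_cohort,
    cohort_mean_deltas,
    ctla4_loci,
    delta_differences,
    distance_vectors,
    greedy_decompose,
    haplotype_to_cycle,
    max_distance_subset,
    select_discriminating_pairs,
    simulate_cohorts,
)

loci = ctla4_loci()
reference = haplotype_to_cycle("GGTTGG", loci).states
records = simulate_cohorts(
    SimulationConfig(
        loci=loci, n_case=286, n_control=288, seed=4,
        absence_fraction=0.77, absence_reference=reference,
    )
)
labels = [r.cohort for r in records]
cycles = [build_personal_cycle(r, loci, "two_state") for r in records]

ref_cycle = PersonalCycle(None, "two_state", reference)
for cohort in ("case", "control"):
    subset = [c for c, l in zip(cycles, labels) if l == cohort]
    ids, census = max_distance_subset(subset, ref_cycle)
    print(f"{cohort}: {len(ids)}/{len(subset)} subjects "
          f"({len(ids) / len(subset):.0%}) at maximal distance 6 from the "
          f"reference; {len(census)} distinct cycles among them")

rrps = greedy_decompose(build_study_graph(cycles, loci))
vectors = distance_vectors(cycles, rrps)
table = delta_differences(vectors)
means = cohort_mean_deltas(table, labels)
selected = select_discriminating_pairs(means, min_abs=0.5, top_k=5)
print(f"\n{len(table.pairs)} distance-difference pairs; top discriminating "
      f"pairs (|case mean - control mean|/sqrt(2) off the diagonal):")
print(selected[["pair", "case_mean", "control_mean",
                "diag_distance"]].to_string(index=False))

result = classify_cohort(vectors, labels, folds=10, seed=0)
print(f"\n10-fold decision tree: accuracy {result.accuracy:.3f}, "
      f"ROC area {result.roc_auc:.3f}")
print("confusion matrix (rows true case/control):")
print(result.confusion)
print(
    "\nThe planted absence fraction (77% of cases vs the chance rate in "
    "controls) is what the distance features pick up; with a shared pool "
    "and no absence constraint the same pipeline returns chance-level "
    "accuracy."
)
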