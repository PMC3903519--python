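"""Edge-mismatch distances, delta tables, and cohort discrimination."""

import itertools

import numpy as np
import pytest

from netphen import (
    DeltaTable,
    PersonalCycle,
    build_personal_cycle,
    build_study_graph,
    classify_cohort,
    cohort_mean_deltas,
    cycle_distance,
    delta_differences,
    delta_histogram,
    distance_vectors,
    greedy_decompose,
    haplotype_to_cycle,
    max_distance_subset,
    select_discriminating_pairs,
)
from netphen.distance import DistanceVector
from netphen.simulate import SimulationConfig, simulate_cohorts

from conftest import record_from_haplotypes


def two_state_cycles():
    return [
        PersonalCycle(None, "two_state", states)
        for states in itertools.product("ab", repeat=6)
    ]


class TestCycleDistance:
    def test_identity_is_zero(self, loci):
        c = haplotype_to_cycle("AGTTGG", loci)
        assert cycle_distance(c, c) == 0

    def test_vertex_disjoint_cycles_at_maximum(self, loci):
        """AACCAT vs GGTTGG share no vertex: all 6 edge slots mismatch."""
        assert cycle_distance(
            haplotype_to_cycle("AACCAT", loci),
            haplotype_to_cycle("GGTTGG", loci),
        ) == 6

    def test_single_locus_change_costs_two_edges(self, loci):
        """AACCAT vs AGCCAT differ only at CT60: both incident edges flip."""
        assert cycle_distance(
            haplotype_to_cycle("AACCAT", loci),
            haplotype_to_cycle("AGCCAT", loci),
        ) == 2

    def test_signed_option_negates(self, loci):
        a = haplotype_to_cycle("AACCAT", loci)
        b = haplotype_to_cycle("GGTTGG", loci)
        assert cycle_distance(a, b, signed=True) == -6

    def test_metric_axioms_exhaustive(self):
        """Nonnegativity, identity, symmetry and triangle inequality over
        all 64 x 64 two-state cycle pairs."""
        cycles = two_state_cycles()
        d = np.array(
            [[cycle_distance(p, q) for q in cycles] for p in cycles]
        )
        assert d.min() >= 0 and d.max() <= 6
        assert (np.diag(d) == 0).all()
        assert ((d > 0) == ~np.eye(64, dtype=bool)).all()  # zero iff equal
        assert (d == d.T).all()
        # triangle inequality: d[i,k] <= d[i,j] + d[j,k] for all i, j, k
        assert (d[:, None, :] <= d[:, :, None] + d[None, :, :]).all()

    def test_distance_counts_unshared_edge_slots(self):
        cycles = two_state_cycles()
        rng = np.random.default_rng(1)
        for _ in range(50):
            p, q = (cycles[i] for i in rng.integers(0, 64, 2))
            shared = sum(e1 == e2 for e1, e2 in zip(p.edges, q.edges))
            assert cycle_distance(p, q) == 6 - shared

    def test_coding_mismatch_rejected(self):
        p = PersonalCycle(None, "two_state", ("a",) * 6)
        q = PersonalCycle(None, "three_state", ("ab",) * 6)
        with pytest.raises(ValueError, match="coding"):
            cycle_distance(p, q)


@pytest.fixture(scope="module")
def cohort(loci):
    records = simulate_cohorts(
        SimulationConfig(loci=loci, n_case=120, n_control=120, seed=13)
    )
    cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
    rrps = greedy_decompose(build_study_graph(cycles, loci))
    return records, cycles, rrps


class TestDistanceVectorsAndDeltas:
    def test_vector_length_equals_reference_count(self, cohort, loci):
        records, cycles, rrps = cohort
        vectors = distance_vectors(cycles, rrps)
        assert all(len(v.distances) == len(rrps) for v in vectors)
        # subject identical to a reference scores 0 in that column
        ref0 = rrps[0].cycle.states
        for v, c in zip(vectors, cycles):
            if c.states == ref0:
                assert v.distances[0] == 0

    @pytest.mark.parametrize("K,columns", [(8, 28), (20, 190)])
    def test_delta_column_counts(self, K, columns):
        vectors = [
            DistanceVector(f"S{i}", tuple(int(x) for x in
                                          np.random.default_rng(i).integers(0, 7, K)))
            for i in range(5)
        ]
        table = delta_differences(vectors)
        assert len(table.pairs) == columns
        assert table.values.shape == (5, columns)

    def test_antisymmetry_and_range(self, cohort):
        _, cycles, rrps = cohort
        table = delta_differences(distance_vectors(cycles, rrps))
        K = len(rrps)
        assert np.abs(table.values).max() <= 6
        d = np.array([v.distances for v in distance_vectors(cycles, rrps)])
        for i, j in [(1, 2), (1, K), (2, K)]:
            col = table.column((i, j))
            assert (col == d[:, i - 1] - d[:, j - 1]).all()
            # swapping the pair roles flips the sign
            assert (col == -(d[:, j - 1] - d[:, i - 1])).all()

    def test_equidistant_subject_has_zero_delta(self, loci):
        refs = greedy_decompose(
            build_study_graph(
                [haplotype_to_cycle("AACCAT", loci)] * 2
                + [haplotype_to_cycle("GGTTGG", loci)] * 1,
                loci,
            )
        )
        subject = haplotype_to_cycle("AGTTGG", loci)
        (v,) = distance_vectors([subject], refs)
        table = delta_differences([v])
        if v.distances[0] == v.distances[1]:
            assert table.values[0, 0] == 0


class TestCohortMeans:
    def make_table(self, case_vals, control_vals):
        values = np.array(case_vals + control_vals)[:, None]
        ids = [f"S{i}" for i in range(len(values))]
        labels = ["case"] * len(case_vals) + ["control"] * len(control_vals)
        return DeltaTable(ids, [(1, 2)], values), labels

    def test_identical_distributions_on_diagonal(self):
        table, labels = self.make_table([1, -1, 2, 0], [1, -1, 2, 0])
        means = cohort_mean_deltas(table, labels)
        assert means.loc[0, "case_mean"] == means.loc[0, "control_mean"]

    def test_opposite_shifts_maximally_off_diagonal(self):
        table, labels = self.make_table([2, 2], [-2, -2])
        means = cohort_mean_deltas(table, labels)
        assert (means.loc[0, "case_mean"], means.loc[0, "control_mean"]) == (
            2.0, -2.0,
        )

    def test_single_subject_cohorts(self):
        table, labels = self.make_table([3], [-1])
        means = cohort_mean_deltas(table, labels)
        assert means.loc[0, "case_mean"] == 3.0
        assert means.loc[0, "control_mean"] == -1.0

    def test_band_rule_excludes_small_means(self):
        values = np.array(
            [[0.3, 2.0], [0.3, 2.0], [-0.3, -2.0], [-0.3, -2.0]]
        )
        table = DeltaTable(
            ["a", "b", "c", "d"], [(1, 2), (1, 3)], values
        )
        labels = ["case", "case", "control", "control"]
        means = cohort_mean_deltas(table, labels)
        selected = select_discriminating_pairs(means, min_abs=0.5)
        assert list(selected["pair"]) == ["d1-d3"]  # 0.3 band-excluded

    def test_diagonal_points_yield_empty_selection(self):
        table, labels = self.make_table([1, 1], [1, 1])
        means = cohort_mean_deltas(table, labels)
        assert len(select_discriminating_pairs(means)) == 0


class TestMaxDistanceSubset:
    def test_absence_marker_fraction(self, loci):
        """77% of cases drawn vertex-disjoint from a designated reference:
        the maximal-distance census recovers that fraction."""
        reference = haplotype_to_cycle("GGTTGG", loci).states
        config = SimulationConfig(
            loci=loci, n_case=300, n_control=100, seed=21,
            absence_fraction=0.77, absence_reference=reference,
        )
        records = simulate_cohorts(config)
        cases = [r for r in records if r.cohort == "case"]
        cycles = [build_personal_cycle(r, loci, "two_state") for r in cases]
        ids, census = max_distance_subset(
            cycles, PersonalCycle(None, "two_state", reference)
        )
        fraction = len(ids) / len(cases)
        assert fraction == pytest.approx(0.77, abs=0.05)
        assert sum(c for _, c in census) == len(ids)

    def test_identical_cycle_excluded_disjoint_included(self, loci):
        ref = haplotype_to_cycle("AACCAT", loci)
        same = haplotype_to_cycle("AACCAT", loci)
        disjoint = haplotype_to_cycle("GGTTGG", loci)
        ids, census = max_distance_subset([same, disjoint], ref)
        assert len(ids) == 1
        assert census == [(disjoint.states, 1)]


class TestClassification:
    def test_separable_cohorts_high_accuracy(self, loci):
        """Disjoint cycle pools give near-perfect tree discrimination."""
        case_pool = (("AACCAT", 0.7), ("AGCCAT", 0.3))
        control_pool = (("GGTTGG", 0.6), ("GGCTGG", 0.4))
        config = SimulationConfig(
            loci=loci, pool=control_pool, case_pool_bias=case_pool,
            n_case=150, n_control=150, seed=3,
        )
        records = simulate_cohorts(config)
        cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
        rrps = greedy_decompose(build_study_graph(cycles, loci))
        vectors = distance_vectors(cycles, rrps)
        labels = [r.cohort for r in records]
        result = classify_cohort(vectors, labels, folds=10, seed=0)
        assert result.accuracy >= 0.95
        assert result.roc_auc >= 0.95
        assert result.confusion.sum() == 300

    def test_permuted_labels_at_chance(self, loci):
        records = simulate_cohorts(
            SimulationConfig(loci=loci, n_case=287, n_control=287, seed=8)
        )
        cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
        rrps = greedy_decompose(build_study_graph(cycles, loci))
        vectors = distance_vectors(cycles, rrps)
        rng = np.random.default_rng(4)
        labels = rng.permutation([r.cohort for r in records])
        result = classify_cohort(vectors, labels, folds=10, seed=0)
        assert result.accuracy == pytest.approx(0.5, abs=0.07)

    def test_constant_vectors_predict_majority(self):
        vectors = [DistanceVector(f"S{i}", (3, 3, 3)) for i in range(40)]
        labels = ["case"] * 25 + ["control"] * 15
        result = classify_cohort(vectors, labels, folds=5, seed=0)
        assert result.roc_auc == 0.5
        assert result.confusion[0].sum() == 25
        # every prediction lands in a single column (majority class)
        assert (result.confusion.sum(axis=0) > 0).sum() == 1

    def test_deterministic_given_seed(self, loci):
        records = simulate_cohorts(
            SimulationConfig(loci=loci, n_case=60, n_control=60, seed=6)
        )
        cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
        rrps = greedy_decompose(build_study_graph(cycles, loci))
        vectors = distance_vectors(cycles, rrps)
        labels = [r.cohort for r in records]
        r1 = classify_cohort(vectors, labels, folds=5, seed=11)
        r2 = classify_cohort(vectors, labels, folds=5, seed=11)
        assert (r1.confusion == r2.confusion).all()
        assert r1.roc_auc == r2.roc_auc

    def test_single_class_rejected(self):
        vectors = [DistanceVector("S", (1, 2))] * 4
        with pytest.raises(ValueError, match="both classes"):
            classify_cohort(vectors, ["case"] * 4, folds=2)


class TestDeltaHistogram:
    def test_counts_sum_to_cohort_sizes(self, loci):
        records = simulate_cohorts(
            SimulationConfig(loci=loci, n_case=50, n_control=70, seed=14)
        )
        cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
        rrps = greedy_decompose(build_study_graph(cycles, loci))
        table = delta_differences(distance_vectors(cycles, rrps))
        labels = [r.cohort for r in records]
        hists = delta_histogram(table, (1, 2), (1, 3), labels)
        assert hists["case"].values.sum() == 50
        assert hists["control"].values.sum() == 70

    def test_single_point_mass(self):
        table = DeltaTable(["a", "b"], [(1, 2), (1, 3)],
                           np.zeros((2, 2), dtype=int))
        hists = delta_histogram(table, (1, 2), (1, 3), ["case", "case"])
        assert hists["case"].loc[0, 0] == 2
        assert hists["case"].values.sum() == 2

    def test_absent_cohort_yields_zero_histogram(self):
        table = DeltaTable(["a"], [(1, 2), (1, 3)], np.zeros((1, 2), int))
        hists = delta_histogram(
            table, (1, 2), (1, 3), ["case"], cohorts=["case", "control"]
        )
        assert hists["control"].values.sum() == 0

    def test_unknown_pair_rejected(self):
        table = DeltaTable(["a"], [(1, 2)], np.zeros((1, 1), int))
        with pytest.raises(ValueError, match="pair not present"):
            delta_histogram(table, (1, 2), (3, 4), ["case"])

    def test_three_component_mixture_recovers_modes(self, loci):
        """Three disjoint diplotype pools appear as three histogram modes."""
        pools = [("AACCAT", "AACCAT"), ("GGTTGG", "GGTTGG"),
                 ("AGCTGG", "AGCTGG")]
        records = []
        for p, (h1, h2) in enumerate(pools):
            for i in range(30):
                records.append(
                    record_from_haplotypes(h1, h2, loci, f"P{p}S{i}",
                                           cohort="case")
                )
        cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
        rrps = greedy_decompose(build_study_graph(cycles, loci))
        assert len(rrps) >= 3
        table = delta_differences(distance_vectors(cycles, rrps))
        hists = delta_histogram(table, (1, 2), (1, 3),
                                [r.cohort for r in records])
        occupied = (hists["case"].values > 0).sum()
        assert occupied == 3
        assert sorted(
            hists["case"].values[hists["case"].values > 0]
        ) == [30, 30, 30]
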