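"""Cycle enumeration, greedy decomposition, and haplotype labelling."""

import itertools
from collections import Counter

import numpy as np
import pytest

from netphen import (
    StudyGraph,
    build_dosage_graph,
    build_personal_cycle,
    build_study_graph,
    decomposition_report,
    enumerate_cycles,
    greedy_decompose,
    haplotype_to_cycle,
    max_bottleneck_cycle,
    rrp_to_haplotype,
)
from netphen.decompose import reference_set_from_file
from netphen.simulate import SimulationConfig, simulate_cohorts

from conftest import record_from_haplotypes
from test_graph_core import graph_from_haplotype_pairs


class TestEnumeration:
    @pytest.mark.parametrize(
        "coding,n_loci,expected",
        [("two_state", 6, 64), ("three_state", 6, 729), ("two_state", 3, 8)],
    )
    def test_candidate_counts(self, loci, toy_loci, coding, n_loci, expected):
        panel = loci if n_loci == 6 else toy_loci
        graph = StudyGraph(panel, coding)
        candidates = enumerate_cycles(graph)
        assert len(candidates) == expected
        assert candidates == sorted(candidates)  # lexicographic, a < ab < b


class TestMaxBottleneck:
    def test_single_cycle_graph(self, loci):
        graph, cycles, _ = graph_from_haplotype_pairs(
            [("AGTTGG", "AGTTGG")] * 12, loci
        )
        states, bottleneck = max_bottleneck_cycle(graph)
        assert states == cycles[0].states
        assert bottleneck == 12.0

    def test_wider_disjoint_cycle_wins(self, loci):
        graph, _, _ = graph_from_haplotype_pairs(
            [("AACCAT", "AACCAT")] * 70 + [("GGTTGG", "GGTTGG")] * 30, loci
        )
        states, bottleneck = max_bottleneck_cycle(graph)
        assert states == ("a",) * 6
        assert bottleneck == 70.0

    def test_tie_broken_by_fewer_minor_states(self, loci):
        graph, _, _ = graph_from_haplotype_pairs(
            [("AACCAT", "AACCAT")] * 50 + [("GGTTGG", "GGTTGG")] * 50, loci
        )
        states, bottleneck = max_bottleneck_cycle(graph)
        assert bottleneck == 50.0
        assert states == ("a",) * 6

    def test_all_zero_graph_rejected(self, loci):
        with pytest.raises(ValueError, match="no cycle"):
            max_bottleneck_cycle(StudyGraph(loci, "two_state"))


class TestGreedyDecompose:
    def test_identical_cycles_single_component(self, loci):
        graph, cycles, _ = graph_from_haplotype_pairs(
            [("AGCTGG", "AGCTGG")] * 9, loci
        )
        (rrp,) = greedy_decompose(graph)
        assert rrp.cycle.states == cycles[0].states
        assert rrp.multiplicity == 9.0
        assert rrp.frequency == 1.0

    def test_disjoint_supports_recovered_exactly(self, loci):
        graph, _, _ = graph_from_haplotype_pairs(
            [("AACCAT", "AACCAT")] * 60 + [("GGTTGG", "GGTTGG")] * 40, loci
        )
        rrps = greedy_decompose(graph)
        assert [(r.multiplicity, r.frequency) for r in rrps] == [
            (60.0, 0.6),
            (40.0, 0.4),
        ]
        assert rrps[0].cycle.states == ("a",) * 6

    def test_shared_vertex_does_not_merge_bottlenecks(self, loci):
        """50x all-major + 50x minor-except-AG49: two components of 50.

        AGTTGG's two-state homozygote cycle is (b,a,b,b,b,b) in cycle order
        (CT318 minor, AG49 major, rest minor) — it shares the AG49 vertex
        with the all-major cycle; the all-a cycle is extracted first by
        the fewer-minor-states tie-break.
        """
        graph, cycles, _ = graph_from_haplotype_pairs(
            [("AACCAT", "AACCAT")] * 50 + [("AGTTGG", "AGTTGG")] * 50, loci
        )
        rrps = greedy_decompose(graph)
        assert [r.multiplicity for r in rrps] == [50.0, 50.0]
        assert rrps[0].cycle.states == ("a",) * 6
        assert rrps[1].cycle.states == cycles[-1].states

    def test_unbalanced_graph_rejected(self, loci):
        graph = StudyGraph(loci, "two_state")
        graph._w2[0, 0, 0] = 2  # one dangling edge cannot balance
        with pytest.raises(ValueError, match="balanced"):
            greedy_decompose(graph)

    @pytest.mark.parametrize("coding", ["two_state", "three_state"])
    def test_exact_conservation_on_random_cohorts(self, loci, coding):
        """Every edge weight is reconstructed exactly (tol 0, subject mode)."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(200, 601))
            config = SimulationConfig(
                loci=loci, n_case=n // 2, n_control=n - n // 2,
                seed=int(rng.integers(2**31)),
            )
            records = simulate_cohorts(config)
            cycles = [build_personal_cycle(r, loci, coding) for r in records]
            graph = build_study_graph(cycles, loci)
            rrps = greedy_decompose(graph)
            residual = graph.weights.copy()
            for r in rrps:
                idx = [graph.state_index(s) for s in r.cycle.states]
                for k in range(6):
                    residual[k, idx[k], idx[(k + 1) % 6]] -= r.multiplicity
            assert np.abs(residual).max() == 0.0
            assert sum(r.frequency for r in rrps) == pytest.approx(1.0)
            assert len(rrps) <= 6 * len(graph.states) ** 2

    def test_multiplicities_decrease_with_rank(self, loci):
        records = simulate_cohorts(
            SimulationConfig(loci=loci, n_case=150, n_control=150, seed=23)
        )
        cycles = [build_personal_cycle(r, loci, "two_state") for r in records]
        rrps = greedy_decompose(build_study_graph(cycles, loci))
        mults = [r.multiplicity for r in rrps]
        assert mults == sorted(mults, reverse=True)
        assert [r.rank for r in rrps] == list(range(1, len(rrps) + 1))

    def test_oracle_exhaustive_extraction_order(self, loci):
        """On edge-disjoint supports, greedy matches the minimal-component
        decomposition found by brute force over extraction orders."""
        pools = [("AACCAT", 37), ("GGTTGG", 21), ("GGCTGG", 11)]
        pairs = [(h, h) for h, n in pools for _ in range(n)]
        graph, _, _ = graph_from_haplotype_pairs(pairs, loci)
        # brute-force: all extraction orders of the candidate cycles whose
        # edges are fully contained in the graph, minimizing component count
        cycles = {
            h: haplotype_to_cycle(h, loci).states for h, _ in pools
        }
        best = None
        for order in itertools.permutations(cycles):
            w = graph.weights.copy()
            parts = []
            for h in order:
                idx = [graph.state_index(s) for s in cycles[h]]
                slots = [(k, idx[k], idx[(k + 1) % 6]) for k in range(6)]
                b = min(w[s] for s in slots)
                if b > 0:
                    for s in slots:
                        w[s] -= b
                    parts.append((cycles[h], b))
            if np.abs(w).max() == 0 and (best is None or len(parts) < len(best)):
                best = parts
        greedy = {
            (r.cycle.states, r.multiplicity) for r in greedy_decompose(graph)
        }
        assert greedy == {(states, float(b)) for states, b in best}

    def test_homozygous_cohort_frequencies_match_empirical(self, loci):
        """Homozygous diplotypes: greedy frequencies = haplotype census."""
        rng = np.random.default_rng(5)
        pool = ["AACCAT", "GGCTGG", "AGTTGG", "AGCTGG", "AGCCAT"]
        draws = rng.choice(len(pool), size=300, p=[.47, .29, .13, .08, .03])
        pairs = [(pool[i], pool[i]) for i in draws]
        graph, _, records = graph_from_haplotype_pairs(pairs, loci)
        census = Counter(h for h, _ in pairs)
        rrps = greedy_decompose(graph)
        assert {
            rrp_to_haplotype(r, loci): r.frequency for r in rrps
        } == {h: c / 300 for h, c in census.items()}


class TestHaplotypeLabels:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (("a",) * 6, "AACCAT"),
            (("b",) * 6, "GGTTGG"),
            (("b", "a", "a", "a", "a", "a"), "AATCAT"),  # minor CT318 only
        ],
    )
    def test_state_to_allele_strings(self, loci, states, expected):
        from netphen import PersonalCycle

        cycle = PersonalCycle(None, "two_state", states)
        assert rrp_to_haplotype(cycle, loci) == expected
        assert haplotype_to_cycle(expected, loci).states == states

    def test_three_state_has_no_haplotype_string(self, loci):
        from netphen import PersonalCycle

        cycle = PersonalCycle(None, "three_state", ("ab",) * 6)
        with pytest.raises(ValueError, match="haplotype"):
            rrp_to_haplotype(cycle, loci)

    def test_reference_set_from_file(self, loci, tmp_path):
        path = tmp_path / "refs.json"
        path.write_text('["AACCAT", "a,b,b,b,b,b"]')
        refs = reference_set_from_file(path, loci)
        assert len(refs) == 2
        assert refs[0].cycle.states == ("a",) * 6
        assert refs[1].cycle.states == ("a", "b", "b", "b", "b", "b")
        assert all(r.multiplicity == 0.0 for r in refs)

    def test_report_contains_ranks_and_frequencies(self, loci):
        graph, _, _ = graph_from_haplotype_pairs(
            [("AACCAT", "AACCAT")] * 3 + [("GGTTGG", "GGTTGG")] * 2, loci
        )
        report = decomposition_report(greedy_decompose(graph), loci)
        assert list(report["rank"]) == [1, 2]
        assert list(report["haplotype"]) == ["AACCAT", "GGTTGG"]
        assert report["frequency"].sum() == pytest.approx(1.0)


class TestDosageDecomposition:
    def test_homozygous_dosage_equals_subject_times_two(self, loci):
        pairs = [("AACCAT", "AACCAT")] * 30 + [("GGCTGG", "GGCTGG")] * 20
        subject, _, records = graph_from_haplotype_pairs(pairs, loci)
        dosage = build_dosage_graph(records, loci)
        sub_rrps = greedy_decompose(subject)
        dos_rrps = greedy_decompose(dosage)
        assert {
            (r.cycle.states, r.multiplicity) for r in dos_rrps
        } == {(r.cycle.states, 2 * r.multiplicity) for r in sub_rrps}
        assert [r.frequency for r in dos_rrps] == [
            r.frequency for r in sub_rrps
        ]

    def test_dosage_conservation_within_tolerance(self, loci):
        records = simulate_cohorts(
            SimulationConfig(loci=loci, n_case=100, n_control=100, seed=31)
        )
        graph = build_dosage_graph(records, loci)
        rrps = greedy_decompose(graph)
        residual = graph.weights.copy()
        for r in rrps:
            idx = [graph.state_index(s) for s in r.cycle.states]
            for k in range(6):
                residual[k, idx[k], idx[(k + 1) % 6]] -= r.multiplicity
        assert np.abs(residual).max() <= 1e-6
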