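"""Personal genotype cycles and cumulative weighted k-partite study graphs.

Each subject's multilocus genotype is encoded as a closed path (a cycle)
visiting exactly one allele-state vertex per locus, in a fixed cyclic locus
order. Summing all subjects' cycles edge-by-edge yields the study graph: a
k-partite graph whose edge weights count co-occurrences of allele states at
adjacent loci. Because every cycle visits one vertex per partition, the full
graph is represented losslessly as one dense weight matrix per adjacent
locus pair; a generic graph container is never needed.

Weights are stored internally as doubled integers so that both the
subject-level construction (+1 per subject per edge) and the chromosome-
dosage construction (allele-dose products, halves) are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype import (
    THREE_STATES,
    TWO_STATES,
    GenotypeRecord,
    dominant_state,
    zygosity_state,
)
from .loci import LocusSpec, cycle_order, validate_loci

__all__ = [
    "PersonalCycle",
    "StudyGraph",
    "states_for_coding",
    "build_personal_cycle",
    "build_study_graph",
    "build_dosage_graph",
    "edge_conditional_probabilities",
]

CODINGS = ("two_state", "three_state")


def states_for_coding(coding: str) -> tuple[str, ...]:
    """The vertex states per partition, in canonical order a < ab < b."""
    if coding == "two_state":
        return TWO_STATES
    if coding == "three_state":
        return THREE_STATES
    raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")


@dataclass(frozen=True)
class PersonalCycle:
    """A subject's genotype as a closed path, one state vertex per locus.

    ``states`` is indexed by cycle position; edge ``k`` joins
    ``(locus k, states[k])`` to ``(locus k+1 mod L, states[k+1 mod L])``.
    """

    sample_id: str | None
    coding: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        allowed = states_for_coding(self.coding)
        bad = [s for s in self.states if s not in allowed]
        if bad:
            raise ValueError(f"states {bad} invalid for coding {self.coding!r}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def edges(self) -> tuple[tuple[tuple[int, str], tuple[int, str]], ...]:
        L = len(self.states)
        return tuple(
            ((k, self.states[k]), ((k + 1) % L, self.states[(k + 1) % L]))
            for k in range(L)
        )


class StudyGraph:
    """Cumulative weighted k-partite graph over a locus panel.

    One ``S x S`` nonnegative weight matrix per adjacent locus pair ``(k,
    k+1 mod L)`` in cycle order. ``weight_unit`` is the total weight each
    subject adds per pair: 1 in subject mode, 2 (chromosome equivalents)
    in dosage mode.
    """

    def __init__(
        self,
        loci: Sequence[LocusSpec],
        coding: str,
        n_subjects: int = 0,
        weight_unit: int = 1,
        _w2: np.ndarray | None = None,
    ) -> None:
        self.loci = cycle_order(validate_loci(loci))
        self.coding = coding
        self.states = states_for_coding(coding)
        self.n_subjects = n_subjects
        self.weight_unit = weight_unit
        L, S = len(self.loci), len(self.states)
        if _w2 is None:
            _w2 = np.zeros((L, S, S), dtype=np.int64)
        if _w2.shape != (L, S, S):
            raise ValueError(f"weight array shape {_w2.shape} != {(L, S, S)}")
        self._w2 = _w2  # doubled weights, exact integers

    # -- basic accessors ----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def weights(self) -> np.ndarray:
        """Weight matrices, shape (L, S, S); halves exact in dosage mode."""
        return self._w2 / 2.0

    @property
    def total_weight(self) -> float:
        """Total weight absorbed: n_subjects * weight_unit (per pair)."""
        return self.n_subjects * self.weight_unit

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def cycle_weights(self, states: Sequence[str]) -> np.ndarray:
        """The L edge weights along a candidate cycle."""
        idx = np.array([self.state_index(s) for s in states])
        L = self.n_loci
        return self._w2[np.arange(L), idx, np.roll(idx, -1)] / 2.0

    # -- construction -------------------------------------------------------

    def _check_cycle(self, cycle: PersonalCycle) -> np.ndarray:
        if cycle.coding != self.coding:
            raise ValueError(
                f"cycle coding {cycle.coding!r} != graph coding {self.coding!r}"
            )
        if len(cycle) != self.n_loci:
            raise ValueError(
                f"cycle length {len(cycle)} != panel size {self.n_loci}"
            )
        return np.array([self.state_index(s) for s in cycle.states])

    def add_cycle(self, cycle: PersonalCycle) -> None:
        """Subject-level absorption: +1 to each of the cycle's L edges."""
        idx = self._check_cycle(cycle)
        L = self.n_loci
        self._w2[np.arange(L), idx, np.roll(idx, -1)] += 2
        self.n_subjects += 1

    # -- invariants ---------------------------------------------------------

    def check_invariants(self) -> None:
        """Nonnegativity, per-pair conservation and vertex balance."""
        if (self._w2 < 0).any():
            raise AssertionError("negative edge weight")
        expected = 2 * self.n_subjects * self.weight_unit
        sums = self._w2.sum(axis=(1, 2))
        if not (sums == expected).all():
            raise AssertionError(
                f"per-pair conservation violated: sums {sums.tolist()} != "
                f"{expected}"
            )
        if not self.is_balanced():
            raise AssertionError("vertex balance violated")

    def is_balanced(self) -> bool:
        """Incoming weight equals outgoing weight at every vertex."""
        outgoing = self._w2.sum(axis=2)  # (L, S): out of (locus k, state s)
        # pair k feeds locus k+1, so row k of the column-sums describes the
        # incoming slot of locus k+1; roll forward to align with locus index
        incoming = np.roll(self._w2.sum(axis=1), shift=1, axis=0)
        return bool((outgoing == incoming).all())

    # -- arithmetic ---------------------------------------------------------

    def copy(self) -> "StudyGraph":
        return StudyGraph(
            self.loci, self.coding, self.n_subjects, self.weight_unit,
            self._w2.copy(),
        )

    def __add__(self, other: "StudyGraph") -> "StudyGraph":
        if (self.coding, self.loci, self.weight_unit) != (
            other.coding, other.loci, other.weight_unit
        ):
            raise ValueError("graphs are not compatible for addition")
        return StudyGraph(
            self.loci, self.coding,
            self.n_subjects + other.n_subjects,
            self.weight_unit,
            self._w2 + other._w2,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyGraph):
            return NotImplemented
        return (
            self.coding == other.coding
            and self.loci == other.loci
            and self.n_subjects == other.n_subjects
            and self.weight_unit == other.weight_unit
            and (self._w2 == other._w2).all()
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coding": self.coding,
            "n_subjects": self.n_subjects,
            "weight_unit": self.weight_unit,
            "loci": [
                {
                    "name": l.name,
                    "rsid": l.rsid,
                    "major": l.major_allele,
                    "minor": l.minor_allele,
                    "cycle_position": l.cycle_position,
                    "report_position": l.report_position,
                }
                for l in self.loci
            ],
            "doubled_weights": self._w2.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StudyGraph":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        loci = [
            LocusSpec(
                name=e["name"], rsid=e["rsid"],
                major_allele=e["major"], minor_allele=e["minor"],
                cycle_position=e["cycle_position"],
                report_position=e["report_position"],
            )
            for e in payload["loci"]
        ]
        return cls(
            loci,
            payload["coding"],
            payload["n_subjects"],
            payload["weight_unit"],
            np.asarray(payload["doubled_weights"], dtype=np.int64),
        )


# ---------------------------------------------------------------------------
# builders


def build_personal_cycle(
    record: GenotypeRecord,
    loci: Sequence[LocusSpec],
    coding: str = "two_state",
) -> PersonalCycle:
    """Encode one subject's genotype as a closed cycle over the panel."""
    ordered = cycle_order(validate_loci(loci))
    record.validate(ordered)
    code = dominant_state if coding == "two_state" else zygosity_state
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    return PersonalCycle(
        sample_id=record.sample_id,
        coding=coding,
        states=tuple(code(record, l) for l in ordered),
    )


def build_study_graph(
    cycles: Sequence[PersonalCycle],
    loci: Sequence[LocusSpec],
) -> StudyGraph:
    """Sum subject cycles into the cumulative study graph (+1 per edge)."""
    cycles = list(cycles)
    if not cycles:
        raise ValueError("cannot build a study graph from an empty cohort")
    codings = {c.coding for c in cycles}
    if len(codings) > 1:
        raise ValueError(f"mixed codings in cycle list: {sorted(codings)}")
    graph = StudyGraph(loci, cycles[0].coding)
    for cycle in cycles:
        graph.add_cycle(cycle)
    graph.check_invariants()
    return graph


def build_dosage_graph(
    records: Sequence[GenotypeRecord],
    loci: Sequence[LocusSpec],
) -> StudyGraph:
    """Chromosome-dosage study graph (two-state, 2 units per subject).

    At each locus a subject carries allele doses ``d_a + d_b = 2``; for an
    adjacent pair the subject adds ``d_x * d_y / 2`` to edge ``(x, y)``, so
    its per-pair total is exactly 2 chromosome equivalents. On a cohort of
    fully homozygous subjects this is exactly twice the subject-level graph.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a dosage graph from an empty cohort")
    ordered = cycle_order(validate_loci(loci))
    graph = StudyGraph(ordered, "two_state", weight_unit=2)
    L = graph.n_loci
    for record in records:
        record.validate(ordered)
        # dose vector per locus: (d_a, d_b) with d_a + d_b = 2
        doses = np.empty((L, 2), dtype=np.int64)
        for k, locus in enumerate(ordered):
            n_minor = sum(
                allele == locus.minor_allele
                for allele in record.genotypes[locus.name]
            )
            doses[k] = (2 - n_minor, n_minor)
        for k in range(L):
            # doubled weight d_x * d_y (true weight d_x*d_y/2)
            graph._w2[k] += np.outer(doses[k], doses[(k + 1) % L])
        graph.n_subjects += 1
    graph.check_invariants()
    return graph


def edge_conditional_probabilities(
    graph: StudyGraph,
    pair: int,
) -> tuple[pd.Series, pd.DataFrame]:
    """Marginal and conditional state probabilities for one adjacent pair.

    Returns ``(marginal, conditional)`` where ``marginal[x]`` estimates
    P(state x at locus ``pair``) and ``conditional.loc[x, y]`` estimates
    P(state y at locus ``pair+1`` | state x at locus ``pair``). Rows with
    zero marginal are left as zeros.
    """
    L = graph.n_loci
    if not 0 <= pair < L:
        raise ValueError(f"pair index {pair} out of range 0..{L - 1}")
    w = graph._w2[pair].astype(float)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"adjacent pair {pair} has zero total weight")
    row_sums = w.sum(axis=1)
    marginal = pd.Series(row_sums / total, index=list(graph.states))
    cond = np.divide(
        w, row_sums[:, None], out=np.zeros_like(w), where=row_sums[:, None] > 0
    )
    conditional = pd.DataFrame(
        cond, index=list(graph.states), columns=list(graph.states)
    )
    return marginal, conditional
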