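"""Greedy decomposition of a study graph into equal-weight reference cycles.

A reference relationship profile (RRP) is a component cycle of the study
graph whose L edges all carry the same weight after extraction; that common
weight is its multiplicity. The decomposition removes reference cycles in
order of decreasing multiplicity: at each step the cycle with the largest
removable multiplicity is extracted — "widest cycle first". A cycle's
removable multiplicity is capped by its bottleneck (minimum edge weight
along it), but subtracting a full bottleneck can strand weight: the
residual stays vertex-balanced yet admits no one-vertex-per-partition
cycle. The extraction therefore also requires the residual to remain
decomposable, verified with a small integer feasibility program over the
candidate cycles; in the common case the widest cycle passes at its full
bottleneck on the first try and the check costs one solve.

The candidate scan is brute force over the at most S^L cycles (S states
per locus; 64 two-state / 729 three-state candidates at L = 6); at panel
scale nothing cleverer is warranted. Subject-mode graphs carry integer
weights and decompose exactly; dosage-mode graphs carry exact half-integer
weights and fall back to a continuous linear program when no half-integer
extraction exists, leaving at most a ``tol`` residual.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .graph import PersonalCycle, StudyGraph, states_for_coding
from .loci import LocusSpec, report_order

__all__ = [
    "ReferenceProfile",
    "enumerate_cycles",
    "max_bottleneck_cycle",
    "greedy_decompose",
    "rrp_to_haplotype",
    "haplotype_to_cycle",
    "reference_set_from_file",
    "decomposition_report",
]


@dataclass(frozen=True)
class ReferenceProfile:
    """One equal-weight component cycle of a study graph.

    ``multiplicity`` is the common edge weight removed; ``frequency`` is the
    multiplicity as a fraction of the total weight absorbed per pair.
    Reference cycles injected from outside a decomposition (to reuse a
    combined-cohort reference set on a sub-cohort) carry multiplicity 0.
    """

    cycle: PersonalCycle
    multiplicity: float
    rank: int
    frequency: float

    def __post_init__(self) -> None:
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be nonnegative")


def enumerate_cycles(graph: StudyGraph) -> list[tuple[str, ...]]:
    """All S^L candidate state sequences, in lexicographic order a < ab < b."""
    return list(itertools.product(graph.states, repeat=graph.n_loci))


def _tie_key(states: Sequence[str]) -> tuple:
    # fewer non-major states first, then lexicographic (a < ab < b)
    return (sum(s != "a" for s in states), tuple(states))


def max_bottleneck_cycle(
    graph: StudyGraph,
) -> tuple[tuple[str, ...], float]:
    """The cycle maximizing the minimum edge weight along it.

    Only cycles whose edges are all strictly positive qualify. Ties are
    broken by fewer non-major states, then lexicographic state order.
    """
    w2 = graph._w2
    L, S = graph.n_loci, len(graph.states)
    best: tuple[int, tuple] | None = None
    best_states: tuple[str, ...] | None = None
    for idx in itertools.product(range(S), repeat=L):
        b2 = min(w2[k, idx[k], idx[(k + 1) % L]] for k in range(L))
        if b2 <= 0:
            continue
        states = tuple(graph.states[i] for i in idx)
        key = (-b2, _tie_key(states))
        if best is None or key < best:
            best = key
            best_states = states
    if best_states is None:
        raise ValueError("graph has no cycle with all-positive edge weights")
    return best_states, -best[0] / 2.0


@lru_cache(maxsize=8)
def _candidate_tables(S: int, L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static per-geometry tables: candidate edge ids, incidence matrix, tie keys.

    Edge id of slot k with states (x, y) is ``k*S*S + x*S + y``; candidates
    are the S^L state-index sequences in lexicographic order.
    """
    idx = np.array(list(itertools.product(range(S), repeat=L)), dtype=np.int64)
    nxt = np.roll(idx, -1, axis=1)
    edge_ids = (np.arange(L)[None, :] * S * S + idx * S + nxt)  # (C, L)
    C = idx.shape[0]
    A = np.zeros((L * S * S, C))
    for c in range(C):
        A[edge_ids[c], c] = 1.0
    # tie key: fewer non-major states first, then lexicographic (row order)
    n_minor = (idx != 0).sum(axis=1)
    return edge_ids, A, n_minor


def _max_component(
    A: np.ndarray,
    w: np.ndarray,
    c: int,
    upper: np.ndarray,
    integer: bool,
) -> float | None:
    """Largest multiplicity of candidate ``c`` over exact decompositions of w.

    Solves max x_c subject to A x = w, 0 <= x <= upper (x integer when
    ``integer``). Returns None when w has no decomposition at all.
    """
    n = A.shape[1]
    cost = np.zeros(n)
    cost[c] = -1.0
    if integer:
        res = milp(
            c=cost,
            constraints=LinearConstraint(A, w, w),
            integrality=np.ones(n),
            bounds=Bounds(0, upper),
        )
    else:
        res = linprog(
            c=cost, A_eq=A, b_eq=w, bounds=np.stack([np.zeros(n), upper], axis=1),
            method="highs",
        )
    if not res.success:
        return None
    return float(res.x[c])


def greedy_decompose(
    graph: StudyGraph,
    tol: float | None = None,
    *,
    check_balance: bool = True,
) -> list[ReferenceProfile]:
    """Decompose a study graph into reference cycles with multiplicities.

    Iteratively extracts the cycle with the largest removable multiplicity
    (widest cycle first, ties to fewer minor/heterozygous states then
    lexicographic state order) until every edge weight is <= ``tol``.
    Subject-mode graphs (integer weights) decompose exactly with the
    default ``tol = 0``; dosage-mode graphs default to
    ``tol = 1e-9 * total weight`` to absorb the continuous-solver residual
    in the rare case no half-integer extraction exists. Vertex balance is
    checked after every subtraction when ``check_balance`` is set; an
    unbalanced graph cannot be a sum of cycles.

    Returns profiles sorted by decreasing multiplicity, ranked from 1.
    """
    if check_balance and not graph.is_balanced():
        raise ValueError(
            "study graph is not vertex-balanced; cycle decomposition is "
            "not guaranteed to terminate cleanly"
        )
    L, S = graph.n_loci, len(graph.states)
    if tol is None:
        tol = 0.0 if graph.weight_unit == 1 else 1e-9 * max(
            graph.total_weight, 1.0
        )
    tol2 = 2.0 * tol
    edge_ids, A, n_minor = _candidate_tables(S, L)
    C = edge_ids.shape[0]
    order_key = np.lexsort((np.arange(C), n_minor))  # tie order within a width

    w = graph._w2.reshape(-1).astype(np.int64).copy()
    integer = True
    components: list[tuple[int, float]] = []  # (candidate index, doubled mult)

    for _ in range(C):
        if w.max() <= tol2:
            break
        bottlenecks = (
            w[edge_ids] if integer else w_float[edge_ids]
        ).min(axis=1)
        if integer:
            ww: np.ndarray = w.astype(float)
        else:
            ww = w_float
        upper = np.maximum(bottlenecks, 0.0).astype(float)

        # scan candidates in decreasing-bottleneck then tie-key order,
        # stopping once no remaining candidate can beat the best found
        scan = sorted(
            (c for c in order_key if bottlenecks[c] > (tol2 if not integer else 0)),
            key=lambda c: (-bottlenecks[c], n_minor[c], c),
        )
        best_c, best_t = -1, 0.0
        infeasible = False
        for c in scan:
            if bottlenecks[c] <= best_t:
                break
            t = _max_component(A, ww, c, upper, integer)
            if t is None:
                infeasible = True
                break
            if integer:
                t = float(round(t))
            if t > best_t:
                best_c, best_t = c, t
                if best_t >= bottlenecks[c]:  # cannot be beaten
                    break

        min_gain = 1.0 if integer else tol2
        if infeasible or best_t < min_gain:
            if integer and graph.weight_unit != 1:
                # dosage weights may admit only a fractional decomposition:
                # continue with the continuous relaxation
                integer = False
                w_float = w.astype(float)
                continue
            raise ValueError(
                "study graph is not decomposable into one-vertex-per-"
                "partition cycles (weight is stranded); the graph is not a "
                "nonnegative combination of personal cycles"
            )

        if integer:
            w[edge_ids[best_c]] -= int(best_t)
            if check_balance and (w < 0).any():
                raise AssertionError("negative residual during decomposition")
        else:
            w_float[edge_ids[best_c]] -= best_t
            w_float[edge_ids[best_c]] = np.maximum(
                w_float[edge_ids[best_c]], 0.0
            )
        components.append((best_c, best_t))
    else:
        residual = (w if integer else w_float).max()
        if residual > tol2:
            raise AssertionError(
                "decomposition failed to terminate within the candidate budget"
            )

    if check_balance:
        res = (w if integer else w_float).reshape(L, S, S)
        balanced = np.allclose(
            res.sum(axis=2), np.roll(res.sum(axis=1), 1, axis=0), atol=tol2 + 1e-9
        )
        if not balanced:
            raise AssertionError("vertex balance lost during decomposition")

    states_of = list(itertools.product(graph.states, repeat=L))
    total = 2.0 * graph.total_weight
    components.sort(key=lambda item: (-item[1], _tie_key(states_of[item[0]])))
    return [
        ReferenceProfile(
            cycle=PersonalCycle(None, graph.coding, states_of[c]),
            multiplicity=t2 / 2.0,
            rank=rank,
            frequency=t2 / total if total > 0 else 0.0,
        )
        for rank, (c, t2) in enumerate(components, start=1)
    ]


# ---------------------------------------------------------------------------
# haplotype labelling (two-state profiles only)


def rrp_to_haplotype(
    rrp: ReferenceProfile | PersonalCycle,
    loci: Sequence[LocusSpec],
) -> str:
    """Allele string of a two-state reference cycle, in report order.

    Per locus, state ``a`` maps to the major and ``b`` to the minor allele.
    Three-state profiles have no nucleotide reading (``ab`` is not an
    allele) and are rejected.
    """
    cycle = rrp.cycle if isinstance(rrp, ReferenceProfile) else rrp
    if cycle.coding != "two_state":
        raise ValueError(
            "only two-state reference cycles have a haplotype string; "
            "three-state profiles are zygosity patterns, not haplotypes"
        )
    allele_at = {
        l.name: (
            l.major_allele
            if cycle.states[l.cycle_position] == "a"
            else l.minor_allele
        )
        for l in loci
    }
    return "".join(allele_at[l.name] for l in report_order(loci))


def haplotype_to_cycle(
    haplotype: str,
    loci: Sequence[LocusSpec],
    sample_id: str | None = None,
) -> PersonalCycle:
    """Inverse of :func:`rrp_to_haplotype`: report-order allele string to cycle."""
    ordered = report_order(loci)
    if len(haplotype) != len(ordered):
        raise ValueError(
            f"haplotype {haplotype!r} has {len(haplotype)} characters for a "
            f"{len(ordered)}-locus panel"
        )
    state_by_cycle_pos: dict[int, str] = {}
    for allele, locus in zip(haplotype, ordered):
        if allele == locus.major_allele:
            state = "a"
        elif allele == locus.minor_allele:
            state = "b"
        else:
            raise ValueError(
                f"haplotype {haplotype!r}: allele {allele!r} invalid at "
                f"{locus.name!r}"
            )
        state_by_cycle_pos[locus.cycle_position] = state
    states = tuple(state_by_cycle_pos[k] for k in range(len(ordered)))
    return PersonalCycle(sample_id, "two_state", states)


def reference_set_from_file(
    path: str | Path,
    loci: Sequence[LocusSpec],
    coding: str = "two_state",
) -> list[ReferenceProfile]:
    """Load an injected reference set (JSON list of state strings).

    Entries are either cycle-order state sequences (e.g. ``"a,b,b,a,b,b"``
    or ``["a","ab","b",...]``) or, for two-state codings, haplotype strings
    in report order. Injected references carry multiplicity and frequency 0;
    their identity for distance work is the cycle's edge set.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a JSON list of reference cycles")
    allowed = set(states_for_coding(coding))
    profiles: list[ReferenceProfile] = []
    for rank, entry in enumerate(data, start=1):
        if isinstance(entry, str) and "," in entry:
            entry = [s.strip() for s in entry.split(",")]
        if isinstance(entry, str):
            cycle = haplotype_to_cycle(entry, loci)
        else:
            if not set(entry) <= allowed:
                raise ValueError(f"{path}: invalid states {entry!r}")
            cycle = PersonalCycle(None, coding, tuple(entry))
        profiles.append(
            ReferenceProfile(cycle=cycle, multiplicity=0.0, rank=rank,
                             frequency=0.0)
        )
    return profiles


def decomposition_report(
    rrps: Sequence[ReferenceProfile],
    loci: Sequence[LocusSpec],
) -> pd.DataFrame:
    """Tabulate a decomposition: rank, states, haplotype, multiplicity, frequency."""
    rows = []
    for rrp in rrps:
        rows.append(
            {
                "rank": rrp.rank,
                "states": "-".join(rrp.cycle.states),
                "haplotype": (
                    rrp_to_haplotype(rrp, loci)
                    if rrp.cycle.coding == "two_state"
                    else ""
                ),
                "multiplicity": rrp.multiplicity,
                "frequency": rrp.frequency,
            }
        )
    return pd.DataFrame(rows)
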