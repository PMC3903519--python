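"""Synthetic genotype cohorts with the statistical structure the method assumes.

Subjects are diplotypes: two independent haplotype draws from a small pool
with strong linkage disequilibrium, i.e. exactly the Hardy-Weinberg
equilibrium model the EM estimator assumes. The default pool is the five
common CTLA-4 haplotypes with their published cohort frequencies
(renormalized to sum to 1, as no residual haplotype is reported):
AACCAT 46.99%, GGCTGG 29.34%, AGTTGG 9.77%, AGCTGG 6.49%, AGCCAT 2.81%.

Optional features emulate the study's findings: cohort-specific pool
biases, an "absence" constraint forcing a fraction of cases to be
vertex-disjoint from a designated reference cycle, and group-dependent
survival times planted around a threshold through a logistic dependence on
a delta feature. All randomness flows from a single seed through a named
generator; seeded runs are bit-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .decompose import haplotype_to_cycle
from .distance import DeltaTable
from .genotype import GenotypeRecord
from .graph import PersonalCycle
from .loci import LocusSpec, ctla4_loci, report_order, validate_loci

__all__ = [
    "DEFAULT_POOL",
    "default_pool",
    "SurvivalSimConfig",
    "SimulationConfig",
    "sample_diplotypes",
    "diplotypes_to_genotypes",
    "simulate_cohorts",
    "simulate_survival",
]

#: Published five-haplotype CTLA-4 pool (report-order strings, raw percents).
DEFAULT_POOL = (
    ("AACCAT", 46.99),
    ("GGCTGG", 29.34),
    ("AGTTGG", 9.77),
    ("AGCTGG", 6.49),
    ("AGCCAT", 2.81),
)


def default_pool() -> list[tuple[str, float]]:
    """The default haplotype pool with frequencies renormalized to 1."""
    total = sum(w for _, w in DEFAULT_POOL)
    return [(h, w / total) for h, w in DEFAULT_POOL]


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Planted survival structure for the case cohort.

    The short/long group around ``threshold_days`` depends on a designated
    delta feature through a logistic link: score = effect_size * z(delta) +
    noise_scale * logistic noise, and the ``short_fraction`` of subjects
    with the highest scores form the short group. ``effect_size = 0`` (or
    noise_scale -> infinity) is the null generator. Short survival times
    are uniform on (300, threshold], long on (threshold, threshold + 1200].
    """

    threshold_days: float = 1820.0
    short_fraction: float = 145.0 / 282.0
    effect_size: float = 0.0
    noise_scale: float = 1.0
    pair: tuple[int, int] = (1, 2)
    time_scale: float = 300.0  # exponential spread of times off the threshold


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for a synthetic case/control cohort.

    Defaults mirror the study design: 286 cases, 288 controls, shared
    default haplotype pool under HWE.
    """

    loci: tuple[LocusSpec, ...] = field(default_factory=ctla4_loci)
    pool: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: tuple(default_pool())
    )
    n_case: int = 286
    n_control: int = 288
    case_pool_bias: tuple[tuple[str, float], ...] | None = None
    absence_fraction: float | None = None
    absence_reference: tuple[str, ...] | None = None
    survival: SurvivalSimConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        validate_loci(self.loci)
        for pool in (self.pool, self.case_pool_bias):
            if pool is None:
                continue
            total = sum(w for _, w in pool)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"pool frequencies sum to {total}, not 1")
            for h, _ in pool:
                haplotype_to_cycle(h, self.loci)  # validates alleles


def sample_diplotypes(
    pool: Sequence[tuple[str, float]],
    n: int,
    rng: np.random.Generator | int,
) -> list[tuple[str, str]]:
    """Draw n diplotypes as two independent haplotype draws (HWE)."""
    if not pool:
        raise ValueError("haplotype pool is empty")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    haplotypes = [h for h, _ in pool]
    weights = np.array([w for _, w in pool], dtype=float)
    weights = weights / weights.sum()
    draws = rng.choice(len(haplotypes), size=(n, 2), p=weights)
    return [(haplotypes[i], haplotypes[j]) for i, j in draws]


def diplotypes_to_genotypes(
    pairs: Sequence[tuple[str, str]],
    loci: Sequence[LocusSpec],
    ids: Sequence[str],
    cohort: str,
) -> list[GenotypeRecord]:
    """Collapse haplotype pairs to unphased genotype records."""
    ordered = report_order(validate_loci(loci))
    if len(ids) != len(pairs):
        raise ValueError("ids and pairs lengths differ")
    records = []
    for sample_id, (h1, h2) in zip(ids, pairs):
        if len(h1) != len(ordered) or len(h2) != len(ordered):
            raise ValueError(
                f"haplotype length mismatch for panel of {len(ordered)} loci"
            )
        genotypes = {
            locus.name: (a1, a2)
            for locus, a1, a2 in zip(ordered, h1, h2)
        }
        records.append(
            GenotypeRecord(
                sample_id=sample_id, cohort=cohort, genotypes=genotypes
            ).validate(ordered)
        )
    return records


def _diplotype_cycle(
    h1: str, h2: str, loci: Sequence[LocusSpec]
) -> PersonalCycle:
    """Two-state (dominant) cycle of the diplotype (h1, h2)."""
    c1 = haplotype_to_cycle(h1, loci)
    c2 = haplotype_to_cycle(h2, loci)
    states = tuple(
        "a" if (s1, s2) == ("a", "a") else "b"
        for s1, s2 in zip(c1.states, c2.states)
    )
    return PersonalCycle(None, "two_state", states)


def _vertex_disjoint(p: PersonalCycle, r: PersonalCycle) -> bool:
    return all(s != t for s, t in zip(p.states, r.states))


def simulate_cohorts(config: SimulationConfig) -> list[GenotypeRecord]:
    """Generate the full case + control genotype table.

    Controls draw from ``pool``; cases draw from ``case_pool_bias`` if
    given, else from ``pool``. If ``absence_fraction`` is set, that
    fraction of cases is drawn only from diplotypes whose two-state cycle
    shares no vertex with ``absence_reference`` (given as cycle-order
    states); the remaining cases are drawn only from non-qualifying
    diplotypes, so the realized fraction is exact up to rounding.
    """
    rng = np.random.default_rng(config.seed)
    loci = config.loci
    case_pool = list(config.case_pool_bias or config.pool)

    if config.absence_fraction is not None:
        if config.absence_reference is None:
            raise ValueError(
                "absence_fraction requires an absence_reference cycle"
            )
        ref = PersonalCycle(None, "two_state", tuple(config.absence_reference))
        haps = [h for h, _ in case_pool]
        weights = {h: w for h, w in case_pool}
        qualifying = [
            (h1, h2)
            for h1, h2 in itertools.combinations_with_replacement(haps, 2)
            if _vertex_disjoint(_diplotype_cycle(h1, h2, loci), ref)
        ]
        if not qualifying:
            raise ValueError(
                "infeasible absence constraint: no diplotype in the pool is "
                "vertex-disjoint from the reference cycle"
            )
        others = [
            (h1, h2)
            for h1, h2 in itertools.combinations_with_replacement(haps, 2)
            if not _vertex_disjoint(_diplotype_cycle(h1, h2, loci), ref)
        ]
        n_absent = int(round(config.absence_fraction * config.n_case))

        def draw_from(pairs: list[tuple[str, str]], n: int) -> list[tuple[str, str]]:
            # HWE-conditional draw: diplotype probability proportional to
            # f1*f2*(2 - [h1==h2]) restricted to the allowed set
            probs = np.array(
                [
                    weights[h1] * weights[h2] * (1 if h1 == h2 else 2)
                    for h1, h2 in pairs
                ]
            )
            probs = probs / probs.sum()
            idx = rng.choice(len(pairs), size=n, p=probs)
            return [pairs[i] for i in idx]

        case_pairs = draw_from(qualifying, n_absent)
        if config.n_case - n_absent > 0:
            if not others:
                raise ValueError(
                    "absence constraint infeasible: every pool diplotype is "
                    "vertex-disjoint from the reference"
                )
            case_pairs += draw_from(others, config.n_case - n_absent)
        perm = rng.permutation(len(case_pairs))
        case_pairs = [case_pairs[i] for i in perm]
    else:
        case_pairs = sample_diplotypes(case_pool, config.n_case, rng)

    control_pairs = sample_diplotypes(list(config.pool), config.n_control, rng)

    width = len(str(config.n_case + config.n_control))
    cases = diplotypes_to_genotypes(
        case_pairs,
        loci,
        [f"CASE{i + 1:0{width}d}" for i in range(config.n_case)],
        "case",
    )
    controls = diplotypes_to_genotypes(
        control_pairs,
        loci,
        [f"CTRL{i + 1:0{width}d}" for i in range(config.n_control)],
        "control",
    )
    return cases + controls


def simulate_survival(
    records: Sequence[GenotypeRecord],
    survival: SurvivalSimConfig,
    table: DeltaTable,
    rng: np.random.Generator | int,
) -> list[GenotypeRecord]:
    """Attach planted survival times driven by a delta feature.

    ``table`` must cover exactly the subjects in ``records`` (same order).
    Returns new records with ``survival_days`` and ``event=True`` set.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    ids = [r.sample_id for r in records]
    if ids != list(table.sample_ids):
        raise ValueError("records and delta table subjects do not match")
    n = len(records)

    if survival.effect_size != 0.0:
        try:
            delta = table.column(survival.pair).astype(float)
        except ValueError as exc:
            raise ValueError(
                f"designated delta pair {survival.pair} missing from table"
            ) from exc
        sd = delta.std()
        z = (delta - delta.mean()) / sd if sd > 0 else np.zeros(n)
        score = survival.effect_size * z + survival.noise_scale * rng.logistic(size=n)
    else:
        score = rng.logistic(size=n)

    n_short = int(round(survival.short_fraction * n))
    order = np.argsort(-score, kind="stable")
    is_short = np.zeros(n, dtype=bool)
    is_short[order[:n_short]] = True

    # survival times cluster around the change point with exponential
    # spread, so partial splits misassign quickly as the threshold moves
    t = survival.threshold_days
    spread = rng.exponential(survival.time_scale, size=n)
    days = np.where(
        is_short,
        np.maximum(t - spread, 30.0),
        t + 1.0 + spread,
    )
    return [
        replace(r, survival_days=float(d), event=True)
        for r, d in zip(records, days)
    ]
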