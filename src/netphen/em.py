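"""Haplotype frequency estimation by EM under Hardy-Weinberg equilibrium.

Given unphased multilocus genotypes, each subject is compatible with a set
of unordered haplotype pairs (diplotypes); under HWE a diplotype (h1, h2)
has prior probability f(h1)^2 if h1 = h2 and 2 f(h1) f(h2) otherwise. The
EM algorithm alternates posterior phase assignment (E-step) with frequency
updates from expected haplotype counts (M-step), yielding maximum
likelihood frequency estimates. This is the classical validation oracle
for the graph-decomposition haplotype frequencies.

A chi-square Hardy-Weinberg goodness-of-fit check per locus is included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeRecord, zygosity_state
from .loci import LocusSpec, report_order, validate_loci

__all__ = [
    "HaplotypeFrequencyTable",
    "compatible_diplotypes",
    "em_fit",
    "hwe_chisq",
    "frequency_table",
]


@dataclass
class HaplotypeFrequencyTable:
    """EM output: haplotype strings (report order) with ML frequencies."""

    haplotypes: list[str]
    frequencies: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_subjects: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be a probability simplex")
        self.frequencies = f

    def frequency_of(self, haplotype: str) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0


def compatible_diplotypes(
    record: GenotypeRecord,
    loci: Sequence[LocusSpec],
) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with an unphased genotype.

    With h heterozygous loci there are 2^(h-1) pairs (1 if fully
    homozygous): the allele assignment at the first heterozygous locus can
    be fixed to the first haplotype without loss of generality.
    """
    ordered = report_order(validate_loci(loci))
    record.validate(ordered)
    fixed: list[tuple[str, str]] = []  # per locus (allele_h1, allele_h2)
    het_positions: list[int] = []
    for i, locus in enumerate(ordered):
        state = zygosity_state(record, locus)
        if state == "a":
            fixed.append((locus.major_allele, locus.major_allele))
        elif state == "b":
            fixed.append((locus.minor_allele, locus.minor_allele))
        else:
            fixed.append((locus.major_allele, locus.minor_allele))
            het_positions.append(i)

    if not het_positions:
        h = "".join(a for a, _ in fixed)
        return [(h, h)]

    pairs: list[tuple[str, str]] = []
    # first heterozygous locus keeps its orientation: unordered pairs only
    for flips in itertools.product((False, True), repeat=len(het_positions) - 1):
        orient = dict(zip(het_positions[1:], flips))
        orient[het_positions[0]] = False
        h1 = "".join(
            (pair[1] if orient.get(i, False) else pair[0])
            for i, pair in enumerate(fixed)
        )
        h2 = "".join(
            (pair[0] if orient.get(i, False) else pair[1])
            for i, pair in enumerate(fixed)
        )
        pairs.append((h1, h2))
    return pairs


def em_fit(
    records: Sequence[GenotypeRecord],
    loci: Sequence[LocusSpec],
    tol: float = 1e-8,
    max_iter: int = 1000,
    min_frequency: float = 1e-6,
) -> HaplotypeFrequencyTable:
    """Maximum likelihood haplotype frequencies by EM under HWE.

    Initialization is uniform over haplotypes appearing in at least one
    compatible diplotype. Convergence is declared when the largest absolute
    frequency change falls below ``tol``. Haplotypes ending below
    ``min_frequency`` are dropped and the table renormalized. The
    observed-data log likelihood is asserted non-decreasing across
    iterations.
    """
    records = list(records)
    if not records:
        raise ValueError("em_fit needs at least one record")
    per_record = [compatible_diplotypes(r, loci) for r in records]

    haplotypes = sorted({h for pairs in per_record for pair in pairs for h in pair})
    index = {h: i for i, h in enumerate(haplotypes)}
    H = len(haplotypes)
    n = len(records)

    # per record: arrays of (i1, i2, het_flag) over compatible pairs
    pair_idx = [
        (
            np.array([index[h1] for h1, _ in pairs]),
            np.array([index[h2] for _, h2 in pairs]),
            np.array([h1 != h2 for h1, h2 in pairs], dtype=float),
        )
        for pairs in per_record
    ]

    freq = np.full(H, 1.0 / H)
    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        counts = np.zeros(H)
        ll = 0.0
        for i1, i2, het in pair_idx:
            w = (2.0 ** het) * freq[i1] * freq[i2]
            total = w.sum()
            if total <= 0:  # record unexplainable under current support
                total = np.finfo(float).tiny
            ll += np.log(total)
            post = w / total
            np.add.at(counts, i1, post)
            np.add.at(counts, i2, post)
        if ll < prev_ll - 1e-9:
            raise AssertionError(
                f"EM log likelihood decreased: {prev_ll} -> {ll}"
            )
        prev_ll = ll
        new_freq = counts / (2.0 * n)
        delta = np.abs(new_freq - freq).max()
        freq = new_freq
        if delta < tol:
            converged = True
            break

    keep = freq >= min_frequency
    haplotypes = [h for h, k in zip(haplotypes, keep) if k]
    freq = freq[keep]
    freq = freq / freq.sum()
    return HaplotypeFrequencyTable(
        haplotypes=haplotypes,
        frequencies=freq,
        log_likelihood=float(ll),
        n_iterations=iteration,
        converged=converged,
        n_subjects=n,
    )


def frequency_table(fit: HaplotypeFrequencyTable) -> pd.DataFrame:
    """Frequencies with binomial-approximation standard errors sqrt(f(1-f)/2n)."""
    f = fit.frequencies
    se = np.sqrt(f * (1.0 - f) / (2.0 * fit.n_subjects))
    return (
        pd.DataFrame(
            {"haplotype": fit.haplotypes, "frequency": f, "standard_error": se}
        )
        .sort_values("frequency", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def hwe_chisq(
    records: Sequence[GenotypeRecord],
    locus: LocusSpec,
) -> tuple[float, float]:
    """1-df chi-square goodness of fit of genotype counts to HWE.

    Expected counts come from the observed allele frequency. A monomorphic
    locus returns (0, 1) by convention.
    """
    records = list(records)
    if not records:
        raise ValueError("hwe_chisq needs at least one record")
    counts = {"a": 0, "ab": 0, "b": 0}
    for r in records:
        counts[zygosity_state(r, locus)] += 1
    n = len(records)
    p = (2 * counts["a"] + counts["ab"]) / (2.0 * n)  # major allele freq
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts["a"], counts["ab"], counts["b"]], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    # 3 categories - 1 constraint - 1 estimated parameter = 1 df
    p_value = float(stats.chi2.sf(statistic, df=1))
    return statistic, p_value
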