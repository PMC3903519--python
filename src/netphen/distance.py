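"""Graph distances from reference profiles and cohort discrimination.

The distance between two genotype cycles is the number of adjacent-locus
edge slots at which they differ — a Hamming-type metric on cycles, ranging
0..L. Each subject is summarised by the vector of distances to all K
reference profiles; the K(K-1)/2 pairwise distance differences
``delta_ij = d_i - d_j`` add directionality (negative: closer to reference
i; positive: closer to reference j; zero: equidistant) and form the feature
space for case/control and survival discrimination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .decompose import ReferenceProfile
from .graph import PersonalCycle

__all__ = [
    "DistanceVector",
    "DeltaTable",
    "cycle_distance",
    "distance_vectors",
    "delta_differences",
    "cohort_mean_deltas",
    "select_discriminating_pairs",
    "max_distance_subset",
    "classify_cohort",
    "ClassificationResult",
    "delta_histogram",
]


def _cycle_of(ref: ReferenceProfile | PersonalCycle) -> PersonalCycle:
    return ref.cycle if isinstance(ref, ReferenceProfile) else ref


def cycle_distance(
    p: PersonalCycle,
    r: ReferenceProfile | PersonalCycle,
    *,
    signed: bool = False,
) -> int:
    """Edge-mismatch distance between two cycles on the same panel.

    Counts the adjacent-pair slots at which the two cycles' edges differ;
    0 iff the cycles are identical, L iff no edge is shared. ``signed``
    negates the count (a presentation convention that makes identity the
    mathematically largest value).
    """
    rc = _cycle_of(r)
    if p.coding != rc.coding:
        raise ValueError(
            f"coding mismatch: cannot compare {p.coding!r} cycle with "
            f"{rc.coding!r} reference"
        )
    if len(p) != len(rc):
        raise ValueError(f"cycle lengths differ: {len(p)} vs {len(rc)}")
    L = len(p)
    d = sum(
        (p.states[k], p.states[(k + 1) % L])
        != (rc.states[k], rc.states[(k + 1) % L])
        for k in range(L)
    )
    return -d if signed else d


@dataclass(frozen=True)
class DistanceVector:
    """One subject's distances to all reference profiles, by rank."""

    sample_id: str
    distances: tuple[int, ...]


def distance_vectors(
    cycles: Sequence[PersonalCycle],
    rrps: Sequence[ReferenceProfile],
) -> list[DistanceVector]:
    """Distance of every subject cycle to every reference profile."""
    if not rrps:
        raise ValueError("distance_vectors needs at least one reference profile")
    return [
        DistanceVector(
            sample_id=c.sample_id or "",
            distances=tuple(cycle_distance(c, r) for r in rrps),
        )
        for c in cycles
    ]


@dataclass
class DeltaTable:
    """Pairwise distance differences for all subjects.

    ``values[s, c]`` is ``d_i - d_j`` for subject ``s`` and the ``c``-th
    pair ``(i, j)`` with ``i < j`` (1-based reference ranks). Positive
    means the subject is closer to reference j, negative closer to i.
    """

    sample_ids: list[str]
    pairs: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sample_ids), len(self.pairs)):
            raise ValueError(
                f"delta matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} subjects x {len(self.pairs)} pairs"
            )

    def column(self, pair: tuple[int, int]) -> np.ndarray:
        return self.values[:, self.pairs.index(tuple(pair))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"d{i}-d{j}" for i, j in self.pairs],
        )


def delta_differences(vectors: Sequence[DistanceVector]) -> DeltaTable:
    """All K(K-1)/2 pairwise distance differences ``d_i - d_j``, i < j."""
    if not vectors:
        raise ValueError("delta_differences needs at least one subject")
    K = len(vectors[0].distances)
    if K < 2:
        raise ValueError("need at least 2 reference profiles for differences")
    d = np.array([v.distances for v in vectors], dtype=np.int64)
    pairs = [(i + 1, j + 1) for i in range(K) for j in range(i + 1, K)]
    values = np.stack(
        [d[:, i - 1] - d[:, j - 1] for i, j in pairs], axis=1
    )
    return DeltaTable(
        sample_ids=[v.sample_id for v in vectors],
        pairs=pairs,
        values=values,
    )


def cohort_mean_deltas(
    table: DeltaTable,
    labels: Sequence[str],
) -> pd.DataFrame:
    """Per-pair mean delta over cases and over controls (2D plot coordinates).

    With identical delta distributions in both cohorts all points fall on
    the diagonal y = x; discriminating pairs sit far from it.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table.sample_ids):
        raise ValueError("labels length does not match the delta table")
    case = labels == "case"
    control = labels == "control"
    if not case.any() or not control.any():
        raise ValueError("both cohorts must be nonempty")
    return pd.DataFrame(
        {
            "pair": [f"d{i}-d{j}" for i, j in table.pairs],
            "i": [i for i, _ in table.pairs],
            "j": [j for _, j in table.pairs],
            "case_mean": table.values[case].mean(axis=0),
            "control_mean": table.values[control].mean(axis=0),
        }
    )


def select_discriminating_pairs(
    means: pd.DataFrame,
    min_abs: float = 0.5,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank reference pairs by distance from the diagonal of the 2D plot.

    Pairs with both cohort means inside the ``min_abs`` band are discarded
    (subjects are on average equally distant from both references there);
    the rest are ranked by perpendicular distance from y = x,
    ``|case_mean - control_mean| / sqrt(2)``.
    """
    df = means.copy()
    df["diag_distance"] = np.abs(df["case_mean"] - df["control_mean"]) / np.sqrt(2)
    df["selected"] = (
        np.maximum(df["case_mean"].abs(), df["control_mean"].abs()) >= min_abs
    ) & (df["diag_distance"] > 0)
    ranked = (
        df[df["selected"]]
        .sort_values("diag_distance", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return ranked.head(top_k) if top_k is not None else ranked


def max_distance_subset(
    cycles: Sequence[PersonalCycle],
    rrp: ReferenceProfile | PersonalCycle,
) -> tuple[list[str], list[tuple[tuple[str, ...], int]]]:
    """Subjects at the maximal possible distance L from a reference.

    These subjects' cycles share no edge with the reference — the cohort is
    recognised by the ABSENCE of that reference pattern. Returns their
    sample ids and a census of the distinct cycles they carry.
    """
    rc = _cycle_of(rrp)
    L = len(rc)
    hits = [c for c in cycles if cycle_distance(c, rc) == L]
    census = Counter(c.states for c in hits)
    return (
        [c.sample_id or "" for c in hits],
        sorted(census.items(), key=lambda kv: (-kv[1], kv[0])),
    )


@dataclass
class ClassificationResult:
    """Cross-validated decision-tree discrimination summary."""

    confusion: np.ndarray          # rows true, cols predicted (case, control)
    roc_auc: float
    fold_accuracies: np.ndarray
    classes: tuple[str, ...]

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def classify_cohort(
    vectors: Sequence[DistanceVector],
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    ccp_alpha: float = 0.005,
) -> ClassificationResult:
    """Stratified k-fold cross-validated pruned decision tree.

    Features are the raw distance vectors; pruning uses cost-complexity
    with a small fixed alpha. Deterministic given the seed.
    """
    X = np.array([v.distances for v in vectors], dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("classification needs both classes present")
    counts = min(np.sum(y == c) for c in classes)
    if folds > counts:
        raise ValueError(f"folds={folds} exceeds smallest class size {counts}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    score = np.empty(len(y), dtype=float)
    accuracies = []
    positive = classes[0]
    for train, test in skf.split(X, y):
        tree = DecisionTreeClassifier(random_state=seed, ccp_alpha=ccp_alpha)
        tree.fit(X[train], y[train])
        p = tree.predict(X[test])
        pred[test] = p
        col = list(tree.classes_).index(positive)
        score[test] = tree.predict_proba(X[test])[:, col]
        accuracies.append(float(np.mean(p == y[test])))

    confusion = confusion_matrix(y, pred.astype(str), labels=list(classes))
    if len(set(score)) > 1:
        auc = float(roc_auc_score(y == positive, score))
    else:
        auc = 0.5  # degenerate scores carry no ranking information
    return ClassificationResult(
        confusion=confusion,
        roc_auc=auc,
        fold_accuracies=np.array(accuracies),
        classes=classes,
    )


def delta_histogram(
    table: DeltaTable,
    pair_x: tuple[int, int],
    pair_y: tuple[int, int],
    labels: Sequence[str],
    cohorts: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-cohort 2D histogram of two delta features over integer bins.

    Returns, per cohort label, a DataFrame indexed by the x-pair delta with
    the y-pair delta as columns; cell counts sum to the cohort size. An
    explicit ``cohorts`` list may name labels absent from the data, which
    yield all-zero histograms.
    """
    labels = np.asarray(labels)
    try:
        x = table.column(pair_x)
        y = table.column(pair_y)
    except ValueError as exc:
        raise ValueError(
            f"pair not present in delta table: {pair_x} / {pair_y}"
        ) from exc
    L = int(np.abs(table.values).max(initial=0))
    bins = np.arange(-L, L + 1)
    out: dict[str, pd.DataFrame] = {}
    for cohort in (cohorts if cohorts is not None else dict.fromkeys(labels)):
        mask = labels == cohort
        counts = pd.DataFrame(0, index=bins, columns=bins)
        for xv, yv in zip(x[mask], y[mask]):
            counts.loc[xv, yv] += 1
        counts.index.name = f"delta_d{pair_x[0]}-d{pair_x[1]}"
        counts.columns.name = f"delta_d{pair_y[0]}-d{pair_y[1]}"
        out[cohort] = counts
    return out
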