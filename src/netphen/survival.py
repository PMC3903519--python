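"""Survival threshold dichotomization and delta-feature survival models.

The survival analysis dichotomizes overall survival at a threshold,
compares the distributions of every pairwise distance difference between
the short- and long-surviving groups (Welch two-sample t-test by default),
scans a threshold range for the split yielding the most significant
separation, and fits a logistic model predicting the short-survival
category from selected delta features — exposing per-subject odds of
short survival for new genotypes. Censoring is deliberately ignored: the
method is an explicit dichotomization, not a hazard model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distance import DeltaTable

__all__ = [
    "SurvivalSplit",
    "survival_group_tests",
    "threshold_scan",
    "LogisticSurvivalModel",
    "survival_logistic",
]


def _pair_tests(xs: np.ndarray, ys: np.ndarray, method: str) -> np.ndarray:
    """Column-wise two-sided two-sample p-values (subjects on axis 0).

    Degenerate convention: a column with zero variance in both groups has
    p = 1 when the constants agree (indistinguishable) and p = 0 when
    they differ (maximally distinct).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "welch":
            pvals = stats.ttest_ind(xs, ys, equal_var=False, axis=0).pvalue
        elif method == "mannwhitney":
            pvals = stats.mannwhitneyu(
                xs, ys, alternative="two-sided", axis=0
            ).pvalue
        else:
            raise ValueError(f"unknown test method {method!r}")
    pvals = np.atleast_1d(np.asarray(pvals, dtype=float))
    flat = (np.ptp(xs, axis=0) == 0) & (np.ptp(ys, axis=0) == 0)
    if flat.any():
        pvals[flat] = np.where(xs[0, flat] == ys[0, flat], 1.0, 0.0)
    return pvals


def survival_group_tests(
    table: DeltaTable,
    groups: Sequence[str],
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-pair comparison of delta distributions between survival groups.

    ``groups`` assigns each subject ``"short"`` or ``"long"``. Raw
    p-values are primary; Benjamini-Hochberg adjusted values are always
    co-reported because K(K-1)/2 tests are run.
    """
    groups = np.asarray(groups)
    if len(groups) != len(table.sample_ids):
        raise ValueError("groups length does not match the delta table")
    short = groups == "short"
    long_ = groups == "long"
    if short.sum() < 2 or long_.sum() < 2:
        raise ValueError("each survival group needs at least 2 subjects")

    xs = table.values[short]
    ys = table.values[long_]
    pvals = _pair_tests(xs, ys, method)
    _, p_bh, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "pair": [f"d{i}-d{j}" for i, j in table.pairs],
            "i": [i for i, _ in table.pairs],
            "j": [j for _, j in table.pairs],
            "short_mean": xs.mean(axis=0),
            "long_mean": ys.mean(axis=0),
            "mean_difference": xs.mean(axis=0) - ys.mean(axis=0),
            "p_value": pvals,
            "p_value_bh": p_bh,
            "significant": pvals < alpha,
        }
    )


@dataclass
class SurvivalSplit:
    """One threshold's dichotomization and its per-pair test outcomes."""

    threshold_days: float
    n_short: int
    n_long: int
    p_values: dict[str, float]
    n_significant: int
    min_p: float
    tests: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def balance(self) -> int:
        return abs(self.n_short - self.n_long)


def threshold_scan(
    survival_days: Sequence[float],
    table: DeltaTable,
    lo: float = 800.0,
    hi: float = 1900.0,
    step: float = 10.0,
    alpha: float = 0.05,
    method: str = "welch",
    min_group: int = 10,
) -> tuple[list[SurvivalSplit], SurvivalSplit]:
    """Scan dichotomization thresholds for the most significant split.

    At each threshold subjects with survival <= threshold form the short
    group, the rest the long group; per-pair tests are run and the best
    split is the statistically most significant one: smallest minimum
    p-value first, ties broken by the larger number of significant pairs,
    then by the most balanced split. (The raw count of significant pairs
    plateaus once an effect is strong, so it ranks behind the minimum p.)
    Thresholds leaving either side with fewer than ``min_group`` subjects
    are skipped: a handful of subjects produces degenerate zero-variance
    p-values that would hijack the minimum-p ranking.
    """
    days = np.asarray(survival_days, dtype=float)
    if len(days) != len(table.sample_ids):
        raise ValueError("survival_days length does not match the delta table")
    if not lo < hi:
        raise ValueError(f"invalid scan range [{lo}, {hi}]")

    min_group = max(min_group, 2)
    splits: list[SurvivalSplit] = []
    for threshold in np.arange(lo, hi + step / 2, step):
        short = days <= threshold
        if short.sum() < min_group or (~short).sum() < min_group:
            continue
        groups = np.where(short, "short", "long")
        tests = survival_group_tests(table, groups, alpha=alpha, method=method)
        splits.append(
            SurvivalSplit(
                threshold_days=float(threshold),
                n_short=int(short.sum()),
                n_long=int((~short).sum()),
                p_values=dict(zip(tests["pair"], tests["p_value"])),
                n_significant=int(tests["significant"].sum()),
                min_p=float(tests["p_value"].min()),
                tests=tests,
            )
        )
    if not splits:
        raise ValueError(
            "every threshold in the scan range leaves one survival group "
            f"with fewer than {min_group} subjects"
        )
    best = min(
        splits, key=lambda s: (s.min_p, -s.n_significant, s.balance)
    )
    return splits, best


def scan_report(splits: Sequence[SurvivalSplit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold_days": [s.threshold_days for s in splits],
            "n_short": [s.n_short for s in splits],
            "n_long": [s.n_long for s in splits],
            "n_significant": [s.n_significant for s in splits],
            "min_p": [s.min_p for s in splits],
        }
    )


@dataclass
class LogisticSurvivalModel:
    """Logistic model for the short-survival category from delta features."""

    pairs: list[tuple[int, int]]
    intercept: float
    coefficients: np.ndarray
    separation: bool
    prob_short: np.ndarray       # fitted probabilities on the training set
    conf_int: np.ndarray | None  # (n_params, 2) Wald CIs incl. intercept

    def predict(self, deltas: Sequence[float]) -> tuple[float, float]:
        """(probability, odds) of short survival for one delta feature row."""
        z = self.intercept + float(np.dot(self.coefficients, deltas))
        p = 1.0 / (1.0 + np.exp(-z))
        odds = p / (1.0 - p) if p < 1.0 else np.inf
        return p, odds

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "pairs": [list(p) for p in self.pairs],
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "separation": self.separation,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticSurvivalModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            pairs=[tuple(p) for p in payload["pairs"]],
            intercept=float(payload["intercept"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            separation=bool(payload["separation"]),
            prob_short=np.array([]),
            conf_int=None,
        )


def survival_logistic(
    table: DeltaTable,
    selected_pairs: Sequence[tuple[int, int]],
    groups: Sequence[str],
    ridge_penalty: float = 1.0,
) -> LogisticSurvivalModel:
    """Fit a logistic model for short survival on selected delta features.

    Uses a maximum-likelihood fit; on (quasi-)perfect separation a warning
    is issued and a ridge-penalized fit with a small fixed penalty is
    used instead, so coefficients stay finite.
    """
    import statsmodels.api as sm

    selected_pairs = [tuple(p) for p in selected_pairs]
    if not selected_pairs:
        raise ValueError("survival_logistic needs at least one delta pair")
    groups = np.asarray(groups)
    y = (groups == "short").astype(float)
    if y.min() == y.max():
        raise ValueError("both survival groups must be present")
    X = np.stack([table.column(p) for p in selected_pairs], axis=1).astype(float)
    Xc = sm.add_constant(X, has_constant="add")

    separation = False
    params = None
    conf = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = fit.params
            conf = np.asarray(fit.conf_int())
            separation = any(
                "separation" in str(w.message).lower() for w in caught
            ) or not np.isfinite(conf).all()
        except Exception:
            separation = True

    if separation or params is None or np.abs(params).max() > 1e3:
        separation = True
        warnings.warn(
            "perfect or quasi-perfect separation detected; falling back to "
            "a ridge-penalized logistic fit",
            stacklevel=2,
        )
        glm = sm.GLM(y, Xc, family=sm.families.Binomial())
        fit = glm.fit_regularized(alpha=ridge_penalty / len(y), L1_wt=0.0)
        params = np.asarray(fit.params)
        conf = None

    prob = 1.0 / (1.0 + np.exp(-(Xc @ params)))
    return LogisticSurvivalModel(
        pairs=selected_pairs,
        intercept=float(params[0]),
        coefficients=np.asarray(params[1:], dtype=float),
        separation=separation,
        prob_short=prob,
        conf_int=conf,
    )
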