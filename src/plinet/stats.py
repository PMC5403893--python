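"""Two-group permutation statistics with t-statistics and FDR correction.

Each feature (an edge's averaged PLI, a node's averaged MST metric, or a
global network value) is compared between groups with a pooled-variance
two-sample t-statistic.  The null distribution is built by relabeling
subjects while preserving group sizes; the two-sided Monte-Carlo p-value
uses the add-one estimator

    p = (1 + #{ |t_perm| >= |t_obs| }) / (n_permutations + 1)

so p is never zero and is bounded below by 1/(n_permutations + 1).  All
features of one call share the same relabeling sequence, mirroring
subject-level resampling and preserving cross-feature dependence.
Multiple testing is controlled per feature family with Benjamini-Hochberg
step-up adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupSample:
    """Per-subject values of one feature, split by group."""

    values_a: np.ndarray
    values_b: np.ndarray
    feature_id: str = ""

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float).ravel()
        self.values_b = np.asarray(self.values_b, dtype=float).ravel()
        if self.values_a.size < 2 or self.values_b.size < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not (
            np.all(np.isfinite(self.values_a))
            and np.all(np.isfinite(self.values_b))
        ):
            raise ValueError("missing/non-finite values may not enter the test")

    @property
    def n_a(self) -> int:
        return self.values_a.size

    @property
    def n_b(self) -> int:
        return self.values_b.size


@dataclass
class PermutationReport:
    feature_id: str
    t_observed: float
    p_perm: float
    n_permutations: int
    seed: int | None
    significant_uncorrected: bool
    p_fdr: float | None = None
    significant_fdr: bool | None = None


def t_statistic(sample: GroupSample) -> float:
    """Pooled-variance two-sample t on the group means (A minus B).

    Zero pooled variance yields t = 0 for equal means, signed infinity
    otherwise (a degenerate-variance flag).
    """
    a, b = sample.values_a, sample.values_b
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    pooled_var = ss / (na + nb - 2)
    if pooled_var == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    return float(diff / se)


def _t_columns(x: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Pooled t for every column of (n_subjects, n_features) under labels."""
    a = x[in_a]
    b = x[~in_a]
    na, nb = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + (
        (b - b.mean(axis=0)) ** 2
    ).sum(axis=0)
    pooled_var = ss / (na + nb - 2)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: t=0 for equal means, +/-inf otherwise
    degenerate = se == 0.0
    if np.any(degenerate):
        t[degenerate] = np.where(
            diff[degenerate] == 0.0, 0.0, np.sign(diff[degenerate]) * np.inf
        )
    return t


def permutation_pvalues(
    values: np.ndarray,
    in_a: np.ndarray,
    n_permutations: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed t and permutation p for each column of a feature matrix.

    ``values`` is (n_subjects, n_features); ``in_a`` marks group-A rows.
    One relabeling sequence is shared by all features.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    in_a = np.asarray(in_a, dtype=bool)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t_obs = _t_columns(x, in_a)
    abs_obs = np.abs(t_obs)
    exceed = np.zeros(x.shape[1], dtype=np.int64)
    n_subjects = x.shape[0]
    for _ in range(n_permutations):
        perm_a = np.zeros(n_subjects, dtype=bool)
        perm_a[rng.permutation(n_subjects)[: in_a.sum()]] = True
        t_perm = _t_columns(x, perm_a)
        exceed += np.abs(t_perm) >= abs_obs
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return t_obs, p


def permutation_test(
    sample: GroupSample,
    n_permutations: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PermutationReport:
    """Two-sided subject-relabeling permutation test for one feature.

    The null is drawn from the sorted pooled values, so swapping the two
    group labels yields the identical p-value for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    t_obs = t_statistic(sample)
    pooled = np.sort(
        np.concatenate([sample.values_a, sample.values_b]), kind="stable"
    )
    n = pooled.size
    n_small = min(sample.n_a, sample.n_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        mask = np.zeros(n, dtype=bool)
        mask[rng.permutation(n)[:n_small]] = True
        t_perm = t_statistic(GroupSample(pooled[mask], pooled[~mask]))
        exceed += abs(t_perm) >= abs(t_obs) - 1e-12
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return PermutationReport(
        feature_id=sample.feature_id,
        t_observed=float(t_obs),
        p_perm=float(p),
        n_permutations=n_permutations,
        seed=seed,
        significant_uncorrected=bool(p <= alpha),
    )


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def run_group_comparison(
    feature_table: pd.DataFrame,
    groups: np.ndarray,
    n_permutations: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Permutation tests plus FDR over one family of features.

    Parameters
    ----------
    feature_table
        Subjects x features; every subject must contribute every feature.
    groups
        Array of 'A'/'B' labels aligned with the table rows.

    Returns a DataFrame with one row per feature: observed t (A minus B),
    permutation p, BH-adjusted p, significance flags and the direction of
    the group difference.
    """
    groups = np.asarray(groups)
    missing = feature_table.columns[feature_table.isna().any(axis=0)]
    if len(missing):
        bad = feature_table.isna().any(axis=1)
        raise ValueError(
            "missing subject features: "
            f"subjects {list(feature_table.index[bad])}, "
            f"features {list(missing)}"
        )
    in_a = groups == "A"
    t_obs, p = permutation_pvalues(
        feature_table.to_numpy(),
        in_a,
        n_permutations=n_permutations,
        seed=seed,
    )
    p_adj, reject = fdr_correct(p, q=fdr_q)
    return pd.DataFrame(
        {
            "feature": list(feature_table.columns),
            "t_observed": t_obs,
            "p_perm": p,
            "p_fdr": p_adj,
            "significant_uncorrected": p <= alpha,
            "significant_fdr": reject,
            "direction": np.where(t_obs > 0, "A>B", np.where(t_obs < 0, "B>A", "=")),
        }
    )
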