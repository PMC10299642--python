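"""Group statistics on per-larva kinocilium lengths.

The unit of analysis is one larva, summarized as the mean length of its
five tallest kinocilia.  Two-group comparisons use the two-tailed Welch
t-test with Welch-Satterthwaite degrees of freedom; multi-group designs use
one-way ANOVA followed by Tukey-Kramer HSD pairwise comparisons (the
studentized-range distribution), with Holm-adjusted pairwise Welch tests as
an alternative.  A small self-validation harness estimates the empirical
type-I error of the Welch implementation under a normal null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "TestResult",
    "AnovaResult",
    "welch_t",
    "anova_oneway",
    "pairwise_adjusted",
    "validate_type_i",
    "simulate_anova_power",
    "groups_from_frame",
]


@dataclass
class GroupSample:
    """Named sample of per-larva mean lengths (um)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def var(self) -> float:
        return float(self.values.var(ddof=1))


@dataclass
class TestResult:
    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.df <= 0:
            raise ValueError("df must be positive")


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def welch_t(a: GroupSample, b: GroupSample) -> TestResult:
    """Two-tailed Welch t-test (unequal variances).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with
    Welch-Satterthwaite degrees of freedom and p = 2 * (1 - T_df(|t|)).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var / a.n, b.var / b.n
    if va + vb == 0.0:
        if a.mean == b.mean:
            raise ValueError("both variances are zero and means agree: "
                             "the t statistic is undefined")
        warnings.warn("zero variance in both groups with distinct means; "
                      "reporting p = 0")
        return TestResult(np.inf if a.mean > b.mean else -np.inf,
                          float(a.n + b.n - 2), 0.0)
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


def anova_oneway(groups: list[GroupSample]) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups])
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    N = int(ns.sum())
    if N <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate([g.values for g in groups]).mean()
    ss_between = float(sum(g.n * (g.mean - grand) ** 2 for g in groups))
    ss_within = float(sum(((g.values - g.mean) ** 2).sum() for g in groups))
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        warnings.warn("zero within-group variance everywhere; F is infinite"
                      if ss_between > 0 else "all observations identical; F = 0")
        F = np.inf if ss_between > 0 else 0.0
        return AnovaResult(F, df1, df2, 0.0 if ss_between > 0 else 1.0)
    F = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(float(F), df1, df2, float(sps.f.sf(F, df1, df2)))


def pairwise_adjusted(groups: list[GroupSample], method: str = "tukey"
                      ) -> pd.DataFrame:
    """All pairwise comparisons with multiplicity adjustment.

    ``tukey`` (default): Tukey-Kramer HSD — the studentized-range statistic
    q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)) referred to
    the studentized-range distribution with k groups and N - k df.
    ``holm``: pairwise Welch t-tests with Holm step-down adjustment.
    Returns k(k-1)/2 rows of (pair, estimate, padj).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    if method == "tukey":
        res = anova_oneway(groups)
        ms_within = float(sum(((g.values - g.mean) ** 2).sum() for g in groups)) / res.df2
        rows = []
        for i, j in pairs:
            gi, gj = groups[i], groups[j]
            est = gi.mean - gj.mean
            if ms_within == 0.0:
                padj = 1.0 if est == 0.0 else 0.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / gi.n + 1.0 / gj.n))
                q = abs(est) / se
                padj = float(sps.studentized_range.sf(q, len(groups), res.df2))
            rows.append((f"{gi.label}-{gj.label}", est, min(padj, 1.0)))
    elif method == "holm":
        raw = [welch_t(groups[i], groups[j]).p for i, j in pairs]
        padj = multipletests(raw, method="holm")[1]
        rows = [(f"{groups[i].label}-{groups[j].label}",
                 groups[i].mean - groups[j].mean, float(pa))
                for (i, j), pa in zip(pairs, padj)]
    else:
        raise ValueError(f"unknown adjustment method {method!r}; "
                         "use 'tukey' or 'holm'")
    return pd.DataFrame(rows, columns=["pair", "estimate", "padj"])


def _welch_p_vectorized(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-tailed Welch p-values for stacked replicate samples.

    ``a`` and ``b`` are (reps, n) arrays; one test per row.  Shares its
    formulas with :func:`welch_t`; agreement is checked in the test suite.
    """
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    return 2.0 * sps.t.sf(np.abs(t), df)


def validate_type_i(n_per_group: int, reps: int, alpha: float = 0.05,
                    rng_seed: int = 0) -> float:
    """Empirical type-I error of the Welch test under a standard-normal null.

    Simulates ``reps`` pairs of null samples of size ``n_per_group`` and
    returns the fraction rejected at level ``alpha``.  Deterministic for a
    fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(rng_seed)
    a = rng.standard_normal((reps, n_per_group))
    b = rng.standard_normal((reps, n_per_group))
    p = _welch_p_vectorized(a, b)
    return float(np.mean(p < alpha))


def simulate_anova_power(group_means: dict[str, float], sd: float,
                         n_per_group: dict[str, int], reps: int = 1000,
                         alpha: float = 0.001, rng_seed: int = 0) -> float:
    """Fraction of simulated studies in which one-way ANOVA rejects.

    Draws per-larva group means as normal with common ``sd`` and the given
    per-group sizes, runs :func:`anova_oneway` on each replicate, and
    returns the rejection rate at level ``alpha``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    labels = list(group_means)
    hits = 0
    for _ in range(reps):
        groups = [GroupSample(lb, rng.normal(group_means[lb], sd,
                                             size=n_per_group[lb]))
                  for lb in labels]
        if anova_oneway(groups).p < alpha:
            hits += 1
    return hits / reps


def groups_from_frame(per_larva: pd.DataFrame) -> list[GroupSample]:
    """Build GroupSamples from a per-larva table (group, larva, mean_um)."""
    required = {"group", "mean_um"}
    if required - set(per_larva.columns):
        raise ValueError("per-larva table needs columns (group, mean_um)")
    return [GroupSample(str(g), sub["mean_um"].to_numpy())
            for g, sub in per_larva.groupby("group", sort=True)]
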