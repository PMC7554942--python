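"""Two-group Wilcoxon rank-sum screening and discriminant-panel building.

The screen mirrors the original two-stage analysis: stage 1 tests all 56
parameters between a discovery contrast (e.g. stage-discordant vs
stage-concordant cases); stage 2 re-tests the stage-1-significant
parameters on the true-F1 vs true-F2 contrast, and the parameters that
remain significant form the discriminant panel.  Significance is strict
p < alpha (default 0.05) with no multiplicity correction by default;
Benjamini-Hochberg is available behind a flag.

``wilcoxon_rank_sum`` reports the rank-sum W of the first sample
(midranks under ties).  Exact mode enumerates the permutation null —
through the tie-free Mann-Whitney U recursion, or full combination
enumeration when ties are present — and defines the two-sided p-value as
min(1, 2 * min(P(W <= w), P(W >= w))).  The approximate mode uses the
normal approximation with tie correction and continuity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .parameters import canonical_name, parameter_schema

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "PanelSpec",
    "wilcoxon_rank_sum",
    "compare_groups",
    "build_panel",
    "screen_and_validate",
]

DEFAULT_ALPHA = 0.05

# exact null enumeration is the default up to this pooled size (tie-free)
EXACT_MAX_POOLED_N = 16
_ENUMERATION_LIMIT = 3_000_000  # max C(N, n_x) for the tied-exact fallback


def _u_count_distribution(m: int, n: int) -> np.ndarray:
    """Counts of the Mann-Whitney U statistic over all C(m+n, m) subsets.

    Classic recursion f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u): the
    largest pooled value is either an x (beating all n y's) or a y.
    """
    max_u = m * n
    table = np.zeros((m + 1, n + 1, max_u + 1), dtype=float)
    table[0, :, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(0, n + 1):
            acc = np.zeros(max_u + 1)
            if j >= 0:
                # x as the largest of an (i, j) pool beats all j y's: U -> U + j
                acc[j:] += table[i - 1, j, : max_u + 1 - j]
            if j >= 1:
                acc += table[i, j - 1]
            table[i, j] = acc
    return table[m, n]


def _exact_p_from_counts(counts: np.ndarray, observed: float, values: np.ndarray | None = None) -> float:
    """Two-sided exact p from a null count distribution.

    ``counts[i]`` is the multiplicity of statistic value ``values[i]``
    (or of value i when values is None).
    """
    total = counts.sum()
    vals = values if values is not None else np.arange(len(counts), dtype=float)
    lo = counts[vals <= observed + 1e-9].sum()
    hi = counts[vals >= observed - 1e-9].sum()
    return float(min(1.0, 2.0 * min(lo, hi) / total))


def _exact_p_tiefree(w: float, n_x: int, n_y: int) -> float:
    u = w - n_x * (n_x + 1) / 2.0  # W and U differ by a constant: same tails
    counts = _u_count_distribution(n_x, n_y)
    return _exact_p_from_counts(counts, u)


def _exact_p_enumeration(ranks: np.ndarray, w: float, n_x: int) -> float:
    n = len(ranks)
    n_comb = math.comb(n, n_x)
    if n_comb > _ENUMERATION_LIMIT:
        raise ValueError(
            f"exact test with ties infeasible for C({n},{n_x}) assignments; "
            "use mode='approx'"
        )
    lo = hi = 0
    for comb in itertools.combinations(range(n), n_x):
        ws = ranks[list(comb)].sum()
        if ws <= w + 1e-9:
            lo += 1
        if ws >= w - 1e-9:
            hi += 1
    return float(min(1.0, 2.0 * min(lo, hi) / n_comb))


def _approx_p(w: float, ranks: np.ndarray, n_x: int, n_y: int) -> float:
    n = n_x + n_y
    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations tied
        return 1.0
    # continuity correction toward the mean
    z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_rank_sum(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum of ``x`` within the pooled
    midranks.  ``mode`` is "exact", "approx" or "auto" (exact when the
    pooled size is at most 16 and there are no ties).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks under ties
    n_x, n_y = x.size, y.size
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = mode == "exact" or (
        mode == "auto" and n_x + n_y <= EXACT_MAX_POOLED_N and not has_ties
    )
    if use_exact:
        p = _exact_p_enumeration(ranks, w, n_x) if has_ties else _exact_p_tiefree(w, n_x, n_y)
    else:
        p = _approx_p(w, ranks, n_x, n_y)
    return w, p


@dataclass
class CohortTable:
    """Per-sample parameter values plus a group label per sample."""

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.rename(columns=canonical_name)
        schema = parameter_schema()
        missing = set(schema) - set(self.values.columns)
        if missing:
            raise ValueError(f"cohort missing {len(missing)} parameters, e.g. {sorted(missing)[:3]}")
        self.values = self.values[schema]
        self.group = pd.Series(self.group, index=self.values.index)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group") -> "CohortTable":
        if group_col not in df.columns:
            raise ValueError(f"missing group column {group_col!r}")
        return cls(values=df.drop(columns=[group_col]), group=df[group_col])

    def groups(self) -> list[str]:
        return sorted(self.group.unique())


@dataclass(frozen=True)
class ComparisonResult:
    """Wilcoxon outcome for one parameter in one two-group contrast."""

    parameter: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    p_adjusted: float | None = None


@dataclass
class PanelSpec:
    """Candidate parameters and those retained at p < alpha."""

    candidate_names: list[str]
    retained_names: list[str]
    alpha: float = DEFAULT_ALPHA
    provenance: str = ""

    def __post_init__(self) -> None:
        if not set(self.retained_names) <= set(self.candidate_names):
            raise ValueError("retained names must be a subset of candidates")

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "provenance": self.provenance,
            "candidates": list(self.candidate_names),
            "retained": list(self.retained_names),
        }


def compare_groups(
    cohort: CohortTable,
    group_a: str,
    group_b: str,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "auto",
    parameters: list[str] | None = None,
    bh: bool = False,
) -> list[ComparisonResult]:
    """Wilcoxon rank-sum per parameter between two groups of a cohort.

    Results follow schema order.  No multiple-testing correction is
    applied unless ``bh=True``, in which case significance is judged on
    Benjamini-Hochberg adjusted p-values (raw p-values are still
    reported).
    """
    present = set(cohort.group.unique())
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"group {g!r} not present in cohort")
    if parameters is None:
        params = parameter_schema()
    else:
        chosen = {canonical_name(p) for p in parameters}
        params = [p for p in parameter_schema() if p in chosen]
    a = cohort.values[cohort.group == group_a]
    b = cohort.values[cohort.group == group_b]
    stats_p = [wilcoxon_rank_sum(a[p].to_numpy(), b[p].to_numpy(), mode=mode) for p in params]
    pvals = np.array([p for _, p in stats_p])
    if bh:
        p_adj = sps.false_discovery_control(pvals, method="bh")
        signif = p_adj < alpha
        adj_list = [float(v) for v in p_adj]
    else:
        signif = pvals < alpha
        adj_list = [None] * len(params)
    return [
        ComparisonResult(
            parameter=name,
            statistic=float(w),
            p_value=float(p),
            significant=bool(s),
            alpha=alpha,
            p_adjusted=adj,
        )
        for name, (w, p), s, adj in zip(params, stats_p, signif, adj_list)
    ]


def build_panel(
    results: list[ComparisonResult],
    candidates: list[str],
    alpha: float = DEFAULT_ALPHA,
    provenance: str = "",
) -> PanelSpec:
    """Retain the candidates with p < alpha, preserving schema order."""
    by_name = {r.parameter: r for r in results}
    order = {name: i for i, name in enumerate(parameter_schema())}
    canon = [canonical_name(c) for c in candidates]
    for c in canon:
        if c not in by_name:
            raise ValueError(f"candidate {c!r} has no comparison result")
    canon.sort(key=order.__getitem__)
    retained = [c for c in canon if by_name[c].p_value < alpha]
    return PanelSpec(
        candidate_names=canon, retained_names=retained, alpha=alpha, provenance=provenance
    )


def screen_and_validate(
    cohort_discordant: CohortTable,
    cohort_true: CohortTable,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "auto",
) -> tuple[list[ComparisonResult], list[ComparisonResult], PanelSpec]:
    """Two-stage screen: discovery contrast, then true-F1 vs true-F2.

    Stage 1 tests all 56 parameters between the two groups of
    ``cohort_discordant``; stage 2 re-tests only the stage-1-significant
    parameters on ``cohort_true``, and the panel is built from stage 2.
    """
    ga, gb = _two_groups(cohort_discordant)
    screen = compare_groups(cohort_discordant, ga, gb, alpha=alpha, mode=mode)
    candidates = [r.parameter for r in screen if r.significant]
    if not candidates:
        return screen, [], PanelSpec([], [], alpha=alpha, provenance="validation")
    ga2, gb2 = _two_groups(cohort_true)
    validation = compare_groups(
        cohort_true, ga2, gb2, alpha=alpha, mode=mode, parameters=candidates
    )
    panel = build_panel(validation, candidates, alpha=alpha, provenance="validation")
    return screen, validation, panel


def _two_groups(cohort: CohortTable) -> tuple[str, str]:
    groups = cohort.groups()
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    return groups[0], groups[1]
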