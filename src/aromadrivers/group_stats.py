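"""One-way ANOVA, Duncan's multiple range test letters, Kruskal-Wallis.

The triplicate concentration table is compared across products by one-way
ANOVA followed by Duncan's multiple range test at alpha = 0.05, reported as a
compact letter display where groups sharing a letter are not significantly
different and "a" marks the group with the smallest mean.  Consumer liking
scores are compared across products with the Kruskal-Wallis rank test
(tie-corrected), treating each rating as an independent observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_oneway",
    "duncan_critical_range",
    "duncan_letters",
    "kruskal_wallis",
    "friedman",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, sd and n (e.g. one concentration-table row)."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("inconsistent group summary lengths")
        if k < 2:
            raise ValueError("need at least two groups")
        if any(sd < 0 for sd in self.sds):
            raise ValueError("negative sd")
        if any(n < 2 for n in self.ns):
            raise ValueError("variance-based tests need n >= 2 per group")

    @classmethod
    def from_raw(cls, groups: Mapping[str, Sequence[float]]) -> "GroupSummary":
        labels, means, sds, ns = [], [], [], []
        for label, values in groups.items():
            arr = np.asarray(values, dtype=float)
            labels.append(str(label))
            means.append(float(arr.mean()))
            sds.append(float(arr.std(ddof=1)))
            ns.append(int(arr.size))
        return cls(tuple(labels), tuple(means), tuple(sds), tuple(ns))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_error: float


def _as_summary(
    groups: GroupSummary | Mapping[str, Sequence[float]],
) -> GroupSummary:
    if isinstance(groups, GroupSummary):
        return groups
    return GroupSummary.from_raw(groups)


def anova_oneway(
    groups: GroupSummary | Mapping[str, Sequence[float]],
) -> AnovaResult:
    """One-way fixed-effects ANOVA from raw replicates or summary statistics.

    The summary route reconstructs SS_between from group means and SS_within
    from group sds, which is exact (identical to the raw decomposition) for
    any design, balanced or not.
    """
    s = _as_summary(groups)
    means = np.asarray(s.means)
    sds = np.asarray(s.sds)
    ns = np.asarray(s.ns)
    n_total = int(ns.sum())
    k = len(s.labels)
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_error = ss_within / df_within
    if ms_error == 0.0:
        f = np.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_error
    p = float(stats.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return AnovaResult(float(f), p, df_between, df_within, ms_error)


@lru_cache(maxsize=None)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    # Duncan's protected studentized-range point: the test of a range spanning
    # p ordered means runs at familywise level 1 - (1 - alpha)^(p - 1).
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df))


def duncan_critical_range(
    alpha: float, p: int, df_error: int, ms_error: float, n: int
) -> float:
    """Least significant range R_p for p ordered means (balanced design)."""
    return _duncan_q(alpha, p, df_error) * np.sqrt(ms_error / n)


def duncan_letters(
    groups: GroupSummary | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    ms_error: float | None = None,
    df_error: int | None = None,
) -> dict[str, str]:
    """Compact letter display for Duncan's multiple range test.

    Means are sorted ascending and every pair spanning p positions is compared
    against the critical range R_p; letters are then assembled with the
    standard insert-and-absorb algorithm, starting at "a" for the smallest
    mean.  Requires a balanced design (equal n per group).
    """
    s = _as_summary(groups)
    ns = set(s.ns)
    if len(ns) != 1:
        raise ValueError(
            "Duncan's critical-range formula requires equal group sizes; "
            "summarize with a harmonic-mean n explicitly if you accept the "
            "unbalanced approximation"
        )
    n = s.ns[0]
    if ms_error is None or df_error is None:
        a = anova_oneway(s)
        ms_error, df_error = a.ms_error, a.df_within

    order = np.argsort(np.asarray(s.means), kind="stable")
    labels = [s.labels[i] for i in order]
    means = [s.means[i] for i in order]
    k = len(labels)

    # significance matrix over sorted positions
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            p = j - i + 1
            r_p = duncan_critical_range(alpha, p, df_error, ms_error, n)
            sig[i, j] = sig[j, i] = (means[j] - means[i]) > r_p

    letters = _compact_letter_display(sig)
    return {labels[i]: letters[i] for i in range(k)}


def _compact_letter_display(sig: np.ndarray) -> list[str]:
    """Insert-and-absorb letter assignment from a pairwise significance
    matrix over means sorted ascending."""
    k = sig.shape[0]
    groups: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            for g in [g for g in groups if i in g and j in g]:
                groups.remove(g)
                gi, gj = g - {j}, g - {i}
                for new in (gi, gj):
                    if not any(new <= other for other in groups):
                        groups.append(new)
            # absorb: drop any group contained in another
            groups = [
                g for g in groups if not any(g < other for other in groups)
            ]
    # order letter groups by their smallest member so "a" goes to low means
    groups.sort(key=lambda g: (min(g), -len(g)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for letter, g in zip(alphabet, groups):
        for i in sorted(g):
            out[i] += letter
    return out


def kruskal_wallis(
    scores: pd.DataFrame, method: str = "asymptotic"
) -> tuple[float, float]:
    """Kruskal-Wallis H test across products (columns of a consumers x
    products score matrix), with tie correction.

    Each rating is treated as an independent observation grouped by product.
    ``method='asymptotic'`` takes p from the chi-square reference with
    (products - 1) df; ``method='exact'`` enumerates every assignment of the
    pooled observations to the groups (small samples only).  Degenerate
    all-identical data gives (0, 1).
    """
    cols = [scores[c].dropna().to_numpy(dtype=float) for c in scores.columns]
    if len(cols) < 2:
        raise ValueError("need at least two products")
    for c, col in zip(scores.columns, cols):
        if col.size == 0:
            raise ValueError(f"product {c!r} has no scores")
    pooled = np.concatenate(cols)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*cols)
    h = float(h)
    if method == "asymptotic":
        return h, float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    sizes = [c.size for c in cols]
    if sum(sizes) > 10:
        raise ValueError("exact enumeration is limited to <= 10 observations")
    from itertools import permutations

    count = total = 0
    for perm in permutations(range(len(pooled))):
        shuffled = pooled[list(perm)]
        groups, start = [], 0
        for s in sizes:
            groups.append(shuffled[start:start + s])
            start += s
        try:
            h_perm, _ = stats.kruskal(*groups)
        except ValueError:  # all identical within permutation (cannot occur
            h_perm = 0.0    # once the pooled data are non-degenerate)
        total += 1
        if h_perm >= h - 1e-12:
            count += 1
    return h, count / total


def friedman(scores: pd.DataFrame) -> tuple[float, float]:
    """Friedman test honoring the repeated-measures design (each consumer
    rated every product).  Off the default analysis path; offered because the
    independent-groups reading of the liking data ignores within-consumer
    correlation."""
    complete = scores.dropna(axis=0)
    stat, p = stats.friedmanchisquare(
        *[complete[c].to_numpy(dtype=float) for c in complete.columns]
    )
    return float(stat), float(p)
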