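"""Invasion statistics on per-cell distance tables.

Implements the quantities reported for the organoid co-culture experiment:
per-organoid min-normalization of distances, the invasion threshold (mean of
the reference group's per-organoid third quartiles), invading-cell counts,
stacked KDE depth profiles, and the group tests (unpaired two-tailed t-test;
one-way ANOVA with Tukey HSD post-hoc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupResult",
    "InvasionSummary",
    "normalize_distances",
    "invasion_threshold",
    "count_invading",
    "kde_profile",
    "compare_two_groups",
    "compare_multi_groups",
    "stars",
]

_DIST = "distance_um"
_NORM = "normalized_distance_um"


def stars(p: float) -> str:
    """Significance label bands used on the figures."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupResult:
    """Outcome of a group comparison."""

    test: str                       # "t_two_sample" | "anova_tukey"
    statistic: float
    p_value: float
    pairwise: list[dict] = field(default_factory=list)
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        if self.pairwise:
            return pd.DataFrame(self.pairwise)
        return pd.DataFrame(
            [{"test": self.test, "statistic": self.statistic,
              "p_value": self.p_value, "label": self.label}]
        )


@dataclass
class InvasionSummary:
    """Invasion threshold and per-organoid invading-cell bookkeeping."""

    threshold_um: float
    reference_group: str
    per_organoid: pd.DataFrame      # organoid_id, group, n_cells, q3_um, n_invading

    def group_counts(self) -> pd.DataFrame:
        return (self.per_organoid.groupby("group", sort=False)
                ["n_invading"].sum().reset_index())


# --------------------------------------------------------------------------
# normalization / threshold / counts
# --------------------------------------------------------------------------

def normalize_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Shift each organoid's distances so its minimum is exactly 0.

    Adds/overwrites ``normalized_distance_um``; the raw column is retained.
    Idempotent: re-normalizing changes nothing.  Organoids with no cells are
    skipped with a warning.
    """
    table = table.copy()
    if table.empty:
        warnings.warn("empty distance table", stacklevel=2)
        table[_NORM] = pd.Series(dtype=float)
        return table
    table[_NORM] = table.groupby("organoid_id")[_DIST].transform(
        lambda d: d - d.min()
    )
    return table


def _q3(values: np.ndarray, method: str = "linear") -> float:
    return float(np.quantile(np.asarray(values, dtype=float), 0.75,
                             method=method))


def invasion_threshold(
    table: pd.DataFrame,
    reference_group: str,
    use_normalized: bool = True,
    quantile_method: str = "linear",
) -> float:
    """Invasion threshold: mean of the reference group's per-organoid Q3.

    For every organoid in ``reference_group`` the third quartile of its
    (by default min-normalized) distances is computed with linear
    interpolation between order statistics; the threshold is the unweighted
    mean of those quartiles.
    """
    col = _NORM if use_normalized else _DIST
    if col == _NORM and _NORM not in table:
        table = normalize_distances(table)
    ref = table[table["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} not found")
    q3s = ref.groupby("organoid_id")[col].apply(
        lambda d: _q3(d.to_numpy(), quantile_method)
    )
    return float(q3s.mean())


def count_invading(
    table: pd.DataFrame,
    threshold: float,
    use_normalized: bool = True,
) -> pd.DataFrame:
    """Cells per organoid whose distance strictly exceeds the threshold.

    Returns one row per organoid: ``organoid_id, group, n_cells, q3_um,
    n_invading`` ("exceeded" = strict ``>``).
    """
    col = _NORM if use_normalized else _DIST
    if col == _NORM and _NORM not in table:
        table = normalize_distances(table)
    rows = []
    for (oid, grp), sub in table.groupby(["organoid_id", "group"], sort=False):
        d = sub[col].to_numpy()
        rows.append({
            "organoid_id": oid,
            "group": grp,
            "n_cells": len(d),
            "q3_um": _q3(d),
            "n_invading": int((d > threshold).sum()),
        })
    return pd.DataFrame(rows)


def summarize_invasion(
    table: pd.DataFrame,
    reference_group: str,
    use_normalized: bool = True,
) -> InvasionSummary:
    """Threshold + per-organoid invading counts in one object."""
    table = normalize_distances(table) if use_normalized else table
    thr = invasion_threshold(table, reference_group, use_normalized)
    per = count_invading(table, thr, use_normalized)
    return InvasionSummary(threshold_um=thr, reference_group=reference_group,
                           per_organoid=per)


__all__.append("summarize_invasion")


# --------------------------------------------------------------------------
# KDE depth profiles
# --------------------------------------------------------------------------

def kde_profile(
    distances,
    bandwidth="scott",
    grid: np.ndarray | None = None,
    n_grid: int = 256,
    pad_factor: float = 3.0,
):
    """Unit-area Gaussian KDE of one or more distance samples.

    ``distances`` may be a single array or a mapping ``{organoid_id:
    values}``; all curves are evaluated on one shared grid so they can be
    stacked.  ``bandwidth`` is Scott's rule by default or a fixed kernel SD
    in µm.  Degenerate samples (all values equal) are handled as a single
    Gaussian of the requested (or a minimal) bandwidth.

    Returns ``(grid, curves)`` with ``curves`` a dict of unit-area density
    arrays.
    """
    if isinstance(distances, dict):
        samples = {k: np.asarray(v, dtype=float) for k, v in distances.items()}
    else:
        samples = {"all": np.asarray(distances, dtype=float)}
    if any(len(v) == 0 for v in samples.values()) or not samples:
        raise ValueError("kde_profile requires non-empty input")

    fixed_h = None if isinstance(bandwidth, str) else float(bandwidth)

    def _h(v: np.ndarray) -> float:
        if fixed_h is not None:
            return fixed_h
        s = v.std(ddof=1) if len(v) > 1 else 0.0
        if s == 0:
            return 1.0  # degenerate spike: minimal 1 µm kernel
        return 1.06 * s * len(v) ** (-0.2) if bandwidth == "silverman" \
            else s * len(v) ** (-0.2)

    if grid is None:
        lo = min(v.min() - pad_factor * _h(v) for v in samples.values())
        hi = max(v.max() + pad_factor * _h(v) for v in samples.values())
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        grid = np.linspace(lo, hi, n_grid)

    curves = {}
    for key, v in samples.items():
        h = _h(v)
        dens = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / h) ** 2).sum(axis=1)
        dens /= len(v) * h * np.sqrt(2.0 * np.pi)
        area = np.trapezoid(dens, grid)
        if area > 0:
            dens = dens / area  # re-normalize for grid truncation
        curves[key] = dens
    return grid, curves


# --------------------------------------------------------------------------
# group tests
# --------------------------------------------------------------------------

def compare_two_groups(a, b, welch: bool = False) -> GroupResult:
    """Unpaired two-tailed t-test (pooled-variance Student by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # zero variance, equal means: no evidence of any difference
            return GroupResult("t_two_sample", 0.0, 1.0,
                               label="ns (zero variance)")
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupResult("t_two_sample", float(t), float(p), label=stars(p))


def compare_multi_groups(groups: dict) -> GroupResult:
    """One-way ANOVA with Tukey HSD post-hoc over k >= 2 labelled groups.

    Pairwise adjusted p-values come from the studentized-range distribution
    with N - k error degrees of freedom (family size k(k-1)/2).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    if np.var(np.concatenate(arrays)) == 0:
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(*arrays)
        if np.isnan(f_stat):     # all groups identical constants
            f_stat, p_anova = 0.0, 1.0

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    codes = np.concatenate([[lab] * len(arr)
                            for lab, arr in zip(labels, arrays)])
    if np.var(values) == 0:
        pairwise = [
            {"pair": (labels[i], labels[j]), "mean_diff": 0.0,
             "adjusted_p": 1.0, "label": "ns"}
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        ]
    else:
        from itertools import combinations

        tk = pairwise_tukeyhsd(values, codes, alpha=0.05)
        pairs = list(combinations(tk.groupsunique, 2))
        pairwise = [
            {"pair": (g1, g2), "mean_diff": float(diff),
             "adjusted_p": float(padj), "label": stars(padj)}
            for (g1, g2), diff, padj in zip(pairs, tk.meandiffs, tk.pvalues)
        ]

    return GroupResult("anova_tukey", float(f_stat), float(p_anova),
                       pairwise=pairwise, label=stars(p_anova))
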