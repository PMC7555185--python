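"""Treatment comparison and quality-marker correlation statistics.

Covers the two statistical surfaces of an accelerated-oxidation study:

* one-way ANOVA over the temperature x airflow grid followed by Tukey's
  HSD with a compact letter display (cells sharing a letter do not differ
  at ``alpha``), and
* Pearson correlation of kernel OSI against quality/oxidation markers
  (moisture, fat, peroxide value, K232/K268 UV absorbances, hexanal,
  oil OSI, sensory rancidity), with the two-tier significance marks
  ``*`` (p < 0.05) and ``**`` (p < 0.001) used in food-chemistry tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import (
    ConstantSeries,
    KeyMismatch,
    LengthMismatch,
    TooFewPairs,
    UnbalancedBelowMinimum,
)

__all__ = [
    "CorrelationResult",
    "TukeyGrouping",
    "pearson",
    "correlation_matrix",
    "anova_tukey",
    "MARKER_COLUMNS",
]

#: Quality-panel marker columns, in canonical reporting order.
MARKER_COLUMNS = (
    "moisture_pct",
    "fat_pct",
    "pv",
    "k232",
    "k268",
    "hexanal_mg_kg",
    "oil_osi_h",
    "rancidity",
)


@dataclass(frozen=True)
class CorrelationResult:
    """A single Pearson correlation with its two-sided p-value.

    ``significance_mark`` follows the two-tier convention: ``"**"`` for
    p < 0.001, ``"*"`` for 0.001 <= p < 0.05, empty otherwise.
    """

    variable_x: str
    variable_y: str
    r: float
    p_value: float
    n: int
    significance_mark: str


@dataclass(frozen=True)
class TukeyGrouping:
    """Compact letter display from a one-way ANOVA + Tukey HSD.

    ``letters`` maps each cell label to its letter string; two cells share
    a letter iff their means are not significantly different at ``alpha``.
    Letters run from ``a`` at the highest mean downwards.
    """

    letters: dict[str, str]
    means: dict[str, float]
    alpha: float
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject


def significance_mark(p_value: float) -> str:
    """Two-tier mark: '**' for p < 0.001, '*' for p < 0.05, else ''."""
    if p_value < 0.001:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def pearson(x: Sequence[float], y: Sequence[float], *, name_x: str = "x", name_y: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-transform p-value.

    ``r`` is the sample correlation coefficient and the p-value comes from
    ``t = r sqrt((n-2) / (1-r^2))`` referred to a Student t distribution
    with n-2 degrees of freedom (two-sided).  Pairs with a missing value
    in either series are dropped.

    Raises
    ------
    LengthMismatch, TooFewPairs, ConstantSeries
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise LengthMismatch(f"series lengths differ: {xa.shape} vs {ya.shape}")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise TooFewPairs(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ConstantSeries("Pearson correlation undefined for a constant series")

    dx, dy = xa - xa.mean(), ya - ya.mean()
    r = float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(
        variable_x=name_x,
        variable_y=name_y,
        r=r,
        p_value=p,
        n=int(n),
        significance_mark=significance_mark(p),
    )


def correlation_matrix(
    osi: pd.DataFrame,
    panel: pd.DataFrame,
    group_by_storage: bool = False,
    markers: Sequence[str] = MARKER_COLUMNS,
) -> pd.DataFrame:
    """Correlate kernel OSI against each quality marker.

    Parameters
    ----------
    osi : DataFrame
        Columns ``label, sample_id, storage_months, osi_h`` — one row per
        sample per operational-parameter set (``label``).
    panel : DataFrame
        Columns ``sample_id, storage_months`` plus the marker columns.
    group_by_storage : bool
        If True, one correlation row per (label, storage time) — the
        storage-resolved table layout; otherwise one row per label pooling
        storage times.
    markers : sequence of str
        Marker columns to correlate (missing ones raise KeyMismatch).

    Returns
    -------
    DataFrame
        Tidy table with columns ``label [, storage_months], marker, r,
        p_value, n, mark``.  Missing marker values are dropped pairwise,
        with the effective n reported per cell.
    """
    for col in ("label", "sample_id", "storage_months", "osi_h"):
        if col not in osi.columns:
            raise KeyMismatch(f"osi table missing column {col!r}")
    missing = [m for m in markers if m not in panel.columns]
    if missing:
        raise KeyMismatch(f"panel missing marker columns: {missing}")

    merged = osi.merge(panel, on=["sample_id", "storage_months"], how="inner")
    if merged.empty:
        raise KeyMismatch("no (sample_id, storage_months) keys shared between osi and panel")

    group_cols = ["label", "storage_months"] if group_by_storage else ["label"]
    rows = []
    for keys, grp in merged.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for marker in markers:
            res = pearson(grp["osi_h"], grp[marker], name_x="kernel_osi", name_y=marker)
            rows.append(
                dict(zip(group_cols, keys))
                | {
                    "marker": marker,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n": res.n,
                    "mark": res.significance_mark,
                }
            )
    return pd.DataFrame(rows)


def _compact_letter_display(
    labels: list[str], means: dict[str, float], distinct: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``distinct`` holds unordered pairs judged significantly different.
    Labels are ranked by descending mean so that 'a' tags the highest mean.
    """
    order = sorted(labels, key=lambda lab: -means[lab])
    columns: list[set[str]] = [set(order)]
    for i, lab1 in enumerate(order):
        for lab2 in order[i + 1 :]:
            if (lab1, lab2) not in distinct and (lab2, lab1) not in distinct:
                continue
            new_columns = []
            for col in columns:
                if lab1 in col and lab2 in col:
                    new_columns.extend([col - {lab1}, col - {lab2}])
                else:
                    new_columns.append(col)
            # absorb: drop empty, duplicate, and strictly contained columns
            uniq: list[set[str]] = []
            for c in new_columns:
                if c and c not in uniq:
                    uniq.append(c)
            columns = [c for c in uniq if not any(c < other for other in uniq)]
    rank = {lab: i for i, lab in enumerate(order)}
    columns.sort(key=lambda col: min(rank[lab] for lab in col))
    letters: dict[str, list[str]] = {lab: [] for lab in order}
    for letter_i, col in enumerate(columns):
        letter = chr(ord("a") + letter_i) if letter_i < 26 else f"z{letter_i}"
        for lab in col:
            letters[lab].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in letters.items()}


def anova_tukey(cells: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyGrouping:
    """One-way ANOVA over treatment cells followed by Tukey's HSD.

    The cells are typically the temperature x airflow combinations of an
    accelerated-oxidation grid, treated as groups of a one-way layout.
    Unequal cell sizes use the Tukey-Kramer adjustment (harmonic-mean n).
    If every cell has zero within variance the HSD statistic is undefined
    and cells are grouped by exact mean equality instead.

    Parameters
    ----------
    cells : mapping of label -> replicate values
        At least two cells, each with >= 2 replicates.
    alpha : float
        Familywise significance level (default 0.05).

    Returns
    -------
    TukeyGrouping
    """
    if len(cells) < 2:
        raise UnbalancedBelowMinimum("need at least two cells")
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in cells.items()}
    for lab, arr in arrays.items():
        if arr.size < 2:
            raise UnbalancedBelowMinimum(f"cell {lab!r} has n={arr.size} < 2")
        if not np.all(np.isfinite(arr)):
            raise UnbalancedBelowMinimum(f"cell {lab!r} contains non-finite values")

    labels = list(arrays)
    means = {lab: float(arr.mean()) for lab, arr in arrays.items()}
    within_ss = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in arrays.values())

    if within_ss == 0.0:
        # degenerate: zero residual variance; any mean difference is exact
        distinct = {
            (a, b)
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
            if means[a] != means[b]
        }
        pairwise = pd.DataFrame(
            [
                {"group1": a, "group2": b, "meandiff": means[b] - means[a],
                 "p_adj": 0.0 if (a, b) in distinct else 1.0,
                 "reject": (a, b) in distinct}
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        )
        f_stat, p_val = float("inf"), 0.0
        if len({round(m, 15) for m in means.values()}) == 1:
            f_stat, p_val = float("nan"), 1.0
    else:
        values = np.concatenate(list(arrays.values()))
        groups = np.concatenate([[lab] * arrays[lab].size for lab in labels])
        f_stat, p_val = stats.f_oneway(*arrays.values())
        hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
        summ = hsd.summary().data[1:]  # rows align with meandiffs/pvalues
        pairwise = pd.DataFrame(
            {
                "group1": [str(row[0]) for row in summ],
                "group2": [str(row[1]) for row in summ],
                "meandiff": np.asarray(hsd.meandiffs, dtype=float),
                "p_adj": np.asarray(hsd.pvalues, dtype=float),
                "reject": np.asarray(hsd.pvalues, dtype=float) < alpha,
            }
        )
        distinct = {
            (row.group1, row.group2) for row in pairwise.itertuples() if row.reject
        }

    letters = _compact_letter_display(labels, means, distinct)
    return TukeyGrouping(
        letters=letters,
        means=means,
        alpha=float(alpha),
        anova_f=float(f_stat),
        anova_p=float(p_val),
        pairwise=pairwise,
    )
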