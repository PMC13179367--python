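"""Cell-type composition, group comparison, and TCR clonotype analysis.

Per-sample cell-type proportions (with optional exclusion of unreliable
types, e.g. neutrophils), exact two-sided Wilcoxon rank-sum comparisons of
proportions between response groups within compartment/timepoint strata, TCR
clonotype expansion binning, and the Gini-Simpson clonal diversity index.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_proportions",
    "compare_groups",
    "rank_sum_p",
    "bin_clonotypes",
    "gini_simpson",
    "CLONOTYPE_BINS",
]

#: Clonotype expansion bins: Single (1); Small (2-5); Medium (6-20);
#: Large (21-100); Hyperexpanded (>100).
CLONOTYPE_BINS = (
    ("Single", 1, 1),
    ("Small", 2, 5),
    ("Medium", 6, 20),
    ("Large", 21, 100),
    ("Hyperexpanded", 101, None),
)


def compute_proportions(
    cells: pd.DataFrame,
    excluded_types: set[str] | frozenset[str] = frozenset(),
    sample_col: str = "sample",
    type_col: str = "cell_type",
    carry_cols: tuple[str, ...] = ("group", "compartment", "timepoint"),
) -> pd.DataFrame:
    """Per-sample cell-type proportions, renormalized over non-excluded types.

    One row per sample x cell type.  Sample-level metadata columns listed in
    ``carry_cols`` are carried through when present and constant per sample.
    Samples left with zero non-excluded cells are dropped with a warning.
    """
    if cells[type_col].isna().any():
        raise ValueError("every cell must have a cell type")
    kept = cells[~cells[type_col].isin(excluded_types)]
    empty = set(cells[sample_col].unique()) - set(kept[sample_col].unique())
    if empty:
        warnings.warn(
            f"dropped {len(empty)} sample(s) with no non-excluded cells: {sorted(empty)}"
        )
    counts = (
        kept.groupby([sample_col, type_col], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby(sample_col)["n_cells"].transform("sum")
    counts["proportion"] = counts["n_cells"] / totals
    carry = [c for c in carry_cols if c in cells.columns]
    if carry:
        meta = kept[[sample_col, *carry]].drop_duplicates()
        if meta[sample_col].duplicated().any():
            raise ValueError(f"columns {carry} are not constant within samples")
        counts = counts.merge(meta, on=sample_col, how="left")
    return counts


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact-conditional two-sided rank-sum p with mid-ranks.

    Enumerates every assignment of the pooled values into the two groups and
    computes P(|W - E W| >= |w_obs - E W|) for the group-A mid-rank sum W.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    n, na = len(pooled), len(a)
    w_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = comb(n, na)
    for idx in combinations(range(n), na):
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_p(a, b, exact_limit: int = 14) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact-conditional enumeration (mid-ranks, correct under ties) when the
    pooled size is at most ``exact_limit``; tie-corrected normal
    approximation via ``scipy.stats.mannwhitneyu`` otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if a.size + b.size <= exact_limit:
        return _exact_rank_sum_p(a, b)
    return float(stats.mannwhitneyu(a, b, method="asymptotic").pvalue)


def compare_groups(
    props: pd.DataFrame,
    stratify_by: tuple[str, ...] = ("compartment", "timepoint"),
    group_col: str = "group",
    value_col: str = "proportion",
    type_col: str = "cell_type",
    sample_col: str = "sample",
    min_samples: int = 2,
    exact_limit: int = 14,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-wise comparison of per-sample proportions per cell type.

    Returns one row per cell type x stratum with the two-sided rank-sum
    p-value, a significance flag at ``alpha``, and ``available=False`` (p is
    NaN) where either group has fewer than ``min_samples`` samples — the
    "not enough samples" rule for sparse strata.
    """
    strata = [c for c in stratify_by if c in props.columns]
    groups = sorted(props[group_col].dropna().unique())
    if len(groups) > 2:
        raise ValueError(f"expected two groups, found {groups}")
    rows = []
    for skey, stratum in (
        props.groupby(strata, observed=True) if strata else [((), props)]
    ):
        skey = skey if isinstance(skey, tuple) else (skey,)
        # samples lacking a cell type contribute proportion 0 for it
        wide = stratum.pivot_table(
            index=sample_col, columns=type_col, values=value_col,
            fill_value=0.0, aggfunc="sum", observed=True,
        )
        sample_group = stratum.drop_duplicates(sample_col).set_index(sample_col)[group_col]
        for cell_type in wide.columns:
            vals = {
                g: wide.loc[sample_group[sample_group == g].index, cell_type]
                for g in groups
            }
            ok = len(groups) == 2 and all(len(v) >= min_samples for v in vals.values())
            p = (
                rank_sum_p(vals[groups[0]], vals[groups[1]], exact_limit=exact_limit)
                if ok
                else float("nan")
            )
            rows.append(
                {type_col: cell_type, **dict(zip(strata, skey)),
                 "p_value": p, "significant": bool(ok and p < alpha), "available": ok}
            )
    return pd.DataFrame(rows)


def bin_clonotypes(sizes, clonotypes=None) -> pd.DataFrame:
    """Assign clonotype expansion bins to clone sizes.

    Size partition: 1 -> Single; 2-5 -> Small; 6-20 -> Medium;
    21-100 -> Large; >100 -> Hyperexpanded.
    """
    sizes = np.asarray(sizes)
    if sizes.size and (sizes < 1).any():
        raise ValueError("clonotype sizes must be >= 1")
    if not np.array_equal(sizes, sizes.astype(int)):
        raise ValueError("clonotype sizes must be integers")
    labels = [name for name, _, _ in CLONOTYPE_BINS]
    edges = [0.5, 1.5, 5.5, 20.5, 100.5, np.inf]
    binned = pd.cut(sizes, bins=edges, labels=labels)
    out = pd.DataFrame(
        {
            "clonotype": clonotypes if clonotypes is not None else np.arange(sizes.size),
            "size": sizes.astype(int),
            "bin": binned,
        }
    )
    return out


def gini_simpson(sizes) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2) over clonotype frequencies."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one clonotype")
    if (sizes <= 0).any():
        raise ValueError("clonotype sizes must be positive")
    p = sizes / sizes.sum()
    return float(1.0 - (p**2).sum())
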