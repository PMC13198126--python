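"""Group comparisons and set-overlap summaries for tiered organic-acid data.

Differential testing follows the study design: per analyte, a two-sided
Student's t test (pooled variance) between two groups, significance called
at p < alpha with no multiple-testing correction by default; Welch's t and
Benjamini-Hochberg adjustment are available behind options for reuse in
larger panels.  Set overlaps between tissues use the exclusive-intersection
convention of UpSet plots: each element is counted once, in the cell of
exactly the tissues that contain it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "students_t",
    "group_compare",
    "exclusive_intersections",
    "SetSummary",
    "zscore_matrix",
    "volcano_table",
]


def students_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> Tuple[float, float]:
    """Two-sided unpaired t test; pooled variance unless ``welch``.

    The degenerate case (zero variance in both groups, equal means) returns
    (0.0, 1.0) by convention instead of NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t test needs >= 2 samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(b.mean() - a.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def group_compare(
    amounts: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "amount_nmol_per_g",
    analyte_col: str = "analyte",
    reference: Optional[str] = None,
    alpha: float = 0.05,
    welch: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-analyte two-group comparison of a long amounts table.

    ``reference`` names the baseline group (e.g. "young"); fold change is
    mean(other) / mean(reference).  Degenerate analytes (zero variance in
    both groups with equal means) get t = 0, p = 1 and flag ``degenerate``.
    With ``bh_correct`` an adjusted q-value column drives the significance
    call instead of the raw p.
    """
    groups = list(pd.unique(amounts[group_col]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if reference is None:
        reference = groups[0]
    other = next(g for g in groups if g != reference)

    rows = []
    for analyte, sub in amounts.groupby(analyte_col, sort=False):
        va = sub.loc[sub[group_col] == reference, value_col].dropna().to_numpy()
        vb = sub.loc[sub[group_col] == other, value_col].dropna().to_numpy()
        if va.size < 2 or vb.size < 2:
            rows.append(
                {
                    analyte_col: analyte,
                    f"mean_{reference}": va.mean() if va.size else np.nan,
                    f"mean_{other}": vb.mean() if vb.size else np.nan,
                    "fold_change": np.nan,
                    "t_statistic": np.nan,
                    "p_value": np.nan,
                    "flag": "insufficient_n",
                }
            )
            continue
        t, p = students_t(va, vb, welch=welch)
        degenerate = va.std(ddof=1) == 0 and vb.std(ddof=1) == 0 and va.mean() == vb.mean()
        fc = vb.mean() / va.mean() if va.mean() != 0 else np.nan
        rows.append(
            {
                analyte_col: analyte,
                f"mean_{reference}": va.mean(),
                f"mean_{other}": vb.mean(),
                "fold_change": fc,
                "t_statistic": t,
                "p_value": p,
                "flag": "degenerate" if degenerate else "",
            }
        )
    out = pd.DataFrame.from_records(rows)

    pcol = "p_value"
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        out["q_value"] = q
        pcol = "q_value"
    out["significant"] = out[pcol] < alpha
    out["direction"] = np.where(
        out["fold_change"] > 1, "up", np.where(out["fold_change"] < 1, "down", "none")
    )
    return out


@dataclass(frozen=True)
class SetSummary:
    """Exclusive (UpSet-style) intersection counts over named sets.

    ``counts`` maps a frozenset of set names (the membership pattern) to
    the number of elements belonging to exactly those sets; patterns with
    zero elements are omitted.  Counts sum to the size of the union.
    """

    set_names: tuple
    counts: Dict[frozenset, int]
    members: Dict[frozenset, frozenset]

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())

    def count(self, *names: str) -> int:
        return self.counts.get(frozenset(names), 0)


def exclusive_intersections(sets: Mapping[str, Set]) -> SetSummary:
    """Exclusive intersection counts for every non-empty combination.

    Each element of the union is assigned to the pattern of exactly the
    sets containing it, so the counts partition the union (the UpSet
    convention, as opposed to cumulative intersections).
    """
    if not sets:
        raise ValueError("need at least one set")
    names = tuple(sets)
    pattern_members: Dict[frozenset, set] = {}
    universe = set().union(*sets.values())
    for el in universe:
        pattern = frozenset(n for n in names if el in sets[n])
        pattern_members.setdefault(pattern, set()).add(el)
    return SetSummary(
        set_names=names,
        counts={p: len(m) for p, m in pattern_members.items()},
        members={p: frozenset(m) for p, m in pattern_members.items()},
    )


def zscore_matrix(
    matrix: pd.DataFrame,
    analytes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Standardize each analyte row to mean 0, sd 1 (n-1) across samples.

    ``matrix`` is analytes x samples.  Zero-variance rows cannot be
    standardized and are dropped with a warning.  Intended for heatmap
    rendering of conserved differential analytes.
    """
    m = matrix.loc[list(analytes)] if analytes is not None else matrix
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} zero-variance analyte rows: "
            f"{list(m.index[zero])[:5]}",
            stacklevel=2,
        )
        m, mu, sd = m.loc[~zero], mu[~zero], sd[~zero]
    return m.sub(mu, axis=0).div(sd, axis=0)


def volcano_table(comparison: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot-ready columns: log2 fold change and -log10 p."""
    out = comparison.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_fold_change"] = np.log2(out["fold_change"])
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out
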