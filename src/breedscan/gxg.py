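"""Haplotype-combination group analysis (gene-by-gene dissection).

Within a stratum fixed by one gene's activity code (typically the major
early/late switch gene), lines are partitioned by the code combination of two
or more interacting genes; per-group DTH summaries, pairwise Student t-tests,
and Tukey-Kramer multiple comparisons quantify whether one gene's effect is
expressed only on a particular background — the signature of epistatic
gating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import HaplotypeTable

__all__ = ["ComboGroup", "combo_groups", "pairwise_ttest", "tukey_kramer"]


@dataclass
class ComboGroup:
    """One haplotype-combination group within a stratum."""

    group_id: int
    combo: dict[str, int]               # gene -> activity code
    lines: list[str]
    summary: pd.DataFrame = field(repr=False, default=None)  # per-year mean, sd, n

    @property
    def n(self) -> int:
        return len(self.lines)


def combo_groups(H: HaplotypeTable, pheno: pd.DataFrame,
                 stratum: dict[str, int] | None, combo_genes: list[str],
                 ) -> list[ComboGroup]:
    """Partition a stratum by the code combination of the combo genes.

    ``stratum`` filters lines by activity code of one or more genes (None = no
    stratification); lines with a missing code at any relevant gene are
    excluded.  One group is returned per observed combination, with per-year
    DTH mean/SD/n; groups are numbered by descending code tuple (the
    all-active combination first).
    """
    codes = H.codes
    for g in list(stratum or {}) + combo_genes:
        if g not in codes.columns:
            raise KeyError(f"gene {g!r} not in haplotype table")
    mask = pd.Series(True, index=codes.index)
    for g, c in (stratum or {}).items():
        mask &= codes[g] == c
    relevant = codes.loc[mask, combo_genes].dropna()
    if len(relevant) == 0:
        raise ValueError("empty stratum after filtering")
    groups: list[ComboGroup] = []
    gid = 0
    for combo in sorted(set(map(tuple, relevant.to_numpy().astype(int).tolist())),
                        reverse=True):
        sel = (relevant == np.array(combo)).all(axis=1)
        lines = list(relevant.index[sel])
        gid += 1
        rows = []
        for year, sub in pheno[pheno["line"].isin(lines)].groupby("year"):
            rows.append((str(year), sub["dth"].mean(), sub["dth"].std(ddof=1), len(sub)))
        summary = pd.DataFrame(rows, columns=["year", "mean", "sd", "n"]).set_index("year")
        groups.append(ComboGroup(gid, dict(zip(combo_genes, combo)), lines, summary))
    return groups


def pairwise_ttest(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series,
                   ) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test between two DTH groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        warnings.warn("zero pooled variance with equal means; t undefined", stacklevel=2)
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def tukey_kramer(groups: list[np.ndarray], labels: list[str] | None = None,
                 alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey-Kramer all-pairs comparison with a compact letter display.

    For each pair, q = |mean_i - mean_j| / sqrt(MSE/2 (1/n_i + 1/n_j)) with
    MSE the within-group variance pooled over all k groups, and the adjusted
    p comes from the exact studentized-range distribution with k groups and
    N - k error df (the unequal-n Tukey-Kramer form; at k = 2 this reduces
    exactly to the two-sided pooled t-test).  Returns (symmetric adjusted-p
    matrix, letters) where groups sharing a letter are not significantly
    different at ``alpha``.  Letters are assigned greedily by descending
    group mean (ties broken by label order).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or [f"g{i + 1}" for i in range(k)]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for lab, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lab} needs n >= 2")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_err = int(ns.sum() - k)
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    mse = sse / df_err
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0:
                p = 1.0 if means[i] == means[j] else 0.0
                if means[i] == means[j]:
                    warnings.warn("zero pooled variance in Tukey-Kramer comparison",
                                  stacklevel=2)
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
                p = float(stats.studentized_range.sf(q, k, df_err))
            pmat.iloc[i, j] = pmat.iloc[j, i] = min(max(p, 0.0), 1.0)
    letters = _compact_letters(pmat, {lab: float(np.mean(arr))
                                      for lab, arr in zip(labels, arrays)}, alpha)
    return pmat, letters


def _compact_letters(pmat: pd.DataFrame, means: dict[str, float],
                     alpha: float) -> dict[str, str]:
    """Greedy compact-letter display: walk groups by descending mean; each group
    joins every existing letter class it is compatible with, else founds a new one."""
    order = sorted(pmat.index, key=lambda g: (-means[g], g))
    classes: list[set[str]] = []
    for g in order:
        joined = False
        for cls in classes:
            if all(pmat.loc[g, h] >= alpha for h in cls):
                cls.add(g)
                joined = True
        if not joined:
            classes.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in pmat.index}
    for letter, cls in zip(alphabet, classes):
        for g in cls:
            letters[g] += letter
    return letters
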