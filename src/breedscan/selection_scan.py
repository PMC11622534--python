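"""Selection during breeding: haplotype-frequency trajectories across breeding
periods, Fisher exact transition tests, and a per-SNP Nei genetic-distance
scan between early and late periods.

Nei's (1972-style) normalized-identity distance is applied per SNP between
the allele frequencies of two period subpopulations: D = -ln(Jxy/sqrt(Jx Jy))
with Jx = p^2 + (1-p)^2 etc.; loci under directional selection between the
periods stand out above per-chromosome empirical thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import GenotypeMatrix, HaplotypeTable, PERIOD_YEARS

__all__ = [
    "FrequencyTrajectory",
    "NeiScan",
    "frequency_trajectory",
    "transition_fisher",
    "nei_distance",
    "nei_scan",
]

#: Finite cap for D when the between-population identity Jxy is exactly zero
#: (fixed for opposite alleles); -ln of a machine-epsilon identity is meaningless.
NEI_D_CAP = 10.0


@dataclass
class FrequencyTrajectory:
    """Per-period carrier counts of a focal haplotype (or AND-combination)."""

    focal: dict[str, object]            # gene -> haplotype label or set of labels
    table: pd.DataFrame                 # index period; columns count, total, fraction

    def fraction(self, period: str) -> float:
        return float(self.table.loc[period, "fraction"])


def frequency_trajectory(H: HaplotypeTable, meta: pd.DataFrame,
                         focal: dict[str, object]) -> FrequencyTrajectory:
    """Count lines matching the focal haplotype specification per breeding period.

    ``focal`` maps gene -> haplotype label (or a set of labels); a multi-gene
    spec is an AND-combination (e.g. the inactive-Hd16 / late-Hd17 set).
    Lines missing any focal gene's haplotype are excluded from both numerator
    and denominator.
    """
    known = set(H.labels.columns)
    for g, labels in focal.items():
        if g not in known:
            raise KeyError(f"unknown gene {g!r} in focal spec; genes: {sorted(known)}")
        want = {labels} if isinstance(labels, str) else set(labels)
        have = {r.label for gd in H.gene_defs if gd.name == g for r in gd.rules}
        if have and not want.issubset(have):
            raise KeyError(f"unknown haplotype(s) {want - have} for gene {g}")
    meta = meta.set_index("line") if "line" in meta.columns else meta
    if not set(H.labels.index).issubset(meta.index):
        raise ValueError("every line in the haplotype table needs a period in metadata")
    rows = []
    periods = [p for p in PERIOD_YEARS if p in set(meta["period"])]
    for period in periods:
        lines = meta.index[meta["period"] == period]
        lines = [l for l in lines if l in H.labels.index]
        sub = H.labels.loc[lines, list(focal)]
        callable_mask = sub.notna().all(axis=1)
        sub = sub[callable_mask]
        match = pd.Series(True, index=sub.index)
        for g, labels in focal.items():
            want = {labels} if isinstance(labels, str) else set(labels)
            match &= sub[g].isin(want)
        count, total = int(match.sum()), int(len(sub))
        rows.append((period, count, total, count / total if total else np.nan))
    table = pd.DataFrame(rows, columns=["period", "count", "total", "fraction"]
                         ).set_index("period")
    return FrequencyTrajectory(dict(focal), table)


def transition_fisher(traj: FrequencyTrajectory,
                      period_pair: tuple[str, str]) -> float:
    """Two-sided Fisher exact p for carrier/non-carrier x period (2x2).

    Tests whether the focal haplotype ratio of the first period was maintained
    in the second, with the conventional probability-mass two-sided rule
    (sum of hypergeometric outcomes no more probable than the observed
    table).  A zero-margin table gives p = 1 with a warning.
    """
    a, b = period_pair
    for per in (a, b):
        if per not in traj.table.index or traj.table.loc[per, "total"] == 0:
            raise ValueError(f"period {per} has no counted lines")
    c1, t1 = int(traj.table.loc[a, "count"]), int(traj.table.loc[a, "total"])
    c2, t2 = int(traj.table.loc[b, "count"]), int(traj.table.loc[b, "total"])
    table = np.array([[c1, t1 - c1], [c2, t2 - c2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin; Fisher p reported as 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def nei_distance(p: float | np.ndarray, q: float | np.ndarray,
                 cap: float = NEI_D_CAP) -> np.ndarray:
    """Per-locus Nei distance between allele frequencies p and q.

    D = -ln(Jxy / sqrt(Jx Jy)) with the biallelic gene identities
    Jx = p^2+(1-p)^2, Jy = q^2+(1-q)^2, Jxy = pq+(1-p)(1-q); D is symmetric
    in (p, q), zero iff p = q, and capped at ``cap`` when Jxy = 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    jx = p ** 2 + (1 - p) ** 2
    jy = q ** 2 + (1 - q) ** 2
    jxy = p * q + (1 - p) * (1 - q)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(jxy / np.sqrt(jx * jy))
    d = np.where(jxy == 0, cap, d)
    return np.minimum(np.where(np.isnan(p) | np.isnan(q), np.nan, d), cap)


@dataclass
class NeiScan:
    """Per-variant Nei D with per-chromosome empirical selection thresholds."""

    table: pd.DataFrame                 # chrom, pos, D, capped, above5pct, above10pct
    thresholds: pd.DataFrame            # per chromosome: top5pct, top10pct


def nei_scan(G_early: GenotypeMatrix, G_late: GenotypeMatrix,
             cap: float = NEI_D_CAP) -> NeiScan:
    """Nei genetic distance per SNP between two period subpopulations.

    Frequencies are computed over non-missing calls within each population;
    variants absent (all-missing) in either give missing D.  Per-chromosome
    95th/90th percentile thresholds localize candidate selected loci.
    """
    if not (np.array_equal(G_early.chrom, G_late.chrom)
            and np.array_equal(G_early.pos, G_late.pos)):
        raise ValueError("the two matrices must share an identical variant set")
    p = G_early.alt_freq()
    q = G_late.alt_freq()
    D = nei_distance(p, q, cap)
    table = pd.DataFrame({"chrom": G_early.chrom, "pos": G_early.pos, "D": D,
                          "capped": (D >= cap)})
    thr_rows = []
    table["above5pct"] = False
    table["above10pct"] = False
    for c in sorted(set(int(x) for x in table["chrom"])):
        mask = table["chrom"] == c
        vals = table.loc[mask, "D"].dropna()
        t5 = float(np.percentile(vals, 95)) if len(vals) else np.nan
        t10 = float(np.percentile(vals, 90)) if len(vals) else np.nan
        thr_rows.append((c, t5, t10))
        table.loc[mask, "above5pct"] = table.loc[mask, "D"] > t5
        table.loc[mask, "above10pct"] = table.loc[mask, "D"] > t10
    thresholds = pd.DataFrame(thr_rows, columns=["chrom", "top5pct", "top10pct"]
                              ).set_index("chrom")
    return NeiScan(table, thresholds)
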