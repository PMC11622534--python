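"""Marginal and partial correlation triage of coded heading-gene haplotypes.

In a heavily bred panel, truncation selection on the phenotype co-selects
favourable allele combinations at physically unlinked loci, creating
trans-chromosomal LD between their 0/1 activity codes.  A marginal
point-biserial correlation between one gene's code and the trait then mixes
the gene's own effect with the effects of its co-selected partners: a null
gene can look significant (Type I) and a true effect can vanish or flip sign
(Type II).  Partial correlation of each code with the trait given all other
codes — computed from the inverse of the joint Pearson correlation matrix,
legitimate because point-biserial and phi are Pearson correlations on 0/1
variables — separates the two, and the triage rule turns the
marginal/partial/LD pattern into an explicit label per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CodedPanel",
    "point_biserial",
    "phi_coefficient",
    "phi_matrix",
    "partial_correlations",
    "holm_adjust",
    "triage",
    "correlation_report",
]


@dataclass
class CodedPanel:
    """Complete-case line x gene 0/1 activity codes with one year's DTH."""

    codes: pd.DataFrame
    dth: pd.Series
    expected_signs: pd.Series
    year: str | None = None

    @classmethod
    def from_data(cls, codes: pd.DataFrame, dth: pd.Series,
                  expected_signs: pd.Series, year: str | None = None) -> "CodedPanel":
        """Listwise-delete lines with any missing code or missing DTH; genes
        monomorphic in the panel (constant code) are dropped with a warning
        since neither a marginal nor a partial correlation is defined for
        them."""
        monomorphic = [g for g in codes.columns if codes[g].dropna().nunique() <= 1]
        if monomorphic:
            warnings.warn(f"dropping monomorphic gene(s) from the coded panel: "
                          f"{monomorphic}", stacklevel=2)
            codes = codes.drop(columns=monomorphic)
        shared = codes.index.intersection(dth.index)
        df = codes.loc[shared].copy()
        y = dth.loc[shared]
        ok = ~(df.isna().any(axis=1) | y.isna())
        return cls(df.loc[ok], y.loc[ok], expected_signs.reindex(df.columns), year)

    def __post_init__(self) -> None:
        vals = self.codes.to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("activity codes must be 0/1 with no missing values "
                             "(use CodedPanel.from_data for listwise deletion)")
        if not self.codes.index.equals(self.dth.index):
            raise ValueError("codes and dth must share the same line index")

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def genes(self) -> list[str]:
        return list(self.codes.columns)


def point_biserial(code: np.ndarray | pd.Series, y: np.ndarray | pd.Series,
                   ) -> tuple[float, float]:
    """Point-biserial correlation of a binary code with a continuous trait.

    Identical to the Pearson correlation of the 0/1 code with y; the p value
    is two-sided from t = r sqrt((n-2)/(1-r^2)).  Pairs with missing entries
    are deleted; a constant y or an empty code group yields (nan, nan) with a
    warning.
    """
    code = np.asarray(code, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(code) & ~np.isnan(y)
    code, y = code[ok], y[ok]
    if code.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not np.isin(code, (0.0, 1.0)).all():
        raise ValueError("code must be binary 0/1")
    if code.min() == code.max() or np.std(y) == 0:
        warnings.warn("degenerate point-biserial input (one group empty or constant y)",
                      stacklevel=2)
        return np.nan, np.nan
    r, p = stats.pearsonr(code, y)
    return float(r), float(p)


def phi_coefficient(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> float:
    """Phi association of two binary codes from the pairwise-complete 2x2 table:
    phi = (ad - bc)/sqrt((a+b)(c+d)(a+c)(b+d)); NaN on a degenerate margin."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return np.nan
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def phi_matrix(codes: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene phi coefficients (pairwise-complete), diagonal 1."""
    genes = list(codes.columns)
    out = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            out.loc[gi, gj] = out.loc[gj, gi] = phi_coefficient(codes[gi], codes[gj])
    return out


def partial_correlations(panel: CodedPanel) -> pd.DataFrame:
    """Partial correlation of each gene's code with DTH given all other genes.

    Built from the inverse P of the (k+1)x(k+1) Pearson correlation matrix of
    [codes, DTH]: r_partial(i, y | rest) = -P[i,y] / sqrt(P[i,i] P[y,y]).
    Two-sided p from t with df = n - 2 - (k-1) conditioned variables.  A
    singular correlation matrix raises an error naming perfectly collinear
    (phi = +/-1) gene pairs.
    """
    k = len(panel.genes)
    if panel.n <= k + 2:
        raise ValueError(f"need n > k+2 complete lines (n={panel.n}, k={k})")
    constant = [g for g in panel.genes if panel.codes[g].nunique() <= 1]
    if constant or panel.dth.nunique() <= 1:
        raise ValueError(f"constant variable(s) in panel: "
                         f"{constant or ['DTH']}; drop before analysis")
    M = pd.concat([panel.codes, panel.dth.rename("__dth__")], axis=1)
    R = np.corrcoef(M.to_numpy(dtype=float), rowvar=False)
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        phis = phi_matrix(panel.codes)
        bad = [(a, b) for i, a in enumerate(panel.genes) for b in panel.genes[i + 1:]
               if abs(phis.loc[a, b]) > 1 - 1e-12]
        raise ValueError(f"singular correlation matrix; perfectly collinear gene "
                         f"pairs: {bad or 'involving DTH'}")
    iy = k
    df = panel.n - 2 - (k - 1)
    rows = []
    for i, g in enumerate(panel.genes):
        r_p = -P[i, iy] / np.sqrt(P[i, i] * P[iy, iy])
        r_p = float(np.clip(r_p, -1.0, 1.0))
        if abs(r_p) >= 1.0:
            p = 0.0
        else:
            t = r_p * np.sqrt(df / (1.0 - r_p ** 2))
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append((g, r_p, p))
    return pd.DataFrame(rows, columns=["gene", "partial_r", "partial_p"]).set_index("gene")


def holm_adjust(pvalues: np.ndarray | pd.Series, m: int | None = None) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, capped at 1).

    ``m`` defaults to the number of finite p values; NaNs pass through
    unadjusted as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    if m is not None and m > ok.sum():
        # pad the family with p=1 sentinels so multipliers reflect the declared family size
        padded = np.concatenate([p[ok], np.ones(m - ok.sum())])
        out[ok] = multipletests(padded, method="holm")[1][: ok.sum()]
    else:
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def triage(marginal: pd.DataFrame, partial: pd.DataFrame, phis: pd.DataFrame,
           expected_signs: pd.Series, alpha: float = 0.05,
           phi_min: float = 0.25) -> pd.Series:
    """Assign per-gene Type I / Type II triage labels.

    Rules, applied in order on Holm-adjusted significance:

    - ``consistent``: marginal and partial both significant with equal signs;
    - ``type-I-candidate``: marginal significant, partial not, and the gene is
      in LD (max |phi| >= phi_min) with some consistent gene — the marginal
      signal is plausibly borrowed;
    - ``type-II-candidate``: partial significant while marginal is not, or the
      marginal and partial signs differ with the partial matching the gene's
      expected sign and at least nominally significant (raw p < alpha) — the
      marginal analysis masked or flipped a real effect;
    - ``null`` otherwise.
    """
    genes = list(marginal.index)
    sig_m = (marginal["marginal_p_holm"] < alpha).fillna(False)
    sig_p = (partial["partial_p_holm"] < alpha).fillna(False)
    consistent = {
        g for g in genes
        if sig_m[g] and sig_p[g]
        and np.sign(marginal.loc[g, "marginal_r"]) == np.sign(partial.loc[g, "partial_r"])
    }
    labels = {}
    for g in genes:
        r_m = marginal.loc[g, "marginal_r"]
        r_p = partial.loc[g, "partial_r"]
        raw_p_partial = partial.loc[g, "partial_p"]
        if g in consistent:
            labels[g] = "consistent"
            continue
        others = [h for h in consistent if h != g]
        max_phi = max((abs(phis.loc[g, h]) for h in others), default=0.0)
        if sig_m[g] and not sig_p[g] and max_phi >= phi_min:
            labels[g] = "type-I-candidate"
            continue
        sign_flip = np.isfinite(r_m) and np.isfinite(r_p) and r_m * r_p < 0
        partial_matches_expected = np.sign(r_p) == np.sign(expected_signs.get(g, np.nan))
        if (sig_p[g] and not sig_m[g]) or (
                sign_flip and partial_matches_expected and raw_p_partial < alpha):
            labels[g] = "type-II-candidate"
            continue
        labels[g] = "null"
    return pd.Series(labels, name="triage")


def correlation_report(panel: CodedPanel, alpha: float = 0.05,
                       phi_min: float = 0.25) -> pd.DataFrame:
    """Full per-gene report: marginal and partial correlations, Holm-adjusted
    p values (family = the genes in this analysis), phi-based triage labels.

    The result mirrors one year's column block of the published-style
    correlation tables; ``attrs`` carry the phi matrix, year, and complete-case n.
    """
    rows = []
    for g in panel.genes:
        r, p = point_biserial(panel.codes[g], panel.dth)
        rows.append((g, r, p))
    marginal = pd.DataFrame(rows, columns=["gene", "marginal_r", "marginal_p"]).set_index("gene")
    marginal["marginal_p_holm"] = holm_adjust(marginal["marginal_p"].to_numpy())
    partial = partial_correlations(panel)
    partial["partial_p_holm"] = holm_adjust(partial["partial_p"].to_numpy())
    phis = phi_matrix(panel.codes)
    labels = triage(marginal, partial, phis, panel.expected_signs, alpha, phi_min)
    report = pd.concat([panel.expected_signs.rename("expected_sign"),
                        marginal, partial, labels], axis=1)
    # plain dict: pandas attrs must stay hashable-comparable for concat/repr
    report.attrs["phi_matrix"] = phis.to_dict()
    report.attrs["n"] = panel.n
    report.attrs["year"] = panel.year
    return report
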