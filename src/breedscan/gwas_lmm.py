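"""Linear mixed-model association scans with conditional covariate re-scans.

The model is the standard single-kinship LMM

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

fitted by REML through a single eigendecomposition of K and a 1-D search over
the variance ratio lambda = sigma_g^2 / sigma_e^2.  Per-marker tests reuse the
null-model variance components (the P3D/EMMAX approximation; exact per-marker
REML is available behind a flag).  Conditional re-scans add the "peak highest
polymorphism" of another peak as a fixed covariate: a peak whose signal
collapses below the suggestive threshold under conditioning is classified as
an LD shadow of the covariate (the operational false-positive rule), while a
peak that survives reciprocal conditioning is independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel_io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "ScanConfig",
    "AssociationResult",
    "Peak",
    "NullModelFit",
    "compute_kinship",
    "fit_null_model",
    "marker_scan",
    "qq_inflation",
    "detect_peaks",
    "classify_peak",
    "ld_r2",
]

#: Median of the 1-df chi-square distribution, the genomic-control null median.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class KinshipMatrix:
    """Realized-relationship matrix between lines (symmetric, PSD up to tolerance)."""

    values: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape inconsistent with line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if np.linalg.eigvalsh(self.values).min() < -1e-8 * max(1.0, np.abs(self.values).max()):
            raise ValueError("kinship matrix is not PSD up to tolerance")


@dataclass
class ScanConfig:
    """Scan thresholds and clumping parameters."""

    significance_p: float = 5.0e-8
    suggestive_p: float = 1.0e-5
    covariates: list[tuple[int, int]] = field(default_factory=list)
    year: str | None = None
    clump_window: int = 1_000_000
    clump_r2: float = 0.4
    exact_reml: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.significance_p <= self.suggestive_p < 1):
            raise ValueError("need 0 < significance_p <= suggestive_p < 1")
        self.covariates = [_parse_marker(m) for m in self.covariates]

    @property
    def suggestive_neglog10(self) -> float:
        return -np.log10(self.suggestive_p)


def _parse_marker(m) -> tuple[int, int]:
    if isinstance(m, str):
        c, p = m.split(":")
        return int(c), int(p.replace(",", ""))
    c, p = m
    return int(c), int(p)


@dataclass
class AssociationResult:
    """Per-variant scan results plus fit metadata."""

    table: pd.DataFrame  # chrom, pos, beta, se, neglog10p, maf
    lambda_v: float
    n: int
    config: ScanConfig

    def neglog10p(self) -> pd.Series:
        return self.table["neglog10p"]


@dataclass
class Peak:
    """A clumped association peak with its peak-highest polymorphism."""

    chrom: int
    start: int
    end: int
    seed: tuple[int, int]           # (chrom, pos) of the peak-highest polymorphism
    neglog10p_by_year: dict[str, float]
    status: str = "candidate"

    def __post_init__(self) -> None:
        if not (self.start <= self.seed[1] <= self.end and self.seed[0] == self.chrom):
            raise ValueError("peak seed variant must lie inside the peak interval")

    @property
    def max_neglog10p(self) -> float:
        return max(self.neglog10p_by_year.values())


@dataclass
class NullModelFit:
    lambda_v: float
    reml_loglik: float
    sigma_g2: float
    sigma_e2: float
    at_boundary: bool
    eigenvalues: np.ndarray = field(repr=False, default=None)
    eigenvectors: np.ndarray = field(repr=False, default=None)


def compute_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Allele-frequency-centered realized relationship matrix.

    K = Z Z^T / sum_k p_k (1 - p_k) with Z the dosage matrix centered by the
    per-variant alt frequency (inbred 0/1 coding); missing dosages are
    mean-imputed, which leaves them at zero after centering.
    """
    X = G.imputed()
    p = X.mean(axis=0)
    denom = float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all variants monomorphic; kinship undefined")
    Z = X - p
    K = Z @ Z.T / denom
    return KinshipMatrix(K, list(G.line_ids))


def _reml_neg_loglik(log_lambda: float, d: np.ndarray, yt: np.ndarray,
                     Xt: np.ndarray) -> float:
    lam = np.exp(log_lambda)
    w = lam * d + 1.0
    n, p = Xt.shape
    Xw = Xt / np.sqrt(w[:, None])
    yw = yt / np.sqrt(w)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2 = rss / (n - p)
    _, logdet_XtWX = np.linalg.slogdet(XtX)
    _, logdet_XtX = np.linalg.slogdet(Xt.T @ Xt)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + (n - p)
                 + np.sum(np.log(w)) + logdet_XtWX - logdet_XtX)
    return -ll


def fit_null_model(y: np.ndarray, X: np.ndarray, K: KinshipMatrix,
                   bounds: tuple[float, float] = (-10.0, 10.0)) -> NullModelFit:
    """REML fit of the variance ratio lambda = sigma_g^2/sigma_e^2.

    Uses one eigendecomposition K = U D U^T and a bounded 1-D optimization
    over log lambda; an optimum at the search boundary is flagged (typical
    when K carries no usable structure, e.g. K = I).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= rank(X)+2, got n={n}, p={p}")
    d, U = np.linalg.eigh(K.values)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    res = optimize.minimize_scalar(_reml_neg_loglik, bounds=bounds, args=(d, yt, Xt),
                                   method="bounded", options={"xatol": 1e-8})
    log_lam = float(res.x)
    at_boundary = min(log_lam - bounds[0], bounds[1] - log_lam) < 1e-3
    if at_boundary:
        warnings.warn("REML optimum at the lambda search boundary; variance ratio "
                      "is weakly identified", stacklevel=2)
    lam = float(np.exp(log_lam))
    w = lam * d + 1.0
    Xw = Xt / np.sqrt(w[:, None])
    yw = yt / np.sqrt(w)
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    sigma_e2 = float(np.sum((yw - Xw @ beta) ** 2) / (n - p))
    return NullModelFit(lam, -float(res.fun), lam * sigma_e2, sigma_e2, at_boundary,
                        eigenvalues=d, eigenvectors=U)


def reml_loglik(lambda_v: float, y: np.ndarray, X: np.ndarray, K: KinshipMatrix) -> float:
    """REML log-likelihood at a fixed variance ratio (diagnostic helper)."""
    d, U = np.linalg.eigh(K.values)
    d = np.clip(d, 0.0, None)
    return -_reml_neg_loglik(np.log(lambda_v), d, U.T @ np.asarray(y, float),
                             U.T @ np.atleast_2d(np.asarray(X, float)))


def marker_scan(y: np.ndarray | pd.Series, G: GenotypeMatrix, K: KinshipMatrix,
                config: ScanConfig | None = None) -> AssociationResult:
    """Per-marker generalized least squares in the eigenrotated space.

    The variance ratio is estimated once under the null design
    [intercept | covariate markers] and reused for every marker (P3D); each
    marker is then tested by a two-sided t-test with df = n - rank(design).
    Markers collinear with a covariate (|r| > 0.999) and zero-variance
    markers yield missing results.
    """
    config = config or ScanConfig()
    if isinstance(y, pd.Series):
        y = y.loc[list(G.line_ids)].to_numpy()
    y = np.asarray(y, dtype=float)
    n = G.n_lines
    X = G.imputed()
    maf = G.maf()

    cov_cols = []
    for (c, p) in config.covariates:
        try:
            cov_cols.append(G.variant_index(c, p))
        except KeyError:
            raise KeyError(f"covariate marker {c}:{p} absent from genotype matrix")
    X0 = np.column_stack([np.ones(n)] + [X[:, j] for j in cov_cols])

    null = fit_null_model(y, X0, K)
    d, U = null.eigenvalues, null.eigenvectors
    w = null.lambda_v * d + 1.0
    sw = np.sqrt(w)
    yw = (U.T @ y) / sw
    X0w = (U.T @ X0) / sw[:, None]
    Xall_w = (U.T @ X) / sw[:, None]

    p0 = X0.shape[1]
    df = n - p0 - 1
    betas = np.full(G.n_variants, np.nan)
    ses = np.full(G.n_variants, np.nan)
    neglogp = np.full(G.n_variants, np.nan)
    for j in range(G.n_variants):
        m = X[:, j]
        if np.std(m) == 0:
            continue
        collinear = any(
            abs(np.corrcoef(m, X[:, jc])[0, 1]) > 0.999 for jc in cov_cols
            if np.std(X[:, jc]) > 0
        )
        if collinear:
            continue
        if config.exact_reml:
            fit_j = fit_null_model(y, np.column_stack([X0, m]), K)
            wj = fit_j.lambda_v * d + 1.0
            swj = np.sqrt(wj)
            A = np.column_stack([(U.T @ X0) / swj[:, None], (U.T @ m) / swj])
            b = (U.T @ y) / swj
        else:
            A = np.column_stack([X0w, Xall_w[:, j]])
            b = yw
        coef, res_, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < A.shape[1]:
            continue
        resid = b - A @ coef
        sigma2 = float(resid @ resid) / df
        AtA_inv = np.linalg.inv(A.T @ A)
        se = np.sqrt(sigma2 * AtA_inv[-1, -1])
        t = coef[-1] / se
        pval = 2.0 * stats.t.sf(abs(t), df)
        betas[j] = coef[-1]
        ses[j] = se
        with np.errstate(divide="ignore"):
            neglogp[j] = -np.log10(max(pval, 5e-324))
    table = pd.DataFrame({
        "chrom": G.chrom, "pos": G.pos, "beta": betas, "se": ses,
        "neglog10p": neglogp, "maf": maf,
    })
    return AssociationResult(table, null.lambda_v, n, config)


def qq_inflation(result: AssociationResult) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and Q-Q quantile pairs.

    lambda_GC = median of the observed 1-df chi-square deviates divided by the
    null median (~0.4549); the returned table pairs expected and observed
    -log10 P quantiles for plotting.
    """
    neglogp = result.table["neglog10p"].dropna().to_numpy()
    if neglogp.size == 0:
        raise ValueError("no non-missing P values")
    if neglogp.size < 100:
        warnings.warn(f"only {neglogp.size} tested markers; inflation estimate unstable",
                      stacklevel=2)
    pvals = 10.0 ** (-neglogp)
    chi2_obs = stats.chi2.isf(pvals, 1)
    lam = float(np.median(chi2_obs) / CHI2_1DF_MEDIAN)
    m = pvals.size
    obs = np.sort(neglogp)[::-1]
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": expected, "observed": obs})
    return lam, qq


def ld_r2(G: GenotypeMatrix, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Squared Pearson correlation of two variants' dosages over
    pairwise-complete lines (NaN when either is constant or <2 lines remain)."""
    xa = G.calls[:, G.variant_index(*_parse_marker(a))]
    xb = G.calls[:, G.variant_index(*_parse_marker(b))]
    ok = ~np.isnan(xa) & ~np.isnan(xb)
    if ok.sum() < 2 or np.std(xa[ok]) == 0 or np.std(xb[ok]) == 0:
        return np.nan
    r = np.corrcoef(xa[ok], xb[ok])[0, 1]
    return float(r * r)


def ld_matrix(G: GenotypeMatrix, chrom: int, start: int, end: int) -> pd.DataFrame:
    """Pairwise r^2 for all variants in [start, end] on one chromosome."""
    mask = (G.chrom == chrom) & (G.pos >= start) & (G.pos <= end)
    sub = G.subset_variants(mask)
    names = [f"{c}:{p}" for c, p in zip(sub.chrom, sub.pos)]
    out = np.full((sub.n_variants, sub.n_variants), np.nan)
    for i in range(sub.n_variants):
        for j in range(i, sub.n_variants):
            r2 = ld_r2(sub, (sub.chrom[i], sub.pos[i]), (sub.chrom[j], sub.pos[j]))
            out[i, j] = out[j, i] = r2
    return pd.DataFrame(out, index=names, columns=names)


def _clump_one_year(result: AssociationResult, G: GenotypeMatrix,
                    config: ScanConfig) -> list[dict]:
    t = result.table.dropna(subset=["neglog10p"])
    above = t[t["neglog10p"] >= config.suggestive_neglog10].copy()
    clumps = []
    while len(above):
        seed_row = above.loc[above["neglog10p"].idxmax()]
        sc, sp = int(seed_row["chrom"]), int(seed_row["pos"])
        same_chr = above[above["chrom"] == sc]
        member = []
        for idx, row in same_chr.iterrows():
            if abs(row["pos"] - sp) <= config.clump_window:
                member.append(idx)
            else:
                r2 = ld_r2(G, (sc, sp), (int(row["chrom"]), int(row["pos"])))
                if np.isfinite(r2) and r2 >= config.clump_r2:
                    member.append(idx)
        sub = above.loc[member]
        clumps.append({
            "chrom": sc,
            "start": int(sub["pos"].min()),
            "end": int(sub["pos"].max()),
            "seed": (sc, sp),
            "neglog10p": float(seed_row["neglog10p"]),
        })
        above = above.drop(index=member)
    return clumps


def detect_peaks(results_by_year: Mapping[str, AssociationResult],
                 G: GenotypeMatrix, config: ScanConfig | None = None) -> list[Peak]:
    """Greedy clumping of suggestive variants per year, merged across years.

    Per year, the highest -log10 P variant above the suggestive threshold
    seeds a clump absorbing variants within the clump window or in LD
    (r^2 >= cutoff) with the seed; clusters whose intervals overlap in every
    scanned year are marked consistent-across-years.  Output order is by
    (chromosome, interval start), independent of variant input order.
    """
    if not results_by_year:
        raise ValueError("need at least one yearly result")
    config = config or next(iter(results_by_year.values())).config
    per_year = {str(yr): _clump_one_year(res, G, config)
                for yr, res in results_by_year.items()}
    clusters: list[dict] = []
    for yr, clumps in per_year.items():
        for c in clumps:
            for cl in clusters:
                if cl["chrom"] == c["chrom"] and not (
                        c["end"] < cl["start"] or c["start"] > cl["end"]):
                    cl["start"] = min(cl["start"], c["start"])
                    cl["end"] = max(cl["end"], c["end"])
                    cl["by_year"][yr] = max(cl["by_year"].get(yr, -np.inf), c["neglog10p"])
                    if c["neglog10p"] > cl["seed_score"]:
                        cl["seed"], cl["seed_score"] = c["seed"], c["neglog10p"]
                    break
            else:
                clusters.append({"chrom": c["chrom"], "start": c["start"], "end": c["end"],
                                 "seed": c["seed"], "seed_score": c["neglog10p"],
                                 "by_year": {yr: c["neglog10p"]}})
    peaks = []
    all_years = set(str(y) for y in results_by_year)
    for cl in sorted(clusters, key=lambda c: (c["chrom"], c["start"])):
        status = "consistent-across-years" if set(cl["by_year"]) == all_years else "candidate"
        peaks.append(Peak(cl["chrom"], cl["start"], cl["end"], cl["seed"],
                          cl["by_year"], status))
    return peaks


def classify_peak(target: Peak, covariate_peak: Peak, y, G: GenotypeMatrix,
                  K: KinshipMatrix, config: ScanConfig | None = None) -> Peak:
    """Conditional re-scan classification of a peak.

    Re-runs the scan with the covariate peak's peak-highest polymorphism as a
    fixed covariate; the target becomes ``LD-shadow`` if the maximum
    -log10 P inside its interval falls below the suggestive threshold (its
    explanatory potential was removed by the conditioning), else
    ``independent``.
    """
    config = config or ScanConfig()
    cond = replace(config, covariates=list(config.covariates) + [covariate_peak.seed])
    res = marker_scan(y, G, K, cond)
    t = res.table
    in_iv = (t["chrom"] == target.chrom) & (t["pos"] >= target.start) & (t["pos"] <= target.end)
    vals = t.loc[in_iv, "neglog10p"].dropna()
    max_cond = float(vals.max()) if len(vals) else -np.inf
    status = "LD-shadow" if max_cond < config.suggestive_neglog10 else "independent"
    year = str(config.year) if config.year is not None else "conditional"
    return replace(target, status=status,
                   neglog10p_by_year={**target.neglog10p_by_year, year + "|cond": max_cond})
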