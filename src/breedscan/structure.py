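"""Population-structure screen: genotype PCA and PC-vs-trait correlation.

Standard pre-association check for a structured panel: compute principal
components of the (mean-imputed, column-centered) dosage matrix and test
whether leading PCs correlate with the trait; a significant correlation flags
a risk that population structure will confound a naive association scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import GenotypeMatrix
from .corr_partial import holm_adjust

__all__ = ["PcaResult", "pca_scores", "pc_trait_screen"]


@dataclass
class PcaResult:
    scores: pd.DataFrame            # line x component
    explained_variance: np.ndarray  # fraction of total variance per component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_scores(G: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Top principal components of the genotype matrix by SVD.

    Missing dosages are mean-imputed per variant and columns are centered but
    not variance-scaled (the usual genotype-PCA convention). Deterministic up
    to component sign.
    """
    if n_components > min(G.n_lines, G.n_variants):
        raise ValueError("n_components exceeds min(lines, variants)")
    X = G.imputed()
    X = X - X.mean(axis=0)
    total_var = float((X ** 2).sum())
    if total_var == 0:
        raise ValueError("zero-variance genotype matrix; PCA undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    evr = (s ** 2) / total_var
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(pd.DataFrame(scores, index=list(G.line_ids), columns=cols),
                     evr[:n_components])


def pc_trait_screen(pca: PcaResult, pheno: pd.DataFrame, year: str,
                    n_pcs: int = 2, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each leading PC with the trait for one year.

    Returns a per-PC table (r, p, p_holm, significant); attrs carry a
    ``structure_risk`` flag set when any Holm-adjusted p < alpha. A constant
    trait yields r=0, p=1 with a warning.
    """
    ph = pheno[pheno["year"].astype(str) == str(year)].set_index("line")["dth"]
    shared = [l for l in pca.scores.index if l in ph.index]
    if len(shared) < 3:
        raise ValueError(f"need >=3 lines shared between PCA and phenotypes, got {len(shared)}")
    y = ph.loc[shared].to_numpy(dtype=float)
    rows = []
    for pc in pca.scores.columns[:n_pcs]:
        x = pca.scores.loc[shared, pc].to_numpy()
        if np.std(y) == 0 or np.std(x) == 0:
            warnings.warn(f"degenerate (constant) input for {pc}; reporting r=0, p=1",
                          stacklevel=2)
            rows.append((pc, 0.0, 1.0))
        else:
            r, p = stats.pearsonr(x, y)
            rows.append((pc, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["pc", "r", "p"]).set_index("pc")
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    out.attrs["structure_risk"] = bool(out["significant"].any())
    out.attrs["n"] = len(shared)
    out.attrs["year"] = str(year)
    return out
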