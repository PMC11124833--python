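"""Population-structure covariates: genotype PCA and the PC1-sign indicator.

The diversity panel splits into two clusters along the first genotype
principal component.  The association model adjusts for structure with four
fixed covariates: the first three PC scores plus a binary indicator that is
1 when PC1 >= 0 and 0 otherwise — a hard cluster assignment that absorbs
the mean difference between the two groups beyond what the linear PC terms
capture.

PCA is computed on the column-centred dosage matrix (no missing calls
allowed; impute first).  Explained-variance percentages (EVP) are
100 * lambda_i / sum(lambda) over *all* components.  Because a PC's sign is
arbitrary, the loading with the largest absolute value in each component is
made positive, which keeps the indicator reproducible across runs and
libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .genotype import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores (n x k), explained-variance percentages and loadings (m x k)."""

    scores: np.ndarray
    evp: np.ndarray
    loadings: np.ndarray
    sample_ids: list


def compute_pcs(G: GenotypeMatrix, k: int = 3) -> PCAResult:
    """Principal components of the centred genotype dosage matrix.

    Raises :class:`DataError` if the matrix still has missing calls or if
    ``k`` exceeds the matrix rank.
    """
    X = np.asarray(G.calls, dtype=float)
    if np.isnan(X).any():
        raise DataError("genotype matrix has missing calls; impute before PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise DataError(f"requested {k} components but matrix rank is {rank}")
    total = float(np.sum(s ** 2))
    evp = 100.0 * (s[:k] ** 2) / total
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    # fix signs: largest-|loading| entry of each component is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(scores=scores, evp=evp, loadings=loadings,
                     sample_ids=list(G.sample_ids))


def pc1_indicator(pc1_scores) -> np.ndarray:
    """Binary structure indicator: 1 where PC1 >= 0, else 0."""
    pc1 = np.asarray(pc1_scores, dtype=float)
    if np.any(~np.isfinite(pc1)):
        raise DataError("PC1 scores must be finite")
    return (pc1 >= 0.0).astype(int)


def build_cv_matrix(pca: PCAResult) -> pd.DataFrame:
    """Covariate matrix: PC1..PCk scores plus the PC1-sign indicator.

    Returns a DataFrame indexed by sample id with columns ``PC1``..``PCk``
    and ``indicator``.  A constant indicator (single-cluster data) is kept
    in the table but logged; the association design drops constant
    covariate columns before fitting.
    """
    k = pca.scores.shape[1]
    cols = {f"PC{j + 1}": pca.scores[:, j] for j in range(k)}
    indicator = pc1_indicator(pca.scores[:, 0])
    cols["indicator"] = indicator
    if indicator.min() == indicator.max():
        logger.warning("PC1-sign indicator is constant (single-cluster data); "
                       "it is collinear with the intercept and will be dropped "
                       "from the association design")
    return pd.DataFrame(cols, index=pd.Index(pca.sample_ids, name="sample"))


def write_covariates(cv: pd.DataFrame, path) -> None:
    """Write the covariates TSV (sample, PC1..PCk, indicator)."""
    cv.to_csv(path, sep="\t", index=True)
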