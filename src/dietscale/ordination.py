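"""Jaccard PCoA of community composition and covariate vector fitting.

Community composition enters the second-stage models through the first two
axes of a principal coordinates analysis (classical MDS) of the pairwise
Jaccard dissimilarities between community species lists. Environmental
covariates are then regressed onto the two ordination axes to show which
environmental gradients align with compositional turnover (and hence where
collinearity between the environment and community predictor sets arises).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Ordination",
    "jaccard_distance",
    "jaccard_matrix",
    "pcoa",
    "fit_covariate_vectors",
]

logger = logging.getLogger(__name__)


@dataclass
class Ordination:
    """PCoA result.

    ``scores[:, j]`` scales as sqrt(eigenvalue j); only positive-eigenvalue
    axes carry scores. ``negative_fraction`` (|sum of negative eigenvalues|
    over the total absolute sum) is reported as a diagnostic — no
    Lingoes/Cailliez correction is applied.
    """

    eigenvalues: np.ndarray  # all, descending
    scores: pd.DataFrame  # community × positive axes, columns PCoA1..
    axis_variance_fraction: np.ndarray  # per positive axis
    negative_fraction: float


def jaccard_distance(a, b) -> float:
    """Jaccard dissimilarity 1 − |A∩B| / |A∪B| between two presence rows."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence rows must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two empty communities")
    return 1.0 - np.logical_and(a, b).sum() / union

def jaccard_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity from a community × species 0/1 table."""
    M = presence.to_numpy()
    if not np.isin(M, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    if (M.sum(axis=1) == 0).any():
        empty = list(presence.index[M.sum(axis=1) == 0])
        raise ValueError(f"all-zero presence row(s): {empty}")
    D = squareform(pdist(M.astype(bool), metric="jaccard"))
    return pd.DataFrame(D, index=presence.index, columns=presence.index)


def pcoa(distance: pd.DataFrame | np.ndarray, index=None) -> Ordination:
    """Classical principal coordinates analysis of a dissimilarity matrix.

    Gower double-centering of −½ D∘D followed by a symmetric
    eigendecomposition. Axes are ordered by decreasing eigenvalue; axes
    with non-positive eigenvalues are reported through ``eigenvalues`` and
    ``negative_fraction`` but excluded from the scores. Each retained axis
    is oriented so its largest-magnitude score is positive, making signs
    deterministic (published ordinations may be flipped relative to ours).
    """
    if isinstance(distance, pd.DataFrame):
        index = distance.index
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        index = index if index is not None else pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    scores = eigvec[:, pos] * np.sqrt(eigval[pos])
    for j in range(scores.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1.0
    pos_sum = eigval[pos].sum()
    neg = float(-eigval[eigval < -tol].sum())
    frac = eigval[pos] / pos_sum if pos_sum > 0 else np.array([])
    cols = [f"PCoA{j + 1}" for j in range(scores.shape[1])]
    return Ordination(
        eigenvalues=eigval,
        scores=pd.DataFrame(scores, index=index, columns=cols),
        axis_variance_fraction=frac,
        negative_fraction=neg / (neg + pos_sum) if (neg + pos_sum) > 0 else 0.0,
    )


def fit_covariate_vectors(ordination: Ordination, covariates: pd.DataFrame) -> pd.DataFrame:
    """Project environmental covariates onto the first two PCoA axes.

    Each covariate is z-standardized and regressed (least squares) on the
    axis-1/axis-2 scores; the returned direction (dx, dy) is the normalized
    coefficient vector and r² the variance explained. Constant covariates
    get a null direction, r² = 0, and a warning.
    """
    if ordination.scores.shape[0] < 3:
        raise ValueError("vector fitting needs at least 3 communities")
    if ordination.scores.shape[1] < 2:
        raise ValueError("ordination has fewer than 2 positive axes")
    S = ordination.scores[["PCoA1", "PCoA2"]].to_numpy()
    X = np.column_stack([np.ones(S.shape[0]), S])
    rows = []
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            logger.warning("covariate %r is constant; null direction", name)
            rows.append((name, 0.0, 0.0, 0.0))
            continue
        z = (v - v.mean()) / sd
        coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
        fitted = X @ coef
        r2 = float(1.0 - np.sum((z - fitted) ** 2) / np.sum(z**2))
        d = coef[1:]
        nrm = np.linalg.norm(d)
        d = d / nrm if nrm > 0 else d
        rows.append((name, float(d[0]), float(d[1]), r2))
    return pd.DataFrame(rows, columns=["covariate", "dx", "dy", "r2"]).set_index("covariate")
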