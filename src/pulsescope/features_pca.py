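"""Six-variable kinetic feature tables and correlation-matrix PCA.

Each cell is phenotyped by six variables — NPQav, NPQmax, Decay, Induction,
Fmax and AreaFrac.  Because the variables mix units (dimensionless NPQ,
min⁻¹ slopes, arbitrary fluorescence units, percent), each column is
z-scored (mean 0, sample SD 1) before the decomposition, which makes the
PCA a singular value decomposition of the correlation matrix.  Metadata
columns such as genotype or cell type are carried through but never enter
the fit; they only colour the score plots afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photoparams import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "assemble_table",
    "drop_incomplete",
    "standardize",
    "principal_components",
]


@dataclass
class PCAResult:
    """Loadings (orthonormal directions), per-cell scores and explained
    variance percentages, components ordered by decreasing variance."""

    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame  # cells × components
    explained_variance_pct: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def assemble_table(
    features: dict[str, "pd.Series | dict"],
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack per-cell feature Series into a table, joining metadata by cell id."""
    df = pd.DataFrame({k: pd.Series(v) for k, v in features.items()}).T
    df = df[FEATURE_COLUMNS]
    df.index.name = "cell"
    if metadata is not None:
        df = df.join(metadata)
    return df


def drop_incomplete(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with any undefined feature value, logging the count."""
    complete = table[FEATURE_COLUMNS].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d cell(s) with undefined features before PCA", n_dropped)
    return table.loc[complete]


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """z-score each analysis column: subtract the mean, divide by the
    sample (n−1) standard deviation.  Zero-variance columns are an error."""
    columns = columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(table) < 2:
        raise ValueError("standardization requires at least 2 rows")
    out = table.copy()
    for col in columns:
        x = table[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (x - x.mean()) / sd
    return out


def principal_components(
    standardized: pd.DataFrame, columns: list[str] | None = None
) -> PCAResult:
    """PCA of a z-scored table via singular value decomposition.

    The right singular vectors of the z-scored data matrix are the
    eigenvectors of its correlation matrix; eigenvalues are s²/(n−1) and the
    explained-variance percentages are eigenvalues normalised to sum to 100
    (the correlation matrix of p z-scored variables has trace p).  Sign
    convention: each loading's largest-magnitude entry is made positive, so
    output is deterministic.  Rank-deficient input simply yields trailing
    (near-)zero eigenvalues.
    """
    columns = columns or [c for c in FEATURE_COLUMNS if c in standardized.columns]
    X = standardized[columns].to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("missing values must be dropped before PCA")
    if n < p:
        logger.warning("PCA with fewer cells (%d) than variables (%d)", n, p)

    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T  # columns are components
    if loadings.shape[1] < p:  # n < p: pad the null space with zeros
        pad = p - loadings.shape[1]
        loadings = np.hstack([loadings, np.zeros((p, pad))])
        eigenvalues = np.concatenate([eigenvalues, np.zeros(pad)])

    # deterministic sign: largest-magnitude loading entry positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    scores = X @ loadings
    comp_names = [f"PC{i + 1}" for i in range(p)]
    explained = eigenvalues / eigenvalues.sum() * 100.0
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=standardized.index, columns=comp_names),
        explained_variance_pct=explained,
        eigenvalues=eigenvalues,
    )


def plot_scores(
    result: PCAResult,
    path,
    components: tuple[str, str] = ("PC1", "PC2"),
    groups: pd.Series | None = None,
) -> None:
    """Scatter of cell scores on two components, optionally coloured by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cx, cy = components
    fig, ax = plt.subplots()
    if groups is None:
        ax.scatter(result.scores[cx], result.scores[cy], s=15, color="black")
    else:
        for name, idx in result.scores.groupby(groups.reindex(result.scores.index)).groups.items():
            sub = result.scores.loc[idx]
            ax.scatter(sub[cx], sub[cy], s=15, label=str(name))
        ax.legend(frameon=False)
    i, j = int(cx[2:]) - 1, int(cy[2:]) - 1
    ax.set_xlabel(f"{cx} ({result.explained_variance_pct[i]:.1f}%)")
    ax.set_ylabel(f"{cy} ({result.explained_variance_pct[j]:.1f}%)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
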