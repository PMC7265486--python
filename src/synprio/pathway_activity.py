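"""Footprint-style pathway activity scoring.

Pathway weights are fitted gene-by-gene from perturbation z-scores, and
samples are scored by multiplying their expression profiles with the weight
matrix. The default pathway set is the 11 signalling pathways commonly used
with this kind of weight matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_PATHWAYS = (
    "EGFR",
    "NFkB",
    "TGFb",
    "MAPK",
    "p53",
    "TNFa",
    "PI3K",
    "VEGF",
    "Hypoxia",
    "Trail",
    "JAK-STAT",
)


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (log scale assumed)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProgenyWeights:
    """Genes x pathways loading matrix; zeros mean 'not in the signature'."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0:
            raise ValueError("weight matrix must have at least one pathway")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "pathway")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PathwayActivityMatrix:
    """Samples x pathways activity scores."""

    values: pd.DataFrame
    standardized: bool = False
    n_shared_genes: int | None = field(default=None, compare=False)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def perturbation_zscores(
    perturbed: ExpressionMatrix, control: ExpressionMatrix
) -> pd.Series:
    """Per-gene z-score of one perturbation experiment versus its controls.

    z_g = (mean(perturbed_g) - mean(control_g)) / pooled_sd_g, using the
    two-group pooled standard deviation. Genes whose pooled sd is zero get
    z = 0 (a warning reports how many).
    """
    shared = perturbed.values.index.intersection(control.values.index)
    if len(shared) == 0:
        raise ValueError("perturbed and control share no genes")
    if control.values.shape[1] < 2:
        raise ValueError("need at least 2 control samples for a sd estimate")

    p = perturbed.values.loc[shared].to_numpy(dtype=float)
    c = control.values.loc[shared].to_numpy(dtype=float)
    n_p, n_c = p.shape[1], c.shape[1]
    diff = p.mean(axis=1) - c.mean(axis=1)

    ss_p = ((p - p.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_c = ((c - c.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    dof = max(n_p + n_c - 2, 1)
    pooled_sd = np.sqrt((ss_p + ss_c) / dof)

    zero = pooled_sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} genes with zero pooled sd set to z = 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero, 0.0, diff / np.where(zero, 1.0, pooled_sd))
    return pd.Series(z, index=shared, name="zscore")


def fit_progeny_weights(
    zscores: pd.DataFrame, design: pd.DataFrame, top_k: int
) -> ProgenyWeights:
    """Fit pathway weights by per-gene OLS of z-scores on pathway statuses.

    Parameters
    ----------
    zscores
        Genes x experiments matrix of perturbation z-scores.
    design
        Experiments x pathways signed indicator matrix (+1 activated,
        -1 inhibited, 0 untouched). Must be full column rank.
    top_k
        Number of genes retained per pathway, ranked by |t| of the
        coefficient; all other weights are set to exactly 0.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    X = design.to_numpy(dtype=float)
    n_exp, n_path = X.shape
    if zscores.shape[1] != n_exp:
        raise ValueError("zscores columns must match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < n_path:
        # name a minimal set of collinear pathways for the error message
        bad = []
        cols = list(design.columns)
        kept: list[int] = []
        for j in range(n_path):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(cols[j])
            else:
                kept.append(j)
        raise ValueError(f"design is rank-deficient; collinear pathways: {bad}")

    Z = zscores.to_numpy(dtype=float)  # genes x experiments
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Z @ X @ XtX_inv  # genes x pathways

    # per-gene residual variance -> t statistics for coefficient ranking
    resid = Z - B @ X.T
    dof = max(n_exp - n_path, 1)
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B / np.where(se > 0, se, 1.0), np.inf * np.sign(B))

    W = np.zeros_like(B)
    for j in range(n_path):
        order = np.argsort(-np.abs(tstat[:, j]), kind="stable")
        keep = order[: min(top_k, len(order))]
        W[keep, j] = B[keep, j]
    return ProgenyWeights(
        pd.DataFrame(W, index=zscores.index, columns=design.columns)
    )


def score_pathways(
    expr: ExpressionMatrix, weights: ProgenyWeights
) -> PathwayActivityMatrix:
    """Score samples: activities = expression' @ weights over shared genes."""
    shared = weights.values.index.intersection(expr.values.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between expression and weights")
    E = expr.values.loc[shared]  # genes x samples
    W = weights.values.loc[shared]  # genes x pathways
    values = E.T @ W
    return PathwayActivityMatrix(values, standardized=False, n_shared_genes=len(shared))


def standardize_activities(pa: PathwayActivityMatrix) -> PathwayActivityMatrix:
    """Z-score each pathway across samples (ddof=1); idempotent."""
    if pa.values.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    v = pa.values.to_numpy(dtype=float)
    mu = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        names = [c for c, f in zip(pa.values.columns, const) if f]
        warnings.warn(f"constant pathway columns set to 0: {names}", stacklevel=2)
    z = np.where(const, 0.0, (v - mu) / np.where(const, 1.0, sd))
    return replace(
        pa,
        values=pd.DataFrame(z, index=pa.values.index, columns=pa.values.columns),
        standardized=True,
    )
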