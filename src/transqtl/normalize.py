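"""Expression filtering, normalization and covariate construction.

The normalization chain is the consortium-standard one for eQTL mapping:
quantile normalization across samples (each sample is forced onto the mean
empirical distribution), then a per-gene rank-based inverse normal transform
so every gene is marginally standard normal across samples. Hidden expression
factors are estimated as expression principal components — a deliberate,
documented surrogate for PEER that captures the same inter-sample covariance
structure at a fraction of the cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._utils import residualize
from .errors import EmptyResultError, RankDeficiencyError, TransQTLError
from .simulate import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "filter_genes",
    "quantile_normalize",
    "inverse_normal_transform",
    "inverse_normal_rows",
    "build_covariates",
    "residualize_expression",
]


def filter_genes(expr: ExpressionMatrix, min_nonzero_samples: int) -> ExpressionMatrix:
    """Drop genes detected (nonzero) in fewer than ``min_nonzero_samples``.

    Gene order of the survivors is preserved. Raises if nothing survives.
    """
    if min_nonzero_samples < 1:
        raise TransQTLError("min_nonzero_samples must be >= 1")
    nonzero = (expr.values != 0).sum(axis=1)
    keep = nonzero >= min_nonzero_samples
    if not keep.any():
        raise EmptyResultError("no genes pass the detection filter")
    return ExpressionMatrix(values=expr.values.loc[keep].copy(),
                            genes=expr.genes.loc[keep].copy())


def _quantile_normalize_matrix(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean of the column-sorted values."""
    n_rows, _ = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie groups span consecutive reference slots; each member gets the
        # mean of the reference values the group spans
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n_rows]])
        col_out = np.empty(n_rows)
        for s, t in zip(starts, stops):
            col_out[order[s:t]] = reference[s:t].mean()
        out[:, j] = col_out
    return out


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) empirical distribution.

    Columns are samples; the reference distribution is the mean of the
    per-sample sorted values. Ties within a sample receive the mean of the
    reference values they span. The operation is idempotent.
    """
    if expr.values.shape[1] < 2:
        raise TransQTLError("quantile normalization requires at least 2 samples")
    out = _quantile_normalize_matrix(expr.values.to_numpy(dtype=float))
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        genes=expr.genes,
    )


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform of one vector.

    The value with (average, i.e. tie-sharing) rank k maps to
    Phi^-1((k - offset) / (n - 2*offset + 1)); the default Blom offset 3/8
    gives (k - 3/8)/(n + 1/4). Strictly monotone in the input ranks.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise TransQTLError("inverse_normal_transform expects a vector with n >= 2")
    if np.all(x == x[0]):
        raise TransQTLError("all values identical: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2.0 * offset + 1.0))


def inverse_normal_rows(expr: ExpressionMatrix, offset: float = 0.375) -> ExpressionMatrix:
    """Apply the inverse normal transform to every gene across samples."""
    out = np.vstack([
        inverse_normal_transform(row, offset=offset)
        for row in expr.values.to_numpy(dtype=float)
    ])
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        genes=expr.genes,
    )


def build_covariates(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix | None = None,
    n_factors: int = 0,
    n_pcs: int = 0,
    sample_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the covariate matrix used by every association scan.

    Hidden expression factors are the top principal components of the
    (normalized) expression matrix — a documented surrogate for PEER factors.
    Genotype PCs are the top principal components of standardized dosages.
    Categorical sample columns (e.g. sex, study) expand to indicator columns
    with the first level dropped. All columns are centered. Raises
    :class:`RankDeficiencyError`, naming the collinear columns, if the
    intercept-augmented matrix is rank deficient.
    """
    samples = expr.sample_ids
    n = len(samples)
    if n_factors >= n or n_pcs >= n:
        raise TransQTLError("n_factors and n_pcs must be smaller than n_samples")
    blocks: list[pd.DataFrame] = []

    if n_factors > 0:
        mat = expr.values.to_numpy(dtype=float).T  # samples x genes
        scores = PCA(n_components=n_factors, svd_solver="full").fit_transform(mat)
        blocks.append(pd.DataFrame(
            scores, index=samples, columns=[f"factor_{i + 1}" for i in range(n_factors)]
        ))
    if n_pcs > 0:
        if genotypes is None:
            raise TransQTLError("genotype PCs requested but no genotypes supplied")
        dos = genotypes.dosage.loc[samples].to_numpy(dtype=float)
        sd = dos.std(axis=0)
        std = (dos - dos.mean(axis=0))[:, sd > 0] / sd[sd > 0]
        scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(std)
        blocks.append(pd.DataFrame(
            scores, index=samples, columns=[f"geno_pc_{i + 1}" for i in range(n_pcs)]
        ))
    if sample_table is not None:
        aligned = sample_table.loc[samples]
        numeric = aligned.select_dtypes(include=[np.number])
        if not numeric.empty:
            blocks.append(numeric.astype(float))
        categorical = aligned.select_dtypes(exclude=[np.number])
        if not categorical.empty:
            blocks.append(pd.get_dummies(categorical, drop_first=True, dtype=float))

    if blocks:
        covars = pd.concat(blocks, axis=1)
    else:
        covars = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    covars = covars - covars.mean(axis=0)

    if covars.shape[1]:
        design = np.column_stack([np.ones(n), covars.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            _, r = np.linalg.qr(design)
            diag = np.abs(np.diag(r))
            bad = diag < max(design.shape) * np.finfo(float).eps * diag.max()
            names = [covars.columns[i - 1] for i in np.flatnonzero(bad) if i > 0]
            raise RankDeficiencyError("covariate matrix is rank deficient", names)
    covars.index = pd.Index(samples, name="sample_id")
    return covars


def residualize_expression(expr: ExpressionMatrix, covars: pd.DataFrame | None) -> ExpressionMatrix:
    """Residualize every gene on the covariates (plus intercept)."""
    c = None if covars is None or covars.shape[1] == 0 else covars.loc[expr.sample_ids].to_numpy()
    res = residualize(expr.values.to_numpy(dtype=float).T, c).T
    return ExpressionMatrix(
        values=pd.DataFrame(res, index=expr.values.index, columns=expr.values.columns),
        genes=expr.genes,
    )
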