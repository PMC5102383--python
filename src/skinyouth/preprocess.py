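"""Count preprocessing: depth normalization, expression filtering, log2
transform, and empirical-Bayes batch adjustment.

The pipeline starts from a raw gene x sample count matrix (3'-end
sequencing, so one counting unit per transcript and no length
correction) and applies, in order:

1. :func:`normalize_counts` — scale every sample to a common sequencing
   depth of 10 million mapped reads;
2. :func:`filter_expressed` — keep genes whose mean normalized value
   exceeds 2;
3. :func:`log2_transform` — ``log2(x + 1)``;
4. :func:`batch_adjust` — parametric empirical-Bayes location/scale
   batch correction of the log2 matrix (the ComBat model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class EmptySampleError(ValueError):
    """A sample has zero total counts and cannot be depth-normalized."""


class DegenerateBatchError(ValueError):
    """A batch has too few samples for location/scale estimation."""


class ConvergenceError(RuntimeError):
    """The empirical-Bayes fixed-point iteration failed to converge."""


def normalize_counts(m: ExpressionMatrix, target: float = 1e7) -> ExpressionMatrix:
    """Scale each sample so its total count equals ``target`` (default 10M).

    Every value becomes ``count * target / column_total``; afterwards every
    column sums to ``target`` exactly (up to float rounding).
    """
    m.require_stage("raw")
    totals = m.values.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise EmptySampleError(
            f"sample(s) with zero total counts: {', '.join(map(str, empty.index))}"
        )
    out = m.values * (target / totals)
    return m.advance(out, "normalized")


def filter_expressed(m: ExpressionMatrix, min_mean: float = 2.0) -> ExpressionMatrix:
    """Keep genes with row mean strictly greater than ``min_mean``.

    Operates on the normalized (count-scale, not log) matrix; survivor
    order is preserved.  An empty result is allowed but warned about.
    """
    m.require_stage("normalized")
    keep = m.values.mean(axis=1) > min_mean
    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return ExpressionMatrix(m.values.loc[keep], stage=m.stage)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(value + pseudocount)`` (pseudocount 1 so zeros map to 0)."""
    m.require_stage("normalized")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return m.advance(np.log2(m.values + pseudocount), "log2")


@dataclass
class BatchModel:
    """Fitted parameters of the empirical-Bayes batch adjustment.

    ``gamma_star`` and ``delta2_star`` are the shrunken per-batch,
    per-gene location shifts and scale factors (on the standardized
    scale); ``gamma_bar``, ``tau2_bar`` are the normal prior moments and
    ``a_prior``, ``b_prior`` the inverse-gamma prior hyperparameters,
    one per batch.
    """

    batches: list
    gamma_star: pd.DataFrame      # batch x gene
    delta2_star: pd.DataFrame     # batch x gene, all > 0
    gamma_bar: pd.Series
    tau2_bar: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    grand_mean: pd.Series
    pooled_var: pd.Series


def _inverse_gamma_moments(delta_hat: np.ndarray) -> tuple[float, float]:
    # Method-of-moments hyperparameters for the inverse-gamma scale prior.
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    a = (2 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def batch_adjust(
    m: ExpressionMatrix,
    batches,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[ExpressionMatrix, BatchModel | None]:
    """Remove batch effects from a log2 matrix by parametric empirical Bayes.

    Implements the standard location/scale model: per gene the matrix is
    standardized by its (batch-design) grand mean and pooled variance;
    per batch and gene a location shift ``gamma`` and scale ``delta^2``
    are estimated and shrunk toward a per-batch normal and inverse-gamma
    prior (hyperparameters by method of moments, shrinkage solved by
    fixed-point iteration); the shrunken effects are removed and the
    grand mean and pooled variance restored.  Each gene's grand mean is
    preserved exactly by a final per-gene recentering.

    With a single batch the input is returned unchanged (no model).

    Parameters
    ----------
    batches
        Per-sample batch labels, aligned with ``m.sample_ids``.
    tol, max_iter
        Fixed-point stopping rule: maximum relative change below ``tol``
        (default 1e-4), at most ``max_iter`` (default 500) iterations.
    """
    m.require_stage("log2")
    batches = pd.Series(np.asarray(batches), index=m.sample_ids)
    levels = list(pd.unique(batches))
    if len(levels) == 1:
        return m.advance(m.values.copy(), "batch_adjusted"), None

    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DegenerateBatchError(
            f"batch(es) with fewer than 2 samples: {', '.join(map(str, small.index))}"
        )

    X = m.values.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samples = X.shape
    masks = {b: (batches == b).to_numpy() for b in levels}
    n_per = {b: masks[b].sum() for b in levels}

    # Standardize: batch-design fit per gene; weighted grand mean; pooled var.
    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([n_per[b] / n_samples for b in levels])
    alpha = batch_means @ weights
    fitted = np.zeros_like(X)
    for k, b in enumerate(levels):
        fitted[:, masks[b]] = batch_means[:, k][:, None]
    pooled_var = ((X - fitted) ** 2).mean(axis=1)
    if (pooled_var <= 0).any():
        raise DegenerateBatchError("gene(s) with zero within-batch variance")
    sigma = np.sqrt(pooled_var)
    Z = (X - alpha[:, None]) / sigma[:, None]

    gamma_star = np.empty((len(levels), n_genes))
    delta2_star = np.empty((len(levels), n_genes))
    gamma_bar = np.empty(len(levels))
    tau2_bar = np.empty(len(levels))
    a_prior = np.empty(len(levels))
    b_prior = np.empty(len(levels))

    for k, b in enumerate(levels):
        Zb = Z[:, masks[b]]
        n_b = n_per[b]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        gamma_bar[k] = g_hat.mean()
        tau2_bar[k] = g_hat.var(ddof=1)
        a_prior[k], b_prior[k] = _inverse_gamma_moments(d_hat)

        g_new = g_hat.copy()
        d_new = d_hat.copy()
        change = np.inf
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = (n_b * tau2_bar[k] * g_hat + d_old * gamma_bar[k]) / (
                n_b * tau2_bar[k] + d_old
            )
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior[k] + 0.5 * sse) / (n_b / 2 + a_prior[k] - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            if change < tol:
                break
        else:
            raise ConvergenceError(
                f"batch {b!r}: EB fixed point not converged after {max_iter} "
                f"iterations (max residual {change:.3g})"
            )
        gamma_star[k] = g_new
        delta2_star[k] = d_new

    adjusted = Z.copy()
    for k, b in enumerate(levels):
        adjusted[:, masks[b]] = (Z[:, masks[b]] - gamma_star[k][:, None]) / np.sqrt(
            delta2_star[k]
        )[:, None]
    adjusted = adjusted * sigma[:, None] + alpha[:, None]
    # Shrinkage leaves a tiny per-gene offset; recenter so each gene's
    # grand mean is preserved exactly.
    adjusted += (X.mean(axis=1) - adjusted.mean(axis=1))[:, None]

    out = pd.DataFrame(adjusted, index=m.gene_ids, columns=m.sample_ids)
    model = BatchModel(
        batches=levels,
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=m.gene_ids),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=m.gene_ids),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau2_bar=pd.Series(tau2_bar, index=levels),
        a_prior=pd.Series(a_prior, index=levels),
        b_prior=pd.Series(b_prior, index=levels),
        grand_mean=pd.Series(alpha, index=m.gene_ids),
        pooled_var=pd.Series(pooled_var, index=m.gene_ids),
    )
    return m.advance(out, "batch_adjusted"), model


def preprocess_counts(
    m: ExpressionMatrix,
    batches=None,
    target: float = 1e7,
    min_mean: float = 2.0,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Run the full raw -> batch-adjusted chain with the standard defaults."""
    m = filter_expressed(normalize_counts(m, target=target), min_mean=min_mean)
    m = log2_transform(m, pseudocount=pseudocount)
    if batches is not None:
        m, _ = batch_adjust(m, batches)
    return m
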