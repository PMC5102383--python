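"""Per-gene linear models with empirical-Bayes moderated t-statistics.

Each gene is regressed on a single covariate (chronological age, or a
binary youthful/non-youthful indicator on age-residualized expression)
by OLS with intercept.  The gene-wise residual variances s_g^2 are then
shrunk toward a common prior: assuming s_g^2 | sigma_g^2 ~
sigma_g^2 * chi^2_d / d and sigma_g^2 ~ s0^2 * d0 / chi^2_{d0}, the
prior (d0, s0^2) is estimated by moment matching on log s_g^2, the
posterior variance is the weighted average
s~^2 = (d0*s0^2 + d*s^2) / (d0 + d), and the moderated t
beta / sqrt(v * s~^2) is referred to a Student t with d0 + d degrees of
freedom.  This is the standard variance-moderation approach for small-
sample expression studies; p-values are two-sided and multiplicity is
handled by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix


class InsufficientGenesError(ValueError):
    """Too few genes with positive residual variance to estimate the prior."""


class InsufficientGroupError(ValueError):
    """A comparison group has fewer than the minimum number of samples."""


@dataclass
class GeneFits:
    """Vectorized per-gene OLS results for one covariate.

    ``beta`` is the covariate coefficient per gene (log2 units per year
    for age, log2 difference for a binary contrast), ``v`` the unscaled
    coefficient variance (the covariate's diagonal element of
    (X'X)^-1, identical across genes), ``s2`` the residual variance and
    ``df`` the residual degrees of freedom.  Genes with s2 == 0 (exact
    fits) are flagged and excluded from prior estimation.
    """

    gene_ids: pd.Index
    beta: np.ndarray
    v: float
    s2: np.ndarray
    df: int

    @property
    def zero_variance(self) -> np.ndarray:
        return self.s2 <= 0


@dataclass
class ModerationPrior:
    """Estimated prior degrees of freedom and variance (d0 may be inf)."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_2 > 0):
            raise ValueError("prior df and variance must be positive")


def fit_gene_models(m: ExpressionMatrix, covariate) -> GeneFits:
    """OLS of every gene on an intercept plus one covariate.

    ``covariate`` is a per-sample numeric vector (e.g. age) or binary
    indicator, aligned with ``m.sample_ids``.
    """
    m.require_stage("log2", "batch_adjusted")
    x = np.asarray(covariate, dtype=float)
    n = m.shape[1]
    if x.shape != (n,):
        raise ValueError(f"covariate length {x.shape} does not match {n} samples")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant covariate: singular design")

    Y = m.values.to_numpy(dtype=float)  # genes x samples
    xc = x - x.mean()
    sxx = float(xc @ xc)
    beta = (Y @ xc) / sxx
    resid = Y - Y.mean(axis=1, keepdims=True) - beta[:, None] * xc[None, :]
    df = n - 2
    s2 = (resid**2).sum(axis=1) / df
    return GeneFits(gene_ids=m.gene_ids, beta=beta, v=1.0 / sxx, s2=s2, df=df)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(fits: GeneFits, min_genes: int = 10) -> ModerationPrior:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Works on e_g = log s_g^2 - digamma(d/2) + log(d/2), whose mean and
    excess variance over trigamma(d/2) identify the prior.  If the
    log-variances are no more dispersed than sampling alone explains,
    d0 is infinite (complete pooling at s0^2 = exp(mean e)).
    """
    s2 = fits.s2[~fits.zero_variance]
    G = s2.size
    if G < min_genes:
        raise InsufficientGenesError(
            f"only {G} genes with positive residual variance (need {min_genes})"
        )
    d = fits.df
    e = np.log(s2) - special.digamma(d / 2.0) + math.log(d / 2.0)
    ebar = float(e.mean())
    excess = float(e.var(ddof=0) * G / (G - 1) - special.polygamma(1, d / 2.0))
    if excess <= 0:
        # log-variances no more dispersed than sampling noise: complete
        # pooling at the mean observed variance
        return ModerationPrior(d0=math.inf, s0_2=float(s2.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_2=s0_2)


def moderated_test(fits: GeneFits, prior: ModerationPrior) -> pd.DataFrame:
    """Moderated t-test for every gene under the given variance prior.

    Returns a DataFrame indexed by gene id with columns ``beta``,
    ``log2fc`` (alias of beta, the log2 fold-change reading), ``t``,
    ``p``, ``direction``.  Genes flagged as zero-variance get NaN t and
    p (untestable rather than infinitely significant).
    """
    d0, s0_2 = prior.d0, prior.s0_2
    d = fits.df
    if math.isinf(d0):
        s2_post = np.full_like(fits.s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + d * fits.s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.beta / np.sqrt(fits.v * s2_post)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    bad = fits.zero_variance
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    out = pd.DataFrame(
        {
            "beta": fits.beta,
            "log2fc": fits.beta,
            "t": t,
            "p": p,
            "direction": np.where(fits.beta >= 0, "up", "down"),
        },
        index=fits.gene_ids,
    )
    out.index.name = "gene_id"
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(table: pd.DataFrame) -> pd.DataFrame:
    ok = table["p"].notna()
    fdr = np.full(len(table), np.nan)
    fdr[ok.to_numpy()] = bh_adjust(table.loc[ok, "p"])
    table = table.assign(fdr=fdr)
    return table.sort_values("p")


def detect_age_genes(
    m: ExpressionMatrix, ages, fdr: float = 0.01
) -> tuple[list, list, pd.DataFrame]:
    """Genes whose expression changes with chronological age.

    Fits every gene on age, moderates, BH-adjusts, and splits genes with
    adjusted p below ``fdr`` by coefficient sign.  Returns (up ids,
    down ids, full result table sorted by p).
    """
    fits = fit_gene_models(m, ages)
    table = _finalize(moderated_test(fits, estimate_prior(fits)))
    hits = table[table["fdr"] < fdr]
    up = hits.index[hits["beta"] > 0].tolist()
    down = hits.index[hits["beta"] < 0].tolist()
    return up, down, table


def residualize_on_age(m: ExpressionMatrix, ages) -> ExpressionMatrix:
    """Replace each gene's values by its residuals from OLS on age.

    The residual matrix is the "relative expression" on which the
    youthfulness contrast is tested: it removes each gene's ordinary
    chronological-age trend before comparing groups.
    """
    m.require_stage("log2", "batch_adjusted")
    x = np.asarray(ages, dtype=float)
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant age vector: singular design")
    Y = m.values.to_numpy(dtype=float)
    xc = x - x.mean()
    beta = (Y @ xc) / float(xc @ xc)
    resid = Y - Y.mean(axis=1, keepdims=True) - beta[:, None] * xc[None, :]
    return ExpressionMatrix(
        pd.DataFrame(resid, index=m.gene_ids, columns=m.sample_ids), stage=m.stage
    )


def detect_sy_genes(
    m: ExpressionMatrix,
    ages,
    classes,
    p_cut: float = 0.01,
    residualize_on: str = "groups",
) -> tuple[list, list, pd.DataFrame]:
    """Genes associated with the skin-youthful phenotype.

    Restricted to SY and non-SY samples, expression is first
    residualized on chronological age, then each gene's residuals are
    regressed on the binary SY indicator with variance moderation.
    Genes are called at UNADJUSTED p below ``p_cut`` (the convention for
    this contrast; the BH-adjusted column is still reported).

    ``residualize_on='all'`` fits the age regression on every sample in
    the matrix before subsetting; the default ``'groups'`` fits it on
    the compared samples only.
    """
    classes = pd.Series(np.asarray(classes, dtype=object), index=m.sample_ids)
    sy = classes == "SY"
    nonsy = classes == "non-SY"
    if sy.sum() < 2 or nonsy.sum() < 2:
        raise InsufficientGroupError(
            f"need >=2 samples per group (SY={int(sy.sum())}, non-SY={int(nonsy.sum())})"
        )
    if residualize_on == "all":
        resid = residualize_on_age(m, ages)
        sub = ExpressionMatrix(resid.values.loc[:, (sy | nonsy)], stage=resid.stage)
    else:
        keep = sy | nonsy
        sub = ExpressionMatrix(m.values.loc[:, keep], stage=m.stage)
        sub = residualize_on_age(sub, np.asarray(ages, dtype=float)[keep.to_numpy()])
    indicator = (classes[sub.sample_ids] == "SY").astype(float).to_numpy()
    fits = fit_gene_models(sub, indicator)
    table = _finalize(moderated_test(fits, estimate_prior(fits)))
    hits = table[table["p"] < p_cut]
    up = hits.index[hits["beta"] > 0].tolist()
    down = hits.index[hits["beta"] < 0].tolist()
    return up, down, table
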