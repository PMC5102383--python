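"""Synthetic cohort and 3'-seq count-matrix generator with ground truth.

Emulates the structure of the study data the pipeline is designed for:
women aged 18-89 rated for apparent skin age by several blinded
clinicians, with the spread of ``delta`` (chronological age minus skin
age score) growing with age; a latent per-subject "youthfulness" drives
both the phenotype and a set of responsive genes, so that downstream
phenotype classification and differential expression can be tested
against known truth.

Counts follow a negative-binomial model: per gene a log2 baseline, an
age slope for age-responsive genes, a group shift for youthfulness
genes, an additive batch shift, and a log-normal library-size factor
per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass
class SimulationConfig:
    """Parameters of the cohort and count simulator.

    Defaults reproduce the study's design: 122 subjects aged 18-89,
    four clinician raters, delta whose mean and spread grow with age,
    ~5000 genes with 100 age-responsive and 50 youthfulness-responsive
    genes, two sequencing batches, and overdispersed counts.
    """

    n_subjects: int = 122
    age_range: tuple[float, float] = (18.0, 89.0)
    n_raters: int = 4
    rater_sd: float = 4.0          # years; clinician disagreement
    delta_slope: float = 0.1       # years of delta per year of age
    delta_noise_base: float = 1.0  # years; delta spread at age 0
    delta_noise_age: float = 0.08  # years per year; growth of delta spread
    n_genes: int = 5000
    n_age_genes: int = 100
    n_sy_genes: int = 50
    age_effect_log2_per_year: float = 0.02
    sy_effect_log2: float = 2.0
    nb_dispersion: float = 0.1     # NB variance = mu + disp * mu^2
    n_batches: int = 2
    batch_shift_log2: float = 0.5
    libsize_log_mean: float = 0.0  # log of the relative depth factor
    libsize_log_sd: float = 0.3
    sy_top_fraction: float = 0.10  # fraction of the >=50 stratum that is truly SY
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_raters <= 0:
            raise InvalidConfigError("n_subjects and n_raters must be positive")
        if self.n_genes <= 0 or self.n_batches <= 0:
            raise InvalidConfigError("n_genes and n_batches must be positive")
        if self.n_age_genes + self.n_sy_genes > self.n_genes:
            raise InvalidConfigError("n_age_genes + n_sy_genes exceeds n_genes")
        if min(self.rater_sd, self.delta_noise_base, self.delta_noise_age) < 0:
            raise InvalidConfigError("standard deviations must be non-negative")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise InvalidConfigError("age_range must satisfy low < high")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery testing.

    ``age_gene_signs`` / ``sy_gene_signs`` map gene id -> +1/-1 effect
    direction; ``true_sy_subjects`` are the subjects with the largest
    latent youthfulness among those aged >= 50; ``true_r_delta`` is the
    latent youthfulness contribution to delta, in years.
    """

    age_gene_signs: dict = field(default_factory=dict)
    sy_gene_signs: dict = field(default_factory=dict)
    true_sy_subjects: set = field(default_factory=set)
    true_r_delta: pd.Series = field(default_factory=pd.Series)


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate subject metadata and per-rater skin-age scores.

    Ages are uniform over ``age_range``.  A latent standard-normal
    youthfulness ``u`` enters the true skin-age score scaled by the
    age-dependent noise sd, so delta = slope*age + u*(base + coef*age):
    its spread widens with age and the top-``u`` subjects aged >= 50 are
    the recoverable true-SY set.  Rater scores are the true score plus
    independent normal error, rounded to whole years and clamped to
    [18, 100].  Covariates (BMI, smoking, prior skin cancer, lifetime UV
    score) are drawn independently of ``u`` so group balance holds by
    construction.

    Returns the cohort table (one row per subject) and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = _subject_ids(n)

    lo, hi = config.age_range
    # ages recorded in whole years, uniform over the range
    ages = rng.integers(int(lo), int(hi), size=n, endpoint=True).astype(float)
    u = rng.normal(0.0, 1.0, size=n)
    noise_sd = config.delta_noise_base + config.delta_noise_age * ages
    true_sas = ages - config.delta_slope * ages - u * noise_sd

    scores = true_sas[:, None] + rng.normal(0.0, config.rater_sd, size=(n, config.n_raters))
    scores = np.clip(np.rint(scores), 18, 100).astype(int)

    latent = u * noise_sd  # the latent contribution to delta, in years
    # Noise-free ground-truth phenotype: the residual of the true delta
    # on age over all subjects — exactly what the scoring recovers when
    # rater noise is zero.  (Raw u is not recoverable: the age-dependent
    # scale and the fitted line's tilt reorder subjects.)
    A = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(A, latent, rcond=None)
    true_r = latent - A @ coef
    eligible = np.where(ages >= 50)[0]
    n_sy = math.ceil(config.sy_top_fraction * len(eligible)) if len(eligible) else 0
    order = eligible[np.argsort(-true_r[eligible], kind="stable")]
    true_sy = {ids[i] for i in order[:n_sy]}

    cohort = pd.DataFrame(
        {
            "subject_id": ids,
            "age": ages,
            "batch": [f"B{(i % config.n_batches) + 1}" for i in range(n)],
            "bmi": np.clip(rng.normal(25.0, 3.5, size=n), 17.0, 40.0),
            "smoking": rng.random(n) < 0.35,
            "skin_cancer": rng.random(n) < 0.28,
            "uv_score": rng.lognormal(3.5, 0.8, size=n),
        }
    )
    for r in range(config.n_raters):
        cohort[f"rater_{r + 1}"] = scores[:, r]
    cohort = cohort.set_index("subject_id", drop=False)

    truth = GroundTruth(
        true_sy_subjects=true_sy,
        true_r_delta=pd.Series(true_r, index=ids, name="true_r_delta"),
    )
    return cohort, truth


def generate_counts(
    cohort: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Simulate the raw count matrix for a cohort, planting effect genes.

    For gene g and sample j the log2 mean is
    ``baseline_g + sign_g * age_effect * (age_j - mean age) [age gene]
    + sign_g * sy_effect * [j in true SY] [SY gene]
    + batch_shift * [batch_j is the second batch, etc.]``;
    counts are negative binomial around ``2**log2mean`` scaled by a
    log-normal library-size factor.  Dispersion 0 degenerates to the
    rounded expected count.  Age is centered at the cohort mean so
    planting an age slope does not move the overall expression level.

    The planted gene ids and signs are recorded in ``truth`` (mutated in
    place) and the matrix is tagged ``stage='raw'``.
    """
    config.validate()
    if len(cohort) == 0:
        raise InvalidConfigError("cohort is empty")
    # independent stream from the cohort's: offset the seed
    rng = np.random.default_rng((config.seed + 1_000_003) % 2**31)

    genes = _gene_ids(config.n_genes)
    n_g, n_s = config.n_genes, len(cohort)
    ages = cohort["age"].to_numpy(dtype=float)
    age_c = ages - ages.mean()
    is_sy = cohort["subject_id"].isin(truth.true_sy_subjects).to_numpy()

    # log2 baselines spanning the observed 3'-seq dynamic range; with
    # ~5000 genes this puts per-sample totals near real sequencing depth
    baseline = rng.uniform(2.0, 14.0, size=n_g)
    # Effect genes are drawn from below the top quintile of abundance:
    # differential transcripts are a tiny share of real library mass, and
    # at scaled-down gene counts planting effects on the most abundant
    # genes would distort every other gene through depth normalization —
    # a compositional regime the real study never operates in.
    n_effect = config.n_age_genes + config.n_sy_genes
    eligible_genes = np.argsort(baseline)[: max(int(0.8 * n_g), n_effect)]
    picks = rng.choice(eligible_genes, size=n_effect, replace=False)
    age_idx = picks[: config.n_age_genes]
    sy_idx = picks[config.n_age_genes :]
    age_sign = rng.choice([-1.0, 1.0], size=config.n_age_genes)
    sy_sign = rng.choice([-1.0, 1.0], size=config.n_sy_genes)
    truth.age_gene_signs = {genes[i]: int(s) for i, s in zip(age_idx, age_sign)}
    truth.sy_gene_signs = {genes[i]: int(s) for i, s in zip(sy_idx, sy_sign)}

    log2mu = np.tile(baseline[:, None], (1, n_s))
    log2mu[age_idx, :] += (
        config.age_effect_log2_per_year * age_sign[:, None] * age_c[None, :]
    )
    log2mu[sy_idx, :] += config.sy_effect_log2 * sy_sign[:, None] * is_sy[None, :]

    # Gene-specific batch shifts (sd = batch_shift_log2, first batch as
    # reference): a shift common to all genes would be a pure depth
    # effect that normalization removes, not a batch effect.
    batch_codes = pd.Categorical(cohort["batch"]).codes
    if config.n_batches > 1 and config.batch_shift_log2 > 0:
        shifts = np.zeros((n_g, config.n_batches))
        shifts[:, 1:] = rng.normal(
            0.0, config.batch_shift_log2, size=(n_g, config.n_batches - 1)
        )
        log2mu += shifts[:, batch_codes]

    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_s)
    mu = np.exp2(log2mu) * libsize[None, :]

    if config.nb_dispersion == 0:
        counts = np.rint(mu)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    values = pd.DataFrame(counts, index=genes, columns=cohort["subject_id"])
    values.columns.name = None
    return ExpressionMatrix(values, stage="raw")


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, ExpressionMatrix, GroundTruth]:
    """Convenience wrapper: cohort + counts + completed ground truth."""
    cohort, truth = generate_cohort(config)
    counts = generate_counts(cohort, truth, config)
    return cohort, counts, truth
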