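"""Skin-youthfulness phenotype: SAS, delta, residual-of-delta, classes.

The quantitative phenotype is built in three steps.  Each subject's
skin age score (SAS) is the median of blinded clinician ratings; delta
is chronological age minus SAS (positive means the skin looks younger
than the calendar age); and because the spread of delta grows with age,
delta is regressed on chronological age over the whole cohort and the
residual, ``r_delta``, is the age-corrected youthfulness measure.

Among subjects aged >= 50 the top decile of ``r_delta`` is labeled SY
(skin-youthful) and the lower half non-SY; subjects under 30 form the
"young" positive-control group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class MissingScoresError(ValueError):
    """No rater scores available for a subject."""


class SingularDesignError(ValueError):
    """The delta-on-age regression is not identifiable."""


#: Phenotype class labels.
CLASSES = ("young", "mid-age", "SY", "non-SY", "unclassified")


@dataclass
class DeltaRegressionFit:
    """OLS fit of delta on chronological age over all subjects."""

    intercept: float
    slope: float
    residuals: pd.Series
    n_fit: int


def aggregate_sas(rater_scores) -> float:
    """Median of the rater scores (midpoint of the central pair for even counts)."""
    scores = np.asarray(rater_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        raise MissingScoresError("no finite rater scores")
    return float(np.median(scores))


def compute_delta(ca: float, sas: float) -> float:
    """Delta = chronological age minus skin age score, in years."""
    if not (np.isfinite(ca) and np.isfinite(sas)):
        raise ValueError("age and SAS must be finite")
    if sas <= 0:
        raise ValueError("SAS must be positive")
    return float(ca) - float(sas)


def fit_delta_regression(ages, deltas) -> DeltaRegressionFit:
    """OLS of delta on chronological age with intercept, over all subjects.

    The residuals are the ``r_delta`` phenotype.  Requires at least 3
    subjects with at least two distinct ages.
    """
    ages = pd.Series(np.asarray(ages, dtype=float)) if not isinstance(ages, pd.Series) else ages.astype(float)
    deltas = pd.Series(np.asarray(deltas, dtype=float), index=ages.index) if not isinstance(deltas, pd.Series) else deltas.astype(float)
    if len(ages) < 3:
        raise SingularDesignError("need at least 3 subjects")
    if ages.nunique() < 2:
        raise SingularDesignError("all ages identical; slope not identifiable")
    X = sm.add_constant(ages.to_numpy())
    fit = sm.OLS(deltas.to_numpy(), X).fit()
    resid = pd.Series(fit.resid, index=ages.index, name="r_delta")
    return DeltaRegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        residuals=resid,
        n_fit=len(ages),
    )


def classify_subjects(
    assignments: pd.DataFrame,
    sy_top_fraction: float = 0.10,
    nonsy_lower_fraction: float = 0.50,
    sy_age_min: float = 50.0,
    young_age_max: float = 30.0,
    nonsy_within_stratum: bool = True,
) -> pd.DataFrame:
    """Assign phenotype classes from ``r_delta`` and age.

    Subjects younger than ``young_age_max`` are "young"; those between
    ``young_age_max`` and ``sy_age_min`` are "mid-age".  Within the
    eligible stratum (age >= ``sy_age_min``, inclusive) the
    ``ceil(sy_top_fraction * m)`` subjects with the highest ``r_delta``
    are "SY" (ties broken by subject id for determinism) and subjects at
    or below the ``nonsy_lower_fraction`` quantile of ``r_delta`` are
    "non-SY"; the rest are "unclassified".

    ``nonsy_within_stratum=False`` computes the lower-half cutoff from
    the whole cohort's ``r_delta`` distribution instead of the eligible
    stratum (the two readings of "lower 50% of individuals").
    """
    df = assignments.copy()
    if "r_delta" not in df or df["r_delta"].isna().any():
        raise ValueError("r_delta must be populated for every subject")

    cls = pd.Series("unclassified", index=df.index, dtype=object)
    cls[df["age"] < young_age_max] = "young"
    cls[(df["age"] >= young_age_max) & (df["age"] < sy_age_min)] = "mid-age"

    eligible = df.index[df["age"] >= sy_age_min]
    if len(eligible) == 0:
        warnings.warn("no subjects at or above the SY age minimum", stacklevel=2)
        df["class"] = cls
        return df

    n_sy = math.ceil(sy_top_fraction * len(eligible))
    # rank by r_delta descending; boundary ties broken by index (subject id)
    ranked = df.loc[eligible, "r_delta"].sort_index().sort_values(
        ascending=False, kind="stable"
    )
    sy_ids = ranked.index[:n_sy]

    pool = df.loc[eligible, "r_delta"] if nonsy_within_stratum else df["r_delta"]
    cutoff = pool.quantile(nonsy_lower_fraction, interpolation="linear")
    nonsy_ids = [i for i in eligible if df.at[i, "r_delta"] <= cutoff and i not in set(sy_ids)]

    cls[eligible] = "unclassified"
    cls[nonsy_ids] = "non-SY"
    cls[sy_ids] = "SY"
    df["class"] = cls
    return df


def assign_phenotypes(
    cohort: pd.DataFrame,
    rater_columns=None,
    **classify_kwargs,
) -> tuple[pd.DataFrame, DeltaRegressionFit]:
    """Full phenotype pass over a cohort table.

    Computes SAS (median of the rater columns), delta, fits the
    delta-on-age regression over all subjects, and classifies.  Returns
    the assignment table (subject_id, age, SAS, delta, r_delta, class)
    and the regression fit.
    """
    if rater_columns is None:
        rater_columns = [c for c in cohort.columns if c.startswith("rater_")]
    if not rater_columns:
        raise MissingScoresError("no rater score columns found")
    sas = cohort[rater_columns].median(axis=1)
    delta = cohort["age"].astype(float) - sas
    fit = fit_delta_regression(cohort["age"], delta)
    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"]
            if "subject_id" in cohort
            else cohort.index,
            "age": cohort["age"].astype(float),
            "SAS": sas,
            "delta": delta,
            "r_delta": fit.residuals,
        },
        index=cohort.index,
    )
    return classify_subjects(out, **classify_kwargs), fit
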