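"""Leisure-walking outcome scoring and random-intercept association models.

The outcome is self-reported leisure walking time per week, reconstructed
from two questionnaire categories by

    minutes/week = duration (h) x 60 (min/h) x frequency (per day) x 7 (day/week)

with fixed per-category weights.  The association between walking time and
each of five neighbourhood greenery indices (overall green visibility and the
four elevation bands) is estimated one index at a time with a linear
mixed-effects model carrying a random intercept at the school-district level:

    Model A: index + age group + gender
    Model B: Model A + marital status + education + family size
             + working status + alcohol consumption
             + population density + number of urban parks

Models are fitted by maximum likelihood (not REML) so AIC values are
comparable across fixed-effect specifications; the index coefficient is
reported with a Wald 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "OutcomeCodebook",
    "ModelResult",
    "walking_minutes_per_week",
    "complete_case_filter",
    "fit_association",
    "fit_table",
    "MODEL_A_COVARIATES",
    "MODEL_B_COVARIATES",
    "INDEX_COLUMNS",
]


class CodebookError(KeyError):
    """Unknown questionnaire category label."""


@dataclass(frozen=True)
class OutcomeCodebook:
    """Per-category weights for the walking-time formula.

    Duration categories carry average hours per activity; frequency
    categories carry average activities per day.
    """

    duration_hours: dict[str, float] = field(default_factory=lambda: {
        "<30min": 0.25,
        "30min-1h": 0.75,
        "1-<2h": 1.5,
        "2-<3h": 2.5,
        "3-<4h": 3.5,
        ">=4h": 4.0,
    })
    frequency_per_day: dict[str, float] = field(default_factory=lambda: {
        "almost none": 0.0,
        "<1/month": 0.5 / 30,
        "1-3/month": 2.0 / 30,
        "1-2/week": 1.5 / 7,
        "3-4/week": 3.5 / 7,
        "almost every day": 1.0,
    })

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.duration_hours.values()):
            raise ValueError("duration weights must be non-negative")
        if any(v < 0 for v in self.frequency_per_day.values()):
            raise ValueError("frequency weights must be non-negative")

    def grid(self) -> pd.DataFrame:
        """Every achievable (duration, frequency, minutes/week) combination."""
        rows = [
            (d, f, dh * 60.0 * fw * 7.0)
            for d, dh in self.duration_hours.items()
            for f, fw in self.frequency_per_day.items()
        ]
        return pd.DataFrame(rows, columns=["duration_cat", "frequency_cat",
                                           "minutes_per_week"])


def walking_minutes_per_week(
    duration_cat: str, frequency_cat: str, codebook: OutcomeCodebook | None = None
) -> float:
    """Score one participant's leisure walking time in minutes per week."""
    codebook = codebook or OutcomeCodebook()
    try:
        dur = codebook.duration_hours[duration_cat]
    except KeyError:
        raise CodebookError(f"unknown duration category {duration_cat!r}") from None
    try:
        freq = codebook.frequency_per_day[frequency_cat]
    except KeyError:
        raise CodebookError(f"unknown frequency category {frequency_cat!r}") from None
    return dur * 60.0 * freq * 7.0


MODEL_A_COVARIATES = ["age_group", "gender"]
MODEL_B_COVARIATES = MODEL_A_COVARIATES + [
    "marital", "education", "family_size", "working", "alcohol",
    "population_density_per_km2", "n_parks",
]
_CATEGORICAL = {
    "age_group": "20s",
    "gender": "male",
    "marital": "married",
    "education": "high school",
    "alcohol": "never",
    "working": False,
}
INDEX_COLUMNS = ["overall_pct", "band1_pct", "band2_pct", "band3_pct", "band4_pct"]


def complete_case_filter(
    cohort: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop rows with any missing model variable.

    Returns the filtered table and the per-variable count of rows in which
    that variable was missing (a row may be counted under several variables).
    Raises if nothing survives.
    """
    variables = variables or [c for c in cohort.columns if c != "participant_id"]
    sub = cohort[variables]
    removed_per_var = sub.isna().sum()
    kept = cohort[~sub.isna().any(axis=1)]
    if kept.empty:
        raise ValueError("complete-case filter removed every row")
    return kept, removed_per_var


@dataclass(frozen=True)
class ModelResult:
    """One index x one specification: slope in minutes/week per index point."""

    index_name: str
    model: str
    beta: float
    ci95_lo: float
    ci95_hi: float
    aic: float
    n_used: int
    random_intercept_sd: float
    converged: bool = True
    singular: bool = False

    def __post_init__(self) -> None:
        if not self.ci95_lo <= self.beta <= self.ci95_hi:
            raise ValueError("CI must bracket the point estimate")


def _formula(index_name: str, covariates: list[str],
             outcome_col: str = "walking_min_per_week",
             data: pd.DataFrame | None = None) -> str:
    terms = [index_name]
    for cov in covariates:
        if cov in _CATEGORICAL:
            ref = _CATEGORICAL[cov]
            if data is not None and ref not in set(data[cov]):
                # configured reference absent from this sample: fall back to
                # the most frequent observed level
                ref = data[cov].mode().iloc[0]
            terms.append(f"C({cov}, Treatment({ref!r}))")
        elif cov == "population_density_per_km2":
            # scaled to thousands per km^2 for numeric conditioning
            terms.append("I(population_density_per_km2 / 1000.0)")
        else:
            terms.append(cov)
    return f"{outcome_col} ~ " + " + ".join(terms)


def fit_association(
    cohort: pd.DataFrame,
    index_name: str,
    model_spec: str = "A",
    group_col: str = "district_id",
    outcome_col: str = "walking_min_per_week",
) -> ModelResult:
    """Fit one greenery index against walking time with a district random
    intercept; ML fit, Wald 95% CI.

    The five indices are always fitted separately, one model per index.
    """
    if model_spec not in ("A", "B"):
        raise ValueError("model_spec must be 'A' or 'B'")
    covariates = MODEL_A_COVARIATES if model_spec == "A" else MODEL_B_COVARIATES
    need = [outcome_col, index_name, group_col] + covariates
    data = cohort.dropna(subset=[c for c in need if c in cohort.columns])
    missing_cols = [c for c in need if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort table lacks columns {missing_cols}")
    if data[group_col].nunique() < 2:
        raise ValueError("need at least 2 districts for a random intercept")
    if np.isclose(float(data[index_name].var()), 0.0):
        raise ValueError(f"index {index_name} has zero variance")

    model = smf.mixedlm(
        _formula(index_name, covariates, outcome_col, data), data,
        groups=data[group_col],
    )
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)

    beta = float(res.fe_params[index_name])
    ci = res.conf_int().loc[index_name]
    # AIC for the ML fit: fixed effects + random-intercept variance + residual
    k = len(res.fe_params) + 2
    aic = float(-2.0 * res.llf + 2.0 * k)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    return ModelResult(
        index_name=index_name,
        model=model_spec,
        beta=beta,
        ci95_lo=float(ci[0]),
        ci95_hi=float(ci[1]),
        aic=aic,
        n_used=len(data),
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        converged=bool(res.converged),
        singular=bool(np.asarray(res.cov_re).ravel()[0] < 1e-8),
    )


def fit_table(
    cohort: pd.DataFrame,
    model_spec: str = "A",
    index_names: list[str] | None = None,
) -> pd.DataFrame:
    """Fit every greenery index separately and tabulate the results."""
    index_names = index_names or INDEX_COLUMNS
    rows = []
    for name in index_names:
        r = fit_association(cohort, name, model_spec)
        rows.append({
            "index": name, "model": r.model, "beta": r.beta,
            "ci95_lo": r.ci95_lo, "ci95_hi": r.ci95_hi,
            "aic": r.aic, "n_used": r.n_used,
            "random_intercept_sd": r.random_intercept_sd,
            "singular": r.singular,
        })
    return pd.DataFrame(rows)
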