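"""Random-intercept and hybrid (between/within) linear mixed models.

The longitudinal association between a window-aggregated keystroke cluster
X and a clinical outcome Y (NHPT seconds or SDMT points) is estimated with
a linear mixed model with a subject-level random intercept,

    Y_ij = beta_0 + beta_1 * X_ij + covariates + u_i + e_ij .

Because the overall beta_1 entangles differences across subjects with
changes within subjects over time, a hybrid model splits the predictor by
person-mean centering: X̄_i is the subject's mean across modeled visits and
d_ij = X_ij − X̄_i the per-visit deviation, giving

    Y_ij = beta_0 + beta_between * X̄_i + beta_within * d_ij + ... + u_i + e_ij .

For the SDMT outcome an additional crossed random intercept over the
measurement occasion (M0...M12) absorbs occasion-common practice effects.
Estimation is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`
with Wald 95% CIs.  Reporting helpers compute the proportional reduction in
total variance relative to the intercept-only model ("explained variance"),
the 10%-change-in-estimate covariate relevance rule, and effects rescaled
per 1 SD of the predictor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

VISIT_LABELS = ("M0", "M3", "M6", "M9", "M12")
EDUCATION_LEVELS = ("low", "middle", "high")


class ModelFitError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


# ---------------------------------------------------------------------------
# visit table preparation
# ---------------------------------------------------------------------------

NHPT_TRIAL_COLUMNS = ["nhpt_trial_1", "nhpt_trial_2", "nhpt_trial_3", "nhpt_trial_4"]


def prepare_visit_table(raw_visits: pd.DataFrame, nhpt_outlier_s: float = 40.0) -> pd.DataFrame:
    """Build the analysis visit table from raw clinical records.

    The NHPT score is the mean of the four trial times (two per hand);
    averaged scores above ``nhpt_outlier_s`` seconds (default 40) are set
    missing as implausible outliers and counted in
    ``result.attrs["nhpt_outliers_removed"]`` /
    ``attrs["nhpt_scores_total"]``.  ``days_since_baseline`` is computed
    from each subject's earliest visit date.  Education is coded as an
    unordered three-level factor (low/middle/high).
    """
    visits = raw_visits.copy()
    if all(c in visits.columns for c in NHPT_TRIAL_COLUMNS):
        trials = visits[NHPT_TRIAL_COLUMNS].astype(float)
        n_missing = trials.isna().any(axis=1) & ~trials.isna().all(axis=1)
        if n_missing.any():
            logger.warning(
                "%d visits have fewer than 4 NHPT trials; NHPT set missing", int(n_missing.sum())
            )
        visits["nhpt_s"] = trials.mean(axis=1, skipna=False)
    elif "nhpt_s" not in visits.columns:
        raise ValueError("raw visits need 4 NHPT trial columns or a precomputed nhpt_s")
    visits["nhpt_s"] = visits["nhpt_s"].astype(float)

    present = visits["nhpt_s"].notna()
    outlier = present & (visits["nhpt_s"] > nhpt_outlier_s)
    visits.loc[outlier, "nhpt_s"] = np.nan
    visits.attrs["nhpt_scores_total"] = int(present.sum())
    visits.attrs["nhpt_outliers_removed"] = int(outlier.sum())
    if outlier.any():
        logger.info(
            "NHPT outlier filter (> %.0f s): removed %d of %d scores",
            nhpt_outlier_s,
            int(outlier.sum()),
            int(present.sum()),
        )

    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    baseline = visits.groupby("subject_id")["visit_date"].transform("min")
    visits["days_since_baseline"] = (visits["visit_date"] - baseline).dt.days
    if "education" in visits.columns:
        visits["education"] = pd.Categorical(visits["education"], categories=EDUCATION_LEVELS)
    if "sdmt_score" in visits.columns:
        visits["sdmt_score"] = visits["sdmt_score"].astype(float)
    return visits


# ---------------------------------------------------------------------------
# hybrid decomposition
# ---------------------------------------------------------------------------


def hybrid_decompose(
    data: pd.DataFrame, value_col: str, subject_col: str = "subject_id"
) -> pd.DataFrame:
    """Person-mean centering: split a predictor into X̄_i and d_ij = X_ij − X̄_i.

    The subject mean is taken over the rows supplied (i.e. the modeled
    visits only).  Deviations sum to zero within every subject by
    construction; a single-visit subject has deviation 0.  Returns a copy
    with ``{value_col}_between`` and ``{value_col}_within`` columns.
    """
    out = data.copy()
    mean = out.groupby(subject_col)[value_col].transform("mean")
    out[f"{value_col}_between"] = mean
    out[f"{value_col}_within"] = out[value_col] - mean
    return out


# ---------------------------------------------------------------------------
# mixed-model fitting
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    """Fixed effects and variance components of one fitted mixed model."""

    label: str
    params: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    pvalues: pd.Series
    variance_components: dict
    total_variance: float
    n_subjects: int
    n_observations: int
    converged: bool = True
    dropped_terms: tuple = ()
    explained_variance_pct: float | None = None

    def beta(self, term: str) -> float:
        return float(self.params[term])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.conf_int.loc[term]
        return float(row["lower"]), float(row["upper"])


def _build_formula(outcome: str, terms: list[str], data: pd.DataFrame) -> str:
    rhs = []
    for t in terms:
        if t in data.columns and (
            data[t].dtype == object or isinstance(data[t].dtype, pd.CategoricalDtype)
        ):
            rhs.append(f"C({t})")
        else:
            rhs.append(t)
    return f"{outcome} ~ " + (" + ".join(rhs) if rhs else "1")


def fit_random_intercept_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed_effects: list[str] | tuple[str, ...] = (),
    group: str = "subject_id",
    occasion_effect: bool = False,
    occasion_col: str = "visit_label",
    label: str | None = None,
) -> MixedModelResult:
    """REML fit of a linear mixed model with a subject random intercept.

    ``fixed_effects`` are column names; string/categorical columns enter as
    unordered factors.  With ``occasion_effect=True`` (the SDMT practice-
    effect adjustment) a crossed random intercept over ``occasion_col`` is
    added via variance components.  Missing rows are dropped per
    observation (complete-case by row).  The total variance is the sum of
    all random-effect variances and the residual variance.
    """
    cols = [outcome, group, *fixed_effects] + ([occasion_col] if occasion_effect else [])
    d = data[list(dict.fromkeys(cols))].dropna().copy()
    if d[group].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    formula = _build_formula(outcome, list(fixed_effects), d)
    for c in d.columns:
        # plain strings keep patsy from emitting columns for unused levels
        if isinstance(d[c].dtype, pd.CategoricalDtype):
            d[c] = d[c].astype(str)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if occasion_effect:
            d["_all"] = 1
            model = sm.MixedLM.from_formula(
                formula,
                groups="_all",
                vc_formula={"subject": f"0 + C({group})", "occasion": f"0 + C({occasion_col})"},
                data=d,
            )
        else:
            model = sm.MixedLM.from_formula(formula, groups=group, data=d)
        res = None
        for method in (["lbfgs"], ["bfgs"], ["powell"], ["nm"], ["cg"]):
            try:
                cand = model.fit(reml=True, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res is None:
                res = cand
            if cand.converged:
                res = cand
                break
        if res is None or not res.converged:
            raise ModelFitError(f"mixed model did not converge: {formula}")
        if occasion_effect:
            vc = {
                "subject_var": float(res.vcomp[model.exog_vc.names.index("subject")]),
                "occasion_var": float(res.vcomp[model.exog_vc.names.index("occasion")]),
                "residual_var": float(res.scale),
            }
        else:
            vc = {
                "subject_var": float(res.cov_re.iloc[0, 0]),
                "residual_var": float(res.scale),
            }

    fe_names = list(res.fe_params.index)
    ci = res.conf_int().loc[fe_names]
    ci.columns = ["lower", "upper"]
    return MixedModelResult(
        label=label or formula,
        params=res.fe_params,
        conf_int=ci,
        pvalues=res.pvalues.loc[fe_names],
        variance_components=vc,
        total_variance=float(sum(vc.values())),
        n_subjects=int(d[group].nunique()),
        n_observations=len(d),
        converged=bool(res.converged),
    )


def fit_hybrid_lmm(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | tuple[str, ...] = (),
    group: str = "subject_id",
    occasion_effect: bool = False,
    occasion_col: str = "visit_label",
    label: str | None = None,
) -> MixedModelResult:
    """Hybrid mixed model with between- and within-subject predictor terms.

    The person-mean decomposition is computed on the modeled rows only
    (those with both outcome and predictor present).  If the predictor is
    constant within every subject the within term is inestimable: the
    deviation column is dropped, flagged in ``result.dropped_terms``.
    """
    need = [outcome, predictor, group, *covariates] + (
        [occasion_col] if occasion_effect else []
    )
    d = data[list(dict.fromkeys(need))].dropna().copy()
    d = hybrid_decompose(d, predictor, group)
    between, within = f"{predictor}_between", f"{predictor}_within"
    terms = [between, within]
    dropped: tuple = ()
    if np.allclose(d[within].to_numpy(), 0.0):
        logger.warning("predictor constant within every subject; within term dropped")
        terms = [between]
        dropped = (within,)
    res = fit_random_intercept_lmm(
        d,
        outcome,
        [*terms, *covariates],
        group=group,
        occasion_effect=occasion_effect,
        occasion_col=occasion_col,
        label=label or f"hybrid: {outcome} ~ {predictor}",
    )
    res.dropped_terms = dropped
    return res


# ---------------------------------------------------------------------------
# reporting arithmetic
# ---------------------------------------------------------------------------


def explained_variance(v_model: float, v_intercept_only: float) -> float:
    """Percent reduction in total variance relative to the intercept-only model.

    ``100 * (V0 - V) / V0``.  Negative values (model variance above the
    intercept-only variance) are allowed with a warning.
    """
    if v_intercept_only <= 0:
        raise ValueError("intercept-only variance must be positive")
    pct = 100.0 * (v_intercept_only - v_model) / v_intercept_only
    if pct < 0:
        logger.warning("explained variance negative (%.1f%%)", pct)
    return pct


def covariate_relevance(
    beta_crude: float, beta_adjusted: float, threshold: float = 0.10
) -> tuple[bool, float]:
    """Change-in-estimate rule: covariates are relevant confounders iff the
    effect estimate changes by ``threshold`` (default 10%) or more.

    Returns ``(relevant, relative_change)``.  With a zero crude estimate
    the rule is undefined; the covariates are then conservatively flagged
    relevant (with NaN change) and a warning issued.
    """
    if beta_crude == 0:
        logger.warning("crude estimate is zero; covariate relevance undefined")
        return True, float("nan")
    change = abs(beta_adjusted - beta_crude) / abs(beta_crude)
    return bool(change >= threshold), float(change)


def sd_scaled_effect(beta: float, sd_of_predictor: float) -> float:
    """Effect per 1-SD change of the predictor (full precision)."""
    if sd_of_predictor < 0:
        raise ValueError("sd must be nonnegative")
    return beta * sd_of_predictor


def format_scaled_effect(value: float) -> float:
    """Reporting precision for SD-scaled effects: one decimal, two when |v| < 1."""
    return round(value, 2 if abs(value) < 1 else 1)
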