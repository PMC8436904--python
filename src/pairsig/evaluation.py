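"""Model evaluation: time-dependent ROC/AUC, Youden cutoff, risk groups,
survival comparison, independence analysis and clinicopathological
association tests.

The ROC at horizon t uses the cumulative-case / dynamic-control construction
with Kaplan-Meier censoring correction: cases are subjects with an event by
t, controls are subjects event-free past t, and both operating
characteristics are estimated from subset Kaplan-Meier curves so that with no
censoring before t the curve reduces exactly to the empirical ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .stattests import rank_sum_test, significance_stars
from .survival import KMCurve, fit_cox, km_estimate, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class ROCCurve:
    horizon: float
    thresholds: np.ndarray  # descending; +inf / -inf sentinels at the ends
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    # raw inputs retained so the cutoff step can fit its two-group Cox model
    scores: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC out of [0,1]: {self.auc}")


@dataclass
class CutoffResult:
    cutoff: float
    youden: float
    sensitivity: float
    specificity: float
    aic: float | None = None


def _align_scores(scores, clinical: pd.DataFrame):
    scores = pd.Series(scores)
    missing = [s for s in clinical["sample_id"] if s not in scores.index]
    if missing:
        raise ValidationError(f"scores missing for samples: {missing[:5]}")
    s = scores.loc[list(clinical["sample_id"])].to_numpy(float)
    return s, clinical["time"].to_numpy(float), clinical["event"].to_numpy(int)


def time_dependent_roc(scores, clinical: pd.DataFrame, t: float) -> ROCCurve:
    """Cumulative/dynamic ROC at horizon ``t`` with KM censoring correction.

    sensitivity(c) = (1 - S(t | score > c)) P(score > c) / (1 - S(t))
    specificity(c) =      S(t | score <= c) P(score <= c) / S(t)

    with the conditional survival curves estimated by Kaplan-Meier on the
    score-defined subsets.  Raw estimates are clipped to [0, 1] and made
    monotone along the threshold sweep.
    """
    s, time, event = _align_scores(scores, clinical)
    if not np.any((event == 1) & (time <= t)):
        raise ValidationError("horizon precedes first event")
    if not np.any(time > t):
        raise ValidationError(f"no subjects at risk after t={t}")
    S_t = km_estimate(time, event).survival_at(t)
    if S_t <= 0 or S_t >= 1:
        raise ValidationError(f"degenerate overall survival S(t)={S_t} at t={t}")

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1], [-np.inf]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, c in enumerate(thresholds):
        hi = s > c
        p_hi = hi.mean()
        if p_hi == 0:
            sens[i] = 0.0
        else:
            S_hi = km_estimate(time[hi], event[hi]).survival_at(t)
            sens[i] = (1.0 - S_hi) * p_hi / (1.0 - S_t)
        if p_hi == 1:
            spec[i] = 0.0
        else:
            S_lo = km_estimate(time[~hi], event[~hi]).survival_at(t)
            spec[i] = S_lo * (1.0 - p_hi) / S_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # KM subset estimates can be locally non-monotone; repair along the sweep
    sens = np.maximum.accumulate(sens)
    spec = np.minimum.accumulate(spec)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(
        horizon=t,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        scores=s,
        time=time,
        event=event,
    )


def optimal_cutoff(roc: ROCCurve) -> CutoffResult:
    """Threshold maximising the Youden index (sens + spec - 1).

    Ties go to the candidate with higher sensitivity.  If the curve retains
    its raw inputs, the AIC of the implied two-group Cox model is reported.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValidationError("ROC curve has no finite thresholds")
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    best = best[np.argmax(sens[best])]
    cutoff = float(thr[best])

    aic = None
    if roc.scores is not None:
        grp = (roc.scores > cutoff).astype(float)
        if 0 < grp.sum() < len(grp):
            fit = fit_cox(grp, roc.time, roc.event, names=["high_risk"])
            if not fit.flagged:
                aic = fit.aic
    return CutoffResult(
        cutoff=cutoff,
        youden=float(youden[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        aic=aic,
    )


def assign_groups(scores, cutoff: float) -> pd.Series:
    """'high' iff score strictly exceeds the cutoff, else 'low'."""
    scores = pd.Series(scores)
    return pd.Series(
        np.where(scores.to_numpy(float) > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


def compare_groups_survival(
    groups: pd.Series, clinical: pd.DataFrame
) -> tuple[dict[str, KMCurve], float, float]:
    """KM curves per risk group plus the two-group log-rank test."""
    g = groups.loc[list(clinical["sample_id"])].to_numpy()
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 risk groups, got {list(labels)}")
    time = clinical["time"].to_numpy(float)
    event = clinical["event"].to_numpy(int)
    curves = {
        str(lbl): km_estimate(time[g == lbl], event[g == lbl]) for lbl in labels
    }
    chi2, p = logrank_test(time, event, g)
    return curves, chi2, p


_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def encode_covariate(series: pd.Series) -> pd.Series:
    """Ordinal numeric coding for a clinical covariate.

    Numeric columns pass through; roman-numeral stages map I-IV -> 1-4;
    labels with a trailing digit (T1, N0, M1...) use that digit; anything
    else falls back to sorted-category codes.
    """
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    vals = series.astype(str)
    if vals.isin(_ROMAN).all():
        return vals.map(_ROMAN).astype(float)
    if vals.str.match(r"^[A-Za-z]+\d+$").all():
        return vals.str.extract(r"(\d+)$")[0].astype(float)
    cats = sorted(vals.unique())
    return vals.map({c: i for i, c in enumerate(cats)}).astype(float)


def independence_analysis(
    scores,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "stage", "T", "N", "M"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Does the risk score predict survival independently of the clinic?

    Returns (univariate table, multivariate table): one Cox model per
    covariate (risk score entered continuously, categoricals coded
    ordinally), then a single joint model over all of them.
    """
    s, time, event = _align_scores(scores, clinical)
    design = {"risk_score": s}
    for cov in covariates:
        if cov not in clinical.columns:
            logger.warning("independence_analysis: covariate %s absent; skipped", cov)
            continue
        design[cov] = encode_covariate(clinical[cov]).to_numpy()
    rows = []
    for name, col in design.items():
        fit = fit_cox(col, time, event, names=[name])
        row = fit.summary().iloc[0].to_dict()
        row["flagged"] = fit.flagged
        rows.append(row)
    uni = pd.DataFrame(rows)

    names = list(design.keys())
    X = np.column_stack([design[n] for n in names])
    if len(names) >= 2:
        corr = np.corrcoef(X.T)
        dup = np.argwhere(np.triu(np.abs(corr) > 0.999, k=1))
        for i, j in dup:
            logger.warning(
                "independence_analysis: covariates %s and %s are collinear",
                names[i], names[j],
            )
    multi_fit = fit_cox(X, time, event, names=names)
    multi = multi_fit.summary()
    multi["flagged"] = multi_fit.flagged
    return uni, multi


def association_tests(
    groups: pd.Series,
    scores,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "stage", "T", "N", "M"),
) -> pd.DataFrame:
    """Risk group vs clinicopathological category associations.

    Chi-square (no continuity correction) on each group x category
    contingency table, flagging expected counts below 5; for two-level
    covariates the risk scores themselves are also compared across the
    covariate's groups with a Wilcoxon rank-sum test.
    """
    g = groups.loc[list(clinical["sample_id"])].to_numpy()
    s = pd.Series(scores).loc[list(clinical["sample_id"])].to_numpy(float)
    rows = []
    for cov in covariates:
        if cov not in clinical.columns:
            continue
        cats = clinical[cov].astype(str).to_numpy()
        table = pd.crosstab(g, cats)
        if table.shape[0] < 2 or table.shape[1] < 2:
            logger.warning("association_tests: %s has a degenerate table; skipped", cov)
            continue
        chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append(
            {
                "covariate": cov,
                "test": "chi2",
                "statistic": float(chi2),
                "p": float(p),
                "stars": significance_stars(p),
                "low_expected": bool((expected < 5).any()),
            }
        )
        levels = np.unique(cats)
        if len(levels) == 2:
            u, p_u = rank_sum_test(s[cats == levels[0]], s[cats == levels[1]])
            rows.append(
                {
                    "covariate": cov,
                    "test": "ranksum",
                    "statistic": u,
                    "p": p_u,
                    "stars": significance_stars(p_u),
                    "low_expected": False,
                }
            )
    return pd.DataFrame(rows)
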