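"""Prognostic pair selection and the risk score.

Selection runs in three stages, mirroring a frequency-counting penalized
workflow: (1) univariate Cox screen at p < 0.05; (2) repeated cross-validated
LASSO-Cox -- each cycle reassigns folds at random, picks the penalty
minimising mean cross-validated partial-likelihood deviance (lambda_min) and
records which pairs carry nonzero coefficients; pairs whose occurrence
frequency strictly exceeds ``freq_thresh`` go forward; (3) a multivariate Cox
fit with backward stepwise elimination on AIC.  The risk score of a sample is
the exact linear combination ``sum_i coef_i * E_i`` over the model's pair
indicators.

The penalized solver is scikit-survival's coordinate-descent Coxnet; the
contract fixed here (lasso path over a log-spaced penalty grid, lambda_min by
CV deviance) keeps backends interchangeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .errors import ValidationError
from .pairs import PairMatrix
from .survival import CoxFit, cox_loglik_path, fit_cox

logger = logging.getLogger(__name__)

# solver tolerance: selection sets are stable well above this, and fold fits
# dominate the repeated-selection runtime
_COXNET_TOL = 1e-5


@dataclass
class SelectionResult:
    """Occurrence frequency of each pair over the LASSO cycles."""

    frequencies: dict[str, int]
    n_cycles: int
    lambda_rule: str = "lambda_min_cv_deviance"

    @property
    def no_signal(self) -> bool:
        return all(f == 0 for f in self.frequencies.values())


@dataclass
class SignatureModel:
    """Ordered pairs with multivariate Cox coefficients; maps E(i) -> score."""

    pair_ids: list[str]
    coef: np.ndarray
    fit: CoxFit
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        ci = self.fit.ci95
        return {
            "pairs": [
                {
                    "pair_id": pid,
                    "coef": float(self.coef[i]),
                    "hr": float(self.fit.hr[i]),
                    "hr_ci95": [float(ci[i, 0]), float(ci[i, 1])],
                    "p": float(self.fit.p[i]),
                }
                for i, pid in enumerate(self.pair_ids)
            ],
            "aic": self.fit.aic,
            "loglik": self.fit.loglik,
            "provenance": self.provenance,
        }


def _align(pm: PairMatrix, clinical: pd.DataFrame):
    """Samples x pairs design matrix aligned to the clinical table order."""
    missing = [s for s in clinical["sample_id"] if s not in pm.values.columns]
    if missing:
        raise ValidationError(f"samples absent from pair matrix: {missing[:5]}")
    X = pm.values[list(clinical["sample_id"])].to_numpy().T.astype(float)
    return X, clinical["time"].to_numpy(float), clinical["event"].to_numpy(int)


def univariate_screen(
    pm: PairMatrix, clinical: pd.DataFrame, p_thresh: float = 0.05
) -> list[str]:
    """Pairs whose single-covariate Cox Wald p is strictly below ``p_thresh``.

    Separation-flagged fits are excluded; a constant pair (which the 20%
    filter should have removed) raises a ValidationError naming it.
    """
    X, time, event = _align(pm, clinical)
    kept = []
    for idx, pid in enumerate(pm.pair_ids):
        col = X[:, idx]
        if col.std() == 0:
            raise ValidationError(f"constant pair {pid!r}; run filter_pairs first")
        fit = fit_cox(col, time, event, names=[pid])
        if fit.flagged:
            logger.warning("univariate_screen: pair %s flagged (separation); excluded", pid)
            continue
        if fit.p[0] < p_thresh:
            kept.append(pid)
    return kept


def _fold_labels(rng, n: int, n_folds: int, event: np.ndarray) -> np.ndarray:
    """Random fold assignment; every training set must contain an event."""
    for _ in range(100):
        folds = rng.permutation(np.arange(n) % n_folds)
        ok = all(event[folds != f].sum() > 0 for f in range(n_folds))
        if ok:
            return folds
    raise ValidationError("could not build folds with events in every training set")


def repeated_lasso(
    pm: PairMatrix,
    clinical: pd.DataFrame,
    n_cycles: int = 1000,
    n_folds: int = 10,
    freq_thresh: int = 100,
    seed: int = 0,
    n_lambdas: int = 100,
    resample: str = "folds",
) -> tuple[SelectionResult, list[str]]:
    """Frequency-counting LASSO-Cox over repeated random fold assignments.

    Each cycle: fresh fold labels -> per-fold lasso path at a common penalty
    grid -> cross-validated deviance by the Verweij-van Houwelingen partial
    likelihood difference -> lambda_min -> pairs with nonzero full-data
    coefficients at lambda_min get a count.  ``resample="bootstrap"`` instead
    refits the full path on a bootstrap resample each cycle (sensitivity
    analysis).  Deterministic given ``seed``.
    """
    if resample not in ("folds", "bootstrap"):
        raise ValidationError(f"unknown resample mode {resample!r}")
    if len(pm.pair_ids) < 2:
        raise ValidationError("repeated_lasso needs at least 2 screened pairs")
    X, time, event = _align(pm, clinical)
    n = len(time)
    if event.sum() < n_folds:
        raise ValidationError(
            f"need at least n_folds={n_folds} events, got {int(event.sum())}"
        )
    freqs = {pid: 0 for pid in pm.pair_ids}
    if n_cycles == 0:
        return SelectionResult(freqs, 0), []

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    base = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_lambdas, alpha_min_ratio=0.01,
        fit_baseline_model=False, tol=_COXNET_TOL,
    )
    base.fit(X, y)
    alphas = np.asarray(base.alphas_)
    full_coefs = np.asarray(base.coef_)  # (p, n_alphas)

    rng = np.random.default_rng(seed)
    pair_ids = np.array(pm.pair_ids)
    for _cycle in range(n_cycles):
        if resample == "bootstrap":
            idx = rng.integers(0, n, size=n)
            if event[idx].sum() == 0:
                continue
            boot = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, tol=_COXNET_TOL
            )
            try:
                boot.fit(X[idx], Surv.from_arrays(event[idx].astype(bool), time[idx]))
            except (ValueError, ArithmeticError):
                continue
            cv_ll = cox_loglik_path(X, time, event, np.asarray(boot.coef_))
            best = int(np.argmax(cv_ll))
            chosen = pair_ids[np.abs(np.asarray(boot.coef_)[:, best]) > 1e-10]
        else:
            folds = _fold_labels(rng, n, n_folds, event)
            cv_ll = np.zeros(len(alphas))
            for f in range(n_folds):
                tr = folds != f
                model = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, alphas=alphas, fit_baseline_model=False,
                    tol=_COXNET_TOL,
                )
                try:
                    model.fit(X[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]))
                except (ValueError, ArithmeticError):
                    continue
                B = np.asarray(model.coef_)
                if B.shape[1] != len(alphas):  # solver truncated the path
                    pad = np.zeros((B.shape[0], len(alphas)))
                    pad[:, : B.shape[1]] = B
                    B = pad
                ll_all = cox_loglik_path(X, time, event, B)
                ll_tr = cox_loglik_path(X[tr], time[tr], event[tr], B)
                cv_ll += ll_all - ll_tr
            best = int(np.argmax(cv_ll))
            chosen = pair_ids[np.abs(full_coefs[:, best]) > 1e-10]
        for pid in chosen:
            freqs[pid] += 1

    result = SelectionResult(freqs, n_cycles)
    selected = [pid for pid in pm.pair_ids if freqs[pid] > freq_thresh]
    if result.no_signal:
        logger.warning("repeated_lasso: no pair ever selected (no signal)")
    return result, selected


def _drop_collinear(X: np.ndarray, names: list[str]):
    """Greedily drop columns until the centred design has full column rank."""
    keep, dropped = [], []
    Xc = X - X.mean(axis=0, keepdims=True)
    for j in range(X.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(Xc[:, cand], tol=1e-8) == len(cand):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        logger.warning("fit_signature: dropped collinear pair(s): %s", dropped)
    return keep, dropped


def fit_signature(
    pm: PairMatrix, clinical: pd.DataFrame, selected_pairs: list[str]
) -> SignatureModel:
    """Multivariate Cox on the selected pairs, backward-eliminated on AIC.

    Collinear or separation-causing pairs are dropped with a warning before
    the stepwise loop.  With a single input pair the AIC step is a no-op.
    """
    if not selected_pairs:
        raise ValidationError("no pairs selected; cannot fit a signature")
    sub = PairMatrix(pm.values.loc[selected_pairs])
    X, time, event = _align(sub, clinical)
    names = list(selected_pairs)
    keep, _ = _drop_collinear(X, names)
    names = [names[j] for j in keep]
    X = X[:, keep]

    def fit_set(cols: list[str], warm: CoxFit | None = None) -> CoxFit:
        idx = [names.index(c) for c in cols]
        beta0 = None
        if warm is not None and not warm.flagged:
            lookup = dict(zip(warm.names, warm.beta))
            beta0 = np.array([lookup.get(c, 0.0) for c in cols])
        return fit_cox(X[:, idx], time, event, names=cols, beta0=beta0)

    current = list(names)
    fit = fit_set(current)
    while fit.flagged and len(current) > 1:
        worst = current[int(np.argmax(np.abs(fit.beta)))]
        logger.warning("fit_signature: dropping separating pair %s", worst)
        current.remove(worst)
        fit = fit_set(current)

    # backward stepwise on AIC
    improved = True
    while improved and len(current) > 1:
        improved = False
        best_aic, best_cols, best_fit = fit.aic, None, None
        for c in current:
            cols = [x for x in current if x != c]
            cand = fit_set(cols, warm=fit)
            if not cand.flagged and cand.aic < best_aic:
                best_aic, best_cols, best_fit = cand.aic, cols, cand
        if best_cols is not None:
            current, fit, improved = best_cols, best_fit, True

    return SignatureModel(
        pair_ids=current,
        coef=fit.beta.copy(),
        fit=fit,
        provenance={"selected_pairs": list(selected_pairs)},
    )


def score_samples(model: SignatureModel, pm: PairMatrix) -> pd.Series:
    """Risk score per sample: the exact linear combination of pair values."""
    missing = [p for p in model.pair_ids if p not in pm.values.index]
    if missing:
        raise ValidationError(f"pair matrix lacks model pairs: {missing}")
    E = pm.values.loc[model.pair_ids].to_numpy().astype(float)
    scores = model.coef @ E
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")
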