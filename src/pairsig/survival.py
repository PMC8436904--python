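"""First-principles survival statistics: Cox partial likelihood, Kaplan-Meier,
log-rank.

The Cox fitter maximises the log partial likelihood by Newton-Raphson with the
Efron tie correction (Breslow available for cross-checks).  Monotone
likelihood -- the binary-covariate separation case where the score never
vanishes -- is detected and reported as a flagged, non-converged fit rather
than silently returning a huge coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

_SEPARATION_BETA = 20.0


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``hr`` is ``exp(beta)``; ``ci95`` the Wald 95% interval on the hazard-ratio
    scale; ``p`` two-sided Wald p-values; ``aic = -2*loglik + 2*k``.
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    flagged: bool = False
    n_iter: int = 0
    ties: str = "efron"

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        """(k, 2) array of hazard-ratio confidence bounds."""
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf)
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def k(self) -> int:
        return len(self.beta)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def summary(self):
        import pandas as pd

        ci = self.ci95
        return pd.DataFrame(
            {
                "covariate": self.names,
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_lo95": ci[:, 0],
                "hr_hi95": ci[:, 1],
                "p": self.p,
            }
        )


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times in increasing order; ``survival``
    the estimate just after each; ``at_risk``/``n_events`` bookkeeping.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function, S=1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def _prepare(X, time, event):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(time)) == X.shape[1]:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, k = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValidationError("X, time and event must agree on the number of subjects")
    if np.any(time <= 0):
        raise ValidationError("survival times must be strictly positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValidationError("event indicator must be 0/1")
    return X, time, event


def _efron_terms(Xs, ws, eta_s, ts, es, ties, derivs: bool = True):
    """Log partial likelihood (and optionally score / observed information)
    on time-sorted data.

    With ``derivs=False`` only the likelihood is computed, skipping the
    O(n k^2) information sums -- used by the step-halving line search.
    """
    n, k = Xs.shape
    ev = np.flatnonzero(es == 1)
    if ev.size == 0:
        return (0.0, np.zeros(k), np.eye(k)) if derivs else 0.0
    uniq, g = np.unique(ts[ev], return_inverse=True)
    d_g = np.bincount(g)
    starts = np.concatenate(([0], np.cumsum(d_g)[:-1]))
    left = np.searchsorted(ts, uniq, side="left")
    # within-group 0..d-1 index for the Efron averaging
    l_i = np.arange(len(ev)) - starts[g]
    frac = l_i / d_g[g] if ties == "efron" else np.zeros(len(ev))

    W_suf = np.cumsum(ws[::-1])[::-1]
    S_D = np.bincount(g, weights=ws[ev])
    phi = W_suf[left[g]] - frac * S_D[g]
    ll = float(eta_s[ev].sum() - np.log(phi).sum())
    if not derivs:
        return ll

    WX = ws[:, None] * Xs
    WX_suf = np.cumsum(WX[::-1], axis=0)[::-1]
    WXX = ws[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    WXX_suf = np.cumsum(WXX[::-1], axis=0)[::-1]
    SX_D = np.add.reduceat(WX[ev], starts, axis=0)
    SXX_D = np.add.reduceat(WXX[ev], starts, axis=0)

    phix = WX_suf[left[g]] - frac[:, None] * SX_D[g]
    phixx = WXX_suf[left[g]] - frac[:, None, None] * SXX_D[g]

    grad = Xs[ev].sum(axis=0) - (phix / phi[:, None]).sum(axis=0)
    xbar = phix / phi[:, None]
    info = (phixx / phi[:, None, None]).sum(axis=0) - np.einsum(
        "ij,il->jl", xbar, phix / phi[:, None]
    )
    return ll, grad, info


def cox_loglik(X, time, event, beta, ties: str = "efron") -> float:
    """Log partial likelihood at a fixed coefficient vector."""
    X, time, event = _prepare(X, time, event)
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ np.asarray(beta, dtype=float)
    ll, _, _ = _efron_terms(Xs, np.exp(eta), eta, ts, es, ties)
    return ll


def cox_loglik_path(X, time, event, B) -> np.ndarray:
    """Breslow log partial likelihood for each column of coefficient matrix B.

    Vectorised over candidate models; used for cross-validated deviance where
    the Efron/Breslow distinction is immaterial.
    """
    X, time, event = _prepare(X, time, event)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] != X.shape[1]:
        B = B.T
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ B  # (n, m)
    eta = eta - eta.max(axis=0, keepdims=True)  # overflow guard; ll shifts cancel
    w = np.exp(eta)
    W_suf = np.cumsum(w[::-1], axis=0)[::-1]
    ev = np.flatnonzero(es == 1)
    if ev.size == 0:
        return np.zeros(B.shape[1])
    uniq = np.unique(ts[ev])
    left = np.searchsorted(ts, uniq, side="left")
    g = np.searchsorted(uniq, ts[ev])
    return eta[ev].sum(axis=0) - np.log(W_suf[left])[g].sum(axis=0)


def fit_cox(
    X,
    time,
    event,
    names: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X : (n, k) covariate matrix (1-d accepted for a single covariate).
    time, event : survival times (>0) and 0/1 event indicators.
    ties : "efron" (default) or "breslow".
    beta0 : optional warm-start coefficients (the optimum is unchanged).

    Raises
    ------
    ValidationError
        On constant covariates, too few subjects, or invalid times/events.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    X, time, event = _prepare(X, time, event)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if len(names) != k:
        raise ValidationError("names length must match number of covariates")
    if n < k + 1:
        raise ValidationError(f"need at least k+1={k + 1} subjects, got {n}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = names[int(np.argmin(sd))]
        raise ValidationError(f"constant covariate: {bad}")
    if event.sum() == 0:
        raise ValidationError("no events observed; Cox model is undefined")

    # centre for numerical stability; partial likelihood is shift-invariant
    mu = X.mean(axis=0)
    Xc = X - mu
    order = np.argsort(time, kind="stable")
    Xs, ts, es = Xc[order], time[order], event[order]

    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll_null, _, _ = _efron_terms(Xs, np.ones(n), np.zeros(n), ts, es, ties)
    ll = ll_null
    info = np.eye(k)
    converged = False
    flagged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        ll, grad, info = _efron_terms(Xs, np.exp(eta), eta, ts, es, ties)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flagged = True
            break
        # step-halving safeguard
        new = beta + step
        for _ in range(30):
            eta_new = Xs @ new
            ll_new = _efron_terms(Xs, np.exp(eta_new), eta_new, ts, es, ties,
                                  derivs=False)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
            new = beta + step
        beta = new
        if np.max(np.abs(beta)) > _SEPARATION_BETA:
            flagged = True
            logger.warning(
                "monotone likelihood suspected (|beta| > %g); fit flagged",
                _SEPARATION_BETA,
            )
            break
    if not converged and not flagged:
        flagged = True
        logger.warning("Cox fit did not converge in %d iterations", max_iter)
    if converged and np.max(np.abs(beta)) > 0.5 * _SEPARATION_BETA:
        # the score can vanish numerically while beta runs off to infinity
        converged = False
        flagged = True
        logger.warning("monotone likelihood: score vanished at |beta| > %g",
                       0.5 * _SEPARATION_BETA)

    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        flagged=flagged,
        n_iter=it,
        ties=ties,
    )


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations leave the risk set without contributing a step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValidationError("time and event must have the same length")
    if np.any(time <= 0):
        raise ValidationError("survival times must be strictly positive")
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    n = len(ts)
    ev_times, d = np.unique(ts[es == 1], return_counts=True)
    at_risk = n - np.searchsorted(ts, ev_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk, n_events=d)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test with hypergeometric variance.

    Returns (chi2, p) with p from a chi-square distribution on 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValidationError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    in_a = group == labels[0]
    ev_times = np.unique(time[event == 1])
    O_a = E_a = V = 0.0
    for t in ev_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = (time == t) & (event == 1)
        d_t = dying.sum()
        d_a = (dying & in_a).sum()
        O_a += d_a
        E_a += d_t * n_a / n_t
        if n_t > 1:
            V += d_t * (n_a / n_t) * (1 - n_a / n_t) * (n_t - d_t) / (n_t - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O_a - E_a) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
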