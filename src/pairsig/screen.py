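"""Immune-related lncRNA screening.

Two stages: (1) retain lncRNAs whose expression correlates with at least one
immune gene above a Pearson threshold (strict ``|r| > r_thresh`` with
``p < p_thresh``); (2) call differential expression between tumor and normal
samples on the retained lncRNAs with a Welch t-test on ``log2(x + eps)`` and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class CorrelationScreenResult:
    lnc_id: str
    best_partner: str
    r: float
    p: float


@dataclass
class DEResult:
    lnc_id: str
    log2fc: float
    p: float
    fdr: float
    direction: str  # "up" | "down"


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t-transform with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlation_screen(
    expr: ExpressionMatrix,
    immune_genes: GeneSet,
    r_thresh: float = 0.4,
    p_thresh: float = 0.001,
) -> list[CorrelationScreenResult]:
    """Retain lncRNAs co-expressed with an immune gene.

    A lncRNA passes iff, over all immune genes present in the matrix, the
    maximum ``|Pearson r|`` strictly exceeds ``r_thresh`` and that best pair's
    p-value is strictly below ``p_thresh``.  Zero-variance genes cannot carry a
    correlation and are skipped with a log message.
    """
    n = len(expr.sample_ids)
    if n < 3:
        raise ValidationError("correlation screen needs at least 3 samples")
    lnc_ids = expr.genes_of_class("lncRNA")
    imm_ids = [g for g in immune_genes.members if g in expr.values.index]
    if not lnc_ids:
        raise ValidationError("no lncRNA-class genes in matrix")
    if not imm_ids:
        raise ValidationError("no immune genes found in matrix")

    L = expr.values.loc[lnc_ids].to_numpy()
    M = expr.values.loc[imm_ids].to_numpy()
    l_sd = L.std(axis=1)
    m_sd = M.std(axis=1)
    n_skip = int((l_sd == 0).sum() + (m_sd == 0).sum())
    if n_skip:
        logger.warning("correlation_screen: %d zero-variance genes skipped", n_skip)

    Lc = L - L.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Lc @ Mc.T) / (np.outer(l_sd, m_sd) * n)
    R = np.where(np.isfinite(R), R, 0.0)  # zero-variance pairs -> no signal

    results = []
    for i, lnc in enumerate(lnc_ids):
        j = int(np.argmax(np.abs(R[i])))
        r = float(R[i, j])
        p = float(pearson_pvalue(r, n))
        if abs(r) > r_thresh and p < p_thresh:
            results.append(CorrelationScreenResult(lnc, imm_ids[j], r, p))
    return results


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_expression(
    expr: ExpressionMatrix,
    tumor_ids,
    normal_ids,
    lnc_ids=None,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
    eps: float = 1e-3,
) -> list[DEResult]:
    """Tumor-vs-normal differential expression on lncRNAs.

    log2fc = log2((mean_tumor + eps) / (mean_normal + eps)); p from a
    two-sided Welch t-test on log2(x + eps); BH-FDR over all tested lncRNAs.
    Retained iff |log2fc| > lfc_thresh and fdr < fdr_thresh (strict).
    """
    tumor_ids, normal_ids = list(tumor_ids), list(normal_ids)
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValidationError("differential expression needs >=2 samples per group")
    if lnc_ids is None:
        lnc_ids = expr.genes_of_class("lncRNA")
    if not lnc_ids:
        raise ValidationError("no lncRNAs to test")
    T = expr.values.loc[lnc_ids, tumor_ids].to_numpy()
    N = expr.values.loc[lnc_ids, normal_ids].to_numpy()
    log2fc = np.log2(T.mean(axis=1) + eps) - np.log2(N.mean(axis=1) + eps)
    with np.errstate(all="ignore"):
        _, p = stats.ttest_ind(
            np.log2(T + eps), np.log2(N + eps), axis=1, equal_var=False
        )
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance identical groups
    fdr = bh_adjust(p)
    out = []
    for i, lnc in enumerate(lnc_ids):
        if abs(log2fc[i]) > lfc_thresh and fdr[i] < fdr_thresh:
            out.append(
                DEResult(
                    lnc_id=lnc,
                    log2fc=float(log2fc[i]),
                    p=float(p[i]),
                    fdr=float(fdr[i]),
                    direction="up" if log2fc[i] > 0 else "down",
                )
            )
    return out


def screen_results_frame(results) -> pd.DataFrame:
    """Tabulate either screen's dataclass list for TSV output."""
    if not results:
        return pd.DataFrame()
    return pd.DataFrame([vars(r) for r in results])
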