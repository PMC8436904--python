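"""Tumor-microenvironment scoring and immune-correlation analysis.

Stromal/immune scores come from a single-sample rank-enrichment statistic
(Barbie-style running sum): per sample, genes are ranked by expression
(descending, average ranks for ties) and the score accumulates the gap
between the weighted in-set ECDF (weights ``rank ** alpha``) and the uniform
out-of-set ECDF over the full ranked list.  The combined score is the exact
sum of the stromal and immune scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSet
from .stattests import rank_sum_test, significance_stars

logger = logging.getLogger(__name__)


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = 0.25,
    min_overlap: int = 10,
) -> pd.Series:
    """Per-sample single-sample enrichment score for one gene set.

    score(sample) = sum over ranked positions i of [P_in(i) - P_out(i)], with
    P_in the rank**alpha-weighted ECDF over set members and P_out the uniform
    ECDF over non-members.  Raw (unnormalised) running-sum scores; no
    cross-sample rescaling.
    """
    members = set(gene_set.members)
    present = [g for g in expr.gene_ids if g in members]
    missing = sorted(members - set(present))
    if len(present) == 0:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no overlap with matrix; missing: {missing[:10]}"
        )
    if len(present) < min_overlap:
        raise ValidationError(
            f"gene set {gene_set.name!r}: only {len(present)} genes overlap "
            f"(min_overlap={min_overlap})"
        )
    n_genes = len(expr.gene_ids)
    if len(present) == n_genes:
        raise ValidationError(f"gene set {gene_set.name!r} covers the whole matrix")

    V = expr.values.to_numpy()
    in_set = np.array([g in members for g in expr.gene_ids])
    # rank 1 = lowest expression => descending-order rank n = top gene
    ranks = stats.rankdata(V, axis=0)  # average ranks for ties
    scores = np.empty(V.shape[1])
    n_out = n_genes - in_set.sum()
    for j in range(V.shape[1]):
        order = np.argsort(-ranks[:, j], kind="stable")  # descending expression
        inmask = in_set[order]
        w = ranks[order, j] ** alpha
        w_in = np.where(inmask, w, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~inmask) / n_out
        scores[j] = np.sum(p_in - p_out)
    return pd.Series(scores, index=expr.sample_ids, name=gene_set.name)


@dataclass
class MicroenvScores:
    """Per-sample stromal/immune scores; combined = stromal + immune exactly."""

    table: pd.DataFrame  # columns: stromal_score, immune_score, estimate_score

    def __post_init__(self):
        t = self.table
        if not np.allclose(
            t["estimate_score"], t["stromal_score"] + t["immune_score"], atol=0, rtol=0
        ):
            raise ValidationError("estimate_score must equal stromal + immune exactly")


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: GeneSet,
    immune_set: GeneSet,
    alpha: float = 0.25,
    min_overlap: int = 10,
) -> MicroenvScores:
    stromal = ssgsea_score(expr, stromal_set, alpha=alpha, min_overlap=min_overlap)
    immune = ssgsea_score(expr, immune_set, alpha=alpha, min_overlap=min_overlap)
    table = pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": stromal + immune,
        }
    )
    table.index.name = "sample_id"
    return MicroenvScores(table)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with tie-corrected ranks; exact permutation p for n < 10."""
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if n < 10:
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def correlate_risk(scores, abundance: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of risk scores with each immune-cell abundance."""
    scores = pd.Series(scores)
    common = [s for s in abundance["sample_id"] if s in scores.index]
    if len(common) < 3:
        raise ValidationError("fewer than 3 samples shared with abundance table")
    ab = abundance.set_index("sample_id").loc[common]
    s = scores.loc[common].to_numpy(float)
    rows = []
    for col in ab.columns:
        if col == "method":
            continue
        y = ab[col].to_numpy(float)
        if np.std(y) == 0:
            logger.warning("correlate_risk: constant abundance %s skipped", col)
            continue
        rho, p = _spearman(s, y)
        row = {"cell_type": col, "rho": rho, "p": p, "stars": significance_stars(p)}
        if "method" in ab.columns:
            row["method"] = ab["method"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def group_expression_test(
    expr: ExpressionMatrix, genes: list[str], groups: pd.Series
) -> pd.DataFrame:
    """Per-gene rank-sum comparison of expression between the two risk groups.

    Direction is the sign of the high-group minus low-group median.
    """
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    common = [s for s in expr.sample_ids if s in groups.index]
    g = groups.loc[common].to_numpy()
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(labels)}")
    hi_label = "high" if "high" in labels else labels[0]
    lo_label = [l for l in labels if l != hi_label][0]
    rows = []
    for gene in genes:
        v = expr.values.loc[gene, common].to_numpy(float)
        hi, lo = v[g == hi_label], v[g == lo_label]
        med_diff = float(np.median(hi) - np.median(lo))
        _, p = rank_sum_test(hi, lo)
        rows.append(
            {
                "gene": gene,
                "direction": "up" if med_diff > 0 else ("down" if med_diff < 0 else "none"),
                "median_diff": med_diff,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
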