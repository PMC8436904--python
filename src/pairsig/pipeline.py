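"""End-to-end orchestration of the pair-signature analysis on one cohort.

``run_pipeline`` wires the stages together exactly as the CLI subcommands do,
reading every intermediate back from disk so a run exercises the readers and
writers; given the same spec and seed it produces byte-identical output
files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .evaluation import (
    assign_groups,
    association_tests,
    compare_groups_survival,
    independence_analysis,
    optimal_cutoff,
    time_dependent_roc,
)
from .io import (
    GeneSet,
    classify_genes_from_gtf,
    read_clinical,
    read_expression,
    read_gene_list,
)
from .microenv import estimate_scores, group_expression_test
from .pairs import build_pair_matrix, filter_pairs, write_pair_matrix
from .screen import correlation_screen, differential_expression, screen_results_frame
from .signature import fit_signature, repeated_lasso, score_samples, univariate_screen
from .synthetic import CohortSpec, write_cohort

logger = logging.getLogger(__name__)


def run_pipeline(
    spec: CohortSpec,
    outdir,
    n_cycles: int = 100,
    n_folds: int = 10,
    freq_thresh: int | None = None,
    horizons: tuple[int, ...] = (365, 730, 1095),
    include_microenv: bool = True,
) -> dict:
    """Simulate a cohort and run the full analysis in ``outdir``.

    ``freq_thresh`` defaults to ``n_cycles // 10``, the same selected fraction
    as the reference 1000-cycle / >100-occurrences rule.
    """
    if freq_thresh is None:
        freq_thresh = n_cycles // 10
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_cohort(spec, outdir)

    gene_class = pd.Series(classify_genes_from_gtf(paths["gtf"]))
    expr = read_expression(paths["expression"])
    expr.gene_class = gene_class.reindex(expr.values.index).fillna("other")
    clinical = read_clinical(paths["clinical"])
    immune = GeneSet("immune", read_gene_list(paths["immune_genes"]))

    tumor_ids = [s for s in clinical["sample_id"] if s in expr.values.columns]
    normal_ids = [s for s in expr.sample_ids if s not in set(tumor_ids)]

    ir = correlation_screen(expr, immune)
    screen_results_frame(ir).to_csv(outdir / "irlncRNAs.tsv", sep="\t", index=False)
    ir_ids = [r.lnc_id for r in ir]
    de = differential_expression(expr, tumor_ids, normal_ids, lnc_ids=ir_ids)
    screen_results_frame(de).to_csv(outdir / "deirlncRNAs.tsv", sep="\t", index=False)
    de_ids = [r.lnc_id for r in de]
    logger.info("screen: %d immune-correlated, %d differentially expressed", len(ir_ids), len(de_ids))

    pm_all = build_pair_matrix(expr.subset_samples(tumor_ids), gene_ids=de_ids)
    pm = filter_pairs(pm_all)
    write_pair_matrix(pm, outdir / "pairs.tsv")
    pm.ones_fraction.rename("ones_fraction").to_csv(
        outdir / "pair_stats.tsv", sep="\t", index_label="pair_id"
    )

    screened = univariate_screen(pm, clinical)
    pm_screened = type(pm)(pm.values.loc[screened])
    selection, selected = repeated_lasso(
        pm_screened,
        clinical,
        n_cycles=n_cycles,
        n_folds=n_folds,
        freq_thresh=freq_thresh,
        seed=spec.seed,
    )
    pd.Series(selection.frequencies, name="frequency").rename_axis("pair_id").to_csv(
        outdir / "selection.tsv", sep="\t"
    )

    model = fit_signature(pm, clinical, selected)
    with open(outdir / "model.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
    scores = score_samples(model, pm)
    scores.rename_axis("sample_id").to_csv(outdir / "risk_scores.tsv", sep="\t")

    rocs = {}
    for t in horizons:
        roc = time_dependent_roc(scores, clinical, t)
        rocs[t] = roc
        pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        ).to_csv(outdir / f"roc_t{t}.tsv", sep="\t", index=False)
    cutoff = optimal_cutoff(rocs[horizons[0]])
    with open(outdir / "cutoff.json", "w") as fh:
        json.dump(
            {
                "cutoff": cutoff.cutoff,
                "youden": cutoff.youden,
                "sensitivity": cutoff.sensitivity,
                "specificity": cutoff.specificity,
                "aic": cutoff.aic,
                "auc": {str(t): rocs[t].auc for t in horizons},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    groups = assign_groups(scores, cutoff.cutoff)
    groups.rename_axis("sample_id").to_csv(outdir / "groups.tsv", sep="\t")
    _, chi2, p = compare_groups_survival(groups, clinical)
    with open(outdir / "km_logrank.json", "w") as fh:
        json.dump({"chi2": chi2, "p": p}, fh, indent=1, sort_keys=True)
    uni, multi = independence_analysis(scores, clinical)
    uni.to_csv(outdir / "independence.tsv", sep="\t", index=False)
    multi.to_csv(outdir / "independence_multivariate.tsv", sep="\t", index=False)
    assoc = association_tests(groups, scores, clinical)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    result = {
        "n_irlnc": len(ir_ids),
        "n_de": len(de_ids),
        "n_pairs_all": len(pm_all.pair_ids),
        "n_pairs_filtered": len(pm.pair_ids),
        "n_screened": len(screened),
        "selected": selected,
        "model": model,
        "scores": scores,
        "auc": {t: rocs[t].auc for t in horizons},
        "cutoff": cutoff,
        "groups": groups,
        "logrank_chi2": chi2,
        "logrank_p": p,
    }

    if include_microenv:
        mrna = expr.genes_of_class("mRNA")
        stromal_members = [g for g in mrna if g not in set(immune.members)]
        if len(stromal_members) >= 10 and len(immune.members) >= 10:
            ms = estimate_scores(
                expr.subset_samples(tumor_ids),
                GeneSet("stromal", stromal_members[:50]),
                GeneSet("immune", immune.members),
            )
            ms.table.to_csv(outdir / "microenv_scores.tsv", sep="\t")
            ici = group_expression_test(
                expr.subset_samples(tumor_ids), immune.members[:4], groups
            )
            ici.to_csv(outdir / "ici_tests.tsv", sep="\t", index=False)
            result["microenv"] = ms
    return result
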