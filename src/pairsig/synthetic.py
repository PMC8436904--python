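"""Synthetic survival cohorts with planted rank-pair effects.

The generator emits a tumor/normal expression matrix (log-normal model), a
clinical table for the tumor samples, and a ground-truth record.  Structure
planted so the downstream pipeline has something to find:

* a subset of lncRNAs is co-expressed with immune mRNAs through a shared
  latent factor (Pearson r > 0.4 in expectation on the expression scale);
* a subset of those is differentially expressed between tumor and normal via
  a class shift of ``ln(2) * de_log2fc`` in log space, so the realized
  log2 fold change matches ``de_log2fc`` in expectation;
* survival times follow a Weibull baseline whose hazard is multiplied by
  ``exp(sum beta_k * I_k)`` where each ``I_k`` is a pair indicator recomputed
  from the *emitted* expression matrix -- the signal is exactly what the
  pipeline models;
* censoring is exponential, its rate calibrated by bisection so the realized
  censoring fraction matches ``censor_rate``.

Everything is driven by one seeded generator: same spec, same bytes out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, write_clinical, write_expression
from .pairs import pair_id

STAGES = ("I", "II", "III", "IV")
STAGE_P = (0.50, 0.25, 0.15, 0.10)
T_CATS = ("T1", "T2", "T3", "T4")
T_P = (0.30, 0.40, 0.20, 0.10)
N_CATS = ("N0", "N1", "N2", "N3")
N_P = (0.55, 0.25, 0.15, 0.05)
M_CATS = ("M0", "M1")
M_P = (0.90, 0.10)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``planted_pairs`` are (i, j, beta) triples indexing *distinct* DE lncRNAs
    (0-based within the DE subset); beta is the log hazard ratio attached to
    the pair indicator I(expr_i >= expr_j).
    """

    n_tumor: int = 400
    n_normal: int = 50
    n_lnc: int = 60
    n_mrna: int = 120
    n_immune_mrna: int = 40
    n_corr_lnc: int = 40
    n_de_lnc: int = 20
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    baseline_shape: float = 1.2
    baseline_scale: float = 1200.0
    censor_rate: float = 0.3
    noise_sd: float = 0.5
    de_log2fc: float = 2.0
    corr_rho: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tumor", "n_normal", "n_lnc", "n_mrna", "n_immune_mrna",
                     "n_corr_lnc", "n_de_lnc"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (self.n_de_lnc <= self.n_corr_lnc <= self.n_lnc):
            raise ValidationError("need n_de_lnc <= n_corr_lnc <= n_lnc")
        if self.n_immune_mrna > self.n_mrna:
            raise ValidationError("n_immune_mrna cannot exceed n_mrna")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValidationError("censor_rate must lie in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValidationError("baseline_shape/baseline_scale must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 < self.corr_rho < 1.0):
            raise ValidationError("corr_rho must lie in (0, 1)")
        seen = set()
        for i, j, beta in self.planted_pairs:
            if i == j:
                raise ValidationError(f"planted_pairs: self-pair ({i}, {j})")
            if not (0 <= i < self.n_de_lnc and 0 <= j < self.n_de_lnc):
                raise ValidationError(
                    f"planted_pairs: index out of DE range ({i}, {j})"
                )
            key = frozenset((i, j))
            if key in seen:
                raise ValidationError(f"planted_pairs: duplicated pair ({i}, {j})")
            seen.add(key)
            if not np.isfinite(beta):
                raise ValidationError("planted_pairs: beta must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "planted_pairs" in d:
            d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        return cls(**d)


@dataclass
class SyntheticTruth:
    de_lnc_ids: list[str]
    corr_lnc_ids: list[str]
    immune_gene_ids: list[str]
    planted_pairs: list[dict]  # {"pair_id", "gene_i", "gene_j", "beta"}
    linear_predictor: dict[str, float]  # tumor sample -> true lp
    latent_time: dict[str, float]
    event: dict[str, int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _lnc_id(i: int) -> str:
    return f"LNC{i + 1:04d}"


def _mrna_id(i: int) -> str:
    return f"MRNA{i + 1:04d}"


def _calibrate_censoring(T: np.ndarray, u: np.ndarray, target: float) -> np.ndarray:
    """Exponential censoring times whose realized fraction censored ~= target.

    The fraction censored, mean(C < T) with C = -ln(u)/rate, is non-decreasing
    in the rate, so bisection on log-rate converges; u is fixed so the result
    is deterministic.
    """
    logu = -np.log(u)

    def frac(rate):
        return float(np.mean(logu / rate < T))

    lo, hi = 1e-12, 1e-12
    while frac(hi) < target and hi < 1e12:
        hi *= 10.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return logu / hi


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort. Returns (expression, clinical, truth)."""
    rng = np.random.default_rng(spec.seed)
    n_s = spec.n_tumor + spec.n_normal
    tumor_ids = [f"TUMOR{i + 1:04d}" for i in range(spec.n_tumor)]
    normal_ids = [f"NORMAL{i + 1:04d}" for i in range(spec.n_normal)]
    sample_ids = tumor_ids + normal_ids
    is_tumor = np.array([1] * spec.n_tumor + [0] * spec.n_normal, dtype=float)

    lnc_ids = [_lnc_id(i) for i in range(spec.n_lnc)]
    mrna_ids = [_mrna_id(i) for i in range(spec.n_mrna)]
    immune_ids = mrna_ids[: spec.n_immune_mrna]
    corr_ids = lnc_ids[: spec.n_corr_lnc]
    de_ids = lnc_ids[: spec.n_de_lnc]

    sd = spec.noise_sd
    mu_lnc = rng.uniform(1.0, 3.0, size=spec.n_lnc)
    mu_mrna = rng.uniform(1.0, 3.0, size=spec.n_mrna)
    de_sign = np.where(np.arange(spec.n_de_lnc) % 4 == 3, -1.0, 1.0)
    shift = np.log(2.0) * spec.de_log2fc * de_sign

    # pair members share a baseline and shift so the indicator stays balanced
    for i, j, _beta in spec.planted_pairs:
        mu_lnc[j] = mu_lnc[i]
        de_sign_i = shift[i]
        shift[j] = de_sign_i

    Z = rng.standard_normal((spec.n_immune_mrna, n_s))  # latent immune factors

    log_m = mu_mrna[:, None] + sd * rng.standard_normal((spec.n_mrna, n_s))
    log_m[: spec.n_immune_mrna] = mu_mrna[: spec.n_immune_mrna, None] + sd * Z

    log_l = mu_lnc[:, None] + sd * rng.standard_normal((spec.n_lnc, n_s))
    rho = spec.corr_rho
    eps = rng.standard_normal((spec.n_corr_lnc, n_s))
    partner = np.arange(spec.n_corr_lnc) % spec.n_immune_mrna
    log_l[: spec.n_corr_lnc] = (
        mu_lnc[: spec.n_corr_lnc, None]
        + sd * (rho * Z[partner] + np.sqrt(1.0 - rho**2) * eps)
    )
    log_l[: spec.n_de_lnc] += shift[:, None] * is_tumor[None, :]

    values = pd.DataFrame(
        np.exp(np.vstack([log_l, log_m])),
        index=lnc_ids + mrna_ids,
        columns=sample_ids,
    )
    gene_class = pd.Series(
        ["lncRNA"] * spec.n_lnc + ["mRNA"] * spec.n_mrna, index=values.index
    )
    expr = ExpressionMatrix(values, gene_class)

    # survival driven by pair indicators recomputed from the emitted matrix
    tumor_expr = values[tumor_ids]
    lp = np.zeros(spec.n_tumor)
    planted = []
    for i, j, beta in spec.planted_pairs:
        gi, gj = de_ids[i], de_ids[j]
        pid = pair_id(gi, gj)
        x, y = (gi, gj) if gi < gj else (gj, gi)
        ind = (tumor_expr.loc[x].to_numpy() >= tumor_expr.loc[y].to_numpy()).astype(float)
        b = beta if (x, y) == (gi, gj) else -beta
        lp += b * ind
        planted.append({"pair_id": pid, "gene_i": x, "gene_j": y, "beta": float(b)})

    E = rng.exponential(size=spec.n_tumor)
    T = spec.baseline_scale * (E / np.exp(lp)) ** (1.0 / spec.baseline_shape)
    if spec.censor_rate == 0:
        obs, event = T, np.ones(spec.n_tumor, dtype=int)
    else:
        C = _calibrate_censoring(T, rng.uniform(size=spec.n_tumor), spec.censor_rate)
        obs = np.minimum(T, C)
        event = (T <= C).astype(int)
    time_days = np.maximum(np.ceil(obs), 1.0)

    clinical = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "time": time_days.astype(int),
            "event": event,
            "age": np.clip(np.round(rng.normal(65, 10, spec.n_tumor)), 30, 90).astype(int),
            "sex": rng.choice(["female", "male"], size=spec.n_tumor),
            "stage": rng.choice(STAGES, size=spec.n_tumor, p=STAGE_P),
            "T": rng.choice(T_CATS, size=spec.n_tumor, p=T_P),
            "N": rng.choice(N_CATS, size=spec.n_tumor, p=N_P),
            "M": rng.choice(M_CATS, size=spec.n_tumor, p=M_P),
        }
    )

    truth = SyntheticTruth(
        de_lnc_ids=de_ids,
        corr_lnc_ids=corr_ids,
        immune_gene_ids=immune_ids,
        planted_pairs=planted,
        linear_predictor={s: float(v) for s, v in zip(tumor_ids, lp)},
        latent_time={s: float(v) for s, v in zip(tumor_ids, T)},
        event={s: int(v) for s, v in zip(tumor_ids, event)},
    )
    return expr, clinical, truth


def write_annotation_gtf(expr: ExpressionMatrix, path) -> None:
    """Emit a minimal Ensembl-dialect GTF assigning each gene its biotype."""
    biotype = {"lncRNA": "lncRNA", "mRNA": "protein_coding", "other": "misc_RNA"}
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for k, gene in enumerate(expr.gene_ids):
            bt = biotype[expr.gene_class[gene]]
            start = 1000 * k + 1
            fh.write(
                f"1\tsynthetic\tgene\t{start}\t{start + 500}\t.\t+\t.\t"
                f'gene_id "{gene}"; gene_name "{gene}"; gene_biotype "{bt}";\n'
            )


def write_cohort(spec: CohortSpec, outdir) -> dict[str, Path]:
    """Generate and write a cohort's files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, clinical, truth = generate_cohort(spec)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
        "gtf": outdir / "annotation.gtf",
        "immune_genes": outdir / "immune_genes.txt",
    }
    write_expression(expr, paths["expression"])
    write_clinical(clinical, paths["clinical"])
    truth.to_json(paths["truth"])
    write_annotation_gtf(expr, paths["gtf"])
    paths["immune_genes"].write_text("".join(g + "\n" for g in truth.immune_gene_ids))
    return paths
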