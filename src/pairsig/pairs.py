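"""Binary lncRNA-pair matrix construction and the rare-value filter.

For an ordered pair (X, Y) -- canonical order is lexicographic on gene id --
the per-sample value is 0 iff expr(X) < expr(Y), else 1 (ties map to 1).
Because only the within-sample ordering of the two genes matters, the matrix
is invariant to any strictly increasing per-sample transform of expression.
A pair whose rarer value occurs in fewer than ``min_frac`` of samples carries
no contrast and is dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


@dataclass
class PairMatrix:
    """Binary pair x sample matrix; rows labelled ``X|Y`` in canonical order."""

    values: pd.DataFrame  # pairs in rows, samples in columns, {0,1}

    def __post_init__(self):
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("pair matrix values must be 0/1")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicated pair id")
        for pid in self.values.index:
            x, y = split_pair_id(pid)
            if x == y:
                raise ValidationError(f"self-pair {pid!r}")

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ones_fraction(self) -> pd.Series:
        return self.values.mean(axis=1)


def pair_id(x: str, y: str) -> str:
    """Canonical id ``X|Y`` with X lexicographically before Y."""
    if x == y:
        raise ValidationError(f"self-pair {x!r}")
    return f"{x}{PAIR_SEP}{y}" if x < y else f"{y}{PAIR_SEP}{x}"


def split_pair_id(pid: str) -> tuple[str, str]:
    x, _, y = pid.partition(PAIR_SEP)
    if not y:
        raise ValidationError(f"malformed pair id {pid!r}")
    return x, y


def build_pair_matrix(expr: ExpressionMatrix, gene_ids=None) -> PairMatrix:
    """All C(n,2) ordered-pair indicators for the given genes.

    For canonical pair (X, Y): value = 0 iff expr(X, s) < expr(Y, s), else 1.
    """
    if gene_ids is None:
        gene_ids = expr.gene_ids
    gene_ids = sorted(gene_ids)
    if len(gene_ids) < 2:
        raise ValidationError("need at least 2 genes to form pairs")
    sub = expr.values.loc[gene_ids]
    E = sub.to_numpy()
    n_ties = 0
    rows, ids = [], []
    for i, j in itertools.combinations(range(len(gene_ids)), 2):
        ind = (E[i] >= E[j]).astype(np.int8)  # tie -> 1
        n_ties += int((E[i] == E[j]).sum())
        ids.append(f"{gene_ids[i]}{PAIR_SEP}{gene_ids[j]}")
        rows.append(ind)
    if n_ties:
        logger.info("build_pair_matrix: %d tied expression comparisons mapped to 1", n_ties)
    values = pd.DataFrame(np.vstack(rows), index=ids, columns=sub.columns)
    return PairMatrix(values)


def filter_pairs(pm: PairMatrix, min_frac: float = 0.2) -> PairMatrix:
    """Drop pairs whose rarer value occurs in < ``min_frac`` of samples.

    The boundary is kept: a pair is excluded iff
    ``min(freq(1), freq(0)) < min_frac`` (strict), so exactly-20% pairs stay.
    Order of surviving pairs is preserved; the operation is idempotent.
    """
    if pm.values.empty:
        raise ValidationError("empty pair matrix")
    frac1 = pm.values.mean(axis=1)
    rarer = np.minimum(frac1, 1.0 - frac1)
    keep = rarer >= min_frac
    logger.info("filter_pairs: kept %d of %d pairs", int(keep.sum()), len(keep))
    return PairMatrix(pm.values.loc[keep])


def write_pair_matrix(pm: PairMatrix, path) -> None:
    pm.values.to_csv(path, sep="\t", index_label="pair_id")


def read_pair_matrix(path) -> PairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairMatrix(df)
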