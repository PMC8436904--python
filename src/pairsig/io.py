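"""Readers and writers for the external formats the pipeline touches.

Expression matrices travel as TSV with genes in rows and a header of sample
ids; clinical tables as TSV with named columns; gene sets as GMT; gene-class
annotation comes from an Ensembl-dialect GTF via the ``gene_biotype``
attribute (``gene_type`` accepted for GENCODE files).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

GENE_CLASSES = ("lncRNA", "mRNA", "other")

CLINICAL_REQUIRED = ("sample_id", "time", "event")


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression with per-gene class labels.

    ``values`` is indexed by gene id (rows) and sample id (columns);
    ``gene_class`` maps each gene id to one of ``lncRNA``/``mRNA``/``other``.
    """

    values: pd.DataFrame
    gene_class: pd.Series

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup}")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.gene_class = self.gene_class.reindex(self.values.index).fillna("other")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValidationError(f"unknown gene class labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == cls])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.gene_class.loc[list(gene_ids)]
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.gene_class)


@dataclass
class GeneSet:
    name: str
    members: list[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        seen, uniq = set(), []
        for m in self.members:
            if m in seen:
                logger.warning("gene set %s: duplicated member %s dropped", self.name, m)
                continue
            seen.add(m)
            uniq.append(m)
        self.members = uniq


def read_expression(path, gene_class: pd.Series | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    First column holds gene ids, header row the sample ids.  Duplicate ids and
    non-numeric cells are parse errors carrying the offending line number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise ParseError(f"{path}: malformed header (expected tab-separated sample ids)", line=1)
        samples = header.split("\t")[1:]
        if len(set(samples)) != len(samples):
            raise ParseError(f"{path}: duplicate sample id in header", line=1)
        genes, rows = [], []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise ParseError(
                    f"{path}: expected {len(samples) + 1} columns, got {len(parts)}",
                    line=lineno,
                )
            gene = parts[0]
            if gene in seen:
                raise ParseError(f"{path}: duplicated gene row {gene!r}", line=lineno)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric cell for gene {gene!r}: {exc}", line=lineno)
            genes.append(gene)
            seen.add(gene)
    values = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    if gene_class is None:
        gene_class = pd.Series("other", index=values.index)
    return ExpressionMatrix(values, gene_class)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    # default float formatting is shortest-round-trip: read∘write is identity
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def classify_genes_from_gtf(gtf_path) -> dict[str, str]:
    """Map gene id -> {lncRNA, mRNA, other} from a GTF's ``gene`` lines.

    ``gene_biotype "lncRNA"`` -> lncRNA; ``"protein_coding"`` -> mRNA; any
    other biotype -> other.  GENCODE's ``gene_type`` key is accepted as a
    fallback.  Unparseable lines are skipped with a logged count.
    """
    classes: dict[str, str] = {}
    skipped = 0
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            gene_id = attrs.get("gene_id")
            biotype = attrs.get("gene_biotype", attrs.get("gene_type"))
            if gene_id is None or biotype is None:
                skipped += 1
                continue
            if biotype == "lncRNA":
                classes[gene_id] = "lncRNA"
            elif biotype == "protein_coding":
                classes[gene_id] = "mRNA"
            else:
                classes[gene_id] = "other"
    if skipped:
        logger.warning("classify_genes_from_gtf: %d gene lines skipped (bad attributes)", skipped)
    return classes


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical TSV, applying the cohort hygiene rules.

    Rows with follow-up time <= 0 are dropped, duplicated sample ids keep the
    first occurrence; both removals are logged with counts.  ``event`` must be
    0/1 and ``time`` numeric.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    try:
        df["time"] = pd.to_numeric(df["time"])
        df["event"] = pd.to_numeric(df["event"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric time/event column: {exc}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "event"].iloc[0]
        raise ValidationError(f"{path}: event indicator must be 0/1, found {bad!r}")
    n0 = len(df)
    df = df[df["time"] > 0]
    if len(df) < n0:
        logger.info("read_clinical: dropped %d rows with follow-up time <= 0", n0 - len(df))
    n1 = len(df)
    df = df.drop_duplicates(subset="sample_id", keep="first")
    if len(df) < n1:
        logger.info("read_clinical: dropped %d duplicated sample ids", n1 - len(df))
    return df.reset_index(drop=True)


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_sets(gmt_path) -> list[GeneSet]:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``."""
    sets = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{gmt_path}: GMT line needs name, description, members", line=lineno)
            members = [m for m in parts[2:] if m.strip()]
            if not members:
                raise ParseError(f"{gmt_path}: gene set {parts[0]!r} has no members", line=lineno)
            sets.append(GeneSet(name=parts[0], members=members))
    return sets


def read_gene_list(path) -> list[str]:
    """One gene id per line; blanks and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out


def read_abundance(path) -> pd.DataFrame:
    """Samples x cell-type abundance table (e.g. deconvolution output).

    First column is the sample id; an optional ``method`` column labels the
    source tool.  Abundances must be non-negative.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "sample_id"})
    value_cols = [c for c in df.columns if c not in ("sample_id", "method")]
    if not value_cols:
        raise ParseError(f"{path}: no cell-type columns found")
    key = ["sample_id"] + (["method"] if "method" in df.columns else [])
    if df.duplicated(subset=key).any():
        raise ValidationError(f"{path}: duplicate sample/method rows")
    if (df[value_cols].values < 0).any():
        raise ValidationError(f"{path}: abundances must be non-negative")
    return df
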