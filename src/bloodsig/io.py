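"""Readers, writers and in-memory containers for the pipeline's standard inputs.

Three containers travel through the whole pipeline:

``ExpressionMatrix``
    log-scale gene-by-sample values (microarray log2 intensity, RNA-seq
    log2 FPKM, or qPCR delta-Ct) with a platform tag.
``PhenotypeTable``
    per-sample risk labels, overall-survival time/event and free-form
    clinical covariates.
``GeneSetCollection``
    named gene sets (GMT dialect), used for pathway and cell-type
    enrichment.

All files are UTF-8, tab-delimited, with ``NA`` marking a missing value.
Gene and sample identifiers are opaque strings compared case-sensitively.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

#: Recognised platform tags for expression matrices.
PLATFORMS = ("microarray_log2", "rnaseq_log2fpkm", "qpcr_deltact")

MICROARRAY = "microarray_log2"
RNASEQ = "rnaseq_log2fpkm"
QPCR = "qpcr_deltact"

_NA = "NA"


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values : pandas.DataFrame
        Gene-by-sample matrix; index = gene ids, columns = sample ids.
        Entries must be finite or NaN (NaN = explicitly missing).
    platform : str
        One of :data:`PLATFORMS`.
    scale_note : str
        Free-text description of the scale (e.g. "log2 RMA intensity").
    """

    values: pd.DataFrame
    platform: str
    scale_note: str = ""

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("expression values must be finite (inf found)")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.platform,
                                self.scale_note)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype: risk label, survival and clinical covariates.

    ``table`` is indexed by sample id.  Recognised columns: ``risk_label``
    ("high"/"low"), ``survival_time`` (months, nonnegative), ``event``
    (0/1, 1 = death observed).  Every other column is kept as a covariate.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if "risk_label" in t.columns:
            bad = set(t["risk_label"].dropna().unique()) - {"high", "low"}
            if bad:
                raise ValidationError(f"risk_label must be high/low, got {bad}")
        if "event" in t.columns:
            ev = t["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValidationError("event values must be 0 or 1")
            if "survival_time" not in t.columns:
                raise ValidationError("event present without survival_time")
            st = t.loc[ev.index, "survival_time"]
            if st.isna().any():
                raise ValidationError("survival_time missing for sample with event")
        if "survival_time" in t.columns:
            st = pd.to_numeric(t["survival_time"], errors="coerce")
            if (st.dropna() < 0).any():
                raise ValidationError("negative survival_time")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def covariate_names(self) -> list[str]:
        reserved = {"risk_label", "survival_time", "event"}
        return [c for c in self.table.columns if c not in reserved]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.covariate_names:
            raise KeyError(name)
        return self.table[name]

    def risk_groups(self) -> pd.Series:
        """Risk labels restricted to labelled samples."""
        if "risk_label" not in self.table.columns:
            raise ValidationError("phenotype table has no risk_label column")
        return self.table["risk_label"].dropna()

    def survival(self) -> pd.DataFrame:
        """(survival_time, event) restricted to samples with both."""
        cols = {"survival_time", "event"}
        if not cols <= set(self.table.columns):
            raise ValidationError("phenotype table lacks survival columns")
        sub = self.table[["survival_time", "event"]].dropna()
        return sub.astype(float)


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicates within a set are collapsed."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    source_note: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = list(dict.fromkeys(genes))
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        kept = {n: [g for g in gs if g in universe] for n, gs in self.sets.items()}
        kept = {n: gs for n, gs in kept.items() if gs}
        return GeneSetCollection(kept, self.source_note, dict(self.descriptions))


# ---------------------------------------------------------------------------
# readers

def read_expression_matrix(path, platform: str,
                           allow_missing: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column = gene id).

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean value (standard probe-collapse heuristic), with a warning.  ``NA``
    cells raise a :class:`ParseError` unless ``allow_missing`` is set, in
    which case they become NaN.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("empty expression file", line=1)
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError("header must contain at least one sample id", line=1)
    sample_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(fields)}", line=lineno)
        gene_ids.append(fields[0])
        row = []
        for cell in fields[1:]:
            if cell == _NA or cell == "":
                if not allow_missing:
                    raise ParseError(
                        f"missing value for gene {fields[0]!r} "
                        "(pass allow_missing=True to flag instead)", line=lineno)
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} for gene {fields[0]!r}",
                    line=lineno) from None
        rows.append(row)
    if not rows:
        raise ParseError("expression file has no data rows", line=2)
    df = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        ndup = int(df.index.duplicated().sum())
        df = df[~df.index.duplicated(keep="first")]
        df = df.loc[[g for g in dict.fromkeys(gene_ids)]]
        warnings.warn(
            f"collapsed {ndup} duplicate gene row(s) by highest mean expression")
    return ExpressionMatrix(df, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            cells = [_NA if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, then gene ids."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue  # blank (incl. trailing) lines ignored
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >=1 gene", line=lineno)
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"gene set {name!r} has no genes", line=lineno)
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", line=lineno)
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, source_note=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_phenotype(path) -> PhenotypeTable:
    """Read a tab-delimited phenotype table; requires a sample_id column."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                         na_values=[_NA], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError("empty phenotype file", line=1) from None
    if "sample_id" not in df.columns:
        raise ParseError("phenotype table must have a sample_id column", line=1)
    df = df.set_index("sample_id")
    for col in ("survival_time", "event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return PhenotypeTable(df)


def write_phenotype(pheno: PhenotypeTable, path) -> None:
    out = pheno.table.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False, na_rep=_NA)


def write_manifest(path, **entries) -> None:
    """Write a JSON run-manifest (config, seeds, provenance of outputs)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
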