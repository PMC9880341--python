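"""Readers, writers and container types for all tabular artifacts.

Everything is plain delimited text: sample x gene matrices (expression,
copy number, gene effect), MAF-like mutation tables, sample annotations,
GMT gene-set collections, two-column ortholog maps, pairwise yeast
genetic-interaction tables, and the prediction tables the screens emit.

The delimiter is inferred from the file extension (.tsv/.txt -> tab,
.csv -> comma) and can be overridden. Missing values are written as empty
strings and read from empty strings or "NA"; missingness survives a
round-trip. Gene identifiers are plain symbols; no ID harmonization is
attempted here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("slscreen.dataio")

_NA_TOKENS = ("", "NA", "NaN", "nan")


class DataValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


class Role(str, Enum):
    """What a sample x gene matrix measures.

    expression: log2-scale abundance; copy_number: gene-level log2 ratio;
    gene_effect: dependency score where more negative = more essential.
    """

    EXPRESSION = "expression"
    COPY_NUMBER = "copy_number"
    GENE_EFFECT = "gene_effect"


def _sep_for(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(values: Iterable[str], what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise DataValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass
class OmicsMatrix:
    """Real-valued sample x gene matrix with a measurement role.

    ``data`` is a float DataFrame indexed by sample, columns = gene symbols.
    NaN encodes a missing measurement.
    """

    data: pd.DataFrame
    role: Role

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        if self.data.size == 0:
            raise DataValidationError("empty omics matrix")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "gene")
        self.data = self.data.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, samples=None, genes=None) -> "OmicsMatrix":
        d = self.data
        if samples is not None:
            d = d.loc[[s for s in samples if s in d.index]]
        if genes is not None:
            d = d[[g for g in genes if g in d.columns]]
        return OmicsMatrix(d.copy(), self.role)


@dataclass
class MutationCatalog:
    """Long-form mutation records: one row per (sample, gene, class) event."""

    records: pd.DataFrame  # columns: sample, gene, variant_classification

    def __post_init__(self) -> None:
        required = ["sample", "gene", "variant_classification"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise DataValidationError(f"mutation catalog lacks columns {missing}")
        self.records = self.records[required].astype(str).reset_index(drop=True)
        empty = (self.records == "").any(axis=1)
        if empty.any():
            raise DataValidationError(
                f"{int(empty.sum())} mutation records have empty fields"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SampleAnnotation:
    """Mapping from sample identifier to cancer-type label."""

    mapping: pd.Series  # index: sample, values: cancer_type

    def __post_init__(self) -> None:
        self.mapping = self.mapping.astype(str)
        _check_unique(self.mapping.index, "sample")
        if (self.mapping == "").any():
            raise DataValidationError("empty cancer-type label in annotation")

    def samples_for(self, cancer_type: str) -> list[str]:
        known = sorted(self.mapping.unique())
        if cancer_type not in known:
            raise DataValidationError(
                f"unknown cancer type {cancer_type!r}; known: {known}"
            )
        return list(self.mapping.index[self.mapping == cancer_type])


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass
class OrthologMap:
    """Yeast gene -> set of human gene symbols."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for src, targets in self.mapping.items():
            if not targets:
                raise DataValidationError(f"ortholog entry {src!r} maps to nothing")
            if src in targets:
                raise DataValidationError(f"self-referential ortholog entry {src!r}")


@dataclass
class YeastInteractionTable:
    """Pairwise SGA records: query gene, array gene, epsilon score, p-value."""

    records: pd.DataFrame  # columns: query_gene, array_gene, epsilon, p_value

    def __post_init__(self) -> None:
        required = ["query_gene", "array_gene", "epsilon", "p_value"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise DataValidationError(f"interaction table lacks columns {missing}")
        rec = self.records[required].reset_index(drop=True)
        rec["epsilon"] = rec["epsilon"].astype(float)
        rec["p_value"] = rec["p_value"].astype(float)
        if not np.all(np.isfinite(rec["epsilon"])):
            raise DataValidationError("non-finite epsilon score")
        if ((rec["p_value"] < 0) | (rec["p_value"] > 1)).any():
            raise DataValidationError("interaction p-values outside [0, 1]")
        same = rec["query_gene"].map(strip_strain_suffix) == rec[
            "array_gene"
        ].map(strip_strain_suffix)
        if same.any():
            raise DataValidationError(
                f"{int(same.sum())} self-interaction records after suffix stripping"
            )
        self.records = rec

    def __len__(self) -> int:
        return len(self.records)


def strip_strain_suffix(gene: str) -> str:
    """Drop the strain/allele suffix an SGA array encodes (text after '_')."""
    return gene.split("_", 1)[0]


# ---------------------------------------------------------------------------
# readers


def read_matrix(
    path,
    role: Role | str,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> OmicsMatrix:
    """Read a delimited matrix with one header row and one identifier column.

    ``orientation="genes_in_rows"`` transposes after parsing. Non-numeric
    cells become missing.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "column")  # pandas would mangle duplicates
    df = pd.read_csv(
        path,
        sep=_sep_for(path, delimiter),
        index_col=0,
        na_values=list(_NA_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df = df.apply(pd.to_numeric, errors="coerce")
    if orientation == "genes_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return OmicsMatrix(df, Role(role))


def write_matrix(matrix: OmicsMatrix, path, delimiter: str | None = None) -> None:
    matrix.data.to_csv(path, sep=_sep_for(path, delimiter), na_rep="")


def read_mutations(
    path,
    sample_col: str = "sample",
    gene_col: str = "gene",
    class_col: str = "variant_classification",
    delimiter: str | None = None,
) -> MutationCatalog:
    """Read a MAF-like mutation table, dropping rows with empty key fields."""
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str,
                     keep_default_na=False)
    for col in (sample_col, gene_col, class_col):
        if col not in df.columns:
            raise DataValidationError(
                f"mutation table {path} lacks required column {col!r}"
            )
    df = df[[sample_col, gene_col, class_col]]
    df.columns = ["sample", "gene", "variant_classification"]
    keep = (df != "").all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_mutations: dropped %d incomplete rows from %s",
                    dropped, path)
    return MutationCatalog(df[keep].reset_index(drop=True))


def write_mutations(catalog: MutationCatalog, path,
                    delimiter: str | None = None) -> None:
    catalog.records.to_csv(path, sep=_sep_for(path, delimiter), index=False)


def read_annotation(path, delimiter: str | None = None) -> SampleAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise DataValidationError("annotation needs sample and cancer_type columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return SampleAnnotation(ser)


def write_annotation(annotation: SampleAnnotation, path,
                     delimiter: str | None = None) -> None:
    df = pd.DataFrame({
        "sample": annotation.mapping.index,
        "cancer_type": annotation.mapping.values,
    })
    df.to_csv(path, sep=_sep_for(path, delimiter), index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise DataValidationError(
                    f"{path}:{lineno}: gene set {name!r} has no members"
                )
            sets[name] = GeneSet(name, desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_orthologs(path, delimiter: str | None = None) -> OrthologMap:
    """Read a two-column (yeast gene, human gene) table; rows aggregate."""
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise DataValidationError("ortholog map needs two columns")
    mapping: dict[str, set[str]] = {}
    for src, dst in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if src and dst:
            mapping.setdefault(src, set()).add(dst)
    return OrthologMap({k: frozenset(v) for k, v in mapping.items()})


def write_orthologs(orthologs: OrthologMap, path,
                    delimiter: str | None = None) -> None:
    sep = _sep_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write(f"yeast_gene{sep}human_gene\n")
        for src in sorted(orthologs.mapping):
            for dst in sorted(orthologs.mapping[src]):
                fh.write(f"{src}{sep}{dst}\n")


def read_yeast_interactions(
    path,
    query_col: str = "query_gene",
    array_col: str = "array_gene",
    epsilon_col: str = "epsilon",
    p_col: str = "p_value",
    delimiter: str | None = None,
) -> YeastInteractionTable:
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    for col in (query_col, array_col, epsilon_col, p_col):
        if col not in df.columns:
            raise DataValidationError(
                f"interaction table {path} lacks column {col!r}"
            )
    df = df[[query_col, array_col, epsilon_col, p_col]]
    df.columns = ["query_gene", "array_gene", "epsilon", "p_value"]
    df["query_gene"] = df["query_gene"].astype(str)
    df["array_gene"] = df["array_gene"].astype(str)
    return YeastInteractionTable(df)


def write_yeast_interactions(table: YeastInteractionTable, path,
                             delimiter: str | None = None) -> None:
    table.records.to_csv(path, sep=_sep_for(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# prediction tables

PREDICTION_COLUMNS = [
    "query_gene",
    "partner_gene",
    "workflow",
    "module",
    "dataset_label",
    "context",
    "statistic",
    "effect_size",
    "p_value",
    "q_value",
    "n_query_group",
    "n_other_group",
    "passed",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One candidate pair's evidence row in the flat prediction schema."""

    query_gene: str
    partner_gene: str
    workflow: str
    module: str
    dataset_label: str
    context: str
    statistic: float
    effect_size: float
    p_value: float
    q_value: float
    n_query_group: int
    n_other_group: int
    passed: bool


def _sort_key_frame(df: pd.DataFrame) -> pd.DataFrame:
    # ascending q then p (NaN last), then lexicographic pair
    return df.sort_values(
        by=["q_value", "p_value", "query_gene", "partner_gene"],
        na_position="last",
        kind="stable",
    )


def predictions_to_frame(predictions: Iterable[PredictionRecord]) -> pd.DataFrame:
    rows = [
        {c: getattr(p, c) for c in PREDICTION_COLUMNS} for p in predictions
    ]
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    return _sort_key_frame(df).reset_index(drop=True)


def write_predictions(predictions, path, delimiter: str | None = None) -> None:
    """Write prediction records sorted by (q, p, pair); lossless round-trip."""
    df = predictions_to_frame(predictions)
    df.to_csv(path, sep=_sep_for(path, delimiter), index=False, na_rep="")


def read_predictions(path, delimiter: str | None = None) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep=_sep_for(path, delimiter),
                     na_values=list(_NA_TOKENS), keep_default_na=False)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"prediction table lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            PredictionRecord(
                query_gene=str(d["query_gene"]),
                partner_gene=str(d["partner_gene"]),
                workflow=str(d["workflow"]),
                module=str(d["module"]),
                dataset_label=str(d["dataset_label"]),
                context=str(d["context"]),
                statistic=float(d["statistic"]) if not pd.isna(d["statistic"]) else math.nan,
                effect_size=float(d["effect_size"]) if not pd.isna(d["effect_size"]) else math.nan,
                p_value=float(d["p_value"]) if not pd.isna(d["p_value"]) else math.nan,
                q_value=float(d["q_value"]) if not pd.isna(d["q_value"]) else math.nan,
                n_query_group=int(d["n_query_group"]),
                n_other_group=int(d["n_other_group"]),
                passed=bool(d["passed"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort bundle


@dataclass
class Cohort:
    """A named dataset bundle: whichever omics layers a source provides."""

    label: str
    expression: OmicsMatrix | None = None
    copy_number: OmicsMatrix | None = None
    gene_effect: OmicsMatrix | None = None
    mutations: MutationCatalog | None = None
    annotation: SampleAnnotation | None = None

    def restrict_samples(self, samples) -> "Cohort":
        keep = list(samples)
        def _sub(m):
            return None if m is None else m.subset(samples=keep)
        mut = self.mutations
        if mut is not None:
            rec = mut.records[mut.records["sample"].isin(set(keep))]
            mut = MutationCatalog(rec.reset_index(drop=True))
        ann = self.annotation
        if ann is not None:
            ann = SampleAnnotation(ann.mapping[ann.mapping.index.isin(set(keep))])
        return Cohort(
            label=self.label,
            expression=_sub(self.expression),
            copy_number=_sub(self.copy_number),
            gene_effect=_sub(self.gene_effect),
            mutations=mut,
            annotation=ann,
        )
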