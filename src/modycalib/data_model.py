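"""Mutation records, the tab-separated exchange format, and dataset filters.

A panel is a collection of nonsynonymous single-nucleotide mutations in a
small set of monogenic diabetes genes, split into disease mutations (cases)
and putatively neutral population variants (controls).  Each record carries
raw prediction scores from a registry of in-silico methods in a dbNSFP-like
layout: one column per method, missing scores marked with a sentinel token.

Filters mirror the dataset-construction steps of a gene-specific calibration
study: restrict to genes with enough disease mutations for ROC analysis,
drop nonsense / stop-loss mutations from the disease set (most protein-level
predictors are not applicable to premature-termination changes), and remove
control variants that are already catalogued as disease-causing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Label",
    "MutationClass",
    "Phenotype",
    "MutationRecord",
    "Dataset",
    "FormatConfig",
    "FormatError",
    "RowError",
    "read_table",
    "write_table",
    "count_by_gene",
    "filter_min_mutation_count",
    "filter_for_analysis",
    "exclude_overlap",
]


class Label(str, enum.Enum):
    DISEASE = "disease"
    CONTROL = "control"


class MutationClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"


class Phenotype(str, enum.Enum):
    MODY = "MODY"
    NEONATAL = "neonatal"
    NONE = "none"


class FormatError(ValueError):
    """Malformed table: missing/duplicated mandatory column or bad header."""


class RowError(ValueError):
    """Unparseable value in a data row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class MutationRecord:
    """One variant with its raw per-method scores.

    ``raw_scores`` maps method name -> raw score (absent methods omitted or
    None).  ``aux`` maps method name -> auxiliary datum needed by some
    conversion rules (LRT's omega<1 flag; MutationTaster / RadialSVM
    prediction-class letter).
    """

    gene: str
    variant_id: str
    label: Label
    mutation_class: MutationClass = MutationClass.MISSENSE
    phenotype: Phenotype = Phenotype.NONE
    raw_scores: Mapping[str, float | None] = field(default_factory=dict)
    aux: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label is Label.CONTROL and self.phenotype is not Phenotype.NONE:
            raise ValueError(
                f"control record {self.variant_id!r} must have phenotype 'none'"
            )

    def score(self, method: str) -> float | None:
        return self.raw_scores.get(method)


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of mutation records over a configured gene set."""

    records: tuple[MutationRecord, ...]
    gene_set: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, pred) -> "Dataset":
        return Dataset(tuple(r for r in self.records if pred(r)), self.gene_set)

    def by_label(self, label: Label) -> "Dataset":
        return self.subset(lambda r: r.label is label)

    def genes(self) -> tuple[str, ...]:
        return self.gene_set

    @property
    def method_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            for m in r.raw_scores:
                seen.setdefault(m)
        return tuple(seen)


MANDATORY_COLUMNS = ("gene", "variant_id", "label", "class", "phenotype")


@dataclass(frozen=True)
class FormatConfig:
    """Column mapping for the tab-separated exchange format.

    ``column_map`` renames external headers to canonical names, which allows
    ingesting dbNSFP-style headers without touching the file.  ``methods``
    lists the score columns; for each method an optional ``<method>_aux``
    column carries the auxiliary datum.  ``sentinel`` marks missing scores
    ("." by dbNSFP convention).
    """

    methods: tuple[str, ...]
    sentinel: str = "."
    column_map: Mapping[str, str] = field(default_factory=dict)


def _canonical_columns(columns: Sequence[str], fc: FormatConfig) -> list[str]:
    return [fc.column_map.get(c, c) for c in columns]


def read_table(path, format_config: FormatConfig) -> Dataset:
    """Read the tab-separated exchange format into a :class:`Dataset`.

    One record per row, row order preserved; sentinel tokens become absent
    scores.  Raises :class:`FormatError` for header problems and
    :class:`RowError` (with the line number) for unparseable numerics.
    """
    # inspect the raw header first: pandas silently mangles duplicates
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    raw_cols = _canonical_columns(header_line.split("\t"), format_config)
    dupes = {c for c in raw_cols if raw_cols.count(c) > 1}
    if dupes:
        raise FormatError(f"duplicate column(s): {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = _canonical_columns(list(df.columns), format_config)
    for c in MANDATORY_COLUMNS:
        if c not in df.columns:
            raise FormatError(f"missing mandatory column: {c!r}")

    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row_d = dict(zip(df.columns, row))
        raw_scores: dict[str, float | None] = {}
        aux: dict[str, object] = {}
        for m in format_config.methods:
            tok = row_d.get(m, format_config.sentinel)
            if tok == format_config.sentinel or tok == "":
                raw_scores[m] = None
                continue
            try:
                raw_scores[m] = float(tok)
            except ValueError:
                raise RowError(f"unparseable score {tok!r} for method {m!r}", line)
            atok = row_d.get(f"{m}_aux", "")
            if atok not in ("", format_config.sentinel):
                aux[m] = _parse_aux(atok)
        try:
            rec = MutationRecord(
                gene=row_d["gene"],
                variant_id=row_d["variant_id"],
                label=Label(row_d["label"]),
                mutation_class=MutationClass(row_d["class"]),
                phenotype=Phenotype(row_d["phenotype"]),
                raw_scores=raw_scores,
                aux=aux,
            )
        except ValueError as e:
            raise RowError(str(e), line)
        records.append(rec)

    gene_set = tuple(dict.fromkeys(r.gene for r in records))
    return Dataset(tuple(records), gene_set)


def _parse_aux(tok: str):
    if tok in ("True", "true"):
        return True
    if tok in ("False", "false"):
        return False
    return tok


def _format_aux(v) -> str:
    if isinstance(v, bool):
        return "True" if v else "False"
    return str(v)


def write_table(ds: Dataset, path, format_config: FormatConfig) -> None:
    """Inverse of :func:`read_table` on dataset content (round-trip safe)."""
    rows = []
    for r in ds.records:
        row: dict[str, str] = {
            "gene": r.gene,
            "variant_id": r.variant_id,
            "label": r.label.value,
            "class": r.mutation_class.value,
            "phenotype": r.phenotype.value,
        }
        for m in format_config.methods:
            v = r.raw_scores.get(m)
            row[m] = format_config.sentinel if v is None else repr(float(v))
            a = r.aux.get(m)
            row[f"{m}_aux"] = format_config.sentinel if a is None else _format_aux(a)
        rows.append(row)
    cols = list(MANDATORY_COLUMNS)
    for m in format_config.methods:
        cols += [m, f"{m}_aux"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def count_by_gene(ds: Dataset) -> pd.DataFrame:
    """Per-(gene, label) record counts; rows = genes, columns = labels.

    Totals over genes and labels always equal the record count.
    """
    idx = pd.Index(ds.gene_set, name="gene")
    out = pd.DataFrame(0, index=idx, columns=[l.value for l in Label])
    for r in ds.records:
        if r.gene not in out.index:
            out.loc[r.gene] = 0
        out.loc[r.gene, r.label.value] += 1
    return out


def filter_min_mutation_count(ds: Dataset, min_count: int) -> Dataset:
    """Retain genes whose disease-mutation count exceeds ``min_count``.

    Genes with too few disease mutations cannot support per-gene ROC
    analysis and are excluded wholesale (both labels).
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts: dict[str, int] = {}
    for r in ds.records:
        if r.label is Label.DISEASE:
            counts[r.gene] = counts.get(r.gene, 0) + 1
    keep = {g for g, n in counts.items() if n > min_count}
    return Dataset(
        tuple(r for r in ds.records if r.gene in keep),
        tuple(g for g in ds.gene_set if g in keep),
    )


def filter_for_analysis(ds: Dataset) -> Dataset:
    """Drop nonsense and stop-loss mutations from the disease label.

    Protein-level predictors are not applicable to premature-termination
    changes, so only missense disease mutations enter the analysis.
    Controls are unaffected.  Idempotent.
    """
    def keep(r: MutationRecord) -> bool:
        if r.label is not Label.DISEASE:
            return True
        return r.mutation_class is MutationClass.MISSENSE

    return ds.subset(keep)


def exclude_overlap(controls: Dataset, known_disease_ids: Iterable[str]) -> Dataset:
    """Drop control records whose variant_id appears in a known-disease set.

    Exact string match on variant_id; no allele normalization or liftover.
    """
    known = set(known_disease_ids)
    return controls.subset(lambda r: r.variant_id not in known)
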