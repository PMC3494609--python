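"""Readers and writers for the external formats used by the pipeline.

FASTA coding sequences, gene-pair tables, expression matrices, and result
tables.  All tabular formats are tab-separated UTF-8 with '.' decimals;
numbers round-trip bit-exactly (serialized with full ``repr`` precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodingSequence",
    "GenePairRecord",
    "ExpressionTable",
    "REPLICONS",
    "CHROMOSOMES",
    "PLASMIDS",
    "read_fasta",
    "write_fasta",
    "read_pair_table",
    "write_pair_table",
    "read_expression_table",
    "write_expression_table",
    "load_reference_pairs",
]

#: Replicon vocabulary of the R. sphaeroides 2.4.1 genome: two chromosomes
#: and five endogenous plasmids.
CHROMOSOMES = frozenset({"CI", "CII"})
PLASMIDS = frozenset({"PA", "PB", "PC", "PD", "PE"})
REPLICONS = CHROMOSOMES | PLASMIDS

_VALID_NT = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised for malformed coding-sequence input."""


class TableFormatError(ValueError):
    """Raised for malformed tabular input."""


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame protein-coding nucleotide sequence for one gene copy.

    The sequence must be non-empty, a multiple of 3 long, and strictly over
    {A, C, G, T} — ambiguity codes are rejected at construction.
    """

    gene_id: str
    nucleotides: str

    def __post_init__(self) -> None:
        seq = self.nucleotides
        if not seq or len(seq) % 3 != 0:
            raise FastaFormatError(
                f"sequence {self.gene_id!r}: length {len(seq)} is not a "
                "positive multiple of 3"
            )
        bad = set(seq) - _VALID_NT
        if bad:
            raise FastaFormatError(
                f"sequence {self.gene_id!r}: invalid characters "
                f"{sorted(bad)} (only A/C/G/T accepted)"
            )

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass
class GenePairRecord:
    """One duplicate gene pair with its constraint and expression statistics.

    Numeric fields are ``None`` when missing (never silently zero).
    ``length`` carries the printed integer of the source table uninterpreted.
    """

    gene1_id: str
    gene2_id: str
    paralog_class: str  # "in" | "out"
    replicon1: str
    replicon2: str
    length: Optional[int] = None
    divergence_pct: Optional[float] = None
    ka: Optional[float] = None
    ks: Optional[float] = None
    omega: Optional[float] = None
    correlation: Optional[float] = None
    cosine: Optional[float] = None
    saturated: bool = False
    function: Optional[str] = None

    def __post_init__(self) -> None:
        if self.paralog_class not in ("in", "out"):
            raise TableFormatError(
                f"pair {self.gene1_id}/{self.gene2_id}: paralog class must "
                f"be 'in' or 'out', got {self.paralog_class!r}"
            )
        for rep in (self.replicon1, self.replicon2):
            if rep not in REPLICONS:
                raise TableFormatError(
                    f"pair {self.gene1_id}/{self.gene2_id}: unknown replicon "
                    f"{rep!r} (expected one of {sorted(REPLICONS)})"
                )


@dataclass
class ExpressionTable:
    """Per-gene expression values over conditions with replicates.

    ``values`` has shape (n_genes, n_conditions, n_replicates); every gene
    row shares the same condition set and replicate count.
    """

    gene_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise TableFormatError("expression values must be 3-dimensional")
        n_genes, n_cond, _ = self.values.shape
        if n_genes != len(self.gene_ids) or n_cond != len(self.condition_labels):
            raise TableFormatError("expression value shape does not match labels")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionTable(list(gene_ids), self.condition_labels, self.values[rows])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file.

    Ids are the first whitespace-delimited token of each header and must be
    unique.  Sequences failing the :class:`CodingSequence` invariants raise
    :class:`FastaFormatError` naming the offending record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(CodingSequence(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(seqs: Sequence[CodingSequence], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.nucleotides), id=s.gene_id, description="") for s in seqs],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Gene-pair tables

_PAIR_REQUIRED = ["gene1", "gene2", "class", "replicon1", "replicon2"]
_PAIR_NUMERIC = {
    "length": "length",
    "divergence": "divergence_pct",
    "ka": "ka",
    "ks": "ks",
    "omega": "omega",
    "correlation": "correlation",
    "cosine": "cosine",
}


def _cell(row: pd.Series, column: str) -> Optional[float]:
    if column not in row.index:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        if value.strip() in ("", "N/A", "NA"):
            return None
        value = float(value)
    return float(value)


def read_pair_table(path: str | Path) -> list[GenePairRecord]:
    """Read a tab-separated gene-pair table.

    Required columns: gene1, gene2, class, replicon1, replicon2.  Recognized
    numeric columns: length, divergence, ka, ks, omega, correlation, cosine.
    Empty / N/A cells map to missing, not zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PAIR_REQUIRED if c not in df.columns]
    if missing:
        raise TableFormatError(f"pair table missing required columns {missing}")
    keys = list(zip(df["gene1"], df["gene2"]))
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise TableFormatError(f"duplicate gene-pair rows: {dupes}")
    records = []
    for _, row in df.iterrows():
        length = _cell(row, "length")
        records.append(
            GenePairRecord(
                gene1_id=row["gene1"],
                gene2_id=row["gene2"],
                paralog_class=row["class"],
                replicon1=row["replicon1"],
                replicon2=row["replicon2"],
                length=int(length) if length is not None else None,
                divergence_pct=_cell(row, "divergence"),
                ka=_cell(row, "ka"),
                ks=_cell(row, "ks"),
                omega=_cell(row, "omega"),
                correlation=_cell(row, "correlation"),
                cosine=_cell(row, "cosine"),
                saturated=str(row.get("saturated", "")).lower() in ("1", "true", "yes"),
                function=row.get("function") or None,
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(float(value))
    return str(value)


def write_pair_table(records: Sequence[GenePairRecord], path: str | Path) -> None:
    """Write records as TSV; floats use full ``repr`` precision."""
    columns = [
        "gene1", "gene2", "class", "replicon1", "replicon2", "length",
        "divergence", "ka", "ks", "omega", "correlation", "cosine",
        "saturated", "function",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in records:
            row = [
                r.gene1_id, r.gene2_id, r.paralog_class, r.replicon1,
                r.replicon2, _fmt(r.length), _fmt(r.divergence_pct),
                _fmt(r.ka), _fmt(r.ks), _fmt(r.omega), _fmt(r.correlation),
                _fmt(r.cosine), _fmt(r.saturated), _fmt(r.function),
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV expression matrix with `<condition>.<replicate>` columns.

    The first column holds gene ids; condition grouping is inferred from the
    header naming convention, preserving first-appearance order.  Ragged rows
    or non-numeric cells are errors.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableFormatError("expression table needs gene id + value columns")
        value_cols = header[1:]
        conditions: list[str] = []
        col_keys: list[tuple[str, str]] = []
        for col in value_cols:
            cond, sep, rep = col.rpartition(".")
            if not sep:
                raise TableFormatError(
                    f"expression column {col!r} not in '<condition>.<replicate>' form"
                )
            if cond not in conditions:
                conditions.append(cond)
            col_keys.append((cond, rep))
        reps_per_cond = {c: [r for cc, r in col_keys if cc == c] for c in conditions}
        n_rep = len(reps_per_cond[conditions[0]])
        for cond, reps in reps_per_cond.items():
            if len(reps) != n_rep:
                raise TableFormatError(
                    f"condition {cond!r} has {len(reps)} replicate columns, "
                    f"expected {n_rep}"
                )
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise TableFormatError(
                    f"line {lineno}: {len(parts) - 1} values, expected {len(value_cols)}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: non-numeric cell ({exc})")
    flat = np.asarray(rows, dtype=float)
    # reorder columns into (condition, replicate) blocks
    order = []
    for cond in conditions:
        order.extend(i for i, (c, _) in enumerate(col_keys) if c == cond)
    values = flat[:, order].reshape(len(gene_ids), len(conditions), n_rep)
    return ExpressionTable(gene_ids, conditions, values)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    n_rep = table.n_replicates
    cols = [f"{c}.{r + 1}" for c in table.condition_labels for r in range(n_rep)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for gid, block in zip(table.gene_ids, table.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in block.ravel()) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference data


def load_reference_pairs() -> list[GenePairRecord]:
    """Load the curated R. sphaeroides 2.4.1 in-paralog pair table.

    The 24 low-Ks in-paralog pairs with published Ka, Ks, ω, amino-acid
    divergence and expression-similarity statistics, shipped with the
    package as plain TSV.
    """
    path = Path(__file__).parent / "data" / "rsphaeroides_inparalogs.tsv"
    return read_pair_table(path)
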