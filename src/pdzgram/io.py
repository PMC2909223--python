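"""Readers and writers for the pipeline's on-disk formats.

Sequences and alignments travel as FASTA; interaction tables, class tables
and region tables as headered TSV (comma-separated accepted via ``sep``);
evaluation reports as a single JSON document.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Sequence",
    "InteractionRecord",
    "ClassRecord",
    "DatasetSummary",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_interactions",
    "write_interactions",
    "read_classes",
    "write_classes",
    "read_regions",
    "dataset_summary",
    "write_report_json",
]

BINDING = "binding"
NON_BINDING = "non-binding"
DOMAIN_CLASSES = ("I", "II", "I-II")

_LABEL_SYNONYMS = {
    "binding": BINDING,
    "non-binding": NON_BINDING,
    "nonbinding": NON_BINDING,
    "non_binding": NON_BINDING,
    "1": BINDING,
    "0": NON_BINDING,
}


@dataclass(frozen=True)
class Sequence:
    """A named amino-acid sequence (domain, peptide, or alignment row)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionRecord:
    """One domain-peptide pair with its observed binary label."""

    pdz_id: str
    peptide_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (BINDING, NON_BINDING):
            raise ValueError(f"label must be '{BINDING}' or '{NON_BINDING}', got {self.label!r}")


@dataclass(frozen=True)
class ClassRecord:
    """Specificity-class assignment of one PDZ domain."""

    pdz_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in DOMAIN_CLASSES:
            raise ValueError(f"class must be one of {DOMAIN_CLASSES}, got {self.label!r}")


class DatasetSummary(NamedTuple):
    n_binding: int
    n_nonbinding: int
    n_domains: int
    n_peptides: int


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file; ids must be unique, the file non-empty."""
    records = [Sequence(id=r.id, residues=str(r.seq).strip().upper())
               for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    dupes = [sid for sid, k in Counter(r.id for r in records).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate sequence ids in {path}: {', '.join(sorted(dupes))}")
    return records


def write_fasta(sequences: Iterable[Sequence], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences),
        str(path), "fasta",
    )


def read_alignment(path: str | Path) -> list[Sequence]:
    """Read an aligned FASTA (gaps ``-`` preserved); rows must share one width."""
    rows = read_fasta(path)
    width = len(rows[0].residues)
    ragged = [r.id for r in rows if len(r.residues) != width]
    if ragged:
        raise ValueError(f"ragged alignment in {path}: rows {', '.join(ragged)} "
                         f"differ from width {width}")
    return rows


def _read_table(path: str | Path, columns: tuple[str, ...], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_interactions(path: str | Path, sep: str = "\t") -> list[InteractionRecord]:
    """Read a headered interaction table (pdz_id, peptide_id, label).

    Labels are normalized case-insensitively; ``1``/``0`` are accepted as
    synonyms for binding/non-binding.
    """
    df = _read_table(path, ("pdz_id", "peptide_id", "label"), sep)
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        label = _LABEL_SYNONYMS.get(str(row.label).strip().lower())
        if label is None:
            raise ValueError(f"{path}: unknown label {row.label!r} at line {i + 2}")
        pair = (row.pdz_id, row.peptide_id)
        if pair in seen:
            raise ValueError(f"{path}: duplicate pair {pair} at line {i + 2}")
        seen.add(pair)
        records.append(InteractionRecord(row.pdz_id, row.peptide_id, label))
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    pd.DataFrame([(r.pdz_id, r.peptide_id, r.label) for r in records],
                 columns=["pdz_id", "peptide_id", "label"]).to_csv(path, sep="\t", index=False)


def read_classes(path: str | Path, sep: str = "\t") -> list[ClassRecord]:
    """Read a headered domain-class table (pdz_id, class)."""
    df = _read_table(path, ("pdz_id", "class"), sep)
    records: list[ClassRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        # "class" is a keyword, so itertuples positional access is unreliable
        label = str(df.iloc[i]["class"]).strip()
        if label not in DOMAIN_CLASSES:
            raise ValueError(f"{path}: unknown class {label!r} at line {i + 2}")
        if row.pdz_id in seen:
            raise ValueError(f"{path}: duplicate pdz_id {row.pdz_id!r} at line {i + 2}")
        seen.add(row.pdz_id)
        records.append(ClassRecord(row.pdz_id, label))
    return records


def write_classes(records: Iterable[ClassRecord], path: str | Path) -> None:
    pd.DataFrame([(r.pdz_id, r.label) for r in records],
                 columns=["pdz_id", "class"]).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path, sep: str = "\t") -> list[tuple[str, int, int]]:
    """Read a secondary-structure region table (label, start_col, end_col).

    Intervals are half-open alignment-column ranges.
    """
    df = _read_table(path, ("label", "start_col", "end_col"), sep)
    return [(row.label, int(row.start_col), int(row.end_col))
            for row in df.itertuples(index=False)]


def dataset_summary(records: Iterable[InteractionRecord],
                    sequences: Iterable[Sequence]) -> DatasetSummary:
    """Label and id counts of an interaction table.

    Every id referenced by a record must resolve to a sequence.
    """
    records = list(records)
    known = {s.id for s in sequences}
    missing = sorted({i for r in records for i in (r.pdz_id, r.peptide_id) if i not in known})
    if missing:
        raise ValueError(f"interaction table references unknown sequence ids: "
                         f"{', '.join(missing[:10])}" + (" ..." if len(missing) > 10 else ""))
    return DatasetSummary(
        n_binding=sum(r.label == BINDING for r in records),
        n_nonbinding=sum(r.label == NON_BINDING for r in records),
        n_domains=len({r.pdz_id for r in records}),
        n_peptides=len({r.peptide_id for r in records}),
    )


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
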