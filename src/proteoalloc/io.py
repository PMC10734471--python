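"""Readers and writers for the four input artifacts and all result tables.

All tabular formats are UTF-8 tab-separated text with a header row:

* abundance table — ``protein_id\\t<sample1>\\t<sample2>...``; blank cells
  (or any configured missing token) are non-detections.  A literal ``0`` is a
  recorded value, not a non-detection: label-free pipelines emit blanks for
  non-detections and the meaning of an explicit zero is ambiguous upstream,
  so the loader is conservative and the log2 stage converts zeros to missing
  explicitly.
* design — ``sample_id\\tcondition\\treplicate``
* annotations — ``protein_id\\tkog\\tkegg`` (multi-letter KOG cells such as
  ``CI`` denote membership in several classes)
* sequences — FASTA; the record id is the token before the first whitespace.

The loaders are deliberately strict: duplicate ids, negative abundances and
ragged rows are hard errors naming the offending entity, and sample columns
are matched to design rows by exact, case-sensitive string equality.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    AMINO_ACIDS,
    AnnotationCatalog,
    ProteinSequenceSet,
    SampleDesign,
    validate_abundance_matrix,
)
from .curation import KOG_CLASSES

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "read_abundance_table",
    "write_abundance_table",
    "read_design",
    "read_annotations",
    "read_fasta_sequences",
    "write_table",
]

#: Cell contents treated as MISSING in the abundance table.  "0" is absent
#: on purpose — an explicit zero is a recorded value.
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA", "NaN", "nan", "N/A"})


def read_abundance_table(
    path: str | Path,
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
) -> pd.DataFrame:
    """Load a proteins x samples abundance table.

    Returns a float DataFrame with protein ids on the index, sample ids on
    the columns, and ``NaN`` wherever the file held a missing token.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty abundance table")
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: header must have a protein_id column and >=1 sample")
    sample_ids = header[1:]
    n_cols = len(header)
    protein_ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {n_cols})"
            )
        pid = row[0]
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r} at line {lineno}")
        seen.add(pid)
        parsed: list[float] = []
        for sample, cell in zip(sample_ids, row[1:]):
            if cell.strip() in missing_tokens:
                parsed.append(np.nan)
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparseable abundance {cell!r} for protein "
                    f"{pid!r} in sample {sample!r} (line {lineno})"
                ) from exc
            if value < 0:
                raise ValueError(
                    f"{path}: negative abundance {cell} for protein "
                    f"{pid!r} in sample {sample!r} (line {lineno})"
                )
            parsed.append(value)
        protein_ids.append(pid)
        data.append(parsed)
    matrix = pd.DataFrame(data, index=protein_ids, columns=sample_ids, dtype=float)
    matrix.index.name = "protein_id"
    return validate_abundance_matrix(matrix)


def write_abundance_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an abundance matrix; ``NaN`` cells become blanks.

    Values are written with shortest round-trip ``repr`` so that
    ``read_abundance_table(write_abundance_table(m))`` is bit-exact.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("protein_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for pid, row in zip(matrix.index, matrix.to_numpy(dtype=float)):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


def read_design(path: str | Path) -> SampleDesign:
    """Load the sample design table (sample_id, condition, replicate)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    if len(table) == 0:
        raise ValueError(f"{path}: no samples")
    required = ["sample_id", "condition", "replicate"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: design table missing columns {missing}")
    reps = table["replicate"]
    as_float = pd.to_numeric(reps, errors="coerce")
    if as_float.isna().any() or (as_float != as_float.round()).any():
        bad = table.loc[as_float.isna() | (as_float != as_float.round()), "sample_id"].iloc[0]
        raise ValueError(f"{path}: non-integer replicate for sample {bad!r}")
    table = table.assign(replicate=as_float.astype(int))
    return SampleDesign(table[required].reset_index(drop=True))


def read_annotations(path: str | Path) -> AnnotationCatalog:
    """Load per-protein KOG letters and KEGG pathway names.

    Multi-letter KOG cells (e.g. ``CI``) split into a set; letters outside
    the 23-letter KOG alphabet are a hard error.  KEGG cells hold pathway
    names separated by ``;``.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein_id", "kog", "kegg"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    if table["protein_id"].duplicated().any():
        dup = table.loc[table["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise ValueError(f"{path}: duplicate protein id {dup!r}")
    kog: dict[str, frozenset[str]] = {}
    kegg: dict[str, frozenset[str]] = {}
    description: dict[str, str] = {}
    has_desc = "description" in table.columns
    for _, row in table.iterrows():
        pid = row["protein_id"]
        letters = frozenset(row["kog"].strip())
        unknown = letters - set(KOG_CLASSES)
        if unknown:
            raise ValueError(
                f"{path}: unknown KOG class {sorted(unknown)} for protein {pid!r}"
            )
        kog[pid] = letters
        paths = frozenset(p.strip() for p in row["kegg"].split(";") if p.strip())
        kegg[pid] = paths
        if has_desc:
            description[pid] = row["description"]
    return AnnotationCatalog(kog=kog, kegg=kegg, description=description)


def write_annotations(catalog: AnnotationCatalog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("protein_id\tkog\tkegg\n")
        for pid in catalog.kog:
            letters = "".join(sorted(catalog.kog[pid]))
            paths = ";".join(sorted(catalog.kegg.get(pid, frozenset())))
            fh.write(f"{pid}\t{letters}\t{paths}\n")


def read_fasta_sequences(path: str | Path) -> ProteinSequenceSet:
    """Load protein sequences from FASTA, cleaning nonstandard residues.

    Letters outside the 20 standard amino acids (X, U, B, Z, ``*``, gaps)
    are removed and counted per protein; a record that becomes empty after
    cleaning, or a duplicated id, is a hard error.
    """
    path = Path(path)
    alphabet = set(AMINO_ACIDS)
    sequences: dict[str, str] = {}
    dropped: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in sequences:
            raise ValueError(f"{path}: duplicate id {pid!r}")
        raw = str(record.seq).upper()
        clean = "".join(ch for ch in raw if ch in alphabet)
        if not clean:
            raise ValueError(f"{path}: record {pid!r} empty after cleaning")
        sequences[pid] = clean
        dropped[pid] = len(raw) - len(clean)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return ProteinSequenceSet(sequences=sequences, dropped_residues=dropped)


def write_fasta_sequences(seqs: ProteinSequenceSet, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for pid, seq in seqs.sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV (deterministic byte layout)."""
    frame.to_csv(Path(path), sep="\t", index=index, lineterminator="\n", na_rep="NA")
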