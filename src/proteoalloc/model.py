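"""Shared data model for the analysis pipeline.

The abundance matrix itself is a plain :class:`pandas.DataFrame` with
protein ids on the index, sample ids on the columns and ``NaN`` marking
non-detections ("MISSING").  The light wrapper classes here carry the
companion artifacts — the sample design, functional annotations and
protein sequences — together with their validity invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "AnnotationCatalog",
    "ProteinSequenceSet",
    "PathwayDefinition",
    "validate_abundance_matrix",
]

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")


def validate_abundance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check abundance-matrix invariants and return the frame unchanged.

    Invariants: unique protein ids (index), unique sample ids (columns),
    at least one protein and one sample, every non-missing value >= 0.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("abundance matrix needs at least 1 protein and 1 sample")
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate protein id: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        row, col = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance {values[row, col]} for protein "
            f"{matrix.index[row]!r} in sample {matrix.columns[col]!r}"
        )
    return matrix


@dataclass(frozen=True)
class SampleDesign:
    """Maps samples to condition groups with replicate indices."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("no samples in design")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in design: {dup!r}")
        reps = self.table["replicate"]
        if not np.issubdtype(np.asarray(reps).dtype, np.integer):
            raise ValueError("replicate indices must be integers")
        if (np.asarray(reps) < 1).any():
            raise ValueError("replicate indices must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        if condition not in set(self.table["condition"]):
            raise KeyError(f"unknown condition: {condition!r}")
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])

    def groups(self) -> dict[str, list[str]]:
        return {c: self.samples_for(c) for c in self.conditions}

    def check_matches(self, matrix: pd.DataFrame) -> None:
        """Every designed sample must be a column of the matrix (exact match)."""
        missing = [s for s in self.sample_ids if s not in matrix.columns]
        if missing:
            raise ValueError(f"design samples absent from abundance matrix: {missing}")


@dataclass(frozen=True)
class AnnotationCatalog:
    """Per-protein functional annotation: KOG class letters and KEGG pathways."""

    kog: dict[str, frozenset[str]]
    kegg: dict[str, frozenset[str]]
    description: dict[str, str] = field(default_factory=dict)

    def proteins_in_class(self, letter: str) -> set[str]:
        return {p for p, classes in self.kog.items() if letter in classes}

    def proteins_in_kegg(self, pathway: str) -> set[str]:
        return {p for p, paths in self.kegg.items() if pathway in paths}

    def __len__(self) -> int:
        return len(self.kog)


@dataclass(frozen=True)
class ProteinSequenceSet:
    """Cleaned amino-acid sequences over the 20-letter standard alphabet.

    Nonstandard residues (X, U, B, Z, ``*``, gaps, ...) are removed at load
    and counted per protein in ``dropped_residues``.
    """

    sequences: dict[str, str]
    dropped_residues: dict[str, int]

    def __post_init__(self) -> None:
        alphabet = set(AMINO_ACIDS)
        for pid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence after cleaning for {pid!r}")
            bad = set(seq) - alphabet
            if bad:
                raise ValueError(f"nonstandard residues {sorted(bad)} in {pid!r}")

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def residue_counts(self, protein_ids: list[str] | None = None) -> pd.DataFrame:
        """Residue-count matrix (proteins x 20 amino acids)."""
        ids = list(self.sequences) if protein_ids is None else list(protein_ids)
        missing = [p for p in ids if p not in self.sequences]
        if missing:
            raise KeyError(f"no sequence for proteins: {missing}")
        counts = np.zeros((len(ids), len(AMINO_ACIDS)), dtype=np.int64)
        # map residue byte values to column indices once, then bincount
        code_of = np.full(128, -1, dtype=np.int64)
        for j, aa in enumerate(AMINO_ACIDS):
            code_of[ord(aa)] = j
        for i, pid in enumerate(ids):
            codes = code_of[
                np.frombuffer(self.sequences[pid].encode("ascii"), dtype=np.uint8)
            ]
            counts[i] = np.bincount(codes, minlength=len(AMINO_ACIDS))
        return pd.DataFrame(counts, index=ids, columns=list(AMINO_ACIDS))


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway: a set of member protein ids (size M).

    Members need not all be quantified in a given matrix; absent members
    simply contribute zero mass fraction.
    """

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("pathway name must be nonempty")
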