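"""Proteome mass-fraction allocation statistics.

Three nested statistics describe how a cell allocates its measured proteome:

* protein mass fraction  f_Pi  = PA_i / sum_k PA_k         (per sample)
* pathway mass fraction  f_Path = sum_{i in pathway} f_Pi
* amino-acid mass fraction
  f_Aj = sum_i AA_ij * f_Pi / sum_j sum_i AA_ij * f_Pi
  where AA_ij is the count of residue j in protein i's sequence — the
  abundance-weighted residue usage of the whole measured proteome.

All three are computed on the RAW abundance matrix, without filtering or
imputation; a missing (undetected) protein contributes zero mass.  The
fractions are dimensionless shares: each f_Pi vector and each f_Aj vector
sums to exactly 1, and every statistic is invariant to rescaling a sample's
abundances by any positive constant.

Condition-level figures aggregate fractions first and average second: the
per-sample fraction vectors of a condition's replicates are averaged, which
keeps the summary invariant to per-sample rescaling (fractions of pooled
raw abundances would not be).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import KOG_CLASSES
from .de import _pooled_t
from .model import (
    AMINO_ACIDS,
    AnnotationCatalog,
    PathwayDefinition,
    ProteinSequenceSet,
    SampleDesign,
)

__all__ = [
    "protein_mass_fractions",
    "mass_fraction_matrix",
    "pathway_mass_fraction",
    "aa_mass_fractions",
    "condition_summary",
    "percent_change",
    "AllocationComparison",
    "compare_pathway_allocation",
    "compare_aa_allocation",
    "class_fraction_table",
    "TopKCoverage",
    "top_k_coverage",
]


def protein_mass_fractions(matrix: pd.DataFrame, sample_id: str) -> pd.Series:
    """Per-protein mass fractions f_Pi for one sample of the raw matrix.

    Missing abundances contribute 0 to both numerator and denominator, so
    the returned vector sums to 1 over the detected proteome.
    """
    if sample_id not in matrix.columns:
        raise KeyError(f"unknown sample: {sample_id!r}")
    col = matrix[sample_id].to_numpy(dtype=float)
    if np.nanmin(col, initial=0.0) < 0:
        raise ValueError("abundances must be non-negative")
    mass = np.nan_to_num(col, nan=0.0)
    total = mass.sum()
    if total <= 0:
        raise ValueError(f"empty proteome: sample {sample_id!r} has no positive abundance")
    return pd.Series(mass / total, index=matrix.index, name=sample_id)


def mass_fraction_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """f_Pi for every sample (proteins x samples; columns each sum to 1)."""
    return pd.concat(
        [protein_mass_fractions(matrix, s) for s in matrix.columns], axis=1
    )


def pathway_mass_fraction(fractions, pathway: PathwayDefinition):
    """f_Path: summed protein fractions of a pathway's members.

    ``fractions`` may be a Series (one sample -> float) or a DataFrame
    (proteins x samples -> Series per sample).  Members absent from the
    index contribute 0.
    """
    present = [p for p in pathway.members if p in fractions.index]
    if isinstance(fractions, pd.Series):
        return float(fractions.loc[present].sum()) if present else 0.0
    summed = fractions.loc[present].sum(axis=0) if present else pd.Series(
        0.0, index=fractions.columns
    )
    summed.name = pathway.name
    return summed


def aa_mass_fractions(
    fractions: pd.Series, sequences: ProteinSequenceSet
) -> pd.Series:
    """Abundance-weighted amino-acid mass fractions f_Aj (20 entries, sum 1)."""
    detected = list(fractions.index[fractions > 0])
    missing = [p for p in detected if p not in sequences]
    if missing:
        raise KeyError(f"no sequence for detected proteins: {missing}")
    counts = sequences.residue_counts(detected)  # proteins x 20
    weighted = counts.to_numpy(dtype=float).T @ fractions.loc[detected].to_numpy()
    total = weighted.sum()
    if total <= 0:
        raise ValueError("all detected proteins have empty sequences")
    return pd.Series(weighted / total, index=list(AMINO_ACIDS), name=fractions.name)


def condition_summary(
    per_sample: pd.Series, design: SampleDesign, condition: str
) -> tuple[float, float, int, pd.Series]:
    """(mean, sd, n, replicate values) of a per-sample statistic in one condition.

    With a single replicate the sd is undefined and reported as NaN with a
    warning.
    """
    samples = design.samples_for(condition)
    missing = [s for s in samples if s not in per_sample.index]
    if missing:
        raise KeyError(f"per-sample values missing for samples: {missing}")
    values = per_sample.loc[samples]
    n = len(values)
    mean = float(values.mean())
    if n < 2:
        warnings.warn(
            f"condition {condition!r} has a single replicate; sd undefined",
            stacklevel=2,
        )
        return mean, float("nan"), n, values
    return mean, float(values.std(ddof=1)), n, values


def percent_change(f_ref: float, f_alt: float) -> float:
    """Relative percent change 100*(f_alt - f_ref)/f_ref; NaN if f_ref = 0."""
    if f_ref == 0:
        warnings.warn("reference fraction is 0; percent change undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (f_alt - f_ref) / f_ref


@dataclass(frozen=True)
class AllocationComparison:
    """Condition-vs-condition comparison of one allocation quantity.

    fold_change is alternate-over-reference on the replicate means;
    percent_change = 100*(fold_change - 1); the p-value comes from a
    two-sided pooled-variance t-test on the replicate-level values.
    """

    name: str
    condition_ref: str
    condition_alt: str
    mean_ref: float
    mean_alt: float
    fold_change: float
    percent_change: float
    p_value: float


def _replicate_fractions(
    matrix: pd.DataFrame, design: SampleDesign, pathway: PathwayDefinition
) -> pd.Series:
    fractions = mass_fraction_matrix(matrix[design.sample_ids])
    return pathway_mass_fraction(fractions, pathway)


def compare_pathway_allocation(
    matrix: pd.DataFrame,
    design: SampleDesign,
    pathway: PathwayDefinition,
    condition_ref: str,
    condition_alt: str,
) -> AllocationComparison:
    """Compare f_Path between two conditions on replicate-level fractions."""
    per_sample = _replicate_fractions(matrix, design, pathway)
    ref = per_sample.loc[design.samples_for(condition_ref)].to_numpy(dtype=float)
    alt = per_sample.loc[design.samples_for(condition_alt)].to_numpy(dtype=float)
    if len(ref) < 2 or len(alt) < 2:
        raise ValueError("both conditions need >= 2 replicates for the comparison")
    mean_ref, mean_alt = float(ref.mean()), float(alt.mean())
    if mean_ref == 0:
        warnings.warn(
            f"reference condition {condition_ref!r} has zero mean fraction for "
            f"{pathway.name!r}; fold change undefined",
            stacklevel=2,
        )
        fold = float("nan")
        pct = float("nan")
    else:
        fold = mean_alt / mean_ref
        pct = 100.0 * (fold - 1.0)
    _, p = _pooled_t(ref[None, :], alt[None, :])
    return AllocationComparison(
        name=pathway.name,
        condition_ref=condition_ref,
        condition_alt=condition_alt,
        mean_ref=mean_ref,
        mean_alt=mean_alt,
        fold_change=fold,
        percent_change=pct,
        p_value=float(p[0]),
    )


def compare_aa_allocation(
    matrix: pd.DataFrame,
    design: SampleDesign,
    sequences: ProteinSequenceSet,
    condition_ref: str,
    condition_alt: str,
) -> pd.DataFrame:
    """Per-amino-acid allocation comparison between two conditions.

    Rows are the 20 amino acids; columns mean_ref, mean_alt, fold_change,
    percent_change, p_value.  Percent change is relative (100 * delta/ref).
    """
    fractions = mass_fraction_matrix(matrix[design.sample_ids])
    detected = list(fractions.index[(fractions > 0).any(axis=1)])
    missing = [p for p in detected if p not in sequences]
    if missing:
        raise KeyError(f"no sequence for detected proteins: {missing}")
    counts = sequences.residue_counts(detected).to_numpy(dtype=float)
    weighted = counts.T @ fractions.loc[detected].to_numpy()  # 20 x samples
    aa_table = pd.DataFrame(
        weighted / weighted.sum(axis=0, keepdims=True),
        index=list(AMINO_ACIDS),
        columns=design.sample_ids,
    )
    ref = aa_table[design.samples_for(condition_ref)].to_numpy(dtype=float)
    alt = aa_table[design.samples_for(condition_alt)].to_numpy(dtype=float)
    if ref.shape[1] < 2 or alt.shape[1] < 2:
        raise ValueError("both conditions need >= 2 replicates for the comparison")
    mean_ref, mean_alt = ref.mean(axis=1), alt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_ref > 0, mean_alt / mean_ref, np.nan)
    _, p = _pooled_t(ref, alt)
    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "fold_change": fold,
            "percent_change": 100.0 * (fold - 1.0),
            "p_value": p,
        },
        index=list(AMINO_ACIDS),
    )


def class_fraction_table(
    matrix: pd.DataFrame,
    annotations: AnnotationCatalog,
    letters: list[str] | None = None,
) -> pd.DataFrame:
    """Per-KOG-class mass fractions (classes x samples).

    A protein annotated to several classes contributes its full mass to
    each of them, so the column sums may exceed 1; an ``unannotated`` row
    carries the mass of proteins without any KOG letter.
    """
    letters = list(KOG_CLASSES) if letters is None else list(letters)
    unknown = [c for c in letters if c not in KOG_CLASSES]
    if unknown:
        raise KeyError(f"unknown KOG class letters: {unknown}")
    fractions = mass_fraction_matrix(matrix)
    rows = {}
    for letter in letters:
        members = annotations.proteins_in_class(letter)
        rows[letter] = pathway_mass_fraction(
            fractions, PathwayDefinition(name=f"KOG:{letter}", members=frozenset(members))
        )
    annotated = {
        p for p, classes in annotations.kog.items() if classes
    }
    unann = frozenset(set(matrix.index) - annotated)
    rows["unannotated"] = pathway_mass_fraction(
        fractions, PathwayDefinition(name="unannotated", members=unann)
    )
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class TopKCoverage:
    classes: tuple[str, ...]
    cumulative_fraction: float
    per_class: pd.Series
    unannotated_fraction: float


def top_k_coverage(
    fractions: pd.Series, annotations: AnnotationCatalog, k: int = 7
) -> TopKCoverage:
    """Top-k KOG classes of one sample's fraction vector by mass share."""
    if not 1 <= k <= len(KOG_CLASSES):
        raise ValueError(f"k must be in [1, {len(KOG_CLASSES)}], got {k}")
    per_class = pd.Series(
        {
            letter: pathway_mass_fraction(
                fractions,
                PathwayDefinition(
                    name=f"KOG:{letter}",
                    members=frozenset(annotations.proteins_in_class(letter)),
                ),
            )
            for letter in KOG_CLASSES
        }
    ).sort_values(ascending=False, kind="stable")
    annotated = {p for p, classes in annotations.kog.items() if classes}
    unann = frozenset(set(fractions.index) - annotated)
    unann_frac = pathway_mass_fraction(
        fractions, PathwayDefinition(name="unannotated", members=unann)
    )
    top = per_class.iloc[:k]
    return TopKCoverage(
        classes=tuple(top.index),
        cumulative_fraction=float(top.sum()),
        per_class=per_class,
        unannotated_fraction=float(unann_frac),
    )
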