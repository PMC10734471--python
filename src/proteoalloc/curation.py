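"""Built-in functional curation.

Two constant tables ship with the package: the 23 single-letter KOG
(euKaryotic Orthologous Groups) functional classes used to annotate the
*Yarrowia lipolytica* proteome, and a hand-curated hydrocarbon-degradation
route from terminal alkane oxidation in the endoplasmic reticulum to
peroxisomal beta-oxidation, with per-step member proteins.

The KOG scheme as originally defined has 25 functional categories; fungal
proteome annotations routinely lack N (cell motility) and W (extracellular
structures), leaving the 23 classes used here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import AnnotationCatalog, PathwayDefinition

__all__ = [
    "KOG_CLASSES",
    "builtin_kog_classes",
    "CuratedPathway",
    "builtin_hydrocarbon_pathway",
    "map_to_pathways",
    "read_curated_pathway",
    "write_curated_pathway",
]

#: The 23 KOG functional classes (letter -> class name).
KOG_CLASSES: dict[str, str] = {
    "A": "RNA processing and modification",
    "B": "Chromatin structure and dynamics",
    "C": "Energy production and conversion",
    "D": "Cell cycle control, cell division, chromosome partitioning",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "G": "Carbohydrate transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "J": "Translation, ribosomal structure and biogenesis",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "M": "Cell wall/membrane/envelope biogenesis",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
    "T": "Signal transduction mechanisms",
    "U": "Intracellular trafficking, secretion, and vesicular transport",
    "V": "Defense mechanisms",
    "Y": "Nuclear structure",
    "Z": "Cytoskeleton",
}

#: Identifier pattern for Y. lipolytica CLIB122-style protein ids.
YALI_ID_PATTERN = re.compile(r"^YALI0[A-F]\d{5}p$")

#: Curated ids that deviate from the pattern, stored verbatim from the
#: source curation (likely a truncated "p" suffix; kept as published).
YALI_ID_EXCEPTIONS: frozenset[str] = frozenset({"YALI0D04422"})


def builtin_kog_classes() -> pd.DataFrame:
    """The constant 23-row KOG class table (columns: letter, name)."""
    return pd.DataFrame(
        {"letter": list(KOG_CLASSES), "name": list(KOG_CLASSES.values())}
    )


@dataclass(frozen=True)
class PathwayStep:
    name: str
    members: frozenset[str]
    note: str = ""


@dataclass(frozen=True)
class CuratedPathway:
    """An ordered multi-step pathway with per-step protein membership."""

    name: str
    steps: tuple[PathwayStep, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [s.name for s in self.steps]
        if len(set(names)) != len(names):
            raise ValueError("step names must be unique")
        seen: set[str] = set()
        for step in self.steps:
            overlap = seen & step.members
            if overlap:
                raise ValueError(f"protein(s) {sorted(overlap)} appear in multiple steps")
            seen |= step.members

    @property
    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= step.members
        return frozenset(out)

    def step_of(self, protein_id: str) -> str:
        for step in self.steps:
            if protein_id in step.members:
                return step.name
        raise KeyError(f"{protein_id!r} is not in pathway {self.name!r}")

    def as_definition(self) -> PathwayDefinition:
        return PathwayDefinition(name=self.name, members=self.all_members)

    def step_definitions(self) -> list[PathwayDefinition]:
        return [PathwayDefinition(name=s.name, members=s.members) for s in self.steps]


def builtin_hydrocarbon_pathway() -> CuratedPathway:
    """The curated n-alkane degradation route of *Y. lipolytica*.

    Five sequential steps from terminal hydroxylation of the alkane to
    peroxisomal beta-oxidation of the activated fatty acid.  Only the
    detected, literature-named members ship here; the full annotated
    rosters (12 cytochrome P450s, 8 beta-oxidation enzymes) are
    user-extensible via :func:`read_curated_pathway`.
    """
    return CuratedPathway(
        name="hydrocarbon degradation",
        steps=(
            PathwayStep(
                "cytochrome P450",
                frozenset(
                    {"YALI0E25982p", "YALI0F01320p", "YALI0B13816p", "YALI0D04422"}
                ),
                note="alkane -> fatty alcohol; 4 detected of 12 annotated",
            ),
            PathwayStep(
                "fatty alcohol dehydrogenase/oxidase",
                frozenset(
                    {
                        "YALI0F09603p",
                        "YALI0E15818p",
                        "YALI0D02167p",
                        "YALI0B14014p",
                        "YALI0D25630p",
                        "YALI0E17787p",
                    }
                ),
                note="fatty alcohol -> fatty aldehyde",
            ),
            PathwayStep(
                "fatty aldehyde dehydrogenase",
                frozenset({"YALI0A17875p", "YALI0E15400p", "YALI0F23793p"}),
                note="fatty aldehyde -> fatty acid",
            ),
            PathwayStep(
                "fatty acid-CoA ligase",
                frozenset({"YALI0D17864p"}),
                note="the only annotated fatty acid-CoA ligase",
            ),
            PathwayStep(
                "beta-oxidation",
                frozenset({"YALI0E27654p", "YALI0C23859p", "YALI0E06567p"}),
                note="acyl-CoA -> acetyl-CoA; 3 named of 8 annotated",
            ),
        ),
    )


def map_to_pathways(
    annotations: AnnotationCatalog, selector: str
) -> PathwayDefinition:
    """Build a PathwayDefinition from an annotation selector.

    A single uppercase letter selects a KOG class; any other string selects
    a KEGG pathway by name.  An empty member set is allowed (f_Path = 0).
    """
    if len(selector) == 1 and selector.isupper():
        if selector not in KOG_CLASSES:
            raise KeyError(f"unknown KOG class letter: {selector!r}")
        members = annotations.proteins_in_class(selector)
        return PathwayDefinition(
            name=f"KOG:{selector}", members=frozenset(members)
        )
    all_kegg: set[str] = set()
    for paths in annotations.kegg.values():
        all_kegg |= paths
    if selector not in all_kegg:
        raise KeyError(f"unknown KEGG pathway: {selector!r}")
    return PathwayDefinition(
        name=selector, members=frozenset(annotations.proteins_in_kegg(selector))
    )


def read_curated_pathway(path: str | Path, name: str = "custom") -> CuratedPathway:
    """Read a user curation from TSV with columns step, protein_id, note."""
    table = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    required = ["step", "protein_id"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"curated pathway table missing columns {missing}")
    steps: list[PathwayStep] = []
    for step_name in dict.fromkeys(table["step"]):
        rows = table[table["step"] == step_name]
        note = rows["note"].iloc[0] if "note" in rows.columns else ""
        steps.append(
            PathwayStep(step_name, frozenset(rows["protein_id"]), note=note)
        )
    return CuratedPathway(name=name, steps=tuple(steps))


def write_curated_pathway(pathway: CuratedPathway, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("step\tprotein_id\tnote\n")
        for step in pathway.steps:
            for pid in sorted(step.members):
                fh.write(f"{step.name}\t{pid}\t{step.note}\n")
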