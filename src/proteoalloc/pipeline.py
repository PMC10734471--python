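"""End-to-end orchestration: load (or simulate) -> filter -> log2 -> impute
-> differential expression -> regulation/presence/overlap -> allocation
(protein, class/pathway, amino acid) -> ordination -> report bundle.

A single integer seed in the config drives every stochastic stage through
independent derived substreams, so adding a stage never perturbs another
stage's draws, and re-running an identical config reproduces every output
table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .allocation import (
    class_fraction_table,
    compare_aa_allocation,
    compare_pathway_allocation,
)
from .curation import KOG_CLASSES, builtin_hydrocarbon_pathway, map_to_pathways
from .de import differential_expression, overlap_counts, presence_call
from .model import PathwayDefinition
from .ordination import hclust_samples, pca_scores
from .preprocess import filter_min_valid, impute_downshifted, log2_transform
from .simulate import default_truth, simulate_dataset

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis", "write_report"]


@dataclass
class RunConfig:
    """Configuration of one analysis run (flat key-value, YAML-serializable)."""

    # either a synthetic scenario ...
    scenario: str | None = None
    # ... or the four input files
    abundance_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    sequences_path: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)  # (ref, alt)
    min_valid_frac: float = 0.70
    filter_mode: str = "all"
    fc_thresh: float = 1.0
    p_thresh: float = 0.05
    presence_min_frac: float = 0.70
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    kog_letters: list[str] = field(default_factory=lambda: list(KOG_CLASSES))
    kegg_pathways: list[str] = field(default_factory=list)
    curated_hydrocarbon: bool = False
    n_components: int = 2
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("min_valid_frac", "presence_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.p_thresh <= 1.0:
            raise ValueError(f"p_thresh must be in (0, 1], got {self.p_thresh}")
        if self.fc_thresh < 0:
            raise ValueError("fc_thresh must be >= 0")
        if self.scenario is None and self.abundance_path is None:
            raise ValueError("config needs either a scenario or input paths")
        self.comparisons = [tuple(c) for c in self.comparisons]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["comparisons"] = [list(c) for c in self.comparisons]
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class ReportBundle:
    config: RunConfig
    tables: dict[str, pd.DataFrame]
    newick: str
    log_lines: list[str]


def _derived_seed(seed: int, tag: int) -> int:
    """An independent 31-bit substream seed for one pipeline stage."""
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        truth = default_truth(config.scenario, seed=_derived_seed(config.seed, 0))
        sim = simulate_dataset(truth)
        return sim.matrix, sim.design, sim.annotations, sim.sequences
    matrix = pio.read_abundance_table(config.abundance_path)
    design = pio.read_design(config.design_path)
    annotations = pio.read_annotations(config.annotations_path)
    sequences = pio.read_fasta_sequences(config.sequences_path)
    design.check_matches(matrix)
    return matrix, design, annotations, sequences


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute every stage and collect the result tables."""
    matrix, design, annotations, sequences = _load_inputs(config)

    declared = set(design.conditions)
    for ref, alt in config.comparisons:
        undeclared = {ref, alt} - declared
        if undeclared:
            raise ValueError(
                f"comparison ({ref}, {alt}) references undeclared "
                f"condition(s) {sorted(undeclared)}"
            )

    log: list[str] = [
        f"proteoalloc {__version__}",
        f"seed: {config.seed}",
        f"conditions: {design.conditions}",
        f"n_proteins: {matrix.shape[0]}  n_samples: {matrix.shape[1]}",
        f"filter: min_valid_frac={config.min_valid_frac} mode={config.filter_mode}",
        (
            f"imputation: downshifted normal, width={config.impute_width}*sigma, "
            f"downshift={config.impute_downshift}*sigma, per sample column"
        ),
        "test: two-sided pooled-variance Student t; FDR: Benjamini-Hochberg "
        "within each comparison",
        (
            f"regulation: |log2FC| > {config.fc_thresh} (strict) and "
            f"p < {config.p_thresh} (strict)"
        ),
        f"presence threshold: {config.presence_min_frac}",
        "allocation: raw abundances, no filtering/imputation; missing = 0 mass; "
        "fractions averaged over replicates",
    ]

    tables: dict[str, pd.DataFrame] = {}

    # --- preprocessing + differential expression (filtered/imputed branch) ---
    filtered, removed = filter_min_valid(
        matrix, design, config.min_valid_frac, config.filter_mode
    )
    log.append(f"filter removed {len(removed)} of {matrix.shape[0]} proteins")
    logm = log2_transform(filtered)
    imputed = impute_downshifted(
        logm,
        width_fraction=config.impute_width,
        downshift_sd=config.impute_downshift,
        seed=_derived_seed(config.seed, 1),
    )

    calls: dict[tuple[str, str], pd.Series] = {}
    for ref, alt in config.comparisons:
        res = differential_expression(
            imputed, design, ref, alt, config.fc_thresh, config.p_thresh
        )
        tables[f"de_{ref}_vs_{alt}"] = res
        calls[(ref, alt)] = res["call"]
        n_up, n_down = int((res["call"] == "UP").sum()), int((res["call"] == "DOWN").sum())
        log.append(f"DE {alt} vs {ref}: {n_up} up, {n_down} down")

    if len(calls) >= 2:
        rows = []
        pairs = list(calls)
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                ov = overlap_counts(calls[pairs[i]], calls[pairs[j]])
                rows.append(
                    {
                        "comparison_a": f"{pairs[i][1]}_vs_{pairs[i][0]}",
                        "comparison_b": f"{pairs[j][1]}_vs_{pairs[j][0]}",
                        "n_common_up": ov.n_common_up,
                        "n_common_down": ov.n_common_down,
                        "n_up_a": ov.n_up_a,
                        "n_up_b": ov.n_up_b,
                        "n_down_a": ov.n_down_a,
                        "n_down_b": ov.n_down_b,
                    }
                )
        tables["overlaps"] = pd.DataFrame(rows)

    tables["presence"] = presence_call(matrix, design, config.presence_min_frac)

    # --- allocation branch (raw matrix) ---
    class_table = class_fraction_table(matrix, annotations, config.kog_letters)
    for cond in design.conditions:
        class_table[f"mean_{cond}"] = class_table[design.samples_for(cond)].mean(axis=1)
    tables["allocation_classes"] = class_table

    pathway_defs: list[PathwayDefinition] = [
        map_to_pathways(annotations, letter) for letter in config.kog_letters
    ] + [map_to_pathways(annotations, name) for name in config.kegg_pathways]
    if config.curated_hydrocarbon:
        curated = builtin_hydrocarbon_pathway()
        pathway_defs.append(curated.as_definition())
        pathway_defs.extend(curated.step_definitions())

    rows = []
    for ref, alt in config.comparisons:
        for pathway in pathway_defs:
            cmp_res = compare_pathway_allocation(matrix, design, pathway, ref, alt)
            rows.append(
                {
                    "pathway": pathway.name,
                    "condition_ref": ref,
                    "condition_alt": alt,
                    "mean_ref": cmp_res.mean_ref,
                    "mean_alt": cmp_res.mean_alt,
                    "fold_change": cmp_res.fold_change,
                    "percent_change": cmp_res.percent_change,
                    "p_value": cmp_res.p_value,
                }
            )
        tables[f"allocation_aa_{ref}_vs_{alt}"] = compare_aa_allocation(
            matrix, design, sequences, ref, alt
        )
    if rows:
        tables["pathway_comparisons"] = pd.DataFrame(rows)

    # --- ordination (imputed branch) ---
    k = min(config.n_components, imputed.shape[1] - 1, imputed.shape[0])
    pca = pca_scores(imputed, n_components=k)
    scores = pca.scores.copy()
    scores.columns = [
        f"{c}_({100 * v:.1f}%)"
        for c, v in zip(scores.columns, pca.explained_variance_ratio)
    ]
    scores.index.name = "sample_id"
    tables["pca_scores"] = scores
    newick = hclust_samples(imputed).to_newick()
    log.append(
        "ordination: PCA on imputed log2 matrix (centered, unscaled); "
        "hierarchical clustering euclidean/average"
    )

    return ReportBundle(config=config, tables=tables, newick=newick, log_lines=log)


def write_report(bundle: ReportBundle, outdir: str | Path | None = None) -> list[Path]:
    """Write the deterministic report file set; returns the paths written."""
    outdir = Path(bundle.config.outdir if outdir is None else outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in bundle.tables.items():
        path = outdir / f"{name}.tsv"
        pio.write_table(frame, path, index=not name.startswith("overlap") and name != "pathway_comparisons")
        written.append(path)
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(bundle.newick + "\n", encoding="utf-8")
    written.append(tree_path)
    log_path = outdir / "run_log.txt"
    config_lines = [
        f"config.{k}: {v}" for k, v in sorted(bundle.config.__dict__.items())
    ]
    log_path.write_text(
        "\n".join(bundle.log_lines + config_lines) + "\n", encoding="utf-8"
    )
    written.append(log_path)
    return written
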