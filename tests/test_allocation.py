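"""Mass-fraction statistics against independent brute-force summation."""

import numpy as np
import pandas as pd
import pytest

from proteoalloc.allocation import (
    aa_mass_fractions,
    class_fraction_table,
    compare_aa_allocation,
    compare_pathway_allocation,
    condition_summary,
    mass_fraction_matrix,
    pathway_mass_fraction,
    percent_change,
    protein_mass_fractions,
    top_k_coverage,
)
from proteoalloc.model import (
    AMINO_ACIDS,
    AnnotationCatalog,
    PathwayDefinition,
    ProteinSequenceSet,
)


def seqset(mapping):
    return ProteinSequenceSet(
        sequences=dict(mapping), dropped_residues={k: 0 for k in mapping}
    )


# ---------------------------------------------------------------- oracles


def brute_protein_fractions(abundances):
    """f_Pi = PA_i / sum(PA), missing treated as zero mass; plain loops."""
    masses = [0.0 if a is None or np.isnan(a) else a for a in abundances]
    total = sum(masses)
    return [m / total for m in masses]


def brute_aa_fractions(fractions, seqs):
    """f_Aj = sum_i AA_ij f_Pi / sum_j sum_i AA_ij f_Pi, written literally."""
    numerators = {}
    for aa in AMINO_ACIDS:
        numerators[aa] = sum(
            seqs[pid].count(aa) * f for pid, f in fractions.items()
        )
    denom = sum(numerators.values())
    return {aa: numerators[aa] / denom for aa in AMINO_ACIDS}


# ------------------------------------------------------------------ tests


class TestProteinFractions:
    def test_forced_arithmetic(self):
        m = pd.DataFrame({"s": [2.0, 3.0, 5.0]}, index=list("abc"))
        np.testing.assert_allclose(
            protein_mass_fractions(m, "s"), [0.2, 0.3, 0.5], rtol=1e-15
        )

    def test_single_detected_protein(self):
        m = pd.DataFrame({"s": [np.nan, 7.0]}, index=list("ab"))
        f = protein_mass_fractions(m, "s")
        assert f["b"] == 1.0 and f["a"] == 0.0

    def test_missing_contributes_zero_mass(self):
        m = pd.DataFrame({"s": [1.0, np.nan, 3.0]}, index=list("abc"))
        np.testing.assert_allclose(
            protein_mass_fractions(m, "s"), [0.25, 0.0, 0.75], rtol=1e-15
        )

    def test_empty_proteome_rejected(self):
        m = pd.DataFrame({"s": [0.0, np.nan]}, index=list("ab"))
        with pytest.raises(ValueError, match="empty proteome"):
            protein_mass_fractions(m, "s")

    def test_normalization_and_scale_invariance(self, hexadecane_sim):
        fractions = mass_fraction_matrix(hexadecane_sim.matrix)
        np.testing.assert_allclose(fractions.sum(axis=0), 1.0, atol=1e-9)
        scaled = hexadecane_sim.matrix * 37.5
        rescaled = mass_fraction_matrix(scaled)
        assert np.nanmax(np.abs(rescaled.to_numpy() - fractions.to_numpy())) < 1e-12


class TestPathwayFractions:
    def test_whole_proteome_sums_to_one(self):
        m = pd.DataFrame({"s": [2.0, 3.0, 5.0]}, index=list("abc"))
        f = protein_mass_fractions(m, "s")
        assert pathway_mass_fraction(f, PathwayDefinition("all", frozenset("abc"))) == 1.0

    def test_absent_members_contribute_zero(self):
        m = pd.DataFrame({"s": [2.0, 3.0]}, index=list("ab"))
        f = protein_mass_fractions(m, "s")
        assert pathway_mass_fraction(f, PathwayDefinition("none", frozenset("xy"))) == 0.0
        assert pathway_mass_fraction(
            f, PathwayDefinition("mix", frozenset("ax"))
        ) == pytest.approx(0.4)

    def test_partition_additivity(self, hexadecane_sim):
        fractions = protein_mass_fractions(hexadecane_sim.matrix, "GP24_r1")
        ids = list(fractions.index)
        parts = [frozenset(ids[i::5]) for i in range(5)]  # disjoint cover
        total = sum(
            pathway_mass_fraction(fractions, PathwayDefinition(f"part{i}", p))
            for i, p in enumerate(parts)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestAAFractions:
    def test_single_protein_single_residue(self):
        f = pd.Series({"p1": 1.0})
        out = aa_mass_fractions(f, seqset({"p1": "AAAA"}))
        assert out["A"] == 1.0 and out.drop("A").sum() == 0.0

    def test_symmetric_two_proteins(self):
        f = pd.Series({"p1": 0.5, "p2": 0.5})
        out = aa_mass_fractions(f, seqset({"p1": "AAAA", "p2": "GGGG"}))
        assert out["A"] == pytest.approx(0.5) and out["G"] == pytest.approx(0.5)

    def test_length_weighting(self):
        # numerators: A 2*0.5=1, G 6*0.5=3 -> 1/4 and 3/4
        f = pd.Series({"p1": 0.5, "p2": 0.5})
        out = aa_mass_fractions(f, seqset({"p1": "AA", "p2": "GGGGGG"}))
        assert out["A"] == pytest.approx(0.25) and out["G"] == pytest.approx(0.75)

    def test_missing_sequence_for_detected_protein_rejected(self):
        f = pd.Series({"p1": 1.0})
        with pytest.raises(KeyError, match="p1"):
            aa_mass_fractions(f, seqset({"p2": "MK"}))

    def test_sums_to_one_on_simulated_proteome(self, hexadecane_sim):
        f = protein_mass_fractions(hexadecane_sim.matrix, "HP24_r2")
        out = aa_mass_fractions(f, hexadecane_sim.sequences)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(out) == 20


class TestBruteForceEquivalence:
    def test_hundred_random_instances(self):
        """Eqs for f_Pi, f_Path and f_Aj vs literal loop summation, 1e-12."""
        rng = np.random.default_rng(42)
        aa = np.array(AMINO_ACIDS)
        for _ in range(100):
            n = 50
            ids = [f"p{i}" for i in range(n)]
            values = np.exp2(rng.normal(18, 3, size=n))
            values[rng.random(n) < 0.15] = np.nan
            if np.nansum(values) == 0:
                continue
            m = pd.DataFrame({"s": values}, index=ids)
            f = protein_mass_fractions(m, "s")
            np.testing.assert_allclose(
                f.to_numpy(), brute_protein_fractions(values), atol=1e-12
            )
            members = frozenset(rng.choice(ids, size=10, replace=False))
            fp = pathway_mass_fraction(m.pipe(protein_mass_fractions, "s"),
                                       PathwayDefinition("pw", members))
            assert fp == pytest.approx(sum(f[p] for p in members), abs=1e-12)
            seqs = {
                pid: "".join(rng.choice(aa, size=rng.integers(5, 30)))
                for pid in ids
            }
            fa = aa_mass_fractions(f, seqset(seqs))
            brute = brute_aa_fractions(f.to_dict(), seqs)
            for j in AMINO_ACIDS:
                assert fa[j] == pytest.approx(brute[j], abs=1e-12)


class TestSummariesAndComparisons:
    def test_condition_summary(self, two_by_three_design):
        vals = pd.Series(
            [0.1, 0.2, 0.3, 0.1, 0.1, 0.1],
            index=two_by_three_design.sample_ids,
        )
        mean, sd, n, _ = condition_summary(vals, two_by_three_design, "A")
        assert mean == pytest.approx(0.2) and sd == pytest.approx(0.1) and n == 3
        mean, sd, n, _ = condition_summary(vals, two_by_three_design, "B")
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_sd_undefined(self):
        from proteoalloc.model import SampleDesign

        design = SampleDesign(
            pd.DataFrame(
                {"sample_id": ["s1"], "condition": ["A"], "replicate": [1]}
            )
        )
        with pytest.warns(UserWarning, match="single replicate"):
            mean, sd, n, _ = condition_summary(pd.Series({"s1": 0.4}), design, "A")
        assert mean == 0.4 and np.isnan(sd)

    @pytest.mark.parametrize(
        "ref,alt,expected", [(0.05, 0.05, 0.0), (0.04, 0.05, 25.0), (0.05, 0.04, -20.0)]
    )
    def test_percent_change(self, ref, alt, expected):
        assert percent_change(ref, alt) == pytest.approx(expected)

    def test_percent_change_zero_reference(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(percent_change(0.0, 0.1))

    def test_pathway_comparison_forced_ratio(self, two_by_three_design):
        # pathway protein holds 10% of mass in A, 20% in B
        m = pd.DataFrame(
            {
                s: [10.0, 90.0] if s.startswith("A") else [20.0, 80.0]
                for s in two_by_three_design.sample_ids
            },
            index=["pw", "rest"],
        )
        with pytest.warns(UserWarning, match="zero pooled variance"):
            cmp_res = compare_pathway_allocation(
                m, two_by_three_design, PathwayDefinition("pw", frozenset(["pw"])),
                "A", "B",
            )
        assert cmp_res.fold_change == pytest.approx(2.0)
        assert cmp_res.percent_change == pytest.approx(100.0)
        assert cmp_res.p_value == 0.0  # zero-variance convention

    def test_pathway_comparison_pooled_t_oracle(self, two_by_three_design):
        ref_vals, alt_vals = [0.10, 0.12, 0.11], [0.20, 0.22, 0.21]
        rows = {"pw": [], "rest": []}
        for s, v in zip(
            two_by_three_design.sample_ids, ref_vals + alt_vals
        ):
            rows["pw"].append(v * 1000)
            rows["rest"].append((1 - v) * 1000)
        m = pd.DataFrame(rows, index=two_by_three_design.sample_ids).T
        cmp_res = compare_pathway_allocation(
            m, two_by_three_design, PathwayDefinition("pw", frozenset(["pw"])),
            "A", "B",
        )
        assert cmp_res.fold_change == pytest.approx(0.21 / 0.11, rel=1e-9)
        from scipy import stats

        ref_t = stats.ttest_ind(ref_vals, alt_vals, equal_var=True)
        assert cmp_res.p_value == pytest.approx(ref_t.pvalue, rel=1e-9)
        assert cmp_res.percent_change == pytest.approx(
            100 * (cmp_res.fold_change - 1), abs=1e-9
        )

    def test_fold_and_percent_consistent_on_aa_table(self, hexadecane_sim):
        aa = compare_aa_allocation(
            hexadecane_sim.matrix,
            hexadecane_sim.design,
            hexadecane_sim.sequences,
            "GP24",
            "HP24",
        )
        np.testing.assert_allclose(
            aa["percent_change"], 100 * (aa["fold_change"] - 1), atol=1e-9
        )
        assert len(aa) == 20


class TestClassCoverage:
    def test_all_mass_in_one_class(self):
        m = pd.DataFrame({"s": [4.0, 6.0]}, index=["a", "b"])
        cat = AnnotationCatalog(
            kog={"a": frozenset("C"), "b": frozenset("C")},
            kegg={"a": frozenset(), "b": frozenset()},
        )
        f = protein_mass_fractions(m, "s")
        cov = top_k_coverage(f, cat, k=1)
        assert cov.classes == ("C",) and cov.cumulative_fraction == pytest.approx(1.0)

    def test_uniform_spread_over_23_classes(self):
        from proteoalloc.curation import KOG_CLASSES

        letters = list(KOG_CLASSES)
        m = pd.DataFrame({"s": [1.0] * 23}, index=[f"p{c}" for c in letters])
        cat = AnnotationCatalog(
            kog={f"p{c}": frozenset(c) for c in letters},
            kegg={f"p{c}": frozenset() for c in letters},
        )
        cov = top_k_coverage(protein_mass_fractions(m, "s"), cat, k=7)
        assert cov.cumulative_fraction == pytest.approx(7 / 23)

    def test_k_out_of_range(self, hexadecane_sim):
        f = protein_mass_fractions(hexadecane_sim.matrix, "GP24_r1")
        with pytest.raises(ValueError):
            top_k_coverage(f, hexadecane_sim.annotations, k=0)
        with pytest.raises(ValueError):
            top_k_coverage(f, hexadecane_sim.annotations, k=24)

    def test_multi_class_proteins_count_in_each_class(self):
        m = pd.DataFrame({"s": [1.0]}, index=["a"])
        cat = AnnotationCatalog(kog={"a": frozenset("CI")}, kegg={"a": frozenset()})
        table = class_fraction_table(m, cat)
        assert table.loc["C", "s"] == 1.0 and table.loc["I", "s"] == 1.0

    def test_unannotated_mass_reported(self):
        m = pd.DataFrame({"s": [3.0, 1.0]}, index=["a", "b"])
        cat = AnnotationCatalog(
            kog={"a": frozenset("C"), "b": frozenset()},
            kegg={"a": frozenset(), "b": frozenset()},
        )
        table = class_fraction_table(m, cat)
        assert table.loc["unannotated", "s"] == pytest.approx(0.25)
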