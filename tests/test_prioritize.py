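"""Variant ingestion, filtering, gene assignment, score fusion, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from embedpvp.prioritize import (
    GeneModel,
    Variant,
    assign_genes,
    combine,
    compute_MS,
    filter_rare,
    normalize_GP,
    rank_patient,
    rank_variants,
    read_patient_vcf,
    write_ranking,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
1\t100\t.\tA\tG\t.\t.\t.
1\t200\t.\tC\tT\t.\t.\t.
1\t300\t.\tG\tA,C\t.\t.\t.
"""

ANNOT_ROWS = [
    {"chrom": "1", "pos": 100, "ref": "A", "alt": "G", "genes": "G1",
     "region_type": "exonic", "maf_1kg": 0.001, "maf_exac": 0.002,
     "maf_gnomad": 0.0005, "cadd": 25.0},
    {"chrom": "1", "pos": 200, "ref": "C", "alt": "T", "genes": "G1,G2",
     "region_type": "intronic", "maf_1kg": 0.0001, "maf_exac": np.nan,
     "maf_gnomad": np.nan, "cadd": 3.5},
    {"chrom": "1", "pos": 300, "ref": "G", "alt": "A", "genes": "G2",
     "region_type": "exonic", "maf_1kg": 0.005, "maf_exac": 0.004,
     "maf_gnomad": 0.003, "cadd": 12.0},
]


@pytest.fixture
def patient_files(tmp_path):
    vcf = tmp_path / "patient.vcf"
    vcf.write_text(VCF_TEXT)
    annot = tmp_path / "patient.annot.tsv"
    pd.DataFrame(ANNOT_ROWS).to_csv(annot, sep="\t", index=False)
    return vcf, annot


@pytest.fixture
def gene_model():
    return GeneModel(
        pd.DataFrame(
            {
                "gene_id": ["G1", "G2", "G3"],
                "chrom": ["1", "1", "1"],
                "start": [50, 180, 1000],
                "end": [150, 400, 1200],
                "strand": ["+", "-", "+"],
            }
        )
    )


class TestReadPatientVcf:
    def test_exact_join(self, patient_files):
        with pytest.warns(UserWarning):
            variants = read_patient_vcf(*patient_files)
        # 2 biallelic + one multi-allelic record split into 2
        assert len(variants) == 4
        annotated = [v for v in variants if v.cadd is not None]
        assert len(annotated) == 3
        assert annotated[0].genes == ["G1"]
        assert annotated[1].genes == ["G1", "G2"]

    def test_multiallelic_decomposition(self, patient_files):
        with pytest.warns(UserWarning, match="no annotation row"):
            variants = read_patient_vcf(*patient_files)
        alts_at_300 = sorted(v.alt for v in variants if v.pos == 300)
        assert alts_at_300 == ["A", "C"]
        missing = next(v for v in variants if v.pos == 300 and v.alt == "C")
        assert missing.genes == [] and missing.cadd is None

    def test_duplicate_annotation_keys_raise(self, tmp_path, patient_files):
        vcf, _ = patient_files
        dup = tmp_path / "dup.tsv"
        pd.DataFrame(ANNOT_ROWS + ANNOT_ROWS[:1]).to_csv(dup, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_patient_vcf(vcf, dup)


class TestFilterRare:
    def test_strict_threshold(self):
        variants = [
            Variant("1", i + 1, "A", "G", maf_by_source={"maf_1kg": maf})
            for i, maf in enumerate([0.001, 0.009, 0.01, 0.2])
        ]
        kept = filter_rare(variants, threshold=0.01)
        assert [v.maf_by_source["maf_1kg"] for v in kept] == [0.001, 0.009]

    def test_max_over_sources(self):
        v = Variant("1", 1, "A", "G",
                    maf_by_source={"maf_1kg": 0.001, "maf_exac": 0.05})
        assert filter_rare([v]) == []

    def test_missing_maf_counts_as_rare(self):
        variants = [Variant("1", i + 1, "A", "G") for i in range(3)]
        assert len(filter_rare(variants)) == 3

    def test_empty_input(self):
        assert filter_rare([]) == []

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            filter_rare([], threshold=0.0)


class TestAssignGenes:
    def test_containment_single_gene(self, gene_model):
        assert assign_genes(Variant("1", 100, "A", "G"), gene_model) == ["G1"]

    def test_overlapping_genes_all_returned(self, gene_model):
        # pos 150 (0-based 149) is the last base of G1 [50,150)
        assert assign_genes(Variant("1", 150, "A", "G"), gene_model) == ["G1"]
        overlap_model = GeneModel(
            pd.DataFrame(
                {"gene_id": ["A", "B"], "chrom": ["1", "1"],
                 "start": [0, 50], "end": [100, 150], "strand": ["+", "+"]}
            )
        )
        assert assign_genes(Variant("1", 60, "A", "G"), overlap_model) == ["A", "B"]

    def test_equidistant_intergenic_ties_return_both(self):
        model = GeneModel(
            pd.DataFrame(
                {"gene_id": ["L", "R"], "chrom": ["1", "1"],
                 "start": [0, 300], "end": [100, 400], "strand": ["+", "+"]}
            )
        )
        # 0-based 199: distance to L = 199-99 = 100; to R = 300-199 = 101
        assert assign_genes(Variant("1", 200, "A", "G"), model) == ["L"]
        # 0-based 200: 101 vs 100 -> R
        assert assign_genes(Variant("1", 201, "A", "G"), model) == ["R"]
        # equidistant midpoint 0-based 199.5 does not exist for ints; build a
        # symmetric model where distances tie exactly at 100 bp
        tied = GeneModel(
            pd.DataFrame(
                {"gene_id": ["L", "R"], "chrom": ["1", "1"],
                 "start": [0, 300], "end": [101, 400], "strand": ["+", "+"]}
            )
        )
        assert assign_genes(Variant("1", 201, "A", "G"), tied) == ["L", "R"]

    def test_unknown_chromosome_warns_empty(self, gene_model):
        with pytest.warns(UserWarning, match="absent"):
            assert assign_genes(Variant("2", 100, "A", "G"), gene_model) == []


class TestScores:
    def test_compute_ms_max_and_skip_rules(self):
        scores = {"G1": 0.2, "G2": 0.7, "G3": 0.4}

        def scorer(gene, patient):
            return scores.get(gene)

        v = Variant("1", 1, "A", "G", genes=["G1", "G2", "G3"])
        assert compute_MS(v, "P", scorer) == (0.7, False)
        v2 = Variant("1", 1, "A", "G", genes=["GX", "G1"])
        assert compute_MS(v2, "P", scorer) == (0.2, False)
        v3 = Variant("1", 1, "A", "G", genes=["GX"])
        assert compute_MS(v3, "P", scorer) == (0.0, True)

    def test_normalize_gp_minmax(self):
        variants = [Variant("1", i + 1, "A", "G", cadd=c) for i, c in
                    enumerate([10.0, 20.0, 30.0])]
        np.testing.assert_allclose(normalize_GP(variants), [0.0, 0.5, 1.0])

    def test_normalize_gp_degenerate_and_missing(self):
        single = [Variant("1", 1, "A", "G", cadd=17.0)]
        np.testing.assert_allclose(normalize_GP(single), [0.5])
        mixed = [Variant("1", 1, "A", "G", cadd=5.0), Variant("1", 2, "A", "G")]
        np.testing.assert_allclose(normalize_GP(mixed), [0.5, 0.0])

    @pytest.mark.parametrize(
        "w,ms,gp,expected",
        [(0.5, 0.6, 0.4, 0.5), (1.0, 0.9, 0.1, 0.9), (0.7, 0.9, 0.1, 0.66)],
    )
    def test_combine(self, w, ms, gp, expected):
        assert combine(ms, gp, w) == pytest.approx(expected)

    def test_combine_rejects_bad_weight(self):
        with pytest.raises(ValueError):
            combine(0.5, 0.5, 1.5)


class TestRankVariants:
    def _scored(self, rows):
        return [
            (Variant("1", pos, "A", "G"), ms, gp, s, [])
            for pos, ms, gp, s in rows
        ]

    def test_descending_by_s(self):
        ranked = rank_variants(
            self._scored([(1, 0, 0, 0.2), (2, 0, 0, 0.9), (3, 0, 0, 0.5)])
        )
        assert [rv.variant.pos for rv in ranked] == [2, 3, 1]
        assert [rv.rank for rv in ranked] == [1, 2, 3]

    def test_gp_breaks_s_ties(self):
        ranked = rank_variants(
            self._scored([(1, 0, 0.1, 0.5), (2, 0, 0.9, 0.5)])
        )
        assert [rv.variant.pos for rv in ranked] == [2, 1]

    def test_coordinate_order_breaks_full_ties(self):
        rows = [(pos, 0.2, 0.3, 0.25) for pos in (5, 3, 9, 1)]
        ranked = rank_variants(self._scored(rows))
        assert [rv.variant.pos for rv in ranked] == [1, 3, 5, 9]
        again = rank_variants(self._scored(list(reversed(rows))))
        assert [rv.variant.pos for rv in again] == [1, 3, 5, 9]


class TestPipelineProperties:
    def _variants(self, cadds):
        genes = ["G1", "G2", "G3"]
        return [
            Variant("1", i + 1, "A", "G", genes=[genes[i % 3]], cadd=c)
            for i, c in enumerate(cadds)
        ]

    def _scorer(self, gene, patient):
        return {"G1": 0.9, "G2": 0.5, "G3": 0.1}[gene]

    def test_w_boundaries_recover_pure_rankings(self):
        variants = self._variants([3.0, 11.0, 7.0, 29.0, 17.0, 23.0])
        phen = rank_patient(variants, "P", self._scorer, w=1.0)
        assert [rv.MS for rv in phen] == sorted((rv.MS for rv in phen), reverse=True)
        assert phen[0].S == phen[0].MS  # w=1: S is exactly MS
        cadd_only = rank_patient(variants, "P", self._scorer, w=0.0)
        assert [rv.variant.cadd for rv in cadd_only] == sorted(
            (v.cadd for v in variants), reverse=True
        )

    @given(st.lists(st.integers(10, 600), min_size=4, max_size=12, unique=True))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_cadd_only_ranking_invariant_to_monotone_rescale(self, deci):
        cadds = [c / 10.0 for c in deci]
        base = rank_patient(self._variants(cadds), "P", self._scorer, w=0.0)
        transformed = rank_patient(
            self._variants([np.expm1(c / 10.0) for c in cadds]),
            "P", self._scorer, w=0.0,
        )
        assert [rv.variant.pos for rv in base] == [rv.variant.pos for rv in transformed]

    @given(
        st.lists(st.integers(10, 600), min_size=4, max_size=12, unique=True),
        st.floats(0.1, 5.0), st.floats(-10.0, 10.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_full_ranking_invariant_to_affine_rescale(self, deci, a, b):
        # min-max normalization absorbs affine transforms exactly, so the
        # combined score ranking is unchanged at any weight
        cadds = [c / 10.0 for c in deci]
        base = rank_patient(self._variants(cadds), "P", self._scorer, w=0.5)
        transformed = rank_patient(
            self._variants([a * c + b for c in cadds]), "P", self._scorer, w=0.5
        )
        assert [rv.variant.pos for rv in base] == [rv.variant.pos for rv in transformed]

    def test_output_tsv_is_deterministic(self, tmp_path):
        variants = self._variants([3.0, 11.0, 7.0, 29.0])
        paths = []
        for i in range(2):
            ranked = rank_patient(variants, "P", self._scorer, w=0.5)
            path = tmp_path / f"out{i}.tsv"
            write_ranking(ranked, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]
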