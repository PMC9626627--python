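"""Core containers, VCF/TSV round-trips, allele frequencies and MAF filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from geoffset.core_data import (
    MISSING,
    AlleleFreqMatrix,
    EnvMatrix,
    GenotypeMatrix,
    PopulationMap,
    VariantTable,
    allele_frequencies,
    classify_alleles,
    global_minor_allele_freq,
    maf_filter,
    read_env_matrix,
    read_freq_matrix,
    read_population_map,
    read_variant_table,
    read_vcf,
    write_env_matrix,
    write_freq_matrix,
    write_population_map,
    write_variant_table,
    write_vcf,
)


def _toy_variants(n=3, vclass="SNP"):
    return VariantTable(
        pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "chrom": "LG01",
                "pos": np.arange(1, n + 1) * 100,
                "vclass": vclass,
                "ref_allele": "A",
                "alt_allele": "C" if vclass == "SNP" else "<DEL>",
                "ancestral": "ref",
                "func_class": "noncoding",
            }
        )
    )


def _toy_popmap():
    coords = pd.DataFrame({"lon": [100.0, 101.0], "lat": [40.0, 41.0]}, index=["A", "B"])
    return PopulationMap({"i1": "A", "i2": "A", "i3": "A", "i4": "B"}, coords)


class TestVariantTable:
    def test_rejects_duplicate_ids(self):
        df = _toy_variants().df.copy()
        df["variant_id"] = "dup"
        with pytest.raises(ValueError, match="unique"):
            VariantTable(df)

    def test_rejects_multibase_snp(self):
        df = _toy_variants().df.copy()
        df.loc[0, "alt_allele"] = "CCT"
        with pytest.raises(ValueError, match="single-base"):
            VariantTable(df)

    def test_rejects_zero_position(self):
        df = _toy_variants().df.copy()
        df.loc[0, "pos"] = 0
        with pytest.raises(ValueError, match="1-based"):
            VariantTable(df)


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,svtype,expected",
        [
            ("A", "C", None, "SNP"),
            ("A", "ACCT", None, "INDEL"),
            ("A", "A" + "C" * 55, None, "SV"),  # 55 bp insertion
            ("A", "<DEL>", None, "SV"),
            ("A", "ACCT", "DEL", "SV"),  # SVTYPE wins over length
            ("ACCT", "A", None, "INDEL"),
        ],
    )
    def test_classify(self, ref, alt, svtype, expected):
        assert classify_alleles(ref, alt, svtype) == expected


class TestVcfRoundTrip:
    def test_round_trip_with_missing_and_sv(self, tmp_path):
        variants = VariantTable(
            pd.DataFrame(
                {
                    "variant_id": ["v0", "v1", "v2"],
                    "chrom": ["LG01", "LG01", "LG02"],
                    "pos": [100, 200, 50],
                    "vclass": ["SNP", "INDEL", "SV"],
                    "ref_allele": ["A", "A", "G"],
                    "alt_allele": ["C", "ATTG", "<DEL>"],
                    "ancestral": ["ref", "ref", "ref"],
                    "func_class": ["synonymous", "noncoding", "deleterious"],
                }
            )
        )
        dosage = np.array([[0, 1, 2], [1, MISSING, 0], [2, 2, 1]], dtype=np.int8)
        G = GenotypeMatrix(["s1", "s2", "s3"], ["v0", "v1", "v2"], dosage)
        path = tmp_path / "toy.vcf"
        write_vcf(path, variants, G)
        vt2, G2 = read_vcf(path)
        assert G2 == G
        assert vt2.df["vclass"].tolist() == ["SNP", "INDEL", "SV"]
        assert vt2.df["func_class"].tolist() == ["synonymous", "noncoding", "deleterious"]

    def test_dosage_definitions(self, tmp_path):
        # GT 0/1 -> dosage 1; ./. -> missing, straight from the VCF GT field
        variants = _toy_variants(1)
        G = GenotypeMatrix(["s1", "s2"], ["v0"], np.array([[1], [MISSING]], dtype=np.int8))
        path = tmp_path / "gt.vcf"
        write_vcf(path, variants, G)
        _, G2 = read_vcf(path)
        assert G2.dosage[0, 0] == 1
        assert G2.dosage[1, 0] == MISSING


class TestAlleleFrequencies:
    def test_examples(self):
        # {0,1,2} -> 0.5; {2,2,missing} -> 1.0 with 4 alleles; all-zero -> 0
        dosage = np.array(
            [[0, 2, 0], [1, 2, 0], [2, MISSING, 0], [0, 0, 0]], dtype=np.int8
        )
        M = _toy_popmap()
        G = GenotypeMatrix(["i1", "i2", "i3", "i4"], ["v0", "v1", "v2"], dosage)
        F = allele_frequencies(G, M)
        a = F.populations.index("A")
        assert F.freq[a, 0] == pytest.approx(0.5)
        assert F.freq[a, 1] == pytest.approx(1.0)
        assert F.n_alleles[a, 1] == 4
        assert F.freq[a, 2] == 0.0

    def test_unmapped_individual_is_hard_error(self):
        M = _toy_popmap()
        G = GenotypeMatrix(["i1", "ghost"], ["v0"], np.zeros((2, 1), np.int8))
        with pytest.raises(KeyError):
            allele_frequencies(G, M)

    def test_count_conservation(self, small_sim):
        """Sum over populations of p * n_alleles equals the total alt count."""
        F = allele_frequencies(small_sim.genotypes, small_sim.popmap)
        counts = np.where(F.n_alleles > 0, F.freq * F.n_alleles, 0.0).sum(axis=0)
        dos = small_sim.genotypes.dosage
        expected = np.where(dos != MISSING, dos, 0).sum(axis=0)
        assert np.allclose(counts, expected, atol=1e-6)


class TestMafFilter:
    def test_boundary_rules(self):
        pops = ["A", "B"]
        freq = np.array([[0.05, 0.5, 0.9], [0.05, 0.5, 0.9]])
        F = AlleleFreqMatrix(pops, ["low", "mid", "high"], freq, np.full((2, 3), 20))
        _, kept = maf_filter(F, 0.10)
        # p=0.05 dropped; p=0.5 kept; p=0.9 has minor freq exactly 0.10 -> dropped (strict)
        assert kept == ["mid"]

    def test_invalid_threshold(self):
        F = AlleleFreqMatrix(["A"], ["v"], np.array([[0.5]]), np.array([[10]]))
        with pytest.raises(ValueError):
            maf_filter(F, 0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n_pop, n_var = 4, 30
        counts = rng.integers(0, 21, (n_pop, n_var))
        n_alleles = np.full((n_pop, n_var), 20)
        F = AlleleFreqMatrix(
            [f"P{i}" for i in range(n_pop)],
            [f"v{j}" for j in range(n_var)],
            counts / 20,
            n_alleles,
        )
        once, kept1 = maf_filter(F, 0.1)
        twice, kept2 = maf_filter(once, 0.1)
        assert kept1 == kept2
        assert twice == once


class TestTsvRoundTrips:
    def test_variant_table(self, tmp_path, small_sim):
        path = tmp_path / "variants.tsv"
        write_variant_table(small_sim.variants, path)
        assert read_variant_table(path) == small_sim.variants

    def test_population_map(self, tmp_path, small_sim):
        path = tmp_path / "pops.tsv"
        write_population_map(small_sim.popmap, path)
        assert read_population_map(path) == small_sim.popmap

    def test_env_matrix_with_metadata(self, tmp_path, small_sim):
        E = small_sim.env_futs[0]
        path = tmp_path / "env.tsv"
        write_env_matrix(E, path)
        back = read_env_matrix(path)
        assert back == E
        assert (back.period, back.model, back.scenario) == (E.period, E.model, E.scenario)

    def test_freq_matrix(self, tmp_path, small_sim):
        F = allele_frequencies(small_sim.genotypes, small_sim.popmap)
        path = tmp_path / "freqs.tsv"
        write_freq_matrix(F, path)
        assert read_freq_matrix(path) == F

    def test_empty_variant_table(self, tmp_path):
        empty = VariantTable(pd.DataFrame(columns=list(VariantTable.COLUMNS)))
        path = tmp_path / "empty.tsv"
        write_variant_table(empty, path)
        assert len(read_variant_table(path)) == 0
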