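from fractions import Fraction

import numpy as np
import pytest

from strpopgen.strdata import (
    MISSING,
    AlleleFrequencyTable,
    Genotype,
    GenotypeTable,
    Locus,
    ParseError,
    SchemaError,
    allele_frequencies,
    format_allele,
    parse_allele,
    read_frequency_db,
    read_genotypes,
    read_genotypes_csv,
    read_genotypes_genepop,
    write_frequency_db,
    write_genotypes_csv,
    write_genotypes_genepop,
)
from conftest import make_table


class TestAlleleLabels:
    @pytest.mark.parametrize(
        "label,tenths", [("9.3", 93), ("16", 160), ("9.30", 93), ("2.2", 22), ("0", 0)]
    )
    def test_parse_and_canonical_format(self, label, tenths):
        assert parse_allele(label) == tenths
        assert parse_allele(format_allele(tenths)) == tenths

    def test_9_30_normalizes_to_9_3(self):
        assert format_allele(parse_allele("9.30")) == "9.3"

    @pytest.mark.parametrize("bad", ["", "abc", "9.33", "-3", "9.x"])
    def test_rejects_non_repeat_labels(self, bad):
        with pytest.raises(ValueError):
            parse_allele(bad)


class TestAlleleLabelProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(tenths=st.integers(min_value=0, max_value=999))
    @settings(deadline=None, derandomize=True)
    def test_format_parse_roundtrip_on_all_tenths(self, tenths):
        assert parse_allele(format_allele(tenths)) == tenths

    @given(
        a=st.integers(min_value=0, max_value=400),
        b=st.integers(min_value=0, max_value=400),
    )
    @settings(deadline=None, derandomize=True)
    def test_genotype_canonicalization_is_order_free(self, a, b):
        g1, g2 = Genotype(a, b), Genotype(b, a)
        assert (g1.a, g1.b) == (g2.a, g2.b)
        assert g1.a <= g1.b


class TestGenotype:
    def test_canonical_order_and_heterozygosity(self):
        g = Genotype.from_labels("17", "16")
        assert (g.a, g.b) == (160, 170)
        assert g.is_heterozygous
        hom = Genotype.from_labels("9.3", "9.3")
        assert not hom.is_heterozygous

    def test_half_missing_rejected(self):
        with pytest.raises(ValueError):
            Genotype(MISSING, 100)


class TestCsvDialect:
    def test_parse_examples(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(
            "sample_id,population,D3S1358,TH01\n"
            "S1,Orel,16/17,9.3/9.3\n"
            "S2,Orel,,6/7\n"
        )
        gt = read_genotypes(p, dialect="csv")
        g = gt.genotype(0, "D3S1358")
        assert (g.a, g.b) == (160, 170) and g.is_heterozygous
        g2 = gt.genotype(0, "TH01")
        assert (g2.a, g2.b) == (93, 93) and not g2.is_heterozygous
        assert gt.genotype(1, "D3S1358").is_missing

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("sample_id,population,TH01\nS1,Orel,6-7\n")
        with pytest.raises(ParseError, match="line 2"):
            read_genotypes_csv(p)

    def test_unknown_locus_is_schema_error(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("sample_id,population,NOPE\nS1,Orel,6/7\n")
        with pytest.raises(SchemaError):
            read_genotypes_csv(p, panel=[Locus("TH01")])

    def test_roundtrip_identity(self, two_pop_table, tmp_path):
        p = tmp_path / "rt.csv"
        write_genotypes_csv(two_pop_table, p)
        assert read_genotypes_csv(p) == two_pop_table


class TestGenePop:
    def test_roundtrip_with_microvariant_code_map(self, two_pop_table, tmp_path):
        p = tmp_path / "rt.gen"
        cmap = {"9.3": 93}
        write_genotypes_genepop(two_pop_table, p, allele_code_map=cmap)
        back = read_genotypes_genepop(p, allele_code_map=cmap)
        for locus in two_pop_table.locus_names:
            assert np.array_equal(back.calls[locus], two_pop_table.calls[locus])

    def test_microvariant_without_map_fails_on_write(self, two_pop_table, tmp_path):
        with pytest.raises(ValueError, match="allele_code_map"):
            write_genotypes_genepop(two_pop_table, tmp_path / "x.gen")

    def test_odd_width_token_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nTH01\nPop\nS1 , 093\n")
        with pytest.raises(ParseError):
            read_genotypes_genepop(p)


class TestAlleleFrequencies:
    def test_basic_counting(self):
        gt = make_table({"p": {"L": [(100, 100), (100, 110)]}})
        aft = allele_frequencies(gt)
        f = aft.freqs("p", "L")
        assert f[100] == pytest.approx(0.75) and f[110] == pytest.approx(0.25)
        assert aft.gene_copies("p", "L") == 4

    def test_all_missing_cell_absent(self):
        gt = make_table(
            {"p": {"L": [(MISSING, MISSING)], "M": [(100, 100)]}}
        )
        aft = allele_frequencies(gt)
        assert aft.freqs("p", "L") == {}
        assert aft.freqs("p", "M") == {100: 1.0}

    def test_pooled_mode_equals_recount_on_merged_table(self, two_pop_table):
        aft = allele_frequencies(two_pop_table, pool={"merged": ["alpha", "beta"]})
        merged = two_pop_table.relabel_populations({"alpha": "merged", "beta": "merged"})
        recount = allele_frequencies(merged)
        for locus in two_pop_table.locus_names:
            assert aft.freqs("merged", locus) == recount.freqs("merged", locus)

    def test_merge_then_count_equals_gene_copy_weighted_average(self, two_pop_table):
        """Exact rational-arithmetic oracle for the pooling identity."""
        aft = allele_frequencies(two_pop_table, pool={"m": ["alpha", "beta"]})
        for locus in two_pop_table.locus_names:
            na = aft.gene_copies("alpha", locus)
            nb = aft.gene_copies("beta", locus)
            fa, fb = aft.freqs("alpha", locus), aft.freqs("beta", locus)
            for allele in set(fa) | set(fb):
                count_a = round(fa.get(allele, 0.0) * na)
                count_b = round(fb.get(allele, 0.0) * nb)
                want = Fraction(count_a + count_b, na + nb)
                assert aft.freqs("m", locus)[allele] == pytest.approx(float(want), abs=1e-12)

    def test_frequencies_sum_to_one(self, rng):
        gt = make_table(
            {"p": {"L": [tuple(sorted(rng.integers(80, 120, 2) * 1)) for _ in range(40)]}}
        )
        aft = allele_frequencies(gt)
        assert sum(aft.freqs("p", "L").values()) == pytest.approx(1.0, abs=1e-9)


class TestFrequencyDb:
    def test_roundtrip_identity(self, two_pop_table, tmp_path):
        aft = allele_frequencies(two_pop_table)
        p = tmp_path / "db.csv"
        write_frequency_db(aft, p)
        assert read_frequency_db(p) == aft

    def test_bad_sum_rejected(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text(
            "population,locus,allele,frequency,n_gene_copies\n"
            "p,L,9,0.5,10\np,L,10,0.48,10\n"
        )
        with pytest.raises(SchemaError, match="sum"):
            read_frequency_db(p)

    def test_reread_table_gives_identical_downstream_he(self, two_pop_table, tmp_path):
        from strpopgen.diversity import expected_heterozygosity

        aft = allele_frequencies(two_pop_table)
        p = tmp_path / "db.csv"
        write_frequency_db(aft, p)
        back = read_frequency_db(p)
        for pop in aft.populations():
            for locus in aft.loci(pop):
                f1, f2 = aft.freqs(pop, locus), back.freqs(pop, locus)
                n = aft.gene_copies(pop, locus)
                assert expected_heterozygosity(f1, n) == pytest.approx(
                    expected_heterozygosity(f2, n), abs=1e-12
                )


class TestTableValidation:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(SchemaError):
            GenotypeTable(
                [Locus("L")],
                ["a", "a"],
                ["p", "p"],
                {"L": np.array([[100, 100], [100, 100]])},
            )

    def test_empty_population_rejected(self):
        with pytest.raises(SchemaError):
            GenotypeTable(
                [Locus("L")], ["a"], [""], {"L": np.array([[100, 100]])}
            )
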