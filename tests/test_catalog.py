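"""Catalog construction: GC content, site-type expansion, scanning, annotation IO."""

import pytest
from hypothesis import given, settings, strategies as st

from mrequant.catalog import (
    MRESite,
    SeedMotif,
    UTRRecord,
    build_mre_catalog,
    find_occurrences,
    gc_content,
    load_utr_annotation,
    reverse_complement,
    seed_to_site_sequences,
)

MIR1 = "UGGAAUGUAAAGAAGUAUGUAU"

dna = st.text(alphabet="ACGT", min_size=1, max_size=500)


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5), ("GCNN", 1.0), ("ANT", 0.0)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    @pytest.mark.parametrize("seq", ["", "NNN", "ATXG"])
    def test_invalid_inputs_rejected(self, seq):
        with pytest.raises(ValueError):
            gc_content(seq)

    @given(a=dna, b=dna)
    @settings(max_examples=50, derandomize=True)
    def test_concatenation_is_length_weighted_mean(self, a, b):
        whole = gc_content(a + b)
        weighted = (gc_content(a) * len(a) + gc_content(b) * len(b)) / (len(a) + len(b))
        assert whole == pytest.approx(weighted)


class TestSeedToSites:
    def test_mir1_expansion(self):
        # reverse complement of miR-1 positions 2-8 (GGAAUGU) is ACATTCC
        assert seed_to_site_sequences(MIR1) == {
            "7mer-m8": "ACATTCC",
            "8mer": "ACATTCCA",
            "7mer-A1": "CATTCCA",
            "6mer": "CATTCC",
        }

    def test_homopolymer(self):
        assert seed_to_site_sequences("AAAAAAAA") == {
            "7mer-m8": "TTTTTTT",
            "8mer": "TTTTTTTA",
            "7mer-A1": "TTTTTTA",
            "6mer": "TTTTTT",
        }

    @given(mirna=st.text(alphabet="ACGU", min_size=8, max_size=24))
    @settings(max_examples=50, derandomize=True)
    def test_definitional_relations(self, mirna):
        s = seed_to_site_sequences(mirna)
        assert s["7mer-m8"].endswith(s["6mer"])
        assert s["7mer-A1"] == s["6mer"] + "A"
        assert s["8mer"] == s["7mer-m8"] + "A"
        # site reproduces miRNA positions 2-8 (8mer case, minus the appended A)
        dna_mirna = mirna.replace("U", "T")
        assert reverse_complement(s["8mer"][:-1]) == dna_mirna[1:8]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            seed_to_site_sequences("UGGAAUG")


def _utr(seq, gene="geneA"):
    return UTRRecord(gene, "chr1", "+", [(0, len(seq))], seq)


class TestBuildCatalog:
    def test_longest_site_wins(self):
        cat = build_mre_catalog([_utr("AAACATTCCAAA")], [SeedMotif("miR-1", MIR1)])
        assert [(s.site_type, s.utr_offset, s.site_seq) for s in cat.sites] == [
            ("8mer", 2, "ACATTCCA")
        ]

    def test_no_match(self):
        cat = build_mre_catalog([_utr("GGGGGG")], [SeedMotif("miR-1", MIR1)])
        assert len(cat) == 0

    def test_6mer_only_scan_finds_both(self):
        cat = build_mre_catalog(
            [_utr("CATTCCGGGCATTCC")], [SeedMotif("miR-1", MIR1)], site_types=["6mer"]
        )
        assert [(s.site_type, s.utr_offset) for s in cat.sites] == [("6mer", 0), ("6mer", 9)]

    def test_n_never_matches(self):
        cat = build_mre_catalog([_utr("AAACATTCCNAA")], [SeedMotif("miR-1", MIR1)])
        # the N kills the 8mer/7mer-A1 (need the final A position intact? offset 2..9 has N at 9)
        assert all("N" not in s.site_seq for s in cat.sites)
        assert [(s.site_type, s.utr_offset) for s in cat.sites] == [("7mer-m8", 2)]

    def test_sites_roundtrip_from_utr(self, small_sim, small_catalog):
        utrs, _, cat = small_catalog
        by_gene = {u.gene_id: u for u in utrs}
        for s in cat.sites:
            u = by_gene[s.gene_id]
            assert u.sequence[s.utr_offset : s.utr_offset + len(s.site_seq)] == s.site_seq

    def test_matches_planted_truth(self, small_sim, small_catalog):
        _, _, cat = small_catalog
        truth = small_sim["annotation"].truth_catalog()
        key = lambda s: (s.gene_id, s.family_id, s.site_type, s.utr_offset, s.site_seq)
        assert sorted(map(key, cat.sites)) == sorted(map(key, truth.sites))


@given(
    seq=dna,
    motif=st.text(alphabet="ACGT", min_size=6, max_size=8),
)
@settings(max_examples=200, derandomize=True)
def test_scanner_matches_naive_substring_oracle(seq, motif):
    naive = [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]
    assert find_occurrences(seq, motif) == naive


class TestUTRRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            UTRRecord("g", "chr1", "+", [(0, 5)], "ACGTAC")  # length mismatch
        with pytest.raises(ValueError):
            UTRRecord("g", "chr1", "+", [(0, 5), (3, 8)], "ACGTAACGTA")  # overlap
        with pytest.raises(ValueError):
            UTRRecord("g", "chr1", "*", [(0, 4)], "ACGT")

    def test_transcript_to_genomic_minus_strand(self):
        u = UTRRecord("g", "chr1", "-", [(100, 110), (150, 160)], "A" * 20)
        # transcript starts at the genomically-last interval for minus strand
        assert u.transcript_to_genomic(0, 5) == [(155, 160)]
        # t=8,9 fall at the left end of (150,160); t=10,11 at the right end of (100,110)
        assert u.transcript_to_genomic(8, 4) == [(108, 110), (150, 152)]


class TestLoadAnnotation:
    def _write(self, tmp_path, bed_lines, fasta):
        bed = tmp_path / "u.bed"
        bed.write_text("".join(l + "\n" for l in bed_lines))
        fa = tmp_path / "g.fa"
        fa.write_text(fasta)
        return bed, fa

    def test_genome_extraction_plus(self, tmp_path):
        genome = "A" * 100 + "ACGTACGTACGT" + "A" * 40
        bed, fa = self._write(
            tmp_path, ["chr1\t100\t112\tgeneA\t0\t+"], f">chr1\n{genome}\n"
        )
        (rec,) = load_utr_annotation(bed, fa)
        assert rec.sequence == "ACGTACGTACGT" and rec.length == 12

    def test_genome_extraction_minus(self, tmp_path):
        genome = "A" * 100 + "ACGTACGTACGT" + "A" * 40
        bed, fa = self._write(
            tmp_path, ["chr1\t100\t112\tgeneA\t0\t-"], f">chr1\n{genome}\n"
        )
        (rec,) = load_utr_annotation(bed, fa)
        assert rec.sequence == reverse_complement("ACGTACGTACGT")

    def test_spliced_two_intervals(self, tmp_path):
        genome = "".join("ACGT"[i % 4] for i in range(200))
        bed, fa = self._write(
            tmp_path,
            ["chr1\t100\t110\tgeneB\t0\t+", "chr1\t150\t160\tgeneB\t0\t+"],
            f">chr1\n{genome}\n",
        )
        (rec,) = load_utr_annotation(bed, fa)
        assert rec.sequence == genome[100:110] + genome[150:160] and rec.length == 20

    def test_per_gene_fasta_mode(self, tmp_path):
        bed, fa = self._write(
            tmp_path, ["chr1\t0\t8\tgeneA\t0\t+"], ">geneA\nACGTACGT\n"
        )
        (rec,) = load_utr_annotation(bed, fa)
        assert rec.sequence == "ACGTACGT"

    def test_missing_contig_lists_ids(self, tmp_path):
        bed, fa = self._write(tmp_path, ["chr9\t0\t8\tgeneA\t0\t+"], ">chr1\nACGTACGT\n")
        with pytest.raises(ValueError, match="chr9"):
            load_utr_annotation(bed, fa)

    def test_malformed_bed_reports_line(self, tmp_path):
        bed, fa = self._write(
            tmp_path, ["chr1\t0\t8\tgeneA\t0\t+", "chr1\tzero\t8\tg2\t0\t+"], ">chr1\nACGTACGT\n"
        )
        with pytest.raises(ValueError, match=":2"):
            load_utr_annotation(bed, fa)
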