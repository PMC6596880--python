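"""Transcript parsing, native-site geometry, normalization and windows."""

import subprocess

import pytest

from mesplice._sequences import reverse_complement
from mesplice.annotation import (
    AnnotationError,
    Interval,
    NormalizedVariant,
    ReferenceMismatchError,
    TranscriptModel,
    UnsupportedVariantError,
    native_sites,
    normalize_variant,
    parse_transcripts,
    site_sequence,
    window_sequences,
)

TOY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";
"""

TOY_GTF_MINUS = TOY_GTF.replace("\t+\t", "\t-\t").replace("tx1", "tx2")

TOY_GFF3 = """\
##gff-version 3
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=tx3
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=tx3.e1;Parent=tx3
chr1\ttest\texon\t301\t400\t.\t+\t.\tID=tx3.e2;Parent=tx3
"""


@pytest.fixture
def toy_gtf(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    return p


class TestParsing:
    def test_two_exon_plus_strand_coordinates(self, toy_gtf):
        (tx,) = parse_transcripts(toy_gtf)
        assert tx.transcript_id == "tx1"
        assert [(e.start, e.end) for e in tx.exons] == [(100, 200), (300, 400)]
        assert [(i.start, i.end) for i in tx.introns()] == [(200, 300)]

    def test_minus_strand_exons_in_transcript_orientation(self, tmp_path):
        p = tmp_path / "minus.gtf"
        p.write_text(TOY_GTF_MINUS)
        (tx,) = parse_transcripts(p)
        # 5'->3' on the minus strand is genomically descending
        assert [(e.start, e.end) for e in tx.exons] == [(300, 400), (100, 200)]

    def test_gff3_parent_attribute(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(TOY_GFF3)
        (tx,) = parse_transcripts(p)
        assert tx.transcript_id == "tx3"
        assert len(tx.exons) == 2

    def test_generated_fixture_round_trips(self, small_fixture,
                                           small_fixture_files):
        parsed = {t.transcript_id: t
                  for t in parse_transcripts(small_fixture_files["gtf"])}
        for tx in small_fixture.transcripts:
            got = parsed[tx.transcript_id]
            assert got.strand == tx.strand
            assert [(e.start, e.end) for e in got.exons] == [
                (e.start, e.end) for e in tx.exons
            ]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError, match="overlapping"):
            TranscriptModel("bad", "chr1", "+",
                            [Interval(0, 100), Interval(50, 150)])


class TestNativeSites:
    def test_single_exon_has_no_sites(self):
        tx = TranscriptModel("solo", "chr1", "+", [Interval(0, 500)])
        assert native_sites(tx) == []

    def test_plus_strand_donor_span(self, toy_gtf):
        (tx,) = parse_transcripts(toy_gtf)
        sites = {(s.site_type,): s for s in native_sites(tx)}
        donor = sites[("donor",)]
        # exon ends at 1-based 200: motif covers 1-based 198..206
        assert (donor.span.start, donor.span.end) == (197, 206)
        acceptor = sites[("acceptor",)]
        # exon 2 starts at 1-based 301: motif covers 1-based 281..303
        assert (acceptor.span.start, acceptor.span.end) == (280, 303)

    def test_counts_and_consensus_on_fixture(self, small_fixture):
        for tx in small_fixture.transcripts:
            sites = native_sites(tx)
            n = len(tx.exons)
            assert len(sites) == 2 * (n - 1)
            for s in sites:
                motif = site_sequence(small_fixture.sequences, s)
                if s.site_type == "donor":
                    assert motif[3:5] == "GT"
                else:
                    assert motif[18:20] == "AG"

    def test_minus_strand_motif_is_reverse_complement(self, small_fixture):
        minus = [t for t in small_fixture.transcripts if t.strand == "-"][0]
        for s in native_sites(minus):
            plus = small_fixture.sequences[s.chrom][s.span.start:s.span.end]
            assert site_sequence(small_fixture.sequences, s) == \
                reverse_complement(plus)

    def test_short_intron_site_omitted_with_warning(self):
        tx = TranscriptModel("tight", "chr1", "+",
                             [Interval(0, 100), Interval(110, 200)])
        with pytest.warns(UserWarning, match="omitted"):
            sites = native_sites(tx)
        assert [s.site_type for s in sites] == ["donor"]


class TestNormalization:
    def test_parsimony_trim_to_snv(self, small_fixture):
        genome = small_fixture.sequences
        seq = genome["chr1"]
        pos = 1000  # 1-based; arbitrary interior position
        ref2 = seq[999:1001]
        alt2 = ref2[0] + ("A" if ref2[1] != "A" else "C")
        v = normalize_variant("chr1", pos, ref2, alt2, genome)
        assert (v.pos, v.ref, v.alt) == (1001, ref2[1], alt2[1])
        assert v.variant_class == "SNV"

    def test_identical_alleles_rejected(self, small_fixture):
        seq = small_fixture.sequences["chr1"]
        with pytest.raises(UnsupportedVariantError, match="REF equals ALT"):
            normalize_variant("chr1", 100, seq[99], seq[99],
                              small_fixture.sequences)

    def test_reference_mismatch_detected(self, small_fixture):
        seq = small_fixture.sequences["chr1"]
        wrong = "A" if seq[99] != "A" else "C"
        with pytest.raises(ReferenceMismatchError):
            normalize_variant("chr1", 100, wrong, "G",
                              small_fixture.sequences)

    def test_symbolic_allele_rejected(self, small_fixture):
        seq = small_fixture.sequences["chr1"]
        with pytest.raises(UnsupportedVariantError, match="symbolic"):
            normalize_variant("chr1", 100, seq[99], "<DEL>",
                              small_fixture.sequences)

    def test_left_alignment_in_homopolymer(self):
        genome = {"chr1": "GGGCAAAATGGG"}
        # deleting any A of the run must normalize to the leftmost placement
        for pos, ref in ((5, "AA"), (6, "AA"), (7, "AA")):
            v = normalize_variant("chr1", pos, ref, ref[0], genome)
            assert (v.pos, v.ref, v.alt) == (4, "CA", "C")

    def test_agreement_with_bcftools_norm(self, small_fixture,
                                          small_fixture_files, tmp_path):
        """Normalization matches an independent left-align implementation."""
        import pysam

        genome = small_fixture.sequences
        seq = genome["chr1"]
        rng_positions = range(400, len(seq) - 400, 110)
        raw = []
        for p in rng_positions:  # build deliberately unnormalized records
            ref = seq[p - 1:p + 3]
            alt = ref[0] + ref[2:]  # 1-bp deletion with redundant suffix
            raw.append((p, ref, alt))
        vcf_path = tmp_path / "raw.vcf"
        header = pysam.VariantHeader()
        header.contigs.add("chr1", length=len(seq))
        with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
            for p, ref, alt in raw:
                vf.write(vf.new_record(contig="chr1", start=p - 1,
                                       alleles=(ref, alt)))
        norm_path = tmp_path / "norm.vcf"
        subprocess.run(
            ["bcftools", "norm", "-f", str(small_fixture_files["fasta"]),
             "-o", str(norm_path), str(vcf_path)],
            check=True, capture_output=True,
        )
        expected = [
            (rec.pos, rec.ref, rec.alts[0])
            for rec in pysam.VariantFile(str(norm_path))
        ]
        got = [
            (v.pos, v.ref, v.alt)
            for v in (normalize_variant("chr1", p, ref, alt, genome)
                      for p, ref, alt in raw)
        ]
        assert got == expected


class TestWindows:
    def _tx(self, small_fixture, strand=None):
        for tx in small_fixture.transcripts:
            if strand is None or tx.strand == strand:
                return tx
        raise AssertionError("no transcript of requested strand")

    def test_snv_yields_exactly_k_frames(self, small_fixture):
        tx = self._tx(small_fixture, "+")
        pos = tx.start + 60
        genome = small_fixture.sequences
        ref = genome["chr1"][pos]
        alt = "A" if ref != "A" else "G"
        v = normalize_variant("chr1", pos + 1, ref, alt, genome)
        for k in (9, 23):
            frames, flags = window_sequences(genome, tx, v, k, "alt")
            assert [f for f, _ in frames] == list(range(k, 0, -1))
            # the variant base occupies window position `frame`
            for frame, kmer in frames:
                assert kmer[frame - 1] == alt

    def test_minus_strand_windows_are_reverse_complements(self, small_fixture):
        genome = small_fixture.sequences
        tx = self._tx(small_fixture, "-")
        pos = tx.start + 61
        ref = genome["chr1"][pos]
        alt = "C" if ref != "C" else "T"
        v = normalize_variant("chr1", pos + 1, ref, alt, genome)
        frames, _ = window_sequences(genome, tx, v, 9, "alt")
        alt_chrom = genome["chr1"][:pos] + alt + genome["chr1"][pos + 1:]
        # frame f places the variant at sense position f; on '-' the sense
        # window is the reverse complement of the plus-strand genomic span
        for frame, kmer in frames:
            start = pos - (9 - frame)
            plus = alt_chrom[start:start + 9]
            assert kmer == reverse_complement(plus)

    def test_insertion_windows_contain_inserted_base(self, small_fixture):
        genome = small_fixture.sequences
        tx = self._tx(small_fixture, "+")
        seq = genome["chr1"]
        # pick a repeat-free insertion point so "the inserted base" is
        # unambiguous and the brute-force set is exactly 9 windows
        pos = next(p for p in range(tx.start + 60, tx.start + 200)
                   if seq[p] != "T" and seq[p + 1] != "T")
        anchor = seq[pos]
        v = normalize_variant("chr1", pos + 1, anchor, anchor + "T", genome)
        frames, _ = window_sequences(genome, tx, v, 9, "alt")
        alt_chrom = seq[:pos + 1] + "T" + seq[pos + 1:]
        brute = {alt_chrom[s:s + 9] for s in range(pos - 7, pos + 2)}
        assert {kmer for _, kmer in frames} == brute

    def test_ref_haplotype_contains_native_motif_for_site_snv(
            self, small_fixture, models):
        """An SNV inside a native donor keeps the native 9-mer among its
        reference windows."""
        genome = small_fixture.sequences
        for tx in small_fixture.transcripts:
            for s in native_sites(tx):
                if s.site_type != "donor":
                    continue
                pos = s.span.start + 1  # second motif base (plus strand)
                ref = genome["chr1"][pos]
                alt = "A" if ref != "A" else "G"
                v = normalize_variant("chr1", pos + 1, ref, alt, genome)
                frames, _ = window_sequences(genome, tx, v, 9, "ref")
                native = site_sequence(genome, s)
                assert native in {kmer for _, kmer in frames}
                return

    def test_edge_truncation_raises_with_missing_frames(self):
        genome = {"chr1": "ACGTACGTACGTACGT"}
        tx = TranscriptModel("t", "chr1", "+", [Interval(0, 16)])
        v = normalize_variant("chr1", 2, "C", "A", genome)
        from mesplice.annotation import TruncatedWindowError

        with pytest.raises(TruncatedWindowError) as err:
            window_sequences(genome, tx, v, 9, "alt")
        assert err.value.missing_frames
        frames, flags = window_sequences(genome, tx, v, 9, "alt",
                                         on_truncate="flag")
        assert "truncated" in flags and frames


def test_variant_class_taxonomy():
    assert NormalizedVariant("c", 5, "A", "G").variant_class == "SNV"
    assert NormalizedVariant("c", 5, "A", "AT").variant_class == "insertion"
    assert NormalizedVariant("c", 5, "AT", "A").variant_class == "deletion"
    assert NormalizedVariant("c", 5, "AT", "GC").variant_class == "complex"
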