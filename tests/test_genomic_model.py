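import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncduplex.genomic_model import (
    BedRecord,
    GenomicInterval,
    ParseError,
    TranscriptModel,
    covered_bases,
    merge_intervals,
    premrna_sequence,
    read_bed,
    read_gtf,
    reverse_complement,
    spliced_sequence,
    transcript_to_genome,
    write_bed,
)


def _tx(exons, strand="+", chrom="chr1", cds=None, tid="t1"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id="g1",
        biotype="lincRNA",
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds] if cds else None,
    )


class TestGtf:
    def test_coordinates_become_zero_based_half_open(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t"; '
            'transcript_biotype "lincRNA";\n'
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t"; '
            'transcript_biotype "lincRNA";\n'
        )
        genes = read_gtf(str(gtf))
        assert len(genes) == 1
        t = genes[0].transcripts[0]
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
        assert len(t.exons[0]) == 100
        assert t.biotype == "lincRNA"

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\tsrc\texon\t101\n")
        with pytest.raises(ParseError, match="bad.gtf:1"):
            read_gtf(str(gtf))

    def test_exon_without_transcript_id_rejected(self, tmp_path):
        gtf = tmp_path / "bad2.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1\t10\t.\t+\t.\tgene_id "g";\n'
            'chr1\tsrc\texon\t1\t10\t.\t+\t.\tgene_id "g";\n'
        )
        with pytest.raises(ParseError, match="transcript_id"):
            read_gtf(str(gtf))

    def test_synthetic_dataset_matches_generator_truth(self, dataset):
        d, truth = dataset
        genes = read_gtf(f"{d}/annotation.gtf")
        tx = {t.transcript_id: t for g in genes for t in g.transcripts}
        for rec in truth.planted_lncrnas:
            assert rec["transcript_id"] in tx
            assert len(tx[rec["transcript_id"]].exons) == 2
            assert tx[rec["transcript_id"]].novel == rec["novel"]
        for rec in truth.decoy_lncrnas:
            assert rec["transcript_id"] in tx


class TestSequenceExtraction:
    def test_spliced_concatenates_exons(self):
        genome = {"chr1": "AAACCGGGT"}
        t = _tx([(0, 3), (5, 8)])
        assert spliced_sequence(t, genome) == "AAAGGG"

    def test_minus_strand_reverse_complements(self):
        genome = {"chr1": "AAACCGGGT"}
        t = _tx([(0, 3), (5, 8)], strand="-")
        assert spliced_sequence(t, genome) == reverse_complement("AAAGGG")

    def test_exon_beyond_chromosome_end_raises(self):
        from lncduplex.genomic_model import BoundsError

        with pytest.raises(BoundsError):
            spliced_sequence(_tx([(0, 50)]), {"chr1": "ACGT"})

    @pytest.mark.parametrize(
        "intron_len,margin,n_masked",
        [(600, 250, 100), (500, 250, 0), (501, 250, 1), (40, 0, 40)],
    )
    def test_premrna_deep_intron_masking(self, intron_len, margin, n_masked):
        exon = 30
        genome = {"chr1": "G" * (2 * exon + intron_len)}
        t = _tx([(0, exon), (exon + intron_len, 2 * exon + intron_len)])
        seq = premrna_sequence(t, genome, margin)
        assert len(seq) == 2 * exon + intron_len
        assert seq.count("N") == n_masked
        if n_masked:
            # masked run is centred in the intron
            first_n = seq.index("N")
            assert first_n == exon + margin

    def test_premrna_single_exon_equals_spliced(self):
        genome = {"chr1": "ACGTACGTACGT"}
        t = _tx([(2, 10)])
        assert premrna_sequence(t, genome, 250) == spliced_sequence(t, genome)


class TestCoordinateProjection:
    def test_interval_crossing_junction_splits(self):
        t = _tx([(0, 3), (10, 13)])
        blocks = transcript_to_genome(t, 2, 5, "spliced")
        assert [(b.start, b.end) for b in blocks] == [(2, 3), (10, 12)]

    def test_minus_strand_blocks_in_genomic_orientation(self):
        t = _tx([(0, 3), (10, 13)], strand="-")
        # transcript position 0 is the genomic end of the last exon
        blocks = transcript_to_genome(t, 0, 4, "spliced")
        assert [(b.start, b.end) for b in blocks] == [(2, 3), (10, 13)]

    def test_premrna_is_offset_shift(self):
        t = _tx([(5, 25)])
        blocks = transcript_to_genome(t, 3, 8, "premrna")
        assert [(b.start, b.end) for b in blocks] == [(8, 13)]

    def test_out_of_range_raises(self):
        from lncduplex.genomic_model import BoundsError

        with pytest.raises(BoundsError):
            transcript_to_genome(_tx([(0, 10)]), 5, 11, "spliced")

    def test_block_lengths_sum_to_interval_length(self):
        rng = random.Random(0)
        for _ in range(100):
            n_ex = rng.randint(1, 4)
            pos, exons = 0, []
            for _ in range(n_ex):
                pos += rng.randint(1, 50)
                end = pos + rng.randint(1, 80)
                exons.append((pos, end))
                pos = end
            strand = rng.choice("+-")
            t = _tx(exons, strand=strand)
            for space, total in (
                ("spliced", t.spliced_length),
                ("premrna", len(t.span)),
            ):
                s = rng.randrange(total)
                e = rng.randint(s + 1, total)
                blocks = transcript_to_genome(t, s, e, space)
                assert sum(len(b) for b in blocks) == e - s
                assert all(
                    b1.end <= b2.start for b1, b2 in zip(blocks, blocks[1:])
                )


iv_list = st.lists(
    st.tuples(st.integers(0, 60), st.integers(1, 20)).map(
        lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
    ),
    min_size=0,
    max_size=12,
)


class TestMergeIntervals:
    def test_examples(self):
        a = GenomicInterval("chr1", 10, 20)
        b = GenomicInterval("chr1", 15, 25)
        assert merge_intervals([a, b]) == [GenomicInterval("chr1", 10, 25)]
        c = GenomicInterval("chr1", 20, 30)
        assert merge_intervals([a, c]) == [GenomicInterval("chr1", 10, 30)]
        assert merge_intervals([]) == []

    @settings(derandomize=True, max_examples=200)
    @given(iv_list)
    def test_idempotent_order_invariant_and_covers_union(self, ivs):
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        assert merge_intervals(list(reversed(ivs))) == merged
        union = {p for iv in ivs for p in range(iv.start, iv.end)}
        covered = {p for iv in merged for p in range(iv.start, iv.end)}
        assert covered == union
        assert covered_bases(ivs) == len(union)
        # disjoint and sorted
        for x, y in zip(merged, merged[1:]):
            assert x.end < y.start or x.chrom != y.chrom


class TestBed:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t10\tsiteA\n")
        track = read_bed(str(p))
        assert track.records[0].interval == GenomicInterval("chr1", 5, 10)
        assert track.records[0].name == "siteA"

    def test_round_trip_identity(self, tmp_path):
        rng = random.Random(1)
        records = []
        for i in range(100):
            s = rng.randrange(10_000)
            records.append(
                BedRecord(
                    GenomicInterval(
                        f"chr{rng.randint(1, 3)}", s, s + rng.randint(1, 500),
                        rng.choice("+-."),
                    ),
                    f"rec{i}",
                    str(rng.randint(0, 1000)),
                )
            )
        p = tmp_path / "rt.bed"
        write_bed(records, str(p))
        back = read_bed(str(p))
        assert back.records == records

    def test_start_ge_end_raises_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t5\t10\tok\n" + "chr1\t10\t10\tbad\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(str(p))

    def test_track_count_matches_generator_truth(self, dataset):
        d, truth = dataset
        editing = read_bed(f"{d}/editing.bed")
        planted = sum(
            1 for r in editing.records if not r.name.startswith("AtoI_decoy")
        )
        n_planted_editing_duplexes = sum(
            1 for p in truth.planted_duplexes if "EDITING" in p["mechanisms"]
        )
        assert planted >= 3 * n_planted_editing_duplexes  # >= 3 sites per duplex
        assert sum(1 for r in editing.records if r.name.startswith("AtoI_decoy")) == 3
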