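import random

import pytest

from _oracles import (
    oracle_alternative_sites,
    oracle_editing,
    oracle_mirna_masking,
    oracle_region,
    oracle_smd,
    oracle_splicing,
    oracle_utr3,
)
from lncduplex.duplex_align import DuplexAlignment
from lncduplex.genomic_model import (
    AnnotationTrack,
    BedRecord,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from lncduplex.mechanisms import (
    MechanismLabel,
    MechanismTracks,
    MiRnaSite,
    alternative_splice_sites,
    annotate_interactions,
    classify_editing,
    classify_mirna_masking,
    classify_region,
    classify_smd,
    classify_splicing,
    predict_seed_sites,
    supported_mirna_sites,
    utr3_intervals,
)


def _iv(s, e, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, s, e, strand)


def _duplex(blocks, target_id="t1", space="spliced", lnc_id="l1"):
    return DuplexAlignment(
        lnc_id=lnc_id,
        target_id=target_id,
        score=500,
        lnc_span=(0, 10),
        target_span=(0, 10),
        pairing="|" * 10,
        lnc_aln="G" * 10,
        target_aln="C" * 10,
        target_space=space,
        genome_blocks=blocks,
    )


def _track(intervals, prefix="x"):
    return AnnotationTrack(
        prefix, [BedRecord(iv, f"{prefix}{i}") for i, iv in enumerate(intervals)]
    )


def _gene(tx_defs, gene_id="g1"):
    txs = [
        TranscriptModel(tid, gene_id, "protein_coding", "+",
                        [_iv(s, e) for s, e in exons],
                        cds=[_iv(s, e) for s, e in cds] if cds else None)
        for tid, exons, cds in tx_defs
    ]
    return GeneModel(gene_id, "G1", "fixture gene", txs)


class TestAlternativeSpliceSites:
    def test_single_isoform_gene_has_none(self):
        g = _gene([("a", [(0, 100), (200, 300)], None)])
        assert alternative_splice_sites(g) == set()

    def test_identical_isoforms_have_none(self):
        g = _gene(
            [
                ("a", [(0, 100), (200, 300)], None),
                ("b", [(0, 100), (200, 300)], None),
            ]
        )
        assert alternative_splice_sites(g) == set()

    def test_alternative_3prime_splice_site_detected(self):
        # isoform b starts exon 2 forty bases earlier
        g = _gene(
            [
                ("a", [(0, 100), (200, 300)], None),
                ("b", [(0, 100), (160, 300)], None),
            ]
        )
        assert alternative_splice_sites(g) == {160, 200}


class TestClassifySplicing:
    def _gene(self):
        return _gene(
            [
                ("a", [(0, 100), (200, 300)], None),
                ("b", [(0, 100), (160, 300)], None),
            ]
        )

    def test_requires_premrna_space(self):
        with pytest.raises(ValueError):
            classify_splicing(_duplex([_iv(0, 50)], "a", "spliced"), self._gene())

    def test_entirely_exonic_footprint_is_negative(self):
        ok, _ = classify_splicing(_duplex([_iv(10, 60)], "a", "premrna"), self._gene())
        assert not ok

    def test_constitutive_junction_without_alternative_site_is_negative(self):
        g = _gene(
            [
                ("a", [(0, 100), (200, 300)], None),
                ("b", [(0, 100), (200, 300)], None),
            ]
        )
        ok, _ = classify_splicing(_duplex([_iv(80, 220)], "a", "premrna"), g)
        assert not ok

    def test_footprint_over_alternative_junction_is_positive(self):
        ok, sites = classify_splicing(
            _duplex([_iv(150, 230)], "a", "premrna"), self._gene()
        )
        assert ok and sites == [160, 200]


class TestSeedSites:
    def test_by_hand_seed_match(self):
        # miRNA positions 2-8 = TAATGCT, reverse complement AGCATTA
        mirna = {"mir-x": "TTAATGCTAATCGTGATAGGGGTT"}
        target = TranscriptModel("t", "g", "protein_coding", "+", [_iv(0, 60)])
        seq = "C" * 30 + "AGCATTA" + "C" * 23
        sites = predict_seed_sites(mirna, target, seq)
        assert len(sites) == 1
        site = sites[0]
        assert site.mirna_id == "mir-x"
        # seed match at 30..37, extended upstream by len(miRNA)-8 = 16
        assert (site.interval.start, site.interval.end) == (14, 37)
        assert not site.clip_supported

    def test_no_seed_complement_no_sites(self):
        mirna = {"mir-x": "TTAATGCTAATCGTGATAGGGGTT"}
        target = TranscriptModel("t", "g", "protein_coding", "+", [_iv(0, 40)])
        assert predict_seed_sites(mirna, target, "C" * 40) == []

    def test_two_matches_two_disjoint_sites(self):
        mirna = {"mir-x": "TTAATGCTAATCGTGATAGGGGTT"}
        target = TranscriptModel("t", "g", "protein_coding", "+", [_iv(0, 100)])
        seq = "C" * 20 + "AGCATTA" + "C" * 40 + "AGCATTA" + "C" * 26
        sites = predict_seed_sites(mirna, target, seq)
        assert len(sites) == 2
        assert sites[0].interval.end <= sites[1].interval.start

    def test_length_bounds_enforced(self):
        target = TranscriptModel("t", "g", "protein_coding", "+", [_iv(0, 40)])
        with pytest.raises(ValueError):
            predict_seed_sites({"short": "ACGTACGTACGT"}, target, "C" * 40)


class TestClipSupport:
    def test_containment_truncation_and_drop(self):
        sites = [MiRnaSite(_iv(100, 122), "m1")]
        kept = supported_mirna_sites(sites, _track([_iv(90, 200)]))
        assert [(s.interval.start, s.interval.end) for s in kept] == [(100, 122)]
        assert kept[0].clip_supported

        kept = supported_mirna_sites(sites, _track([_iv(115, 200)]))
        assert [(s.interval.start, s.interval.end) for s in kept] == [(115, 122)]

        assert supported_mirna_sites(sites, _track([_iv(300, 400)])) == []


class TestHalfSiteRule:
    @pytest.mark.parametrize("overlap,expected", [(7, True), (6, False), (14, True)])
    def test_boundary(self, overlap, expected, params):
        site = MiRnaSite(_iv(100, 114), "m1", True)  # length 14, need >= 7
        d = _duplex([_iv(114 - overlap, 300)])
        ok, _ = classify_mirna_masking(d, [site], params)
        assert ok is expected


class TestSmd:
    def _target(self):
        # CDS in first exon part; 3'UTR = [150, 400)
        return TranscriptModel(
            "t", "g", "protein_coding", "+", [_iv(0, 400)], cds=[_iv(50, 150)]
        )

    def test_alu_inside_footprint_and_utr3(self):
        ok, alus = classify_smd(
            _duplex([_iv(160, 360)]), _track([_iv(200, 300)]), self._target()
        )
        assert ok and len(alus) == 1

    def test_alu_overhanging_footprint_by_one_base_fails(self):
        ok, _ = classify_smd(
            _duplex([_iv(160, 360)]), _track([_iv(199, 360)]), self._target()
        )
        assert ok  # [199, 360) still inside [160, 360)
        ok, _ = classify_smd(
            _duplex([_iv(200, 360)]), _track([_iv(199, 360)]), self._target()
        )
        assert not ok

    def test_alu_in_5prime_utr_fails(self):
        ok, _ = classify_smd(
            _duplex([_iv(0, 50)]), _track([_iv(10, 40)]), self._target()
        )
        assert not ok

    def test_target_without_cds_fails(self):
        t = TranscriptModel("t", "g", "lincRNA", "+", [_iv(0, 400)])
        ok, _ = classify_smd(_duplex([_iv(0, 400)]), _track([_iv(10, 40)]), t)
        assert not ok


class TestEditing:
    def test_half_open_boundaries(self):
        d = _duplex([_iv(100, 200)])
        ok, _ = classify_editing(d, _track([_iv(100, 101)]))
        assert ok  # at footprint start
        ok, _ = classify_editing(d, _track([_iv(200, 201)]))
        assert not ok  # at footprint end coordinate
        ok, hits = classify_editing(
            d, _track([_iv(p, p + 1) for p in (110, 150, 199, 250, 300)])
        )
        assert ok and len(hits) == 3

    def test_multibase_record_rejected(self):
        with pytest.raises(ValueError):
            classify_editing(_duplex([_iv(0, 10)]), _track([_iv(1, 3)]))


class TestRegion:
    def _target(self):
        return TranscriptModel(
            "t", "g", "protein_coding", "+", [_iv(0, 400)], cds=[_iv(100, 200)]
        )

    def test_partition(self):
        t = self._target()
        assert classify_region(_duplex([_iv(250, 350)]), t) == "UTR"
        assert classify_region(_duplex([_iv(120, 180)]), t) == "CDS"
        assert classify_region(_duplex([_iv(150, 250)]), t) == "UTR_CDS_OVERLAP"
        lnc = TranscriptModel("t", "g", "lincRNA", "+", [_iv(0, 400)])
        assert classify_region(_duplex([_iv(0, 50)]), lnc) == "NONCODING"


class TestRandomizedOracles:
    """Each classifier against a per-base position-set brute force."""

    def _random_target(self, rng):
        n_ex = rng.randint(1, 3)
        pos, exons = rng.randint(0, 50), []
        for _ in range(n_ex):
            end = pos + rng.randint(40, 200)
            exons.append((pos, end))
            pos = end + rng.randint(30, 120)
        strand = rng.choice("+-")
        coding = rng.random() < 0.8
        cds = None
        if coding:
            s, e = exons[0]
            cds = [(s + 10, min(e, s + 10 + rng.randint(10, 100)))]
        return TranscriptModel(
            "t",
            "g",
            "protein_coding" if coding else "lincRNA",
            strand,
            [_iv(s, e, strand=strand) for s, e in exons],
            cds=[_iv(s, e, strand=strand) for s, e in cds] if cds else None,
        )

    def test_editing_smd_masking_region_match_brute_force(self, params):
        rng = random.Random(99)
        for _ in range(80):
            t = self._random_target(rng)
            span = t.span
            blocks = []
            for _ in range(rng.randint(1, 3)):
                s = rng.randint(span.start, span.end - 2)
                blocks.append(_iv(s, min(span.end, s + rng.randint(5, 150))))
            d = _duplex(blocks, space="spliced")

            positions = [
                _iv(p, p + 1)
                for p in rng.sample(range(span.start, span.end), k=8)
            ]
            ok, hits = classify_editing(d, _track(positions))
            expected = oracle_editing(blocks, positions)
            assert hits == expected and ok == bool(expected)

            alus = []
            for _ in range(4):
                s = rng.randint(span.start, span.end - 2)
                alus.append(_iv(s, min(span.end, s + rng.randint(5, 120))))
            utr3 = utr3_intervals(t)
            assert utr3 == oracle_utr3(t)
            ok, hits = classify_smd(d, _track(alus), t)
            expected = oracle_smd(blocks, alus, utr3)
            assert hits == expected and ok == bool(expected)

            sites = []
            for _ in range(4):
                s = rng.randint(span.start, span.end - 8)
                sites.append(
                    MiRnaSite(_iv(s, s + rng.randint(7, 22)), "m", True)
                )
            ok, hits = classify_mirna_masking(d, sites, params)
            expected = oracle_mirna_masking(blocks, sites, params.half_site_rule)
            assert hits == expected and ok == bool(expected)

            assert classify_region(d, t) == oracle_region(blocks, t.cds or [])

    def test_splicing_matches_brute_force(self):
        rng = random.Random(101)
        for _ in range(80):
            # two isoforms over the same span with jittered internal boundaries
            e2s = 200 + rng.randint(-30, 30)
            e2s_b = 200 + rng.randint(-30, 30)
            g = _gene(
                [
                    ("a", [(0, 100), (e2s, 300), (380, 450)], None),
                    ("b", [(0, 100), (e2s_b, 300), (380, 450)], None),
                ]
            )
            assert alternative_splice_sites(g) == oracle_alternative_sites(
                g.transcripts
            )
            s = rng.randint(0, 440)
            blocks = [_iv(s, s + rng.randint(5, 200))]
            d = _duplex(blocks, "a", "premrna")
            ok, _ = classify_splicing(d, g)
            assert ok == oracle_splicing(
                blocks, g.transcripts[0], oracle_alternative_sites(g.transcripts)
            )

    def test_shrinking_footprint_never_gains_a_mechanism(self, params):
        rng = random.Random(102)
        for _ in range(40):
            t = self._random_target(rng)
            span = t.span
            s = rng.randint(span.start, span.end - 30)
            e = min(span.end, s + rng.randint(20, 200))
            big = _duplex([_iv(s, e)])
            small = _duplex([_iv(s + 5, max(s + 6, e - 5))])
            positions = [_iv(p, p + 1) for p in rng.sample(range(span.start, span.end), k=6)]
            alus = [_iv(s + 2, e - 2)] if e - s > 6 else []
            sites = [MiRnaSite(_iv(s, s + 10), "m", True)] if s + 10 <= span.end else []
            for classifier in (
                lambda d: classify_editing(d, _track(positions))[0],
                lambda d: classify_smd(d, _track(alus), t)[0] if alus else False,
                lambda d: classify_mirna_masking(d, sites, params)[0] if sites else False,
            ):
                assert not (classifier(small) and not classifier(big))


class TestAnnotate:
    def test_without_tracks_only_splicing_possible(self):
        g = _gene(
            [
                ("a", [(0, 100), (160, 300)], None),
                ("b", [(0, 100), (200, 300)], None),
            ]
        )
        d_pre = _duplex([_iv(150, 230)], "a", "premrna")
        d_spl = _duplex([_iv(10, 60)], "b", "spliced")
        records = annotate_interactions([d_pre, d_spl], [g], MechanismTracks())
        assert all(r.mechanisms <= {MechanismLabel.SPLICING} for r in records)
        assert any(r.mechanisms == {MechanismLabel.SPLICING} for r in records)

    def test_unknown_target_raises(self):
        with pytest.raises(KeyError):
            annotate_interactions(
                [_duplex([_iv(0, 10)], "nope")], [_gene([("a", [(0, 50)], None)])],
                MechanismTracks(),
            )

    def test_smd_plus_editing_combination(self):
        t_def = ("a", [(0, 500)], [(50, 150)])
        g = _gene([t_def])
        d = _duplex([_iv(200, 400)], "a")
        tracks = MechanismTracks(
            alu=_track([_iv(250, 350)]), editing=_track([_iv(300, 301)])
        )
        records = annotate_interactions([d], [g], tracks)
        assert records[0].mechanisms == {MechanismLabel.SMD, MechanismLabel.EDITING}
        assert records[0].region == "UTR"

    def test_same_footprint_in_both_spaces_merges_to_one_record(self):
        g = _gene([("a", [(0, 500)], [(50, 150)])])
        d1 = _duplex([_iv(200, 400)], "a", "spliced")
        d2 = _duplex([_iv(200, 400)], "a", "premrna")
        records = annotate_interactions([d1, d2], [g], MechanismTracks())
        assert len(records) == 1
        assert records[0].duplex.target_space == "spliced"
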