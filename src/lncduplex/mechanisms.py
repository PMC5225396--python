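"""Assign duplexes to candidate regulatory mechanisms.

Four mechanisms are considered for each lncRNA:RNA duplex:

* SPLICING — the duplex (in pre-mRNA space) covers an exon-intron border of
  the target and overlaps an alternative splice site of the gene, so the
  lncRNA could mask splicing signals.
* MIRNA_MASKING — at least half of a CLIP-supported miRNA target site lies
  within the duplex footprint, so the lncRNA could occlude the site.
* EDITING — an A-to-I editing position falls inside the footprint; the duplex
  provides the double-stranded substrate ADAR requires.
* SMD — an Alu element lies entirely within the footprint and within the
  target's 3'UTR, the configuration that recruits Staufen and triggers decay.

All interval comparisons are half-open and strand-agnostic by default
(``stranded=True`` restricts every classifier to same-strand evidence). The
"interaction region" is the union of the duplex's genomic blocks; pass
``span_region=True`` to use the enclosing interval instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import ceil
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .duplex_align import DuplexAlignment
from .genomic_model import (
    AnnotationTrack,
    GeneModel,
    GenomicInterval,
    ScoringParams,
    TranscriptModel,
    merge_intervals,
    overlap_size,
    transcript_to_genome,
)


class MechanismLabel(str, Enum):
    SPLICING = "SPLICING"
    MIRNA_MASKING = "MIRNA_MASKING"
    EDITING = "EDITING"
    SMD = "SMD"


REGIONS = ("UTR", "CDS", "UTR_CDS_OVERLAP", "NONCODING")


@dataclass
class MiRnaSite:
    interval: GenomicInterval
    mirna_id: str
    clip_supported: bool = False

    def __post_init__(self) -> None:
        if len(self.interval) < 6:
            raise ValueError("miRNA site shorter than 6 nt")


@dataclass
class InteractionRecord:
    """One row of the interaction table: a duplex plus its annotations."""

    duplex: DuplexAlignment
    mechanisms: Set[MechanismLabel] = field(default_factory=set)
    region: str = "NONCODING"
    gene_id: str = ""
    gene_name: str = ""
    gene_description: str = ""
    target_biotype: str = ""
    evidence: Dict[str, list] = field(default_factory=dict)

    @property
    def lnc_id(self) -> str:
        return self.duplex.lnc_id

    @property
    def target_id(self) -> str:
        return self.duplex.target_id


def footprint(d: DuplexAlignment, span_region: bool = False) -> List[GenomicInterval]:
    """Genomic interaction region of a duplex (merged blocks or the span)."""
    blocks = merge_intervals(d.genome_blocks)
    if not blocks:
        return []
    if span_region:
        return [GenomicInterval(blocks[0].chrom, blocks[0].start, blocks[-1].end)]
    return blocks


def _strand_ok(stranded: bool, a_strand: str, b_strand: str) -> bool:
    return not stranded or a_strand == "." or b_strand == "." or a_strand == b_strand


def _contains_point_interior(blocks: Sequence[GenomicInterval], chrom: str, p: int) -> bool:
    """True when the junction point p (between bases p-1 and p) is strictly
    inside a block, i.e. the block covers both flanking bases."""
    return any(b.chrom == chrom and b.start < p < b.end for b in blocks)


def splice_sites(t: TranscriptModel) -> List[int]:
    """Exon-intron junction coordinates of one transcript (both intron ends)."""
    sites: List[int] = []
    for intron in t.introns:
        sites.append(intron.start)
        sites.append(intron.end)
    return sites


def alternative_splice_sites(g: GeneModel) -> Set[int]:
    """Splice-site positions used by some isoforms but skipped by others.

    A site counts as alternative when at least one isoform uses it and at
    least one isoform whose genomic span contains the position does not.
    """
    use: Dict[int, Set[str]] = {}
    for t in g.transcripts:
        for p in splice_sites(t):
            use.setdefault(p, set()).add(t.transcript_id)
    out: Set[int] = set()
    for p, users in use.items():
        for t in g.transcripts:
            if (
                t.transcript_id not in users
                and t.span.start <= p < t.span.end
            ):
                out.add(p)
                break
    return out


def classify_splicing(
    d: DuplexAlignment,
    g: GeneModel,
    span_region: bool = False,
) -> Tuple[bool, List[int]]:
    """Splicing-modulation call: requires a pre-mRNA-space duplex whose region
    covers an exon-intron border of the target transcript in its interior and
    overlaps at least one alternative splice site of the gene."""
    if d.target_space != "premrna":
        raise ValueError("splicing calls require pre-mRNA-space alignments")
    target = next(
        (t for t in g.transcripts if t.transcript_id == d.target_id), None
    )
    if target is None:
        raise KeyError(f"duplex target {d.target_id!r} not in gene {g.gene_id!r}")
    blocks = footprint(d, span_region)
    if not blocks:
        return False, []
    chrom = blocks[0].chrom
    covers_border = any(
        _contains_point_interior(blocks, chrom, p) for p in splice_sites(target)
    )
    if not covers_border:
        return False, []
    hit_sites = sorted(
        p
        for p in alternative_splice_sites(g)
        if _contains_point_interior(blocks, chrom, p)
    )
    return bool(hit_sites), hit_sites


def predict_seed_sites(
    mirnas: Mapping[str, str],
    target: TranscriptModel,
    target_seq: str,
) -> List[MiRnaSite]:
    """7mer-m8 seed-match miRNA site prediction on a spliced target.

    A site is reported wherever the reverse complement of miRNA positions 2-8
    occurs exactly in the target; the interval extends the seed match to the
    putative full pairing footprint (len(miRNA)-8 bases 3'-ward on the target)
    and is mapped to genomic coordinates (enclosing interval if the footprint
    crosses an exon junction).
    """
    from .genomic_model import reverse_complement
    from .duplex_align import normalize_rna

    sites: List[MiRnaSite] = []
    seq = normalize_rna(target_seq)
    for mirna_id in sorted(mirnas):
        mseq = normalize_rna(mirnas[mirna_id])
        if not (18 <= len(mseq) <= 26):
            raise ValueError(
                f"{mirna_id}: mature miRNA length {len(mseq)} outside 18-26 nt"
            )
        seed_rc = reverse_complement(mseq[1:8])
        start = seq.find(seed_rc)
        while start != -1:
            tx_start = max(0, start - (len(mseq) - 8))
            tx_end = start + 7
            blocks = transcript_to_genome(target, tx_start, tx_end, "spliced")
            iv = GenomicInterval(
                blocks[0].chrom, blocks[0].start, blocks[-1].end, target.strand
            )
            sites.append(MiRnaSite(interval=iv, mirna_id=mirna_id))
            start = seq.find(seed_rc, start + 1)
    return sites


def supported_mirna_sites(
    predicted: List[MiRnaSite],
    clip: AnnotationTrack,
    stranded: bool = False,
) -> List[MiRnaSite]:
    """Keep predicted sites overlapping merged CLIP intervals; the surviving
    site is the common part (intersection) and is flagged clip_supported."""
    merged = merge_intervals(clip.intervals)
    out: List[MiRnaSite] = []
    for site in predicted:
        for clip_iv in merged:
            if site.interval.overlaps(clip_iv) and _strand_ok(
                stranded, site.interval.strand, clip_iv.strand
            ):
                common = GenomicInterval(
                    site.interval.chrom,
                    max(site.interval.start, clip_iv.start),
                    min(site.interval.end, clip_iv.end),
                    site.interval.strand,
                )
                if len(common) >= 6:
                    out.append(
                        MiRnaSite(common, site.mirna_id, clip_supported=True)
                    )
    return out


def classify_mirna_masking(
    d: DuplexAlignment,
    sites: List[MiRnaSite],
    params: ScoringParams = ScoringParams(),
    span_region: bool = False,
    stranded: bool = False,
) -> Tuple[bool, List[MiRnaSite]]:
    """miRNA-site-masking call: at least half (rounded up) of a supported site
    must lie within the interaction region."""
    blocks = footprint(d, span_region)
    hits = []
    for site in sites:
        if stranded and blocks and not _strand_ok(
            stranded, site.interval.strand, blocks[0].strand
        ):
            continue
        need = ceil(params.half_site_rule * len(site.interval))
        if overlap_size(site.interval, blocks) >= need:
            hits.append(site)
    return bool(hits), hits


def utr3_intervals(t: TranscriptModel) -> List[GenomicInterval]:
    """Genomic intervals of the 3'UTR (spliced region downstream of the CDS)."""
    if not t.cds:
        return []
    cds_blocks = []
    offset = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    # transcript-space extent of the CDS
    cds_tx = []
    for exon in exons:
        for c in t.cds:
            if exon.contains(c):
                if t.strand == "+":
                    s = offset + (c.start - exon.start)
                else:
                    s = offset + (exon.end - c.end)
                cds_tx.append((s, s + len(c)))
        offset += len(exon)
    if not cds_tx:
        return []
    cds_end = max(e for _, e in cds_tx)
    if cds_end >= t.spliced_length:
        return []
    return transcript_to_genome(t, cds_end, t.spliced_length, "spliced")


def utr5_intervals(t: TranscriptModel) -> List[GenomicInterval]:
    if not t.cds:
        return []
    offset = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    starts = []
    for exon in exons:
        for c in t.cds:
            if exon.contains(c):
                if t.strand == "+":
                    starts.append(offset + (c.start - exon.start))
                else:
                    starts.append(offset + (exon.end - c.end))
        offset += len(exon)
    if not starts:
        return []
    cds_start = min(starts)
    if cds_start == 0:
        return []
    return transcript_to_genome(t, 0, cds_start, "spliced")


def _covered_by(iv: GenomicInterval, blocks: Sequence[GenomicInterval]) -> bool:
    """Every base of iv lies within the union of blocks."""
    return overlap_size(iv, blocks) == len(iv)


def classify_smd(
    d: DuplexAlignment,
    alu: AnnotationTrack,
    target: TranscriptModel,
    span_region: bool = False,
    stranded: bool = False,
) -> Tuple[bool, List[GenomicInterval]]:
    """Staufen-mediated-decay call: an Alu element entirely within the
    interaction region and entirely within the target's 3'UTR."""
    utr3 = utr3_intervals(target)
    if not utr3:
        return False, []
    blocks = footprint(d, span_region)
    hits = []
    for iv in alu.intervals:
        if not _strand_ok(stranded, iv.strand, target.strand):
            continue
        if _covered_by(iv, blocks) and _covered_by(iv, utr3):
            hits.append(iv)
    return bool(hits), hits


def classify_editing(
    d: DuplexAlignment,
    editing: AnnotationTrack,
    span_region: bool = False,
    stranded: bool = False,
) -> Tuple[bool, List[GenomicInterval]]:
    """Editing-trigger call: any A-to-I position inside the interaction region
    (half-open: a position at the region's end coordinate is outside)."""
    blocks = footprint(d, span_region)
    hits = []
    for iv in editing.intervals:
        if len(iv) != 1:
            raise ValueError("editing records must be single-base intervals")
        if not blocks or not _strand_ok(stranded, iv.strand, blocks[0].strand):
            continue
        if any(b.chrom == iv.chrom and b.start <= iv.start < b.end for b in blocks):
            hits.append(iv)
    return bool(hits), hits


def classify_region(
    d: DuplexAlignment,
    target: TranscriptModel,
    span_region: bool = False,
) -> str:
    """Partition the duplex by target region: NONCODING (no CDS), UTR (no CDS
    overlap), CDS (entirely within CDS) or UTR_CDS_OVERLAP."""
    if not target.cds:
        return "NONCODING"
    blocks = footprint(d, span_region)
    cds = merge_intervals(target.cds)
    inter = sum(overlap_size(b, cds) for b in blocks)
    total = sum(len(b) for b in blocks)
    if inter == 0:
        return "UTR"
    if inter == total:
        return "CDS"
    return "UTR_CDS_OVERLAP"


@dataclass
class MechanismTracks:
    """The annotation evidence consumed by the classifiers; all optional."""

    clip: Optional[AnnotationTrack] = None
    alu: Optional[AnnotationTrack] = None
    editing: Optional[AnnotationTrack] = None


def annotate_interactions(
    duplexes: List[DuplexAlignment],
    genes: List[GeneModel],
    tracks: MechanismTracks,
    mirnas: Optional[Mapping[str, str]] = None,
    genome: Optional[Mapping[str, str]] = None,
    params: ScoringParams = ScoringParams(),
    span_region: bool = False,
    stranded: bool = False,
) -> List[InteractionRecord]:
    """Run all four classifiers plus region classification on every duplex.

    Duplexes found in both spliced and pre-mRNA space with the same genomic
    blocks describe the same physical pairing; they are merged into a single
    record whose mechanism set is the union over both spaces.
    """
    from .genomic_model import spliced_sequence

    tx_index: Dict[str, TranscriptModel] = {}
    gene_index: Dict[str, GeneModel] = {}
    for g in genes:
        for t in g.transcripts:
            tx_index[t.transcript_id] = t
            gene_index[t.transcript_id] = g

    # precompute CLIP-supported miRNA sites per target transcript
    site_cache: Dict[str, List[MiRnaSite]] = {}

    def sites_for(target: TranscriptModel) -> List[MiRnaSite]:
        tid = target.transcript_id
        if tid not in site_cache:
            if mirnas and tracks.clip is not None and genome is not None:
                predicted = predict_seed_sites(
                    mirnas, target, spliced_sequence(target, genome)
                )
                site_cache[tid] = supported_mirna_sites(
                    predicted, tracks.clip, stranded
                )
            else:
                site_cache[tid] = []
        return site_cache[tid]

    records: Dict[Tuple[str, str, tuple], InteractionRecord] = {}
    for d in duplexes:
        if d.target_id not in tx_index:
            raise KeyError(f"duplex references unknown target {d.target_id!r}")
        target = tx_index[d.target_id]
        gene = gene_index[d.target_id]

        mechanisms: Set[MechanismLabel] = set()
        evidence: Dict[str, list] = {}
        if d.target_space == "premrna":
            ok, ev = classify_splicing(d, gene, span_region)
            if ok:
                mechanisms.add(MechanismLabel.SPLICING)
                evidence["SPLICING"] = ev
        sites = sites_for(target)
        ok, ev_sites = classify_mirna_masking(d, sites, params, span_region, stranded)
        if ok:
            mechanisms.add(MechanismLabel.MIRNA_MASKING)
            evidence["MIRNA_MASKING"] = ev_sites
        if tracks.alu is not None:
            ok, ev_alu = classify_smd(d, tracks.alu, target, span_region, stranded)
            if ok:
                mechanisms.add(MechanismLabel.SMD)
                evidence["SMD"] = ev_alu
        if tracks.editing is not None:
            ok, ev_ed = classify_editing(d, tracks.editing, span_region, stranded)
            if ok:
                mechanisms.add(MechanismLabel.EDITING)
                evidence["EDITING"] = ev_ed

        key = (
            d.lnc_id,
            d.target_id,
            tuple((b.chrom, b.start, b.end) for b in sorted(
                d.genome_blocks, key=lambda b: (b.chrom, b.start)
            )),
        )
        if key in records:
            rec = records[key]
            rec.mechanisms |= mechanisms
            for k, v in evidence.items():
                rec.evidence.setdefault(k, []).extend(
                    x for x in v if x not in rec.evidence.get(k, [])
                )
            if rec.duplex.target_space == "premrna" and d.target_space == "spliced":
                rec.duplex = d  # prefer the mature-transcript view for export
        else:
            records[key] = InteractionRecord(
                duplex=d,
                mechanisms=mechanisms,
                region=classify_region(d, target, span_region),
                gene_id=gene.gene_id,
                gene_name=gene.name,
                gene_description=gene.description,
                target_biotype=target.biotype,
                evidence=evidence,
            )
    return sorted(
        records.values(),
        key=lambda r: (r.lnc_id, r.target_id, r.duplex.target_span),
    )


def write_interactions_tsv(records: List[InteractionRecord], path: str) -> None:
    """Interaction table in the layout of the database search results."""
    with open(path, "w") as fh:
        fh.write(
            "lnc_id\ttarget_id\tmechanisms\tgene_name\tgene_description\t"
            "target_biotype\tregion\tscore\ttarget_space\n"
        )
        for r in records:
            mechs = ",".join(sorted(m.value for m in r.mechanisms))
            fh.write(
                f"{r.lnc_id}\t{r.target_id}\t{mechs}\t{r.gene_name}\t"
                f"{r.gene_description}\t{r.target_biotype}\t{r.region}\t"
                f"{r.duplex.score}\t{r.duplex.target_space}\n"
            )
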