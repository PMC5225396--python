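"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: the alignment
oracle enumerates match-anchored chains (no affine-gap state machine), the ORF
oracle walks from every ATG, and the classifier oracles operate on explicit
per-base position sets.
"""

from math import ceil
from typing import Dict, List, Set, Tuple

from lncduplex.genomic_model import GenomicInterval, ScoringParams, TranscriptModel
from lncduplex.duplex_align import pair_score

_STOPS = {"TAA", "TAG", "TGA"}


def oracle_best_duplex_score(lnc: str, target: str, params: ScoringParams) -> int:
    """Best local duplex score by exhaustive chaining of paired columns.

    Every local alignment is a sequence of paired (match/mismatch) columns
    separated by gap runs; enumerate all chains over the lncRNA and the
    reversed target, charging |open| + k*|extend| per k-length gap run.
    """
    b = target[::-1]
    n, m = len(lnc), len(b)
    go, ge = abs(params.gap_open), abs(params.gap_extend)

    def gapcost(k: int) -> int:
        return 0 if k == 0 else go + k * ge

    best = 0
    G = [[0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            prefix = 0
            for pi in range(i):
                for pj in range(j):
                    v = G[pi][pj] - gapcost(i - pi - 1) - gapcost(j - pj - 1)
                    if v > prefix:
                        prefix = v
            G[i][j] = pair_score(lnc[i], b[j], params) + prefix
            if G[i][j] > best:
                best = G[i][j]
    return best


def oracle_longest_peptide(seq: str) -> int:
    """Longest ORF by walking from every ATG to its first in-frame stop."""
    seq = seq.upper()
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        aa = 0
        pos = i
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            if "N" not in codon and codon in _STOPS:
                best = max(best, aa)
                break
            aa += 1
            pos += 3
    return best


# ---------------------------------------------------------------------------
# per-base position-set oracles for the mechanism classifiers


def baseset(intervals) -> Set[Tuple[str, int]]:
    out: Set[Tuple[str, int]] = set()
    for iv in intervals:
        out.update((iv.chrom, p) for p in range(iv.start, iv.end))
    return out


def oracle_editing(blocks, editing_positions) -> List[GenomicInterval]:
    fp = baseset(blocks)
    return [iv for iv in editing_positions if (iv.chrom, iv.start) in fp]


def oracle_smd(blocks, alus, utr3_blocks) -> List[GenomicInterval]:
    fp = baseset(blocks)
    utr = baseset(utr3_blocks)
    return [iv for iv in alus if baseset([iv]) <= fp and baseset([iv]) <= utr]


def oracle_mirna_masking(blocks, sites, half: float = 0.5) -> List:
    fp = baseset(blocks)
    hits = []
    for site in sites:
        need = ceil(half * len(site.interval))
        if len(baseset([site.interval]) & fp) >= need:
            hits.append(site)
    return hits


def oracle_region(blocks, cds_intervals) -> str:
    if not cds_intervals:
        return "NONCODING"
    fp = baseset(blocks)
    cds = baseset(cds_intervals)
    inter = fp & cds
    if not inter:
        return "UTR"
    if fp <= cds:
        return "CDS"
    return "UTR_CDS_OVERLAP"


def oracle_splice_sites(t: TranscriptModel) -> Set[int]:
    sites = set()
    exons = sorted(t.exons, key=lambda e: e.start)
    for a, b in zip(exons, exons[1:]):
        if b.start > a.end:
            sites.add(a.end)
            sites.add(b.start)
    return sites


def oracle_alternative_sites(transcripts: List[TranscriptModel]) -> Set[int]:
    out = set()
    per_tx = {t.transcript_id: oracle_splice_sites(t) for t in transcripts}
    all_sites = set().union(*per_tx.values()) if per_tx else set()
    for p in all_sites:
        users = {tid for tid, s in per_tx.items() if p in s}
        nonusers = [
            t
            for t in transcripts
            if t.transcript_id not in users
            and t.span.start <= p < t.span.end
        ]
        if users and nonusers:
            out.add(p)
    return out


def oracle_splicing(blocks, target: TranscriptModel, alt_sites: Set[int]) -> bool:
    fp = baseset(blocks)
    chrom = target.chrom

    def interior(p: int) -> bool:
        return (chrom, p - 1) in fp and (chrom, p) in fp

    if not any(interior(p) for p in oracle_splice_sites(target)):
        return False
    return any(interior(p) for p in alt_sites)


def oracle_utr3(t: TranscriptModel) -> List[GenomicInterval]:
    """3'UTR genomic positions: spliced bases past the last CDS base, walked
    base by base in transcript orientation."""
    if not t.cds:
        return []
    cds = baseset(t.cds)
    order = t.exons if t.strand == "+" else list(reversed(t.exons))
    tx_positions: List[Tuple[str, int]] = []
    for exon in order:
        rng = (
            range(exon.start, exon.end)
            if t.strand == "+"
            else range(exon.end - 1, exon.start - 1, -1)
        )
        tx_positions.extend((exon.chrom, p) for p in rng)
    cds_indices = [i for i, pos in enumerate(tx_positions) if pos in cds]
    if not cds_indices:
        return []
    last = max(cds_indices)
    utr_positions = sorted(p for _, p in tx_positions[last + 1 :])
    # pack back into intervals
    out: List[GenomicInterval] = []
    for p in utr_positions:
        if out and out[-1].end == p:
            out[-1] = GenomicInterval(t.chrom, out[-1].start, p + 1)
        else:
            out.append(GenomicInterval(t.chrom, p, p + 1))
    return out
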