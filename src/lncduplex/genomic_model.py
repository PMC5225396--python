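"""Domain types, coordinate conventions, standard-format I/O and sequence extraction.

All internal coordinates are 0-based half-open on the forward genomic strand.
GTF input (1-based inclusive) is converted on read; BED is native. Transcript
space runs 5'->3' of the transcript, i.e. for minus-strand transcripts it runs
against the genomic coordinate direction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gffutils

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class BoundsError(ValueError):
    """Raised when coordinates fall outside the addressed sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    Exons are kept sorted by genomic start regardless of strand; transcript
    (5'->3') order is derived from the strand when sequences are extracted.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    strand: str
    exons: List[GenomicInterval]
    cds: Optional[List[GenomicInterval]] = None
    novel: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chroms")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds:
            self.cds = sorted(self.cds, key=lambda c: c.start)
            for c in self.cds:
                if not any(e.contains(c) for e in self.exons):
                    raise ValueError(
                        f"{self.transcript_id}: CDS interval {c} outside exons"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]


@dataclass
class GeneModel:
    gene_id: str
    name: str = ""
    description: str = ""
    transcripts: List[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.transcripts[0].strand)


@dataclass
class ScoringParams:
    """Every numeric constant of the procedure, overridable via config.

    Alignment scores follow the custom complementarity matrix: G:C, A:T and
    G:T (wobble) pairs score 4, 2 and 1; anything else is a mismatch at -6.
    A gap of length k costs |gap_open| + k*|gap_extend| = 20 + 8k.
    """

    match_gc: int = 4
    match_at: int = 2
    match_gu: int = 1
    mismatch: int = -6
    gap_open: int = -20
    gap_extend: int = -8
    min_score: int = 500
    intron_margin: int = 250
    min_tpm: float = 1.0
    min_lnc_length: int = 200
    max_peptide_aa: int = 100
    fdr_threshold: float = 0.01
    fc_threshold: float = 1.5
    half_site_rule: float = 0.5

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ScoringParams":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown scoring parameters: {sorted(bad)}")
        return cls(**d)


@dataclass
class ExpressionMatrix:
    """Feature x sample TPM values with a sample -> group assignment."""

    tpm: "pandas.DataFrame"  # type: ignore[name-defined]  # noqa: F821
    group_of: Dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.tpm.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")

    def samples(self, group: Optional[str] = None) -> List[str]:
        if group is None:
            return list(self.tpm.columns)
        return [s for s in self.tpm.columns if self.group_of[s] == group]

    def max_tpm(self, feature_id: str, group: Optional[str] = None) -> float:
        if feature_id not in self.tpm.index:
            raise KeyError(f"no expression row for {feature_id!r}")
        row = self.tpm.loc[feature_id, self.samples(group)]
        return float(row.max()) if len(row) else 0.0

    def has_feature(self, feature_id: str) -> bool:
        return feature_id in self.tpm.index


# ---------------------------------------------------------------------------
# Sequence extraction


def _check_bounds(exon: GenomicInterval, genome: Mapping[str, str]) -> None:
    if exon.chrom not in genome:
        raise BoundsError(f"chromosome {exon.chrom!r} not in genome")
    if exon.end > len(genome[exon.chrom]):
        raise BoundsError(
            f"exon [{exon.start}, {exon.end}) beyond end of {exon.chrom} "
            f"(length {len(genome[exon.chrom])})"
        )


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Exon sequences concatenated in transcription (5'->3') order."""
    parts = []
    for exon in t.exons:
        _check_bounds(exon, genome)
        parts.append(genome[exon.chrom][exon.start : exon.end].upper())
    seq = "".join(parts)
    return reverse_complement(seq) if t.strand == "-" else seq


def premrna_sequence(
    t: TranscriptModel, genome: Mapping[str, str], margin: int = 250
) -> str:
    """Unspliced transcript sequence with deep-intron positions masked to N.

    Within each intron, positions farther than ``margin`` bases from both
    flanking splice sites are replaced by 'N'; introns of length <= 2*margin
    are left fully unmasked. The returned string runs 5'->3' of the transcript.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    span = t.span
    _check_bounds(GenomicInterval(t.chrom, span.start, span.end), genome)
    seq = list(genome[t.chrom][span.start : span.end].upper())
    for intron in t.introns:
        lo = intron.start + margin  # first maskable position
        hi = intron.end - margin  # one past last maskable position
        for pos in range(max(lo, intron.start), min(hi, intron.end)):
            seq[pos - span.start] = "N"
    out = "".join(seq)
    return reverse_complement(out) if t.strand == "-" else out


def transcript_to_genome(
    t: TranscriptModel, tx_start: int, tx_end: int, space: str = "spliced"
) -> List[GenomicInterval]:
    """Project a transcript-space interval onto genomic blocks.

    Transcript space runs 5'->3' of the transcript. Blocks are returned in
    genomic orientation (sorted by start) and their lengths sum to
    ``tx_end - tx_start``.
    """
    if space not in ("spliced", "premrna"):
        raise ValueError(f"unknown space {space!r}")
    length = t.spliced_length if space == "spliced" else len(t.span)
    if not (0 <= tx_start < tx_end <= length):
        raise BoundsError(
            f"[{tx_start}, {tx_end}) out of range for {space} length {length}"
        )
    if space == "premrna":
        span = t.span
        if t.strand == "+":
            g = GenomicInterval(t.chrom, span.start + tx_start, span.start + tx_end)
        else:
            g = GenomicInterval(t.chrom, span.end - tx_end, span.end - tx_start)
        return [g]

    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    blocks: List[GenomicInterval] = []
    offset = 0
    for exon in exons:
        elen = len(exon)
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + elen)
        if lo < hi:
            if t.strand == "+":
                blocks.append(
                    GenomicInterval(t.chrom, exon.start + lo - offset, exon.start + hi - offset)
                )
            else:
                blocks.append(
                    GenomicInterval(t.chrom, exon.end - (hi - offset), exon.end - (lo - offset))
                )
        offset += elen
    return sorted(blocks, key=lambda b: b.start)


# ---------------------------------------------------------------------------
# Interval arithmetic


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Strand-agnostic per-chromosome union; bookended intervals merge.

    Matches `bedtools merge` semantics: output sorted, disjoint, and two
    intervals touching end-to-start are joined.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def covered_bases(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(list(intervals)))


def overlap_size(a: GenomicInterval, blocks: Iterable[GenomicInterval]) -> int:
    """Bases of ``a`` covered by the union of ``blocks`` (strand-agnostic)."""
    total = 0
    for b in merge_intervals(list(blocks)):
        if b.chrom == a.chrom:
            total += max(0, min(a.end, b.end) - max(a.start, b.start))
    return total


# ---------------------------------------------------------------------------
# Annotation tracks (BED)


@dataclass
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: str = "."

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (CLIP, Alu, editing, miRNA sites)."""

    name: str
    records: List[BedRecord] = field(default_factory=list)

    @property
    def intervals(self) -> List[GenomicInterval]:
        return [r.interval for r in self.records]

    def merged(self) -> List[GenomicInterval]:
        return merge_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.records)


def read_bed(path: str, name: str = "") -> AnnotationTrack:
    """Read BED3/BED6 into an AnnotationTrack (0-based half-open, native)."""
    records: List[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has < 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            bname = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "."
            strand = fields[5] if len(fields) > 5 else "."
            records.append(
                BedRecord(GenomicInterval(chrom, start, end, strand), bname, score)
            )
    return AnnotationTrack(name or path, records)


def write_bed(records: Sequence[BedRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.interval.chrom,
                        str(r.interval.start),
                        str(r.interval.end),
                        r.name,
                        r.score,
                        r.interval.strand,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF / FASTA / expression input


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF line has < 9 columns")
            if fields[2] in ("exon", "CDS") and "transcript_id" not in fields[8]:
                raise ParseError(
                    f"{path}:{lineno}: {fields[2]} feature without transcript_id"
                )


def _attr(feature, *keys: str, default: str = "") -> str:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return default


def read_gtf(path: str) -> List[GeneModel]:
    """Parse an Ensembl-dialect GTF into GeneModels.

    GTF's 1-based inclusive coordinates become 0-based half-open. Transcript
    biotype comes from transcript_biotype/transcript_type ("" if absent);
    novelty from a truthy "novel" attribute.
    """
    _validate_gtf_lines(path)
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted internals
        raise ParseError(f"{path}: GTF parse failed: {exc}") from exc

    gene_meta: Dict[str, Tuple[str, str]] = {}
    tx_exons: Dict[str, List[GenomicInterval]] = {}
    tx_cds: Dict[str, List[GenomicInterval]] = {}
    tx_info: Dict[str, dict] = {}
    gene_order: List[str] = []

    for f in db.all_features():
        if f.featuretype == "gene":
            gid = _attr(f, "gene_id")
            gene_meta[gid] = (
                _attr(f, "gene_name"),
                _attr(f, "gene_description", "description"),
            )
            continue
        if f.featuretype not in ("exon", "CDS"):
            continue
        tid = _attr(f, "transcript_id")
        gid = _attr(f, "gene_id")
        iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        if tid not in tx_info:
            tx_info[tid] = {
                "gene_id": gid,
                "strand": f.strand,
                "biotype": _attr(f, "transcript_biotype", "transcript_type"),
                "novel": _attr(f, "novel").lower() in ("1", "true", "yes"),
            }
            if gid not in gene_meta:
                gene_meta[gid] = (_attr(f, "gene_name"), "")
            if gid not in gene_order:
                gene_order.append(gid)
        if f.featuretype == "exon":
            tx_exons.setdefault(tid, []).append(iv)
        else:
            tx_cds.setdefault(tid, []).append(iv)

    genes: Dict[str, GeneModel] = {}
    for gid in gene_order:
        name, desc = gene_meta.get(gid, ("", ""))
        genes[gid] = GeneModel(gene_id=gid, name=name, description=desc)
    for tid in sorted(tx_exons):
        info = tx_info[tid]
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            biotype=info["biotype"],
            strand=info["strand"],
            exons=tx_exons[tid],
            cds=tx_cds.get(tid),
            novel=info["novel"],
        )
        if info["gene_id"] not in genes:
            genes[info["gene_id"]] = GeneModel(gene_id=info["gene_id"])
        genes[info["gene_id"]].transcripts.append(t)
    return [genes[g] for g in genes if genes[g].transcripts]


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_expression(tpm_path: str, groups_path: str) -> ExpressionMatrix:
    """Read a TPM TSV (first column = feature id, header = sample ids) and a
    two-column sample->group map (groups: case/control)."""
    import pandas as pd

    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
    group_of = dict(zip(groups["sample"].astype(str), groups["group"].astype(str)))
    bad = set(group_of.values()) - {"case", "control"}
    if bad:
        raise ParseError(f"{groups_path}: unknown group labels {sorted(bad)}")
    return ExpressionMatrix(tpm=tpm, group_of=group_of)
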