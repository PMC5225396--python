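"""Self-contained toy dataset with planted ground truth for every stage.

The generator emulates the inputs of the full pipeline for a case/control
cornea-style cohort: a toy genome, multi-isoform gene models, expression and
differential-expression tables, annotation tracks (Argonaute CLIP, Alu,
A-to-I editing), mature miRNAs — and, crucially, reverse-complementary
lncRNA:target duplex segments planted either in 3'UTRs (for the miRNA-masking,
editing and SMD mechanisms) or across an alternative splice junction in
pre-mRNA (for the splicing mechanism).

Planted duplex segments are GC-rich: with the complementarity matrix
(G:C=+4, A:T=+2) a perfect pairing of uniform-composition RNA scores about
3 per column, so the score-500 threshold is only reachable at these lengths
(130-200 nt) by GC-dense pairings, as in natural Alu-mediated duplexes. The
generator guarantees each planted segment a perfect-pairing score safely above
the threshold and caps the number of point mutations accordingly, so the
planted duplex always clears it; every planted duplex is re-aligned before
emission.

All randomness flows from one integer seed; the same seed reproduces every
output file byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .duplex_align import align_duplex, best_duplex_score, normalize_rna
from .genomic_model import (
    BedRecord,
    GeneModel,
    GenomicInterval,
    ScoringParams,
    TranscriptModel,
    merge_intervals,
    premrna_sequence,
    reverse_complement,
    spliced_sequence,
    write_bed,
    write_fasta,
)
from .lnc_identify import classify_lncrna, longest_peptide_length

_BASES = np.array(list("ACGT"))

MECHANISMS = ("SPLICING", "MIRNA_MASKING", "EDITING", "SMD")
FAILURE_MODES = ("expression", "length", "peptide", "biotype", "novel_structure")


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_chroms: int = 2
    chrom_length: int = 100_000
    duplexes_per_mechanism: int = 2
    combo_duplexes: int = 1  # extra duplexes carrying both SMD and EDITING
    idle_lncrnas: int = 2  # lncRNAs with no planted duplex
    decoys_per_failure_mode: int = 2
    samples_per_group: int = 5
    duplex_length_min: int = 130
    duplex_length_max: int = 200
    mutation_rate_max: float = 0.05
    gc_fraction: float = 0.9  # composition of planted duplex segments
    utr3_length: int = 900

    def validate(self) -> None:
        if self.duplex_length_min < 125 or self.duplex_length_max < self.duplex_length_min:
            raise GeneratorError("invalid duplex length range")
        if self.duplex_length_max + 60 > self.utr3_length:
            raise GeneratorError(
                f"duplex ({self.duplex_length_max} nt) does not fit in the "
                f"3'UTR ({self.utr3_length} nt) with evidence margins"
            )
        if self.samples_per_group < 1:
            raise GeneratorError("need at least one sample per group")
        if not (0 <= self.mutation_rate_max <= 0.2):
            raise GeneratorError("mutation rate must be in [0, 0.2]")


@dataclass
class PlantedDuplex:
    lnc_id: str
    gene_id: str
    target_ids: List[str]
    mechanisms: List[str]
    region: str
    chrom: str
    start: int  # genomic footprint of the planted segment
    end: int
    target_space: str
    n_mutations: int
    condition_specific: bool


@dataclass
class TruthRecord:
    """Ground truth planted by the generator, resolvable against the files."""

    seed: int
    planted_lncrnas: List[Dict[str, object]] = field(default_factory=list)
    decoy_lncrnas: List[Dict[str, str]] = field(default_factory=list)
    planted_duplexes: List[Dict[str, object]] = field(default_factory=list)
    expected_interactions: List[Dict[str, object]] = field(default_factory=list)
    de_pass: Dict[str, str] = field(default_factory=dict)
    de_fail: List[str] = field(default_factory=list)
    condition_specific_pairs: List[List[str]] = field(default_factory=list)
    overlap_truth: Dict[str, object] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, p: Optional[Sequence[float]] = None) -> str:
    return "".join(rng.choice(_BASES, size=n, p=p))


def _noncoding_seq(rng: np.random.Generator, n: int, max_aa: int = 80) -> str:
    """Random sequence whose longest forward ORF stays safely non-coding."""
    for _ in range(500):
        seq = _random_seq(rng, n)
        if longest_peptide_length(seq) < max_aa:
            return seq
    raise GeneratorError(f"could not draw a non-coding sequence of length {n}")


def _gc_rich_segment(
    rng: np.random.Generator,
    length: int,
    gc: float,
    fixed: Optional[Dict[int, str]] = None,
    min_perfect_score: int = 512,
) -> Tuple[str, int]:
    """Duplex donor segment with a guaranteed perfect-pairing score.

    ``fixed`` pins bases (planted evidence such as a miRNA seed complement or
    editing adenosines); only free A/T positions are promoted to G/C when the
    drawn composition falls short of ``min_perfect_score``.
    """
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(_random_seq(rng, length, p))
    fixed = fixed or {}
    for i, c in fixed.items():
        seq[i] = c

    score = sum(4 if c in "GC" else 2 for c in seq)
    at_positions = [
        i for i, c in enumerate(seq) if c in "AT" and i not in fixed
    ]
    rng.shuffle(at_positions)
    while score < min_perfect_score and at_positions:
        i = at_positions.pop()
        seq[i] = "G" if rng.random() < 0.5 else "C"
        score += 2
    if score < min_perfect_score:
        raise GeneratorError("cannot reach the required duplex score")
    return "".join(seq), score


def _mutate(
    rng: np.random.Generator, seq: str, n_mut: int, lo: int = 8, hi_margin: int = 8
) -> str:
    """Apply n point mutations away from the segment ends."""
    if n_mut == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(
        np.arange(lo, len(seq) - hi_margin), size=n_mut, replace=False
    )
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


class _Builder:
    """Accumulates genes, tracks and truth while laying out the genome."""

    def __init__(self, config: GeneratorConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.params = ScoringParams()
        self.chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
        self.genome = {
            c: np.array(list(_random_seq(self.rng, config.chrom_length)))
            for c in self.chroms
        }
        self.cursor = {c: 1000 for c in self.chroms}
        self.genes: List[GeneModel] = []
        self.clip: List[BedRecord] = []
        self.alu: List[BedRecord] = []
        self.editing: List[BedRecord] = []
        self.mirnas: Dict[str, str] = {}
        self.tpm_rows: Dict[str, np.ndarray] = {}
        self.truth = TruthRecord(seed=seed)
        self.samples = [
            f"case_{i + 1}" for i in range(config.samples_per_group)
        ] + [f"ctrl_{i + 1}" for i in range(config.samples_per_group)]
        self.footprints: List[GenomicInterval] = []
        self._de_rows: Dict[str, List[Tuple[str, float, float]]] = {
            "deseq2": [],
            "edger": [],
        }

    # -- genome bookkeeping -------------------------------------------------

    def _alloc(self, chrom: str, length: int, gap: int = 600) -> int:
        start = self.cursor[chrom]
        if start + length + gap > self.config.chrom_length:
            raise GeneratorError(
                f"{chrom} too short for the configured gene content"
            )
        self.cursor[chrom] = start + length + gap
        return start

    def _write(self, chrom: str, start: int, seq: str) -> None:
        self.genome[chrom][start : start + len(seq)] = list(seq)

    def _read(self, chrom: str, start: int, end: int) -> str:
        return "".join(self.genome[chrom][start:end])

    # -- expression / DE ----------------------------------------------------

    def _expr(
        self, transcript_id: str, case_high: bool = True, control_high: bool = True
    ) -> None:
        n = self.config.samples_per_group
        case = self.rng.uniform(2, 10, n) if case_high else self.rng.uniform(0.0, 0.4, n)
        ctrl = self.rng.uniform(2, 10, n) if control_high else self.rng.uniform(0.0, 0.4, n)
        self.tpm_rows[transcript_id] = np.round(np.concatenate([case, ctrl]), 3)

    def _de(self, gene_id: str, direction: str = "up", passing: bool = True) -> None:
        for method in ("deseq2", "edger"):
            fdr = float(self.rng.uniform(1e-6, 1e-3))
            fc = float(self.rng.uniform(1.6, 4.0))
            if direction == "down":
                fc = 1.0 / fc
            self._de_rows[method].append((gene_id, round(fc, 4), fdr))
        if passing:
            self.truth.de_pass[gene_id] = direction

    # -- gene construction --------------------------------------------------

    def add_lnc_gene(
        self,
        name: str,
        planted_segment: Optional[str] = None,
        novel: bool = False,
        strand: str = "+",
        case_only: bool = False,
    ) -> TranscriptModel:
        """Two-exon lncRNA gene; the planted segment (already the reverse
        complement of the target side, mutations applied) lands in exon 2."""
        chrom = self.chroms[-1]
        exon1_len, intron_len, exon2_len = 400, 300, 600
        g0 = self._alloc(chrom, exon1_len + intron_len + exon2_len)
        exon1 = GenomicInterval(chrom, g0, g0 + exon1_len, strand)
        e2s = g0 + exon1_len + intron_len
        exon2 = GenomicInterval(chrom, e2s, e2s + exon2_len, strand)

        for _ in range(500):
            spliced = _noncoding_seq(self.rng, exon1_len + exon2_len, max_aa=200)
            if planted_segment:
                off = exon1_len + 100
                spliced = (
                    spliced[:off]
                    + planted_segment
                    + spliced[off + len(planted_segment) :]
                )
            if longest_peptide_length(spliced) < 80:
                break
        else:
            raise GeneratorError("could not assemble a non-coding lncRNA sequence")

        if strand == "+":
            self._write(chrom, g0, spliced[:exon1_len])
            self._write(chrom, e2s, spliced[exon1_len:])
        else:
            rc = reverse_complement(spliced)
            self._write(chrom, g0, rc[:exon1_len])
            self._write(chrom, e2s, rc[exon1_len:])

        tid, gid = f"T{name}", f"G{name}"
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            biotype="" if novel else "lincRNA",
            strand=strand,
            exons=[exon1, exon2],
            novel=novel,
        )
        self.genes.append(
            GeneModel(gene_id=gid, name=name, description=f"synthetic lncRNA {name}", transcripts=[t])
        )
        self._expr(tid, case_high=True, control_high=not case_only)
        self._de(gid, "up")
        self.truth.planted_lncrnas.append(
            {"transcript_id": tid, "gene_id": gid, "novel": novel}
        )
        return t

    def add_utr_target_gene(
        self, name: str, mechanisms: List[str], case_only: bool
    ) -> Dict[str, object]:
        """Protein-coding gene (two isoforms) whose 3'UTR hosts a planted
        duplex segment plus the evidence for the given UTR mechanisms."""
        cfg = self.config
        chrom = self.chroms[0]
        g0 = self._alloc(chrom, 2400)
        e1 = GenomicInterval(chrom, g0, g0 + 300, "+")
        e2a = GenomicInterval(chrom, g0 + 700, g0 + 1000, "+")
        e2b = GenomicInterval(chrom, g0 + 760, g0 + 1000, "+")
        e3 = GenomicInterval(chrom, g0 + 1400, g0 + 1400 + 100 + cfg.utr3_length, "+")
        cds_end = g0 + 1500
        cds_a = [
            GenomicInterval(chrom, g0 + 100, g0 + 300, "+"),
            GenomicInterval(chrom, g0 + 700, g0 + 1000, "+"),
            GenomicInterval(chrom, g0 + 1400, cds_end, "+"),
        ]
        cds_b = [
            GenomicInterval(chrom, g0 + 100, g0 + 300, "+"),
            GenomicInterval(chrom, g0 + 760, g0 + 1000, "+"),
            GenomicInterval(chrom, g0 + 1400, cds_end, "+"),
        ]
        gid = f"G{name}"
        tx_a = TranscriptModel(f"T{name}_A", gid, "protein_coding", "+", [e1, e2a, e3], cds=cds_a)
        tx_b = TranscriptModel(f"T{name}_B", gid, "protein_coding", "+", [e1, e2b, e3], cds=cds_b)
        self.genes.append(
            GeneModel(gid, name, f"synthetic coding gene {name}", [tx_a, tx_b])
        )

        # plant the duplex segment in the shared 3'UTR
        utr_start = cds_end
        evidence_margin = 14
        min_perfect = self.params.min_score + 12

        # the planted evidence bases (seed complement, adenosines) are not
        # GC-boostable, so short draws can cap the achievable pairing score
        # below the threshold; redraw longer segments in that case
        for attempt in range(50):
            lo = cfg.duplex_length_min if attempt == 0 else min(
                145, cfg.duplex_length_max
            )
            L = int(self.rng.integers(lo, cfg.duplex_length_max + 1))
            fixed: Dict[int, str] = {}
            mirna_id = None
            if "MIRNA_MASKING" in mechanisms:
                mseq = _random_seq(self.rng, 22)
                mirna_id = f"mir-{name}"
                # seed (miRNA positions 2-8) complement embedded inside the
                # segment; the predicted site is [m-14, m+7) around the match
                m_off = int(
                    self.rng.integers(evidence_margin + 14, L - evidence_margin - 7)
                )
                seed_rc = reverse_complement(normalize_rna(mseq)[1:8])
                fixed.update({m_off + k: c for k, c in enumerate(seed_rc)})
            editing_offsets: List[int] = []
            if "EDITING" in mechanisms:
                k = int(self.rng.integers(3, 6))
                editing_offsets = sorted(
                    int(x)
                    for x in self.rng.choice(
                        np.arange(evidence_margin, L - evidence_margin), k,
                        replace=False,
                    )
                    if int(x) not in fixed
                )
                # adenosines for the A-to-I events (paired with U on the lncRNA)
                fixed.update({eo: "A" for eo in editing_offsets})
            achievable = 4 * (L - len(fixed)) + sum(
                4 if c in "GC" else 2 for c in fixed.values()
            )
            if achievable >= min_perfect:
                break
        else:
            raise GeneratorError(
                "duplex length range cannot host the planted evidence at the "
                "required pairing score"
            )

        if mirna_id is not None:
            self.mirnas[mirna_id] = mseq
        off = int(self.rng.integers(30, cfg.utr3_length - L - 30))
        seg_start = utr_start + off
        seg, perfect = _gc_rich_segment(
            self.rng, L, cfg.gc_fraction, fixed, min_perfect_score=min_perfect
        )
        self._write(chrom, seg_start, seg)

        # evidence tracks
        if mirna_id is not None:
            site = GenomicInterval(chrom, seg_start + m_off - 14, seg_start + m_off + 7, "+")
            self.clip.append(BedRecord(site, f"clip_{name}", "."))
        if "SMD" in mechanisms:
            alu_len = int(self.rng.integers(60, min(120, L - 2 * evidence_margin)))
            a0 = int(
                self.rng.integers(
                    evidence_margin, L - evidence_margin - alu_len
                )
            )
            self.alu.append(
                BedRecord(
                    GenomicInterval(chrom, seg_start + a0, seg_start + a0 + alu_len, "+"),
                    f"AluY_synth_{name}",
                    ".",
                )
            )
        for eo in editing_offsets:
            self.editing.append(
                BedRecord(
                    GenomicInterval(chrom, seg_start + eo, seg_start + eo + 1, "+"),
                    f"AtoI_{name}_{eo}",
                    ".",
                )
            )

        # lncRNA partner: reverse complement of the segment, with mutations
        max_mut = max(0, (perfect - self.params.min_score - 12) // 10)
        rate = float(self.rng.uniform(0.0, cfg.mutation_rate_max))
        n_mut = min(int(round(rate * L)), max_mut, max(0, L - 16 - 1))
        lnc_seq_segment = _mutate(self.rng, reverse_complement(seg), n_mut)
        lnc_tx = self.add_lnc_gene(
            f"LNC_{name}",
            planted_segment=lnc_seq_segment,
            novel=bool(self.rng.integers(2)),
            case_only=case_only,
        )

        for tid in (tx_a.transcript_id, tx_b.transcript_id):
            self._expr(tid, case_high=True, control_high=not case_only)
        self._de(gid, "up" if self.rng.integers(2) else "down")

        footprint = GenomicInterval(chrom, seg_start, seg_start + L)
        self.footprints.append(footprint)
        planted = PlantedDuplex(
            lnc_id=lnc_tx.transcript_id,
            gene_id=gid,
            target_ids=[tx_a.transcript_id, tx_b.transcript_id],
            mechanisms=sorted(mechanisms),
            region="UTR",
            chrom=chrom,
            start=seg_start,
            end=seg_start + L,
            target_space="spliced",
            n_mutations=n_mut,
            condition_specific=case_only,
        )
        self._record_planted(planted)
        return {"planted": planted, "transcripts": [tx_a, tx_b], "lnc": lnc_tx}

    def add_splicing_target_gene(self, name: str, case_only: bool) -> Dict[str, object]:
        """Two-isoform gene with an alternative 3' splice site; the duplex is
        planted across isoform A's exon-intron border in pre-mRNA space."""
        chrom = self.chroms[0]
        g0 = self._alloc(chrom, 2200)
        s2 = g0 + 1000
        e1 = GenomicInterval(chrom, g0, g0 + 300, "+")
        e2a = GenomicInterval(chrom, s2, s2 + 250, "+")
        e2b = GenomicInterval(chrom, s2 - 40, s2 + 250, "+")
        e3 = GenomicInterval(chrom, g0 + 1600, g0 + 2200, "+")
        cds_a = [
            GenomicInterval(chrom, g0 + 100, g0 + 300, "+"),
            e2a,
            GenomicInterval(chrom, g0 + 1600, g0 + 1700, "+"),
        ]
        cds_b = [
            GenomicInterval(chrom, g0 + 100, g0 + 300, "+"),
            e2b,
            GenomicInterval(chrom, g0 + 1600, g0 + 1700, "+"),
        ]
        gid = f"G{name}"
        tx_a = TranscriptModel(f"T{name}_A", gid, "protein_coding", "+", [e1, e2a, e3], cds=cds_a)
        tx_b = TranscriptModel(f"T{name}_B", gid, "protein_coding", "+", [e1, e2b, e3], cds=cds_b)
        self.genes.append(
            GeneModel(gid, name, f"synthetic coding gene {name}", [tx_a, tx_b])
        )

        # duplex across the border: 60 exonic nt, the rest intronic, so the
        # spliced-space score stays far below threshold for both isoforms
        L = int(self.rng.integers(140, 151))
        seg_start = s2 - (L - 60)
        seg, perfect = _gc_rich_segment(self.rng, L, self.config.gc_fraction)
        self._write(chrom, seg_start, seg)

        max_mut = max(0, (perfect - self.params.min_score - 12) // 10)
        rate = float(self.rng.uniform(0.0, self.config.mutation_rate_max))
        n_mut = min(int(round(rate * L)), max_mut, max(0, L - 16 - 1))
        lnc_seq_segment = _mutate(self.rng, reverse_complement(seg), n_mut)
        lnc_tx = self.add_lnc_gene(
            f"LNC_{name}", planted_segment=lnc_seq_segment, case_only=case_only
        )

        for tid in (tx_a.transcript_id, tx_b.transcript_id):
            self._expr(tid, case_high=True, control_high=not case_only)
        self._de(gid, "up" if self.rng.integers(2) else "down")

        footprint = GenomicInterval(chrom, seg_start, seg_start + L)
        self.footprints.append(footprint)
        planted = PlantedDuplex(
            lnc_id=lnc_tx.transcript_id,
            gene_id=gid,
            target_ids=[tx_a.transcript_id, tx_b.transcript_id],
            mechanisms=["SPLICING"],
            region="UTR_CDS_OVERLAP",
            chrom=chrom,
            start=seg_start,
            end=seg_start + L,
            target_space="premrna",
            n_mutations=n_mut,
            condition_specific=case_only,
        )
        self._record_planted(planted)
        return {"planted": planted, "transcripts": [tx_a, tx_b], "lnc": lnc_tx}

    def _record_planted(self, planted: PlantedDuplex) -> None:
        self.truth.planted_duplexes.append(dataclasses.asdict(planted))
        for tid in planted.target_ids:
            self.truth.expected_interactions.append(
                {
                    "lnc_id": planted.lnc_id,
                    "target_id": tid,
                    "mechanisms": planted.mechanisms,
                    "region": planted.region,
                    "chrom": planted.chrom,
                    "start": planted.start,
                    "end": planted.end,
                    "condition_specific": planted.condition_specific,
                }
            )
            if planted.condition_specific:
                self.truth.condition_specific_pairs.append([planted.lnc_id, tid])

    # -- decoys and fixtures -------------------------------------------------

    def add_decoy_lnc(self, mode: str, index: int) -> None:
        chrom = self.chroms[-1]
        name = f"DEC_{mode.upper()}_{index}"
        tid, gid = f"T{name}", f"G{name}"
        if mode == "length":
            exon_lens, biotype, novel = (100, 99), "lincRNA", False
        elif mode == "novel_structure":
            exon_lens, biotype, novel = (300,), "", True
        elif mode == "biotype":
            exon_lens, biotype, novel = (150, 150), "snoRNA", False
        elif mode == "peptide":
            exon_lens, biotype, novel = (300, 300), "lincRNA", False
        else:  # expression
            exon_lens, biotype, novel = (150, 150), "lincRNA", False

        total = sum(exon_lens)
        span = total + 200 * (len(exon_lens) - 1)
        g0 = self._alloc(chrom, span, gap=400)
        exons = []
        pos = g0
        for el in exon_lens:
            exons.append(GenomicInterval(chrom, pos, pos + el, "+"))
            pos += el + 200

        if mode == "peptide":
            # exactly one 100-aa ORF: ATG + 99 sense codons + stop = 303 nt
            for _ in range(500):
                seq = _noncoding_seq(self.rng, total, max_aa=60)
                codons = []
                while len(codons) < 99:
                    c = _random_seq(self.rng, 3)
                    if c not in ("TAA", "TAG", "TGA", "ATG"):
                        codons.append(c)
                orf = "ATG" + "".join(codons) + "TAA"
                seq = seq[:100] + orf + seq[100 + len(orf) :]
                if longest_peptide_length(seq) == 100:
                    break
            else:
                raise GeneratorError("could not plant a 100-aa decoy ORF")
        else:
            seq = _noncoding_seq(self.rng, total)

        off = 0
        for exon, el in zip(exons, exon_lens):
            self._write(chrom, exon.start, seq[off : off + el])
            off += el

        t = TranscriptModel(tid, gid, biotype, "+", exons, novel=novel)
        self.genes.append(GeneModel(gid, name, f"decoy ({mode})", [t]))
        if mode == "expression":
            self.tpm_rows[tid] = np.round(
                self.rng.uniform(0.2, 0.9, 2 * self.config.samples_per_group), 3
            )
        else:
            self._expr(tid)
        self.truth.decoy_lncrnas.append({"transcript_id": tid, "failure_mode": mode})

    def add_overlap_fixture(self) -> None:
        """Two overlapping DE gene pairs: one concordant pair containing a
        lncRNA isoform, one discordant pair without."""
        chrom = self.chroms[0]
        for pair, (d1, d2) in (("A", ("up", "up")), ("B", ("up", "down"))):
            g0 = self._alloc(chrom, 3200)
            for k, (shift, direction) in enumerate(((0, d1), (1100, d2)), start=1):
                gid = f"GOVL_{pair}{k}"
                exons = [
                    GenomicInterval(chrom, g0 + shift, g0 + shift + 700, "+"),
                    GenomicInterval(chrom, g0 + shift + 1100, g0 + shift + 2000, "+"),
                ]
                txs = [
                    TranscriptModel(f"TOVL_{pair}{k}", gid, "protein_coding", "+", exons)
                ]
                if pair == "A" and k == 1:
                    lnc_exons = [
                        GenomicInterval(chrom, g0 + 50, g0 + 400, "+"),
                        GenomicInterval(chrom, g0 + 600, g0 + 1000, "+"),
                    ]
                    seq = _noncoding_seq(self.rng, 750)
                    self._write(chrom, g0 + 50, seq[:350])
                    self._write(chrom, g0 + 600, seq[350:])
                    lnc = TranscriptModel(
                        f"TOVL_{pair}{k}_lnc", gid, "lincRNA", "+", lnc_exons
                    )
                    txs.append(lnc)
                    self._expr(lnc.transcript_id)
                    self.truth.planted_lncrnas.append(
                        {
                            "transcript_id": lnc.transcript_id,
                            "gene_id": gid,
                            "novel": False,
                        }
                    )
                self.genes.append(
                    GeneModel(gid, f"OVL_{pair}{k}", "overlap fixture gene", txs)
                )
                self._expr(f"TOVL_{pair}{k}")
                self._de(gid, direction)
        self.truth.overlap_truth = {
            "n_overlapping_genes": 4,
            "n_overlapping_pairs": 2,
            "n_concordant_pairs": 1,
            "n_pairs_with_lnc_isoform": 1,
        }

    def add_de_boundary_decoys(self) -> None:
        p = self.params
        rows = [
            ("GDEC_FC_AT_THRESHOLD", p.fc_threshold, 1e-4, p.fc_threshold, 1e-4, True, "up"),
            ("GDEC_FDR_AT_THRESHOLD", 2.0, p.fdr_threshold, 2.0, p.fdr_threshold, False, ""),
            ("GDEC_FC_BELOW", 1.4, 1e-4, 1.4, 1e-4, False, ""),
            ("GDEC_DISCORDANT", 2.0, 1e-4, 0.4, 1e-4, False, ""),
        ]
        for gid, fc1, fdr1, fc2, fdr2, passes, direction in rows:
            self._de_rows["deseq2"].append((gid, fc1, fdr1))
            self._de_rows["edger"].append((gid, fc2, fdr2))
            if passes:
                self.truth.de_pass[gid] = direction
            else:
                self.truth.de_fail.append(gid)

    def add_decoy_tracks(self) -> None:
        """Track intervals that violate their classifier's geometry: away from
        every planted footprint (editing, CLIP) or breaking the containment
        and 3'UTR rules (Alu)."""
        chrom = self.chroms[0]
        far = self.config.chrom_length - 3000
        for i in range(3):
            self.editing.append(
                BedRecord(
                    GenomicInterval(chrom, far + 50 * i, far + 50 * i + 1),
                    f"AtoI_decoy_{i}",
                    ".",
                )
            )
        self.clip.append(
            BedRecord(GenomicInterval(chrom, far + 500, far + 560), "clip_decoy", ".")
        )
        # an Alu overhanging a planted UTR footprint (fails "entirely
        # within"; the 30-base overhang keeps it outside any chance extension
        # of the recovered alignment), plus one far from everything
        utr_fp = next(
            (
                d
                for d in self.truth.planted_duplexes
                if d["target_space"] == "spliced"
            ),
            None,
        )
        if utr_fp is not None:
            self.alu.append(
                BedRecord(
                    GenomicInterval(
                        utr_fp["chrom"], utr_fp["start"] - 30, utr_fp["start"] + 60
                    ),
                    "Alu_decoy_overhang",
                    ".",
                )
            )
        self.alu.append(
            BedRecord(GenomicInterval(chrom, far + 800, far + 1100), "Alu_decoy_far", ".")
        )
        # a decoy miRNA whose seed complement occurs in no transcript
        genome = self.genome_dict()
        all_seqs = [
            spliced_sequence(t, genome)
            for g in self.genes
            for t in g.transcripts
        ]
        for _ in range(200):
            mseq = _random_seq(self.rng, 22)
            seed_rc = reverse_complement(mseq[1:8])
            if not any(seed_rc in s for s in all_seqs):
                self.mirnas["mir-decoy"] = mseq
                break

    # -- assembly ------------------------------------------------------------

    def genome_dict(self) -> Dict[str, str]:
        return {c: "".join(self.genome[c]) for c in self.chroms}

    def validate_planted(self, cross: bool = False) -> None:
        genome = self.genome_dict()
        tx = {
            t.transcript_id: t for g in self.genes for t in g.transcripts
        }
        lnc_seqs = {}
        for d in self.truth.planted_duplexes:
            lnc_seqs[d["lnc_id"]] = spliced_sequence(tx[d["lnc_id"]], genome)
        for d in self.truth.planted_duplexes:
            lnc_seq = lnc_seqs[d["lnc_id"]]
            for tid in d["target_ids"]:
                target = tx[tid]
                seq = (
                    premrna_sequence(target, genome, self.params.intron_margin)
                    if d["target_space"] == "premrna"
                    else spliced_sequence(target, genome)
                )
                alns = align_duplex(lnc_seq, seq, self.params)
                if not alns:
                    raise GeneratorError(
                        f"planted duplex {d['lnc_id']}x{tid} not recovered "
                        "by self-validation"
                    )
        # decoy lncRNAs must fail exactly their planted criterion
        samples = self.samples
        for decoy in self.truth.decoy_lncrnas:
            t = tx[decoy["transcript_id"]]
            tpm = dict(zip(samples, self.tpm_rows[t.transcript_id]))
            decision = classify_lncrna(
                t, spliced_sequence(t, genome), tpm, self.params
            )
            if decision.failed_criteria != {decoy["failure_mode"]}:
                raise GeneratorError(
                    f"decoy {t.transcript_id} fails {decision.failed_criteria}, "
                    f"expected {{{decoy['failure_mode']!r}}}"
                )
        # decoy geometry
        fp = merge_intervals(self.footprints)
        for rec in self.editing:
            if rec.name.startswith("AtoI_decoy") and any(
                b.chrom == rec.interval.chrom
                and b.start <= rec.interval.start < b.end
                for b in fp
            ):
                raise GeneratorError("editing decoy fell inside a footprint")
        for rec in self.alu:
            if rec.name.startswith("Alu_decoy") and any(
                b.contains(rec.interval) for b in fp
            ):
                raise GeneratorError("Alu decoy contained in a footprint")
        if cross:
            targets = {
                t.transcript_id: spliced_sequence(tx[t.transcript_id], genome)
                for g in self.genes
                for t in g.transcripts
                if t.biotype == "protein_coding"
            }
            partners = {
                (d["lnc_id"], tid)
                for d in self.truth.planted_duplexes
                for tid in d["target_ids"]
            }
            for lnc_id, lnc_seq in lnc_seqs.items():
                for tid, seq in targets.items():
                    if (lnc_id, tid) in partners:
                        continue
                    score = best_duplex_score(lnc_seq, seq, self.params)
                    if score >= self.params.min_score:
                        raise GeneratorError(
                            f"spurious complementarity {lnc_id}x{tid} ({score})"
                        )

    def emit(self, outdir: str) -> TruthRecord:
        os.makedirs(outdir, exist_ok=True)
        genome = self.genome_dict()
        paths = {
            "genome": "genome.fa",
            "gtf": "annotation.gtf",
            "tpm": "expression_tpm.tsv",
            "groups": "sample_groups.tsv",
            "de_deseq2": "de_deseq2.tsv",
            "de_edger": "de_edger.tsv",
            "clip": "clip.bed",
            "alu": "alu.bed",
            "editing": "editing.bed",
            "mirnas": "mirnas.fa",
            "truth": "truth.json",
        }
        self.truth.files = paths
        write_fasta(genome, os.path.join(outdir, paths["genome"]))
        _write_gtf(self.genes, os.path.join(outdir, paths["gtf"]))

        with open(os.path.join(outdir, paths["tpm"]), "w") as fh:
            fh.write("transcript_id\t" + "\t".join(self.samples) + "\n")
            for tid in sorted(self.tpm_rows):
                vals = "\t".join(f"{v:g}" for v in self.tpm_rows[tid])
                fh.write(f"{tid}\t{vals}\n")
        with open(os.path.join(outdir, paths["groups"]), "w") as fh:
            for s in self.samples:
                group = "case" if s.startswith("case") else "control"
                fh.write(f"{s}\t{group}\n")
        for method in ("deseq2", "edger"):
            with open(os.path.join(outdir, paths[f"de_{method}"]), "w") as fh:
                fh.write("gene_id\tfold_change\tfdr\n")
                for gid, fc, fdr in sorted(self._de_rows[method]):
                    fh.write(f"{gid}\t{fc:g}\t{fdr:.8g}\n")
        write_bed(self.clip, os.path.join(outdir, paths["clip"]))
        write_bed(self.alu, os.path.join(outdir, paths["alu"]))
        write_bed(self.editing, os.path.join(outdir, paths["editing"]))
        write_fasta(
            dict(sorted(self.mirnas.items())), os.path.join(outdir, paths["mirnas"])
        )
        self.truth.to_json(os.path.join(outdir, paths["truth"]))
        return self.truth


def _write_gtf(genes: List[GeneModel], path: str) -> None:
    def attrs(pairs: List[Tuple[str, str]]) -> str:
        return " ".join(f'{k} "{v}";' for k, v in pairs if v != "")

    lines = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        span = g.span
        lines.append(
            (g.chrom, span.start, "gene", span.start + 1, span.end, span.strand,
             attrs([("gene_id", g.gene_id), ("gene_name", g.name),
                    ("gene_description", g.description)]))
        )
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            base = [
                ("gene_id", g.gene_id),
                ("transcript_id", t.transcript_id),
                ("gene_name", g.name),
                ("gene_description", g.description),
                ("transcript_biotype", t.biotype),
            ]
            if t.novel:
                base.append(("novel", "1"))
            tspan = t.span
            lines.append(
                (t.chrom, tspan.start, "transcript", tspan.start + 1, tspan.end,
                 t.strand, attrs(base))
            )
            for e in t.exons:
                lines.append(
                    (t.chrom, e.start, "exon", e.start + 1, e.end, t.strand, attrs(base))
                )
            for c in t.cds or []:
                lines.append(
                    (t.chrom, c.start, "CDS", c.start + 1, c.end, t.strand, attrs(base))
                )
    with open(path, "w") as fh:
        for chrom, _, ftype, start, end, strand, attr in lines:
            fh.write(
                f"{chrom}\tlncduplex_synth\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr}\n"
            )


def verify_recovery(records, truth: TruthRecord) -> Dict[str, object]:
    """Compare annotated interaction records against a TruthRecord.

    Returns recovery (planted interactions found, with footprint covering the
    planted segment core), false positives (observed (lncRNA, target) pairs
    never planted) and mechanism mismatches (recovered interactions whose
    mechanism set differs from the planted one).
    """
    observed: Dict[Tuple[str, str], object] = {}
    for rec in records:
        observed.setdefault((rec.lnc_id, rec.target_id), rec)
    expected_pairs = {
        (e["lnc_id"], e["target_id"]): e for e in truth.expected_interactions
    }

    recovered = 0
    mismatches: List[str] = []
    for key, exp in expected_pairs.items():
        rec = observed.get(key)
        if rec is None:
            mismatches.append(f"missing {key}")
            continue
        blocks = merge_intervals(rec.duplex.genome_blocks)
        core = GenomicInterval(exp["chrom"], exp["start"] + 5, exp["end"] - 5)
        covered = any(b.contains(core) for b in blocks)
        mech_ok = sorted(m.value for m in rec.mechanisms) == exp["mechanisms"]
        region_ok = rec.region == exp["region"]
        if covered and mech_ok and region_ok:
            recovered += 1
        else:
            mismatches.append(
                f"{key}: covered={covered} mechanisms={sorted(m.value for m in rec.mechanisms)}"
                f" vs {exp['mechanisms']} region={rec.region} vs {exp['region']}"
            )
    false_positives = sorted(set(observed) - set(expected_pairs))
    return {
        "n_expected": len(expected_pairs),
        "n_recovered": recovered,
        "recovery_pct": 100.0 * recovered / len(expected_pairs)
        if expected_pairs
        else 100.0,
        "false_positives": false_positives,
        "n_false_positives": len(false_positives),
        "mismatches": mismatches,
    }


def generate_dataset(
    outdir: str,
    config: Optional[GeneratorConfig] = None,
    seed: int = 1,
    validate: str = "planted",
) -> TruthRecord:
    """Emit the synthetic dataset into ``outdir`` and return its TruthRecord.

    ``validate`` is "none", "planted" (re-align every planted duplex and check
    decoy geometry; the default) or "full" (additionally verify that no
    lncRNA shows threshold-level complementarity to a non-partner target).
    """
    cfg = config or GeneratorConfig()
    b = _Builder(cfg, seed)

    mech_plan = {
        "MIRNA_MASKING": ["MIRNA_MASKING"],
        "EDITING": ["EDITING"],
        "SMD": ["SMD"],
    }
    for mech, labels in mech_plan.items():
        for i in range(cfg.duplexes_per_mechanism):
            b.add_utr_target_gene(f"{mech}_{i + 1}", labels, case_only=(i == 0))
    for i in range(cfg.duplexes_per_mechanism):
        b.add_splicing_target_gene(f"SPLICING_{i + 1}", case_only=(i == 0))
    for i in range(cfg.combo_duplexes):
        b.add_utr_target_gene(f"COMBO_{i + 1}", ["EDITING", "SMD"], case_only=False)

    for i in range(cfg.idle_lncrnas):
        b.add_lnc_gene(f"LNC_IDLE_{i + 1}", strand="-" if i % 2 else "+")
    for mode in FAILURE_MODES:
        for i in range(cfg.decoys_per_failure_mode):
            b.add_decoy_lnc(mode, i + 1)
    b.add_overlap_fixture()
    b.add_de_boundary_decoys()
    b.add_decoy_tracks()

    if validate in ("planted", "full"):
        b.validate_planted(cross=(validate == "full"))
    elif validate != "none":
        raise ValueError(f"unknown validate level {validate!r}")
    return b.emit(outdir)
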