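"""Classify transcripts as lncRNAs.

A transcript qualifies as a lncRNA candidate when it (i) reaches at least
1 TPM in at least one library, (ii) is at least 200 nt long, (iii) encodes no
peptide of 100 amino acids or more in any forward reading frame and (iv) does
not carry a protein-coding or short-non-coding biotype. Novel (assembled)
transcripts must additionally be multi-exonic and at least 200 nt; the peptide
rule stands in for an external coding/non-coding predictor, and a
per-transcript coding-verdict table can override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set

from .genomic_model import (
    ExpressionMatrix,
    GeneModel,
    ScoringParams,
    TranscriptModel,
    spliced_sequence,
)

# Ensembl biotype groups "Protein coding" and "Short non-coding"; configurable.
DEFAULT_EXCLUDED_BIOTYPES: Set[str] = {
    # protein coding group
    "protein_coding",
    "IG_C_gene",
    "IG_D_gene",
    "IG_J_gene",
    "IG_V_gene",
    "TR_C_gene",
    "TR_D_gene",
    "TR_J_gene",
    "TR_V_gene",
    "polymorphic_pseudogene",
    "nonsense_mediated_decay",
    "non_stop_decay",
    # short non-coding group
    "miRNA",
    "snRNA",
    "snoRNA",
    "rRNA",
    "tRNA",
    "Mt_rRNA",
    "Mt_tRNA",
    "misc_RNA",
    "scaRNA",
    "sRNA",
    "vaultRNA",
    "ribozyme",
}

_STOPS = {"TAA", "TAG", "TGA"}


class ClassificationError(ValueError):
    pass


@dataclass
class LncDecision:
    transcript_id: str
    gene_id: str
    is_lncrna: bool
    failed_criteria: Set[str] = field(default_factory=set)
    longest_peptide_aa: int = 0
    max_tpm: float = 0.0

    def __post_init__(self) -> None:
        assert self.is_lncrna == (not self.failed_criteria)


def longest_peptide_length(seq: str) -> int:
    """Longest ORF (ATG..stop) over the three forward frames, in amino acids.

    The stop codon is required and not counted; codons containing N neither
    start nor stop an ORF (they extend one as an unknown residue). Returns 0
    when no complete ORF exists.
    """
    seq = seq.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        open_start: Optional[int] = None  # codon index of earliest ATG since last stop
        ci = 0
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                ci += 1
                continue
            if codon in _STOPS:
                if open_start is not None:
                    best = max(best, ci - open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = ci
            ci += 1
    return best


def classify_lncrna(
    t: TranscriptModel,
    seq: str,
    tpm: Mapping[str, float],
    params: ScoringParams = ScoringParams(),
    excluded_biotypes: Optional[Set[str]] = None,
    coding_verdict: Optional[Mapping[str, bool]] = None,
) -> LncDecision:
    """Apply the four lncRNA criteria (plus novel-transcript structure rules).

    ``tpm`` maps sample id -> TPM for this transcript. ``coding_verdict``
    optionally supplies an external per-transcript coding call for novel
    transcripts (True = coding), overriding the peptide rule for them.
    """
    if excluded_biotypes is None:
        excluded_biotypes = DEFAULT_EXCLUDED_BIOTYPES
    if tpm is None or len(tpm) == 0:
        raise ClassificationError(f"no expression values for {t.transcript_id}")

    failed: Set[str] = set()
    max_tpm = max(tpm.values())
    peptide = longest_peptide_length(seq)

    if max_tpm < params.min_tpm:
        failed.add("expression")
    if len(seq) < params.min_lnc_length:
        failed.add("length")
    if peptide >= params.max_peptide_aa:
        failed.add("peptide")
    if t.biotype and t.biotype in excluded_biotypes:
        failed.add("biotype")
    if t.novel:
        noncoding = (
            not coding_verdict[t.transcript_id]
            if coding_verdict and t.transcript_id in coding_verdict
            else peptide < params.max_peptide_aa
        )
        if len(t.exons) < 2 or len(seq) < 200 or not noncoding:
            failed.add("novel_structure")

    return LncDecision(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        is_lncrna=not failed,
        failed_criteria=failed,
        longest_peptide_aa=peptide,
        max_tpm=max_tpm,
    )


def build_lnc_catalog(
    genes: List[GeneModel],
    genome: Mapping[str, str],
    expr: ExpressionMatrix,
    params: ScoringParams = ScoringParams(),
    excluded_biotypes: Optional[Set[str]] = None,
    coding_verdict: Optional[Mapping[str, bool]] = None,
) -> List[LncDecision]:
    """One decision per transcript, ordered by transcript_id."""
    decisions = []
    for gene in genes:
        for t in gene.transcripts:
            if not expr.has_feature(t.transcript_id):
                raise ClassificationError(
                    f"no expression row for transcript {t.transcript_id!r}"
                )
            row = expr.tpm.loc[t.transcript_id]
            decisions.append(
                classify_lncrna(
                    t,
                    spliced_sequence(t, genome),
                    dict(row),
                    params,
                    excluded_biotypes,
                    coding_verdict,
                )
            )
    return sorted(decisions, key=lambda d: d.transcript_id)


def write_catalog(decisions: List[LncDecision], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tis_lncrna\tfailed_criteria\t"
            "longest_peptide_aa\tmax_tpm\n"
        )
        for d in decisions:
            fh.write(
                f"{d.transcript_id}\t{d.gene_id}\t{str(d.is_lncrna).lower()}\t"
                f"{','.join(sorted(d.failed_criteria))}\t"
                f"{d.longest_peptide_aa}\t{d.max_tpm:g}\n"
            )
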