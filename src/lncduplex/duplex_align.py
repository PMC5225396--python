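"""lncRNA:RNA duplex discovery by local complementarity alignment.

A duplex is an antiparallel pairing between a lncRNA (5'->3') and a target
transcript, so the lncRNA is aligned against the *reversed* (not
reverse-complemented) target with a complementarity substitution matrix:
G:C pairs score +4, A:T +2, G:T (wobble) +1, anything else (including any
column containing N) -6. A gap of length k costs 20 + 8k, i.e. the first
gapped base pays both the opening and the extension penalty, as in LAST.
Alignment is exact Smith-Waterman; multiple sub-optimal duplexes per pair are
enumerated Waterman-Eggert style: the lncRNA and target positions consumed by
each reported alignment are masked and the matrix is re-run until no alignment
reaches the score threshold (default 500), so reported duplexes for one pair
never overlap on either sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
from numba import njit

from .genomic_model import GenomicInterval, ScoringParams

_BASES = "ACGTN"
_ENCODE = {c: i for i, c in enumerate(_BASES)}
_NEG = np.int32(-(10**9))

# pairing-string symbols
WATSON_CRICK = "|"
WOBBLE = ":"
MISMATCH = "."
GAP = "-"


def pair_score(a: str, b: str, params: ScoringParams = ScoringParams()) -> int:
    """Complementarity score of one antiparallel column (symmetric)."""
    if a not in _ENCODE or b not in _ENCODE:
        raise ValueError(f"non-nucleotide symbol in pair ({a!r}, {b!r})")
    pair = frozenset((a, b))
    if pair == frozenset("GC"):
        return params.match_gc
    if pair == frozenset("AT"):
        return params.match_at
    if pair == frozenset("GT"):
        return params.match_gu
    return params.mismatch


def substitution_matrix(params: ScoringParams) -> np.ndarray:
    sub = np.full((5, 5), params.mismatch, dtype=np.int32)
    for x, y, s in (
        ("G", "C", params.match_gc),
        ("A", "T", params.match_at),
        ("G", "T", params.match_gu),
    ):
        sub[_ENCODE[x], _ENCODE[y]] = s
        sub[_ENCODE[y], _ENCODE[x]] = s
    return sub


def encode(seq: str) -> np.ndarray:
    arr = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        code = _ENCODE.get(c)
        if code is None:
            raise ValueError(f"non-nucleotide symbol {c!r} at position {i}")
        arr[i] = code
    return arr


def normalize_rna(seq: str) -> str:
    """Uppercase and map U->T (all internal sequences use the DNA alphabet)."""
    return seq.upper().replace("U", "T")


@njit(cache=True)
def _sw_fill(a, b, sub, gap_first, gap_ext, mask):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in lncRNA (consumes b)
    F = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in target (consumes a)
    best = np.int32(0)
    bi = -1
    bj = -1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_first
            t = E[i, j - 1] - gap_ext
            if t > e:
                e = t
            f = H[i - 1, j] - gap_first
            t = F[i - 1, j] - gap_ext
            if t > f:
                f = t
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            v = h
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = 0
            if mask[i - 1, j - 1]:
                v = np.int32(0)
                e = _NEG
                f = _NEG
            H[i, j] = v
            E[i, j] = e
            F[i, j] = f
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj, H, E, F


@njit(cache=True)
def _sw_traceback(a, b, sub, gap_first, gap_ext, H, E, F, bi, bj):  # pragma: no cover
    # ops: 0 = paired column, 1 = gap in target (consumes lncRNA base),
    # 2 = gap in lncRNA (consumes target base); returned in reverse order.
    max_len = bi + bj
    ops = np.empty(max_len, np.int8)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=F, 2=E
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            # tie-break: diagonal > gap-in-target > gap-in-lncRNA
            if H[i, j] == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            if F[i, j] == H[i - 1, j] - gap_first:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            if E[i, j] == H[i, j - 1] - gap_first:
                state = 0
            j -= 1
    return ops[:k], i, j


@dataclass
class DuplexAlignment:
    """One scored lncRNA:target duplex.

    ``lnc_span``/``target_span`` are half-open transcript-space intervals;
    the target span is reported in target 5'->3' orientation. ``lnc_aln`` runs
    lncRNA 5'->3'; ``target_aln`` is the paired target fragment as aligned,
    i.e. target 3'->5' (antiparallel). ``pairing`` holds one symbol per
    alignment column: '|' Watson-Crick, ':' wobble, '.' mismatch, '-' gap.
    """

    lnc_id: str
    target_id: str
    score: int
    lnc_span: Tuple[int, int]
    target_span: Tuple[int, int]
    pairing: str
    lnc_aln: str
    target_aln: str
    target_space: str = "spliced"
    genome_blocks: List[GenomicInterval] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.pairing)


def recompute_score(aln: DuplexAlignment, params: ScoringParams = ScoringParams()) -> int:
    """Re-derive the alignment score from the pairing columns and gap runs."""
    total = 0
    gap_run = 0
    for la, ta in zip(aln.lnc_aln, aln.target_aln):
        if la == GAP or ta == GAP:
            gap_run += 1
            continue
        if gap_run:
            total -= abs(params.gap_open) + gap_run * abs(params.gap_extend)
            gap_run = 0
        total += pair_score(la, ta, params)
    if gap_run:
        total -= abs(params.gap_open) + gap_run * abs(params.gap_extend)
    return total


def _column_symbol(la: str, ta: str, sub_val: int, params: ScoringParams) -> str:
    if sub_val == params.match_gu:
        return WOBBLE
    if sub_val in (params.match_gc, params.match_at):
        return WATSON_CRICK
    return MISMATCH


def align_duplex(
    lnc_seq: str,
    target_seq: str,
    params: ScoringParams = ScoringParams(),
    max_alignments: int = 64,
) -> List[DuplexAlignment]:
    """All maximal local duplexes with score >= params.min_score.

    The lncRNA is aligned against the reversed target; reported target
    coordinates are converted back to target 5'->3'. Output is ordered by
    (score desc, lnc start, target start) and is deterministic.
    """
    lnc_seq = normalize_rna(lnc_seq)
    target_seq = normalize_rna(target_seq)
    if not lnc_seq or not target_seq:
        return []
    a = encode(lnc_seq)
    b_rev = encode(target_seq)[::-1].copy()
    sub = substitution_matrix(params)
    gap_first = np.int32(abs(params.gap_open) + abs(params.gap_extend))
    gap_ext = np.int32(abs(params.gap_extend))
    mask = np.zeros((len(a), len(b_rev)), dtype=np.bool_)
    m = len(target_seq)

    out: List[DuplexAlignment] = []
    for _ in range(max_alignments):
        best, bi, bj, H, E, F = _sw_fill(a, b_rev, sub, gap_first, gap_ext, mask)
        if best < params.min_score or bi < 0:
            break
        ops_rev, si, sj = _sw_traceback(
            a, b_rev, sub, gap_first, gap_ext, H, E, F, bi, bj
        )
        ops = ops_rev[::-1]
        lnc_chars: List[str] = []
        tgt_chars: List[str] = []
        pairing_chars: List[str] = []
        i, j = si, sj
        for op in ops:
            if op == 0:
                la = lnc_seq[i]
                ta = _BASES[b_rev[j]]
                sval = int(sub[a[i], b_rev[j]])
                lnc_chars.append(la)
                tgt_chars.append(ta)
                pairing_chars.append(_column_symbol(la, ta, sval, params))
                i += 1
                j += 1
            elif op == 1:  # gap in target: lncRNA base unpaired
                lnc_chars.append(lnc_seq[i])
                tgt_chars.append(GAP)
                pairing_chars.append(GAP)
                i += 1
            else:  # gap in lncRNA: target base unpaired
                lnc_chars.append(GAP)
                tgt_chars.append(_BASES[b_rev[j]])
                pairing_chars.append(GAP)
                j += 1
        # exclude the consumed positions from later rounds
        mask[si:bi, :] = True
        mask[:, sj:bj] = True
        # spans: [si, bi) on lncRNA; [sj, bj) on reversed target
        target_span = (m - bj, m - sj)
        out.append(
            DuplexAlignment(
                lnc_id="",
                target_id="",
                score=int(best),
                lnc_span=(si, bi),
                target_span=target_span,
                pairing="".join(pairing_chars),
                lnc_aln="".join(lnc_chars),
                target_aln="".join(tgt_chars),
            )
        )
    out.sort(key=lambda d: (-d.score, d.lnc_span[0], d.target_span[0]))
    return out


def best_duplex_score(lnc_seq: str, target_seq: str, params: ScoringParams) -> int:
    """Best local duplex score regardless of threshold (0 if none positive)."""
    lnc_seq = normalize_rna(lnc_seq)
    target_seq = normalize_rna(target_seq)
    if not lnc_seq or not target_seq:
        return 0
    a = encode(lnc_seq)
    b_rev = encode(target_seq)[::-1].copy()
    sub = substitution_matrix(params)
    best, _, _, _, _, _ = _sw_fill(
        a,
        b_rev,
        sub,
        np.int32(abs(params.gap_open) + abs(params.gap_extend)),
        np.int32(abs(params.gap_extend)),
        np.zeros((len(a), len(b_rev)), dtype=np.bool_),
    )
    return int(best)


def enumerate_interactions(
    lncs: Mapping[str, str],
    targets: Mapping[str, Tuple[str, str]],
    params: ScoringParams = ScoringParams(),
    de_targets: Optional[Set[str]] = None,
) -> List[DuplexAlignment]:
    """All-vs-all duplex search: lncRNAs form the database, targets the query.

    ``targets`` maps target id -> (sequence, space) with space in
    {"spliced", "premrna"}. Self-pairs are skipped. When ``de_targets`` is
    given, only targets in that set (the differentially expressed ones) are
    scanned.
    """
    out: List[DuplexAlignment] = []
    for lnc_id in sorted(lncs):
        for target_id in sorted(targets):
            if target_id == lnc_id:
                continue
            if de_targets is not None and target_id not in de_targets:
                continue
            seq, space = targets[target_id]
            for aln in align_duplex(lncs[lnc_id], seq, params):
                aln.lnc_id = lnc_id
                aln.target_id = target_id
                aln.target_space = space
                out.append(aln)
    return out


def write_alignments_tsv(alignments: List[DuplexAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "lnc_id\ttarget_id\tscore\ttarget_space\tlnc_start\tlnc_end\t"
            "target_start\ttarget_end\tpairing\n"
        )
        for d in alignments:
            fh.write(
                f"{d.lnc_id}\t{d.target_id}\t{d.score}\t{d.target_space}\t"
                f"{d.lnc_span[0]}\t{d.lnc_span[1]}\t"
                f"{d.target_span[0]}\t{d.target_span[1]}\t{d.pairing}\n"
            )


def write_alignments_bed12(alignments: List[DuplexAlignment], path: str) -> None:
    """Genomic footprint of each duplex as BED12 (blocks = genome blocks)."""
    with open(path, "w") as fh:
        for d in alignments:
            if not d.genome_blocks:
                continue
            blocks = sorted(d.genome_blocks, key=lambda b: b.start)
            chrom = blocks[0].chrom
            start = blocks[0].start
            end = blocks[-1].end
            sizes = ",".join(str(len(b)) for b in blocks)
            starts = ",".join(str(b.start - start) for b in blocks)
            name = f"{d.lnc_id}|{d.target_id}|{d.target_space}"
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t{d.score}\t.\t{start}\t{end}\t"
                f"0,0,0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )
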