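"""Differential-expression gating, condition-specific filtering and summaries.

Differential-expression tables (one per method, e.g. DESeq2 and edgeR) are
inputs; this module only thresholds them (FDR < 0.01, linear fold change
>= 1.5 or <= 1/1.5) and, in the default intersection mode, requires every
table to agree on the direction. Fold changes are case/control, so FC > 1 is
up in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from .genomic_model import ExpressionMatrix, GeneModel, ScoringParams
from .mechanisms import InteractionRecord, MechanismLabel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeCall:
    gene_id: str
    fold_change: float  # linear scale, case/control
    fdr: float
    method: str = ""

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.gene_id}: fold change must be > 0")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.gene_id}: FDR outside [0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.fold_change >= 1.0 else "down"


def read_de_table(path: str, method: str = "") -> List[DeCall]:
    """TSV with columns gene_id, fold_change (linear), fdr."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fold_change", "fdr"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        DeCall(str(r.gene_id), float(r.fold_change), float(r.fdr), method)
        for r in df.itertuples(index=False)
    ]


def _passes(call: DeCall, params: ScoringParams) -> bool:
    # FDR boundary is strict, fold-change boundary inclusive.
    if call.fdr >= params.fdr_threshold:
        return False
    return (
        call.fold_change >= params.fc_threshold
        or call.fold_change <= 1.0 / params.fc_threshold
    )


def de_gate(
    tables: List[List[DeCall]],
    params: ScoringParams = ScoringParams(),
    mode: str = "intersection",
) -> Dict[str, str]:
    """Gene -> direction map of genes passing the DE thresholds.

    Intersection mode (default) requires a gene to pass every table with a
    concordant direction; genes with discordant directions are dropped with a
    warning. Union mode accepts a gene passing any table (first-passing-table
    direction, tables in the given order).
    """
    if not tables:
        raise ValueError("need at least one DE table")
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")

    per_table: List[Dict[str, str]] = []
    for table in tables:
        passing: Dict[str, str] = {}
        for call in table:
            if _passes(call, params):
                passing[call.gene_id] = call.direction
        per_table.append(passing)

    out: Dict[str, str] = {}
    if mode == "union":
        for passing in per_table:
            for gid, direction in passing.items():
                out.setdefault(gid, direction)
        return out

    common = set(per_table[0])
    for passing in per_table[1:]:
        common &= set(passing)
    for gid in sorted(common):
        directions = {passing[gid] for passing in per_table}
        if len(directions) == 1:
            out[gid] = directions.pop()
        else:
            logger.warning(
                "gene %s passes all DE tables with discordant directions; dropped",
                gid,
            )
    return out


def condition_specific(
    records: List[InteractionRecord],
    expr: ExpressionMatrix,
    params: ScoringParams = ScoringParams(),
) -> List[InteractionRecord]:
    """Keep interactions whose two partners are expressed (max TPM >= min_tpm)
    in case samples and not expressed (max TPM < min_tpm) in controls."""
    out = []
    for rec in records:
        for fid in (rec.lnc_id, rec.target_id):
            if not expr.has_feature(fid):
                raise KeyError(f"no expression row for {fid!r}")
        case_ok = all(
            expr.max_tpm(fid, "case") >= params.min_tpm
            for fid in (rec.lnc_id, rec.target_id)
        )
        control_silent = all(
            expr.max_tpm(fid, "control") < params.min_tpm
            for fid in (rec.lnc_id, rec.target_id)
        )
        if case_ok and control_silent:
            out.append(rec)
    return out


def overlap_concordance(
    de: Mapping[str, str],
    genes: List[GeneModel],
    lnc_gene_ids: Set[str],
) -> Dict[str, object]:
    """Overlap statistics among differentially expressed gene loci.

    Reports (a) how many DE genes overlap another DE gene's genomic span
    (strand-agnostic), (b) the fraction of unordered overlapping DE pairs with
    the same direction of change and (c) how many pairs contain a gene with a
    lncRNA isoform. Fractions are None when undefined.
    """
    de_genes = [g for g in genes if g.gene_id in de]
    pairs: List[Tuple[str, str]] = []
    overlapping: Set[str] = set()
    for i, a in enumerate(de_genes):
        for b in de_genes[i + 1 :]:
            if a.span.overlaps(b.span):
                pairs.append((a.gene_id, b.gene_id))
                overlapping.add(a.gene_id)
                overlapping.add(b.gene_id)
    concordant = sum(1 for a, b in pairs if de[a] == de[b])
    with_lnc = sum(
        1 for a, b in pairs if a in lnc_gene_ids or b in lnc_gene_ids
    )
    n_de = len(de_genes)
    return {
        "n_de_genes": n_de,
        "n_overlapping_genes": len(overlapping),
        "frac_overlapping_genes": (len(overlapping) / n_de) if n_de else None,
        "n_overlapping_pairs": len(pairs),
        "n_concordant_pairs": concordant,
        "frac_concordant_pairs": (concordant / len(pairs)) if pairs else None,
        "n_pairs_with_lnc_isoform": with_lnc,
        "pairs": [
            {
                "gene_a": a,
                "gene_b": b,
                "direction_a": de[a],
                "direction_b": de[b],
                "concordant": de[a] == de[b],
                "has_lnc_isoform": a in lnc_gene_ids or b in lnc_gene_ids,
            }
            for a, b in pairs
        ],
    }


def mechanism_summary(records: List[InteractionRecord]) -> Dict[str, object]:
    """Counting conventions of the interaction catalogue.

    Per-mechanism counts are unique lncRNAs (a lncRNA pairing with several
    splice isoforms counts once). The multi-mechanism breakdown is per target
    transcript: mechanisms are unioned over all records of a target, and the
    combination shares are computed among targets with more than one
    mechanism.
    """
    per_mech_lnc: Dict[str, Set[str]] = {m.value: set() for m in MechanismLabel}
    lncs: Set[str] = set()
    targets: Set[str] = set()
    target_genes: Set[str] = set()
    region_counts: Dict[str, int] = {}
    target_mechs: Dict[str, Set[str]] = {}

    for rec in records:
        lncs.add(rec.lnc_id)
        targets.add(rec.target_id)
        if rec.gene_id:
            target_genes.add(rec.gene_id)
        region_counts[rec.region] = region_counts.get(rec.region, 0) + 1
        tm = target_mechs.setdefault(rec.target_id, set())
        for m in rec.mechanisms:
            per_mech_lnc[m.value].add(rec.lnc_id)
            tm.add(m.value)

    n = len(records)
    with_mech = {t: ms for t, ms in target_mechs.items() if ms}
    multi = {t: ms for t, ms in with_mech.items() if len(ms) > 1}
    combo_counts: Dict[str, int] = {}
    for ms in multi.values():
        combo = "+".join(sorted(ms))
        combo_counts[combo] = combo_counts.get(combo, 0) + 1

    return {
        "n_interactions": n,
        "n_unique_lncrnas": len(lncs),
        "n_unique_targets": len(targets),
        "n_unique_target_genes": len(target_genes),
        "lncrnas_per_mechanism": {
            m: len(ids) for m, ids in sorted(per_mech_lnc.items())
        },
        "region_counts": dict(sorted(region_counts.items())),
        "region_fractions": {
            r: c / n for r, c in sorted(region_counts.items())
        }
        if n
        else {},
        "n_targets_with_mechanism": len(with_mech),
        "n_targets_multi_mechanism": len(multi),
        "frac_targets_multi_mechanism": (
            len(multi) / len(with_mech) if with_mech else None
        ),
        "combination_shares": {
            combo: c / len(multi) for combo, c in sorted(combo_counts.items())
        }
        if multi
        else {},
    }
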