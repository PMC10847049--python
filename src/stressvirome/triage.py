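"""Multi-evidence viral contig triage.

A contig is called putatively viral when ANY of five independent evidence
routes fires:

1. nucleotide: >= 85% of the contig length covered by the union of
   nucleotide hits with >= 50% identity (hits pre-filtered to e <= 1e-10);
2. protein: >= 2 distinct ORFs hit by any protein/HMM comparison, and the
   hit ORFs make up >= 50% of the contig's ORF count;
3. virsorter2 positive;
4. deepvirfinder positive;
5. circular contig (VRCA).

A contig with any rRNA hit is vetoed regardless of routes.  Proviruses are
then trimmed to their predicted viral region and the >= 3 kb length filter is
re-applied on the trimmed (effective) length.  A separate, stricter quality
gate (completeness >= 50%, >= 1 viral gene, viral genes >= 10% of genes)
controls inclusion in quantitative analysis.

Threshold comparisons on integer-valued quantities (coverage, ORF and gene
fractions) use exact integer arithmetic so boundary cases are decided
without float artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence

from .intervals import merged_length
from .model import (
    Contig,
    NucHit,
    OrfCall,
    ProteinHit,
    QualityRecord,
    RrnaHit,
    ToolCall,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_LENGTH_BP = 3000
NUC_MIN_IDENTITY = 50.0
NUC_MIN_COVER = 0.85
PROTEIN_MIN_ORFS_HIT = 2
PROTEIN_MIN_FRACTION = 0.5
QUANT_MIN_COMPLETENESS = 50.0
QUANT_MIN_VIRAL_GENES = 1
QUANT_MIN_VIRAL_FRACTION = 0.10


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    nucleotide_route: bool
    protein_route: bool
    virsorter2_route: bool
    deepvirfinder_route: bool
    circular_route: bool
    rrna_excluded: bool
    viral: bool
    effective_length: int
    quant_included: bool = False


def filter_by_length(contigs: Sequence[Contig], min_length: int = MIN_LENGTH_BP) -> List[Contig]:
    """Retain only contigs of at least ``min_length`` bp (inclusive)."""
    kept = [c for c in contigs if c.length >= min_length]
    logger.info("length filter: kept %d of %d contigs", len(kept), len(contigs))
    return kept


def merged_coverage_fraction(
    hits: Iterable[NucHit], contig_length: int, min_identity: float
) -> float:
    """Fraction of the contig covered by the union of qualifying hit intervals."""
    if contig_length < 1:
        raise ValidationError("contig_length must be >= 1")
    ivs = []
    for h in hits:
        if h.q_end > contig_length:
            raise ValidationError(
                f"hit interval {h.q_start}..{h.q_end} exceeds contig length "
                f"{contig_length}"
            )
        if h.pct_identity >= min_identity:
            ivs.append((h.q_start, h.q_end))
    if not ivs:
        return 0.0
    return merged_length(ivs) / contig_length


def nucleotide_rule(contig: Contig, hits: Iterable[NucHit]) -> bool:
    """>= 85% of the contig length covered at >= 50% identity.

    The boundary is decided on integers: covered_bases * 100 >= 85 * length.
    """
    ivs = [
        (h.q_start, h.q_end)
        for h in hits
        if h.pct_identity >= NUC_MIN_IDENTITY
    ]
    for s, e in ivs:
        if e > contig.length:
            raise ValidationError(
                f"{contig.id}: hit interval {s}..{e} exceeds length {contig.length}"
            )
    covered = merged_length(ivs)
    return covered * 100 >= 85 * contig.length


def protein_rule(orfs: Sequence[OrfCall], hits: Iterable[ProteinHit]) -> bool:
    """>= 2 distinct ORFs hit, making up >= 50% of the contig's ORF count."""
    orf_ids = {o.orf_id for o in orfs}
    hit_orfs = {h.orf_id for h in hits}
    unknown = hit_orfs - orf_ids
    if unknown:
        raise ValidationError(f"protein hits on unknown ORFs: {sorted(unknown)}")
    if not orf_ids:
        if hit_orfs:
            raise ValidationError("protein hits present but contig has no ORFs")
        return False
    h = len(hit_orfs)
    return h >= PROTEIN_MIN_ORFS_HIT and 2 * h >= len(orf_ids)


def triage_contigs(
    contigs: Sequence[Contig],
    nuc_hits: Iterable[NucHit] = (),
    orfs: Iterable[OrfCall] = (),
    protein_hits: Iterable[ProteinHit] = (),
    tool_calls: Iterable[ToolCall] = (),
    rrna_hits: Iterable[RrnaHit] = (),
    min_length: int = MIN_LENGTH_BP,
) -> List[TriageDecision]:
    """Evaluate every evidence route for every contig.

    Route flags are set independently; ``viral`` is their OR, vetoed by any
    rRNA hit and by an (untrimmed) length below ``min_length``.
    """
    by_id = {c.id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise ValidationError("duplicate contig ids")

    hits_by_contig: Dict[str, List[NucHit]] = {}
    for h in nuc_hits:
        hits_by_contig.setdefault(h.query_id, []).append(h)
    orfs_by_contig: Dict[str, List[OrfCall]] = {}
    orf_owner: Dict[str, str] = {}
    for o in orfs:
        orfs_by_contig.setdefault(o.contig_id, []).append(o)
        orf_owner[o.orf_id] = o.contig_id
    prot_by_contig: Dict[str, List[ProteinHit]] = {}
    for p in protein_hits:
        owner = orf_owner.get(p.orf_id)
        if owner is None:
            raise ValidationError(f"protein hit on unknown ORF {p.orf_id!r}")
        prot_by_contig.setdefault(owner, []).append(p)
    tools_by_contig: Dict[str, Dict[str, bool]] = {}
    for t in tool_calls:
        tools_by_contig.setdefault(t.contig_id, {})[t.tool] = t.positive
    rrna_contigs = {r.contig_id for r in rrna_hits}

    decisions = []
    for c in contigs:
        nuc = nucleotide_rule(c, hits_by_contig.get(c.id, ()))
        prot = protein_rule(
            orfs_by_contig.get(c.id, ()), prot_by_contig.get(c.id, ())
        )
        tools = tools_by_contig.get(c.id, {})
        vs2 = tools.get("virsorter2", False)
        dvf = tools.get("deepvirfinder", False)
        circ = tools.get("vrca_circular", False) or c.circular
        rrna = c.id in rrna_contigs
        viral = (nuc or prot or vs2 or dvf or circ) and not rrna and c.length >= min_length
        decisions.append(
            TriageDecision(
                c.id, nuc, prot, vs2, dvf, circ, rrna, viral, c.length
            )
        )
    logger.info(
        "triage: %d of %d contigs called viral",
        sum(d.viral for d in decisions), len(decisions),
    )
    return decisions


def refine_and_filter(
    decisions: Sequence[TriageDecision],
    quality: Iterable[QualityRecord],
    contigs: Optional[Sequence[Contig]] = None,
    min_length: int = MIN_LENGTH_BP,
) -> List[TriageDecision]:
    """Trim proviruses to their viral region and re-apply the length filter.

    Provirus contigs get effective_length = region_end - region_start + 1;
    a viral call is withdrawn when the effective length drops below
    ``min_length``.  Contigs without a quality record are left untrimmed.
    """
    qual_by_id = {q.contig_id: q for q in quality}
    lengths = {c.id: c.length for c in contigs} if contigs is not None else {}
    out = []
    for d in decisions:
        q = qual_by_id.get(d.contig_id)
        eff = d.effective_length
        if q is not None and q.provirus:
            if d.contig_id in lengths and q.region_end > lengths[d.contig_id]:
                raise ValidationError(
                    f"{d.contig_id}: provirus region end {q.region_end} exceeds "
                    f"contig length {lengths[d.contig_id]}"
                )
            eff = q.region_end - q.region_start + 1
        viral = d.viral and eff >= min_length
        out.append(replace(d, effective_length=eff, viral=viral))
    return out


def quant_inclusion(decision: TriageDecision, quality: Optional[QualityRecord]) -> bool:
    """Quality gate for quantitative analysis of a viral contig.

    Requires completeness >= 50 (unknown fails), >= 1 viral gene, and viral
    genes >= 10% of the total gene count.  gene_count of zero makes the
    fraction undefined and fails with a warning.
    """
    if not decision.viral:
        return False
    if quality is None or quality.completeness is None:
        return False
    if quality.gene_count == 0:
        logger.warning(
            "%s: gene_count is 0, viral-gene fraction undefined", decision.contig_id
        )
        return False
    return (
        quality.completeness >= QUANT_MIN_COMPLETENESS
        and quality.viral_gene_count >= QUANT_MIN_VIRAL_GENES
        and 10 * quality.viral_gene_count >= quality.gene_count
    )


def run_triage(
    contigs: Sequence[Contig],
    nuc_hits: Iterable[NucHit] = (),
    orfs: Iterable[OrfCall] = (),
    protein_hits: Iterable[ProteinHit] = (),
    tool_calls: Iterable[ToolCall] = (),
    rrna_hits: Iterable[RrnaHit] = (),
    quality: Iterable[QualityRecord] = (),
    min_length: int = MIN_LENGTH_BP,
) -> List[TriageDecision]:
    """Full triage: routes, rRNA veto, provirus refinement, quality gate."""
    quality = list(quality)
    decisions = triage_contigs(
        contigs, nuc_hits, orfs, protein_hits, tool_calls, rrna_hits, min_length
    )
    decisions = refine_and_filter(decisions, quality, contigs, min_length)
    qual_by_id = {q.contig_id: q for q in quality}
    return [
        replace(d, quant_included=quant_inclusion(d, qual_by_id.get(d.contig_id)))
        for d in decisions
    ]
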