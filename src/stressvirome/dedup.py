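"""Redundancy removal for the pooled contig set.

Two contigs are redundant when qualifying alignment hits (each individually
at or above the identity threshold) jointly cover at least ``min_cover`` of
the SHORTER contig; the shorter member of every such pair is removed, longest
contigs first, until no qualifying pair remains among the retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .intervals import merged_length
from .model import Contig, NucHit, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RedundancyPair:
    """keep_id stays, drop_id is the shorter (or lexicographically larger) member."""

    keep_id: str
    drop_id: str
    shorter_len: int
    covered_fraction: float


def _ordered(a: Contig, b: Contig) -> Tuple[Contig, Contig]:
    """Return (keep, drop): longer first; equal lengths keep the smaller id."""
    if a.length != b.length:
        return (a, b) if a.length > b.length else (b, a)
    return (a, b) if a.id < b.id else (b, a)


def find_redundancy_pairs(
    contigs: Sequence[Contig],
    hits: Iterable[NucHit],
    min_identity: float = 90.0,
    min_cover: float = 0.9,
) -> List[RedundancyPair]:
    """Detect redundant pairs from all-vs-all nucleotide hits.

    Coverage of a pair is the merged-interval fraction of the shorter contig
    covered by hits (query = the shorter contig) with identity >= min_identity.
    Self-hits are ignored.
    """
    by_id: Dict[str, Contig] = {c.id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise ValidationError("duplicate contig ids")

    # collect qualifying intervals on the shorter member of each unordered pair
    intervals: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in by_id or h.subject_id not in by_id:
            raise ValidationError(
                f"hit references unknown contig: {h.query_id!r} or {h.subject_id!r}"
            )
        if h.pct_identity < min_identity:
            continue
        q, s = by_id[h.query_id], by_id[h.subject_id]
        keep, drop = _ordered(q, s)
        if h.query_id != drop.id:
            # only hits whose query is the shorter member carry usable intervals
            continue
        if h.q_end > drop.length:
            raise ValidationError(
                f"hit interval {h.q_start}..{h.q_end} exceeds contig "
                f"{drop.id} length {drop.length}"
            )
        intervals.setdefault((keep.id, drop.id), []).append((h.q_start, h.q_end))

    pairs = []
    for (keep_id, drop_id), ivs in sorted(intervals.items()):
        shorter_len = by_id[drop_id].length
        frac = merged_length(ivs) / shorter_len
        if frac >= min_cover:
            pairs.append(RedundancyPair(keep_id, drop_id, shorter_len, frac))
    logger.info("find_redundancy_pairs: %d qualifying pairs", len(pairs))
    return pairs


def deduplicate(
    contigs: Sequence[Contig], pairs: Iterable[RedundancyPair]
) -> Tuple[Set[str], List[RedundancyPair]]:
    """Greedy longest-first removal of redundant contigs.

    Contigs are visited in descending length (ties by ascending id); a contig
    is removed iff it is the drop member of a pair whose keep member is still
    retained.  Returns (retained ids, removal log of applied pairs).
    """
    drop_map: Dict[str, List[RedundancyPair]] = {}
    for p in pairs:
        drop_map.setdefault(p.drop_id, []).append(p)

    retained: Set[str] = set()
    removals: List[RedundancyPair] = []
    for c in sorted(contigs, key=lambda c: (-c.length, c.id)):
        applied = next(
            (p for p in drop_map.get(c.id, ()) if p.keep_id in retained), None
        )
        if applied is not None:
            removals.append(applied)
        else:
            retained.add(c.id)
    logger.info(
        "deduplicate: retained %d of %d contigs", len(retained), len(contigs)
    )
    return retained, removals


def deduplicate_contigs(
    contigs: Sequence[Contig],
    hits: Iterable[NucHit],
    min_identity: float = 90.0,
    min_cover: float = 0.9,
) -> Tuple[Set[str], List[RedundancyPair]]:
    """Convenience: detect pairs then deduplicate."""
    pairs = find_redundancy_pairs(contigs, hits, min_identity, min_cover)
    return deduplicate(contigs, pairs)
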