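"""1-based inclusive interval arithmetic used by triage and dedup."""

from __future__ import annotations

from typing import Iterable, List, Tuple


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def merged_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total number of positions covered by the union of intervals."""
    return sum(end - start + 1 for start, end in merge_intervals(intervals))
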