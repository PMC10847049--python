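"""Relative and spike-anchored absolute abundance from read-mapping records.

Spurious mappings are first removed by zeroing counts for any contig covered
at 1x over less than 75% of its length in a sample.  Counts are then length-
normalised, divided by the sample's total mapped reads, and total-sum scaled
so each sample column is a composition summing to 1.  Anchoring those
relative abundances to a spiked feature of known absolute amount (the
lactococcal phage Q33 standard in the source protocol, ~1e6 pfu per sample)
converts them to absolute scale.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import AbundanceMatrix, MappingRecord, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_BREADTH = 0.75
DEFAULT_SPIKE_AMOUNT = 1e6  # 10 ul of 1e8 pfu/ml


def apply_breadth_filter(
    mapping: Sequence[MappingRecord], min_breadth: float = DEFAULT_MIN_BREADTH
) -> List[MappingRecord]:
    """Zero mapped_reads for records with breadth strictly below the threshold.

    Records at or above the threshold pass untouched; the number of zeroed
    records is reported.  Idempotent, and monotone in ``min_breadth``.
    """
    out = []
    zeroed = 0
    for r in mapping:
        if r.breadth < min_breadth and r.mapped_reads > 0:
            out.append(MappingRecord(r.contig_id, r.sample_id, 0, 0.0))
            zeroed += 1
        else:
            out.append(r)
    logger.info("breadth filter: zeroed %d of %d records", zeroed, len(out))
    return out


def mapping_counts(
    mapping: Sequence[MappingRecord],
    feature_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Pivot mapping records to a features x samples integer count matrix."""
    mat = pd.DataFrame(
        0, index=list(feature_ids), columns=list(sample_ids), dtype=np.int64
    )
    for r in mapping:
        if r.contig_id in mat.index and r.sample_id in mat.columns:
            mat.loc[r.contig_id, r.sample_id] = r.mapped_reads
    return mat


def relative_abundance(
    mapping: Sequence[MappingRecord],
    feature_lengths: pd.Series,
    design: pd.DataFrame,
) -> AbundanceMatrix:
    """Length-normalised, library-size-normalised, total-sum-scaled abundances.

    v_ij = (reads_ij / length_i) / total_reads_j, then each sample column is
    rescaled to sum to 1 (the final rescale makes the column a composition;
    the intermediate division only changes the column by a constant).
    All-zero samples stay zero with a warning.
    """
    counts = mapping_counts(mapping, feature_lengths.index, design["sample_id"])
    unknown = [f for f in {r.contig_id for r in mapping} if f not in feature_lengths.index]
    if unknown:
        raise ValidationError(f"mapping records for features without length: {sorted(unknown)[:5]}")
    lengths = feature_lengths.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("feature lengths must be positive")
    dens = counts.to_numpy(dtype=float) / lengths[:, None]
    dens = dens / design["total_mapped_reads"].to_numpy(dtype=float)[None, :]
    colsums = dens.sum(axis=0)
    zero_cols = colsums == 0
    if zero_cols.any():
        logger.warning(
            "all-zero samples in relative_abundance: %s",
            list(np.asarray(counts.columns)[zero_cols]),
        )
    safe = np.where(zero_cols, 1.0, colsums)
    rel = dens / safe[None, :]
    values = pd.DataFrame(rel, index=counts.index, columns=counts.columns)
    return AbundanceMatrix(values, "relative", feature_lengths)


def spike_absolute(
    rel: AbundanceMatrix,
    spike_feature_id: str,
    spike_amount: float = DEFAULT_SPIKE_AMOUNT,
) -> Tuple[AbundanceMatrix, List[str]]:
    """Anchor relative abundances to the spiked feature of known amount.

    abs_ij = (rel_ij / rel_spike,j) * spike_amount.  Samples in which the
    spike has zero relative abundance cannot be anchored: they are returned
    in the flagged list and their absolute values are NaN, never a silent 0.
    """
    if rel.scale != "relative":
        raise ValidationError("spike_absolute needs a relative-scale matrix")
    if spike_feature_id not in rel.values.index:
        raise ValidationError(f"spike feature {spike_feature_id!r} not in matrix")
    spike_row = rel.values.loc[spike_feature_id].to_numpy(dtype=float)
    flagged = [s for s, v in zip(rel.values.columns, spike_row) if v == 0.0]
    if flagged:
        logger.warning("spike absent in samples: %s", flagged)
    safe = np.where(spike_row == 0.0, np.nan, spike_row)
    values = rel.values.to_numpy(dtype=float) / safe[None, :] * spike_amount
    out = pd.DataFrame(values, index=rel.values.index, columns=rel.values.columns)
    return AbundanceMatrix(out, "absolute"), flagged
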