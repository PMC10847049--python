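"""Phage-bacteria association network across omic layers.

Every (phage, bacterium) pair is tested for Pearson correlation of clr
abundances across shared samples; p-values come from the t transform with
n - 2 degrees of freedom and are BH-FDR adjusted over the full pair set.
Edges with q below the cut-off (0.1 by default) are retained, annotated with
the deepest taxonomic rank at which the phage's predicted host matches the
bacterium, and flagged when both endpoints show a restoration effect.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AbundanceMatrix, HostPrediction, ValidationError
from .restoration import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_Q_CUTOFF = 0.1
DEFAULT_RESTORATION_P_CUTOFF = 0.05

RANKS = ("family", "order", "phylum")  # deepest first

EDGE_COLUMNS = [
    "phage_id", "bacterium_id", "pearson_r", "p_value", "q_value",
    "predicted_host_match", "restoration_flagged",
]


def crosslayer_correlations(
    phage_clr: AbundanceMatrix,
    bact_clr: AbundanceMatrix,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> pd.DataFrame:
    """All-pairs Pearson correlations with BH-FDR over the full pair set.

    Zero-variance features are skipped with a warning (their pairs are not
    tested and do not enter the BH family).
    """
    if list(phage_clr.sample_ids) != list(bact_clr.sample_ids):
        raise ValidationError("phage and bacterial matrices must share samples, in order")
    n = len(phage_clr.sample_ids)
    if n < 3:
        raise ValidationError("need at least 3 shared samples")

    P = phage_clr.values.to_numpy(dtype=float)
    B = bact_clr.values.to_numpy(dtype=float)
    p_sd = P.std(axis=1, ddof=1)
    b_sd = B.std(axis=1, ddof=1)
    p_keep = np.flatnonzero(p_sd > 0)
    b_keep = np.flatnonzero(b_sd > 0)
    skipped = (len(p_sd) - len(p_keep)) + (len(b_sd) - len(b_keep))
    if skipped:
        logger.warning("skipping %d zero-variance features", skipped)

    Pz = (P[p_keep] - P[p_keep].mean(axis=1, keepdims=True)) / p_sd[p_keep][:, None]
    Bz = (B[b_keep] - B[b_keep].mean(axis=1, keepdims=True)) / b_sd[b_keep][:, None]
    R = (Pz @ Bz.T) / (n - 1)
    R = np.clip(R, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1 - R ** 2, 1e-300))
    pvals = 2 * stats.t.sf(np.abs(t), n - 2)
    q = bh_fdr(pvals.ravel()).reshape(pvals.shape)

    phage_ids = np.asarray(phage_clr.feature_ids)[p_keep]
    bact_ids = np.asarray(bact_clr.feature_ids)[b_keep]
    ii, jj = np.nonzero(q < q_cutoff)
    edges = pd.DataFrame(
        {
            "phage_id": phage_ids[ii],
            "bacterium_id": bact_ids[jj],
            "pearson_r": R[ii, jj],
            "p_value": pvals[ii, jj],
            "q_value": q[ii, jj],
            "predicted_host_match": "unknown",
            "restoration_flagged": False,
        }
    )
    logger.info(
        "crosslayer_correlations: %d of %d pairs retained at q < %g",
        len(edges), pvals.size, q_cutoff,
    )
    return edges


def annotate_host_concordance(
    edges: pd.DataFrame,
    predictions: Iterable[HostPrediction],
    taxonomy: pd.DataFrame,
    synonyms: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Set predicted_host_match to the deepest rank at which the phage's
    predicted host taxon equals the bacterium's taxon.

    ``taxonomy`` carries one row per bacterial feature with columns
    feature_id, phylum, order, family.  Matching is by case-folded string
    equality, after applying the optional synonym map (for renamed taxa such
    as Firmicutes/Bacillota).
    """
    synonyms = {k.casefold(): v.casefold() for k, v in (synonyms or {}).items()}

    def canon(name) -> Optional[str]:
        if name is None or (isinstance(name, float) and np.isnan(name)):
            return None
        s = str(name).casefold()
        return synonyms.get(s, s)

    pred_by_phage = {p.contig_id: p for p in predictions}
    tax = taxonomy.set_index("feature_id")
    match = []
    for row in edges.itertuples(index=False):
        pred = pred_by_phage.get(row.phage_id)
        if pred is None:
            match.append("unknown")
            continue
        level = "none"
        for rank in RANKS:
            host_taxon = canon(getattr(pred, f"host_{rank}"))
            bact_taxon = (
                canon(tax.loc[row.bacterium_id, rank])
                if row.bacterium_id in tax.index and rank in tax.columns
                else None
            )
            if host_taxon is not None and bact_taxon is not None and host_taxon == bact_taxon:
                level = rank
                break
        match.append(level)
    out = edges.copy()
    out["predicted_host_match"] = match
    return out


def flag_restored_edges(
    edges: pd.DataFrame,
    phage_restoration: pd.DataFrame,
    bact_restoration: pd.DataFrame,
    p_cutoff: float = DEFAULT_RESTORATION_P_CUTOFF,
) -> pd.DataFrame:
    """Flag edges whose BOTH endpoints have restoration p strictly below cut-off."""
    def p_of(table: pd.DataFrame, feature: str) -> float:
        if feature not in table.index:
            raise ValidationError(f"no restoration result for {feature!r}")
        return float(table.loc[feature, "p_restoration"])

    flags = [
        p_of(phage_restoration, r.phage_id) < p_cutoff
        and p_of(bact_restoration, r.bacterium_id) < p_cutoff
        for r in edges.itertuples(index=False)
    ]
    out = edges.copy()
    out["restoration_flagged"] = flags
    return out
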