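"""Compositional preprocessing and community-level statistics.

Counts are feature-filtered (minimum total count for bacterial taxa,
minimum prevalence for phage contigs), zeros are replaced by a constant
fraction of the smallest observed positive value ('const' replacement),
and the matrix is centred-log-ratio transformed.  Beta diversity is the
Aitchison distance (Euclidean distance between clr vectors) assessed by
PERMANOVA; alpha diversity is reported as Hill numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .model import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL_COUNT = 5
DEFAULT_MIN_PREVALENCE = 0.5
DEFAULT_CONST_FACTOR = 0.65


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------

def min_count_filter(
    counts: AbundanceMatrix, min_total: int = DEFAULT_MIN_TOTAL_COUNT
) -> AbundanceMatrix:
    """Drop features whose total count across samples is below ``min_total``."""
    if counts.scale != "count":
        raise ValidationError("min_count_filter needs the count scale")
    totals = counts.values.sum(axis=1)
    keep = totals[totals >= min_total].index
    logger.info("min_count_filter: kept %d of %d features", len(keep), len(totals))
    return counts.subset_features(keep)


def prevalence_filter(
    matrix: AbundanceMatrix, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> AbundanceMatrix:
    """Drop features nonzero in a fraction of samples below ``min_prevalence``."""
    nonzero = (matrix.values > 0).sum(axis=1)
    n = matrix.values.shape[1]
    # exact boundary: keep when nonzero / n >= min_prevalence
    keep = nonzero[nonzero >= min_prevalence * n].index
    logger.info("prevalence_filter: kept %d of %d features", len(keep), len(nonzero))
    return matrix.subset_features(keep)


def zero_replace_const(
    matrix: AbundanceMatrix, factor: float = DEFAULT_CONST_FACTOR
) -> AbundanceMatrix:
    """'const' zero replacement: zeros become factor x (matrix-wide minimum
    positive value); nonzero entries are untouched."""
    arr = matrix.values.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValidationError("all-zero matrix: nothing to anchor replacement to")
    delta = factor * positive.min()
    out = np.where(arr == 0, delta, arr)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(values, matrix.scale, matrix.feature_lengths)


def clr_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Centred log-ratio transform per sample: clr_ij = ln(x_ij / g_j),
    g_j the geometric mean of sample j.  Requires strictly positive values."""
    arr = matrix.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValidationError("clr needs strictly positive values (replace zeros first)")
    logs = np.log(arr)
    clr = logs - logs.mean(axis=0, keepdims=True)
    values = pd.DataFrame(clr, index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(values, "clr")


def aitchison_distances(clr_matrix: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample clr vectors."""
    if clr_matrix.scale != "clr":
        raise ValidationError("aitchison_distances needs the clr scale")
    samples = clr_matrix.sample_ids
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples")
    d = squareform(pdist(clr_matrix.values.to_numpy(dtype=float).T, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(s) for s in samples])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix and group labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with free permutation of sample labels.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)); R^2 = SS_between /
    SS_total; p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), so p is
    never 0 and never below 1/(n_permutations+1).
    """
    labels = np.asarray(list(groups))
    d = dist.data
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValidationError("group labels must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    k = uniq.size
    if k < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    d2 = d ** 2
    ss_total, ss_within = _permanova_ss(d2, labels)
    if ss_total == 0:
        logger.warning("all samples identical: SS_total = 0, p = 1.0")
        return PermanovaResult(0.0, 0.0, 1.0, n_permutations, seed)
    ss_between = ss_total - ss_within

    def f_stat(ss_w):
        if ss_w == 0:
            return np.inf
        return ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, ss_w = _permanova_ss(d2, perm)
        if f_stat(ss_w) >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(ss_between / ss_total, float(f_obs), p, n_permutations, seed)


# ---------------------------------------------------------------------------
# ordination and alpha diversity
# ---------------------------------------------------------------------------

def pca_on_clr(clr_matrix: AbundanceMatrix) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the feature-centred clr matrix.

    Returns (scores with samples as rows and PCs as columns, explained-
    variance fractions).  The sign of each component is fixed by forcing its
    largest-magnitude loading positive.
    """
    if clr_matrix.scale != "clr":
        raise ValidationError("pca_on_clr needs the clr scale")
    X = clr_matrix.values.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=clr_matrix.sample_ids, columns=cols), frac


def hill_alpha(counts: Sequence[float], q: int) -> float:
    """Hill number of order q for one sample's counts.

    q=0: richness; q=1: exp(Shannon entropy); q=2: inverse Simpson.
    Computed on relative proportions of the positive counts.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise ValidationError("zero total count")
    p = arr[arr > 0] / total
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p ** 2).sum())
    raise ValidationError(f"unsupported Hill order q={q}")


def alpha_diversity_table(counts: AbundanceMatrix, orders=(0, 1, 2)) -> pd.DataFrame:
    """Hill numbers per sample, one column per order."""
    rows = {
        s: [hill_alpha(counts.values[s].to_numpy(), q) for q in orders]
        for s in counts.sample_ids
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"q{q}" for q in orders]
    )
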