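"""Restoration-effect differential abundance / expression statistics.

The headline statistic is a planned orthogonal contrast on the three study
groups, weighing control (Ctr) and virome-treated stressed (FVTStress)
animals against stressed animals (CtrStress):

    L = 0.5 * m_Ctr - m_CtrStress + 0.5 * m_FVTStress

A nonzero L means the stressed group deviates from the average of control
and treated groups — the feature was altered by stress and moved back by
the transplant.  Per-feature contrast p-values are BH-FDR adjusted
(discovery threshold q < 0.2), with Tukey post hoc tests on the
Ctr-CtrStress and CtrStress-FVTStress pairs.  A longitudinal variant
absorbs per-subject baseline differences with a random intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .model import GROUPS, AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)

CONTRAST_WEIGHTS = {"Ctr": 0.5, "CtrStress": -1.0, "FVTStress": 0.5}
TUKEY_PAIRS = (("Ctr", "CtrStress"), ("CtrStress", "FVTStress"))
DEFAULT_Q_CUTOFF = 0.2
DEFAULT_SD_LIMIT = 2.5
DEFAULT_VARIANCE_CUTOFF = 0.5


@dataclass(frozen=True)
class RestorationResult:
    feature_id: str
    contrast_estimate: float
    t_statistic: float
    df: float
    p_restoration: float
    q_value: float
    p_ctr_vs_stress: float
    p_stress_vs_fvt: float
    direction: int


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float


# ---------------------------------------------------------------------------
# pre-filters applied to assay endpoints / expression matrices
# ---------------------------------------------------------------------------

def exclude_outliers(
    values: Sequence[float], sd_limit: float = DEFAULT_SD_LIMIT, max_removed: int = 2
) -> Tuple[List[float], List[float]]:
    """Single-pass 2.5-SD outlier rule for assay endpoints.

    Values more than ``sd_limit`` sample SDs from the group mean are removed,
    at most ``max_removed`` per test (largest deviations first), without
    recomputing mean/SD after removal.  Never applied to count matrices.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValidationError("outlier rule needs at least 3 values")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if sd == 0:
        return list(arr), []
    z = np.abs(arr - mean) / sd
    flag_idx = np.flatnonzero(z > sd_limit)
    flag_idx = flag_idx[np.argsort(-z[flag_idx])][:max_removed]
    keep = np.ones(arr.size, dtype=bool)
    keep[flag_idx] = False
    return list(arr[keep]), list(arr[~keep])


def variance_prefilter(
    matrix: AbundanceMatrix, cutoff: float = DEFAULT_VARIANCE_CUTOFF
) -> AbundanceMatrix:
    """Drop features with across-sample variance below the absolute cutoff."""
    var = matrix.values.var(axis=1, ddof=1)
    keep = var[var >= cutoff].index
    logger.info("variance_prefilter: kept %d of %d features", len(keep), len(var))
    return matrix.subset_features(keep)


# ---------------------------------------------------------------------------
# cross-sectional contrast
# ---------------------------------------------------------------------------

def _group_arrays(
    values: Sequence[float], groups: Sequence[str]
) -> Dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(list(groups))
    out = {g: values[groups == g] for g in GROUPS}
    missing = [g for g, v in out.items() if v.size < 2]
    if missing:
        raise ValidationError(f"groups missing or with <2 samples: {missing}")
    return out


def _pooled(by_group: Dict[str, np.ndarray]) -> Tuple[Dict[str, float], float, int]:
    """Group means, pooled SD and residual df (N - k)."""
    means = {g: float(v.mean()) for g, v in by_group.items()}
    n_total = sum(v.size for v in by_group.values())
    df = n_total - len(by_group)
    ss = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    s_pooled = float(np.sqrt(ss / df))
    return means, s_pooled, df


def restoration_contrast(
    values: Sequence[float],
    groups: Sequence[str],
    feature_id: str = "",
) -> RestorationResult:
    """Planned orthogonal restoration contrast on a one-way fixed-effects model.

    t = L / (s_pooled * sqrt(sum w_g^2 / n_g)) with df = N - 3; two-sided p.
    Zero pooled variance degenerates to p = 0 (L != 0) or 1 (L == 0), with a
    warning.  Tukey pairwise p-values and q_value are filled by the table-
    level drivers; here they default to NaN.
    """
    by_group = _group_arrays(values, groups)
    means, s_pooled, df = _pooled(by_group)
    L = sum(CONTRAST_WEIGHTS[g] * means[g] for g in GROUPS)
    wsum = sum(CONTRAST_WEIGHTS[g] ** 2 / by_group[g].size for g in GROUPS)
    if s_pooled == 0:
        logger.warning("%s: zero pooled variance", feature_id or "<feature>")
        p = 0.0 if L != 0 else 1.0
        t = np.inf * np.sign(L) if L != 0 else 0.0
    else:
        se = s_pooled * np.sqrt(wsum)
        t = L / se
        p = 2 * stats.t.sf(abs(t), df)
    direction = int(np.sign(means["CtrStress"] - means["Ctr"]))
    return RestorationResult(
        feature_id, float(L), float(t), float(df), float(p),
        np.nan, np.nan, np.nan, direction,
    )


def tukey_pairwise(
    values: Sequence[float],
    groups: Sequence[str],
    pairs: Sequence[Tuple[str, str]] = TUKEY_PAIRS,
) -> Dict[Tuple[str, str], float]:
    """Tukey HSD adjusted p-values for the requested group pairs.

    q = |m_i - m_j| / (s_pooled * sqrt(0.5 * (1/n_i + 1/n_j))); adjusted p
    from the studentized-range distribution with k = 3 and df = N - 3.
    """
    by_group = _group_arrays(values, groups)
    means, s_pooled, df = _pooled(by_group)
    k = len(GROUPS)
    out = {}
    for a, b in pairs:
        if s_pooled == 0:
            out[(a, b)] = 1.0 if means[a] == means[b] else 0.0
            continue
        se = s_pooled * np.sqrt(0.5 * (1 / by_group[a].size + 1 / by_group[b].size))
        q = abs(means[a] - means[b]) / se
        out[(a, b)] = float(stats.studentized_range.sf(q, k, df))
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_frame(matrix) -> pd.DataFrame:
    """Accept an AbundanceMatrix or a plain features x samples DataFrame."""
    return matrix.values if isinstance(matrix, AbundanceMatrix) else matrix


def restoration_table(
    matrix, design: pd.DataFrame, tukey: bool = True
) -> pd.DataFrame:
    """Per-feature restoration contrasts with Tukey post hocs and BH-FDR.

    ``matrix`` columns must match the design's sample_ids; rows of the output
    mirror RestorationResult fields.  Vectorised over features.  The
    studentized-range tail evaluation dominates the run time on large
    matrices; pass ``tukey=False`` to skip the post hocs (columns become
    NaN) when only contrast p/q values are needed.
    """
    frame = _as_frame(matrix)
    samples = list(frame.columns)
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    groups = design.loc[samples, "group"].to_numpy()
    X = frame.to_numpy(dtype=float)
    idx = {g: np.flatnonzero(groups == g) for g in GROUPS}
    for g, ii in idx.items():
        if ii.size < 2:
            raise ValidationError(f"group {g} has <2 samples")
    n = {g: ii.size for g, ii in idx.items()}
    N = sum(n.values())
    df = N - 3
    means = {g: X[:, idx[g]].mean(axis=1) for g in GROUPS}
    ss = sum(
        ((X[:, idx[g]] - means[g][:, None]) ** 2).sum(axis=1) for g in GROUPS
    )
    s_pooled = np.sqrt(ss / df)
    L = sum(CONTRAST_WEIGHTS[g] * means[g] for g in GROUPS)
    wsum = sum(CONTRAST_WEIGHTS[g] ** 2 / n[g] for g in GROUPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = L / (s_pooled * np.sqrt(wsum))
    degenerate = s_pooled == 0
    p = np.where(
        degenerate,
        np.where(L != 0, 0.0, 1.0),
        2 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df),
    )
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(L) * np.inf, t)
    t = np.where(degenerate & (L == 0), 0.0, t)
    q = bh_fdr(p)

    tukey_p = {}
    for a, b in TUKEY_PAIRS:
        if not tukey:
            tukey_p[(a, b)] = np.full(X.shape[0], np.nan)
            continue
        se = s_pooled * np.sqrt(0.5 * (1 / n[a] + 1 / n[b]))
        with np.errstate(divide="ignore", invalid="ignore"):
            qstat = np.abs(means[a] - means[b]) / se
        padj = np.where(
            degenerate,
            np.where(means[a] == means[b], 1.0, 0.0),
            stats.studentized_range.sf(np.where(degenerate, 0.0, qstat), 3, df),
        )
        tukey_p[(a, b)] = padj

    return pd.DataFrame(
        {
            "feature_id": list(frame.index),
            "contrast_estimate": L,
            "t_statistic": t,
            "df": float(df),
            "p_restoration": p,
            "q_value": q,
            "p_ctr_vs_stress": tukey_p[("Ctr", "CtrStress")],
            "p_stress_vs_fvt": tukey_p[("CtrStress", "FVTStress")],
            "direction": np.sign(means["CtrStress"] - means["Ctr"]).astype(int),
        }
    ).set_index("feature_id", drop=False)


def restoration_power(
    effect: float, n_per_group: Sequence[int], alpha: float = 0.05
) -> float:
    """Closed-form two-sided power of the restoration contrast.

    ``effect`` is the contrast value in pooled-SD units; the noncentrality is
    effect / sqrt(sum w_g^2 / n_g), df = N - 3.
    """
    n = dict(zip(GROUPS, n_per_group))
    df = sum(n.values()) - 3
    ncp = effect / np.sqrt(sum(CONTRAST_WEIGHTS[g] ** 2 / n[g] for g in GROUPS))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


# ---------------------------------------------------------------------------
# longitudinal variant: random intercept per subject
# ---------------------------------------------------------------------------

def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, subject_idx: np.ndarray, n_subjects: int
) -> Tuple[np.ndarray, float, float, np.ndarray]:
    """Profiled REML for y = X b + Z u + e with Z the subject indicator.

    Returns (beta_hat, sigma2_hat, tau2_hat, blup u_hat).  The covariance
    V = I + rho Z Z' is inverted per subject block via Woodbury, leaving a
    1-D REML profile over log-rho.
    """
    N, p = X.shape
    counts = np.bincount(subject_idx, minlength=n_subjects).astype(float)

    def fit(rho: float):
        # V^-1 x = x - (rho/(1+k rho)) * J x per subject block
        shrink = rho / (1.0 + counts * rho)  # per subject

        def vinv(M: np.ndarray) -> np.ndarray:
            sums = np.zeros((n_subjects, M.shape[1]))
            np.add.at(sums, subject_idx, M)
            return M - (shrink[subject_idx, None] * sums[subject_idx])

        XtVX = X.T @ vinv(X)
        XtVy = X.T @ vinv(y[:, None])[:, 0]
        beta = np.linalg.solve(XtVX, XtVy)
        resid = y - X @ beta
        quad = float(resid @ vinv(resid[:, None])[:, 0])
        sigma2 = quad / (N - p)
        logdet_v = float(np.log1p(counts * rho).sum())
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        reml = logdet_v + (N - p) * np.log(max(sigma2, 1e-300)) + logdet_xvx
        return reml, beta, sigma2, XtVX, shrink

    def objective(log_rho: float) -> float:
        return fit(np.exp(log_rho))[0]

    # bracket rho in [~0, 1e4]; include the boundary rho = 0 explicitly
    res = optimize.minimize_scalar(
        objective, bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
        options={"xatol": 1e-8},
    )
    reml_best, beta, sigma2, _, shrink = fit(np.exp(res.x))
    reml_zero, beta0, sigma2_0, _, _ = fit(0.0)
    if reml_zero <= reml_best:
        rho = 0.0
        beta, sigma2 = beta0, sigma2_0
        shrink = np.zeros(n_subjects)
    else:
        rho = float(np.exp(res.x))
    tau2 = rho * sigma2
    # BLUP: u_s = (rho k_s / (1 + rho k_s)) * mean-corrected residual sum / k_s
    resid = y - X @ beta
    sums = np.zeros(n_subjects)
    np.add.at(sums, subject_idx, resid)
    u_hat = shrink * sums
    return beta, sigma2, tau2, u_hat


def longitudinal_restoration(
    matrix, design: pd.DataFrame
) -> pd.DataFrame:
    """Restoration contrasts over a repeated-measures design.

    Per feature, a saturated group x timepoint fixed-effects (cell-means)
    model with a random intercept per subject is fitted by profiled REML,
    yielding the residual and subject variance components (``sigma2``,
    ``tau2``).  Two contrasts are reported:

    * the restoration contrast on baseline-adjusted final-timepoint values.
      Each subject's final value is adjusted by the model-implied shrinkage
      slope b = tau^2 / (tau^2 + sigma^2) times the subject's first-timepoint
      (pre-stress baseline) value, which removes the predictable part of the
      between-subject variation from the contrast estimate and its error
      coherently (covariance-style adjustment with the slope fixed by the
      variance components, not re-estimated per group; the baseline carries
      no group effects, so the contrast estimate is not attenuated).  The
      adjusted values feed the cross-sectional contrast machinery, so when
      the estimated subject variance is zero (b = 0) the result reduces
      exactly to the cross-sectional contrast on the final timepoint.  p/q
      values refer to this contrast.
    * ``trend_estimate``: the same contrast applied to the within-subject
      change from the first to the final timepoint.  Per-subject constant
      offsets cancel exactly in this difference-in-differences estimate
      (random-intercept absorption).
    """
    frame = _as_frame(matrix)
    samples = list(frame.columns)
    design = design.loc[samples]
    groups = design["group"].to_numpy()
    subjects = design["subject_id"].to_numpy()
    times = design["timepoint"].to_numpy()

    subj_group = {}
    for s, g in zip(subjects, groups):
        if subj_group.setdefault(s, g) != g:
            raise ValidationError(f"subject {s!r} appears in two groups")
    time_levels = sorted(set(times))
    if len(time_levels) < 2:
        raise ValidationError("longitudinal model needs >= 2 timepoints")
    final_time = time_levels[-1]

    # saturated cell-means design matrix (group x time)
    cells = sorted({(g, t) for g, t in zip(groups, times)})
    cell_idx = {c: i for i, c in enumerate(cells)}
    X = np.zeros((len(samples), len(cells)))
    for i, (g, t) in enumerate(zip(groups, times)):
        X[i, cell_idx[(g, t)]] = 1.0
    subj_levels = sorted(set(subjects))
    subj_map = {s: i for i, s in enumerate(subj_levels)}
    subject_idx = np.array([subj_map[s] for s in subjects])
    final_mask = times == final_time
    first_mask = times == time_levels[0]

    # subject-wise indices of the final and first (baseline) samples
    final_by_subj = {}
    first_by_subj = {}
    for i, s in enumerate(subjects):
        if final_mask[i]:
            final_by_subj[s] = i
        if first_mask[i]:
            first_by_subj[s] = i
    paired = sorted(set(final_by_subj) & set(first_by_subj))
    adj_subjects = [s for s in subj_levels if s in final_by_subj and s in first_by_subj]

    rows = []
    Y = frame.to_numpy(dtype=float)
    for fi, fid in enumerate(frame.index):
        y = Y[fi]
        _, sigma2, tau2, _ = _reml_random_intercept(
            y, X, subject_idx, len(subj_levels)
        )
        # model-implied baseline-adjustment slope; 0 when tau2-hat is 0
        b = tau2 / (tau2 + sigma2) if (tau2 + sigma2) > 0 else 0.0
        adj = np.array(
            [y[final_by_subj[s]] - b * y[first_by_subj[s]] for s in adj_subjects]
        )
        adj_groups = [subj_group[s] for s in adj_subjects]
        res = restoration_contrast(adj, adj_groups, feature_id=fid)
        deltas = {
            g: [y[final_by_subj[s]] - y[first_by_subj[s]]
                for s in paired if subj_group[s] == g]
            for g in ("Ctr", "CtrStress", "FVTStress")
        }
        trend = sum(
            CONTRAST_WEIGHTS[g] * float(np.mean(v)) for g, v in deltas.items() if v
        )
        rows.append(
            {
                "feature_id": fid,
                "contrast_estimate": res.contrast_estimate,
                "t_statistic": res.t_statistic,
                "df": res.df,
                "p_restoration": res.p_restoration,
                "trend_estimate": trend,
                "sigma2": sigma2,
                "tau2": tau2,
                "direction": res.direction,
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id", drop=False)
    out["q_value"] = bh_fdr(out["p_restoration"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    query: set, term: set, universe_size: int, term_id: str = ""
) -> EnrichmentResult:
    """Upper-tail (inclusive) hypergeometric over-representation test.

    p = P(X >= |query & term|) drawing |query| items from a universe with
    |term| marked items.
    """
    overlap = len(query & term)
    if len(term) > universe_size or len(query) > universe_size:
        raise ValidationError("term/query larger than the universe")
    if overlap > min(len(term), len(query)):
        raise ValidationError("overlap exceeds set sizes")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(term), len(query)))
    return EnrichmentResult(
        term_id, overlap, len(term), len(query), universe_size, min(p, 1.0)
    )
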