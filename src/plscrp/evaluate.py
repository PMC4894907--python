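"""Comparison machinery: sign alignment, similarity coefficients, linear-fit
agreement, variability across projection seeds, and causal-recovery scoring.

Weight profiles from two fits are compared after joint sign alignment
(an SVD sign is arbitrary, but flipping both blocks' weights together
leaves the model unchanged) using Pearson correlation, the cosine
measure, and the extended Jaccard similarity
a·b / (‖a‖² + ‖b‖² − a·b), which unlike cosine also penalizes scale
differences.  A simple OLS of one profile on the other summarizes
agreement as intercept ≈ 0, slope ≈ 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("plscrp")


@dataclass
class SimilarityReport:
    pearson_r: float
    cosine: float
    extended_jaccard: float
    fit_intercept: float | None
    fit_slope: float | None
    fit_p_value: float | None
    n_variables: int
    sign_flipped: bool = False


def align_signs(
    ref_weights: tuple[np.ndarray, np.ndarray],
    target_weights: tuple[np.ndarray, np.ndarray],
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Jointly sign-align target weight pairs to reference pairs.

    Per component, both target blocks' columns are flipped iff the dot
    product of the concatenated target and reference weights is negative
    (a zero dot product leaves the sign unchanged).  Returns the aligned
    pair and the per-component flip flags.
    """
    r1, r2 = ref_weights
    t1, t2 = target_weights
    if r1.shape != t1.shape or r2.shape != t2.shape:
        raise ValueError("weight shapes do not match")
    one_d = t1.ndim == 1
    as2d = lambda w: w[:, None] if w.ndim == 1 else w
    ref_cat = np.vstack([as2d(r1), as2d(r2)])
    tgt_cat = np.vstack([as2d(t1), as2d(t2)])
    flipped = np.einsum("ij,ij->j", tgt_cat, ref_cat) < 0
    sign = np.where(flipped, -1.0, 1.0)
    a1 = as2d(t1) * sign
    a2 = as2d(t2) * sign
    if one_d:
        return (a1[:, 0], a2[:, 0]), flipped
    return (a1, a2), flipped


def weight_similarity(a: np.ndarray, b: np.ndarray) -> SimilarityReport:
    """Pearson, cosine, and extended Jaccard similarity of weight vectors."""
    a = np.ravel(np.asarray(a, dtype=np.float64))
    b = np.ravel(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm weight vector")
    dot = float(a @ b)
    cosine = dot / (na * nb)
    jaccard = dot / (na**2 + nb**2 - dot)
    pearson = float(np.corrcoef(a, b)[0, 1]) if a.size >= 3 else cosine
    return SimilarityReport(
        pearson_r=pearson, cosine=float(cosine), extended_jaccard=float(jaccard),
        fit_intercept=None, fit_slope=None, fit_p_value=None,
        n_variables=a.size)


def linear_fit(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """OLS of b on a: (intercept, slope, slope p-value).

    A perfect agreement between two weight profiles gives intercept 0 and
    slope 1.
    """
    a = np.ravel(a)
    b = np.ravel(b)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(a) == 0.0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(a, b)
    return float(res.intercept), float(res.slope), float(res.pvalue)


def compare_weights(
    ref_weights: tuple[np.ndarray, np.ndarray],
    target_weights: tuple[np.ndarray, np.ndarray],
    component: int = 0,
    block: int = 1,
) -> SimilarityReport:
    """Full similarity report for one component of one block, sign-aligned.

    The two fits may retain different numbers of components; only the
    requested component (matched by singular-value rank) is compared.
    """
    r1 = ref_weights[0][:, component]
    r2 = ref_weights[1][:, component]
    (t1, t2), flipped = align_signs(
        (r1, r2), (target_weights[0][:, component], target_weights[1][:, component]))
    a = r1 if block == 1 else r2
    b = t1 if block == 1 else t2
    rep = weight_similarity(a, b)
    rep.fit_intercept, rep.fit_slope, rep.fit_p_value = linear_fit(a, b)
    rep.sign_flipped = bool(flipped[0])
    return rep


# ---------------------------------------------------------------------------
# Variability across projection seeds
# ---------------------------------------------------------------------------

#: |mean weight| below which percent deviation is reported as missing.
PCT_DEV_MEAN_TOL = 1e-8


def _pct_deviation(w: np.ndarray) -> np.ndarray:
    """Mean over runs of |w_run − mean| / |mean| × 100, per variable."""
    mean = w.mean(axis=0)
    out = np.full(mean.shape, np.nan)
    ok = np.abs(mean) > PCT_DEV_MEAN_TOL
    out[ok] = 100.0 * np.mean(np.abs(w[:, ok] - mean[ok]), axis=0) / np.abs(mean[ok])
    return out


def variability_study(
    fit_fn,
    seeds,
    component: int = 0,
    truth=None,
) -> dict:
    """Weight variability of a stochastic fit across projection seeds.

    ``fit_fn(seed)`` must refit the same data with a different random
    matrix and return (weights_1, weights_2) in the original spaces.  Runs
    are jointly sign-aligned to the first before aggregating.  Reports
    per-variable variance and average absolute percent deviation from the
    per-variable mean; when a truth record is supplied, causal and
    non-causal variables are summarized separately.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least 2 runs")
    runs1, runs2 = [], []
    ref = None
    for s in seeds:
        w1, w2 = fit_fn(s)
        cat = np.concatenate([w1[:, component], w2[:, component]])
        if ref is None:
            ref = cat
        elif cat @ ref < 0:
            cat = -cat
        runs1.append(cat[:w1.shape[0]])
        runs2.append(cat[w1.shape[0]:])
    w1 = np.vstack(runs1)
    w2 = np.vstack(runs2)
    result = {
        "variance_1": w1.var(axis=0, ddof=1),
        "variance_2": w2.var(axis=0, ddof=1),
        "pct_deviation_1": _pct_deviation(w1),
        "pct_deviation_2": _pct_deviation(w2),
        "n_runs": len(seeds),
    }
    if truth is not None:
        causal1 = np.zeros(w1.shape[1], dtype=bool)
        causal1[truth.causal_block] = True
        causal2 = np.zeros(w2.shape[1], dtype=bool)
        causal2[truth.causal_genotype_indices] = True
        for tag, mask, var, dev in (
            ("1", causal1, result["variance_1"], result["pct_deviation_1"]),
            ("2", causal2, result["variance_2"], result["pct_deviation_2"]),
        ):
            result[f"causal_variance_{tag}"] = float(np.nanmean(var[mask]))
            result[f"noncausal_variance_{tag}"] = float(np.nanmean(var[~mask]))
            result[f"causal_pct_deviation_{tag}"] = float(np.nanmean(dev[mask]))
            result[f"noncausal_pct_deviation_{tag}"] = float(np.nanmedian(dev[~mask]))
    return result


def recovery_score(
    weights: np.ndarray,
    causal_indices,
    top_fraction: float = 0.01,
) -> dict:
    """Precision/recall of causal variables among top-|weight| variables.

    Variables are ranked by decreasing |weight|; the hit set is the top
    ``top_fraction`` of variables (at least as many as there are causal
    variables is NOT enforced — a tiny fraction can make recall < 1 by
    construction).
    """
    w = np.abs(np.ravel(weights))
    causal = np.asarray(sorted(causal_indices), dtype=int)
    if causal.size == 0 or causal.max() >= w.size:
        raise ValueError("invalid causal indices")
    order = np.argsort(-w)
    rank = np.empty(w.size, dtype=int)
    rank[order] = np.arange(w.size)
    top_n = max(1, int(np.ceil(top_fraction * w.size)))
    hits = int(np.sum(rank[causal] < top_n))
    return {
        "precision": hits / top_n,
        "recall": hits / causal.size,
        "ranks": (rank[causal] + 1).tolist(),  # 1-based ranks
        "top_n": top_n,
    }
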