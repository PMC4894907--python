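"""Gaussian random projection and the Johnson–Lindenstrauss/Menon calculus.

Random projection multiplies an N×d data matrix by a d×k random matrix
with unit Euclidean column norms, embedding the N samples in k dimensions
while approximately preserving pairwise distances (Johnson–Lindenstrauss).
The reduced dimension is chosen from the Menon bound

    k >= k0 = ((16 + 8β) / ε²) · ln(N),

which guarantees distortion within 1±ε with probability at least 1 − N^(−β).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("plscrp")

#: Below this source dimension Gram–Schmidt orthogonalization is applied by
#: default; at or above it, high-dimensional Gaussian columns are already
#: nearly orthogonal and the expensive orthogonalization step is skipped.
GRAM_SCHMIDT_DIM_THRESHOLD = 1000

#: Interval of the distortion tolerance in which the Menon bound adapts
#: best; values outside it trigger a warning, not an error.
MENON_EPSILON_RANGE = (0.75, 1.5)


# ---------------------------------------------------------------------------
# Dimension calculus
# ---------------------------------------------------------------------------

def beta_from_success(n_samples: int, success_probability: float) -> float:
    """Tail exponent β such that 1 − N^(−β) equals the success probability."""
    if n_samples < 2:
        raise ValueError("need N >= 2")
    if not 0.0 < success_probability < 1.0:
        raise ValueError(f"success probability must be in (0,1), got {success_probability}")
    return -math.log(1.0 - success_probability) / math.log(n_samples)


def menon_dimension(
    n_samples: int,
    epsilon: float,
    beta: float,
    chosen_k: int | None = None,
) -> "ProjectionPlan":
    """Menon lower bound k0 = ((16+8β)/ε²)·ln N and a projection plan.

    ``k`` defaults to ceil(k0); callers may override upward (e.g. round
    97.6486 up to a convenient 100).  An ε outside [3/4, 3/2] warns because
    the bound is loosest there.
    """
    if n_samples < 2:
        raise ValueError("need N >= 2")
    if epsilon <= 0 or beta <= 0:
        raise ValueError("epsilon and beta must be positive")
    lo, hi = MENON_EPSILON_RANGE
    if not lo <= epsilon <= hi:
        warnings.warn(
            f"epsilon={epsilon:g} is outside [{lo}, {hi}] where the Menon "
            "bound adapts best", stacklevel=2)
    k0 = (16.0 + 8.0 * beta) / epsilon**2 * math.log(n_samples)
    k = int(math.ceil(k0 - 1e-9)) if chosen_k is None else int(chosen_k)
    if k < k0 - 1e-9:
        raise ValueError(f"chosen k={k} is below the Menon bound k0={k0:.4f}")
    return ProjectionPlan(
        n_samples=n_samples,
        epsilon=float(epsilon),
        beta=float(beta),
        k_min=k0,
        k=k,
    )


def epsilon_from_dimension(n_samples: int, k: int, success_probability: float) -> float:
    """Distortion ε achievable at reduced dimension k (inverts the bound).

    ε = sqrt(((16+8β)·ln N)/k) with β from the success probability; the
    diagonal N = k of this map is the accuracy-versus-sample-size table of
    the method.
    """
    if n_samples < 2:
        raise ValueError("need N >= 2")
    if k < 1:
        raise ValueError("need k >= 1")
    beta = beta_from_success(n_samples, success_probability)
    return math.sqrt((16.0 + 8.0 * beta) * math.log(n_samples) / k)


@dataclass
class ProjectionPlan:
    """Reduced dimension k with its Johnson–Lindenstrauss/Menon pedigree."""

    n_samples: int
    epsilon: float
    beta: float
    k_min: float
    k: int

    def __post_init__(self) -> None:
        if self.k < self.k_min - 1e-9:
            raise ValueError(f"k={self.k} below Menon bound k0={self.k_min:.4f}")
        recomputed = (16.0 + 8.0 * self.beta) / self.epsilon**2 * math.log(self.n_samples)
        if abs(recomputed - self.k_min) > 1e-6:
            raise ValueError("stored k_min inconsistent with (N, epsilon, beta)")

    @property
    def success_probability(self) -> float:
        return 1.0 - self.n_samples ** (-self.beta)


# ---------------------------------------------------------------------------
# Random matrices
# ---------------------------------------------------------------------------

@dataclass
class RandomMatrix:
    """A seeded d×k Gaussian projection matrix with unit-norm columns."""

    entries: np.ndarray
    seed: int
    orthogonalized: bool

    @property
    def source_dim(self) -> int:
        return self.entries.shape[0]

    @property
    def target_dim(self) -> int:
        return self.entries.shape[1]

    def sidecar(self) -> str:
        """JSON sidecar from which the matrix is exactly regenerable."""
        return json.dumps({
            "seed": self.seed,
            "source_dim": self.source_dim,
            "target_dim": self.target_dim,
            "orthogonalized": self.orthogonalized,
        })

    @classmethod
    def from_sidecar(cls, text: str) -> "RandomMatrix":
        meta = json.loads(text)
        return generate_random_matrix(
            meta["source_dim"], meta["target_dim"],
            seed=meta["seed"], orthogonalize=meta["orthogonalized"])


def _gram_schmidt(m: np.ndarray) -> np.ndarray:
    # thin QR with positive R-diagonal == classical Gram-Schmidt result
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def generate_random_matrix(
    d: int,
    k: int,
    seed: int,
    orthogonalize: bool | None = None,
    max_retries: int = 5,
) -> RandomMatrix:
    """Draw a d×k i.i.d. N(0,1) matrix, optionally orthogonalize, normalize.

    ``orthogonalize=None`` applies the dimension rule: Gram–Schmidt below
    ``GRAM_SCHMIDT_DIM_THRESHOLD`` source dimensions, plain column
    normalization at or above it (high-dimensional Gaussian columns are
    already nearly orthogonal).  The same seed regenerates the matrix
    bit-identically.
    """
    if k < 1:
        raise ValueError("need k >= 1")
    if orthogonalize is None:
        orthogonalize = d < GRAM_SCHMIDT_DIM_THRESHOLD
    if orthogonalize and k > d:
        raise ValueError(f"cannot orthogonalize k={k} > d={d} columns")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        m = rng.standard_normal((d, k))
        if orthogonalize:
            q, r = np.linalg.qr(m)
            if np.min(np.abs(np.diag(r))) < 1e-12:
                logger.warning("numerically dependent columns at attempt %d; "
                               "regenerating", attempt)
                continue
            m = q * np.sign(np.diag(r))
        m = m / np.linalg.norm(m, axis=0)
        return RandomMatrix(entries=m, seed=seed, orthogonalized=bool(orthogonalize))
    raise RuntimeError("could not draw an independent random matrix")


def project(block, random_matrix: RandomMatrix):
    """Project a block onto the reduced space: X_rp = X·R.

    The reduced block keeps the sample axis, gets synthetic variable ids
    ("rp_0001", ...) and is deliberately NOT re-standardized: the
    back-transformation algebra operates on X·R directly.
    """
    from .core import DataBlock  # local import to avoid a cycle

    if block.n_variables != random_matrix.source_dim:
        raise ValueError(
            f"block has {block.n_variables} variables but R expects "
            f"{random_matrix.source_dim}")
    k = random_matrix.target_dim
    width = max(4, len(str(k)))
    return DataBlock(
        values=block.values @ random_matrix.entries,
        sample_ids=list(block.sample_ids),
        variable_ids=[f"rp_{i + 1:0{width}d}" for i in range(k)],
        standardized=block.standardized,  # scores scale consistently; see docs
        dtype_role="continuous",
    )


# ---------------------------------------------------------------------------
# Distortion audit
# ---------------------------------------------------------------------------

def distortion_profile(
    original,
    reduced,
    epsilon: float,
    max_pairs: int | None = None,
    seed: int = 0,
) -> dict:
    """Audit pairwise-distance distortion of an embedding.

    Compares reduced to original pairwise Euclidean distances (reduced
    distances rescaled by sqrt(d/k), the expectation-preserving scale for
    unit-norm-column projections) over all pairs or a seeded subsample.
    Reports the max and mean absolute relative distortion, the fraction of
    pairs within the 1±ε band, and the number of coincident (skipped) pairs.
    """
    if original.n_samples != reduced.n_samples:
        raise ValueError("blocks do not share a sample axis")
    n = original.n_samples
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    d_orig = np.linalg.norm(original.values[ii] - original.values[jj], axis=1)
    scale = math.sqrt(original.n_variables / reduced.n_variables)
    d_red = scale * np.linalg.norm(reduced.values[ii] - reduced.values[jj], axis=1)
    ok = d_orig > 0
    n_skipped = int(np.sum(~ok))
    if n_skipped:
        logger.warning("skipping %d coincident sample pair(s)", n_skipped)
    ratio = d_red[ok] / d_orig[ok]
    rel = np.abs(ratio - 1.0)
    # JL band is stated on squared distances: (1-eps)||·||² <= ||·||² <= (1+eps)||·||²
    sq = ratio**2
    within = np.mean((sq >= 1.0 - epsilon) & (sq <= 1.0 + epsilon)) if rel.size else float("nan")
    return {
        "max": float(rel.max()) if rel.size else float("nan"),
        "mean": float(rel.mean()) if rel.size else float("nan"),
        "fraction_within_band": float(within),
        "n_pairs": int(rel.size),
        "n_skipped": n_skipped,
    }
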