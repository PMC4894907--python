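"""Exact Partial Least Squares Correlation (PLSC) between two data blocks.

PLSC finds pairs of weight vectors (w1_i, w2_i) maximizing the covariance
between the latent scores X1·w1_i and X2·w2_i of two column-standardized
blocks sharing a sample axis.  The solution is the singular value
decomposition of the cross-product matrix A = X1'X2: left singular vectors
are the block-1 weights, right singular vectors the block-2 weights, and
the singular values are the (unnormalized) score covariances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import svd as _dense_svd
from scipy.sparse.linalg import LinearOperator, svds

logger = logging.getLogger("plscrp")

#: Above this many entries of A = X1'X2, plsc_fit and the back-transformation
#: switch to a matrix-free code path that never materializes A.
DEFAULT_MEMORY_BUDGET = 50_000_000

#: Default cumulative explained-covariance fraction used to pick the number
#: of components when the caller gives neither n_components nor a target.
DEFAULT_VARIANCE_TARGET = 0.80


class DegenerateBlockError(ValueError):
    """Raised when a block has no usable (non-constant) columns."""


# ---------------------------------------------------------------------------
# DataBlock
# ---------------------------------------------------------------------------

@dataclass
class DataBlock:
    """A sample-by-variable numeric matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
    sample_ids, variable_ids : sequences of unique identifiers
    standardized : whether every column has zero mean and unit sample
        standard deviation (ddof=1)
    dtype_role : ``"continuous"`` or ``"count"`` (additive minor-allele
        counts in {0, 1, 2})
    dropped_variables : identifiers removed during cleaning (e.g.
        zero-variance columns dropped by :func:`standardize`)
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]
    standardized: bool = False
    dtype_role: str = "continuous"
    dropped_variables: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample×variable matrix")
        n, d = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.variable_ids) != d:
            raise ValueError(f"{len(self.variable_ids)} variable_ids for {d} columns")
        if len(set(self.variable_ids)) != d:
            seen: set[str] = set()
            dup = next(v for v in self.variable_ids if v in seen or seen.add(v))
            raise ValueError(f"duplicate variable id: {dup!r}")
        if self.dtype_role not in ("continuous", "count"):
            raise ValueError(f"invalid dtype_role: {self.dtype_role!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, index: np.ndarray) -> "DataBlock":
        """Row-subset (or resample) keeping variable metadata."""
        return replace(
            self,
            values=self.values[index],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(index)],
        )


def _check_missing(block: DataBlock) -> None:
    bad = np.flatnonzero(~np.isfinite(block.values).all(axis=0))
    if bad.size:
        names = [block.variable_ids[j] for j in bad[:10]]
        raise ValueError(f"missing/non-finite values in columns: {names}")


def standardize(block: DataBlock) -> DataBlock:
    """Column-standardize a block to zero mean and unit sample sd (ddof=1).

    Zero-variance columns (monomorphic SNPs, dead voxels) are dropped with a
    warning; their identifiers are recorded in ``dropped_variables``.
    Already-standardized blocks pass through idempotently.

    Raises
    ------
    DegenerateBlockError
        if every column is constant.
    ValueError
        if the block contains missing values (offending columns named) or
        has fewer than 3 samples.
    """
    if block.n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {block.n_samples}")
    _check_missing(block)
    vals = block.values
    sd = vals.std(axis=0, ddof=1)
    # constant up to rounding: std below machine noise for the column scale
    scale = np.maximum(np.abs(vals).max(axis=0), 1.0)
    keep = sd > 1e-12 * scale
    if not keep.any():
        raise DegenerateBlockError("degenerate block: all columns constant")
    dropped = tuple(v for v, k in zip(block.variable_ids, keep) if not k)
    if dropped:
        logger.warning("dropping %d zero-variance column(s): %s",
                       len(dropped), list(dropped[:10]))
    x = block.values[:, keep]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    return DataBlock(
        values=z,
        sample_ids=list(block.sample_ids),
        variable_ids=[v for v, k in zip(block.variable_ids, keep) if k],
        standardized=True,
        dtype_role=block.dtype_role,
        dropped_variables=block.dropped_variables + dropped,
    )


# ---------------------------------------------------------------------------
# Cross-product matrix A = X1'X2 (materialized or matrix-free)
# ---------------------------------------------------------------------------

def _check_pair(block1: DataBlock, block2: DataBlock) -> None:
    if not (block1.standardized and block2.standardized):
        raise ValueError("both blocks must be standardized")
    if block1.n_samples != block2.n_samples or block1.sample_ids != block2.sample_ids:
        raise ValueError("sample axes of the two blocks do not match")


class CrossProductOperator(LinearOperator):
    """Action of A = X1'X2 (and its transpose) without materializing A.

    ``matvec`` computes A·v as X1'·(X2·v); ``rmatvec`` computes A'·u as
    X2'·(X1·u).  Cost is O(N·(d1+d2)) per product, independent of d1·d2.
    """

    def __init__(self, x1: np.ndarray, x2: np.ndarray):
        self.x1 = x1
        self.x2 = x2
        super().__init__(dtype=np.float64, shape=(x1.shape[1], x2.shape[1]))

    def _matvec(self, v: np.ndarray) -> np.ndarray:
        return self.x1.T @ (self.x2 @ np.ravel(v))

    def _rmatvec(self, u: np.ndarray) -> np.ndarray:
        return self.x2.T @ (self.x1 @ np.ravel(u))

    def _matmat(self, v: np.ndarray) -> np.ndarray:
        return self.x1.T @ (self.x2 @ v)

    def total_squared_singular_values(self) -> float:
        """‖A‖_F² = Σ_i s_i² computed via the N×N Gram matrices."""
        g1 = self.x1 @ self.x1.T
        g2 = self.x2 @ self.x2.T
        return float(np.sum(g1 * g2))


def cross_product(block1: DataBlock, block2: DataBlock) -> np.ndarray:
    """Materialize the cross-product matrix A = X1'X2 (d1×d2).

    Entry (j, l) is the dot product of column j of block 1 with column l of
    block 2; on standardized columns this is (N−1) times their Pearson
    correlation.
    """
    _check_pair(block1, block2)
    return block1.values.T @ block2.values


def cross_product_operator(block1: DataBlock, block2: DataBlock) -> CrossProductOperator:
    """Matrix-free handle on A = X1'X2 for large d1·d2."""
    _check_pair(block1, block2)
    return CrossProductOperator(block1.values, block2.values)


# ---------------------------------------------------------------------------
# PLSC fit
# ---------------------------------------------------------------------------

@dataclass
class PlscModel:
    """SVD-derived PLSC solution.

    ``weights_1`` (d1×p) and ``weights_2`` (d2×p) hold unit-norm weight
    columns; ``singular_values`` the nonincreasing score covariances
    (raw X1'X2 scale); ``scores_1`` / ``scores_2`` the N×p latent variables;
    ``explained_fraction`` each component's share of the summed squared
    cross-block covariance.
    """

    weights_1: np.ndarray
    weights_2: np.ndarray
    singular_values: np.ndarray
    scores_1: np.ndarray
    scores_2: np.ndarray
    explained_fraction: np.ndarray
    n_components: int

    def score_covariance(self, per_sample: bool = False) -> np.ndarray:
        """Covariance between paired scores per component.

        Raw (= singular value) by default; divided by N−1 when
        ``per_sample`` is true.  The underlying method never disambiguates
        the divisor, so both scales are exposed side by side.
        """
        cov = np.einsum("ij,ij->j", self.scores_1, self.scores_2)
        if per_sample:
            cov = cov / (self.scores_1.shape[0] - 1)
        return cov


def explained_variance(singular_values: np.ndarray) -> np.ndarray:
    """Fraction of summed squared cross-block covariance per component."""
    s = np.asarray(singular_values, dtype=np.float64)
    if (s < 0).any():
        raise ValueError("singular values must be nonnegative")
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("all singular values are zero")
    return s**2 / total


def fix_svd_signs(w1: np.ndarray, w2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD sign convention.

    The entry of largest absolute value in each block-2 weight column is
    made positive; the paired block-1 column is flipped jointly so score
    covariances are unchanged.
    """
    w1 = w1.copy()
    w2 = w2.copy()
    for i in range(w2.shape[1]):
        j = int(np.argmax(np.abs(w2[:, i])))
        if w2[j, i] < 0:
            w2[:, i] = -w2[:, i]
            w1[:, i] = -w1[:, i]
    return w1, w2


def _svd_components(a, n_components: int, p_full: int):
    """Leading singular triplets of a (dense array or LinearOperator)."""
    if isinstance(a, np.ndarray):
        u, s, vt = _dense_svd(a, full_matrices=False)
        return u[:, :n_components], s, vt[:n_components]
    # matrix-free: svds needs k < min(shape)
    k = min(n_components, p_full - 1) if n_components >= p_full else n_components
    u, s, vt = svds(a, k=k, random_state=0)
    order = np.argsort(s)[::-1]
    return u[:, order], s[order], vt[order]


def plsc_fit(
    block1: DataBlock,
    block2: DataBlock,
    n_components: int | None = None,
    variance_target: float | None = None,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
) -> PlscModel:
    """Fit exact PLSC by SVD of the cross-product matrix A = X1'X2.

    Exactly one of ``n_components`` / ``variance_target`` may be given;
    with a variance target, the smallest m whose cumulative explained
    fraction reaches the target is kept (default 0.80).  When d1·d2
    exceeds ``memory_budget`` entries, A is never materialized and a
    truncated matrix-free SVD is used instead.

    The component sign is fixed deterministically (largest-|entry| of each
    block-2 weight column positive).
    """
    _check_pair(block1, block2)
    d1, d2 = block1.n_variables, block2.n_variables
    p_full = min(d1, d2)
    if n_components is not None and variance_target is not None:
        raise ValueError("give n_components or variance_target, not both")
    if n_components is not None and not (1 <= n_components <= p_full):
        raise ValueError(f"n_components must be in [1, {p_full}], got {n_components}")
    if variance_target is None and n_components is None:
        variance_target = DEFAULT_VARIANCE_TARGET

    matrix_free = d1 * d2 > memory_budget
    if matrix_free:
        op = cross_product_operator(block1, block2)
        total_sq = op.total_squared_singular_values()
        if n_components is not None:
            u, s, vt = _svd_components(op, n_components, p_full)
        else:
            k = min(16, p_full - 1)
            while True:
                u, s, vt = _svd_components(op, k, p_full)
                if np.cumsum(s**2).max() / total_sq >= variance_target or k >= p_full - 1:
                    break
                k = min(2 * k, p_full - 1)
        frac_all = s**2 / total_sq
    else:
        a = cross_product(block1, block2)
        u, s, vt = _dense_svd(a, full_matrices=False)
        total_sq = float(np.sum(s**2))
        if total_sq == 0.0:
            raise DegenerateBlockError("cross-product matrix is zero")
        frac_all = s**2 / total_sq

    # attainable rank (components with non-negligible singular value)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_components is not None:
        if n_components > rank:
            raise ValueError(
                f"requested {n_components} components but cross-product rank is {rank}")
        p = n_components
    else:
        cum = np.cumsum(frac_all)
        p = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        p = min(p, rank if rank else 1)

    w1, w2 = fix_svd_signs(u[:, :p], vt[:p].T)
    return PlscModel(
        weights_1=w1,
        weights_2=w2,
        singular_values=s[:p].copy(),
        scores_1=block1.values @ w1,
        scores_2=block2.values @ w2,
        explained_fraction=frac_all[:p].copy(),
        n_components=p,
    )


# ---------------------------------------------------------------------------
# Causal-component selection by cross-validated out-of-sample covariance
# ---------------------------------------------------------------------------

def select_component(
    block1: DataBlock,
    block2: DataBlock,
    n_components: int | None = None,
    variance_target: float | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the causal component by out-of-sample score covariance.

    K-fold cross-validation: weights fit on the training rows are applied
    to the held-out rows; the held-out per-sample score covariance per
    component, sign-aligned to the full-data fit, is averaged over folds.
    Returns the zero-based index of the argmax component and the vector of
    mean out-of-sample covariances.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = block1.n_samples
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample size ({n})")
    if n < 2 * folds:
        raise ValueError(f"need N >= 2*folds, got N={n}, folds={folds}")
    full = plsc_fit(block1, block2, n_components=n_components,
                    variance_target=variance_target)
    p = full.n_components
    ref = np.vstack([full.weights_1, full.weights_2])

    rng = np.random.default_rng(seed)
    assignment = np.array_split(rng.permutation(n), folds)
    oos = np.zeros((folds, p))
    for f, test_idx in enumerate(assignment):
        train = np.setdiff1d(np.arange(n), test_idx)
        a = block1.values[train].T @ block2.values[train]
        u, s, vt = _dense_svd(a, full_matrices=False)
        w1f, w2f = u[:, :p], vt[:p].T
        # joint sign alignment to the full-data fit; unaligned folds cancel
        cat = np.vstack([w1f, w2f])
        sign = np.where(np.einsum("ij,ij->j", cat, ref) < 0, -1.0, 1.0)
        w1f = w1f * sign
        w2f = w2f * sign
        z1 = block1.values[test_idx] @ w1f
        z2 = block2.values[test_idx] @ w2f
        oos[f] = np.einsum("ij,ij->j", z1, z2) / max(len(test_idx) - 1, 1)
    mean_oos = oos.mean(axis=0)
    return int(np.argmax(mean_oos)), mean_oos
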