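"""Resampling inference: permutation significance and bootstrap reliability.

Significance of each latent-variable covariance is assessed by permuting
the rows of block 2 (equivalent to randomly reassigning observations
without replacement) and refitting; reliability of individual variable
weights is assessed by bootstrap resampling of observations.  For
PLSC-RP fits the random matrices are held fixed across resamples, so
permutation testing operates entirely in the reduced space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DataBlock, plsc_fit, standardize
from .fusion import PlscRpModel, fit_reduce_both, fit_reduce_one
from .projection import ProjectionPlan, generate_random_matrix, project

logger = logging.getLogger("plscrp")


@dataclass
class FitSpec:
    """Names a fitting route so resampling can re-run it reproducibly.

    ``method`` is ``"plsc"`` (exact), ``"rp_one"`` (one block projected;
    ``reduce_side`` says which) or ``"rp_both"``.  Random-projection seeds
    and plans are stored here, so every resample reuses the same random
    matrices.
    """

    method: str = "plsc"
    reduce_side: str = "block1"
    plan: ProjectionPlan | None = None
    plan2: ProjectionPlan | None = None
    rp_seed: int = 0
    rp_seed2: int = 1
    orthogonalize: bool | None = None
    n_components: int | None = None
    variance_target: float | None = None
    allow_below_bound: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("plsc", "rp_one", "rp_both"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "rp_one" and self.plan is None:
            raise ValueError("rp_one requires a projection plan")
        if self.method == "rp_both" and (self.plan is None or self.plan2 is None):
            raise ValueError("rp_both requires two projection plans")

    def fit(self, block1: DataBlock, block2: DataBlock):
        """Run the named fit; returns a PlscModel or PlscRpModel."""
        kw = dict(n_components=self.n_components, variance_target=self.variance_target)
        if self.method == "plsc":
            return plsc_fit(block1, block2, **kw)
        if self.method == "rp_one":
            return fit_reduce_one(block1, block2, self.reduce_side, self.plan,
                                  seed=self.rp_seed, orthogonalize=self.orthogonalize,
                                  allow_below_bound=self.allow_below_bound, **kw)
        return fit_reduce_both(block1, block2, self.plan, self.plan2,
                               seed1=self.rp_seed, seed2=self.rp_seed2,
                               orthogonalize=self.orthogonalize,
                               allow_below_bound=self.allow_below_bound, **kw)

    def working_matrices(self, block1: DataBlock, block2: DataBlock
                         ) -> tuple[np.ndarray, np.ndarray]:
        """The (possibly projected) matrices the reduced SVD operates on."""
        y1, y2 = block1.values, block2.values
        if self.method in ("rp_one", "rp_both"):
            if self.method == "rp_both" or self.reduce_side == "block1":
                r1 = generate_random_matrix(block1.n_variables, self.plan.k,
                                            seed=self.rp_seed,
                                            orthogonalize=self.orthogonalize)
                y1 = y1 @ r1.entries
            if self.method == "rp_both":
                r2 = generate_random_matrix(block2.n_variables, self.plan2.k,
                                            seed=self.rp_seed2,
                                            orthogonalize=self.orthogonalize)
                y2 = y2 @ r2.entries
            elif self.reduce_side == "block2":
                r2 = generate_random_matrix(block2.n_variables, self.plan.k,
                                            seed=self.rp_seed,
                                            orthogonalize=self.orthogonalize)
                y2 = y2 @ r2.entries
        return y1, y2

    def model_weights(self, model) -> tuple[np.ndarray, np.ndarray]:
        """Original-space weight matrices (d1×p, d2×p) of a fitted model."""
        if isinstance(model, PlscRpModel):
            return model.weights_1_original, model.weights_2_original
        return model.weights_1, model.weights_2


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: np.ndarray          # per-component score covariance (singular value)
    permuted: np.ndarray          # B × p null statistics
    p_values: np.ndarray
    n_permutations: int
    seed: int


def permutation_test(
    block1: DataBlock,
    block2: DataBlock,
    fit_spec: FitSpec | None = None,
    n_permutations: int = 199,
    seed: int = 0,
) -> PermutationResult:
    """Permutation significance of the per-component score covariance.

    Rows of block 2 are permuted without replacement ``n_permutations``
    times; each permutation refits the (reduced-space) SVD and records the
    singular values, matched to the observed components by rank.  The
    add-one convention p = (1 + #{permuted >= observed}) / (B + 1) keeps
    p-values in (0, 1]; ties count against significance.
    """
    if n_permutations < 19:
        raise ValueError("cannot resolve alpha = 0.05: need at least 19 permutations")
    spec = fit_spec or FitSpec()
    y1, y2 = spec.working_matrices(block1, block2)
    s_all = np.linalg.svd(y1.T @ y2, compute_uv=False)
    # component count mirrors the named fit's rule
    probe = plsc_fit(
        DataBlock(y1, block1.sample_ids, [f"a{i}" for i in range(y1.shape[1])],
                  standardized=True),
        DataBlock(y2, block2.sample_ids, [f"b{i}" for i in range(y2.shape[1])],
                  standardized=True),
        n_components=spec.n_components, variance_target=spec.variance_target)
    p = probe.n_components
    observed = s_all[:p]

    rng = np.random.default_rng(seed)
    y1t = y1.T
    permuted = np.empty((n_permutations, p))
    n = y2.shape[0]
    for b in range(n_permutations):
        perm = rng.permutation(n)
        permuted[b] = np.linalg.svd(y1t @ y2[perm], compute_uv=False)[:p]
    exceed = (permuted >= observed[None, :]).sum(axis=0)
    p_values = (1.0 + exceed) / (n_permutations + 1.0)
    return PermutationResult(observed=observed, permuted=permuted,
                             p_values=p_values, n_permutations=n_permutations,
                             seed=seed)


# ---------------------------------------------------------------------------
# Bootstrap reliability
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    weight_se_1: np.ndarray
    weight_se_2: np.ndarray
    bootstrap_ratio_1: np.ndarray
    bootstrap_ratio_2: np.ndarray
    reliable_mask_1: np.ndarray
    reliable_mask_2: np.ndarray
    n_bootstrap: int
    threshold: float
    seed: int
    n_redrawn: int = 0
    component: int = 0
    replicate_weights_1: np.ndarray = field(default=None, repr=False)
    replicate_weights_2: np.ndarray = field(default=None, repr=False)


def _ratio(w: np.ndarray, se: np.ndarray) -> np.ndarray:
    out = np.zeros_like(w)
    nz = se > 0
    out[nz] = w[nz] / se[nz]
    out[~nz & (w != 0)] = np.inf
    return out


def bootstrap_reliability(
    block1: DataBlock,
    block2: DataBlock,
    fit_spec: FitSpec | None = None,
    n_bootstrap: int = 100,
    threshold: float = 2.0,
    seed: int = 0,
    component: int = 0,
) -> BootstrapResult:
    """Bootstrap standard errors and reliability of component weights.

    Observations are resampled with replacement and the named fit re-run;
    replicate weights are jointly sign-aligned to the original fit before
    aggregation.  A variable is flagged reliable when |weight / SE| meets
    the threshold (default 2, roughly a two-sided z-test at 0.05).
    Replicates whose resampled block has a constant column are redrawn
    (counted and logged).
    """
    if n_bootstrap < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    spec = fit_spec or FitSpec()
    full = spec.fit(block1, block2)
    w1_full, w2_full = spec.model_weights(full)
    c = component
    if not 0 <= c < w1_full.shape[1]:
        raise ValueError(f"component {c} out of range")
    ref = np.concatenate([w1_full[:, c], w2_full[:, c]])

    rng = np.random.default_rng(seed)
    n = block1.n_samples
    reps1 = np.empty((n_bootstrap, block1.n_variables))
    reps2 = np.empty((n_bootstrap, block2.n_variables))
    n_redrawn = 0
    b = 0
    while b < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        v1 = block1.values[idx]
        v2 = block2.values[idx]
        if (v1.max(axis=0) == v1.min(axis=0)).any() \
                or (v2.max(axis=0) == v2.min(axis=0)).any():
            n_redrawn += 1
            if n_redrawn > 50 * n_bootstrap:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        b1 = standardize(DataBlock(v1, [str(i) for i in range(n)],
                                   block1.variable_ids, dtype_role=block1.dtype_role))
        b2 = standardize(DataBlock(v2, [str(i) for i in range(n)],
                                   block2.variable_ids, dtype_role=block2.dtype_role))
        if b1.n_variables != block1.n_variables or b2.n_variables != block2.n_variables:
            n_redrawn += 1  # a column went (numerically) constant in this resample
            continue
        model = spec.fit(b1, b2)
        w1, w2 = spec.model_weights(model)
        if w1.shape[1] <= c:
            n_redrawn += 1
            continue
        cat = np.concatenate([w1[:, c], w2[:, c]])
        if cat @ ref < 0:
            cat = -cat
        reps1[b] = cat[:block1.n_variables]
        reps2[b] = cat[block1.n_variables:]
        b += 1
    if n_redrawn:
        logger.warning("redrew %d degenerate bootstrap replicate(s)", n_redrawn)

    se1 = reps1.std(axis=0, ddof=1)
    se2 = reps2.std(axis=0, ddof=1)
    r1 = _ratio(w1_full[:, c], se1)
    r2 = _ratio(w2_full[:, c], se2)
    return BootstrapResult(
        weight_se_1=se1, weight_se_2=se2,
        bootstrap_ratio_1=r1, bootstrap_ratio_2=r2,
        reliable_mask_1=np.abs(r1) >= threshold,
        reliable_mask_2=np.abs(r2) >= threshold,
        n_bootstrap=n_bootstrap, threshold=threshold, seed=seed,
        n_redrawn=n_redrawn, component=c,
        replicate_weights_1=reps1, replicate_weights_2=reps2,
    )
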