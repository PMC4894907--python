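"""PLSC-RP: PLSC fit in a randomly projected space, with back-transformation.

One-sided reduction projects the high-dimensional block (X1·R), fits PLSC
on the (reduced, raw) pair, and maps the reduced-space weights back to the
original variables through the SVD identity

    w1_i = (1 / (s_i · ‖w2_i‖²)) · A · w2_i,        A = X1'X2,

where s_i and w2_i come from the reduced-space SVD.  Two-sided reduction
projects both blocks and back-transforms each side through the
cross-product of the original block with the *other* block's reduced
matrix.  The product A·w is always available matrix-free (X1'·(X2·w)), so
the cost never depends on d1·d2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_MEMORY_BUDGET,
    DataBlock,
    PlscModel,
    cross_product,
    cross_product_operator,
    fix_svd_signs,
    plsc_fit,
)
from .projection import ProjectionPlan, RandomMatrix, generate_random_matrix, project

logger = logging.getLogger("plscrp")


@dataclass
class PlscRpModel:
    """A reduced-space PLSC fit plus original-space weights.

    ``side`` records which block(s) were projected; ``reduced_model`` is the
    PLSC solution in the reduced space; ``weights_1_original`` /
    ``weights_2_original`` (d1×p, d2×p) are unit-norm columns in the
    original variable spaces — exact SVD outputs for an un-reduced block,
    back-transformed otherwise.
    """

    side: str  # "block1" | "block2" | "both"
    plans: tuple[ProjectionPlan, ...]
    random_matrices: tuple[RandomMatrix, ...]
    reduced_model: PlscModel
    weights_1_original: np.ndarray
    weights_2_original: np.ndarray

    @property
    def singular_values(self) -> np.ndarray:
        return self.reduced_model.singular_values

    @property
    def n_components(self) -> int:
        return self.weights_1_original.shape[1]


def _validate_plan(plan: ProjectionPlan, allow_below_bound: bool) -> None:
    if plan.k < plan.k_min - 1e-9:
        if not allow_below_bound:
            raise ValueError(
                f"k={plan.k} is below the Menon bound k0={plan.k_min:.4f}; "
                "pass allow_below_bound=True to override")
        logger.warning("overriding Menon bound: k=%d < k0=%.4f", plan.k, plan.k_min)


def _unit_columns(w: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(w, axis=0)
    return w / norms


def _apply_cross(block_left: DataBlock, block_right: DataBlock,
                 w: np.ndarray, memory_budget: int) -> np.ndarray:
    """(X_left' X_right) @ w, matrix-free above the memory budget."""
    d1, d2 = block_left.n_variables, block_right.n_variables
    if d1 * d2 > memory_budget:
        return cross_product_operator(block_left, block_right) @ w
    return cross_product(block_left, block_right) @ w


def back_transform_one(
    model: PlscRpModel,
    block_reduced_original: DataBlock,
    block_other: DataBlock,
) -> np.ndarray:
    """Original-space weights for the reduced side of a one-sided fit.

    For each component i, w = A·w_other,i / (s_i·‖w_other,i‖²) with A the
    cross-product of the original (un-projected) block with the other
    block, computed as X'·(X_other·w) so A is never materialized for large
    problems; columns are unit-normalized afterwards.  Components with a
    zero singular value are skipped with a warning.
    """
    if model.side not in ("block1", "block2"):
        raise ValueError("back_transform_one requires a one-sided fit")
    rm = model.reduced_model
    if model.side == "block1":
        w_other = rm.weights_2  # exact SVD outputs for the raw block
    else:
        w_other = rm.weights_1
    s = rm.singular_values
    keep = s > 0
    if not keep.all():
        logger.warning("skipping %d component(s) with zero singular value",
                       int(np.sum(~keep)))
    w_other = w_other[:, keep]
    s = s[keep]
    norms_sq = np.sum(w_other**2, axis=0)
    if model.side == "block1":
        raw = _apply_cross(block_reduced_original, block_other, w_other,
                           DEFAULT_MEMORY_BUDGET)
    else:
        # w2 = A'·w1 = (X2'X1)·w1 = X2'·(X1·w1)
        raw = _apply_cross(block_reduced_original, block_other, w_other,
                           DEFAULT_MEMORY_BUDGET)
    return _unit_columns(raw / (s * norms_sq))


def fit_reduce_one(
    block1: DataBlock,
    block2: DataBlock,
    reduce_side: str,
    plan: ProjectionPlan,
    seed: int,
    orthogonalize: bool | None = None,
    n_components: int | None = None,
    variance_target: float | None = None,
    allow_below_bound: bool = False,
) -> PlscRpModel:
    """One-sided PLSC-RP: project one block, fit, back-transform.

    The designated block is projected to ``plan.k`` dimensions with a
    seeded Gaussian random matrix; PLSC is fit on the (reduced, raw) pair;
    the un-reduced block's weights are exact outputs of the reduced SVD
    while the reduced block's original-space weights are recovered by
    :func:`back_transform_one`.  Reproducible bit-for-bit from
    (data, seed, plan).
    """
    if reduce_side not in ("block1", "block2"):
        raise ValueError(f"reduce_side must be 'block1' or 'block2', got {reduce_side!r}")
    _validate_plan(plan, allow_below_bound)
    target = block1 if reduce_side == "block1" else block2
    rmat = generate_random_matrix(target.n_variables, plan.k, seed=seed,
                                  orthogonalize=orthogonalize)
    reduced = project(target, rmat)
    if reduce_side == "block1":
        rm = plsc_fit(reduced, block2, n_components=n_components,
                      variance_target=variance_target)
    else:
        rm = plsc_fit(block1, reduced, n_components=n_components,
                      variance_target=variance_target)
    model = PlscRpModel(
        side=reduce_side,
        plans=(plan,),
        random_matrices=(rmat,),
        reduced_model=rm,
        weights_1_original=np.empty((block1.n_variables, 0)),
        weights_2_original=np.empty((block2.n_variables, 0)),
    )
    if reduce_side == "block1":
        w1 = back_transform_one(model, block1, block2)
        keep = rm.singular_values > 0
        w2 = rm.weights_2[:, keep]
    else:
        w2 = back_transform_one(model, block2, block1)
        keep = rm.singular_values > 0
        w1 = rm.weights_1[:, keep]
    model.weights_1_original, model.weights_2_original = fix_svd_signs(w1, w2)
    return model


def back_transform_both(
    model: PlscRpModel,
    block1: DataBlock,
    block2: DataBlock,
) -> tuple[np.ndarray, np.ndarray]:
    """Original-space weights for both sides of a two-sided fit.

    w1_i comes from the cross-product of original block 1 with *reduced*
    block 2 applied to w2RP_i; w2_i symmetrically from the transposed
    cross-product of reduced block 1 with original block 2 applied to
    w1RP_i; each scaled by 1/(s_i·‖·‖²) and unit-normalized.  The joint
    sign is fixed by the same convention as the exact fit.
    """
    if model.side != "both":
        raise ValueError("back_transform_both requires a two-sided fit")
    rm = model.reduced_model
    s = rm.singular_values
    keep = s > 0
    if not keep.all():
        logger.warning("skipping %d component(s) with zero singular value",
                       int(np.sum(~keep)))
    s = s[keep]
    w1rp = rm.weights_1[:, keep]
    w2rp = rm.weights_2[:, keep]
    r1, r2 = model.random_matrices
    x2rp = block2.values @ r2.entries
    x1rp = block1.values @ r1.entries
    # cov(X1, X2RP)·w2RP  ==  X1'·(X2RP·w2RP)
    w1 = _unit_columns((block1.values.T @ (x2rp @ w2rp)) / (s * np.sum(w2rp**2, axis=0)))
    # (cov(X1RP, X2))'·w1RP  ==  X2'·(X1RP·w1RP)
    w2 = _unit_columns((block2.values.T @ (x1rp @ w1rp)) / (s * np.sum(w1rp**2, axis=0)))
    return fix_svd_signs(w1, w2)


def fit_reduce_both(
    block1: DataBlock,
    block2: DataBlock,
    plan1: ProjectionPlan,
    plan2: ProjectionPlan,
    seed1: int,
    seed2: int,
    orthogonalize: bool | None = None,
    joint_matrix: bool = False,
    n_components: int | None = None,
    variance_target: float | None = None,
    allow_below_bound: bool = False,
) -> PlscRpModel:
    """Two-sided PLSC-RP: project both blocks, fit, back-transform both.

    With ``joint_matrix`` (valid only when d1 == d2) a single seeded
    random matrix is shared by both sides; otherwise the sides use
    independent matrices from seed1/seed2.
    """
    _validate_plan(plan1, allow_below_bound)
    _validate_plan(plan2, allow_below_bound)
    d1, d2 = block1.n_variables, block2.n_variables
    if joint_matrix:
        if d1 != d2 or plan1.k != plan2.k:
            raise ValueError("joint random matrix requires d1 == d2 and k1 == k2")
        r1 = generate_random_matrix(d1, plan1.k, seed=seed1, orthogonalize=orthogonalize)
        r2 = r1
    else:
        if seed1 == seed2 and d1 == d2:
            raise ValueError("independent projections need distinct seeds "
                             "(or request a joint matrix)")
        r1 = generate_random_matrix(d1, plan1.k, seed=seed1, orthogonalize=orthogonalize)
        r2 = generate_random_matrix(d2, plan2.k, seed=seed2, orthogonalize=orthogonalize)
    rm = plsc_fit(project(block1, r1), project(block2, r2),
                  n_components=n_components, variance_target=variance_target)
    model = PlscRpModel(
        side="both",
        plans=(plan1, plan2),
        random_matrices=(r1, r2),
        reduced_model=rm,
        weights_1_original=np.empty((d1, 0)),
        weights_2_original=np.empty((d2, 0)),
    )
    model.weights_1_original, model.weights_2_original = back_transform_both(
        model, block1, block2)
    return model
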