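"""Synthetic genotype–phenotype data with a planted multivariate association.

The generator emulates the study conditions the method was validated
under: multivariate-normal continuous phenotypes (e.g. flattened voxel
activations) with an equicorrelated "collinear" causal block, additive
Hardy–Weinberg SNP counts in {0, 1, 2}, and a planted linear relationship
between the causal phenotype block and a small set of causal SNPs whose
pairwise phenotype–SNP correlation averages a configurable target
(default 0.3, in line with reported imaging-genetics effect sizes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import DataBlock

logger = logging.getLogger("plscrp")

#: Default size and internal correlation of the collinear causal block.
DEFAULT_BLOCK_SIZE = 20
DEFAULT_BLOCK_RHO = 0.5
DEFAULT_MAF_RANGE = (0.05, 0.5)
DEFAULT_TARGET_CORRELATION = 0.3
DEFAULT_N_CAUSAL_SNPS = 3


@dataclass
class SimulationTruth:
    """Planted causal structure of a simulated dataset."""

    causal_phenotype_index: int
    collinear_phenotype_indices: list[int]
    causal_genotype_indices: list[int]
    target_correlation: float = DEFAULT_TARGET_CORRELATION
    seed: int = 0
    design_tag: str = "pheno_high"
    realized_correlation: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_correlation < 1.0:
            raise ValueError("target correlation must be in [0, 1)")
        if self.causal_phenotype_index in self.causal_genotype_indices:
            pass  # indices live in different blocks; nothing to check across
        if len(set(self.causal_genotype_indices)) != len(self.causal_genotype_indices):
            raise ValueError("causal genotype indices must be distinct")

    @property
    def causal_block(self) -> list[int]:
        return sorted({self.causal_phenotype_index, *self.collinear_phenotype_indices})


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def simulate_phenotypes(
    n_samples: int,
    n_variables: int,
    block_size: int = DEFAULT_BLOCK_SIZE,
    within_block_rho: float = DEFAULT_BLOCK_RHO,
    seed: int = 0,
    block_start: int | None = None,
) -> tuple[DataBlock, list[int]]:
    """Multivariate-normal phenotypes with one equicorrelated block.

    The covariance is block-diagonal: ``block_size`` adjacent variables
    share pairwise correlation ``within_block_rho`` (a parametric stand-in
    for the collinearity of neighbouring voxels), all other variables are
    independent; every variance is 1.  Returns the block and the indices
    of the correlated block (placed at a seeded random start unless
    ``block_start`` is given).
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if not 1 <= block_size <= n_variables:
        raise ValueError("need d >= block_size >= 1")
    if not 0.0 <= within_block_rho < 1.0:
        raise ValueError("within-block correlation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_samples, n_variables))
    if block_start is None:
        block_start = int(rng.integers(0, n_variables - block_size + 1))
    idx = list(range(block_start, block_start + block_size))
    if within_block_rho > 0 and block_size > 1:
        # equicorrelated factor construction: v = sqrt(rho) f + sqrt(1-rho) e
        f = rng.standard_normal((n_samples, 1))
        x[:, idx] = (np.sqrt(within_block_rho) * f
                     + np.sqrt(1.0 - within_block_rho) * x[:, idx])
    block = DataBlock(
        values=x,
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        variable_ids=[f"vox_{j + 1}" for j in range(n_variables)],
        dtype_role="continuous",
    )
    return block, idx


def simulate_genotypes(
    n_samples: int,
    n_variables: int,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    seed: int = 0,
) -> DataBlock:
    """Additive-coded SNP counts under Hardy–Weinberg equilibrium.

    Per SNP, a minor-allele frequency q is drawn uniformly from
    ``maf_range`` and genotypes as Binomial(2, q) minor-allele counts.
    Monomorphic columns are redrawn (logged) so every SNP is polymorphic.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = np.random.default_rng(seed)
    q = rng.uniform(lo, hi, size=n_variables)
    g = rng.binomial(2, q, size=(n_samples, n_variables)).astype(np.float64)
    n_redrawn = 0
    for _ in range(1000):
        mono = np.flatnonzero(g.std(axis=0) == 0.0)
        if mono.size == 0:
            break
        n_redrawn += mono.size
        g[:, mono] = rng.binomial(2, q[mono], size=(n_samples, mono.size))
    else:
        raise RuntimeError("could not draw polymorphic genotypes")
    if n_redrawn:
        logger.warning("redrew %d monomorphic SNP column(s)", n_redrawn)
    return DataBlock(
        values=g,
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        variable_ids=[f"snp_{j + 1}" for j in range(n_variables)],
        dtype_role="count",
    )


def induce_association(
    pheno: DataBlock,
    geno: DataBlock,
    truth: SimulationTruth,
) -> tuple[DataBlock, DataBlock, SimulationTruth]:
    """Plant a linear phenotype–SNP relationship of a target mean correlation.

    Let g be the standardized row-sum of the (standardized) causal SNP
    columns.  Every phenotype column of the causal collinear block is
    rewritten as the blend  v ← α·g + sqrt(1−α²)·z(v)  with a single α
    solved from the realized correlations corr(g, snp_j) so that the
    expected correlation between a causal phenotype and a causal SNP,
    averaged over the causal SNPs, equals ``truth.target_correlation``.
    Blending every block member preserves the within-block collinearity
    while letting the whole block inherit the association.  The realized
    mean |correlation| is recorded in the returned truth.

    Raises
    ------
    ValueError
        if the target exceeds the attainable maximum (the mean
        |corr(g, snp_j)|, reached at α = 1).
    """
    snp_idx = truth.causal_genotype_indices
    block_idx = truth.causal_block
    if max(block_idx) >= pheno.n_variables or max(snp_idx) >= geno.n_variables:
        raise ValueError("truth indices out of range")
    snps = geno.values[:, snp_idx]
    z_snps = (snps - snps.mean(axis=0)) / snps.std(axis=0, ddof=1)
    g = z_snps.sum(axis=1)
    g = (g - g.mean()) / g.std(ddof=1)
    c = np.array([np.corrcoef(g, z_snps[:, j])[0, 1] for j in range(len(snp_idx))])
    c_bar = float(np.mean(np.abs(c)))
    alpha = truth.target_correlation / c_bar
    if alpha > 1.0:
        raise ValueError(
            f"target correlation {truth.target_correlation} unreachable; "
            f"attainable maximum is {c_bar:.4f}")
    values = pheno.values.copy()
    v = values[:, block_idx]
    zv = (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)
    values[:, block_idx] = alpha * g[:, None] + np.sqrt(1.0 - alpha**2) * zv
    new_pheno = replace(pheno, values=values)
    causal_col = values[:, truth.causal_phenotype_index]
    realized = float(np.mean(np.abs(
        [np.corrcoef(causal_col, snps[:, j])[0, 1] for j in range(len(snp_idx))])))
    return new_pheno, geno, replace(truth, realized_correlation=realized)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: Desk-scale defaults for the three study designs: high-dimensional
#: phenotypes vs candidate SNPs, candidate phenotypes vs high-dimensional
#: SNPs, and both blocks high-dimensional.  The collinear causal block
#: spans a fifth of the phenotype variables, emulating the extensive
#: inter-voxel collinearity of real contrast images (which makes the
#: planted association the dominant covariance component, as in the
#: study designs this generator reproduces).  The two-phenotype design
#: plants a stronger per-SNP correlation, the desk-scale analogue of a
#: genome-wide-significant association.
SCENARIOS: dict[str, dict] = {
    "pheno_high": {"d1": 1000, "d2": 50, "block_fraction": 0.2,
                   "n_causal_snps": 3, "target_correlation": 0.3},
    "geno_high": {"d1": 2, "d2": 1000, "block_fraction": None,
                  "n_causal_snps": 3, "target_correlation": 0.45},
    "both_high": {"d1": 1000, "d2": 1000, "block_fraction": 0.2,
                  "n_causal_snps": 3, "target_correlation": 0.3},
}


def make_scenario(
    design_tag: str = "pheno_high",
    n_samples: int = 100,
    d1: int | None = None,
    d2: int | None = None,
    n_causal_snps: int | None = None,
    target_correlation: float | None = None,
    block_size: int | None = None,
    within_block_rho: float = DEFAULT_BLOCK_RHO,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    seed: int = 0,
) -> tuple[DataBlock, DataBlock, SimulationTruth]:
    """Generate one full (phenotype, genotype, truth) dataset.

    Deterministic given (configuration, seed): phenotype, genotype and
    causal-SNP draws use independent child seeds of ``seed``.
    """
    if design_tag not in SCENARIOS:
        raise ValueError(f"unknown design {design_tag!r}; choose from {list(SCENARIOS)}")
    preset = SCENARIOS[design_tag]
    d1 = preset["d1"] if d1 is None else d1
    d2 = preset["d2"] if d2 is None else d2
    if n_causal_snps is None:
        n_causal_snps = preset["n_causal_snps"]
    if target_correlation is None:
        target_correlation = preset["target_correlation"]
    if block_size is None:
        frac = preset["block_fraction"]
        block_size = 1 if frac is None else max(1, int(round(frac * d1)))
    s_pheno, s_geno, s_pick = _child_seeds(seed, 3)
    pheno, block_idx = simulate_phenotypes(
        n_samples, d1, block_size=block_size,
        within_block_rho=within_block_rho, seed=s_pheno)
    geno = simulate_genotypes(n_samples, d2, maf_range=maf_range, seed=s_geno)
    rng = np.random.default_rng(s_pick)
    snp_idx = sorted(rng.choice(d2, size=n_causal_snps, replace=False).tolist())
    causal_vox = int(rng.choice(block_idx))
    truth = SimulationTruth(
        causal_phenotype_index=causal_vox,
        collinear_phenotype_indices=[i for i in block_idx if i != causal_vox],
        causal_genotype_indices=snp_idx,
        target_correlation=target_correlation,
        seed=seed,
        design_tag=design_tag,
    )
    return induce_association(pheno, geno, truth)
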