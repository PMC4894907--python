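"""Matrix readers/writers, truth sidecars, and the seeded run pipeline.

Interchange format is delimited text (TSV/CSV): header row of variable
identifiers, first column of sample identifiers, samples as rows and
variables as columns everywhere.  An HDF5 container covers matrices too
large for text.  Every pipeline run writes a manifest (flags, seeds,
input digests, version) from which the outputs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DataBlock, plsc_fit, select_component, standardize
from .evaluate import compare_weights, recovery_score
from .fusion import fit_reduce_both, fit_reduce_one
from .inference import FitSpec, permutation_test
from .projection import beta_from_success, menon_dimension
from .simulate import SimulationTruth, make_scenario

logger = logging.getLogger("plscrp")


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

def _infer_dtype_role(values: np.ndarray) -> str:
    return "count" if np.isin(values, (0.0, 1.0, 2.0)).all() else "continuous"


def load_matrix(path, fmt: str | None = None, dtype_role: str | None = None) -> DataBlock:
    """Load a sample×variable matrix as a DataBlock.

    Format is inferred from the suffix unless given ("tsv", "csv", "h5").
    A matrix whose values all lie in {0, 1, 2} is inferred as additive
    genotype counts; pass ``dtype_role`` to override.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or {".tsv": "tsv", ".csv": "csv", ".h5": "h5", ".hdf5": "h5"}.get(
        path.suffix.lower(), "tsv")
    if fmt == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            values = np.asarray(f["values"], dtype=np.float64)
            sample_ids = [s.decode() for s in f["sample_ids"][:]]
            variable_ids = [v.decode() for v in f["variable_ids"][:]]
    else:
        sep = "\t" if fmt == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        seen: set[str] = set()
        for name in header:
            if name in seen:
                raise ValueError(f"duplicate variable id: {name!r}")
            seen.add(name)
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise ValueError(f"non-numeric cells in columns: {bad[:10]}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy(dtype=np.float64)
        sample_ids = [str(i) for i in df.index]
        variable_ids = [str(c) for c in df.columns]
    if np.isnan(values).any():
        bad_cols = [variable_ids[j] for j in
                    np.flatnonzero(np.isnan(values).any(axis=0))[:10]]
        raise ValueError(f"missing values in columns: {bad_cols}")
    role = dtype_role or _infer_dtype_role(values)
    logger.info("loaded %s: %d samples × %d variables (%s)",
                path.name, values.shape[0], values.shape[1], role)
    return DataBlock(values=values, sample_ids=sample_ids,
                     variable_ids=variable_ids, dtype_role=role)


def save_matrix(block: DataBlock, path, fmt: str | None = None) -> Path:
    """Write a DataBlock; inverse of :func:`load_matrix`."""
    path = Path(path)
    fmt = fmt or {".tsv": "tsv", ".csv": "csv", ".h5": "h5", ".hdf5": "h5"}.get(
        path.suffix.lower(), "tsv")
    if fmt == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=block.values)
            f.create_dataset("sample_ids",
                             data=np.array(block.sample_ids, dtype="S"))
            f.create_dataset("variable_ids",
                             data=np.array(block.variable_ids, dtype="S"))
    else:
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(block.values, index=block.sample_ids,
                     columns=block.variable_ids).to_csv(path, sep=sep)
    return path


def save_truth(truth: SimulationTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(truth), indent=2))
    return path


def load_truth(path) -> SimulationTruth:
    return SimulationTruth(**json.loads(Path(path).read_text()))


def save_weights(variable_ids, weights: np.ndarray, path) -> Path:
    """Weight table: variable_id, one column per component."""
    df = pd.DataFrame(weights, index=variable_ids,
                      columns=[f"component_{i + 1}" for i in range(weights.shape[1])])
    df.index.name = "variable_id"
    df.to_csv(path, sep="\t")
    return Path(path)


def _digest(block: DataBlock) -> str:
    return hashlib.sha256(np.ascontiguousarray(block.values).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "scenario": "pheno_high",
    "n_samples": 100,
    "d1": None,            # scenario default
    "d2": None,
    "target_r": None,  # scenario default
    "data_seed": 0,
    "rp_seed": 1,
    "rp_seed2": 2,
    "perm_seed": 3,
    "cv_seed": 4,
    "reduce": "x1",        # x1 | x2 | both | none
    "k": "auto",           # integer or "auto" (ceil of the Menon bound)
    "epsilon": 1.0,
    "success_prob": 0.95,
    "orthogonalize": "auto",
    "components": "var80",  # integer or "var80"
    "n_permutations": 199,
}


def _resolve_components(value) -> dict:
    if value == "var80":
        return {"n_components": None, "variance_target": 0.80}
    return {"n_components": int(value), "variance_target": None}


def run_pipeline(config: dict, out_dir) -> Path:
    """Simulate → standardize → fit exact + PLSC-RP → select → permute → compare.

    Writes matrices, weight tables, a similarity report, a permutation
    table, the truth sidecar and a manifest into ``out_dir``; every stage
    seeds its own generator from the config, so the run is reproducible.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    pheno, geno, truth = make_scenario(
        cfg["scenario"], n_samples=cfg["n_samples"], d1=cfg["d1"], d2=cfg["d2"],
        target_correlation=cfg["target_r"], seed=cfg["data_seed"])
    save_matrix(pheno, out / "phenotypes.tsv")
    save_matrix(geno, out / "genotypes.tsv")
    save_truth(truth, out / "truth.json")

    b1 = standardize(pheno)
    b2 = standardize(geno)
    comp = _resolve_components(cfg["components"])

    beta = beta_from_success(cfg["n_samples"], cfg["success_prob"])
    plan = menon_dimension(cfg["n_samples"], cfg["epsilon"], beta,
                           chosen_k=None if cfg["k"] == "auto" else int(cfg["k"]))
    ortho = None if cfg["orthogonalize"] == "auto" else cfg["orthogonalize"] in (True, "on")

    exact = plsc_fit(b1, b2, **comp)
    if cfg["reduce"] == "none":
        rp = None
    elif cfg["reduce"] == "both":
        rp = fit_reduce_both(b1, b2, plan, plan, seed1=cfg["rp_seed"],
                             seed2=cfg["rp_seed2"], orthogonalize=ortho, **comp)
        spec = FitSpec(method="rp_both", plan=plan, plan2=plan,
                       rp_seed=cfg["rp_seed"], rp_seed2=cfg["rp_seed2"],
                       orthogonalize=ortho, **comp)
    else:
        side = "block1" if cfg["reduce"] == "x1" else "block2"
        rp = fit_reduce_one(b1, b2, side, plan, seed=cfg["rp_seed"],
                            orthogonalize=ortho, **comp)
        spec = FitSpec(method="rp_one", reduce_side=side, plan=plan,
                       rp_seed=cfg["rp_seed"], orthogonalize=ortho, **comp)

    causal_idx, oos = select_component(b1, b2, folds=10, seed=cfg["cv_seed"], **comp)

    save_weights(b1.variable_ids, exact.weights_1, out / "weights_x1_plsc.tsv")
    save_weights(b2.variable_ids, exact.weights_2, out / "weights_x2_plsc.tsv")
    report: dict = {
        "version": __version__,
        "config": cfg,
        "plan": {"k": plan.k, "k0": plan.k_min, "epsilon": plan.epsilon,
                 "beta": plan.beta},
        "input_digests": {"phenotypes": _digest(pheno), "genotypes": _digest(geno)},
        "causal_component": causal_idx + 1,
        "out_of_sample_covariance": oos.tolist(),
        "singular_values_plsc": exact.singular_values.tolist(),
        "explained_fraction_plsc": exact.explained_fraction.tolist(),
    }
    if rp is not None:
        save_weights(b1.variable_ids, rp.weights_1_original, out / "weights_x1_rp.tsv")
        save_weights(b2.variable_ids, rp.weights_2_original, out / "weights_x2_rp.tsv")
        c = min(causal_idx, rp.n_components - 1, exact.n_components - 1)
        sim1 = compare_weights((exact.weights_1, exact.weights_2),
                               (rp.weights_1_original, rp.weights_2_original),
                               component=c, block=1)
        sim2 = compare_weights((exact.weights_1, exact.weights_2),
                               (rp.weights_1_original, rp.weights_2_original),
                               component=c, block=2)
        perm = permutation_test(b1, b2, spec, n_permutations=cfg["n_permutations"],
                                seed=cfg["perm_seed"])
        rec = recovery_score(rp.weights_2_original[:, c],
                             truth.causal_genotype_indices, top_fraction=0.1)
        report.update({
            "singular_values_rp": rp.singular_values.tolist(),
            "similarity_x1": dataclasses.asdict(sim1),
            "similarity_x2": dataclasses.asdict(sim2),
            "permutation_p_values": perm.p_values.tolist(),
            "snp_recovery": rec,
        })
    report["elapsed_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline finished in %.1fs → %s", report["elapsed_seconds"], out)
    return out
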