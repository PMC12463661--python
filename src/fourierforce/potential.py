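"""The deployable trained potential: prediction, evaluation, persistence.

A trained potential bundles the descriptor spec, the per-species
standardizer, the frozen random-feature map, the learned weight vector and
the per-species energy baseline.  Energy is the baseline plus the pooled
feature dot product; forces are the exact analytic negative gradient, so
the model is a conservative force field by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .descriptors import (DescriptorSpec, Standardizer, compute_descriptors,
                          fit_standardizer)
from .random_features import RandomFeatureMap, build_feature_map, featurize
from .solver import (DEFAULT_ALPHAS, DEFAULT_LAMBDAS, GridSearchResult,
                     LossHyperparameters, accumulate_statistics, baseline_energy,
                     config_design_rows, fit_energy_baseline, grid_search,
                     solve_weights)
from .structures_io import AtomicConfiguration

__all__ = [
    "TrainedPotential",
    "EvaluationReport",
    "fit_potential",
    "predict_energy",
    "predict_forces",
    "predict",
    "evaluate",
    "save_potential",
    "load_potential",
]

_FORMAT_VERSION = 1


@dataclass
class TrainedPotential:
    """A complete random-feature interatomic potential."""

    spec: DescriptorSpec
    standardizer: Standardizer
    feature_map: RandomFeatureMap
    weights: np.ndarray
    baseline: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_map.dimension != self.spec.dimension:
            raise ValueError("feature map dimension does not match descriptor spec")
        if self.weights.shape != (self.feature_map.n_features,):
            raise ValueError("weight vector length does not match feature count")

    # calculator-style adapter for external MD engines
    def get_energy(self, config: AtomicConfiguration) -> float:
        return predict_energy(config, self)

    def get_forces(self, config: AtomicConfiguration) -> np.ndarray:
        return predict_forces(config, self)


@dataclass
class EvaluationReport:
    """Error metrics in the field's reporting units.

    Energy errors are per atom (residual divided by the frame's atom count
    before aggregation), in meV/atom; force errors are pooled over all
    Cartesian components, in meV/Angstrom.
    """

    energy_rmse: float
    energy_mae: float
    force_rmse: float
    force_mae: float
    n_configs: int
    n_atoms: int


def predict_energy(config: AtomicConfiguration, potential: TrainedPotential) -> float:
    """Baseline energy plus pooled-feature dot product, eV."""
    res = compute_descriptors(config, potential.spec)
    from .descriptors import standardize
    Z = standardize(res.H, config.species, potential.standardizer)
    phibar = featurize(Z, potential.feature_map).sum(axis=0)
    return baseline_energy(config, potential.baseline) + float(phibar @ potential.weights)


def predict_forces(config: AtomicConfiguration, potential: TrainedPotential) -> np.ndarray:
    """Exact negative gradient of :func:`predict_energy`, eV/Angstrom."""
    return predict(config, potential)[1]


def predict(config: AtomicConfiguration,
            potential: TrainedPotential) -> tuple[float, np.ndarray]:
    """Energy and forces in one descriptor+Jacobian pass."""
    rows = config_design_rows(config, potential.spec, potential.standardizer,
                              potential.feature_map)
    energy = baseline_energy(config, potential.baseline) + float(rows.phibar @ potential.weights)
    forces = (-rows.G @ potential.weights).reshape(config.n_atoms, 3)
    return energy, forces


def evaluate(configs, potential: TrainedPotential) -> EvaluationReport:
    """RMSE/MAE on a labeled set, meV/atom for energy, meV/Angstrom for forces."""
    e_res, f_res = [], []
    n_atoms = 0
    for t, cfg in enumerate(configs):
        if cfg.energy is None or cfg.forces is None:
            raise ValueError(f"configuration {t} lacks energy/force labels")
        energy, forces = predict(cfg, potential)
        e_res.append((energy - cfg.energy) / cfg.n_atoms)
        f_res.append((forces - cfg.forces).ravel())
        n_atoms += cfg.n_atoms
    if not e_res:
        raise ValueError("no labeled configurations to evaluate")
    e = np.asarray(e_res) * 1e3   # eV/atom -> meV/atom
    f = np.concatenate(f_res) * 1e3  # eV/A -> meV/A
    return EvaluationReport(
        energy_rmse=float(np.sqrt(np.mean(e ** 2))),
        energy_mae=float(np.mean(np.abs(e))),
        force_rmse=float(np.sqrt(np.mean(f ** 2))),
        force_mae=float(np.mean(np.abs(f))),
        n_configs=len(e_res),
        n_atoms=n_atoms,
    )


# ---------------------------------------------------------------------------
# end-to-end training
# ---------------------------------------------------------------------------

def fit_potential(train_configs, val_configs=None, *,
                  spec: DescriptorSpec | None = None,
                  n_features: int = 1024, sigmas=None, seed: int = 0,
                  scheme: str = "orthogonal",
                  alphas=None, lambdas=None,
                  hyperparameters: LossHyperparameters | None = None,
                  ) -> tuple[TrainedPotential, list[dict]]:
    """Train a potential end to end.

    Fits the per-species baseline and standardizer on the training split,
    builds the (frozen) feature map from ``seed``, then either solves once at
    fixed ``hyperparameters`` or grid-searches (alpha, lambda) against the
    validation split.  Returns the potential and the grid-search table.
    """
    train_configs = list(train_configs)
    if not train_configs:
        raise ValueError("empty training set")
    if spec is None:
        vocab = tuple(sorted({s for c in train_configs for s in c.species}))
        spec = DescriptorSpec.default(vocab)

    H_rows, tags = [], []
    for cfg in train_configs:
        H_rows.append(compute_descriptors(cfg, spec).H)
        tags.extend(cfg.species)
    standardizer = fit_standardizer(np.vstack(H_rows), tags, spec.species)
    baseline = fit_energy_baseline(train_configs)
    fmap = build_feature_map(spec.dimension, n_features, sigmas=sigmas,
                             seed=seed, scheme=scheme)

    if hyperparameters is not None:
        stats = accumulate_statistics(train_configs, spec, standardizer, fmap,
                                      baseline=baseline)
        weights = solve_weights(stats, hyperparameters)
        hp, table = hyperparameters, []
    else:
        if val_configs is None:
            raise ValueError("grid search needs a validation split "
                             "(or pass fixed hyperparameters)")
        result = grid_search(train_configs, val_configs, spec, standardizer,
                             fmap, baseline=baseline, alphas=alphas, lambdas=lambdas)
        hp, weights, table = result.best, result.weights, result.table

    metadata = {
        "seed": int(seed),
        "n_features": int(n_features),
        "sigmas": list(fmap.sigmas),
        "alpha": hp.alpha,
        "lambda": hp.lam,
        "n_train": len(train_configs),
        "n_val": 0 if val_configs is None else len(list(val_configs)),
        "scheme": scheme,
    }
    potential = TrainedPotential(spec=spec, standardizer=standardizer,
                                 feature_map=fmap, weights=weights,
                                 baseline=baseline, metadata=metadata)
    return potential, table


# ---------------------------------------------------------------------------
# persistence (single .npz archive, versioned)
# ---------------------------------------------------------------------------

def save_potential(potential: TrainedPotential, path: str | Path) -> None:
    """Serialize to a single versioned archive; predictions round-trip bitwise."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "spec": {
            "cutoff": potential.spec.cutoff,
            "centers": list(potential.spec.centers),
            "eta": potential.spec.eta,
            "species": list(potential.spec.species),
        },
        "baseline": potential.baseline,
        "metadata": potential.metadata,
        "std_species": list(potential.standardizer.species),
    }
    arrays: dict[str, np.ndarray] = {
        "weights": potential.weights,
        "meta_json": np.asarray(json.dumps(meta)),
    }
    arrays.update(potential.feature_map.to_arrays())
    for s in potential.standardizer.species:
        arrays[f"std_mean_{s}"] = potential.standardizer.means[s]
        arrays[f"std_scale_{s}"] = potential.standardizer.scales[s]
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_potential(path: str | Path) -> TrainedPotential:
    """Load a saved potential, refusing unknown format versions."""
    try:
        payload = np.load(path, allow_pickle=False)
        meta = json.loads(str(payload["meta_json"]))
    except Exception as exc:
        raise ValueError(f"cannot read potential archive {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported potential format version {version!r} "
                         f"(expected {_FORMAT_VERSION})")
    spec = DescriptorSpec(
        cutoff=float(meta["spec"]["cutoff"]),
        centers=tuple(float(c) for c in meta["spec"]["centers"]),
        eta=float(meta["spec"]["eta"]),
        species=tuple(meta["spec"]["species"]),
    )
    std = Standardizer(
        species=tuple(meta["std_species"]),
        means={s: np.asarray(payload[f"std_mean_{s}"]) for s in meta["std_species"]},
        scales={s: np.asarray(payload[f"std_scale_{s}"]) for s in meta["std_species"]},
    )
    return TrainedPotential(
        spec=spec,
        standardizer=std,
        feature_map=RandomFeatureMap.from_arrays(payload),
        weights=np.asarray(payload["weights"]),
        baseline={k: float(v) for k, v in meta["baseline"].items()},
        metadata=meta["metadata"],
    )
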