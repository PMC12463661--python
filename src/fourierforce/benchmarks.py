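"""The standard desk-scale Lennard-Jones benchmark used across the test suite.

Argon-parameterized LJ clusters (8 atoms, jittered fcc-like lattice sites)
with exact analytic labels; the interaction cutoff matches the descriptor
cutoff so the two-body model class can represent the target almost exactly,
which makes recovery a sharp test of the regression machinery rather than of
descriptor expressivity.
"""

from __future__ import annotations

import numpy as np

from .descriptors import DescriptorSpec
from .potential import TrainedPotential, evaluate, fit_potential
from .synthetic_data import PairPotentialParams, generate_cluster_dataset

__all__ = [
    "LJ_ARGON",
    "lj_benchmark_spec",
    "lj_benchmark_dataset",
    "train_lj_benchmark",
]

#: Argon Lennard-Jones parameters (epsilon = 10.4 meV, sigma = 3.4 Angstrom),
#: truncated and shifted at 5 Angstrom to match the descriptor cutoff.
LJ_ARGON = PairPotentialParams(
    family="lennard-jones",
    pairs={("Ar", "Ar"): {"epsilon": 0.0104, "sigma": 3.40}},
    cutoff=5.0,
)


def lj_benchmark_spec() -> DescriptorSpec:
    """Radial centers span the thermally sampled distance range [2.5, 5] A;
    centers deep inside the repulsive wall would be dead channels."""
    return DescriptorSpec(cutoff=5.0, centers=tuple(np.linspace(2.5, 5.0, 8)),
                          eta=0.3125, species=("Ar",))


def lj_benchmark_dataset(n_configs: int, seed: int, n_atoms: int = 8,
                         jitter: float = 0.4, min_distance: float = 3.0):
    """Labeled LJ argon clusters; reproducible from the seed.

    The jitter amplitude is a Lindemann-scale fraction of the lattice spacing
    (strong thermal disorder, melt-adjacent); the minimum pair distance is
    roughly the thermally accessible closest approach of the argon dimer.
    """
    return generate_cluster_dataset(
        n_configs=n_configs, n_atoms=n_atoms, species=["Ar"], params=LJ_ARGON,
        jitter=jitter, min_distance=min_distance, seed=seed)


def train_lj_benchmark(n_train: int = 64, n_val: int = 32, *,
                       n_features: int = 1024, sigmas=None, seed: int = 0,
                       alphas=None, lambdas=None,
                       ) -> tuple[TrainedPotential, float]:
    """Train on the standard split and return (potential, validation force RMSE).

    Train and validation sets come from disjoint generator seeds derived
    from ``seed``; the same seed also fixes the random feature map.
    """
    train = lj_benchmark_dataset(n_train, seed=2 * seed + 1)
    val = lj_benchmark_dataset(n_val, seed=2 * seed + 2)
    potential, _ = fit_potential(train, val, spec=lj_benchmark_spec(),
                                 n_features=n_features, sigmas=sigmas, seed=seed,
                                 alphas=alphas, lambdas=lambdas)
    report = evaluate(val, potential)
    return potential, report.force_rmse
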