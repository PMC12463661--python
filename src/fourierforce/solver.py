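"""Closed-form training of the random-feature potential on energies and forces.

The model is linear in the pooled feature vector: the predicted total energy
of a configuration is E(R; w) = phibar(R)^T w with phibar = sum_n phi_n, and
predicted forces are the exact negative gradient, F = -G w, where
G[(m, k), r] = d phibar_r / d positions[m, k].  Training minimizes the convex
combined loss

    l_alpha(w) = (1 - alpha) sum_t (phibar_t^T w - E_t)^2
               + alpha       sum_t || G_t w + vec(F_t) ||^2
               + lambda ||w||^2,

whose unique global minimizer solves the D x D normal equations

    [(1 - alpha) C_E + alpha C_F + lambda I] w = (1 - alpha) b_E + alpha b_F

with C_E = sum phibar phibar^T, b_E = sum E_t phibar, C_F = sum G^T G and
b_F = -sum G^T vec(F_t).  The statistics are accumulated in a single
streaming pass and are additive over dataset partitions, so hyperparameter
grid search reuses one accumulation for every (alpha, lambda) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .descriptors import (DescriptorSpec, Standardizer, compute_descriptor_jacobian,
                          scale_jacobian, standardize)
from .random_features import RandomFeatureMap, featurize, featurize_jacobian
from .structures_io import AtomicConfiguration

__all__ = [
    "DEFAULT_ALPHAS",
    "DEFAULT_LAMBDAS",
    "ConfigDesignRows",
    "RegressionStatistics",
    "LossHyperparameters",
    "GridSearchResult",
    "fit_energy_baseline",
    "baseline_energy",
    "config_design_rows",
    "accumulate_statistics",
    "solve_weights",
    "grid_search",
]

#: Default force-weight grid for the combined loss.
DEFAULT_ALPHAS: tuple[float, ...] = (0.01, 0.5, 0.99)
#: Default ridge-strength grid (six decades).
DEFAULT_LAMBDAS: tuple[float, ...] = (1e-6, 1e-7, 1e-8, 1e-9, 1e-10, 1e-11)

# streaming-accumulation call counter (introspection for efficiency contracts)
_n_accumulate_calls = 0


@dataclass(frozen=True)
class LossHyperparameters:
    """alpha in [0, 1] weights forces against energies; lambda > 0 is the ridge."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class ConfigDesignRows:
    """Design rows of one configuration: pooled features and force design.

    phibar : (D,) column sum of the per-atom feature matrix.
    G : (3N, D) with G[3m + k, r] = d phibar_r / d positions[m, k].
    """

    phibar: np.ndarray
    G: np.ndarray


@dataclass
class RegressionStatistics:
    """Streaming sufficient statistics of the combined quadratic loss."""

    C_E: np.ndarray
    b_E: np.ndarray
    C_F: np.ndarray
    b_F: np.ndarray
    n_configs: int = 0
    n_atoms: int = 0

    @staticmethod
    def zeros(D: int) -> "RegressionStatistics":
        return RegressionStatistics(
            C_E=np.zeros((D, D)), b_E=np.zeros(D),
            C_F=np.zeros((D, D)), b_F=np.zeros(D),
        )

    def __add__(self, other: "RegressionStatistics") -> "RegressionStatistics":
        return RegressionStatistics(
            C_E=self.C_E + other.C_E, b_E=self.b_E + other.b_E,
            C_F=self.C_F + other.C_F, b_F=self.b_F + other.b_F,
            n_configs=self.n_configs + other.n_configs,
            n_atoms=self.n_atoms + other.n_atoms,
        )


# ---------------------------------------------------------------------------
# per-species energy baseline
# ---------------------------------------------------------------------------

def fit_energy_baseline(configs: list[AtomicConfiguration]) -> dict[str, float]:
    """Least-squares fit of total energies on per-species atom counts.

    Returns per-species offsets (eV/atom of that species); the regression
    head is then trained on baseline-subtracted residual energies.  Forces
    are unaffected by any per-species constant.  The minimum-norm solution
    is taken when the count matrix is rank deficient (e.g. all configurations
    share the same composition).
    """
    labeled = [c for c in configs if c.energy is not None]
    if not labeled:
        raise ValueError("no energy labels to fit a baseline on")
    species = sorted({s for c in labeled for s in c.species})
    counts = np.array([[c.species.count(s) for s in species] for c in labeled],
                      dtype=float)
    energies = np.array([c.energy for c in labeled])
    offsets, *_ = np.linalg.lstsq(counts, energies, rcond=None)
    return dict(zip(species, (float(o) for o in offsets)))


def baseline_energy(config: AtomicConfiguration, offsets: dict[str, float]) -> float:
    """Sum of per-species offsets over the configuration's composition."""
    return float(sum(offsets.get(s, 0.0) for s in config.species))


# ---------------------------------------------------------------------------
# design rows and statistics
# ---------------------------------------------------------------------------

def config_design_rows(config: AtomicConfiguration, spec: DescriptorSpec,
                       standardizer: Standardizer,
                       fmap: RandomFeatureMap) -> ConfigDesignRows:
    """Pooled feature vector and its position Jacobian for one configuration.

    Chains descriptor Jacobian -> standardization scaling -> feature-map
    Jacobian, all analytic.
    """
    res = compute_descriptor_jacobian(config, spec)
    Z = standardize(res.H, config.species, standardizer)
    Jz = scale_jacobian(res.J, config.species, standardizer)  # (N, d, N, 3)
    Phi = featurize(Z, fmap)                                   # (N, D)
    B = featurize_jacobian(Z, fmap)                            # (N, D, d)
    phibar = Phi.sum(axis=0)
    n = config.n_atoms
    # G[(m,k), r] = sum_{n,i} B[n, r, i] * Jz[n, i, m, k]
    G = np.einsum("nri,nimk->mkr", B, Jz, optimize=True).reshape(3 * n, -1)
    return ConfigDesignRows(phibar=phibar, G=G)


def accumulate_statistics(configs, spec: DescriptorSpec, standardizer: Standardizer,
                          fmap: RandomFeatureMap,
                          baseline: dict[str, float] | None = None,
                          with_forces: bool = True) -> RegressionStatistics:
    """Single streaming pass over a labeled dataset.

    The result is independent of dataset order and of partitioning: the
    statistics of a concatenation equal the elementwise sum of the parts.
    """
    global _n_accumulate_calls
    _n_accumulate_calls += 1
    stats = RegressionStatistics.zeros(fmap.n_features)
    for t, cfg in enumerate(configs):
        if cfg.energy is None:
            raise ValueError(f"configuration {t} lacks an energy label")
        rows = config_design_rows(cfg, spec, standardizer, fmap)
        resid = cfg.energy - (baseline_energy(cfg, baseline) if baseline else 0.0)
        stats.C_E += np.outer(rows.phibar, rows.phibar)
        stats.b_E += resid * rows.phibar
        if with_forces:
            if cfg.forces is None:
                raise ValueError(f"configuration {t} lacks force labels")
            stats.C_F += rows.G.T @ rows.G
            stats.b_F += -rows.G.T @ cfg.forces.ravel()
        stats.n_configs += 1
        stats.n_atoms += cfg.n_atoms
    return stats


def solve_weights(stats: RegressionStatistics,
                  hp: LossHyperparameters) -> np.ndarray:
    """Solve the combined normal equations by Cholesky factorization.

    The system matrix is symmetric positive definite for lambda > 0; a single
    jittered retry (10x lambda) covers borderline conditioning, after which a
    failure asks for a larger ridge.
    """
    a, lam = hp.alpha, hp.lam
    A = (1.0 - a) * stats.C_E + a * stats.C_F
    rhs = (1.0 - a) * stats.b_E + a * stats.b_F
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(rhs))):
        raise ValueError("non-finite regression statistics")
    D = A.shape[0]
    for ridge in (lam, 10.0 * lam):
        M = A + ridge * np.eye(D)
        try:
            cf = scipy.linalg.cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            continue
        w = scipy.linalg.cho_solve(cf, rhs)
        # one step of iterative refinement recovers accuracy lost to
        # conditioning when lambda is many orders below the top eigenvalue
        w += scipy.linalg.cho_solve(cf, rhs - M @ w)
        return w
    raise np.linalg.LinAlgError(
        "normal equations could not be factorized; increase lambda")


# ---------------------------------------------------------------------------
# hyperparameter grid search with covariance reuse
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best: LossHyperparameters
    weights: np.ndarray
    table: list[dict]


def grid_search(train_configs, val_configs, spec: DescriptorSpec,
                standardizer: Standardizer, fmap: RandomFeatureMap,
                baseline: dict[str, float] | None = None,
                alphas=None, lambdas=None) -> GridSearchResult:
    """Exhaustive (alpha, lambda) search reusing one statistics accumulation.

    Training statistics and validation design rows are each computed once;
    every grid point costs only a D x D solve plus the validation metric.
    Selection minimizes validation force RMSE; ties break toward larger
    lambda (more regularization).
    """
    alphas = DEFAULT_ALPHAS if alphas is None else tuple(alphas)
    lambdas = DEFAULT_LAMBDAS if lambdas is None else tuple(lambdas)
    if not alphas or not lambdas:
        raise ValueError("empty hyperparameter grid")
    stats = accumulate_statistics(train_configs, spec, standardizer, fmap,
                                  baseline=baseline)

    val_rows = [config_design_rows(c, spec, standardizer, fmap) for c in val_configs]
    val_forces = []
    val_eresid = []
    for t, c in enumerate(val_configs):
        if c.forces is None or c.energy is None:
            raise ValueError(f"validation configuration {t} lacks labels")
        val_forces.append(c.forces.ravel())
        val_eresid.append(c.energy - (baseline_energy(c, baseline) if baseline else 0.0))

    table: list[dict] = []
    best_key = None
    best: tuple[LossHyperparameters, np.ndarray] | None = None
    for a in alphas:
        for lam in lambdas:
            hp = LossHyperparameters(alpha=a, lam=lam)
            w = solve_weights(stats, hp)
            f_se, f_n, e_se = 0.0, 0, 0.0
            for rows, fvec, eres in zip(val_rows, val_forces, val_eresid):
                df = (-rows.G @ w) - fvec
                f_se += float(df @ df)
                f_n += df.size
                e_se += float((rows.phibar @ w - eres) ** 2)
            force_rmse = np.sqrt(f_se / f_n)
            energy_rmse = np.sqrt(e_se / len(val_rows))
            table.append({"alpha": a, "lambda": lam,
                          "val_force_rmse": force_rmse,
                          "val_energy_rmse": energy_rmse})
            key = (force_rmse, -lam)  # ties: prefer larger lambda
            if best_key is None or key < best_key:
                best_key, best = key, (hp, w)
    hp, w = best
    return GridSearchResult(best=hp, weights=w, table=table)
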