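"""Normal-equation assembly, closed-form optimality, and grid search."""

import numpy as np
import pytest

import fourierforce.solver as solver
from fourierforce import benchmarks
from fourierforce.descriptors import compute_descriptors, fit_standardizer
from fourierforce.random_features import build_feature_map
from fourierforce.solver import (DEFAULT_ALPHAS, DEFAULT_LAMBDAS,
                                 LossHyperparameters, RegressionStatistics,
                                 accumulate_statistics, baseline_energy,
                                 config_design_rows, fit_energy_baseline,
                                 grid_search, solve_weights)
from fourierforce.structures_io import AtomicConfiguration


@pytest.fixture(scope="module")
def pipeline():
    """Small shared pipeline: spec, standardizer, map, baseline, datasets."""
    spec = benchmarks.lj_benchmark_spec()
    train = benchmarks.lj_benchmark_dataset(10, seed=51, n_atoms=6)
    val = benchmarks.lj_benchmark_dataset(5, seed=52, n_atoms=6)
    H, tags = [], []
    for c in train:
        H.append(compute_descriptors(c, spec).H)
        tags.extend(c.species)
    std = fit_standardizer(np.vstack(H), tags, spec.species)
    fmap = build_feature_map(spec.dimension, 64, sigmas=(4.0, 8.0), seed=5)
    baseline = fit_energy_baseline(train)
    return spec, std, fmap, baseline, train, val


def stacked_lstsq_oracle(rows_list, configs, baseline, alpha, lam, D):
    """Explicit weighted ridge design matrix solved by lstsq."""
    X, y = [], []
    for rows, cfg in zip(rows_list, configs):
        e = cfg.energy - baseline_energy(cfg, baseline)
        X.append(np.sqrt(1 - alpha) * rows.phibar[None, :])
        y.append([np.sqrt(1 - alpha) * e])
        X.append(np.sqrt(alpha) * rows.G)
        y.append(-np.sqrt(alpha) * cfg.forces.ravel())
    X.append(np.sqrt(lam) * np.eye(D))
    y.append(np.zeros(D))
    w, *_ = np.linalg.lstsq(np.vstack(X), np.concatenate(y), rcond=None)
    return w


class TestEnergyBaseline:
    def test_exact_linear_composition_recovered(self):
        def make(nA, nB):
            n = nA + nB
            pos = np.arange(3 * n, dtype=float).reshape(n, 3) * 10
            return AtomicConfiguration(pos, ["A"] * nA + ["B"] * nB,
                                       energy=2.0 * nA - 1.0 * nB)
        configs = [make(1, 2), make(3, 1), make(2, 2)]
        offsets = fit_energy_baseline(configs)
        assert offsets["A"] == pytest.approx(2.0, abs=1e-12)
        assert offsets["B"] == pytest.approx(-1.0, abs=1e-12)
        for c in configs:
            assert c.energy - baseline_energy(c, offsets) == pytest.approx(0, abs=1e-10)

    def test_single_species_minimum_norm(self, rng):
        # all configs share atom count: count matrix rank 1, pinv solution
        energies = rng.normal(-3.0, 0.5, 6)
        configs = [AtomicConfiguration(np.eye(4, 3) * 40 + i, ["Ar"] * 4, energy=e)
                   for i, e in enumerate(energies)]
        offsets = fit_energy_baseline(configs)
        counts = np.full((6, 1), 4.0)
        expected = float((np.linalg.pinv(counts) @ energies)[0])
        assert offsets["Ar"] == pytest.approx(expected, rel=1e-12)

    def test_residuals_orthogonal_to_counts(self, pipeline):
        *_, baseline, train, _ = pipeline
        res = np.array([c.energy - baseline_energy(c, baseline) for c in train])
        counts = np.array([[c.species.count("Ar")] for c in train])
        np.testing.assert_allclose(counts.T @ res, 0.0, atol=1e-9)

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            fit_energy_baseline([AtomicConfiguration([[0, 0, 0]], ["Ar"])])


class TestDesignRows:
    def test_single_atom_config(self, pipeline):
        spec, std, fmap, *_ = pipeline
        cfg = AtomicConfiguration([[1.0, 2.0, 3.0]], ["Ar"])
        rows = config_design_rows(cfg, spec, std, fmap)
        assert rows.phibar.shape == (64,)
        np.testing.assert_array_equal(rows.G, np.zeros((3, 64)))

    def test_G_matches_finite_differences_of_phibar(self, pipeline):
        spec, std, fmap, _, train, _ = pipeline
        cfg = train[0]
        rows = config_design_rows(cfg, spec, std, fmap)
        h = 1e-5
        for m in range(0, cfg.n_atoms, 2):
            for k in range(3):
                p1 = cfg.positions.copy(); p1[m, k] += h
                p2 = cfg.positions.copy(); p2[m, k] -= h
                f1 = config_design_rows(AtomicConfiguration(p1, cfg.species),
                                        spec, std, fmap).phibar
                f2 = config_design_rows(AtomicConfiguration(p2, cfg.species),
                                        spec, std, fmap).phibar
                np.testing.assert_allclose(rows.G[3 * m + k], (f1 - f2) / (2 * h),
                                           atol=1e-6)

    def test_translation_nullity_of_G(self, pipeline):
        spec, std, fmap, _, train, _ = pipeline
        rows = config_design_rows(train[1], spec, std, fmap)
        G3 = rows.G.reshape(train[1].n_atoms, 3, -1)
        np.testing.assert_allclose(G3.sum(axis=0), 0.0, atol=1e-10)

    def test_permutation_consistency(self, pipeline, rng):
        spec, std, fmap, _, train, _ = pipeline
        cfg = train[2]
        perm = rng.permutation(cfg.n_atoms)
        permuted = AtomicConfiguration(cfg.positions[perm],
                                       [cfg.species[p] for p in perm])
        a = config_design_rows(cfg, spec, std, fmap)
        b = config_design_rows(permuted, spec, std, fmap)
        np.testing.assert_allclose(b.phibar, a.phibar, atol=1e-12)
        Ga = a.G.reshape(cfg.n_atoms, 3, -1)
        Gb = b.G.reshape(cfg.n_atoms, 3, -1)
        np.testing.assert_allclose(Gb, Ga[perm], atol=1e-12)


class TestStatistics:
    def test_additivity_and_order_invariance(self, pipeline, rng):
        spec, std, fmap, baseline, train, _ = pipeline
        whole = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        part = (accumulate_statistics(train[:4], spec, std, fmap, baseline=baseline)
                + accumulate_statistics(train[4:], spec, std, fmap, baseline=baseline))
        shuffled = list(train)
        rng.shuffle(shuffled)
        shuf = accumulate_statistics(shuffled, spec, std, fmap, baseline=baseline)
        for a, b in ((whole, part), (whole, shuf)):
            np.testing.assert_allclose(a.C_E, b.C_E, atol=1e-10)
            np.testing.assert_allclose(a.C_F, b.C_F, atol=1e-10)
            np.testing.assert_allclose(a.b_E, b.b_E, atol=1e-10)
            np.testing.assert_allclose(a.b_F, b.b_F, atol=1e-10)
        assert whole.n_configs == part.n_configs == len(train)

    def test_against_dense_design_oracle(self, pipeline):
        spec, std, fmap, baseline, train, _ = pipeline
        subset = train[:5]
        stats = accumulate_statistics(subset, spec, std, fmap, baseline=baseline)
        rows = [config_design_rows(c, spec, std, fmap) for c in subset]
        Phi = np.vstack([r.phibar for r in rows])
        E = np.array([c.energy - baseline_energy(c, baseline) for c in subset])
        Gall = np.vstack([r.G for r in rows])
        F = np.concatenate([c.forces.ravel() for c in subset])
        np.testing.assert_allclose(stats.C_E, Phi.T @ Phi, atol=1e-9)
        np.testing.assert_allclose(stats.b_E, Phi.T @ E, atol=1e-9)
        np.testing.assert_allclose(stats.C_F, Gall.T @ Gall, atol=1e-9)
        np.testing.assert_allclose(stats.b_F, -Gall.T @ F, atol=1e-9)

    def test_empty_dataset_gives_zeros(self, pipeline):
        spec, std, fmap, *_ = pipeline
        stats = accumulate_statistics([], spec, std, fmap)
        assert stats.n_configs == 0
        assert np.all(stats.C_E == 0) and np.all(stats.C_F == 0)

    def test_psd_symmetry(self, pipeline):
        spec, std, fmap, baseline, train, _ = pipeline
        stats = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        for C in (stats.C_E, stats.C_F):
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() > -1e-9

    def test_missing_force_labels_named(self, pipeline):
        spec, std, fmap, *_ = pipeline
        cfg = AtomicConfiguration([[0, 0, 0]], ["Ar"], energy=0.0)
        with pytest.raises(ValueError, match="0"):
            accumulate_statistics([cfg], spec, std, fmap)


class TestSolveWeights:
    def test_diagonal_closed_form(self):
        D = 8
        stats = RegressionStatistics.zeros(D)
        stats.C_E = np.eye(D)
        stats.b_E = np.eye(D)[0]
        w = solve_weights(stats, LossHyperparameters(alpha=0.0, lam=1.0))
        np.testing.assert_allclose(w, np.eye(D)[0] / 2.0, atol=1e-14)

    def test_matches_stacked_lstsq_oracle(self, pipeline):
        spec, std, fmap, baseline, train, _ = pipeline
        stats = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        rows = [config_design_rows(c, spec, std, fmap) for c in train]
        for alpha in (0.1, 0.5, 0.9):
            hp = LossHyperparameters(alpha=alpha, lam=1e-4)
            w = solve_weights(stats, hp)
            w_ref = stacked_lstsq_oracle(rows, train, baseline, alpha, 1e-4, 64)
            assert np.linalg.norm(w - w_ref) / np.linalg.norm(w_ref) < 1e-8

    def test_analytic_gradient_vanishes_at_solution(self, pipeline):
        spec, std, fmap, baseline, train, _ = pipeline
        stats = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        hp = LossHyperparameters(alpha=0.7, lam=1e-5)
        w = solve_weights(stats, hp)
        A = 0.3 * stats.C_E + 0.7 * stats.C_F + 1e-5 * np.eye(64)
        b = 0.3 * stats.b_E + 0.7 * stats.b_F
        assert np.linalg.norm(2 * (A @ w - b)) < 1e-8

    def test_perturbations_never_decrease_loss(self, pipeline, rng):
        spec, std, fmap, baseline, train, _ = pipeline
        stats = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        rows = [config_design_rows(c, spec, std, fmap) for c in train]
        hp = LossHyperparameters(alpha=0.5, lam=1e-4)
        w = solve_weights(stats, hp)

        def loss(wv):
            out = 1e-4 * wv @ wv
            for r, cfg in zip(rows, train):
                e = cfg.energy - baseline_energy(cfg, baseline)
                out += 0.5 * (r.phibar @ wv - e) ** 2
                out += 0.5 * np.sum((r.G @ wv + cfg.forces.ravel()) ** 2)
            return out

        base = loss(w)
        for _ in range(20):
            delta = rng.normal(size=64)
            delta *= 1e-3 / np.linalg.norm(delta)
            assert loss(w + delta) >= base - 1e-12

    def test_strong_ridge_shrinks_weights(self):
        D = 4
        stats = RegressionStatistics.zeros(D)
        stats.C_E = np.eye(D)
        stats.b_E = np.array([1.0, 0, 0, 0])
        w = solve_weights(stats, LossHyperparameters(alpha=0.0, lam=1e6))
        assert np.linalg.norm(w) <= 1.01e-6

    def test_nonfinite_statistics_rejected(self):
        stats = RegressionStatistics.zeros(3)
        stats.C_E[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            solve_weights(stats, LossHyperparameters(alpha=0.0, lam=1.0))

    def test_alpha_zero_and_one_paths(self, pipeline):
        spec, std, fmap, baseline, train, _ = pipeline
        stats = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        # alpha = 0: pure energy normal equations
        w0 = solve_weights(stats, LossHyperparameters(alpha=0.0, lam=1e-4))
        ref = np.linalg.solve(stats.C_E + 1e-4 * np.eye(64), stats.b_E)
        np.testing.assert_allclose(w0, ref, atol=1e-10)
        # alpha = 1: energies ignored entirely
        stats2 = RegressionStatistics(C_E=np.zeros((64, 64)), b_E=np.zeros(64),
                                      C_F=stats.C_F, b_F=stats.b_F)
        w1 = solve_weights(stats, LossHyperparameters(alpha=1.0, lam=1e-4))
        w1b = solve_weights(stats2, LossHyperparameters(alpha=1.0, lam=1e-4))
        np.testing.assert_allclose(w1, w1b, atol=1e-12)


class TestGridSearch:
    def test_default_grids(self):
        assert DEFAULT_ALPHAS == (0.01, 0.5, 0.99)
        assert DEFAULT_LAMBDAS == (1e-6, 1e-7, 1e-8, 1e-9, 1e-10, 1e-11)

    def test_single_point_grid(self, pipeline):
        spec, std, fmap, baseline, train, val = pipeline
        res = grid_search(train, val, spec, std, fmap, baseline=baseline,
                          alphas=[0.5], lambdas=[1e-5])
        assert res.best == LossHyperparameters(alpha=0.5, lam=1e-5)
        assert len(res.table) == 1

    def test_selection_minimizes_validation_force_rmse(self, pipeline):
        spec, std, fmap, baseline, train, val = pipeline
        res = grid_search(train, val, spec, std, fmap, baseline=baseline)
        assert len(res.table) == len(DEFAULT_ALPHAS) * len(DEFAULT_LAMBDAS)
        # exhaustive recomputation: chosen point attains the tabulated minimum
        best_row = min(res.table, key=lambda r: (r["val_force_rmse"], -r["lambda"]))
        assert res.best.alpha == best_row["alpha"]
        assert res.best.lam == best_row["lambda"]
        stats = accumulate_statistics(train, spec, std, fmap, baseline=baseline)
        w = solve_weights(stats, res.best)
        np.testing.assert_allclose(res.weights, w, atol=1e-12)

    def test_single_accumulation_regardless_of_grid_size(self, pipeline):
        spec, std, fmap, baseline, train, val = pipeline
        before = solver._n_accumulate_calls
        grid_search(train, val, spec, std, fmap, baseline=baseline)
        assert solver._n_accumulate_calls == before + 1

    def test_empty_grid_rejected(self, pipeline):
        spec, std, fmap, baseline, train, val = pipeline
        with pytest.raises(ValueError, match="empty"):
            grid_search(train, val, spec, std, fmap, alphas=[], lambdas=[1e-6])
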