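import numpy as np
import pytest
from scipy import linalg, optimize

import pathfactor as pf
from pathfactor.inference import (
    FitConfig,
    fit,
    infer_loadings,
    load_model,
    save_model,
    update_B,
    update_U,
    update_hyperparameters,
    update_scales,
)
from pathfactor.model import (
    FactorModel,
    ModalityData,
    gradients,
    hessians,
    neg_log_joint,
)
from pathfactor.genesets import PathwayMask

from conftest import make_random_model


class TestUpdateB:
    def test_zero_step_is_identity(self, small_model):
        out = update_B(small_model, step_size=0.0)
        np.testing.assert_array_equal(out.B, small_model.B)

    def test_full_step_zeroes_gradient(self, bimodal_model):
        out = update_B(bimodal_model, step_size=1.0)
        _, G_B = gradients(out)
        assert np.abs(G_B).max() < 1e-9 * max(1.0, np.abs(out.B).max())

    def test_matches_dense_kronecker_newton(self, rng):
        model = make_random_model(rng, m=8, p=4, k=2, n=3)
        pair = hessians(model)
        _, G_B = gradients(model)
        H_dense = np.kron(pair.A_B, np.eye(model.n_samples))
        expected = model.B.ravel() - 0.6 * np.linalg.solve(H_dense, G_B.ravel())
        out = update_B(model, pair, step_size=0.6)
        np.testing.assert_allclose(out.B.ravel(), expected, rtol=1e-10)


class TestUpdateU:
    def test_negative_entries_clamped_to_zero(self, rng):
        # force a step through zero with a strongly negative data pull
        model = make_random_model(rng)
        model.U = np.full_like(model.U, 0.01)
        mod = model.modalities[0]
        model.modalities[0] = ModalityData(
            -10 * np.abs(mod.Y), mod.mask, mod.sigma, mod.scale, mod.label
        )
        out = update_U(model, step_size=1.0)
        assert (out.U >= 0).all()
        assert (out.U == 0).any()

    def test_full_step_matches_linear_solve_when_interior(self, rng):
        model = make_random_model(rng)
        pair = hessians(model)
        G_U, _ = gradients(model)
        candidate = model.U.ravel() - np.linalg.solve(pair.H_U, G_U.ravel())
        if (candidate >= 0).all():  # interior: plain Newton
            out = update_U(model, pair, step_size=1.0)
            np.testing.assert_allclose(out.U.ravel(), candidate, rtol=1e-10)
            G_after, _ = gradients(out)
            assert np.abs(G_after).max() < 1e-8

    def test_prec_max_lambda_keeps_entry_pinned(self, small_model):
        model = small_model.copy()
        model.U[0, 0] = 0.0
        model.Lambda[0, 0] = FitConfig().prec_max
        out = update_U(model, step_size=1.0, prec_max=FitConfig().prec_max)
        assert out.U[0, 0] == 0.0

    def test_never_increases_objective(self, rng):
        for trial in range(5):
            model = make_random_model(np.random.default_rng(trial), bimodal=trial % 2 == 0)
            before = neg_log_joint(model)
            for gamma in (0.1, 0.5, 1.0):
                after = neg_log_joint(update_U(model, step_size=gamma))
                assert after <= before + 1e-8 * abs(before)


class TestUpdateHyperparameters:
    def test_matches_dense_inverse_reference(self, rng):
        model = make_random_model(rng, bimodal=True)
        pair = hessians(model)
        out = update_hyperparameters(model, pair)
        HU_inv = np.linalg.inv(pair.H_U)
        lam_ref = (1 - model.Lambda.ravel() * np.diag(HU_inv)) / model.U.ravel() ** 2
        lam_ref = np.clip(lam_ref.reshape(model.U.shape), 1e-6, 1e12)
        np.testing.assert_allclose(out.Lambda, lam_ref, rtol=1e-8)
        AB_inv = np.linalg.inv(pair.A_B)
        n = model.n_samples
        dlt_ref = np.clip(
            n * (1 - model.delta * np.diag(AB_inv)) / (model.B**2).sum(axis=1),
            1e-6,
            1e12,
        )
        np.testing.assert_allclose(out.delta, dlt_ref, rtol=1e-8)

    def test_zero_U_entry_prunes_to_prec_max(self, small_model):
        model = small_model.copy()
        model.U[1, 1] = 0.0
        out = update_hyperparameters(model, hessians(model))
        assert out.Lambda[1, 1] == FitConfig().prec_max

    def test_zero_residual_floors_sigma(self, rng):
        from test_model import zero_residual_model

        model, _ = zero_residual_model(rng)
        out = update_hyperparameters(model, hessians(model))
        floor = np.sqrt(FitConfig().sigma_floor)
        np.testing.assert_allclose(out.modalities[0].sigma, floor)

    @pytest.mark.parametrize("dof_mode", ["sbl", "as_printed"])
    def test_sigma_positive_even_when_pathways_exceed_samples(self, dof_mode):
        # adversarial p > n regime where a naive 'n - p' denominator goes negative
        rng = np.random.default_rng(7)
        model = make_random_model(rng, m=30, p=12, k=3, n=4)
        out = update_hyperparameters(model, hessians(model), dof_mode=dof_mode)
        for mod in out.modalities:
            assert (mod.sigma > 0).all()
            assert np.isfinite(mod.sigma).all()


class TestUpdateScales:
    def test_self_match_gives_unit_scale(self, rng):
        from test_model import zero_residual_model

        model, mod = zero_residual_model(rng)
        # Y built with scale 1.3, so the refit scale must return to 1.3
        out = update_scales(model)
        assert out.modalities[0].scale == pytest.approx(1.3)

    def test_doubled_observations_double_the_scale(self, rng):
        from test_model import zero_residual_model

        model, mod = zero_residual_model(rng)
        model.modalities[0] = ModalityData(2 * mod.Y, mod.mask, mod.sigma, mod.scale)
        out = update_scales(model)
        assert out.modalities[0].scale == pytest.approx(2 * 1.3)

    def test_matches_1d_numeric_minimization(self, rng):
        model = make_random_model(rng)
        # tilt Y toward the reconstruction so the optimal scale is interior
        mod = model.modalities[0]
        R0 = mod.mask.matrix @ model.U @ model.B
        model.modalities[0] = ModalityData(
            1.7 * R0 + 0.1 * mod.Y, mod.mask, mod.sigma, mod.scale, mod.label
        )
        out = update_scales(model)

        def objective_of_scale(c):
            trial = model.copy()
            mod = trial.modalities[0]
            trial.modalities[0] = ModalityData(mod.Y, mod.mask, mod.sigma, c, mod.label)
            return neg_log_joint(trial)

        best = optimize.minimize_scalar(
            objective_of_scale, bounds=(1e-3, 10.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert out.modalities[0].scale == pytest.approx(best.x, abs=1e-6)

    def test_zero_reconstruction_leaves_scale_unchanged(self, small_model):
        model = small_model.copy()
        model.U = np.zeros_like(model.U)
        out = update_scales(model)
        assert out.modalities[0].scale == small_model.modalities[0].scale


class TestFit:
    def test_initial_precisions_are_logspace(self, rng):
        cfg = pf.SimConfig(n=8, p=6, k_true=2, markers_per_pathway=10, seed=0)
        mods = pf.simulate_dataset(pf.simulate_truth(cfg), cfg)
        model, _ = fit(mods, FitConfig(k=3, n_iter=0))
        np.testing.assert_allclose(model.delta, [1e-4, 1e0, 1e4])
        np.testing.assert_allclose(model.Lambda, np.outer(np.ones(6), [1e-4, 1, 1e4]))

    def test_zero_iterations_returns_initialization(self, rng):
        cfg = pf.SimConfig(n=8, p=6, k_true=2, markers_per_pathway=10, seed=0)
        mods = pf.simulate_dataset(pf.simulate_truth(cfg), cfg)
        model, report = fit(mods, FitConfig(k=3, n_iter=0))
        assert report.iterations_run == 0
        np.testing.assert_array_equal(model.U, 0.0)
        # B carries the scaled right singular vectors of the RNA matrix
        _, s, Vt = np.linalg.svd(mods[0].Y, full_matrices=False)
        np.testing.assert_allclose(np.abs(model.B), np.abs(s[:3, None] * Vt[:3]))

    def test_noiseless_instance_is_reconstructed(self):
        cfg = pf.SimConfig(
            p=10, k_true=3, n=50, markers_per_pathway=20, n_genes=200,
            noise_spread={"rna": 0.0, "prot": 0.0},
            noise_mean={"rna": 1e-3, "prot": 1e-3},
            seed=5,
        )
        truth = pf.simulate_truth(cfg)
        mods = pf.simulate_dataset(truth, cfg)
        model, report = fit(mods, FitConfig(k=3, n_iter=200))
        for mod, ref in zip(model.modalities, mods):
            target = truth.scales[mod.label] * (
                mod.mask.matrix @ truth.U_true @ truth.B_true
            )
            recon = mod.reconstruction(model.U, model.B)
            rel = np.linalg.norm(recon - target) / np.linalg.norm(target)
            assert rel < 0.1

    def test_seeded_fit_is_bit_reproducible(self):
        cfg = pf.SimConfig(n=10, p=8, k_true=3, markers_per_pathway=15, seed=3)
        mods = pf.simulate_dataset(pf.simulate_truth(cfg), cfg)
        a, _ = fit(mods, FitConfig(k=4, n_iter=30))
        b, _ = fit(mods, FitConfig(k=4, n_iter=30))
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.Lambda, b.Lambda)
        for ma, mb in zip(a.modalities, b.modalities):
            np.testing.assert_array_equal(ma.sigma, mb.sigma)
            assert ma.scale == mb.scale

    def test_each_hessian_formed_at_most_once_per_iteration(self):
        cfg = pf.SimConfig(n=10, p=8, k_true=3, markers_per_pathway=15, seed=3)
        mods = pf.simulate_dataset(pf.simulate_truth(cfg), cfg)
        before = hessians.calls
        _, report = fit(mods, FitConfig(k=4, n_iter=25, rel_tol=0))
        assert hessians.calls - before == report.iterations_run

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(k=0)
        with pytest.raises(ValueError):
            FitConfig(step_size=0.0)
        with pytest.raises(ValueError):
            FitConfig(dof_mode="other")

    def test_mismatched_pathways_rejected(self, rng):
        cfg = pf.SimConfig(n=6, p=5, k_true=2, markers_per_pathway=8, seed=0)
        mods = pf.simulate_dataset(pf.simulate_truth(cfg), cfg)
        other = mods[1]
        renamed = PathwayMask(
            other.mask.matrix,
            other.mask.marker_ids,
            [f"other_{n}" for n in other.mask.pathway_names],
        )
        bad = ModalityData(other.Y, renamed, None, 1.0, "prot")
        with pytest.raises(ValueError, match="same pathways"):
            fit([mods[0], bad], FitConfig(k=2, n_iter=1))


@pytest.fixture(scope="module")
def fitted():
    cfg = pf.SimConfig(n=30, p=10, k_true=3, markers_per_pathway=20, seed=11)
    truth = pf.simulate_truth(cfg)
    mods = pf.simulate_dataset(truth, cfg)
    train, test = pf.train_test_split(mods, 20)
    model, _ = fit(train, FitConfig(k=4, n_iter=60))
    return model, test, truth


class TestInferLoadings:

    def test_zero_observations_give_zero_loadings(self, fitted):
        model, test, _ = fitted
        zeros = [
            ModalityData(np.zeros_like(t.Y), t.mask, None, 1.0, t.label) for t in test
        ]
        np.testing.assert_array_equal(infer_loadings(model, zeros), 0.0)

    def test_equals_full_newton_step_from_zero(self, fitted):
        model, test, _ = fitted
        B_direct = infer_loadings(model, test)
        surrogate = FactorModel(
            model.U,
            np.zeros((model.n_latents, test[0].n_samples)),
            model.Lambda,
            model.delta,
            [
                ModalityData(t.Y, ref.mask, ref.sigma, ref.scale, ref.label)
                for t, ref in zip(test, model.modalities)
            ],
        )
        via_update = update_B(surrogate, step_size=1.0).B
        np.testing.assert_allclose(B_direct, via_update, rtol=1e-10, atol=1e-12)

    def test_recovers_loadings_in_low_noise_weak_prior_limit(self, rng):
        model = make_random_model(rng, m=40, p=6, k=3, n=8)
        model.delta = np.full(model.n_latents, 1e-8)
        mod = model.modalities[0]
        model.modalities[0] = ModalityData(
            mod.Y, mod.mask, np.full(mod.n_markers, 1e-4), mod.scale, mod.label
        )
        b_true = rng.normal(size=(model.n_latents, 5))
        ref = model.modalities[0]
        y = ref.scale * (ref.mask.matrix @ model.U @ b_true)
        new = [ModalityData(y, ref.mask, None, 1.0, ref.label)]
        b_hat = infer_loadings(model, new)
        assert np.linalg.norm(b_hat - b_true) / np.linalg.norm(b_true) < 1e-6

    def test_marker_mismatch_rejected(self, fitted):
        model, test, _ = fitted
        t = test[0]
        renamed = PathwayMask(
            t.mask.matrix, [f"x_{m}" for m in t.mask.marker_ids], t.mask.pathway_names
        )
        bad = [ModalityData(t.Y, renamed, None, 1.0, t.label)] + test[1:]
        with pytest.raises(ValueError, match="marker"):
            infer_loadings(model, bad)


def test_model_roundtrips_through_directory(tmp_path):
    cfg = pf.SimConfig(n=12, p=6, k_true=2, markers_per_pathway=10, seed=2)
    mods = pf.simulate_dataset(pf.simulate_truth(cfg), cfg)
    model, report = fit(mods, FitConfig(k=3, n_iter=20))
    save_model(model, tmp_path / "model", report, FitConfig(k=3, n_iter=20))
    back = load_model(tmp_path / "model")
    np.testing.assert_allclose(back.U, model.U)
    np.testing.assert_allclose(back.B, model.B)
    np.testing.assert_allclose(back.delta, model.delta)
    for a, b in zip(back.modalities, model.modalities):
        np.testing.assert_allclose(a.sigma, b.sigma)
        assert a.scale == pytest.approx(b.scale)
        np.testing.assert_array_equal(a.mask.matrix, b.mask.matrix)
        assert a.mask.marker_ids == b.mask.marker_ids
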