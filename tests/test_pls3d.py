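"""NIPALS PLS, cross-validation, field contributions, SRD/FFD, contours."""

import numpy as np
import pytest

from triazqsar import mif_engine as me
from triazqsar import pls3d
from triazqsar.synthdata import (
    SyntheticMifConfig,
    gen_field_activity,
    gen_grouped_benchmark,
    gen_molecule_set,
    triazine_like_benchmark,
)

from conftest import make_mif


class TestFitPls:
    def test_rank_one_single_component_is_exact(self, rng):
        t = rng.standard_normal(10)
        X = np.outer(t, rng.standard_normal(6))
        y = 2.0 * t + 1.0
        model = pls3d.fit_pls(X, y, 1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_full_component_fit_equals_ols(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        model = pls3d.fit_pls(X, y, 4)
        D = np.column_stack([np.ones(12), X])
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), D @ beta, atol=1e-6)

    def test_prediction_at_column_means_is_y_mean(self, rng):
        X = rng.standard_normal((15, 5))
        y = rng.standard_normal(15)
        model = pls3d.fit_pls(X, y, 2)
        assert model.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.standard_normal((15, 8))
        y = X @ rng.standard_normal(8) + 0.3 * rng.standard_normal(15)
        model = pls3d.fit_pls(X, y, 4)
        gram = model.scores.T @ model.scores
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() < 1e-8

    @pytest.mark.parametrize("n_components", [1, 2, 3, 4])
    def test_matches_sklearn_pls_predictions(self, rng, n_components):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((15, 40))
        y = X @ rng.standard_normal(40) * 0.1 + rng.standard_normal(15)
        mine = pls3d.fit_pls(X, y, n_components).predict(X)
        ref = PLSRegression(n_components=n_components, scale=False).fit(X, y)
        np.testing.assert_allclose(mine, ref.predict(X).ravel(), atol=1e-6)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError):
            pls3d.fit_pls(rng.standard_normal((8, 3)), np.ones(8), 1)


class TestLooCv:
    def test_noiseless_synthetic_scores_high(self):
        *_, mif, y, truth = triazine_like_benchmark(seed=0, noise_sd=0.0)
        result = pls3d.loo_cv(mif.X, y, truth["n_latent"])
        assert result.q2 > 0.95

    def test_equals_manual_fold_loop(self, rng):
        X = rng.standard_normal((8, 5))
        y = X @ rng.standard_normal(5) + 0.2 * rng.standard_normal(8)
        result = pls3d.loo_cv(X, y, 2)
        preds = np.empty(8)
        for i in range(8):
            mask = np.arange(8) != i
            model = pls3d.fit_pls(X[mask], y[mask], 2)
            preds[i] = model.predict(X[i : i + 1])[0]
        q2 = 1 - ((y - preds) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert result.q2 == pytest.approx(q2, abs=1e-12)
        assert result.sdep == pytest.approx(np.sqrt(((y - preds) ** 2).mean()), abs=1e-12)

    def test_mean_predictions_give_zero_q2(self):
        # q2 formula: predictions equal to the observed mean score exactly 0
        y = np.array([1.0, 2.0, 3.0, 4.0])
        preds = np.full(4, y.mean())
        q2 = 1 - ((y - preds) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert q2 == 0.0

    def test_q2_and_r2_kernels_agree_on_identical_inputs(self, rng):
        from triazqsar.qsar2d import goodness_of_fit

        y = rng.standard_normal(10)
        pred = y + 0.3 * rng.standard_normal(10)
        r2 = goodness_of_fit(y, pred)["r2"]
        q2 = pls3d._q2(y, pred, float(y.mean()))
        assert q2 == pytest.approx(r2, abs=1e-12)


class TestLmoCv:
    def test_same_seed_bit_identical(self, rng):
        X = rng.standard_normal((12, 6))
        y = X @ rng.standard_normal(6)
        a = pls3d.lmo_cv(X, y, 2, repetitions=10, seed=3)
        b = pls3d.lmo_cv(X, y, 2, repetitions=10, seed=3)
        assert a.q2 == b.q2 and a.sdep == b.sdep
        for (ia, pa), (ib, pb) in zip(a.per_fold, b.per_fold):
            assert ia == ib
            np.testing.assert_array_equal(pa, pb)

    def test_noiseless_synthetic_scores_high(self):
        *_, mif, y, truth = triazine_like_benchmark(seed=1, noise_sd=0.0)
        result = pls3d.lmo_cv(mif.X, y, truth["n_latent"], repetitions=20, seed=0)
        assert result.q2 > 0.95

    def test_lmo_is_harsher_than_loo(self):
        # leaving out a quarter is a harder test than leaving out one
        diffs = []
        for seed in range(20):
            *_, mif, y, _ = triazine_like_benchmark(seed=seed, noise_sd=0.3)
            loo = pls3d.loo_cv(mif.X, y, 3)
            lmo = pls3d.lmo_cv(mif.X, y, 3, repetitions=50, seed=seed)
            diffs.append(lmo.q2 - loo.q2)
        assert max(diffs) <= 0.05


class TestModelSummary:
    def test_perfect_fit_reports_infinite_f(self, rng):
        t = rng.standard_normal(10)
        X = np.outer(t, np.ones(3))
        y = t * 2
        model = pls3d.fit_pls(X, y, 1)
        summary = pls3d.model_summary(model, X, y)
        assert summary["sdec"] == pytest.approx(0.0, abs=1e-8)
        assert summary["f_test"] == np.inf


class TestFieldContributions:
    def test_zero_electrostatic_coefficients_give_pure_steric(self, rng):
        values = rng.standard_normal((10, 6))
        mif = make_mif(values, ["steric"] * 3 + ["electrostatic"] * 3, range(6))
        model = pls3d.fit_pls(values, rng.standard_normal(10), 2)
        model.coefficients = np.array([1.0, -2.0, 0.5, 0.0, 0.0, 0.0])
        contrib = pls3d.field_contributions(model, mif)
        assert contrib.shares["steric"] == pytest.approx(100.0)
        assert contrib.shares["electrostatic"] == pytest.approx(0.0)

    def test_duplicated_columns_split_fifty_fifty(self, rng):
        half = rng.standard_normal((10, 4))
        values = np.concatenate([half, half], axis=1)
        mif = make_mif(values, ["steric"] * 4 + ["electrostatic"] * 4, list(range(4)) * 2)
        model = pls3d.fit_pls(values, rng.standard_normal(10), 2)
        coef = rng.standard_normal(4)
        model.coefficients = np.concatenate([coef, coef])
        contrib = pls3d.field_contributions(model, mif)
        assert contrib.shares["steric"] == pytest.approx(50.0, abs=1e-9)

    def test_invariant_under_column_order_within_field(self, rng):
        values = rng.standard_normal((10, 6))
        kinds = ["steric", "steric", "steric", "electrostatic", "electrostatic", "electrostatic"]
        y = rng.standard_normal(10)
        mif = make_mif(values, kinds, range(6))
        model = pls3d.fit_pls(values, y, 2)
        base = pls3d.field_contributions(model, mif)
        perm = [2, 0, 1, 5, 3, 4]  # permute within each field block
        mif_p = make_mif(values[:, perm], [kinds[p] for p in perm],
                         [list(range(6))[p] for p in perm])
        model_p = pls3d.fit_pls(values[:, perm], y, 2)
        permuted = pls3d.field_contributions(model_p, mif_p)
        assert permuted.shares["steric"] == pytest.approx(base.shares["steric"], abs=1e-8)


class TestParameterRecovery:
    def test_zero_noise_recovery(self):
        *_, mif, y, truth = triazine_like_benchmark(seed=3, noise_sd=0.0)
        model = pls3d.fit_pls(mif, y, truth["n_latent"])
        corr = np.corrcoef(model.coefficients, truth["weights_dense"])[0, 1]
        assert corr > 0.99
        assert pls3d.loo_cv(mif.X, y, truth["n_latent"]).q2 > 0.95

    def test_q2_degrades_with_noise(self):
        medians = []
        for noise in (0.0, 0.5, 1.0):
            q2s = [
                pls3d.loo_cv(mif.X, y, 3).q2
                for *_, mif, y, _ in (
                    triazine_like_benchmark(seed=s, noise_sd=noise) for s in range(5)
                )
            ]
            medians.append(float(np.median(q2s)))
        assert medians[0] > medians[1] > medians[2]


class TestSrd:
    def _toy_mif(self, rng, n_nodes=64):
        grid = me.Grid(
            me.GridSpec(extents=(6, 6, 6), spacing=2.0, origin=(0, 0, 0)),
            np.zeros(3),
        )
        assert grid.n_points == n_nodes
        values = rng.standard_normal((10, n_nodes))
        return make_mif(values, ["steric"] * n_nodes, range(n_nodes), grid=grid)

    def test_matches_brute_force_nearest_seed(self, rng):
        mif = self._toy_mif(rng)
        weights = rng.standard_normal(64)
        critical, collapse = 2.0, 4.0
        result = pls3d.srd_group(mif, weights, n_seeds=6,
                                 critical_radius=critical, collapse_radius=collapse)
        coords = mif.grid.origin + mif.grid.linear_to_ijk(mif.kept_indices) * 2.0
        seeds = result.seeds
        assert seeds == list(np.argsort(-np.abs(weights), kind="stable")[:6])
        # brute-force nearest-seed assignment
        member_of = {}
        for g_idx, group in enumerate(result.groups):
            for c in group:
                member_of[c] = g_idx
        for j in range(64):
            d = [np.linalg.norm(coords[j] - coords[s]) for s in seeds]
            if min(d) > critical:
                assert result.groups[member_of[j]] == [j]  # singleton
            else:
                nearest = seeds[int(np.argmin(d))]
                assert member_of[j] == member_of[nearest]

    def test_one_dominant_seed_single_group(self, rng):
        mif = self._toy_mif(rng)
        weights = np.zeros(64)
        weights[0] = 10.0
        result = pls3d.srd_group(mif, weights, n_seeds=1, critical_radius=100.0)
        assert result.n_groups == 1
        assert sorted(result.groups[0]) == list(range(64))

    def test_two_distant_clusters_stay_separate(self, rng):
        grid = me.Grid(
            me.GridSpec(extents=(40, 2, 2), spacing=2.0, origin=(0, 0, 0)),
            np.zeros(3),
        )
        n = grid.n_points
        values = rng.standard_normal((10, n))
        mif = make_mif(values, ["steric"] * n, range(n), grid=grid)
        coords = grid.origin + grid.linear_to_ijk(np.arange(n)) * 2.0
        weights = np.full(n, 0.1)
        weights[int(np.argmin(coords[:, 0]))] = 5.0  # one seed per end
        weights[int(np.argmax(coords[:, 0]))] = 4.9
        result = pls3d.srd_group(mif, weights, n_seeds=2,
                                 critical_radius=4.0, collapse_radius=8.0)
        seed_x = coords[result.seeds][:, 0]
        assert abs(seed_x[0] - seed_x[1]) > 8.0
        assert result.n_groups >= 2


class TestFfd:
    def test_planted_benchmark_drops_noise_keeps_signal(self):
        total_noise, dropped_noise, dropped_signal = 0, 0, 0
        for seed in range(10):
            X, y, groups, n_signal = gen_grouped_benchmark(seed=seed)
            result = pls3d.ffd_select(X, y, groups, n_components=5, seed=seed)
            dropped_signal += sum(1 for g in result.dropped_groups if g < n_signal)
            dropped_noise += sum(1 for g in result.dropped_groups if g >= n_signal)
            total_noise += len(groups) - n_signal
        assert dropped_signal == 0
        assert dropped_noise / total_noise >= 0.8

    def test_single_group_kept_trivially(self, rng):
        X = rng.standard_normal((10, 3))
        y = X @ np.ones(3)
        result = pls3d.ffd_select(X, y, [[0, 1, 2]], n_components=1, seed=0)
        assert result.kept_groups == [0]
        assert result.dropped_groups == []

    def test_same_seed_identical_selection(self):
        X, y, groups, _ = gen_grouped_benchmark(seed=4)
        a = pls3d.ffd_select(X, y, groups, n_components=5, seed=9)
        b = pls3d.ffd_select(X, y, groups, n_components=5, seed=9)
        assert a.kept_groups == b.kept_groups
        np.testing.assert_array_equal(a.effects, b.effects)


class TestContour:
    def _planted_setup(self, seed=3):
        config = SyntheticMifConfig(n_molecules=20, noise_sd=0.0, seed=seed)
        mols = gen_molecule_set(config)
        grid = me.make_grid(me.GridSpec(), mols)
        mif = me.preprocess_fields(me.compute_fields(mols, grid), grid=grid)
        sd_cols = mif.X.std(axis=0)
        steric = mif.kept_kinds == "steric"
        anchor = int(np.argmax(np.where(steric, sd_cols, -1)))
        coords = grid.origin + grid.linear_to_ijk(mif.kept_indices) * grid.spec.spacing
        dist = np.linalg.norm(coords - coords[anchor], axis=1)
        region = np.where(steric & (dist <= 2 * grid.spec.spacing))[0]
        wmap = {int(c): 1.0 / max(sd_cols[c], 1e-6) for c in region}
        y, _ = gen_field_activity(mif, config, true_weight_map=wmap)
        return mif, grid, y, region

    def test_planted_favorable_region_recovered(self, tmp_path):
        mif, grid, y, region = self._planted_setup()
        model = pls3d.fit_pls(mif, y, pls3d.choose_components(mif.X, y))
        cmap = pls3d.export_contour(model, mif, tmp_path, percentile=95)
        flat = cmap.volumes["steric"].transpose(2, 1, 0).ravel()
        planted_nodes = set(int(mif.kept_indices[c]) for c in region)
        assert int(np.argmax(flat)) in planted_nodes
        top = np.where(flat >= cmap.levels["steric"]["positive"])[0]
        assert np.mean([t in planted_nodes for t in top]) >= 0.5

    def test_dropped_columns_exported_as_exact_zero(self, tmp_path):
        mif, grid, y, _ = self._planted_setup(seed=5)
        model = pls3d.fit_pls(mif, y, 2)
        cmap = pls3d.export_contour(model, mif, tmp_path)
        flat = cmap.volumes["steric"].transpose(2, 1, 0).ravel()
        steric_dropped = [
            int(idx)
            for idx, kind, kept in zip(mif.grid_indices, mif.kinds, mif.kept)
            if kind == "steric" and not kept
        ]
        assert (flat[steric_dropped] == 0).all()

    def test_dx_export_reread_roundtrip(self, tmp_path):
        from triazqsar import molio

        mif, grid, y, _ = self._planted_setup(seed=6)
        model = pls3d.fit_pls(mif, y, 2)
        pls3d.export_contour(model, mif, tmp_path, basename="rt")
        vol, origin, delta = molio.read_dx(tmp_path / "rt_steric.dx")
        sd_cols = mif.X.std(axis=0)
        full = np.zeros(grid.n_points)
        mask = mif.kept_kinds == "steric"
        full[mif.kept_indices[mask]] = (model.coefficients * sd_cols)[mask]
        np.testing.assert_allclose(vol, grid.values_to_volume(full), atol=1e-6)
        np.testing.assert_allclose(origin, grid.origin, atol=1e-6)
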