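import numpy as np
import pandas as pd
import pytest

from synprio import factorization as fz
from synprio import synthetic_data as syn


def make_fit(U, V, beta_d, beta_c, targets, pathways, orientation="sensitivity"):
    """Hand-built MacauFit from explicit per-sample arrays."""
    S, n_d, L = U.shape
    return fz.MacauFit(
        U=U,
        V=V,
        beta_d=beta_d,
        beta_c=beta_c,
        mu_u=np.zeros((S, L)),
        mu_v=np.zeros((S, L)),
        tau=np.ones(S),
        rmse_trace=np.zeros(S),
        config=fz.MacauConfig(L=L, n_samples=S, n_burnin=0),
        drugs=[f"d{i}" for i in range(n_d)],
        cells=[f"c{j}" for j in range(V.shape[1])],
        targets=targets,
        pathways=pathways,
        orientation=orientation,
    )


class TestResponseMatrix:
    def test_rejects_empty_drug_row(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [np.nan, np.nan]], index=["d0", "d1"], columns=["c0", "c1"]
        )
        with pytest.raises(ValueError, match="d1"):
            fz.ResponseMatrix(values)

    def test_rejects_empty_cell_column(self):
        values = pd.DataFrame(
            [[1.0, np.nan], [1.0, np.nan]], index=["d0", "d1"], columns=["c0", "c1"]
        )
        with pytest.raises(ValueError, match="c1"):
            fz.ResponseMatrix(values)


class TestSideInfo:
    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            fz.SideInfo(cell_side=pd.DataFrame({"p": [np.nan]}))

    def test_rejects_nonbinary_drug_side(self):
        with pytest.raises(ValueError, match="binary"):
            fz.SideInfo(drug_side=pd.DataFrame({"t": [0.5]}))


class TestFitMacau:
    def test_rank1_noiseless_reconstruction(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=30)
        Y = np.outer(a, b)
        y = fz.ResponseMatrix(
            pd.DataFrame(Y, index=[f"d{i}" for i in range(20)],
                         columns=[f"c{j}" for j in range(30)]),
            orientation="sensitivity",
        )
        cfg = fz.MacauConfig(
            L=1, n_burnin=100, n_samples=400, standardize_per_drug=False, seed=1
        )
        fit = fz.fit_macau(y, None, cfg)
        recon = np.einsum("sil,sjl->ij", fit.U, fit.V) / fit.n_collected
        rmse = np.sqrt(np.mean((recon - Y) ** 2))
        assert rmse < 0.05 * Y.std()

    def test_deterministic_given_seed(self, small_panel):
        y = fz.ResponseMatrix(small_panel.response)
        side = fz.SideInfo(
            drug_side=small_panel.target_annotation,
            cell_side=small_panel.pathway_activity_true,
        )
        cfg = fz.MacauConfig(L=3, n_burnin=10, n_samples=20, seed=7)
        f1 = fz.fit_macau(y, side, cfg)
        f2 = fz.fit_macau(y, side, cfg)
        np.testing.assert_array_equal(f1.U, f2.U)
        np.testing.assert_array_equal(f1.beta_c, f2.beta_c)

    def test_rmse_trace_finite(self, small_panel):
        y = fz.ResponseMatrix(small_panel.response)
        side = fz.SideInfo(
            drug_side=small_panel.target_annotation,
            cell_side=small_panel.pathway_activity_true,
        )
        fit = fz.fit_macau(y, side, fz.MacauConfig(L=3, n_burnin=10, n_samples=20, seed=1))
        assert np.isfinite(fit.rmse_trace).all()

    def test_cell_relabeling_equivariance(self, small_truth):
        panel = syn.generate_panel(
            small_truth, n_drugs=8, n_cells=40, noise_sd=0.2, seed=3
        )
        y = fz.ResponseMatrix(panel.response)
        side = fz.SideInfo(
            drug_side=panel.target_annotation,
            cell_side=panel.pathway_activity_true,
        )
        cfg = fz.MacauConfig(L=5, n_burnin=100, n_samples=300, seed=5)
        i1 = fz.interaction_matrix(fz.fit_macau(y, side, cfg))

        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.response.shape[1])
        y_p = fz.ResponseMatrix(panel.response.iloc[:, perm])
        side_p = fz.SideInfo(
            drug_side=panel.target_annotation,
            cell_side=panel.pathway_activity_true.iloc[perm],
        )
        i2 = fz.interaction_matrix(fz.fit_macau(y_p, side_p, cfg))
        r = np.corrcoef(
            i1.values.to_numpy().ravel(), i2.values.to_numpy().ravel()
        )[0, 1]
        assert r > 0.99

    def test_axis_transpose_property(self, rng):
        # both side matrices binary so the axes are literally exchangeable
        n_d, n_c, n_t, n_p = 16, 24, 4, 5
        X_d = (rng.random((n_d, n_t)) < 0.4).astype(int)
        X_d[np.arange(n_d), rng.integers(0, n_t, n_d)] = 1
        X_c = (rng.random((n_c, n_p)) < 0.4).astype(int)
        X_c[np.arange(n_c), rng.integers(0, n_p, n_c)] = 1
        A = rng.normal(size=(n_t, n_p))
        Y = X_d @ A @ X_c.T + 0.2 * rng.normal(size=(n_d, n_c))
        drugs = [f"d{i}" for i in range(n_d)]
        cells = [f"c{j}" for j in range(n_c)]
        targets = [f"t{k}" for k in range(n_t)]
        pathways = [f"p{k}" for k in range(n_p)]

        def run(values, dside, cside, index, columns):
            y = fz.ResponseMatrix(
                pd.DataFrame(values, index=index, columns=columns),
                orientation="sensitivity",
            )
            side = fz.SideInfo(
                drug_side=pd.DataFrame(dside, index=index, columns=targets if dside is X_d else pathways),
                cell_side=pd.DataFrame(cside, index=columns, columns=pathways if cside is X_c else targets),
            )
            cfg = fz.MacauConfig(
                L=5, n_burnin=150, n_samples=400, seed=5, standardize_per_drug=False
            )
            return fz.interaction_matrix(fz.fit_macau(y, side, cfg)).values.to_numpy()

        i1 = run(Y, X_d, X_c, drugs, cells)
        i2 = run(Y.T, X_c, X_d, cells, drugs)
        r = np.corrcoef(i1.ravel(), i2.T.ravel())[0, 1]
        assert r > 0.95

    def test_missing_side_rows_error(self, small_panel):
        y = fz.ResponseMatrix(small_panel.response)
        side = fz.SideInfo(
            drug_side=small_panel.target_annotation.iloc[:-1],
            cell_side=small_panel.pathway_activity_true,
        )
        with pytest.raises(ValueError, match="missing rows"):
            fz.fit_macau(y, side, fz.MacauConfig(L=2, n_burnin=1, n_samples=1))

    def test_heldout_prediction_on_synthetic_panel(self):
        truth = syn.generate_ground_truth(8, 11, 100, seed=17)
        panel_full = syn.generate_panel(
            truth, n_drugs=40, n_cells=120, noise_sd=0.3, missing_frac=0.0, seed=17
        )
        panel = syn.generate_panel(
            truth, n_drugs=40, n_cells=120, noise_sd=0.3, missing_frac=0.1, seed=17
        )
        # identical rng stream up to masking: observed values agree
        mask = panel.response.isna().to_numpy()
        assert mask.any()
        y = fz.ResponseMatrix(panel.response)
        side = fz.SideInfo(
            drug_side=panel.target_annotation,
            cell_side=panel.pathway_activity_true,
        )
        cfg = fz.MacauConfig(L=10, n_burnin=200, n_samples=600, seed=17)
        fit = fz.fit_macau(y, side, cfg)
        recon = np.einsum("sil,sjl->ij", fit.U, fit.V) / fit.n_collected
        recon = recon * fit.drug_sds[:, None] + fit.drug_means[:, None]
        held_truth = panel_full.response.to_numpy()[mask]
        r = np.corrcoef(recon[mask], held_truth)[0, 1]
        assert r >= 0.6


class TestInteractionMatrix:
    def test_single_sample_literal_product(self):
        beta_d = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
        beta_c = np.array([[[2.0, 0.0], [0.0, 3.0]]])
        fit = make_fit(
            np.zeros((1, 3, 2)), np.zeros((1, 2, 2)), beta_d, beta_c,
            targets=["t0", "t1", "t2"], pathways=["p0", "p1"],
        )
        inter = fz.interaction_matrix(fit)
        np.testing.assert_allclose(
            inter.values.to_numpy(), beta_d[0] @ beta_c[0].T
        )

    def test_two_sample_mean_is_elementwise_mean(self, rng):
        beta_d = rng.normal(size=(2, 3, 2))
        beta_c = rng.normal(size=(2, 4, 2))
        fit = make_fit(
            np.zeros((2, 3, 2)), np.zeros((2, 5, 2)), beta_d, beta_c,
            targets=list("abc"), pathways=list("wxyz"),
        )
        inter = fz.interaction_matrix(fit)
        expected = (beta_d[0] @ beta_c[0].T + beta_d[1] @ beta_c[1].T) / 2
        np.testing.assert_allclose(inter.values.to_numpy(), expected)

    def test_ic50_orientation_negates(self, rng):
        beta_d = rng.normal(size=(1, 2, 2))
        beta_c = rng.normal(size=(1, 3, 2))
        fit_sens = make_fit(
            np.zeros((1, 2, 2)), np.zeros((1, 3, 2)), beta_d, beta_c,
            targets=["t0", "t1"], pathways=list("xyz"), orientation="sensitivity",
        )
        fit_ic50 = make_fit(
            np.zeros((1, 2, 2)), np.zeros((1, 3, 2)), beta_d, beta_c,
            targets=["t0", "t1"], pathways=list("xyz"), orientation="ic50",
        )
        np.testing.assert_allclose(
            fz.interaction_matrix(fit_ic50).values.to_numpy(),
            -fz.interaction_matrix(fit_sens).values.to_numpy(),
        )

    def test_no_link_matrices_error(self):
        fit = make_fit(
            np.zeros((1, 2, 2)), np.zeros((1, 3, 2)), None, None, [], []
        )
        with pytest.raises(ValueError, match="link"):
            fz.interaction_matrix(fit)


class TestAveragedInteractions:
    def test_single_repeat_matches_single_chain(self, small_panel):
        y = fz.ResponseMatrix(small_panel.response)
        side = fz.SideInfo(
            drug_side=small_panel.target_annotation,
            cell_side=small_panel.pathway_activity_true,
        )
        cfg = fz.MacauConfig(L=3, n_burnin=20, n_samples=40, n_repeats=1, seed=9)
        avg = fz.averaged_interactions(y, side, cfg)
        chain_seed = fz.derive_chain_seeds(9, 1)[0]
        single = fz.interaction_matrix(
            fz.fit_macau(y, side, fz.MacauConfig(
                L=3, n_burnin=20, n_samples=40, seed=chain_seed
            ))
        )
        pd.testing.assert_frame_equal(avg.values, single.values)
        assert avg.n_chains_averaged == 1

    def test_derived_seeds_distinct(self):
        seeds = fz.derive_chain_seeds(0, 40)
        assert len(set(seeds)) == 40

    def test_averaging_reduces_monte_carlo_variance(self, small_panel):
        y = fz.ResponseMatrix(small_panel.response)
        side = fz.SideInfo(
            drug_side=small_panel.target_annotation,
            cell_side=small_panel.pathway_activity_true,
        )
        base = fz.MacauConfig(L=3, n_burnin=30, n_samples=60)
        singles = []
        averages = []
        for k in range(8):
            cfg = fz.MacauConfig(L=3, n_burnin=30, n_samples=60, n_repeats=1, seed=100 + k)
            singles.append(fz.averaged_interactions(y, side, cfg).values.to_numpy())
            cfg4 = fz.MacauConfig(L=3, n_burnin=30, n_samples=60, n_repeats=4, seed=200 + k)
            averages.append(fz.averaged_interactions(y, side, cfg4).values.to_numpy())
        var_single = np.stack(singles).var(axis=0).mean()
        var_avg = np.stack(averages).var(axis=0).mean()
        assert var_single > var_avg


class TestPredictResponse:
    def test_zero_side_zero_mu_gives_zero(self):
        beta_c = np.zeros((2, 3, 2))
        fit = make_fit(
            np.ones((2, 4, 2)), np.zeros((2, 5, 2)), np.zeros((2, 2, 2)), beta_c,
            targets=["t0", "t1"], pathways=list("xyz"),
        )
        new_side = pd.DataFrame(np.zeros((3, 3)), columns=list("xyz"))
        pred = fz.predict_response(fit, new_side)
        np.testing.assert_allclose(pred.to_numpy(), 0.0)

    def test_linearity_in_side_info(self, rng):
        beta_c = rng.normal(size=(3, 4, 2))
        fit = make_fit(
            rng.normal(size=(3, 5, 2)), np.zeros((3, 6, 2)),
            rng.normal(size=(3, 2, 2)), beta_c,
            targets=["t0", "t1"], pathways=list("wxyz"),
        )
        x = pd.DataFrame(rng.normal(size=(2, 4)), columns=list("wxyz"))
        p1 = fz.predict_response(fit, x)
        p3 = fz.predict_response(fit, 3 * x)
        np.testing.assert_allclose(p3.to_numpy(), 3 * p1.to_numpy(), atol=1e-10)

    def test_column_mismatch_lists_missing(self, rng):
        fit = make_fit(
            rng.normal(size=(1, 2, 2)), np.zeros((1, 3, 2)),
            rng.normal(size=(1, 2, 2)), rng.normal(size=(1, 3, 2)),
            targets=["t0", "t1"], pathways=list("xyz"),
        )
        with pytest.raises(ValueError, match="z"):
            fz.predict_response(fit, pd.DataFrame(np.zeros((1, 2)), columns=list("xy")))

    def test_training_cell_side_correlates_with_fitted_column(self):
        truth = syn.generate_ground_truth(4, 11, 60, seed=23)
        panel = syn.generate_panel(
            truth, n_drugs=8, n_cells=50, noise_sd=0.05, seed=23
        )
        y = fz.ResponseMatrix(panel.response)
        side = fz.SideInfo(
            drug_side=panel.target_annotation,
            cell_side=panel.pathway_activity_true,
        )
        fit = fz.fit_macau(y, side, fz.MacauConfig(L=6, n_burnin=150, n_samples=400, seed=2))
        cell = panel.pathway_activity_true.index[0]
        pred = fz.predict_response(
            fit, panel.pathway_activity_true.loc[[cell]]
        )
        fitted_col = panel.response[cell].to_numpy()
        r = np.corrcoef(pred.iloc[:, 0].to_numpy(), fitted_col)[0, 1]
        assert r > 0.9


class TestStabilityReport:
    def _mats(self, arrays):
        targets = [f"t{i}" for i in range(arrays[0].shape[0])]
        pathways = [f"p{j}" for j in range(arrays[0].shape[1])]
        return [
            fz.InteractionMatrix(pd.DataFrame(a, index=targets, columns=pathways))
            for a in arrays
        ]

    def test_identical_matrices(self, rng):
        base = rng.normal(size=(4, 6))
        report = fz.stability_report(self._mats([base] * 5), subsample_size=3, n_draws=10, seed=0)
        assert report["mean_pairwise_r"] == pytest.approx(1.0)
        assert (report["similarity_cv"]["cv"].abs() < 1e-12).all()

    def test_pairwise_r_increases_with_subsample_size(self, rng):
        base = rng.normal(size=(4, 8))
        mats = self._mats([base + 0.8 * rng.normal(size=base.shape) for _ in range(16)])
        rs = [
            fz.stability_report(mats, subsample_size=s, n_draws=30, seed=1)[
                "mean_pairwise_r"
            ]
            for s in (2, 4, 8)
        ]
        assert rs[0] < rs[1] < rs[2]

    def test_error_contracts(self, rng):
        mats = self._mats([rng.normal(size=(3, 4)) for _ in range(4)])
        with pytest.raises(ValueError):
            fz.stability_report(mats[:1], subsample_size=1)
        with pytest.raises(ValueError):
            fz.stability_report(mats, subsample_size=2, n_draws=1)
        with pytest.raises(ValueError):
            fz.stability_report(mats, subsample_size=10)
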