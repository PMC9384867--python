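import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from parasdm import maxent
from parasdm.maxent import (
    FeatureDef,
    build_feature_space,
    build_features,
    compute_lambdas,
    fit,
    predict_logistic,
    predict_raw,
    project,
    variable_contribution,
)
from parasdm.occurrences import SampleTable
from parasdm.raster import Grid, RasterStack


def _samples(rng, n_var=1, nb=14, mp=6, low=0.0, high=10.0):
    vals = rng.uniform(low, high, size=(nb + mp, n_var))
    labels = np.array([0] * nb + [1] * mp)
    return SampleTable(
        variables=[f"Bio{i+1}" for i in range(n_var)],
        values=vals, label=labels, cell=np.arange(nb + mp),
    )


class TestBuildFeatures:
    def test_linear_count(self, rng):
        st = _samples(rng, n_var=3, nb=30, mp=10)
        assert len(build_features(st, "L")) == 3

    def test_lq_count(self, rng):
        st = _samples(rng, n_var=3, nb=30, mp=10)
        assert len(build_features(st, "LQ")) == 6

    def test_product_count(self, rng):
        st = _samples(rng, n_var=4, nb=30, mp=10)
        feats = build_features(st, "P")
        assert len(feats) == 6  # C(4,2)

    def test_hinge_knots_track_quantiles(self, rng):
        st = _samples(rng, n_var=1, nb=2000, mp=10)
        feats = build_features(st, "H", n_knots=9)
        knots = sorted({f.knot for f in feats})
        expected = np.quantile(st.values[:, 0], np.arange(1, 10) / 10)
        np.testing.assert_allclose(knots, expected, atol=1e-12)
        # uniform sample -> roughly evenly spaced knots
        gaps = np.diff(knots)
        assert gaps.max() < 3 * gaps.min()

    def test_unknown_class_letter(self, rng):
        with pytest.raises(ValueError, match="letters"):
            build_features(_samples(rng), "LX")

    def test_constant_variable_dropped(self, rng):
        st = _samples(rng, n_var=2, nb=20, mp=5)
        st.values[:, 1] = 7.0
        feats = build_features(st, "LQ")
        assert all(f.parents == ("Bio1",) for f in feats)


from _oracles import brute_force_beta as _brute_force_beta


class TestFit:
    def test_huge_rm_zeroes_all(self, rng):
        st = _samples(rng, n_var=2, nb=30, mp=10)
        model = fit(st, "LQ", rm=1e9)
        assert model.k == 0
        np.testing.assert_array_equal(model.beta, 0.0)
        q = predict_raw(model, st)
        np.testing.assert_allclose(q[st.label == 0], 1.0 / 30)

    def test_separating_feature_ranks_presences_first(self, rng):
        nb, mp = 30, 8
        vals = np.concatenate([rng.uniform(0, 1, nb), rng.uniform(4, 5, mp)])
        st = SampleTable(variables=["Bio1"], values=vals[:, None],
                         label=np.array([0] * nb + [1] * mp),
                         cell=np.arange(nb + mp))
        model = fit(st, "L", rm=0.05, on_no_convergence="warn")
        assert model.beta[0] > 0
        scores = predict_raw(model, st)
        assert scores[st.label == 1].min() > scores[st.label == 0].max()

    @pytest.mark.parametrize("fc,rm,seed", [("L", 1.0, 0), ("L", 0.5, 1),
                                            ("LQ", 1.0, 7), ("LQ", 2.0, 3)])
    def test_matches_brute_force_oracle(self, fc, rm, seed):
        rng = np.random.default_rng(seed)
        st = _samples(rng, n_var=1, nb=14, mp=6)
        model = fit(st, fc, rm=rm)
        beta_star, f_star, obj = _brute_force_beta(st, fc, rm)
        assert obj(model.beta) <= f_star + 1e-6
        np.testing.assert_allclose(model.beta, beta_star, atol=1e-3)

    def test_nonfinite_rejected(self, rng):
        st = _samples(rng, n_var=1)
        st.values[0, 0] = 1.0
        st.values = st.values  # keep valid for SampleTable
        space = build_feature_space(st, "L")
        space.matrix[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit(space, "L", 1.0)

    def test_needs_presences_and_background(self, rng):
        st = _samples(rng, nb=30, mp=6)
        st_nopres = SampleTable(variables=st.variables, values=st.values,
                                label=np.zeros(36, int), cell=st.cell)
        with pytest.raises(ValueError, match="presence"):
            fit(st_nopres, "L", 1.0)

    def test_sparsity_weakly_monotone_in_rm(self):
        ks = {0.5: [], 4.0: []}
        for seed in range(5):
            rng = np.random.default_rng(seed)
            st = _samples(rng, n_var=3, nb=60, mp=25)
            for rm in ks:
                ks[rm].append(fit(st, "LQ", rm, on_no_convergence="warn").k)
        assert np.mean(ks[4.0]) <= np.mean(ks[0.5])


class TestPredict:
    def test_raw_sums_to_one(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        q = predict_raw(model, small_samples)
        assert q[small_samples.label == 0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_null_logistic_exactly_half(self, rng):
        st = _samples(rng, n_var=2, nb=25, mp=5)
        model = fit(st, "LQ", rm=1e9)
        L = predict_logistic(model, st)
        assert set(np.unique(L)) == {0.5}

    def test_logistic_monotone_in_eta(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        cols = {v: small_samples.values[:, i]
                for i, v in enumerate(small_samples.variables)}
        eta = model.eta(cols)
        L = predict_logistic(model, small_samples)
        order = np.argsort(eta)
        assert np.all(np.diff(L[order]) >= -1e-12)

    def test_raw_and_logistic_rank_identical(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        q = predict_raw(model, small_samples)
        L = predict_logistic(model, small_samples)
        assert spearmanr(q, L).statistic == pytest.approx(1.0)

    def test_projection_consistent_on_training_background(self, small_study,
                                                          small_samples):
        data, _ = small_study
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        q_samples = predict_raw(model, small_samples)
        q_grid = predict_raw(model, data.current)
        flat = q_grid.values.ravel()
        bg = small_samples.label == 0
        np.testing.assert_array_equal(flat[small_samples.cell[bg]],
                                      q_samples[bg])


class TestProject:
    def _shifted_stack(self, stack, shift):
        return RasterStack(
            {v: g.copy(values=g.values + shift) for v, g in stack.layers.items()}
        )

    def test_training_stack_identity(self, small_study, small_samples):
        data, _ = small_study
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        direct = predict_logistic(model, data.current, clamp=False)
        projected = project(model, data.current, clamp=True)
        np.testing.assert_allclose(projected.grid.values, direct.grid.values)

    def test_clamp_matches_range_edge(self, small_study, small_samples):
        data, _ = small_study
        model = fit(small_samples, "L", 1.0, on_no_convergence="warn")
        far = self._shifted_stack(data.current, 1e4)
        clamped = project(model, far, clamp=True)
        # clamping pins every variable at its training max
        edge_cols = {v: np.array([model.training_range[v][1]])
                     for v in model.variables}
        u = model.H + model.eta(edge_cols) - model.logZ
        expected = 1.0 / (1.0 + np.exp(-u)) if u > 0 else np.exp(u) / (1 + np.exp(u))
        np.testing.assert_allclose(clamped.grid.values, expected[0])

    def test_clamp_false_differs_out_of_range(self, small_study, small_samples):
        data, _ = small_study
        model = fit(small_samples, "L", 1.0, on_no_convergence="warn")
        far = self._shifted_stack(data.current, 1e4)
        a = project(model, far, clamp=True).grid.values
        b = project(model, far, clamp=False).grid.values
        assert not np.allclose(a, b)

    def test_nodata_propagates(self, small_study, small_samples):
        data, _ = small_study
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        layers = {v: g.copy() for v, g in data.current.layers.items()}
        first = next(iter(layers))
        layers[first].values[0, 0] = np.nan
        sm = project(model, RasterStack(layers))
        assert np.isnan(sm.grid.values[0, 0])


class TestVariableContribution:
    def test_single_variable_full_share(self, rng):
        st = _samples(rng, n_var=1, nb=40, mp=15)
        model = fit(st, "LQ", 1.0, on_no_convergence="warn")
        report = variable_contribution(model, st)
        assert report.percent["Bio1"] == pytest.approx(100.0)

    def test_percent_sums_to_100(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        report = variable_contribution(model, small_samples)
        assert sum(report.percent.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(p >= 0 for p in report.percent.values())

    def test_pure_noise_variable_small(self, rng):
        n = 400
        signal = rng.uniform(0, 10, n)
        noise = rng.uniform(0, 10, n)
        # presences concentrated at high signal values, independent of noise
        label = (signal + rng.normal(0, 1, n) > 8).astype(int)
        if label.sum() < 5:
            label[np.argsort(signal)[-10:]] = 1
        st = SampleTable(variables=["sig", "noise"],
                         values=np.column_stack([signal, noise]),
                         label=label, cell=np.arange(n))
        model = fit(st, "LQ", 1.0, on_no_convergence="warn")
        report = variable_contribution(model, st)
        assert report.percent["noise"] < 10.0
        assert report.percent["sig"] > 90.0
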