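import math

import numpy as np
import pytest
from scipy.special import logsumexp

from parasdm import tuning
from parasdm.maxent import FeatureDef, MaxentModel, fit, predict_logistic
from parasdm.occurrences import SampleTable
from parasdm.tuning import (
    aggregate,
    aicc,
    auc,
    fit_replicates,
    split_replicates,
    tss,
    tune,
)


def _presence_table(samples, idx=None):
    sel = samples.label == 1 if idx is None else idx
    return SampleTable(
        variables=samples.variables,
        values=samples.values[sel],
        label=np.ones(int(np.sum(sel)), int),
        cell=samples.cell[sel],
    )


def _background_table(samples):
    sel = samples.label == 0
    return SampleTable(
        variables=samples.variables,
        values=samples.values[sel],
        label=np.zeros(int(np.sum(sel)), int),
        cell=samples.cell[sel],
    )


class TestAicc:
    def test_hand_formula(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        pres = _presence_table(small_samples)
        study = _background_table(small_samples)
        loglik, k, value = aicc(model, pres, study)
        # independent recomputation from raw exponentials
        cols = {v: study.values[:, i] for i, v in enumerate(study.variables)}
        eta_all = model.eta(cols)
        cols_p = {v: pres.values[:, i] for i, v in enumerate(pres.variables)}
        q_hat = np.exp(model.eta(cols_p)) / np.exp(eta_all).sum()
        ll_oracle = float(np.log(q_hat).sum())
        n = pres.values.shape[0]
        assert loglik == pytest.approx(ll_oracle, rel=1e-10)
        assert value == pytest.approx(
            2 * k - 2 * ll_oracle + 2 * k * (k + 1) / (n - k - 1), rel=1e-10
        )

    def test_k_guard_infinite(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        pres = _presence_table(small_samples)
        tiny = SampleTable(
            variables=pres.variables,
            values=pres.values[: model.k + 1],
            label=np.ones(model.k + 1, int),
            cell=pres.cell[: model.k + 1],
        )
        _, _, value = aicc(model, tiny, _background_table(small_samples))
        assert value == math.inf

    def test_zero_coefficient_feature_neutral(self, small_samples):
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        pres = _presence_table(small_samples)
        study = _background_table(small_samples)
        base = aicc(model, pres, study)
        padded = MaxentModel(
            features=model.features
            + [FeatureDef("linear", ("Bio1",), scale=(0.0, 1.0))],
            beta=np.append(model.beta, 0.0),
            rm=model.rm, fc=model.fc, variables=model.variables,
            background_cells=model.background_cells,
            logZ=model.logZ, H=model.H,
            training_range=model.training_range,
            lambdas=np.append(model.lambdas, 1.0),
            n_presence=model.n_presence,
        )
        assert aicc(padded, pres, study) == pytest.approx(base)


class TestTune:
    def test_table_shape_and_selection(self, small_samples):
        res = tune(small_samples, rm_grid=(1.0, 2.0), fc_sets=("L", "LQ"),
                   n_knots=6, on_no_convergence="warn")
        assert len(res.candidates) == 4
        assert res.candidates["delta_AICc"].min() == 0.0
        sel = res.candidates.set_index(["rm", "fc"]).loc[res.selected]
        assert sel["delta_AICc"] == 0.0

    def test_single_candidate(self, small_samples):
        res = tune(small_samples, rm_grid=(1.0,), fc_sets=("L",),
                   on_no_convergence="warn")
        assert res.selected == (1.0, "L")
        assert len(res.candidates) == 1


class TestSplitReplicates:
    def test_frac_one_rejected(self):
        with pytest.raises(ValueError, match="test"):
            split_replicates(10, frac=1.0, n_rep=3, rng=0)

    def test_union_and_disjoint(self, rng):
        for train, test in split_replicates(17, rng=rng):
            assert len(np.intersect1d(train, test)) == 0
            assert sorted(np.concatenate([train, test])) == list(range(17))
            assert len(train) == math.ceil(0.75 * 17)

    def test_train_frequency_matches_fraction(self):
        n, n_rep = 8, 1000
        counts = np.zeros(n)
        for train, _ in split_replicates(n, frac=0.75, n_rep=n_rep, rng=3):
            counts[train] += 1
        p = math.ceil(0.75 * n) / n
        sigma = math.sqrt(p * (1 - p) * n_rep)
        assert np.all(np.abs(counts - p * n_rep) < 5 * sigma)

    def test_seed_reproducible(self):
        a = split_replicates(20, rng=9)
        b = split_replicates(20, rng=9)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_identical_constant(self):
        assert auc([0.5] * 5, [0.5] * 7) == 0.5

    def test_matches_pair_enumeration(self, rng):
        sp = rng.choice(np.linspace(0, 1, 21), size=50)   # force ties
        sb = rng.choice(np.linspace(0, 1, 21), size=50)
        wins = sum(
            1.0 if p > b else 0.5 if p == b else 0.0
            for p in sp for b in sb
        )
        assert auc(sp, sb) == pytest.approx(wins / (50 * 50), abs=1e-12)


class TestTss:
    def test_perfect_separation(self):
        score = tss([0.9, 0.8], [0.1, 0.2])
        assert score.tss == 1.0
        assert 0.2 < score.threshold_at_max_tss <= 0.9

    def test_identical_distributions_near_zero(self):
        score = tss([0.4] * 10, [0.4] * 10)
        assert score.tss == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self, rng):
        sp = rng.uniform(size=40)
        sb = rng.uniform(size=60)
        best = -2.0
        for t in np.unique(np.concatenate([sp, sb])):
            sens = np.mean(sp >= t)
            spec = np.mean(sb < t)
            best = max(best, sens + spec - 1)
        score = tss(sp, sb)
        assert score.tss == pytest.approx(best, abs=1e-12)
        # returned threshold is the argmax
        t = score.threshold_at_max_tss
        assert np.mean(sp >= t) + np.mean(sb < t) - 1 == pytest.approx(score.tss)


class TestAggregate:
    def _ensemble(self, small_study, small_samples, n_rep=3):
        data, _ = small_study
        pres = _presence_table(small_samples)
        bg = _background_table(small_samples)
        return fit_replicates(pres, bg, fc="LQ", rm=1.0, stack=data.current,
                              n_rep=n_rep, rng=4, n_knots=6)

    def test_replicate_count_and_bounds(self, small_study, small_samples):
        ens = self._ensemble(small_study, small_samples)
        assert len(ens.replicates) == 3
        arr = np.stack([predict_logistic(m, small_samples)
                        for m in ens.replicates])
        flat = ens.mean_map.grid.values.ravel()[small_samples.cell]
        assert np.all(flat <= arr.max(axis=0) + 1e-12)
        assert np.all(flat >= arr.min(axis=0) - 1e-12)

    def test_identical_replicates_mean_is_each(self, small_study, small_samples):
        data, _ = small_study
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        sm = predict_logistic(model, data.current)
        score = tuning.EvalScore(auc=0.9, tss=0.7, threshold_at_max_tss=0.5)
        ens = aggregate([model] * 3, [score] * 3, [sm] * 3)
        np.testing.assert_allclose(ens.mean_map.grid.values, sm.grid.values)
        assert ens.auc_mean == 0.9
        assert ens.auc_sd == 0.0

    def test_two_replicate_hand_mean(self, small_study, small_samples):
        data, _ = small_study
        model = fit(small_samples, "LQ", 1.0, on_no_convergence="warn")
        sm = predict_logistic(model, data.current)
        sm2 = tuning.SuitabilityMap(grid=sm.grid.copy(values=sm.grid.values / 2))
        s1 = tuning.EvalScore(auc=0.8, tss=0.5, threshold_at_max_tss=0.5)
        s2 = tuning.EvalScore(auc=0.9, tss=0.7, threshold_at_max_tss=0.5)
        ens = aggregate([model, model], [s1, s2], [sm, sm2])
        np.testing.assert_allclose(
            ens.mean_map.grid.values, 0.75 * sm.grid.values
        )
        assert ens.auc_mean == pytest.approx(0.85)
        assert ens.tss_mean == pytest.approx(0.6)
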