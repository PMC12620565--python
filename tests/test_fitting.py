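import numpy as np
import pytest

from rwwfit.connectome import normalize_sc
from rwwfit.estimator import WholeBrainModel
from rwwfit.fc_metrics import FCMatrix
from rwwfit.fitting import (
    Adam,
    FitConfig,
    count_free_parameters,
    fit,
    fit_cohort,
    loss,
    warmup,
)
from rwwfit.params import GainParameters
from rwwfit.synthetic import generate_cohort, generate_sc


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(n_subjects=3, n_nodes=8, variant="cm", noise_sd=0.05,
                           seed=21, n_trs=60, tr=1.0, dt=0.005, sigma=0.005,
                           coupling_mode="adjacency")


def _tiny_config(**kw):
    base = dict(variant="gm", epochs=4, warmup_epochs=1, epoch_trs=20, tr=1.0,
                dt=0.005, eval_trs=20, seed=3, sigma=0.005,
                coupling_mode="adjacency")
    base.update(kw)
    return FitConfig(**base)


class TestParameterCounts:
    @pytest.mark.parametrize("variant,n,expected", [
        ("gm", 219, 4),
        ("gm", 10, 4),
        ("lm", 219, 658),
        ("cm", 219, 23_875),
        ("cm", 3, 7),
        ("lm", 10, 31),
    ])
    def test_free_parameter_formulas(self, variant, n, expected):
        assert count_free_parameters(variant, n) == expected

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            count_free_parameters("xm", 10)


class TestLoss:
    def test_perfect_global_fit_is_minus_one(self, rng):
        a = rng.standard_normal((6, 12))
        fc = FCMatrix(np.corrcoef(a))
        params = GainParameters.defaults("gm")
        assert loss(fc, fc, params) == pytest.approx(-1.0)

    def test_anchored_connectivity_penalty_vanishes(self, rng):
        a = rng.standard_normal((6, 12))
        fc = FCMatrix(np.corrcoef(a))
        sc = normalize_sc(generate_sc(6, density=0.5, seed=1)).weights
        params = GainParameters.defaults("cm", sc_mod=sc)
        assert loss(fc, fc, params, sc_emp=sc) == pytest.approx(-1.0)

    def test_connectivity_penalty_hand_value(self, rng):
        a = rng.standard_normal((6, 12))
        fc = FCMatrix(np.corrcoef(a))
        sc = normalize_sc(generate_sc(6, density=0.5, seed=1)).weights
        mod = sc.copy()
        mod[0, 1] = mod[1, 0] = np.clip(sc[0, 1] + 0.2, 0, 1)
        params = GainParameters("cm", g=0.5, g_ei=0.15, g_ie=1.0, g_ee=0.21,
                                sc_mod=mod)
        delta = mod[0, 1] - sc[0, 1]
        expected = -1.0 + 0.5 * delta**2
        assert loss(fc, fc, params, sc_emp=sc) == pytest.approx(expected)

    def test_uniform_local_gains_carry_no_dispersion_penalty(self, rng):
        a = rng.standard_normal((6, 12))
        fc = FCMatrix(np.corrcoef(a))
        params = GainParameters.defaults("lm", n_nodes=6)
        assert loss(fc, fc, params) == pytest.approx(-1.0)


class TestWarmup:
    def test_zero_warmup_returns_initial_state(self, tiny_cohort):
        sc = tiny_cohort.scs[0]
        cfg = _tiny_config(warmup_epochs=0)
        state = warmup(sc, GainParameters.defaults("gm"), cfg)
        np.testing.assert_array_equal(state.E, np.full((1, 8), cfg.e0))
        np.testing.assert_array_equal(state.v, np.ones((1, 8)))

    def test_warmup_reproducible_and_noise_driven(self, tiny_cohort):
        sc = tiny_cohort.scs[0]
        cfg = _tiny_config(warmup_epochs=1)
        s1 = warmup(sc, GainParameters.defaults("gm"), cfg,
                    rng=np.random.default_rng(5))
        s2 = warmup(sc, GainParameters.defaults("gm"), cfg,
                    rng=np.random.default_rng(5))
        np.testing.assert_array_equal(s1.E, s2.E)
        assert np.abs(s1.E - cfg.e0).max() > 1e-4  # state actually moved


class TestFit:
    def test_zero_epochs_echo_initial_parameters(self, tiny_cohort):
        cfg = _tiny_config(epochs=0)
        res = fit(tiny_cohort.scs[0], tiny_cohort.fcs[0], cfg)
        assert res.loss_trace == []
        assert res.final_params.g == pytest.approx(
            FitConfig().init_gains["g"], rel=1e-9)

    def test_fit_reproducible_from_seed(self, tiny_cohort):
        cfg = _tiny_config(epochs=3)
        r1 = fit(tiny_cohort.scs[0], tiny_cohort.fcs[0], cfg)
        r2 = fit(tiny_cohort.scs[0], tiny_cohort.fcs[0], cfg)
        assert r1.loss_trace == r2.loss_trace
        np.testing.assert_array_equal(r1.final_fc.values, r2.final_fc.values)

    def test_cm_constraints_hold_after_every_epoch(self, tiny_cohort):
        cfg = _tiny_config(variant="cm", epochs=3, learning_rate=0.3)
        res = fit(tiny_cohort.scs[0], tiny_cohort.fcs[0], cfg)
        for row in res.loss_trace:
            assert 0.0 <= row["sc_mod_min"] <= row["sc_mod_max"] <= 1.0
        m = res.final_params.sc_mod
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_lm_fit_returns_per_node_gains(self, tiny_cohort):
        cfg = _tiny_config(variant="lm", epochs=2)
        res = fit(tiny_cohort.scs[0], tiny_cohort.fcs[0], cfg)
        assert np.asarray(res.final_params.g_ei).shape == (8,)
        assert np.isscalar(res.final_params.g) or np.ndim(res.final_params.g) == 0

    def test_trainable_subset_freezes_other_gains(self, tiny_cohort):
        cfg = _tiny_config(epochs=3, trainable=("g",))
        res = fit(tiny_cohort.scs[0], tiny_cohort.fcs[0], cfg)
        init = FitConfig().init_gains
        assert res.final_params.g_ei == pytest.approx(init["g_ei"], rel=1e-9)
        assert res.final_params.g_ie == pytest.approx(init["g_ie"], rel=1e-9)

    def test_batched_cohort_fit_returns_one_result_per_subject(self, tiny_cohort):
        cfg = _tiny_config(epochs=2)
        results = fit_cohort(tiny_cohort.scs, tiny_cohort.fcs, cfg)
        assert len(results) == 3
        assert all(len(r.loss_trace) == 2 for r in results)

    def test_optimization_improves_goodness_of_fit(self):
        """Gradient steps on the correlation loss raise fc_fit on average."""
        cohort = generate_cohort(n_subjects=4, n_nodes=8, variant="cm",
                                 noise_sd=0.05, seed=33, n_trs=120, tr=1.0,
                                 dt=0.005, sigma=0.005, coupling_mode="adjacency")
        cfg = FitConfig(variant="cm", epochs=25, warmup_epochs=2, epoch_trs=40,
                        tr=1.0, dt=0.005, eval_trs=120, seed=5, sigma=0.005,
                        learning_rate=0.05, coupling_mode="adjacency")
        results = fit_cohort(cohort.scs, cohort.fcs, cfg)
        first = np.mean([r.loss_trace[0]["fc_fit"] for r in results])
        last = np.mean([np.mean([row["fc_fit"] for row in r.loss_trace[-5:]])
                        for r in results])
        assert last > first


class TestAdam:
    def test_descends_a_quadratic(self):
        params = {"x": np.array([5.0])}
        opt = Adam(params)
        for _ in range(300):
            opt.step(params, {"x": 2 * params["x"]}, lr=0.1)
        assert abs(params["x"][0]) < 1e-2


class TestEstimator:
    def test_sklearn_contract(self, tiny_cohort):
        from sklearn.base import clone

        model = WholeBrainModel(epochs=2, warmup_epochs=1, epoch_trs=20,
                                eval_trs=20, sigma=0.005, random_state=3,
                                coupling_mode="adjacency")
        cloned = clone(model)
        assert cloned.get_params()["epochs"] == 2
        model.set_params(epochs=3)
        assert model.epochs == 3

    def test_fit_sets_trailing_underscore_attributes(self, tiny_cohort):
        model = WholeBrainModel(epochs=2, warmup_epochs=1, epoch_trs=20,
                                eval_trs=20, sigma=0.005, random_state=3,
                                coupling_mode="adjacency")
        X = tiny_cohort.scs[0].weights
        y = tiny_cohort.fcs[0].values
        model.fit(X, y)
        assert model.n_features_in_ == 8
        assert isinstance(model.gains_, GainParameters)
        assert len(model.loss_trace_) == 2
        assert model.predict().shape == (8, 8)
        assert -1.0 <= model.score() <= 1.0

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            WholeBrainModel().predict()


class TestConfigValidation:
    def test_tr_must_be_multiple_of_dt(self):
        with pytest.raises(ValueError, match="multiple"):
            FitConfig(tr=1.0, dt=0.003)

    def test_unknown_trainable_rejected(self):
        with pytest.raises(ValueError, match="trainable"):
            FitConfig(trainable=("g", "bogus"))
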