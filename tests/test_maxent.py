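import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

from nichespread import maxent
from nichespread.maxent import (
    FeatureSpec,
    MaxentModel,
    build_features,
    fit_matrix,
    make_feature_spec,
)
from nichespread.raster import EnvStack
from nichespread.synthetic import generate_env, true_response

from conftest import make_template


def simple_spec(classes="lq", n_vars=1, lo=0.0, hi=1.0, **kw):
    names = [f"v{j + 1}" for j in range(n_vars)]
    return FeatureSpec(
        classes=classes,
        variable_names=names,
        calibration_ranges={n: (lo, hi) for n in names},
        **kw,
    )


class TestBuildFeatures:
    def test_range_minimum_maps_to_zero(self):
        spec = simple_spec("lq", lo=2.0, hi=6.0)
        F, names, classes = build_features([[2.0]], spec)
        assert np.allclose(F, 0.0)
        assert classes == ["l", "q"]

    def test_lqp_feature_count_for_two_variables(self):
        spec = simple_spec("lqp", n_vars=2)
        F, names, _ = build_features([[0.3, 0.7]], spec)
        assert F.shape[1] == 5  # 2 linear + 2 quadratic + 1 product

    def test_threshold_knots_match_hand_evaluation(self):
        spec = simple_spec("t", threshold_knots=3)
        F, names, _ = build_features([[0.6]], spec)
        # knots at 1/4, 2/4, 3/4 -> indicators for z >= knot at z=0.6
        assert list(F[0]) == [1.0, 1.0, 0.0]

    def test_hinge_ramps_scaled_to_unit(self):
        spec = simple_spec("h", hinge_knots=4)
        F, _, _ = build_features([[1.0]], spec)
        assert np.allclose(F, 1.0)  # at range max every hinge is at its peak

    def test_unknown_class_letter_rejected(self):
        with pytest.raises(ValueError):
            simple_spec("lx")


def fit_toy(seed=0, classes="lq", rm=1.0, n_bg=500, n_pres=50):
    rng = np.random.default_rng(seed)
    x_bg = rng.uniform(0, 1, n_bg)
    # presences biased toward x ~ 0.7
    w = np.exp(-((x_bg - 0.7) ** 2) / 0.02)
    pres_idx = rng.choice(n_bg, n_pres, p=w / w.sum())
    spec = simple_spec(classes)
    F_bg, _, cls = build_features(x_bg[:, None], spec)
    F_pres, _, _ = build_features(x_bg[pres_idx, None], spec)
    from nichespread.maxent import _betas

    beta = _betas(F_bg, cls, rm, n_pres)
    lam, obj, trace = fit_matrix(F_pres, F_bg, beta)
    return lam, obj, F_pres, F_bg, beta


class TestFit:
    def test_extreme_regularization_shrinks_everything(self):
        lam, _, _, F_bg, _ = fit_toy(rm=1e6)
        assert np.allclose(lam, 0.0)
        # uniform raw output under zero weights
        s = F_bg @ lam
        raw = np.exp(s) / np.exp(s).sum()
        assert np.allclose(raw, 1.0 / F_bg.shape[0])

    @pytest.mark.parametrize("seed", range(20))
    def test_null_presences_yield_near_uniform_density(self, seed):
        """Presences drawn uniformly from the background carry no signal,
        so the fitted density must stay close to uniform. Individual
        weights are not a reliable null statistic here: the linear and
        quadratic features of one variable are strongly collinear, so
        large opposing weight pairs can encode a near-flat density; the
        invariant checked is the entropy of the fitted distribution."""
        from scipy.special import logsumexp

        rng = np.random.default_rng(seed)
        x_bg = rng.uniform(0, 1, 1000)
        pres = rng.choice(1000, 100, replace=True)
        spec = simple_spec("lq")
        F_bg, _, cls = build_features(x_bg[:, None], spec)
        F_pres, _, _ = build_features(x_bg[pres, None], spec)
        from nichespread.maxent import _betas

        lam, _, _ = fit_matrix(F_pres, F_bg, _betas(F_bg, cls, 1.0, 100))
        s = F_bg @ lam
        p = np.exp(s - logsumexp(s))
        H = -np.sum(p * np.log(p))
        assert H >= 0.99 * np.log(1000)

    def test_single_feature_matches_1d_numeric_oracle(self):
        # one binary feature: presence mean 0.8, background mean 0.5
        F_bg = np.zeros((1000, 1))
        F_bg[:500, 0] = 1.0
        F_pres = np.zeros((100, 1))
        F_pres[:80, 0] = 1.0
        beta = np.array([1e-9])  # rm -> 0+
        lam, _, _ = fit_matrix(F_pres, F_bg, beta)

        def objective(l):
            s = F_bg[:, 0] * l
            m = s.max()
            return -0.8 * l + m + np.log(np.exp(s - m).sum())

        res = minimize_scalar(objective, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        assert abs(lam[0] - res.x) < 1e-4

    def test_multistart_objectives_agree(self):
        _, obj0, F_pres, F_bg, beta = fit_toy(seed=3, classes="lq")
        rng = np.random.default_rng(0)
        for _ in range(5):
            x0 = rng.uniform(-1, 1, F_bg.shape[1])
            _, obj, _ = fit_matrix(F_pres, F_bg, beta, x0=x0)
            assert abs(obj - obj0) < 1e-5

    def test_raw_conservation_after_fit(self, virtual_species):
        vs = virtual_species
        bg = np.ones(vs.env.template.shape, dtype=bool)
        spec = make_feature_spec(vs.env, bg, "lq")
        rows, cols = np.unravel_index(
            np.argsort(vs.true_suitability.values.ravel())[-50:], vs.env.template.shape
        )
        model = maxent.fit((rows, cols), np.nonzero(bg), vs.env, spec, 1.0)
        raw = maxent.raw_values(model, vs.env.to_matrix(np.nonzero(bg)))
        assert abs(raw.sum() - 1.0) < 1e-6
        assert 0.0 <= model.entropy_H <= np.log(bg.sum())


class TestPredict:
    def make_uniform_model(self, n_vars=1, n_bg=50):
        spec = simple_spec("l", n_vars=n_vars)
        lam = np.zeros(n_vars)
        return MaxentModel(
            spec=spec,
            rm=1.0,
            lambdas=lam,
            feature_names=[f"l(v{j + 1})" for j in range(n_vars)],
            log_partition=np.log(n_bg),
            entropy_H=np.log(n_bg),
        )

    def test_zero_lambdas_give_uniform_raw_and_closed_form_cloglog(self):
        model = self.make_uniform_model(n_bg=50)
        raw = maxent.raw_values(model, np.array([[0.3], [0.9]]))
        assert np.allclose(raw, 1.0 / 50)
        clog = maxent.cloglog_values(model, np.array([[0.3]]))
        assert abs(clog[0] - (1 - np.exp(-1))) < 1e-12

    def test_cloglog_is_monotone_in_raw(self):
        spec = simple_spec("l")
        model = MaxentModel(spec, 1.0, np.array([2.0]), ["l(v1)"], 0.0, 1.0)
        X = np.linspace(0, 1, 11)[:, None]
        raw = maxent.raw_values(model, X)
        clog = maxent.cloglog_values(model, X)
        assert np.all(np.diff(raw) > 0)
        assert np.all(np.diff(clog) > 0)
        assert np.argmax(raw) == np.argmax(clog)

    def test_hand_set_lambdas_match_direct_evaluation(self):
        rng = np.random.default_rng(8)
        X_bg = rng.uniform(0, 1, (10, 2))
        spec = simple_spec("lq", n_vars=2)
        lam = np.array([0.7, -1.2, 0.4, 0.9])
        F, _, _ = build_features(X_bg, spec)
        s = F @ lam
        log_Z = np.log(np.exp(s).sum())
        model = MaxentModel(spec, 1.0, lam, ["a"] * 4, log_Z, 1.0)
        raw = maxent.raw_values(model, X_bg)
        expected = np.exp(s) / np.exp(s).sum()
        assert np.allclose(raw, expected, atol=1e-10)


class TestTransfer:
    def make_model_and_stacks(self):
        t = make_template(n_rows=2, n_cols=3, cell_size=1.0, origin_lat=2.0)
        spec = simple_spec("lq", lo=0.0, hi=1.0)
        model = MaxentModel(spec, 1.0, np.array([1.5, -0.5]), ["l", "q"], 0.0, 1.0)
        inside = EnvStack({"v1": t.copy_with(np.linspace(0.1, 0.9, 6).reshape(2, 3))})
        vals = np.linspace(0.1, 0.9, 6).reshape(2, 3).copy()
        vals[0, 0] = 1.7  # above calibration max
        outside = EnvStack({"v1": t.copy_with(vals)})
        return model, inside, outside

    def test_modes_agree_within_calibration_range(self):
        model, inside, _ = self.make_model_and_stacks()
        layers = [maxent.transfer(model, inside, mode=m) for m in ("E", "EC", "NE")]
        assert np.allclose(layers[0].values, layers[1].values)
        assert np.allclose(layers[0].values, layers[2].values)

    def test_clamped_cell_equals_range_maximum_prediction(self):
        model, _, outside = self.make_model_and_stacks()
        ec = maxent.transfer(model, outside, mode="EC")
        at_max = maxent.cloglog_values(model, np.array([[1.0]]))
        assert abs(ec.values[0, 0] - at_max[0]) < 1e-12

    def test_no_extrapolation_masks_out_of_range_cell(self):
        model, _, outside = self.make_model_and_stacks()
        ne = maxent.transfer(model, outside, mode="NE")
        assert ne.values[0, 0] == ne.nodata
        assert ne.values[1, 2] != ne.nodata

    def test_unknown_mode_rejected(self):
        model, inside, _ = self.make_model_and_stacks()
        with pytest.raises(ValueError):
            maxent.transfer(model, inside, mode="X")


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_lq_model_ranks_cells_like_the_true_quadratic_niche(self, seed):
        """A fitted lq model recovers the ranking of a quadratic 1-variable
        truth (rank correlation > 0.9)."""
        env = generate_env(seed + 100, n_rows=45, n_cols=45, n_vars=2)
        truth = true_response(
            env, {"env1": (0.0, -2.5), "env2": (0.0, 0.0), "intercept": 1.0}
        )
        rng = np.random.default_rng(seed)
        p = truth.values.ravel() / truth.values.sum()
        pres = rng.choice(p.size, 200, p=p)
        bg = rng.choice(p.size, 2000, replace=False)
        rows_p, cols_p = np.unravel_index(pres, truth.shape)
        rows_b, cols_b = np.unravel_index(bg, truth.shape)
        sub = env.subset(["env1"])
        bg_mask = np.zeros(truth.shape, dtype=bool)
        bg_mask[rows_b, cols_b] = True
        spec = make_feature_spec(sub, bg_mask, "lq")
        model = maxent.fit((rows_p, cols_p), (rows_b, cols_b), sub, spec, 1.0)
        pred = maxent.raw_values(model, sub.to_matrix((rows_b, cols_b)))
        rho = spearmanr(pred, truth.values[rows_b, cols_b]).statistic
        assert rho > 0.9
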