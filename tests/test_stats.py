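"""Effect models, binwise t-tests, and fit-to-data correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from noisylex.stats import (
    binwise_ttests,
    effect_model_accuracy,
    factor_focused_fit,
    overall_fit,
)


def _simulate_trials(n, beta_int, beta_pos, beta_grp, seed, intercept=1.5):
    """Logistic trials over a 2 x 2 x 2-ish factorial with known effects."""
    rng = np.random.default_rng(seed)
    sd = rng.choice([0.0, 0.3, 0.6, 0.9], size=n)
    pos = rng.choice(["initial", "final"], size=n)
    grp = rng.choice(["native", "nonnative"], size=n)
    x_int = sd / 0.9
    eta = (intercept + beta_int * x_int + beta_pos * (pos == "initial")
           + beta_grp * (grp == "nonnative"))
    p = 1 / (1 + np.exp(-eta))
    return pd.DataFrame({
        "sd": sd, "position": pos, "version": grp,
        "correct": rng.random(n) < p,
        "replication": rng.integers(0, 5, size=n),
    })


def _irls_logistic(X, y, iters=50):
    """Plain iteratively-reweighted least squares, as an independent check."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / np.maximum(W, 1e-10)
        beta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
    return beta


class TestEffectModel:
    def test_null_group_effect_recovered(self):
        trials = _simulate_trials(4000, beta_int=-2.0, beta_pos=-0.5,
                                  beta_grp=0.0, seed=1)
        est = effect_model_accuracy(trials)
        assert abs(est["group_nonnative"].z) < 1.96

    def test_signs_recovered(self):
        trials = _simulate_trials(4000, beta_int=-2.0, beta_pos=-0.6,
                                  beta_grp=-0.4, seed=2)
        est = effect_model_accuracy(trials)
        assert est["intensity"].coef < 0
        assert est["position_initial"].coef < 0
        assert est["group_nonnative"].coef < 0

    def test_matches_independent_irls_fit(self):
        trials = _simulate_trials(200, beta_int=-1.5, beta_pos=-0.5,
                                  beta_grp=-0.3, seed=3)
        est = effect_model_accuracy(trials)
        X = np.column_stack([
            np.ones(len(trials)),
            trials["sd"] / 0.9,
            (trials["position"] == "initial").astype(float),
            (trials["version"] == "nonnative").astype(float),
        ])
        beta = _irls_logistic(X, trials["correct"].to_numpy(float))
        assert est["intensity"].coef == pytest.approx(beta[1], abs=1e-6)
        assert est["position_initial"].coef == pytest.approx(beta[2], abs=1e-6)
        assert est["group_nonnative"].coef == pytest.approx(beta[3], abs=1e-6)

    def test_parameter_recovery_error_shrinks_with_trials(self):
        beta_true = -1.8
        errs = []
        for n in (500, 50_000):
            err = []
            for seed in range(3):
                trials = _simulate_trials(n, beta_true, -0.5, -0.3, seed=10 + seed)
                est = effect_model_accuracy(trials)
                err.append(abs(est["intensity"].coef - beta_true))
            errs.append(np.mean(err))
        assert errs[1] < errs[0]

    def test_single_level_factor_dropped_with_warning(self):
        trials = _simulate_trials(500, -1.0, -0.5, -0.3, seed=4)
        trials["version"] = "native"
        with pytest.warns(UserWarning, match="group"):
            est = effect_model_accuracy(trials)
        assert "group_nonnative" not in est


class TestBinwiseTtests:
    def test_all_items_at_baseline_give_t0_p_half(self):
        df = pd.DataFrame({
            "word": list("abc") * 3,
            "t": [0] * 3 + [1] * 3 + [2] * 3,
            "log_pref_raw": [0.4] * 9,
        })
        res = binwise_ttests(df)
        assert (res["t_stat"] == 0).all()
        assert (res["p"] == 0.5).all()

    def test_matches_hand_computed_paired_t(self):
        # 3 items, baseline vs one bin
        base = np.array([0.1, 0.2, 0.3])
        bin1 = np.array([0.5, 0.4, 0.9])
        df = pd.DataFrame({
            "word": list("abc") * 2,
            "t": [0, 0, 0, 1, 1, 1],
            "log_pref_raw": np.concatenate([base, bin1]),
        })
        res = binwise_ttests(df)
        d = bin1 - base
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_hand = scipy.stats.t.sf(t_hand, df=2)
        assert res.loc[0, "t_stat"] == pytest.approx(t_hand)
        assert res.loc[0, "p"] == pytest.approx(p_hand)

    def test_zero_variance_nonzero_mean_gives_missing_p(self):
        df = pd.DataFrame({
            "word": list("abc") * 2,
            "t": [0, 0, 0, 1, 1, 1],
            "log_pref_raw": [0.0, 0.0, 0.0, 0.2, 0.2, 0.2],
        })
        res = binwise_ttests(df)
        assert np.isnan(res.loc[0, "p"])

    def test_fewer_than_two_items_rejected(self):
        df = pd.DataFrame({"word": ["a", "a"], "t": [0, 1],
                           "log_pref_raw": [0.0, 1.0]})
        with pytest.raises(ValueError):
            binwise_ttests(df)


def _table(values, source_measure="accuracy"):
    rows = []
    for (i, p, g), v in values.items():
        rows.append({"measure": source_measure, "intensity": i, "position": p,
                     "group": g, "value": v})
    return pd.DataFrame(rows)


@pytest.fixture()
def factorial_tables():
    cells = [(i, p, g) for i in (0.0, 0.9) for p in ("ini", "fin")
             for g in ("nat", "non")]
    rng = np.random.default_rng(3)
    human = {c: float(rng.random()) for c in cells}
    return cells, human


class TestFitCorrelations:
    def test_duplicated_table_gives_r_one(self, factorial_tables):
        _, human = factorial_tables
        r, p = overall_fit(_table(human), _table(human), "accuracy")
        assert r == pytest.approx(1.0)

    def test_anti_ordered_tables_give_r_minus_one(self, factorial_tables):
        cells, human = factorial_tables
        anti = {c: -v for c, v in human.items()}
        r, _ = overall_fit(_table(anti), _table(human), "accuracy")
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self):
        model = {(i, "ini", "nat"): v for i, v in
                 zip((0.0, 0.3, 0.6, 0.9, 1.2, 1.5), (9, 7, 6, 4, 3, 1))}
        human = {(i, "ini", "nat"): v for i, v in
                 zip((0.0, 0.3, 0.6, 0.9, 1.2, 1.5), (8, 8, 5, 5, 2, 2))}
        r, _ = overall_fit(_table(model), _table(human), "accuracy")
        x = np.array([9, 7, 6, 4, 3, 1], float)
        y = np.array([8, 8, 5, 5, 2, 2], float)
        r_brute = (((x - x.mean()) * (y - y.mean())).sum()
                   / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(r_brute)

    def test_too_few_cells_rejected(self):
        t = _table({(0.0, "ini", "nat"): 1.0, (0.9, "ini", "nat"): 0.5})
        with pytest.raises(ValueError):
            overall_fit(t, t, "accuracy")

    def test_invariant_to_constant_shift(self, factorial_tables):
        _, human = factorial_tables
        model = {c: v * 0.5 + 0.1 for c, v in human.items()}
        r1, _ = overall_fit(_table(model), _table(human), "accuracy")
        shifted_m = {c: v + 5 for c, v in model.items()}
        shifted_h = {c: v + 5 for c, v in human.items()}
        r2, _ = overall_fit(_table(shifted_m), _table(shifted_h), "accuracy")
        assert r1 == pytest.approx(r2)


class TestFactorFocusedFit:
    def test_identical_tables_give_r_one(self, factorial_tables):
        _, human = factorial_tables
        r, _ = factor_focused_fit(_table(human), _table(human), "accuracy",
                                  factor="group", baseline_level="nat")
        assert r == pytest.approx(1.0)

    def test_zero_model_differences_reported_as_non_capture(self, factorial_tables):
        cells, human = factorial_tables
        # a model identical across groups (the untrained baseline's signature)
        flat = {c: human[(c[0], c[1], "nat")] for c in cells}
        r, p = factor_focused_fit(_table(flat), _table(human), "accuracy",
                                  factor="group", baseline_level="nat")
        assert np.isnan(r) and np.isnan(p)

    def test_matches_hand_enumerated_difference_vector(self, factorial_tables):
        cells, human = factorial_tables
        rng = np.random.default_rng(9)
        model = {c: float(rng.random()) for c in cells}
        r, _ = factor_focused_fit(_table(model), _table(human), "accuracy",
                                  factor="intensity", baseline_level=0.0)
        dm, dh = [], []
        for p in ("ini", "fin"):
            for g in ("nat", "non"):
                dm.append(model[(0.9, p, g)] - model[(0.0, p, g)])
                dh.append(human[(0.9, p, g)] - human[(0.0, p, g)])
        r_hand, _ = scipy.stats.pearsonr(dm, dh)
        assert r == pytest.approx(r_hand)

    def test_incomplete_cells_rejected(self, factorial_tables):
        cells, human = factorial_tables
        partial = dict(human)
        del partial[(0.9, "fin", "non")]
        with pytest.raises(ValueError, match="incomplete"):
            factor_focused_fit(_table(partial), _table(human), "accuracy",
                               factor="intensity", baseline_level=0.0)
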