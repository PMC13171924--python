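import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from tubertrace import (
    PresenceMap,
    GroupKey,
    SeparationError,
    bh_adjust,
    bias_reduced_fit,
    build_trials,
    classify_transfer,
    fit_binomial_glm,
    paired_wilcoxon,
)


def _trials(successes, trials, **factors):
    df = pd.DataFrame({"successes": successes, "trials": trials})
    for k, v in factors.items():
        df[k] = v
    return df


class TestBuildTrials:
    def _classification(self, seed, daughter, granddaughter):
        pm = PresenceMap({
            GroupKey(generation=g, compartment="flesh", cultivar="N"): frozenset(s)
            for g, s in [("seed", seed), ("daughter", daughter),
                         ("granddaughter", granddaughter)]
        })
        return classify_transfer(pm, ("flesh", "N", None), mode="chain")

    def test_successes_and_trials_from_chain(self):
        seed = {f"t{i}" for i in range(50)}
        daughter = {f"t{i}" for i in range(9)} | {"x1", "x2"}
        cls = self._classification(seed, daughter, {"t0", "t1"})
        rows = build_trials([cls])
        assert rows.iloc[0].to_dict() == {
            "compartment": "flesh", "cultivar": "N", "field": "(none)",
            "transition": "seed_to_daughter", "successes": 9, "trials": 50,
        }
        assert rows.iloc[1]["trials"] == 9 and rows.iloc[1]["successes"] == 2

    def test_conservation(self):
        cls = self._classification(set("abcdef"), set("abcz"), set("ab"))
        rows = build_trials([cls])
        assert (rows["successes"] <= rows["trials"]).all()

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="no usable contexts"):
            rows = build_trials([])
        assert rows.empty


class TestBinomialGlm:
    def test_intercept_only_is_pooled_logit(self):
        res = fit_binomial_glm(_trials([3, 5], [10, 10]), [])
        assert res.coef.iloc[0] == pytest.approx(np.log(0.4 / 0.6), abs=1e-9)

    def test_two_by_two_closed_form(self):
        data = _trials([8, 2], [10, 10], g=["a", "b"])
        res = fit_binomial_glm(data, ["g"], coding="treatment")
        assert res.coef["g[T.a]"] == pytest.approx(np.log(16.0), abs=1e-7)
        se2 = 1 / 8 + 1 / 2 + 1 / 2 + 1 / 8
        chi2 = np.log(16.0) ** 2 / se2
        assert res.wald["chi2"].iloc[0] == pytest.approx(chi2, rel=1e-6)
        # term chi-square is invariant to the coding
        res_sum = fit_binomial_glm(data, ["g"], coding="sum")
        assert res_sum.wald["chi2"].iloc[0] == pytest.approx(chi2, rel=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 24
        data = _trials(
            rng.integers(1, 9, n), 10,
            g=np.repeat(["a", "b", "c"], 8), h=list("xy") * 12,
        )
        res = fit_binomial_glm(data, ["g", "h"], coding="treatment")
        X = pd.get_dummies(data[["g", "h"]], drop_first=False)
        Xm = np.column_stack([
            np.ones(n), X["g_a"], X["g_b"], X["h_x"],
        ]).astype(float)
        fit = sm.GLM(
            np.column_stack([data.successes, data.trials - data.successes]),
            Xm, family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(np.sort(res.coef.to_numpy()),
                                   np.sort(fit.params), rtol=1e-6)

    def test_cluster_robust_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 20
        data = _trials(
            rng.integers(1, 9, n), 10,
            g=np.repeat(["a", "b"], 10), field=list("pqrs") * 5,
        )
        res = fit_binomial_glm(data, ["g"], robust_cluster="field",
                               coding="treatment")
        X = np.column_stack([
            np.ones(n), (data["g"] == "a").to_numpy(float)
        ])
        fit = sm.GLM(
            np.column_stack([data.successes, data.trials - data.successes]),
            X, family=sm.families.Binomial(),
        ).fit(cov_type="cluster",
              cov_kwds={"groups": data["field"].to_numpy(), "use_correction": False})
        np.testing.assert_allclose(
            np.sort(res.se.to_numpy()), np.sort(fit.bse), rtol=1e-5
        )

    def test_separation_raises_with_advice(self):
        data = _trials([10, 3], [10, 10], g=["a", "b"])
        with pytest.raises(SeparationError, match="bias_reduced_fit"):
            fit_binomial_glm(data, ["g"])

    def test_quasi_dispersion_inflates_se(self):
        rng = np.random.default_rng(11)
        data = _trials(rng.integers(0, 11, 30), 10)
        plain = fit_binomial_glm(data, [])
        quasi = fit_binomial_glm(data, [], quasi=True)
        assert quasi.dispersion > 1
        assert (quasi.se > plain.se).all()

    def test_marginal_probabilities_bounded_and_ordered(self):
        data = _trials([8, 7, 2, 3], [10, 10, 10, 10], g=list("aabb"))
        res = fit_binomial_glm(data, ["g"])
        m = res.marginal
        assert ((m["ci_low"] <= m["prob"]) & (m["prob"] <= m["ci_high"])).all()
        assert ((m["prob"] >= 0) & (m["prob"] <= 1)).all()

    def test_recovers_compartment_contrast(self):
        """Flesh-vs-peel retention difference is recovered from trials
        simulated at 0.05 vs 0.03 (study-scale design)."""
        from tubertrace import simulate_retention_trials

        rng = np.random.default_rng(99)
        data = simulate_retention_trials(
            {"flesh": 0.05, "peel": 0.03}, 20, 300, rng
        )
        res = fit_binomial_glm(data, ["compartment"])
        m = res.marginal.set_index("level")
        assert m.loc["flesh", "prob"] == pytest.approx(0.05, abs=0.01)
        assert m.loc["peel", "prob"] == pytest.approx(0.03, abs=0.01)
        assert m.loc["flesh", "prob"] > m.loc["peel", "prob"]


class TestFirthFit:
    def test_finite_under_separation(self):
        data = _trials([10, 3], [10, 10], g=["a", "b"])
        res = bias_reduced_fit(data, ["g"])
        assert np.isfinite(res.coef).all()
        assert res.converged

    def test_close_to_ml_on_large_samples(self):
        rng = np.random.default_rng(8)
        p = {"a": 0.3, "b": 0.6}
        data = _trials(
            [rng.binomial(200, p[g]) for g in "ab"], 200, g=["a", "b"]
        )
        ml = fit_binomial_glm(data, ["g"])
        firth = bias_reduced_fit(data, ["g"])
        np.testing.assert_allclose(
            firth.coef.to_numpy(), ml.coef.to_numpy(), atol=0.05
        )

    def test_label_swap_flips_sign(self):
        d1 = _trials([8, 2], [10, 10], g=["a", "b"])
        d2 = _trials([2, 8], [10, 10], g=["a", "b"])
        r1 = bias_reduced_fit(d1, ["g"], coding="sum")
        r2 = bias_reduced_fit(d2, ["g"], coding="sum")
        assert r1.coef["g[S.a]"] == pytest.approx(-r2.coef["g[S.a]"], abs=1e-6)


def oracle_signed_rank_p(d):
    """Exact two-sided signed-rank p by full enumeration of sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.asarray(ws, dtype=float)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


class TestPairedWilcoxon:
    def test_five_concordant_pairs_exact(self):
        x = np.array([2.0, 3.0, 5.0, 9.0, 4.0])
        y = x - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(0.0625)

    def test_three_pairs_exact(self):
        _, p = paired_wilcoxon(np.array([3.0, 5.0, 9.0]), np.array([1.0, 2.0, 3.0]))
        assert p == pytest.approx(0.25)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.normal(size=n)
        y = x - rng.normal(0.3, 1.0, size=n)
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(oracle_signed_rank_p(x - y), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(size=40)
        y = x - rng.normal(0.5, 1.0, size=40)
        _, p = paired_wilcoxon(x, y)
        assert 0 < p < 0.05


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_dominates_raw_and_monotone(self, rng):
        p = rng.random(30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
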