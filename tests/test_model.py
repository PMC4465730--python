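"""Conditional-logit likelihood, fitting, LR tests and recovery behavior."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

import paypref as pp
from paypref.model import (
    ConditionalLogit,
    ConditionalLogitResults,
    EstimationError,
    IdentifiabilityError,
    ModelSpec,
    log_likelihood,
)
from paypref.simulate import TruthSpec


def loglike_oracle(dataset, beta):
    """Brute-force per-set probability product, in log space row by row."""
    from paypref.schema import effects_code

    schema = dataset.schema
    total = 0.0
    for (_, _), grp in dataset.choices.groupby(["respondent_id", "set_id"]):
        grp = grp.sort_values("alt")
        utils = []
        for _, row in grp.iterrows():
            prof = {a: row[a] for a in schema.ids}
            utils.append(float(effects_code(schema, prof) @ beta))
        u = np.array(utils)
        p = np.exp(u - u.max())
        p = p / p.sum()
        chosen = int(np.flatnonzero(grp["chosen"].to_numpy())[0])
        total += np.log(p[chosen])
    return total


@pytest.fixture(scope="module")
def toy_dataset(tiny_design):
    truth = TruthSpec(base=np.linspace(-0.6, 0.6, 8), completion=0.8)
    pop = pp.generate_population(30, seed=21, n_blocks=1)
    return pp.simulate_choices(tiny_design, pop, truth, seed=22)


class TestLogLikelihood:
    def test_null_closed_form(self, toy_dataset):
        n = toy_dataset.n_answered
        ll = log_likelihood(toy_dataset, ModelSpec(), np.zeros(8))
        assert ll == n * np.log(0.5)

    def test_matches_brute_force_oracle(self, toy_dataset):
        rng = np.random.default_rng(2)
        for _ in range(3):
            beta = rng.normal(scale=0.8, size=8)
            ll = log_likelihood(toy_dataset, ModelSpec(), beta)
            assert ll == pytest.approx(loglike_oracle(toy_dataset, beta), abs=1e-10)

    def test_saturation_limit_single_set(self, toy_dataset):
        """On one answered set, pushing the chosen alternative's utility to
        +infinity drives the log-likelihood to 0 from below."""
        from paypref.model import _loglike

        model = ConditionalLogit(toy_dataset, ModelSpec())
        z = model.exog[0]
        y = np.array([model.endog[0]])
        s = 2.0 * model.endog[0] - 1.0
        lls = [_loglike(z[None, :], y, t * s * z) for t in (0.0, 1.0, 10.0)]
        assert lls[0] < lls[1] < lls[2] < 0.0
        assert lls[2] == pytest.approx(0.0, abs=1e-3)

    def test_dimension_mismatch(self, toy_dataset):
        with pytest.raises(EstimationError):
            log_likelihood(toy_dataset, ModelSpec(), np.zeros(5))


class TestFit:
    def test_matches_statsmodels_logit_on_differences(self, toy_dataset):
        """Independent route: binary logit on the differenced design matrix."""
        import statsmodels.api as sm

        model = ConditionalLogit(toy_dataset, ModelSpec())
        res = model.fit()
        ref = sm.Logit(model.endog, model.exog).fit(disp=0)
        assert res.params == pytest.approx(ref.params, abs=1e-6)
        assert res.bse == pytest.approx(ref.bse, abs=1e-6)
        assert res.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_deterministic_refit(self, toy_dataset):
        r1 = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        r2 = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        assert np.array_equal(r1.params, r2.params)

    def test_optimum_beats_null(self, toy_dataset):
        res = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        assert res.converged
        assert res.llf > res.llnull

    def test_never_varying_attribute_rejected(self, toy_dataset):
        """Freezing one attribute equal across profiles kills its columns."""
        ch = toy_dataset.choices.copy()
        ch["a4"] = "no_change"
        ds = pp.ChoiceDataset(toy_dataset.schema, toy_dataset.respondents, ch)
        with pytest.raises(IdentifiabilityError) as err:
            ConditionalLogit(ds, ModelSpec())
        assert "a4" in str(err.value)

    def test_invariant_to_alternative_relabeling(self, toy_dataset):
        """Swapping alt 1/2 rows (and the chosen flags with them) must leave
        the estimates untouched."""
        ch = toy_dataset.choices.copy()
        ch["alt"] = 3 - ch["alt"]
        ds = pp.ChoiceDataset(toy_dataset.schema, toy_dataset.respondents, ch)
        r1 = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        r2 = ConditionalLogit(ds, ModelSpec()).fit()
        assert r1.params == pytest.approx(r2.params, abs=1e-8)

    def test_interaction_columns_labeled(self, toy_dataset):
        spec = ModelSpec(interactions=(("female", "a1"),), adjustments=("age",))
        model = ConditionalLogit(toy_dataset, spec)
        assert "female*a1:pos" in model.exog_names
        assert "age*a1:pos" in model.exog_names
        assert model.exog.shape[1] == 8 + 2 + 8

    def test_fit_report_roundtrip(self, toy_dataset, tmp_path):
        res = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        path = tmp_path / "fit.json"
        res.save(path)
        loaded = ConditionalLogitResults.load(path, toy_dataset.schema)
        assert loaded.params == pytest.approx(res.params)
        assert loaded.llf == pytest.approx(res.llf)
        assert loaded.lr_table()["p_value"].tolist() == pytest.approx(
            res.lr_table()["p_value"].tolist()
        )

    def test_summary_mentions_fit_quality(self, toy_dataset):
        res = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        text = res.summary()
        assert "Log-likelihood" in text
        assert "a1:pos" in text


class TestLrTest:
    def test_statistic_nonnegative_df_and_p(self, toy_dataset):
        res = ConditionalLogit(toy_dataset, ModelSpec()).fit()
        stat, df, p = res.lr_test("a2")
        assert stat >= 0
        assert df == 2
        assert 0 <= p <= 1

    def test_full_as_reduced_gives_zero_statistic(self, toy_dataset):
        """Refitting the untouched full matrix as the 'reduced' model must
        reproduce the full log-likelihood, i.e. LR statistic 0 and p = 1."""
        from scipy.stats import chi2

        from paypref.model import _newton_loglike

        model = ConditionalLogit(toy_dataset, ModelSpec())
        res = model.fit()
        ll_red = _newton_loglike(model.exog, model.endog)
        stat = max(0.0, 2.0 * (res.llf - ll_red))
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert chi2.sf(stat, 2) == pytest.approx(1.0, abs=1e-6)

    def test_matches_two_fit_construction(self, toy_dataset):
        """LR stat equals 2*(LL_full - LL_reduced) with the reduced model
        refitted independently on the column-dropped matrix."""
        import statsmodels.api as sm

        model = ConditionalLogit(toy_dataset, ModelSpec())
        res = model.fit()
        j0, j1 = toy_dataset.schema.columns_of("a3")
        keep = [j for j in range(model.exog.shape[1]) if j not in (j0, j1)]
        red = sm.Logit(model.endog, model.exog[:, keep]).fit(disp=0)
        stat, df, p = res.lr_test("a3")
        assert stat == pytest.approx(2 * (res.llf - red.llf), abs=1e-6)


class TestRecoveryScaling:
    def test_error_decreases_with_sample_size(self, tiny_design):
        """Mean absolute estimation error shrinks from n=80 to n=500 (two
        replicates each, fixed seeds)."""
        truth = TruthSpec(base=np.linspace(-0.6, 0.6, 8), completion=0.9)
        maes = {}
        for n in (80, 500):
            errs = []
            for rep in range(2):
                pop = pp.generate_population(n, seed=100 + rep, n_blocks=1)
                ds = pp.simulate_choices(tiny_design, pop, truth, seed=200 + rep)
                res = ConditionalLogit(ds, ModelSpec()).fit()
                errs.append(np.abs(res.params - truth.base).mean())
            maes[n] = np.mean(errs)
        assert maes[500] < maes[80]
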