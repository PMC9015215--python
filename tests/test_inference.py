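"""Sampler behaviour, diagnostics and reduced-model oracles."""

import numpy as np
import pytest

import coopsem as cs
from coopsem.gibbs import GibbsSampler, Priors
from coopsem.inference import gelman_rubin, hpdi, senescence_onset, senescence_onset_draws
from coopsem.simulate import ordinalize
from coopsem.validation import make_single_factor_problem


def test_identical_seed_gives_identical_draws(tiny_dataset):
    spec = cs.build_model_spec("M6")
    mcmc = cs.McmcConfig(n_chains=1, n_iterations=150, n_burnin=50, thin=2, seed=13)
    a = cs.fit(spec, tiny_dataset, mcmc)
    b = cs.fit(spec, tiny_dataset, mcmc)
    for name in a.draws:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])
    np.testing.assert_array_equal(a.predictive.yrep_mean, b.predictive.yrep_mean)


def test_reference_loadings_fixed_at_one(small_fit):
    for name in ("lambda[wg_offspring]", "lambda[group_size]", "lambda[territory_size]"):
        assert np.all(small_fit.draws[name] == 1.0)


def test_constrained_parameters_identical_between_sexes(small_fit):
    """Under ♀=♂ flags the two samples literally share draws."""
    d = small_fit.by_sample("beta_se", "female") - small_fit.by_sample("beta_se", "male")
    assert np.all(d == 0.0)


def test_unconstrained_model_lets_sexes_differ(tiny_dataset):
    spec = cs.build_model_spec("M1")
    mcmc = cs.McmcConfig(n_chains=1, n_iterations=200, n_burnin=100, thin=2, seed=3)
    samples = cs.fit(spec, tiny_dataset, mcmc)
    f = samples.by_sample("beta_se", "female")
    m = samples.by_sample("beta_se", "male")
    assert not np.array_equal(f, m)


def test_threshold_draws_strictly_ordered(small_fit):
    for name in ("wg_offspring", "group_size", "insect_avail"):
        cols = sorted(k for k in small_fit.draws if k.startswith(f"tau[{name},"))
        stacked = np.stack([small_fit.draws[c] for c in cols])
        assert np.all(np.diff(stacked, axis=0) > 0)


def test_validation_errors_before_sampling(small_dataset):
    spec = cs.build_model_spec("M6")
    # categories outside the declared range
    broken = small_dataset.records.copy()
    broken.loc[broken.index[0], "n_helpers"] = 9
    with pytest.raises(ValueError, match="outside"):
        cs.fit(spec, cs.Dataset(records=broken, categories=small_dataset.categories))
    # entirely missing indicator
    broken = small_dataset.records.copy()
    broken["insect_avail"] = np.nan
    broken["insect_avail"] = broken["insect_avail"].astype("Int64")
    with pytest.raises(ValueError, match="missing"):
        cs.fit(spec, cs.Dataset(records=broken, categories=small_dataset.categories))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_gelman_rubin_duplicate_chains_is_exactly_one():
    chain = np.random.default_rng(0).standard_normal(500)
    stat = gelman_rubin({"x": np.stack([chain, chain])})["x"]
    assert stat == 1.0


def test_gelman_rubin_flags_separated_chains():
    rng = np.random.default_rng(1)
    chains = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 5.0])
    assert gelman_rubin({"x": chains})["x"] > 1.05


def test_gelman_rubin_requires_two_chains():
    with pytest.raises(ValueError):
        gelman_rubin({"x": np.zeros((1, 100))})


def test_hpdi_constant_draws():
    lo, hi = hpdi(np.full(100, 2.5))
    assert lo == hi == 2.5


def test_hpdi_standard_normal():
    x = np.random.default_rng(2).standard_normal(200_000)
    lo, hi = hpdi(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hpdi_matches_exhaustive_search_and_beats_equal_tails():
    rng = np.random.default_rng(3)
    x = rng.gamma(2.0, size=5000)  # skewed
    lo, hi = hpdi(x, 0.9)
    # brute-force shortest window oracle
    xs = np.sort(x)
    n_inc = int(np.ceil(0.9 * xs.size))
    widths = [xs[i + n_inc - 1] - xs[i] for i in range(xs.size - n_inc + 1)]
    k = int(np.argmin(widths))
    assert (lo, hi) == (xs[k], xs[k + n_inc - 1])
    eq_lo, eq_hi = np.quantile(x, [0.05, 0.95])
    assert hi - lo < eq_hi - eq_lo
    # independent implementation cross-check
    az = pytest.importorskip("arviz")
    ref = az.hdi(x, hdi_prob=0.9)
    assert lo == pytest.approx(ref[0], abs=0.02) and hi == pytest.approx(ref[1], abs=0.02)


def test_hpdi_input_validation():
    with pytest.raises(ValueError):
        hpdi(np.array([]))
    with pytest.raises(ValueError):
        hpdi(np.array([1.0]))
    with pytest.raises(ValueError):
        hpdi(np.arange(10), prob=1.2)


def test_senescence_onset_vertex():
    assert senescence_onset(1.4, -0.1) == pytest.approx(7.0)
    assert senescence_onset(0.6, -0.05) == pytest.approx(6.0)
    # back-transform to years when coefficients act on standardised age
    assert senescence_onset(0.4, -0.3, age_center=5.0, age_scale=3.0) == pytest.approx(7.0)


def test_senescence_onset_requires_concave_profile():
    with pytest.raises(ValueError):
        senescence_onset(1.0, 0.0)
    with pytest.raises(ValueError):
        senescence_onset(1.0, 0.2)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_summary_empty_without_missingness(small_fit):
    assert cs.impute_summary(small_fit).empty


def test_impute_probabilities_normalised(tiny_dataset):
    masked = cs.apply_missingness(tiny_dataset, 0.15, seed=7)
    spec = cs.build_model_spec("M6")
    mcmc = cs.McmcConfig(n_chains=1, n_iterations=200, n_burnin=100, thin=2, seed=8)
    samples = cs.fit(spec, masked, mcmc)
    summary = cs.impute_summary(samples)
    assert len(summary) == int(masked.records.isna().sum().sum())
    probs = summary[[c for c in summary.columns if c.startswith("p")]].to_numpy()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# reduced-model oracles
# ---------------------------------------------------------------------------

def test_reduction_to_single_level_fit(tiny_dataset):
    """With group/individual variances absent from the data, the three-level
    machinery and an explicitly single-level fit agree on the SE effect."""
    params = cs.default_true_parameters("direct")
    params.sigma2[:, 2] += params.sigma2[:, 0] + params.sigma2[:, 1]
    params.sigma2[:, 0] = 0.0
    params.sigma2[:, 1] = 0.0
    ds = cs.generate_dataset(
        cs.GeneratorConfig(n_groups=60, years=4, true_params=params, seed=17)
    )
    spec = cs.build_model_spec("M6")
    mcmc3 = cs.McmcConfig(n_chains=1, n_iterations=1200, n_burnin=500, thin=3, seed=19)
    mcmc1 = cs.McmcConfig(
        n_chains=1, n_iterations=1200, n_burnin=500, thin=3, seed=19,
        disable_levels=("group", "individual"),
    )
    full = cs.fit(spec, ds, mcmc3).flat("beta_se").mean()
    single = cs.fit(spec, ds, mcmc1).flat("beta_se").mean()
    assert full == pytest.approx(single, abs=0.15)


def test_ordinal_probit_regression_against_ml_oracle():
    """Degenerate single-latent case is ordinal probit regression; the
    posterior mean tracks the maximum-likelihood estimate and the 95% HPDI
    covers the generating coefficient in most replicates."""
    OrderedModel = pytest.importorskip(
        "statsmodels.miscmodels.ordinal_model"
    ).OrderedModel
    gamma_true = np.array([0.8, -0.5])
    cuts = np.array([-0.7, 0.8])
    hits, ml_agree = 0, 0
    n_rep = 8
    for rep in range(n_rep):
        rng = np.random.default_rng(100 + rep)
        x = rng.standard_normal((400, 2))
        y = ordinalize(x @ gamma_true + rng.standard_normal(400), cuts)
        problem = make_single_factor_problem(
            y[:, None], (3,), covariates=x, fix_within_variance=0.0
        )
        sampler = GibbsSampler(problem, priors=Priors(), seed=rep, adapt=True)
        draws = []
        for it in range(900):
            sampler.sweep(burnin=it < 300)
            if it >= 300 and it % 2 == 0:
                draws.append(sampler.state.gamma.copy())
        draws = np.array(draws)
        res = OrderedModel(y, x, distr="probit").fit(method="bfgs", disp=False)
        mle = res.params[:2]
        se = res.bse[:2]
        if np.all(np.abs(draws.mean(0) - mle) < 2.5 * se):
            ml_agree += 1
        lo0, hi0 = hpdi(draws[:, 0])
        lo1, hi1 = hpdi(draws[:, 1])
        if lo0 <= gamma_true[0] <= hi0 and lo1 <= gamma_true[1] <= hi1:
            hits += 1
    assert ml_agree >= n_rep - 1
    assert hits >= n_rep - 2


def test_senescence_onset_draws_use_age_scale(small_fit):
    onset = senescence_onset_draws(small_fit)
    assert onset.size > 0
    g1 = small_fit.flat("gamma1")
    g2 = small_fit.flat("gamma2")
    neg = g2 < 0
    manual = 5.0 + 3.0 * (-g1[neg] / (2 * g2[neg]))
    np.testing.assert_allclose(onset, manual)
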