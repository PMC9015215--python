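"""Sampler validation utilities: reduced models and joint-distribution checks.

The strongest correctness check for a Gibbs sampler is the joint-distribution
(simulator-vs-sampler) test: alternate (a) an exact forward draw of latent
values and data given the current parameters with (b) one Gibbs transition of
parameters and latents given the data. The resulting Markov chain leaves the
joint distribution ``p(theta) p(latents, y | theta)`` invariant, so the
marginal distribution of each parameter along the chain must equal its prior.
Any error in a conditional update shows up as a detectable deviation, which we
measure with Kolmogorov-Smirnov tests against the analytic prior CDFs.

The check runs on a reduced single-factor model (one latent, two ordinal
indicators, a handful of independent records) that still exercises every kind
of conditional: truncated-normal augmentation, latent shocks, a free loading,
thresholds by Metropolis-Hastings, and the variance component.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .gibbs import GibbsSampler, Priors, Problem
from .simulate import ordinalize

GEWEKE_PRIORS = Priors(
    coef_sd=1.0, tau_sd=1.0, sigma_prior="inv_gamma", ig_shape=3.0, ig_rate=2.0
)


def make_single_factor_problem(
    y: np.ndarray,
    categories: tuple[int, ...],
    covariates: np.ndarray | None = None,
    fixed_tau: list | None = None,
    fix_within_variance: float | None = None,
) -> Problem:
    """Compile a one-latent, one-sample, single-level ordinal factor model.

    With ``covariates`` given, ``fix_within_variance=0`` and fixed thresholds
    this reduces to ordinal probit regression; with a free loading and free
    variance it is the reduced model used for sampler validation.
    """
    y = np.asarray(y, dtype=int)
    n, j = y.shape
    fixed_sigma2 = np.full((1, 3), np.nan)
    if fix_within_variance is not None:
        fixed_sigma2[0, 2] = fix_within_variance
    return Problem(
        y=y,
        categories=tuple(categories),
        ind_latent=np.zeros(j, dtype=int),
        ref=np.array([True] + [False] * (j - 1)),
        lam_shared=np.ones(j, dtype=bool),
        tau_shared=np.ones(j, dtype=bool),
        n_latents=1,
        structure="none",
        sample_idx=np.zeros(n, dtype=int),
        n_samples=1,
        group_idx=None,
        n_groups=1,
        ind_idx=None,
        n_individuals=1,
        covariates=covariates,
        fixed_tau=fixed_tau,
        fixed_sigma2=fixed_sigma2,
    )


def _prior_draw(rng: np.random.Generator, priors: Priors, n_thresholds: int = 2):
    lam = priors.coef_sd * rng.standard_normal()
    sigma2 = priors.ig_rate / rng.gamma(priors.ig_shape)
    taus = [
        np.sort(priors.tau_sd * rng.standard_normal(n_thresholds)) for _ in range(2)
    ]
    return lam, sigma2, taus


def geweke_draws(
    n_records: int = 20,
    n_cycles: int = 30_000,
    thin: int = 60,
    seed: int = 0,
    priors: Priors = GEWEKE_PRIORS,
) -> dict[str, np.ndarray]:
    """Successive-conditional chain; returns parameter draws to compare to priors."""
    rng = np.random.default_rng(seed)
    lam, sigma2, taus = _prior_draw(rng, priors)
    # initial forward data
    f = np.sqrt(sigma2) * rng.standard_normal(n_records)
    ystar = np.column_stack([f, lam * f]) + rng.standard_normal((n_records, 2))
    y = np.column_stack([ordinalize(ystar[:, k], taus[k]) for k in range(2)])
    problem = make_single_factor_problem(y, (3, 3))
    sampler = GibbsSampler(
        problem,
        priors=priors,
        seed=rng.integers(2**31),
        adapt=False,
        scale_reps=1,
        tau_reps=1,
    )
    for key in sampler.tau_scales:
        sampler.tau_scales[key] = 0.5
    st = sampler.state
    st.lam[0, 1] = lam
    st.sigma2[0, 2] = sigma2
    for k in range(2):
        st.tau[k][0] = taus[k]
    st.w[:, 0] = f
    st.ystar = ystar

    def tau_independence_move() -> None:
        # propose threshold vectors from the prior (sorted iid normals);
        # prior and proposal densities cancel, leaving the likelihood ratio.
        # Cheap full decorrelation at this data size; follows the same
        # collapsed-then-redraw pattern as the random-walk update.
        means = sampler._means()
        rows = np.ones(problem.n_records, dtype=bool)
        for _ in range(10):
            for jj in range(problem.n_indicators):
                cur = st.tau[jj][0]
                prop = np.sort(priors.tau_sd * rng.standard_normal(cur.size))
                ll_cur = sampler._tau_loglik(jj, rows, cur, means[:, jj])
                ll_prop = sampler._tau_loglik(jj, rows, prop, means[:, jj])
                if np.log(rng.random()) < ll_prop - ll_cur:
                    st.tau[jj][:] = prop
        sampler._draw_ystar()

    out = {"lambda": [], "sigma2": [], "tau_first": []}
    for cycle in range(n_cycles):
        sampler.forward_redraw()
        sampler.sweep(burnin=False)
        tau_independence_move()
        if cycle % thin == 0:
            out["lambda"].append(st.lam[0, 1])
            out["sigma2"].append(st.sigma2[0, 2])
            out["tau_first"].append(st.tau[0][0, 0])
    return {k: np.asarray(v) for k, v in out.items()}


def geweke_ks_pvalues(
    seed: int = 0,
    n_records: int = 20,
    n_cycles: int = 30_000,
    thin: int = 60,
    priors: Priors = GEWEKE_PRIORS,
) -> dict[str, float]:
    """KS p-values of sampler marginals against the analytic prior CDFs."""
    draws = geweke_draws(
        n_records=n_records, n_cycles=n_cycles, thin=thin, seed=seed, priors=priors
    )
    lam_cdf = stats.norm(scale=priors.coef_sd).cdf
    sig_cdf = stats.invgamma(priors.ig_shape, scale=priors.ig_rate).cdf

    def min2_cdf(x):  # first cut point = min of two iid normals
        return 1.0 - (1.0 - ndtr(np.asarray(x) / priors.tau_sd)) ** 2

    return {
        "lambda": float(stats.kstest(draws["lambda"], lam_cdf).pvalue),
        "sigma2": float(stats.kstest(draws["sigma2"], sig_cdf).pvalue),
        "tau_first": float(stats.kstest(draws["tau_first"], min2_cdf).pvalue),
    }
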