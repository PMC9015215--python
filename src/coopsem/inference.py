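"""Fitting the model family by MCMC: configuration, draws and diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import GibbsSampler, Priors, Problem
from .simulate import Dataset
from .specs import (
    AGE_CENTER,
    AGE_SCALE,
    INDICATORS,
    LATENTS,
    LEVELS,
    SAMPLES,
    ModelSpec,
)


@dataclass
class McmcConfig:
    """Chain layout and priors for one fit.

    Defaults (3 chains of 10,000 iterations, half burn-in, thin 5) are sized so
    that a full-model fit on a synthetic population of ~100 territories
    completes in minutes on one core; recovery and selection experiments in the
    test-suite run far shorter chains.
    """

    n_chains: int = 3
    n_iterations: int = 10_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    jitter: float = 0.5  # overdispersion of chain starting points
    adapt: bool = True
    disable_levels: tuple[str, ...] = ()  # e.g. ("group", "individual")

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.n_burnin < self.n_iterations:
            raise ValueError("burn-in must be positive and below n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for lev in self.disable_levels:
            if lev not in ("group", "individual"):
                raise ValueError(f"cannot disable level {lev!r}")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PredictiveSummary:
    """Per-cell posterior-predictive moments on the continuous scale."""

    yrep_mean: np.ndarray  # (N, J) E(y_rep | Y, M)
    yrep_var: np.ndarray  # (N, J) Var(y_rep | Y, M)
    y_continuous: np.ndarray  # (N, J) posterior mean of the augmented data
    observed: np.ndarray  # (N, J) bool, False for missing cells


@dataclass
class PosteriorSamples:
    """MCMC output of one fit: named draws plus predictive accumulators."""

    draws: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    free_names: list[str]
    spec: ModelSpec
    config: McmcConfig
    predictive: PredictiveSummary
    impute_cells: np.ndarray  # (M, 2) record/indicator index of missing cells
    impute_probs: np.ndarray  # (M, max_categories) posterior category probs
    acceptance: dict[str, float]

    @property
    def n_chains(self) -> int:
        return self.config.n_chains

    def by_sample(self, base: str, sample: str) -> np.ndarray:
        """Draws of a parameter for one sample, resolving ♀=♂ pooling.

        ``base`` is the shared name (e.g. ``"beta_se"`` or
        ``"lambda[n_helpers]"``); if the parameter is sex-specific in this
        model the per-sample entry is returned instead.
        """
        if base in self.draws:
            return self.draws[base]
        keyed = f"{base[:-1]},{sample}]" if base.endswith("]") else f"{base}[{sample}]"
        if keyed in self.draws:
            return self.draws[keyed]
        raise KeyError(base)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Posterior mean, HPDI and Gelman-Rubin statistic per free parameter."""
        rhats = gelman_rubin(self) if self.n_chains >= 2 else {}
        rows = []
        for name in self.free_names:
            d = self.flat(name)
            lo, hi = hpdi(d, prob)
            rows.append((name, d.mean(), lo, hi, rhats.get(name, np.nan)))
        g2 = self.flat("gamma2")
        valid = g2 < 0
        if valid.any():
            onset = senescence_onset_draws(self)
            lo, hi = hpdi(onset, prob)
            rows.append(
                ("senescence_onset_years", onset.mean(), lo, hi, np.nan)
            )
        return pd.DataFrame(
            rows, columns=["parameter", "mean", "hpdi_low", "hpdi_high", "rhat"]
        ).set_index("parameter")

    def to_inference_data(self):
        """Export draws as an ArviZ ``InferenceData`` (chain × draw × variable)."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.draws.items()})


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def compile_problem(
    spec: ModelSpec, data: Dataset, disable_levels: tuple[str, ...] = ()
) -> Problem:
    """Translate a model spec plus dataset into the Gibbs kernel's form."""
    records = data.records
    if tuple(data.categories) != spec.categories:
        raise ValueError(
            f"dataset categories {tuple(data.categories)} do not match "
            f"spec categories {spec.categories}"
        )
    unknown = set(records["sample"].unique()) - set(SAMPLES)
    if unknown:
        raise ValueError(f"unknown sample labels {sorted(unknown)}")
    sample_idx = (records["sample"] == SAMPLES[1]).to_numpy().astype(int)
    group_codes, _ = pd.factorize(records["group_id"])
    ind_codes, _ = pd.factorize(records["individual_id"])
    age_z = (records["age"].to_numpy(dtype=float) - AGE_CENTER) / AGE_SCALE
    y = data.indicator_array()
    return Problem(
        y=y,
        categories=spec.categories,
        ind_latent=np.array([LATENTS.index(ind.latent) for ind in INDICATORS]),
        ref=np.array([ind.reference for ind in INDICATORS]),
        lam_shared=np.array([spec.loading_shared(j) for j in range(len(INDICATORS))]),
        tau_shared=np.array([spec.threshold_shared(j) for j in range(len(INDICATORS))]),
        n_latents=3,
        structure=spec.structure,
        sample_idx=sample_idx,
        n_samples=2,
        group_idx=None if "group" in disable_levels else group_codes,
        n_groups=int(group_codes.max()) + 1,
        ind_idx=None if "individual" in disable_levels else ind_codes,
        n_individuals=int(ind_codes.max()) + 1,
        age_z=age_z,
        se_shared=spec.se_effect_shared,
        tq_shared=spec.tq_effect_shared,
        indicator_names=tuple(ind.name for ind in INDICATORS),
    )


def _draw_names(spec: ModelSpec) -> list[tuple[str, str]]:
    """(name, extractor-key) pairs for every reported scalar, refs included."""
    names: list[tuple[str, str]] = []
    for j, ind in enumerate(INDICATORS):
        if ind.reference:
            names.append((f"lambda[{ind.name}]", f"lam:0:{j}"))
        elif spec.loading_shared(j):
            names.append((f"lambda[{ind.name}]", f"lam:0:{j}"))
        else:
            for si, s in enumerate(SAMPLES):
                names.append((f"lambda[{ind.name},{s}]", f"lam:{si}:{j}"))
    for j, ind in enumerate(INDICATORS):
        for k in range(spec.categories[j] - 1):
            if spec.threshold_shared(j):
                names.append((f"tau[{ind.name},{k + 1}]", f"tau:0:{j}:{k}"))
            else:
                for si, s in enumerate(SAMPLES):
                    names.append((f"tau[{ind.name},{s},{k + 1}]", f"tau:{si}:{j}:{k}"))
    if spec.se_effect_shared:
        names.append(("beta_se", "beta_se:0"))
    else:
        for si, s in enumerate(SAMPLES):
            names.append((f"beta_se[{s}]", f"beta_se:{si}"))
    tq = "beta_tq" if spec.structure == "direct" else "b_tq_se"
    key = "beta_tq" if spec.structure == "direct" else "b"
    if spec.tq_effect_shared:
        names.append((tq, f"{key}:0"))
    else:
        for si, s in enumerate(SAMPLES):
            names.append((f"{tq}[{s}]", f"{key}:{si}"))
    names.append(("gamma1", "gamma:0"))
    names.append(("gamma2", "gamma:1"))
    for li, latent in enumerate(LATENTS):
        for lev, level in enumerate(LEVELS):
            names.append((f"sigma2[{latent},{level}]", f"sigma2:{li}:{lev}"))
    return names


def _extract(sampler: GibbsSampler, key: str) -> float:
    parts = key.split(":")
    st = sampler.state
    if parts[0] == "lam":
        return float(st.lam[int(parts[1]), int(parts[2])])
    if parts[0] == "tau":
        return float(st.tau[int(parts[2])][int(parts[1]), int(parts[3])])
    if parts[0] == "beta_se":
        return float(st.beta_se[int(parts[1])])
    if parts[0] == "beta_tq":
        return float(st.beta_tq[int(parts[1])])
    if parts[0] == "b":
        return float(st.b[int(parts[1])])
    if parts[0] == "gamma":
        return float(st.gamma[int(parts[1])])
    if parts[0] == "sigma2":
        return float(st.sigma2[int(parts[1]), int(parts[2])])
    raise KeyError(key)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(spec: ModelSpec, data: Dataset, mcmc: McmcConfig | None = None) -> PosteriorSamples:
    """Run the Gibbs sampler and collect draws plus predictive summaries.

    Identical ``spec``/``data``/``mcmc`` inputs produce identical output.
    """
    mcmc = mcmc or McmcConfig()
    problem = compile_problem(spec, data, mcmc.disable_levels)
    names = _draw_names(spec)
    n_kept = mcmc.n_kept
    draws = {name: np.empty((mcmc.n_chains, n_kept)) for name, _ in names}

    n, j = problem.n_records, problem.n_indicators
    yrep_sum = np.zeros((n, j))
    yrep_sq = np.zeros((n, j))
    ycont_sum = np.zeros((n, j))
    miss_r, miss_j = np.where(problem.missing)
    max_cat = max(spec.categories)
    imp_counts = np.zeros((miss_r.size, max_cat))
    total_draws = 0

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    acc_tau = acc_sigma = np.zeros(2)
    for chain, ss in enumerate(seeds):
        sampler = GibbsSampler(problem, priors=mcmc.priors, seed=ss, adapt=mcmc.adapt)
        if mcmc.jitter > 0:
            sampler.overdisperse(mcmc.jitter)
        kept = 0
        for it in range(mcmc.n_iterations):
            sampler.sweep(burnin=it < mcmc.n_burnin)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                for name, key in names:
                    draws[name][chain, kept] = _extract(sampler, key)
                # Rao-Blackwellised predictive moments: y_rep = mean + unit
                # noise, so accumulating the cell means is exact conditional
                # on each draw and removes the synthetic-noise Monte Carlo
                # error from Var(y_rep) and E(y_rep)
                cell_means = sampler.cell_means()
                yrep_sum += cell_means
                yrep_sq += cell_means * cell_means
                ycont_sum += sampler.state.ystar
                if miss_r.size:
                    st = sampler.state
                    for jj in np.unique(miss_j):
                        sel = miss_j == jj
                        rows = miss_r[sel]
                        si = problem.sample_idx[rows]
                        vals = st.ystar[rows, jj]
                        cats = np.empty(rows.size, dtype=int)
                        for s in range(problem.n_samples):
                            m = si == s
                            cats[m] = (
                                np.searchsorted(st.tau[jj][s], vals[m], side="left") + 1
                            )
                        imp_counts[np.where(sel)[0], cats - 1] += 1
                kept += 1
                total_draws += 1
        acc_tau = acc_tau + np.array(sampler.accept["tau"])
        acc_sigma = acc_sigma + np.array(sampler.accept["sigma"])

    yrep_mean = yrep_sum / total_draws
    mean_var = (yrep_sq - total_draws * yrep_mean**2) / max(total_draws - 1, 1)
    predictive = PredictiveSummary(
        yrep_mean=yrep_mean,
        yrep_var=np.maximum(mean_var, 0.0) + 1.0,  # + unit measurement noise
        y_continuous=ycont_sum / total_draws,
        observed=~problem.missing,
    )
    imp_probs = imp_counts / max(total_draws, 1)
    free = {e.name for e in spec.parameter_registry()}
    free_names = [name for name, _ in names if _registry_name(name) in free]
    return PosteriorSamples(
        draws=draws,
        free_names=free_names,
        spec=spec,
        config=mcmc,
        predictive=predictive,
        impute_cells=np.column_stack([miss_r, miss_j]),
        impute_probs=imp_probs,
        acceptance={
            "tau": float(acc_tau[0] / max(acc_tau[1], 1)),
            "sigma": float(acc_sigma[0] / max(acc_sigma[1], 1)),
        },
    )


def _registry_name(draw_name: str) -> str:
    """Map a flattened draw name back to its parameter-registry block name."""
    if draw_name.startswith("tau["):
        inner = draw_name[4:-1].split(",")
        return f"tau[{inner[0]}]" if len(inner) == 2 else f"tau[{inner[0]},{inner[1]}]"
    return draw_name


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(samples: PosteriorSamples | dict[str, np.ndarray]) -> dict[str, float]:
    """Potential scale reduction per parameter (between/within chain form).

    Computed as ``sqrt((W + B/n) / W)`` where ``W`` is the mean within-chain
    variance and ``B/n`` the variance of the chain means, so two identical
    chains give exactly 1.0. Requires at least two chains.
    """
    if isinstance(samples, PosteriorSamples):
        arrays = {k: samples.draws[k] for k in samples.free_names}
    else:
        arrays = samples
    out: dict[str, float] = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("Gelman-Rubin requires >= 2 chains")
        w = arr.var(axis=1, ddof=1).mean()
        b_n = arr.mean(axis=1).var(ddof=1)
        if w == 0:
            out[name] = 1.0 if b_n == 0 else math.inf
        else:
            out[name] = float(np.sqrt((w + b_n) / w))
    return out


def rhat_ok(samples: PosteriorSamples, threshold: float = 1.05) -> bool:
    """Convergence flag: every free parameter's statistic at or below 1.05."""
    return max(gelman_rubin(samples).values()) <= threshold


def hpdi(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("hpdi of empty sample")
    if draws.size < 2:
        raise ValueError("hpdi requires at least two draws")
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(draws)
    n = x.size
    n_inc = int(np.ceil(prob * n))
    if n_inc >= n:
        return float(x[0]), float(x[-1])
    widths = x[n_inc - 1 :] - x[: n - n_inc + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + n_inc - 1])


def senescence_onset(
    gamma1: float, gamma2: float, age_center: float = 0.0, age_scale: float = 1.0
) -> float:
    """Age at which the quadratic age effect peaks, ``-gamma1 / (2 gamma2)``.

    ``gamma2`` must be negative for a finite onset (concave age profile); the
    result is mapped back to years when the coefficients act on standardised
    age.
    """
    if gamma2 >= 0:
        raise ValueError("no finite senescence onset: quadratic term must be negative")
    return age_center + age_scale * (-gamma1 / (2.0 * gamma2))


def senescence_onset_draws(samples: PosteriorSamples) -> np.ndarray:
    """Posterior draws of the senescence onset (years), where defined."""
    g1 = samples.flat("gamma1")
    g2 = samples.flat("gamma2")
    valid = g2 < 0
    return AGE_CENTER + AGE_SCALE * (-g1[valid] / (2.0 * g2[valid]))


def impute_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior category probabilities for every cell imputed during the fit."""
    cells = samples.impute_cells
    cols = [f"p{k + 1}" for k in range(samples.impute_probs.shape[1])]
    if cells.size == 0:
        return pd.DataFrame(columns=["record", "indicator", *cols])
    df = pd.DataFrame(
        {
            "record": cells[:, 0],
            "indicator": [INDICATORS[j].name for j in cells[:, 1]],
        }
    )
    for k, c in enumerate(cols):
        df[c] = samples.impute_probs[:, k]
    return df
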