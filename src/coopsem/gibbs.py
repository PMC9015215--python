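"""Metropolis-within-Gibbs kernel for multilevel ordinal factor models.

The kernel operates on a compiled :class:`Problem` — a generic description of
an ordinal confirmatory factor model with up to three latent variables, an
optional structural layer (direct or mediated), up to three variance levels
(group, individual, observation) and one or two samples with block-wise
parameter pooling. The two-sample three-level reproduction models compile to
this form (see :mod:`coopsem.inference`), as do reduced single-factor models
used for sampler validation.

Sweep structure (all conditionals standard):

1. thresholds — joint random-walk on (first cut point, log spacings), accepted
   against the ordinal likelihood with the underlying values integrated out;
2. underlying continuous values — truncated-normal draws cell by cell (plain
   normal draws for missing cells, which is the missing-at-random imputation);
3. observation / individual / group shocks — conjugate multivariate normals;
4. free loadings — conjugate normals, pooled across samples where invariant;
5. structural paths and age (or covariate) coefficients — conjugate normal
   block draw;
6. mediation path (mediated structure only) — conjugate normal;
7. variance components — conjugate inverse-gamma, or under the half-Cauchy
   prior an independence Metropolis proposal from the flat-prior conditional
   whose acceptance ratio reduces to a prior-density ratio;
8. joint latent-scale Metropolis moves (with an occasional large jump) that
   travel along the soft ridge between a latent's scale and its coefficients.

Measurement residuals are fixed at unit variance (probit convention);
reference loadings are fixed at 1 and never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

_TINY = 1e-300
_EPS = 1e-12


@dataclass
class Priors:
    """Weakly informative defaults for all free parameters.

    All observed variables are ordinal with unit-variance probit residuals, so
    loadings, structural paths and thresholds live on a standardised scale
    where magnitudes beyond ~2.5 are implausible, and latent standard
    deviations beyond ~2 would dwarf the measurement scale. The defaults
    encode exactly that and nothing more. Genuinely vague settings
    (``coef_sd=10``, ``hc_scale=2.5``) are available but leave soft scale
    ridges in weakly identified directions that slow MCMC mixing drastically
    on small ordinal datasets.
    """

    coef_sd: float = 2.5  # loadings, paths, covariate coefficients
    tau_sd: float = 2.5  # ordered-normal prior on thresholds
    sigma_prior: str = "half_cauchy"  # or "inv_gamma"
    hc_scale: float = 1.0
    ig_shape: float = 0.01
    ig_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_prior not in ("half_cauchy", "inv_gamma"):
            raise ValueError("sigma_prior must be 'half_cauchy' or 'inv_gamma'")


@dataclass
class Problem:
    """Compiled model + data, ready for the Gibbs kernel."""

    y: np.ndarray  # (N, J) int categories, -1 for missing
    categories: tuple[int, ...]
    ind_latent: np.ndarray  # (J,) latent index per indicator
    ref: np.ndarray  # (J,) bool, loading fixed at 1
    lam_shared: np.ndarray  # (J,) bool, loading pooled across samples
    tau_shared: np.ndarray  # (J,) bool, thresholds pooled across samples
    n_latents: int
    structure: str  # "direct" | "mediated" | "none"
    sample_idx: np.ndarray  # (N,) 0-based sample per record
    n_samples: int
    group_idx: np.ndarray | None  # None disables the group level
    n_groups: int
    ind_idx: np.ndarray | None  # None disables the individual level
    n_individuals: int
    age_z: np.ndarray | None = None  # standardised age (structural models)
    covariates: np.ndarray | None = None  # (N, p) latent-0 regressors ("none")
    se_shared: bool = True
    tq_shared: bool = True
    fixed_tau: list | None = None  # known threshold vectors, not sampled
    fixed_sigma2: np.ndarray | None = None  # (L, 3); NaN = free
    indicator_names: tuple | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        n, j = self.y.shape
        self.n_records = n
        self.n_indicators = j
        if self.indicator_names is None:
            self.indicator_names = tuple(f"y{k}" for k in range(j))
        self.missing = self.y < 0
        for jj in range(j):
            col = self.y[:, jj]
            obs = col[col > 0]
            if obs.size == 0:
                raise ValueError(f"indicator {self.indicator_names[jj]} is entirely missing")
            if obs.max() > self.categories[jj] or (col[~self.missing[:, jj]] < 1).any():
                raise ValueError(
                    f"indicator {self.indicator_names[jj]} has categories outside "
                    f"[1, {self.categories[jj]}]"
                )
        self.sample_masks = [self.sample_idx == s for s in range(self.n_samples)]
        fixed = np.full((self.n_latents, 3), np.nan)
        if self.fixed_sigma2 is not None:
            fixed = np.asarray(self.fixed_sigma2, dtype=float).copy()
        if self.group_idx is None:
            fixed[:, 0] = 0.0
            self.group_idx = np.zeros(n, dtype=int)
            self.n_groups = 1
        if self.ind_idx is None:
            fixed[:, 1] = 0.0
            self.ind_idx = np.zeros(n, dtype=int)
            self.n_individuals = 1
        self.fixed_sigma2 = fixed
        # level activity: a component participates if its variance is free or
        # fixed to a positive value
        self.active = [
            np.where(~((~np.isnan(fixed[:, lev])) & (fixed[:, lev] == 0.0)))[0]
            for lev in range(3)
        ]
        # counts for the group-level update (records per group per sample)
        self.group_counts = np.zeros((self.n_groups, self.n_samples), dtype=int)
        for s in range(self.n_samples):
            np.add.at(self.group_counts[:, s], self.group_idx[self.sample_masks[s]], 1)
        self.ind_counts = np.bincount(self.ind_idx, minlength=self.n_individuals)
        # each individual belongs to exactly one sample
        self.ind_sample = np.zeros(self.n_individuals, dtype=int)
        self.ind_sample[self.ind_idx] = self.sample_idx
        if self.structure in ("direct", "mediated") and self.age_z is None:
            raise ValueError("structural models require age_z")


@dataclass
class State:
    lam: np.ndarray  # (S, J)
    tau: list[np.ndarray]  # per j: (S, c_j - 1)
    beta_se: np.ndarray  # (S,)
    beta_tq: np.ndarray  # (S,)
    b: np.ndarray  # (S,) mediation path
    gamma: np.ndarray  # (2,) age coefficients, or (p,) covariate coefficients
    sigma2: np.ndarray  # (L, 3)
    u: np.ndarray  # (G, L)
    v: np.ndarray  # (I, L)
    w: np.ndarray  # (N, L)
    ystar: np.ndarray  # (N, J)


def _pad_tau(tau: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], tau, [np.inf]))


class GibbsSampler:
    """One MCMC chain for a compiled :class:`Problem`."""

    def __init__(
        self,
        problem: Problem,
        priors: Priors | None = None,
        seed: int = 0,
        adapt: bool = True,
        scale_reps: int = 6,
        tau_reps: int = 2,
    ) -> None:
        self.p = problem
        self.priors = priors or Priors()
        self.rng = np.random.default_rng(seed)
        self.adapt = adapt
        # cheap extra repetitions of the slowest-mixing updates per sweep
        self.scale_reps = scale_reps
        self.tau_reps = tau_reps
        self.tau_scales: dict[tuple[int, int], float] = {}
        self.scale_move_scales = np.full(problem.n_latents, 0.1)
        self.accept: dict[str, list[int]] = {
            "tau": [0, 0],
            "sigma": [0, 0],
            "scale": [0, 0],
        }
        self.state = self._init_state()

    # ------------------------------------------------------------------
    # initialisation
    # ------------------------------------------------------------------
    def _init_state(self, jitter: float = 0.0) -> State:
        p, rng = self.p, self.rng
        s, j, n = p.n_samples, p.n_indicators, p.n_records
        lam = np.ones((s, j))  # free loadings start at the reference scale
        lam[:, ~p.ref] += jitter * rng.standard_normal((s, (~p.ref).sum()))
        if jitter:
            lam[:, p.lam_shared & ~p.ref] = lam[:1, p.lam_shared & ~p.ref]
        tau = []
        for jj in range(j):
            if p.fixed_tau is not None and p.fixed_tau[jj] is not None:
                t = np.asarray(p.fixed_tau[jj], dtype=float)
                tau.append(np.tile(t, (s, 1)))
                continue
            block = np.empty((s, p.categories[jj] - 1))
            for si in range(s):
                rows = p.sample_masks[si] if not p.tau_shared[jj] else slice(None)
                col = p.y[rows, jj]
                col = col[col > 0]
                freqs = np.bincount(col, minlength=p.categories[jj] + 1)[1:]
                cum = np.cumsum(freqs)[:-1] / max(freqs.sum(), 1)
                cum = np.clip(cum, 0.02, 0.98)
                t = ndtri(cum)
                t = np.maximum.accumulate(t + np.arange(t.size) * 1e-3)
                if jitter:
                    t = np.sort(t + jitter * 0.2 * rng.standard_normal(t.size))
                    t += np.arange(t.size) * 1e-6
                block[si] = t
            if p.tau_shared[jj]:
                block[:] = block[:1]
            tau.append(block)
        def coef_init() -> float:
            return float(jitter * rng.standard_normal()) if jitter else 0.0

        beta_se = np.full(s, coef_init())
        beta_tq = np.full(s, coef_init())
        b = np.full(s, coef_init())
        n_gamma = 2 if p.structure != "none" else (
            0 if p.covariates is None else p.covariates.shape[1]
        )
        gamma = (jitter * rng.standard_normal(n_gamma)) if n_gamma else np.zeros(0)
        sigma2 = np.exp(jitter * rng.standard_normal((p.n_latents, 3)) * 0.5)
        fixed = ~np.isnan(p.fixed_sigma2)
        sigma2[fixed] = p.fixed_sigma2[fixed]
        st = State(
            lam=lam,
            tau=tau,
            beta_se=beta_se,
            beta_tq=beta_tq,
            b=b,
            gamma=gamma,
            sigma2=sigma2,
            u=np.zeros((p.n_groups, p.n_latents)),
            v=np.zeros((p.n_individuals, p.n_latents)),
            w=np.zeros((n, p.n_latents)),
            ystar=np.zeros((n, j)),
        )
        self.state = st
        self._draw_ystar()  # consistent with categories from the start
        for jj in range(j):
            key_scale = 0.08 if n > 500 else 0.25
            for block in range(1 if p.tau_shared[jj] else s):
                self.tau_scales[(jj, block)] = key_scale
        return st

    def overdisperse(self, jitter: float) -> None:
        """Re-initialise with jittered starting values (overdispersed chains)."""
        self._init_state(jitter=jitter)

    # ------------------------------------------------------------------
    # linear structure helpers
    # ------------------------------------------------------------------
    def _transform(self, si: int) -> np.ndarray:
        L = self.p.n_latents
        t = np.eye(L)
        if self.p.structure == "direct":
            t[0, 1] = self.state.beta_se[si]
            t[0, 2] = self.state.beta_tq[si]
        elif self.p.structure == "mediated":
            b = self.state.b[si]
            t[0, 1] = self.state.beta_se[si]
            t[0, 2] = self.state.beta_se[si] * b
            t[1, 2] = b
        return t

    def _fixed_effect(self) -> np.ndarray:
        """Fixed-covariate contribution to latent 0, per record."""
        p, st = self.p, self.state
        if p.structure in ("direct", "mediated"):
            z = p.age_z
            return st.gamma[0] * z + st.gamma[1] * z * z
        if p.covariates is not None and st.gamma.size:
            return p.covariates @ st.gamma
        return np.zeros(p.n_records)

    def _shocks(self) -> np.ndarray:
        st, p = self.state, self.p
        return st.u[p.group_idx] + st.v[p.ind_idx] + st.w

    def _latent_totals(self, shocks: np.ndarray | None = None) -> np.ndarray:
        p = self.p
        if shocks is None:
            shocks = self._shocks()
        out = np.empty_like(shocks)
        for si in range(p.n_samples):
            m = p.sample_masks[si]
            out[m] = shocks[m] @ self._transform(si).T
        out[:, 0] += self._fixed_effect()
        return out

    def _means(self, lat_tot: np.ndarray | None = None) -> np.ndarray:
        p, st = self.p, self.state
        if lat_tot is None:
            lat_tot = self._latent_totals()
        return lat_tot[:, p.ind_latent] * st.lam[p.sample_idx, :]

    def _coef_matrix(self, si: int) -> np.ndarray:
        """C (J, L): row j maps own-level shocks to the mean of indicator j."""
        t = self._transform(si)
        return self.state.lam[si][:, None] * t[self.p.ind_latent, :]

    # ------------------------------------------------------------------
    # conditional updates
    # ------------------------------------------------------------------
    def _draw_ystar(self) -> None:
        p, st, rng = self.p, self.state, self.rng
        m = self._means()
        ystar = st.ystar
        for jj in range(p.n_indicators):
            lo = np.empty(p.n_records)
            hi = np.empty(p.n_records)
            for si in range(p.n_samples):
                rows = p.sample_masks[si]
                pad = _pad_tau(st.tau[jj][si])
                cats = np.clip(p.y[rows, jj], 1, None)
                lo[rows] = pad[cats - 1]
                hi[rows] = pad[cats]
            miss = p.missing[:, jj]
            mu = m[:, jj]
            a = ndtr(lo - mu)
            bb = ndtr(hi - mu)
            u = a + rng.random(p.n_records) * np.maximum(bb - a, _EPS)
            draw = mu + ndtri(np.clip(u, _EPS, 1 - _EPS))
            draw = np.clip(draw, np.where(np.isfinite(lo), lo, -np.inf),
                           np.where(np.isfinite(hi), hi, np.inf))
            draw[miss] = mu[miss] + rng.standard_normal(int(miss.sum()))
            ystar[:, jj] = draw

    def _draw_components(self, level: int) -> None:
        """Conjugate update of u (level 0), v (level 1) or w (level 2)."""
        p, st, rng = self.p, self.state, self.rng
        act = p.active[level]
        if act.size == 0:
            return
        target = (st.u, st.v, st.w)[level]
        sig = st.sigma2[act, level]
        if np.any(sig <= 0):
            return
        prior_prec = np.diag(1.0 / sig)
        fe = self._fixed_effect()
        # residual excluding this level's own contribution
        others = self._shocks() - (
            target[p.group_idx] if level == 0 else target[p.ind_idx] if level == 1 else target
        )
        c_full = [self._coef_matrix(si) for si in range(p.n_samples)]
        resid = np.empty_like(st.ystar)
        for si in range(p.n_samples):
            msk = p.sample_masks[si]
            resid[msk] = st.ystar[msk] - others[msk] @ c_full[si].T
        resid[:, :] -= fe[:, None] * st.lam[p.sample_idx, :] * (p.ind_latent == 0)
        c_act = [c[:, act] for c in c_full]
        a_mats = [c.T @ c for c in c_act]
        proj = np.empty((p.n_records, act.size))
        for si in range(p.n_samples):
            msk = p.sample_masks[si]
            proj[msk] = resid[msk] @ c_act[si]
        if level == 2:
            for si in range(p.n_samples):
                msk = p.sample_masks[si]
                q = a_mats[si] + prior_prec
                cov = np.linalg.inv(q)
                mean = proj[msk] @ cov.T
                chol = np.linalg.cholesky(cov)
                draw = mean + rng.standard_normal(mean.shape) @ chol.T
                tmp = np.zeros((int(msk.sum()), p.n_latents))
                tmp[:, act] = draw
                st.w[msk] = tmp
            return
        if level == 1:
            nunits = p.n_individuals
            bsum = np.zeros((nunits, act.size))
            np.add.at(bsum, p.ind_idx, proj)
            qs = (
                p.ind_counts[:, None, None] * np.stack(a_mats)[p.ind_sample]
                + prior_prec[None, :, :]
            )
        else:
            nunits = p.n_groups
            bsum = np.zeros((nunits, act.size))
            np.add.at(bsum, p.group_idx, proj)
            qs = prior_prec[None, :, :] + sum(
                p.group_counts[:, si, None, None] * a_mats[si][None, :, :]
                for si in range(p.n_samples)
            )
        cov = np.linalg.inv(qs)
        mean = np.einsum("nij,nj->ni", cov, bsum)
        chol = np.linalg.cholesky(cov)
        draw = mean + np.einsum("nij,nj->ni", chol, rng.standard_normal(mean.shape))
        out = np.zeros((nunits, p.n_latents))
        out[:, act] = draw
        if level == 1:
            st.v = out
        else:
            st.u = out

    def _draw_loadings(self) -> None:
        p, st, rng = self.p, self.state, self.rng
        lat_tot = self._latent_totals()
        prior_prec = 1.0 / self.priors.coef_sd**2
        for jj in range(p.n_indicators):
            if p.ref[jj]:
                continue
            t = lat_tot[:, p.ind_latent[jj]]
            if p.lam_shared[jj] or p.n_samples == 1:
                prec = t @ t + prior_prec
                mu = (t @ st.ystar[:, jj]) / prec
                val = mu + rng.standard_normal() / np.sqrt(prec)
                st.lam[:, jj] = val
            else:
                for si in range(p.n_samples):
                    msk = p.sample_masks[si]
                    ts = t[msk]
                    prec = ts @ ts + prior_prec
                    mu = (ts @ st.ystar[msk, jj]) / prec
                    st.lam[si, jj] = mu + rng.standard_normal() / np.sqrt(prec)

    def _structural_design(self):
        """Columns of the latent-0 regression and the unpack recipe."""
        p, st = self.p, self.state
        shocks = self._shocks()
        cols, names = [], []
        if p.structure in ("direct", "mediated"):
            lat = np.empty((p.n_records, p.n_latents))
            for si in range(p.n_samples):
                msk = p.sample_masks[si]
                lat[msk] = shocks[msk] @ self._transform(si).T
            se_tot, tq_tot = lat[:, 1], lat[:, 2]
            def split(colvals, shared, tag):
                if shared or p.n_samples == 1:
                    cols.append(colvals)
                    names.append((tag, "shared"))
                else:
                    for si in range(p.n_samples):
                        cols.append(np.where(p.sample_masks[si], colvals, 0.0))
                        names.append((tag, si))
            split(se_tot, p.se_shared, "beta_se")
            if p.structure == "direct":
                split(tq_tot, p.tq_shared, "beta_tq")
            cols.append(p.age_z)
            names.append(("gamma", 0))
            cols.append(p.age_z**2)
            names.append(("gamma", 1))
        elif p.covariates is not None:
            for k in range(p.covariates.shape[1]):
                cols.append(p.covariates[:, k])
                names.append(("gamma", k))
        return shocks, cols, names

    def _draw_structural(self) -> None:
        p, st, rng = self.p, self.state, self.rng
        shocks, cols, names = self._structural_design()
        if not cols:
            return
        x = np.column_stack(cols)
        jr = np.where(p.ind_latent == 0)[0]
        lam_r = st.lam[:, jr]
        c = (lam_r**2).sum(axis=1)[p.sample_idx]
        s1 = np.einsum("nj,nj->n", st.ystar[:, jr], st.lam[p.sample_idx][:, jr])
        e0 = shocks[:, 0]
        xtx = x.T @ (x * c[:, None])
        xty = x.T @ (s1 - c * e0)
        q = xtx + np.eye(x.shape[1]) / self.priors.coef_sd**2
        cov = np.linalg.inv(q)
        mean = cov @ xty
        draw = mean + np.linalg.cholesky(cov) @ rng.standard_normal(mean.size)
        gamma = np.zeros(st.gamma.size)
        for val, (tag, which) in zip(draw, names):
            if tag == "gamma":
                gamma[which] = val
                continue
            target = st.beta_se if tag == "beta_se" else st.beta_tq
            if which == "shared":
                target[:] = val
            else:
                target[which] = val
        st.gamma = gamma

    def _draw_mediation(self) -> None:
        p, st, rng = self.p, self.state, self.rng
        if p.structure != "mediated":
            return
        shocks = self._shocks()
        e0, e_se, e_tq = shocks[:, 0], shocks[:, 1], shocks[:, 2]
        fe = self._fixed_effect()
        jse = np.where(p.ind_latent == 1)[0]
        jr = np.where(p.ind_latent == 0)[0]
        lam = st.lam[p.sample_idx]
        bse = st.beta_se[p.sample_idx]
        qa = np.zeros(p.n_samples)
        qb = np.zeros(p.n_samples)
        for jj in jse:
            coef = lam[:, jj] * e_tq
            resp = st.ystar[:, jj] - lam[:, jj] * e_se
            for si in range(p.n_samples):
                msk = p.sample_masks[si]
                qa[si] += coef[msk] @ coef[msk]
                qb[si] += coef[msk] @ resp[msk]
        for jj in jr:
            coef = lam[:, jj] * bse * e_tq
            resp = st.ystar[:, jj] - lam[:, jj] * (bse * e_se + fe + e0)
            for si in range(p.n_samples):
                msk = p.sample_masks[si]
                qa[si] += coef[msk] @ coef[msk]
                qb[si] += coef[msk] @ resp[msk]
        prior_prec = 1.0 / self.priors.coef_sd**2
        if p.tq_shared or p.n_samples == 1:
            prec = qa.sum() + prior_prec
            mu = qb.sum() / prec
            st.b[:] = mu + rng.standard_normal() / np.sqrt(prec)
        else:
            for si in range(p.n_samples):
                prec = qa[si] + prior_prec
                mu = qb[si] / prec
                st.b[si] = mu + rng.standard_normal() / np.sqrt(prec)

    def _draw_variances(self, burnin: bool) -> None:
        p, st, rng, pri = self.p, self.state, self.rng, self.priors
        comps = (st.u, st.v, st.w)
        for lev in range(3):
            vals = comps[lev]
            nobs = vals.shape[0]
            for l in range(p.n_latents):
                if not np.isnan(p.fixed_sigma2[l, lev]):
                    continue
                ss = float(vals[:, l] @ vals[:, l])
                if pri.sigma_prior == "inv_gamma":
                    shape = pri.ig_shape + nobs / 2.0
                    rate = pri.ig_rate + ss / 2.0
                    st.sigma2[l, lev] = rate / rng.gamma(shape)
                elif nobs >= 2 and ss > 0:
                    # half-Cauchy prior on sigma: independence proposal from
                    # the flat-prior conditional IG((n-1)/2, ss/2); the
                    # likelihood and the sqrt-Jacobian of the prior cancel,
                    # leaving the acceptance ratio (A^2+x)/(A^2+x').
                    cur = st.sigma2[l, lev]
                    prop = (ss / 2.0) / rng.gamma((nobs - 1) / 2.0)
                    a2 = pri.hc_scale**2
                    self.accept["sigma"][1] += 1
                    if np.log(rng.random()) < np.log(a2 + cur) - np.log(a2 + prop):
                        st.sigma2[l, lev] = prop
                        self.accept["sigma"][0] += 1

    def _tau_loglik(self, jj: int, rows, tau: np.ndarray, means: np.ndarray) -> float:
        p = self.p
        obs = ~p.missing[rows, jj]
        cats = p.y[rows, jj][obs]
        m = means[rows][obs]
        pad = _pad_tau(tau)
        prob = ndtr(pad[cats] - m) - ndtr(pad[cats - 1] - m)
        return float(np.log(np.maximum(prob, _TINY)).sum())

    def _draw_thresholds(self, burnin: bool) -> None:
        p, st, rng, pri = self.p, self.state, self.rng, self.priors
        means = self._means()
        for jj in range(p.n_indicators):
            if p.fixed_tau is not None and p.fixed_tau[jj] is not None:
                continue
            blocks = 1 if p.tau_shared[jj] else p.n_samples
            for block in range(blocks):
                rows = (
                    np.ones(p.n_records, dtype=bool)
                    if blocks == 1
                    else p.sample_masks[block]
                )
                cur = st.tau[jj][block if blocks > 1 else 0].copy()
                eta = np.concatenate(([cur[0]], np.log(np.diff(cur)))) if cur.size > 1 else cur.copy()
                scale = self.tau_scales[(jj, block)]
                eta_prop = eta + scale * rng.standard_normal(eta.size)
                if cur.size > 1:
                    prop = np.concatenate(
                        ([eta_prop[0]], eta_prop[0] + np.cumsum(np.exp(eta_prop[1:])))
                    )
                else:
                    prop = eta_prop.copy()

                def logprior(t: np.ndarray) -> float:
                    lp = float(-(t @ t) / (2 * pri.tau_sd**2))
                    if t.size > 1:
                        lp += float(np.log(np.diff(t)).sum())  # Jacobian
                    return lp

                ll_cur = self._tau_loglik(jj, rows, cur, means[:, jj])
                ll_prop = self._tau_loglik(jj, rows, prop, means[:, jj])
                alpha = (ll_prop + logprior(prop)) - (ll_cur + logprior(cur))
                self.accept["tau"][1] += 1
                accepted = np.log(rng.random()) < alpha
                if accepted:
                    self.accept["tau"][0] += 1
                    if blocks == 1:
                        st.tau[jj][:] = prop
                    else:
                        st.tau[jj][block] = prop
                if self.adapt and burnin:
                    self.tau_scales[(jj, block)] *= np.exp(
                        0.05 * ((1.0 if accepted else 0.0) - 0.35)
                    )

    def _log_sigma2_prior(self, x: float) -> float:
        """Log prior density in the sigma^2 coordinate."""
        pri = self.priors
        if pri.sigma_prior == "inv_gamma":
            return float(-(pri.ig_shape + 1) * np.log(x) - pri.ig_rate / x)
        s = np.sqrt(x)
        # half-Cauchy on sigma, transformed: p(s^2) = HC(s) / (2 s)
        return float(-np.log1p((s / pri.hc_scale) ** 2) - np.log(s))

    def _scale_move(self, latent: int, burnin: bool) -> None:
        """Joint rescaling of one latent's shocks, variances, loadings, paths.

        Single-site Gibbs mixes slowly along the soft ridge between a latent's
        scale (variance components) and the coefficients attached to it; this
        Metropolis move travels along the ridge. All means except the latent's
        reference indicator are left exactly unchanged by construction, so the
        likelihood ratio involves only that one indicator column.
        """
        p, st, rng, pri = self.p, self.state, self.rng, self.priors
        free_levels = [
            lev for lev in range(3) if latent in p.active[lev] and np.isnan(p.fixed_sigma2[latent, lev])
        ]
        if not free_levels or any(
            latent in p.active[lev] and not np.isnan(p.fixed_sigma2[latent, lev])
            for lev in range(3)
        ):
            return
        ref_candidates = np.where(p.ref & (p.ind_latent == latent))[0]
        if ref_candidates.size == 0:
            return
        ref_j = int(ref_candidates[0])
        # mixture proposal: mostly local steps, occasionally a large jump so
        # the chain can cross between well-separated scale regimes
        is_local = rng.random() < 0.8
        step = self.scale_move_scales[latent] if is_local else 1.5
        logc = step * rng.standard_normal()
        c = float(np.exp(logc))

        lat_tot = self._latent_totals()
        m = lat_tot[:, latent]
        y = st.ystar[:, ref_j]
        dlog = -0.5 * float(((y - c * m) ** 2 - (y - m) ** 2).sum())

        # Shock coordinates scale with their own standard deviation, so their
        # Gaussian prior change cancels the corresponding Jacobian exactly;
        # only the sigma^2 entries contribute prior and Jacobian terms.
        for lev in free_levels:
            old = st.sigma2[latent, lev]
            dlog += self._log_sigma2_prior(c * c * old) - self._log_sigma2_prior(old)
            dlog += 2 * logc

        coef_prior = 1.0 / (2 * pri.coef_sd**2)

        def coef_change(value: float, up: bool) -> float:
            """Prior + Jacobian contribution of one free scalar scaled by c."""
            new = value * c if up else value / c
            return -coef_prior * (new * new - value * value) + (logc if up else -logc)

        # collect the free coefficient scalars this move rescales
        lam_jobs: list[tuple[int, int]] = []  # (sample, indicator), down-scaled
        for jj in np.where((p.ind_latent == latent) & ~p.ref)[0]:
            blocks = 1 if p.lam_shared[jj] else p.n_samples
            for si in range(blocks):
                lam_jobs.append((si, int(jj)))
                dlog += coef_change(st.lam[si, jj], up=False)
        path_jobs: list[tuple[np.ndarray, bool]] = []  # (array, scale-up flag)

        def add_path(arr: np.ndarray, shared: bool, up: bool) -> None:
            blocks = 1 if (shared or p.n_samples == 1) else p.n_samples
            for si in range(blocks):
                dlog_nonlocal[0] += coef_change(arr[si], up)
            path_jobs.append((arr, up))

        dlog_nonlocal = [dlog]
        if p.structure in ("direct", "mediated"):
            if latent == 0:
                add_path(st.beta_se, p.se_shared, up=True)
                if p.structure == "direct":
                    add_path(st.beta_tq, p.tq_shared, up=True)
                for k in range(st.gamma.size):
                    dlog_nonlocal[0] += coef_change(st.gamma[k], up=True)
            elif latent == 1:
                add_path(st.beta_se, p.se_shared, up=False)
                if p.structure == "mediated":
                    add_path(st.b, p.tq_shared, up=True)
            else:
                if p.structure == "direct":
                    add_path(st.beta_tq, p.tq_shared, up=False)
                else:
                    add_path(st.b, p.tq_shared, up=False)
        elif p.covariates is not None and latent == 0:
            for k in range(st.gamma.size):
                dlog_nonlocal[0] += coef_change(st.gamma[k], up=True)
        dlog = dlog_nonlocal[0]

        self.accept["scale"][1] += 1
        accepted = np.log(rng.random()) < dlog
        if accepted:
            self.accept["scale"][0] += 1
            st.u[:, latent] *= c
            st.v[:, latent] *= c
            st.w[:, latent] *= c
            for lev in free_levels:
                st.sigma2[latent, lev] *= c * c
            for si, jj in lam_jobs:
                st.lam[si, jj] /= c
            for jj in np.where((p.ind_latent == latent) & ~p.ref)[0]:
                if p.lam_shared[jj]:
                    st.lam[:, jj] = st.lam[0, jj]
            for arr, up in path_jobs:
                arr *= c if up else 1.0 / c
                shared = (arr is st.beta_se and p.se_shared) or (
                    arr is not st.beta_se and p.tq_shared
                )
                if shared:
                    arr[:] = arr[0]
            if latent == 0 and st.gamma.size and (
                p.structure in ("direct", "mediated") or p.covariates is not None
            ):
                st.gamma *= c
        if self.adapt and burnin and is_local:
            self.scale_move_scales[latent] *= np.exp(
                0.1 * ((1.0 if accepted else 0.0) - 0.44)
            )

    # ------------------------------------------------------------------
    def sweep(self, burnin: bool = False) -> None:
        """One full cycle over all conditionals."""
        self._draw_thresholds(burnin)
        self._draw_ystar()
        self._draw_components(2)
        self._draw_components(1)
        self._draw_components(0)
        self._draw_loadings()
        self._draw_structural()
        self._draw_mediation()
        self._draw_variances(burnin)
        for _ in range(self.scale_reps):
            for latent in range(self.p.n_latents):
                self._scale_move(latent, burnin)
        for _ in range(self.tau_reps - 1):
            self._draw_thresholds(burnin)
            self._draw_ystar()

    # ------------------------------------------------------------------
    def cell_means(self) -> np.ndarray:
        """Current model means of every continuous indicator cell."""
        return self._means()

    def predictive_draw(self) -> np.ndarray:
        """One posterior-predictive replicate of the continuous indicators."""
        m = self._means()
        return m + self.rng.standard_normal(m.shape)

    def forward_redraw(self) -> None:
        """Redraw shocks, continuous indicators and categories given parameters.

        Used by the joint-distribution (simulator-vs-sampler) validation: this
        is an exact draw from the model given the current parameter values.
        """
        p, st, rng = self.p, self.state, self.rng
        sd = np.sqrt(st.sigma2)
        st.u = rng.standard_normal((p.n_groups, p.n_latents)) * sd[:, 0]
        st.v = rng.standard_normal((p.n_individuals, p.n_latents)) * sd[:, 1]
        st.w = rng.standard_normal((p.n_records, p.n_latents)) * sd[:, 2]
        m = self._means()
        st.ystar = m + rng.standard_normal(m.shape)
        y = np.empty_like(p.y)
        for jj in range(p.n_indicators):
            for si in range(p.n_samples):
                rows = p.sample_masks[si]
                y[rows, jj] = (
                    np.searchsorted(st.tau[jj][si], st.ystar[rows, jj], side="left") + 1
                )
        p.y = y
        p.missing = np.zeros_like(p.missing)
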