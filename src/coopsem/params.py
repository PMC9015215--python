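"""Generating parameter sets for the simulator and recovery experiments."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .specs import (
    DEFAULT_CATEGORIES,
    INDICATORS,
    LATENTS,
    LEVELS,
    SAMPLES,
    ModelSpec,
)


@dataclass
class TrueParameters:
    """A complete generating parameter set for the two-sample three-level SEM.

    Arrays indexed by sample follow the order ``("female", "male")``; the
    latent axis follows ``("R", "SE", "TQ")`` and the level axis
    ``("group", "individual", "within")``. Reference loadings are fixed at 1;
    measurement residuals have unit variance (probit convention), so latent
    scales are set by the reference indicators.
    """

    loadings: np.ndarray  # (2, 7); reference entries must equal 1
    beta_se: np.ndarray  # (2,) SE -> R per sample
    beta_tq: np.ndarray  # (2,) TQ -> R per sample (direct structure)
    b_tq_se: np.ndarray  # (2,) TQ -> SE per sample (mediated structure)
    gamma1: float  # linear age coefficient (standardised age), shared
    gamma2: float  # quadratic age coefficient, shared
    thresholds: list[np.ndarray]  # per indicator, strictly increasing
    sigma2: np.ndarray  # (3 latents, 3 levels) latent variance components
    thresholds_male: list[np.ndarray] | None = None  # optional sex-specific set

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.beta_se = np.asarray(self.beta_se, dtype=float)
        self.beta_tq = np.asarray(self.beta_tq, dtype=float)
        self.b_tq_se = np.asarray(self.b_tq_se, dtype=float)
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        if self.thresholds_male is not None:
            self.thresholds_male = [np.asarray(t, dtype=float) for t in self.thresholds_male]
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.loadings.shape != (len(SAMPLES), len(INDICATORS)):
            raise ValueError("loadings must be (2 samples, 7 indicators)")
        for si in range(len(SAMPLES)):
            for j, ind in enumerate(INDICATORS):
                if ind.reference and self.loadings[si, j] != 1.0:
                    raise ValueError(f"reference loading {ind.name} must be 1")
        for t in self.threshold_sets():
            for tau in t:
                if np.any(np.diff(tau) <= 0):
                    raise ValueError("thresholds must be strictly increasing")
        if self.sigma2.shape != (len(LATENTS), len(LEVELS)):
            raise ValueError("sigma2 must be (3 latents, 3 levels)")
        if np.any(self.sigma2 < 0):
            raise ValueError("variances must be non-negative")

    def threshold_sets(self) -> list[list[np.ndarray]]:
        sets = [self.thresholds]
        if self.thresholds_male is not None:
            sets.append(self.thresholds_male)
        return sets

    def thresholds_for(self, sample_index: int) -> list[np.ndarray]:
        if sample_index == 1 and self.thresholds_male is not None:
            return self.thresholds_male
        return self.thresholds

    @property
    def categories(self) -> tuple[int, ...]:
        return tuple(len(t) + 1 for t in self.thresholds)


# Default thresholds: mildly right-skewed for the offspring counts (most
# breeder-years produce few offspring) and roughly balanced for the
# group-level indicators. Lengths imply the default 4/3/3/5/3/4/4 categories.
_DEFAULT_THRESHOLDS = [
    np.array([-0.5, 0.7, 1.8]),  # wg_offspring
    np.array([0.2, 1.4]),  # eg_offspring
    np.array([0.5, 1.6]),  # op_offspring
    np.array([-1.5, -0.4, 0.6, 1.7]),  # group_size
    np.array([0.3, 1.3]),  # n_helpers
    np.array([-1.1, 0.0, 1.1]),  # territory_size
    np.array([-1.0, 0.1, 1.2]),  # insect_avail
]

# Variance components (rows R, SE, TQ; columns group, individual, within).
# SE and TQ vary mostly between groups; R carries the largest within share.
_DEFAULT_SIGMA2 = np.array(
    [
        [0.2, 0.3, 0.5],
        [0.5, 0.2, 0.4],
        [0.6, 0.1, 0.3],
    ]
)


def default_true_parameters(
    structure: str = "direct",
    *,
    beta_se: tuple[float, float] | float = 0.6,
    beta_tq: tuple[float, float] | float = 0.1,
    b_tq_se: tuple[float, float] | float = 0.5,
    gamma1: float = 0.4,
    gamma2: float = -0.3,
    sex_specific_loadings: bool = False,
) -> TrueParameters:
    """Default generating values.

    Signs mirror the qualitative pattern reported for this system: a clear
    positive SE→R effect, a near-zero TQ→R effect, and a concave age profile
    (``gamma1 > 0 > gamma2`` on the standardised age scale) peaking around
    seven years.
    """

    def pair(x) -> np.ndarray:
        return np.asarray(x if np.ndim(x) else (x, x), dtype=float)

    loadings = np.ones((2, 7))
    free = {"eg_offspring": 0.7, "op_offspring": 0.6, "n_helpers": 0.8, "insect_avail": 0.7}
    for j, ind in enumerate(INDICATORS):
        if ind.name in free:
            loadings[:, j] = free[ind.name]
            if sex_specific_loadings and ind.name in ("n_helpers", "insect_avail"):
                loadings[1, j] = free[ind.name] + 0.3
    return TrueParameters(
        loadings=loadings,
        beta_se=pair(beta_se),
        beta_tq=pair(beta_tq) if structure == "direct" else np.zeros(2),
        b_tq_se=pair(b_tq_se) if structure == "mediated" else np.zeros(2),
        gamma1=gamma1,
        gamma2=gamma2,
        thresholds=[t.copy() for t in _DEFAULT_THRESHOLDS],
        sigma2=_DEFAULT_SIGMA2.copy(),
    )


def validate_params(spec: ModelSpec, params: TrueParameters) -> None:
    """Check that a parameter set conforms to a model's constraint grid.

    Raises ``ValueError`` when an invariance flag demands ♀ = ♂ but the female
    and male entries differ (e.g. M6 requested with sex-specific SE effects),
    when category counts disagree with the spec, or when a path is present
    that the causal structure excludes.
    """
    if params.categories != spec.categories:
        raise ValueError(
            f"threshold lengths imply categories {params.categories}, "
            f"spec declares {spec.categories}"
        )
    if spec.structure == "direct" and np.any(params.b_tq_se != 0):
        raise ValueError("direct models have no TQ->SE path")
    if spec.structure == "mediated" and np.any(params.beta_tq != 0):
        raise ValueError("mediated models have no direct TQ->R path")
    if spec.se_effect_shared and params.beta_se[0] != params.beta_se[1]:
        raise ValueError(f"{spec.model_id} requires the SE effect to be sex-invariant")
    tq = params.beta_tq if spec.structure == "direct" else params.b_tq_se
    if spec.tq_effect_shared and tq[0] != tq[1]:
        raise ValueError(f"{spec.model_id} requires the TQ effect to be sex-invariant")
    for j, ind in enumerate(INDICATORS):
        if not ind.reference and spec.loading_shared(j):
            if params.loadings[0, j] != params.loadings[1, j]:
                raise ValueError(
                    f"{spec.model_id} requires loading of {ind.name} to be sex-invariant"
                )
        if spec.threshold_shared(j) and params.thresholds_male is not None:
            if not np.array_equal(params.thresholds[j], params.thresholds_male[j]):
                raise ValueError(
                    f"{spec.model_id} requires thresholds of {ind.name} to be sex-invariant"
                )
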