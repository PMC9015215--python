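"""Model family: latent variables, ordinal indicators and sex-invariance grids.

The family describes yearly reproductive output of breeding females and males in
a group-living bird. Three latent variables are measured by seven ordinal
indicators:

* ``R``  (reproduction) — within-group offspring (reference), extra-group
  offspring, offspring with one known parent;
* ``SE`` (social environment) — group size (reference), number of helpers;
* ``TQ`` (territory quality) — territory size class (reference), insect
  availability class.

Ten competing models ``M1``–``M10`` share this measurement core and differ in

1. the causal structure — *direct* models (M1–M6) regress R on both SE and TQ,
   *mediated* models (M7–M10) let TQ act on R only through SE; and
2. a grid of six invariance flags stating which SE/TQ parameter blocks are
   forced equal between the female and male samples (the device used to encode
   competing hypotheses about sex differences).

A quadratic age effect on R (and hence the onset of reproductive senescence) is
invariant between the sexes in every model, as are the loadings and thresholds
of the R indicators.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

SAMPLES = ("female", "male")
LATENTS = ("R", "SE", "TQ")
LEVELS = ("group", "individual", "within")

#: Age (years) is standardised internally as (age - AGE_CENTER) / AGE_SCALE.
AGE_CENTER = 5.0
AGE_SCALE = 3.0


@dataclass(frozen=True)
class Indicator:
    """One ordinal observed variable loading on a single latent variable."""

    name: str
    latent: str
    reference: bool
    n_categories: int


#: Canonical indicator order used by every array in the package (axis of size 7).
INDICATORS: tuple[Indicator, ...] = (
    Indicator("wg_offspring", "R", True, 4),
    Indicator("eg_offspring", "R", False, 3),
    Indicator("op_offspring", "R", False, 3),
    Indicator("group_size", "SE", True, 5),
    Indicator("n_helpers", "SE", False, 3),
    Indicator("territory_size", "TQ", True, 4),
    Indicator("insect_avail", "TQ", False, 4),
)

INDICATOR_NAMES = tuple(ind.name for ind in INDICATORS)
DEFAULT_CATEGORIES = tuple(ind.n_categories for ind in INDICATORS)

#: Indicators that may contain missing values (group-level measurements).
MISSING_ELIGIBLE = ("group_size", "n_helpers", "territory_size", "insect_avail")

MODEL_IDS = tuple(f"M{i}" for i in range(1, 11))

GRID_FLAGS = (
    "se_effect",
    "se_intercepts",
    "se_loadings",
    "tq_effect",
    "tq_intercepts",
    "tq_loadings",
)


@dataclass(frozen=True)
class ConstraintGrid:
    """Six boolean invariance flags; ``True`` means the block is forced ♀ = ♂.

    For direct models ``tq_effect`` governs the TQ→R path; for mediated models
    it governs the TQ→SE path. "Intercepts" of ordinal indicators are realised
    as their threshold vectors (intercepts and thresholds are confounded for
    ordinal data, so invariance of one is invariance of the other).
    """

    se_effect: bool
    se_intercepts: bool
    se_loadings: bool
    tq_effect: bool
    tq_intercepts: bool
    tq_loadings: bool

    def flag(self, name: str) -> bool:
        return getattr(self, name)


# Invariance grids of the ten models. Order of flags matches GRID_FLAGS.
_TABLE: dict[str, tuple[str, tuple[bool, ...]]] = {
    "M1": ("direct", (False, False, False, False, False, False)),
    "M2": ("direct", (False, False, True, False, False, True)),
    "M3": ("direct", (False, True, True, False, True, True)),
    "M4": ("direct", (True, True, True, False, True, True)),
    "M5": ("direct", (False, True, True, True, True, True)),
    "M6": ("direct", (True, True, True, True, True, True)),
    "M7": ("mediated", (False, True, True, False, True, True)),
    "M8": ("mediated", (True, True, True, False, True, True)),
    "M9": ("mediated", (False, True, True, True, True, True)),
    "M10": ("mediated", (True, True, True, True, True, True)),
}


@dataclass(frozen=True)
class ParameterEntry:
    """One named block in the free-parameter registry of a model."""

    name: str
    block: str  # loading | threshold | path | age | variance
    sample: str  # "female" | "male" | "shared"
    size: int


@dataclass(frozen=True)
class ModelSpec:
    """One of the ten competing models: structure + invariance grid."""

    model_id: str
    structure: str  # "direct" | "mediated"
    grid: ConstraintGrid
    categories: tuple[int, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if self.structure not in ("direct", "mediated"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if len(self.categories) != len(INDICATORS):
            raise ValueError("categories must have one entry per indicator")
        for c in self.categories:
            if c not in (3, 4, 5):
                raise ValueError("indicators are ordinal with 3, 4 or 5 categories")

    # -- block sharing ----------------------------------------------------
    def loading_shared(self, j: int) -> bool:
        """Whether indicator ``j``'s free loading is invariant between sexes."""
        latent = INDICATORS[j].latent
        if latent == "R":
            return True
        return self.grid.se_loadings if latent == "SE" else self.grid.tq_loadings

    def threshold_shared(self, j: int) -> bool:
        latent = INDICATORS[j].latent
        if latent == "R":
            return True
        return self.grid.se_intercepts if latent == "SE" else self.grid.tq_intercepts

    @property
    def se_effect_shared(self) -> bool:
        return self.grid.se_effect

    @property
    def tq_effect_shared(self) -> bool:
        """Sharing of TQ→R (direct) or TQ→SE (mediated)."""
        return self.grid.tq_effect

    # -- registry ---------------------------------------------------------
    def parameter_registry(self) -> list[ParameterEntry]:
        """Every free scalar block after constraints and reference fixings.

        Reference loadings (fixed to 1) and measurement residual variances
        (fixed to 1, probit convention) are not free and do not appear.
        """
        entries: list[ParameterEntry] = []
        for j, ind in enumerate(INDICATORS):
            if ind.reference:
                continue
            if self.loading_shared(j):
                entries.append(ParameterEntry(f"lambda[{ind.name}]", "loading", "shared", 1))
            else:
                for s in SAMPLES:
                    entries.append(
                        ParameterEntry(f"lambda[{ind.name},{s}]", "loading", s, 1)
                    )
        for j, ind in enumerate(INDICATORS):
            size = self.categories[j] - 1
            if self.threshold_shared(j):
                entries.append(ParameterEntry(f"tau[{ind.name}]", "threshold", "shared", size))
            else:
                for s in SAMPLES:
                    entries.append(ParameterEntry(f"tau[{ind.name},{s}]", "threshold", s, size))
        if self.se_effect_shared:
            entries.append(ParameterEntry("beta_se", "path", "shared", 1))
        else:
            for s in SAMPLES:
                entries.append(ParameterEntry(f"beta_se[{s}]", "path", s, 1))
        tq_name = "beta_tq" if self.structure == "direct" else "b_tq_se"
        if self.tq_effect_shared:
            entries.append(ParameterEntry(tq_name, "path", "shared", 1))
        else:
            for s in SAMPLES:
                entries.append(ParameterEntry(f"{tq_name}[{s}]", "path", s, 1))
        entries.append(ParameterEntry("gamma1", "age", "shared", 1))
        entries.append(ParameterEntry("gamma2", "age", "shared", 1))
        for latent in LATENTS:
            for level in LEVELS:
                entries.append(
                    ParameterEntry(f"sigma2[{latent},{level}]", "variance", "shared", 1)
                )
        return entries

    def to_json(self) -> str:
        payload = {
            "model_id": self.model_id,
            "structure": self.structure,
            "grid": asdict(self.grid),
            "categories": list(self.categories),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            model_id=d["model_id"],
            structure=d["structure"],
            grid=ConstraintGrid(**d["grid"]),
            categories=tuple(d["categories"]),
        )


def build_model_spec(model_id: str, categories: tuple[int, ...] = DEFAULT_CATEGORIES) -> ModelSpec:
    """Return the :class:`ModelSpec` for one of ``M1``..``M10``."""
    if model_id not in _TABLE:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    structure, flags = _TABLE[model_id]
    return ModelSpec(model_id, structure, ConstraintGrid(*flags), tuple(categories))


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free scalar parameters of a model after all constraints."""
    return sum(e.size for e in spec.parameter_registry())


def render_grid(spec: ModelSpec) -> str:
    """Human-readable one-line rendering of the invariance grid (♀ = ♂ / ♀ ≠ ♂)."""
    cells = ["♀ = ♂" if spec.grid.flag(f) else "♀ ≠ ♂" for f in GRID_FLAGS]
    return f"{spec.model_id}\t" + "\t".join(cells)


def render_constraint_table(categories: tuple[int, ...] = DEFAULT_CATEGORIES) -> str:
    """Render the full ten-model invariance table (one row per model)."""
    header = (
        "Model\tSE effect\tSE intercepts\tSE loadings\t"
        "TQ effect\tTQ intercepts\tTQ loadings"
    )
    rows = [render_grid(build_model_spec(mid, categories)) for mid in MODEL_IDS]
    return "\n".join([header, *rows])


# ---------------------------------------------------------------------------
# Model-implied moments (oracle algebra shared with the simulator tests)
# ---------------------------------------------------------------------------

def structural_transform(params, spec: ModelSpec, sample_index: int) -> np.ndarray:
    """Matrix T mapping own-level shocks (e_R, e_SE, e_TQ) to total latents.

    Total latents are ``[R, SE, TQ] = T @ [e_R, e_SE, e_TQ]`` (plus the fixed
    age contribution to R, which is handled separately).
    """
    b = 0.0
    beta_tq = 0.0
    if spec.structure == "mediated":
        b = float(params.b_tq_se[sample_index])
    else:
        beta_tq = float(params.beta_tq[sample_index])
    beta_se = float(params.beta_se[sample_index])
    return np.array(
        [
            [1.0, beta_se, beta_se * b + beta_tq],
            [0.0, 1.0, b],
            [0.0, 0.0, 1.0],
        ]
    )


def loading_matrix(params, sample_index: int) -> np.ndarray:
    """7x3 loading matrix Λ for one sample (column order R, SE, TQ)."""
    lam = np.zeros((len(INDICATORS), 3))
    for j, ind in enumerate(INDICATORS):
        lam[j, LATENTS.index(ind.latent)] = params.loadings[sample_index, j]
    return lam


def sem_implied_moments(spec: ModelSpec, params, age: float | None = None):
    """Model-implied mean and covariance of the underlying continuous indicators.

    Returns ``{(sample, level): (mean, cov)}`` for each of the two samples and
    three levels. The measurement residual (unit variance, probit convention)
    enters at the within level only; the age polynomial contributes to the
    within-level mean when ``age`` (in years) is given.
    """
    from .params import validate_params  # local import to avoid a cycle

    validate_params(spec, params)
    out = {}
    for si, sample in enumerate(SAMPLES):
        lam = loading_matrix(params, si)
        t = structural_transform(params, spec, si)
        c = lam @ t
        for li, level in enumerate(LEVELS):
            psi = np.diag(params.sigma2[:, li])
            cov = c @ psi @ c.T
            mean = np.zeros(len(INDICATORS))
            if level == "within":
                cov = cov + np.eye(len(INDICATORS))
                if age is not None:
                    z = (age - AGE_CENTER) / AGE_SCALE
                    age_term = params.gamma1 * z + params.gamma2 * z * z
                    mean = lam[:, 0] * age_term
            out[(sample, level)] = (mean, cov)
    return out
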