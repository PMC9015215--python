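"""Synthetic breeder-year datasets from a known multilevel ordinal SEM.

The generator is the exact generative counterpart of the model family in
:mod:`coopsem.specs`: latent shocks are drawn per group (territory), per
individual and per observation; total latents follow the structural equations
of the chosen model; underlying continuous indicators are ``loading x latent +
unit-variance noise`` and are cut into ordinal categories by strictly
increasing thresholds. Each group-year contributes a paired female and male
record sharing the same group-level shocks, mimicking a breeding pair on a
territory; individuals hold their territory for at least two consecutive
years. True latent values and the underlying continuous indicators are
retained so that inference can be validated against the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import TrueParameters, default_true_parameters, validate_params
from .specs import (
    AGE_CENTER,
    AGE_SCALE,
    INDICATOR_NAMES,
    INDICATORS,
    MISSING_ELIGIBLE,
    SAMPLES,
    ModelSpec,
    build_model_spec,
    loading_matrix,
    structural_transform,
)

SCHEMA_VERSION = 1
ID_COLUMNS = ("sample", "individual_id", "group_id", "year", "age")


def ordinalize(values, thresholds) -> np.ndarray:
    """Map continuous values to 1-based categories via ordered cut points.

    Returns ``k`` such that ``tau[k-2] < value <= tau[k-1]`` with the outer
    cut points at ±infinity; a value exactly on a threshold falls in the lower
    category.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty 1-d vector")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    values = np.asarray(values, dtype=float)
    return np.searchsorted(thresholds, values, side="left") + 1


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic population."""

    n_groups: int = 110
    years: int = 5
    group_size_range: tuple[int, int] = (2, 8)
    model_id: str = "M6"
    true_params: TrueParameters | None = None
    missing_rate: float = 0.0
    seed: int = 0
    age_range: tuple[int, int] = (1, 13)
    min_tenure: int = 2

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.years < self.min_tenure:
            raise ValueError("need at least one group and years >= min_tenure")
        lo, hi = self.group_size_range
        if not (2 <= lo <= hi <= 8):
            raise ValueError("group_size_range must lie within [2, 8]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.age_range[0] < 1 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("invalid age_range")

    def resolved_params(self) -> TrueParameters:
        spec = build_model_spec(self.model_id)
        params = self.true_params
        if params is None:
            params = default_true_parameters(spec.structure)
        validate_params(spec, params)
        return params

    def spec(self) -> ModelSpec:
        params = self.resolved_params()
        return build_model_spec(self.model_id, params.categories)


@dataclass
class SimTruth:
    """Generating truth retained alongside an ordinal dataset."""

    params: TrueParameters
    model_id: str
    latents: pd.DataFrame  # columns R, SE, TQ plus own-level shocks
    y_continuous: np.ndarray  # (n_records, 7) underlying indicators


@dataclass
class Dataset:
    """Breeder-year records (one row per breeder per year) plus metadata."""

    records: pd.DataFrame
    categories: tuple[int, ...]
    truth: SimTruth | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS + INDICATOR_NAMES if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def indicator_array(self) -> np.ndarray:
        """Categories as int array (n_records, 7); -1 marks missing cells."""
        arr = np.full((self.n_records, len(INDICATORS)), -1, dtype=int)
        for j, name in enumerate(INDICATOR_NAMES):
            col = self.records[name]
            ok = col.notna().to_numpy()
            arr[ok, j] = col[ok].astype(int).to_numpy()
        return arr

    # -- persistence ------------------------------------------------------
    def write(self, path: str | Path, include_truth: bool = True) -> None:
        """Write records as CSV plus a sidecar meta JSON (and truth JSON)."""
        path = Path(path)
        self.records.to_csv(path, index=False)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "categories": list(self.categories),
            "indicators": list(INDICATOR_NAMES),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
        if include_truth and self.truth is not None:
            t = self.truth
            payload = {
                "model_id": t.model_id,
                "params": {
                    "loadings": t.params.loadings.tolist(),
                    "beta_se": t.params.beta_se.tolist(),
                    "beta_tq": t.params.beta_tq.tolist(),
                    "b_tq_se": t.params.b_tq_se.tolist(),
                    "gamma1": t.params.gamma1,
                    "gamma2": t.params.gamma2,
                    "thresholds": [x.tolist() for x in t.params.thresholds],
                    "thresholds_male": None
                    if t.params.thresholds_male is None
                    else [x.tolist() for x in t.params.thresholds_male],
                    "sigma2": t.params.sigma2.tolist(),
                },
                "latents": t.latents.to_dict(orient="list"),
                "y_continuous": t.y_continuous.tolist(),
            }
            path.with_suffix(".truth.json").write_text(json.dumps(payload))

    @classmethod
    def read(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        records = pd.read_csv(path, dtype={"sample": str, "individual_id": str, "group_id": str})
        for name in INDICATOR_NAMES:
            records[name] = records[name].astype("Int64")
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            categories = tuple(meta["categories"])
        else:
            categories = tuple(
                int(records[name].max()) for name in INDICATOR_NAMES
            )
        truth = None
        truth_path = path.with_suffix(".truth.json")
        if truth_path.exists():
            d = json.loads(truth_path.read_text())
            p = d["params"]
            params = TrueParameters(
                loadings=np.array(p["loadings"]),
                beta_se=np.array(p["beta_se"]),
                beta_tq=np.array(p["beta_tq"]),
                b_tq_se=np.array(p["b_tq_se"]),
                gamma1=p["gamma1"],
                gamma2=p["gamma2"],
                thresholds=[np.array(x) for x in p["thresholds"]],
                thresholds_male=None
                if p["thresholds_male"] is None
                else [np.array(x) for x in p["thresholds_male"]],
                sigma2=np.array(p["sigma2"]),
            )
            truth = SimTruth(
                params=params,
                model_id=d["model_id"],
                latents=pd.DataFrame(d["latents"]),
                y_continuous=np.array(d["y_continuous"]),
            )
        return cls(records=records, categories=categories, truth=truth)


def _tenures(years: int, min_tenure: int, rng: np.random.Generator) -> list[int]:
    """Partition a span of years into tenures, each at least ``min_tenure``."""
    out, remaining = [], years
    while remaining > 0:
        if remaining < 2 * min_tenure:
            out.append(remaining)
            break
        # leave either nothing or at least min_tenure for the successor
        choices = [t for t in range(min_tenure, remaining + 1) if t == remaining or remaining - t >= min_tenure]
        out.append(int(rng.choice(choices)))
        remaining -= out[-1]
    return out


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw a complete paired female/male breeder-year dataset.

    The output is fully determined by ``config.seed``.
    """
    params = config.resolved_params()
    spec = config.spec()
    rng = np.random.default_rng(config.seed)

    n_groups, years = config.n_groups, config.years
    rows = []
    ind_index: list[int] = []  # individual code per record
    n_individuals = 0
    for g in range(n_groups):
        for si, sample in enumerate(SAMPLES):
            year = 0
            for tenure in _tenures(years, config.min_tenure, rng):
                code = n_individuals
                n_individuals += 1
                max_start = max(config.age_range[1] - tenure + 1, config.age_range[0])
                age0 = int(rng.integers(config.age_range[0], max_start + 1))
                for k in range(tenure):
                    rows.append(
                        (
                            sample,
                            f"{sample[0].upper()}{code:04d}",
                            f"G{g:03d}",
                            year + k + 1,
                            min(age0 + k, config.age_range[1]),
                        )
                    )
                    ind_index.append(code)
                year += tenure

    records = pd.DataFrame(rows, columns=list(ID_COLUMNS))
    n = len(records)
    sample_idx = (records["sample"] == SAMPLES[1]).to_numpy().astype(int)
    group_idx = records["group_id"].str.slice(1).astype(int).to_numpy()
    ind_idx = np.asarray(ind_index)

    # latent shocks: group, individual, observation level for each latent
    sd = np.sqrt(params.sigma2)  # (3 latents, 3 levels)
    u = rng.standard_normal((n_groups, 3)) * sd[:, 0]
    v = rng.standard_normal((n_individuals, 3)) * sd[:, 1]
    w = rng.standard_normal((n, 3)) * sd[:, 2]
    shocks = u[group_idx] + v[ind_idx] + w  # (n, 3) own-level sums per latent

    z = (records["age"].to_numpy() - AGE_CENTER) / AGE_SCALE
    age_term = params.gamma1 * z + params.gamma2 * z * z

    latents = np.empty((n, 3))
    y_cont = np.empty((n, len(INDICATORS)))
    for si in range(len(SAMPLES)):
        mask = sample_idx == si
        t = structural_transform(params, spec, si)
        latents[mask] = shocks[mask] @ t.T
        latents[mask, 0] += age_term[mask]
        lam = loading_matrix(params, si)
        y_cont[mask] = latents[mask] @ lam.T
    y_cont += rng.standard_normal(y_cont.shape)

    for j, name in enumerate(INDICATOR_NAMES):
        cats = np.empty(n, dtype=int)
        for si in range(len(SAMPLES)):
            mask = sample_idx == si
            cats[mask] = ordinalize(y_cont[mask, j], params.thresholds_for(si)[j])
        records[name] = pd.array(cats, dtype="Int64")

    truth_df = pd.DataFrame(
        {
            "R": latents[:, 0],
            "SE": latents[:, 1],
            "TQ": latents[:, 2],
            "e_R": shocks[:, 0],
            "e_SE": shocks[:, 1],
            "e_TQ": shocks[:, 2],
        }
    )
    dataset = Dataset(
        records=records,
        categories=params.categories,
        truth=SimTruth(params=params, model_id=config.model_id, latents=truth_df, y_continuous=y_cont),
    )
    if config.missing_rate > 0:
        dataset = apply_missingness(dataset, config.missing_rate, seed=config.seed + 1)
    return dataset


def apply_missingness(dataset: Dataset, rate: float, seed: int) -> Dataset:
    """Mask eligible group-level indicator cells independently at ``rate``.

    Only group size, number of helpers, territory size and insect availability
    can be missing; reproduction indicators and age are always complete.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    records = dataset.records.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        for name in MISSING_ELIGIBLE:
            mask = rng.random(len(records)) < rate
            col = records[name].copy()
            col[mask] = pd.NA
            records[name] = col
    return Dataset(records=records, categories=dataset.categories, truth=dataset.truth)
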