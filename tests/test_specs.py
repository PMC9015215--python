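"""Model-family definitions: grids, registries, implied moments."""

import numpy as np
import pytest

import coopsem as cs
from coopsem.params import default_true_parameters, validate_params
from coopsem.specs import (
    GRID_FLAGS,
    INDICATORS,
    MODEL_IDS,
    ConstraintGrid,
    build_model_spec,
    render_constraint_table,
    render_grid,
)

# ♀=♂ pattern of the ten models: (structure, six flags in GRID_FLAGS order)
EXPECTED_GRIDS = {
    "M1": ("direct", "≠≠≠≠≠≠"),
    "M2": ("direct", "≠≠=≠≠="),
    "M3": ("direct", "≠==≠=="),
    "M4": ("direct", "===≠=="),
    "M5": ("direct", "≠====="),
    "M6": ("direct", "======"),
    "M7": ("mediated", "≠==≠=="),
    "M8": ("mediated", "===≠=="),
    "M9": ("mediated", "≠====="),
    "M10": ("mediated", "======"),
}


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_grid_matches_published_pattern(model_id):
    """Each model's invariance flags reproduce the published grid row."""
    spec = build_model_spec(model_id)
    structure, pattern = EXPECTED_GRIDS[model_id]
    assert spec.structure == structure
    rendered = render_grid(spec)
    got = "".join("=" if "= ♂" in cell else "≠" for cell in rendered.split("\t")[1:])
    assert got == pattern
    # round trip through the flag accessors as well
    flags = "".join("=" if spec.grid.flag(f) else "≠" for f in GRID_FLAGS)
    assert flags == pattern


def test_render_table_covers_all_models():
    table = render_constraint_table()
    assert len(table.splitlines()) == 11
    for mid in MODEL_IDS:
        assert any(line.startswith(mid + "\t") for line in table.splitlines())


def test_unknown_model_id_rejected():
    with pytest.raises(ValueError):
        build_model_spec("M11")


def test_parameter_count_orderings():
    """Progressively constrained models have strictly fewer free parameters."""
    counts = {mid: cs.count_free_parameters(build_model_spec(mid)) for mid in MODEL_IDS}
    assert counts["M6"] < counts["M3"] < counts["M1"]
    assert counts["M10"] < counts["M7"]
    assert counts["M6"] <= min(counts[m] for m in ("M1", "M2", "M3", "M4", "M5"))


@pytest.mark.parametrize("flag", GRID_FLAGS)
def test_relaxing_any_flag_increases_count(flag):
    spec6 = build_model_spec("M6")
    relaxed = cs.ModelSpec(
        "M6",
        "direct",
        ConstraintGrid(**{f: (f != flag) for f in GRID_FLAGS}),
        spec6.categories,
    )
    assert cs.count_free_parameters(relaxed) > cs.count_free_parameters(spec6)


def test_registry_covers_every_equation_symbol():
    """No orphans: every measurement/structural symbol appears exactly once."""
    spec = build_model_spec("M1")
    names = [e.name for e in spec.parameter_registry()]
    assert len(names) == len(set(names))
    blocks = {e.block for e in spec.parameter_registry()}
    assert blocks == {"loading", "threshold", "path", "age", "variance"}
    for ind in INDICATORS:
        if not ind.reference:
            assert any(n.startswith(f"lambda[{ind.name}") for n in names)
        assert any(n.startswith(f"tau[{ind.name}") for n in names)
    # mediated models expose the TQ->SE path instead of a direct TQ->R path
    med = [e.name for e in build_model_spec("M10").parameter_registry()]
    assert "b_tq_se" in med and not any(n.startswith("beta_tq") for n in med)


def test_mediated_and_direct_structures_exclusive():
    assert all(build_model_spec(m).structure == "direct" for m in ("M1", "M6"))
    assert all(build_model_spec(m).structure == "mediated" for m in ("M7", "M10"))


def test_json_round_trip():
    spec = build_model_spec("M8")
    again = cs.ModelSpec.from_json(spec.to_json())
    assert again == spec


def test_constraint_validation_rejects_sex_specific_values():
    params = default_true_parameters("direct", beta_se=(0.8, 0.2))
    with pytest.raises(ValueError, match="sex-invariant"):
        validate_params(build_model_spec("M6"), params)
    # but M5 allows a sex-specific SE effect
    validate_params(build_model_spec("M5"), params)


def test_implied_moments_diagonal_case():
    """Zero paths, unit variances: covariance is the loading pattern plus noise."""
    spec = build_model_spec("M6")
    params = default_true_parameters("direct", beta_se=0.0, beta_tq=0.0)
    params.sigma2[:, :] = [[0.0, 0.0, 1.0]] * 3
    moments = cs.sem_implied_moments(spec, params)
    _, cov = moments[("female", "within")]
    lam = np.zeros((7, 3))
    for j, ind in enumerate(INDICATORS):
        lam[j, ("R", "SE", "TQ").index(ind.latent)] = params.loadings[0, j]
    expected = lam @ lam.T + np.eye(7)
    np.testing.assert_allclose(cov, expected, atol=1e-12)
    # group/individual levels carry no variance here
    np.testing.assert_allclose(moments[("male", "group")][1], 0.0, atol=1e-12)


def test_implied_moments_mediated_se_variance():
    """Mediated structure: Var(SE) = b^2 Var(TQ) + own variance, per level."""
    spec = build_model_spec("M10")
    params = default_true_parameters("mediated", b_tq_se=0.5, beta_se=0.0)
    moments = cs.sem_implied_moments(spec, params)
    for level in ("group", "individual", "within"):
        _, cov = moments[("female", level)]
        li = ("group", "individual", "within").index(level)
        var_tq = params.sigma2[2, li]
        var_se = params.sigma2[1, li]
        # group-size indicator (reference for SE) isolates the SE variance
        expected = 0.5**2 * var_tq + var_se + (1.0 if level == "within" else 0.0)
        assert cov[3, 3] == pytest.approx(expected, rel=1e-12)


def test_implied_moments_match_simulated_covariance():
    """Monte-Carlo check: empirical covariance of the retained continuous
    indicators matches the closed-form single-level covariance."""
    params = default_true_parameters("direct")
    params.sigma2[:, 0] = 0.0
    params.sigma2[:, 1] = 0.0
    cfg = cs.GeneratorConfig(n_groups=400, years=4, model_id="M6", true_params=params, seed=3)
    ds = cs.generate_dataset(cfg)
    spec = cfg.spec()
    moments = cs.sem_implied_moments(spec, params)
    _, cov_expected = moments[("female", "within")]
    fem = (ds.records["sample"] == "female").to_numpy()
    resid = ds.truth.y_continuous[fem]
    # remove the age-driven mean from the reproduction indicators
    resid = resid - resid.mean(axis=0)
    cov_emp = np.cov(resid.T)
    # age variation inflates R-indicator variances; compare the SE/TQ block
    np.testing.assert_allclose(cov_emp[3:, 3:], cov_expected[3:, 3:], atol=0.2)
    # and the R-block correlation structure net of age via off-diagonals
    np.testing.assert_allclose(cov_emp[1, 2], cov_expected[1, 2], atol=0.15)
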