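"""Synthetic-data generator: determinism, pairing, ordinalization, missingness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtr
from scipy.stats import binom

import coopsem as cs
from coopsem.params import default_true_parameters
from coopsem.simulate import MISSING_ELIGIBLE, ordinalize
from coopsem.specs import INDICATOR_NAMES


def test_ordinalize_boundaries():
    th = np.array([-1.0, 0.0, 1.0])
    assert ordinalize(-5.0, th) == 1
    assert ordinalize(0.5, th) == 3
    assert ordinalize(5.0, th) == 4
    # a value exactly on a cut point falls in the lower category
    assert ordinalize(0.0, th) == 2


def test_ordinalize_rejects_nonmonotone_thresholds():
    with pytest.raises(ValueError):
        ordinalize(0.0, np.array([0.0, -1.0]))
    with pytest.raises(ValueError):
        ordinalize(0.0, np.array([0.0, 0.0]))


@given(
    st.lists(st.floats(-3, 3), min_size=2, max_size=4, unique=True),
    st.floats(-10, 10),
)
def test_ordinalize_category_bounds(cuts, value):
    th = np.sort(np.asarray(cuts))
    cat = int(ordinalize(value, th))
    assert 1 <= cat <= len(th) + 1
    if cat > 1:
        assert value > th[cat - 2]
    if cat <= len(th):
        assert value <= th[cat - 1]


def test_generator_is_deterministic(tmp_path):
    cfg = cs.GeneratorConfig(n_groups=15, years=4, seed=9, missing_rate=0.1)
    a = cs.generate_dataset(cfg)
    b = cs.generate_dataset(cfg)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.write(pa, include_truth=False)
    b.write(pb, include_truth=False)
    assert pa.read_bytes() == pb.read_bytes()


def test_paired_records_and_group_count():
    ds = cs.generate_dataset(cs.GeneratorConfig(n_groups=110, years=5, seed=1))
    assert ds.records["group_id"].nunique() == 110
    by = ds.records.groupby(["group_id", "year"])["sample"].agg(set)
    assert all(s == {"female", "male"} for s in by)


def test_individuals_persist_at_least_two_years(small_dataset):
    tenures = small_dataset.records.groupby("individual_id")["year"].count()
    assert (tenures >= 2).all()
    # ages increase along an individual's record and stay in range
    for _, grp in small_dataset.records.groupby("individual_id"):
        ages = grp.sort_values("year")["age"].to_numpy()
        assert (np.diff(ages) >= 0).all()
        assert ages.min() >= 1 and ages.max() <= 13


def test_categories_within_declared_range(small_dataset):
    arr = small_dataset.indicator_array()
    for j, c in enumerate(small_dataset.categories):
        col = arr[:, j][arr[:, j] > 0]
        assert col.min() >= 1 and col.max() <= c


def test_missingness_rate_zero_is_identity(small_dataset):
    out = cs.apply_missingness(small_dataset, 0.0, seed=1)
    assert out.records.equals(small_dataset.records)


def test_missingness_only_touches_group_level_indicators():
    ds = cs.generate_dataset(cs.GeneratorConfig(n_groups=60, years=5, seed=2))
    masked = cs.apply_missingness(ds, 0.3, seed=3)
    for name in INDICATOR_NAMES:
        n_missing = masked.records[name].isna().sum()
        if name in MISSING_ELIGIBLE:
            assert n_missing > 0
        else:
            assert n_missing == 0
    assert not masked.records["age"].isna().any()


def test_missingness_binomial_count():
    """Masked-cell count lies in the central 99% binomial interval."""
    ds = cs.generate_dataset(cs.GeneratorConfig(n_groups=250, years=5, seed=4))
    n_cells = 4 * ds.n_records
    assert n_cells >= 10_000
    masked = cs.apply_missingness(ds, 0.1, seed=5)
    count = int(masked.records[list(MISSING_ELIGIBLE)].isna().sum().sum())
    lo, hi = binom(n_cells, 0.1).ppf(0.005), binom(n_cells, 0.1).ppf(0.995)
    assert lo <= count <= hi


def test_category_frequencies_match_threshold_probabilities():
    """With no structure the reference indicator's category frequencies follow
    the normal-CDF probabilities implied by its thresholds."""
    params = default_true_parameters("direct", beta_se=0.0, beta_tq=0.0, gamma1=0.0, gamma2=-1e-9)
    params.sigma2[:, :] = 0.0
    params.sigma2[:, 2] = 1e-12  # degenerate latents: pure measurement noise
    cfg = cs.GeneratorConfig(n_groups=400, years=4, true_params=params, seed=6)
    ds = cs.generate_dataset(cfg)
    j = INDICATOR_NAMES.index("territory_size")
    th = params.thresholds[j]
    probs = np.diff(np.concatenate(([0.0], ndtr(th), [1.0])))
    counts = ds.records["territory_size"].value_counts(normalize=True).sort_index()
    np.testing.assert_allclose(counts.to_numpy(), probs, atol=0.02)


def test_variance_components_recovered_from_retained_latents():
    """Moment identities of the three-level decomposition hold empirically:
    paired female/male records share only the group effect, and the same
    individual's years share the group plus individual effects."""
    params = default_true_parameters("direct", beta_se=0.0, beta_tq=0.0)
    cfg = cs.GeneratorConfig(n_groups=500, years=6, true_params=params, seed=8)
    ds = cs.generate_dataset(cfg)
    df = ds.records[["sample", "group_id", "individual_id", "year"]].copy()
    df["tq"] = ds.truth.latents["TQ"].to_numpy()
    sig = params.sigma2[2]  # (group, individual, within) variances of TQ

    wide = df.pivot(index=["group_id", "year"], columns="sample", values="tq")
    cov_fm = np.cov(wide["female"], wide["male"])[0, 1]
    assert cov_fm == pytest.approx(sig[0], abs=0.08)

    sdf = df.sort_values(["individual_id", "year"]).reset_index(drop=True)
    prev = sdf.groupby("individual_id")["tq"].shift(1)
    pairs = np.column_stack([sdf["tq"].to_numpy(), prev.to_numpy()])
    pairs = pairs[~np.isnan(pairs[:, 1])]
    cov_ind = np.cov(pairs.T)[0, 1]
    assert cov_ind == pytest.approx(sig[0] + sig[1], abs=0.08)

    assert df["tq"].var() == pytest.approx(sig.sum(), abs=0.08)


def test_dataset_round_trip(tmp_path, small_dataset):
    path = tmp_path / "ds.csv"
    small_dataset.write(path)
    again = cs.Dataset.read(path)
    assert again.records.equals(small_dataset.records)
    assert again.categories == small_dataset.categories
    np.testing.assert_allclose(again.truth.y_continuous, small_dataset.truth.y_continuous)


def test_generator_rejects_inconsistent_constraints():
    params = default_true_parameters("direct", beta_se=(0.9, 0.1))
    cfg = cs.GeneratorConfig(n_groups=10, years=4, model_id="M6", true_params=params, seed=1)
    with pytest.raises(ValueError):
        cs.generate_dataset(cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        cs.GeneratorConfig(n_groups=10, years=4, group_size_range=(1, 8))
    with pytest.raises(ValueError):
        cs.GeneratorConfig(n_groups=10, years=4, missing_rate=1.5)
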