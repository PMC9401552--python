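import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import slidenorm as sn


def _one_slide(values, slide="s1"):
    values = list(values)
    return pd.DataFrame(
        {"slide_id": [slide] * len(values), "image_id": [slide + "_im"] * len(values),
         "m1": values}
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def test_log10_at_powers_of_ten():
    np.testing.assert_allclose(sn.transform_log10([0, 9, 99]), [0, 1, 2])
    np.testing.assert_allclose(sn.transform_log10([0]), [0])
    # log10(3 + 1) checked against an independent high-precision evaluation
    np.testing.assert_allclose(sn.transform_log10([3]), [0.6020599913279624])


def test_log10_rejects_negatives():
    with pytest.raises(ValueError):
        sn.transform_log10([-1.0, 2.0])


def test_mean_divide_single_slide():
    out = sn.transform_mean_divide(_one_slide([2, 4, 6]), ["m1"], "slide_id")
    np.testing.assert_allclose(out["m1"], [0.5, 1.0, 1.5])


def test_mean_divide_constant_marker_maps_to_one():
    df = pd.concat([_one_slide([3, 3, 3], "a"), _one_slide([3, 3, 3], "b")])
    out = sn.transform_mean_divide(df, ["m1"], "slide_id")
    np.testing.assert_allclose(out["m1"], 1.0)


def test_mean_divide_removes_exact_multiplicative_effect():
    base = [1.0, 2.5, 4.0, 0.5]
    df = pd.concat([_one_slide(base, "a"), _one_slide([2 * v for v in base], "b")])
    out = sn.transform_mean_divide(df, ["m1"], "slide_id")
    a = out[out.slide_id == "a"]["m1"].to_numpy()
    b = out[out.slide_id == "b"]["m1"].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_mean_divide_zero_mean_group_is_degenerate():
    df = pd.concat([_one_slide([0.0, 0.0], "a"), _one_slide([1.0, 2.0], "b")])
    with pytest.raises(sn.DegenerateGroupError, match="'a'"):
        sn.transform_mean_divide(df, ["m1"], "slide_id")


def test_log10_mean_divide_composition():
    out = sn.transform_log10_mean_divide(_one_slide([2, 4, 6]), ["m1"], "slide_id")
    np.testing.assert_allclose(out["m1"], np.log10([1.5, 2.0, 2.5]))
    # constant positive marker -> log10(2) everywhere
    out = sn.transform_log10_mean_divide(_one_slide([5, 5, 5]), ["m1"], "slide_id")
    np.testing.assert_allclose(out["m1"], np.log10(2.0))


@given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=30))
@settings(max_examples=50, deadline=None)
def test_log10_mean_divide_equals_log10_after_mean_divide(values):
    df = _one_slide(values)
    direct = sn.transform_log10_mean_divide(df, ["m1"], "slide_id")["m1"].to_numpy()
    staged = sn.transform_log10(
        sn.transform_mean_divide(df, ["m1"], "slide_id")["m1"].to_numpy()
    )
    np.testing.assert_allclose(direct, staged, rtol=1e-12)


@given(
    st.lists(st.floats(0.01, 50.0), min_size=3, max_size=20),
    st.lists(st.floats(0.01, 50.0), min_size=3, max_size=20),
)
@settings(max_examples=50, deadline=None)
def test_mean_divide_idempotent(a, b):
    df = pd.concat([_one_slide(a, "a"), _one_slide(b, "b")], ignore_index=True)
    once = sn.transform_mean_divide(df, ["m1"], "slide_id")
    twice = sn.transform_mean_divide(once, ["m1"], "slide_id")
    np.testing.assert_allclose(once["m1"], twice["m1"], rtol=1e-10)


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

def _gaussian_slides(effects, n_per, seed, sd=1.0, scales=None, n_markers=2, mu=10.0):
    rng = np.random.default_rng(seed)
    scales = scales or [1.0] * len(effects)
    rows = []
    for s, (eff, sc) in enumerate(zip(effects, scales)):
        data = {"slide_id": f"s{s}", "image_id": f"s{s}_im"}
        for m in range(n_markers):
            data[f"m{m + 1}"] = mu + eff * (1 if m % 2 == 0 else -0.5) + sc * rng.normal(
                0, sd, n_per
            )
        rows.append(pd.DataFrame(data))
    return pd.concat(rows, ignore_index=True)


def test_combat_recovers_simulated_slide_shifts():
    """Posterior location effects match the simulated shifts after centering."""
    effects = [1.0, -1.0]
    df = _gaussian_slides(effects, n_per=5000, seed=21)
    model = sn.fit_combat(df, ["m1", "m2"], "slide_id")
    # gamma* lives on the standardized scale; map back to intensity units
    gamma_units = model.gamma_star.mul(np.sqrt(model.pooled_var), axis=1)
    recovered = gamma_units["m1"] - gamma_units["m1"].mean()
    truth = np.array(effects) - np.mean(effects)
    np.testing.assert_allclose(recovered.to_numpy(), truth, atol=0.05)


def test_combat_shrinks_exchangeable_slides():
    df = _gaussian_slides([0.0, 0.0, 0.0], n_per=500, seed=22)
    model = sn.fit_combat(df, ["m1", "m2"], "slide_id")
    assert np.abs(model.gamma_star.to_numpy()).max() < 0.15
    np.testing.assert_allclose(model.delta_star_sq.to_numpy(), 1.0, atol=0.25)
    # shrinkage moves estimates toward the prior relative to least squares
    assert (
        np.abs(model.gamma_star.to_numpy() - model.gamma_bar.to_numpy()[:, None]).sum()
        <= np.abs(model.gamma_hat.to_numpy() - model.gamma_bar.to_numpy()[:, None]).sum()
    )


def test_combat_degenerate_and_error_cases():
    with pytest.raises(sn.InsufficientBatchesError):
        sn.fit_combat(_gaussian_slides([0.0], 50, 1), ["m1", "m2"], "slide_id")
    # a marker constant within every slide has zero pooled residual variance
    df = _gaussian_slides([1.0, -1.0], 50, 2)
    df["m1"] = df["slide_id"].map({"s0": 1.0, "s1": 2.0})
    with pytest.raises(sn.DegenerateGroupError):
        sn.fit_combat(df, ["m1", "m2"], "slide_id")


def test_apply_combat_identity_when_no_effects():
    df = _gaussian_slides([0.5, -0.5], 100, 4)
    model = sn.fit_combat(df, ["m1", "m2"], "slide_id")
    model.gamma_star.loc[:, :] = 0.0
    model.delta_star_sq.loc[:, :] = 1.0
    out = sn.apply_combat(df, model, "slide_id")
    np.testing.assert_allclose(out[["m1", "m2"]], df[["m1", "m2"]], rtol=1e-12)


def test_apply_combat_shifts_positive_gamma_down():
    df = _gaussian_slides([2.0, -2.0], 500, 5)
    model = sn.fit_combat(df, ["m1", "m2"], "slide_id")
    out = sn.apply_combat(df, model, "slide_id")
    s0 = model.gamma_star.loc["s0", "m1"]
    assert s0 > 0
    before = df[df.slide_id == "s0"]["m1"].mean()
    after = out[out.slide_id == "s0"]["m1"].mean()
    assert after < before


def test_apply_combat_rejects_unseen_slide():
    df = _gaussian_slides([1.0, -1.0], 50, 6)
    model = sn.fit_combat(df, ["m1", "m2"], "slide_id")
    other = df.copy()
    other["slide_id"] = other["slide_id"].str.replace("s0", "s9")
    with pytest.raises(ValueError, match="s9"):
        sn.apply_combat(other, model, "slide_id")


def test_combat_homogenizes_additive_and_scale_effects():
    df = _gaussian_slides([2.5, -2.5, 0.0], 2000, 7, scales=[1.0, 2.0, 1.0])
    model = sn.fit_combat(df, ["m1", "m2"], "slide_id")
    out = sn.apply_combat(df, model, "slide_id")
    for m in ["m1", "m2"]:
        before = df.groupby("slide_id")[m].mean().std()
        after = out.groupby("slide_id")[m].mean().std()
        assert after <= 0.1 * before
        variances = out.groupby("slide_id")[m].var()
        assert variances.max() / variances.min() < 1.25


def test_combat_matches_reference_adjustment():
    """Frozen oracle: adjusted values from the Bioconductor reference ComBat
    (sva::ComBat, parametric priors) on a fixed 3-slide, 3-marker fixture."""
    rng = np.random.default_rng(20240917)
    rows = []
    for s, (shift, scale) in enumerate([(0.8, 1.0), (-0.4, 1.6), (0.1, 0.7)]):
        n = 8
        rows.append(pd.DataFrame({
            "slide_id": f"s{s}", "image_id": f"s{s}_im1",
            "m1": 5.0 + shift + scale * rng.normal(0, 1, n),
            "m2": 7.0 - shift + scale * rng.normal(0, 1.3, n),
            "m3": 3.0 + 0.5 * shift + rng.normal(0, 0.8, n),
        }))
    df = pd.concat(rows, ignore_index=True)
    model = sn.fit_combat(df, ["m1", "m2", "m3"], "slide_id")
    out = sn.apply_combat(df, model, "slide_id")
    expected = np.array([
        [5.6017909516, 3.637643768, 3.903834756],
        [5.1576564235, 9.0470387473, 3.3586889207],
        [4.8445064718, 5.6624940211, 1.8763990925],
        [6.2757182116, 5.6595427668, 2.0651336253],
        [4.3676094565, 7.7663851578, 3.7713232023],
        [6.117115671, 7.0532110076, 3.3550241161],
        [6.1766142534, 3.9163676261, 2.7272272719],
        [5.1259383967, 6.7920497917, 4.3798913447],
        [5.6955051823, 9.7496482164, 3.8970443064],
        [5.0392965392, 7.7668530088, 3.4795138658],
        [4.5133440525, 3.9860644188, 3.4213593086],
        [6.4858993296, 5.1766371393, 4.0244941683],
        [5.3550993135, 6.0356746157, 3.3790751841],
        [5.944099927, 5.4643597827, 2.1696034811],
        [4.3333973732, 6.6321117109, 2.5058391529],
        [3.7225914771, 6.4990146773, 4.2595326744],
        [5.4892848073, 8.2474361417, 2.8289371303],
        [5.883178, 5.1488021344, 3.8066441491],
        [4.7026524029, 8.2680703369, 3.293514164],
        [5.2196204497, 7.3572287075, 3.1012964733],
        [5.2673126504, 3.3644414727, 3.5405247584],
        [6.5256473989, 6.2066730813, 4.2054181799],
        [3.2868688675, 7.3661145351, 3.2752905468],
        [5.1937334687, 7.3134413549, 1.7476898133],
    ])
    np.testing.assert_allclose(out[["m1", "m2", "m3"]].to_numpy(), expected, atol=1e-6)


# ---------------------------------------------------------------------------
# normalize() driver
# ---------------------------------------------------------------------------

def test_normalize_mean_divide_records_provenance(minimal_dataset):
    ds = sn.normalize(minimal_dataset, "mean_divide", "None")
    assert ds.norm_data is not None
    assert ds.transform == "mean_divide" and ds.method == "None"
    means = ds.norm_data.groupby("slide_id")[ds.marker_cols].mean()
    np.testing.assert_allclose(means.to_numpy(), 1.0, atol=1e-10)
    # raw is untouched
    np.testing.assert_array_equal(
        ds.data[ds.marker_cols].to_numpy(),
        minimal_dataset.data[ds.marker_cols].to_numpy(),
    )


def test_normalize_identity(minimal_dataset):
    ds = sn.normalize(minimal_dataset, "None", "None")
    np.testing.assert_array_equal(
        ds.norm_data[ds.marker_cols].to_numpy(), ds.data[ds.marker_cols].to_numpy()
    )


@pytest.mark.parametrize("transform", sn.TRANSFORMS)
def test_shape_preserved_for_every_transform(small_dataset, transform):
    ds = sn.normalize(small_dataset, transform, "None")
    assert ds.norm_data.shape == ds.data.shape
    assert list(ds.norm_data.columns) == list(ds.data.columns)
    pd.testing.assert_series_equal(ds.norm_data["slide_id"], ds.data["slide_id"])


def test_normalize_combat_runs_on_dataset(small_dataset):
    ds = sn.normalize(small_dataset, "log10", "ComBat")
    assert ds.method == "ComBat" and ds.transform == "log10"
    assert ds.norm_data.shape == ds.data.shape


def test_unknown_names_list_registry(minimal_dataset):
    with pytest.raises(sn.RegistryError, match="mean_divide"):
        sn.normalize(minimal_dataset, "sqrt", "None")
    with pytest.raises(sn.RegistryError, match="ComBat"):
        sn.normalize(minimal_dataset, "None", "quantile")


def test_user_defined_normalizer(minimal_dataset):
    def add_offset(table, marker_cols, slide_id, image_id, offset=1.0):
        out = table.copy()
        out[marker_cols] = out[marker_cols] + offset
        return out

    ds = sn.normalize(minimal_dataset, "None", add_offset, method_params={"offset": 1.0})
    np.testing.assert_allclose(
        ds.norm_data[ds.marker_cols].to_numpy(),
        ds.data[ds.marker_cols].to_numpy() + 1.0,
    )
    assert ds.method == "add_offset"


def test_user_normalizer_contract_violations(minimal_dataset):
    def drops_rows(table, marker_cols, slide_id, image_id):
        return table.iloc[:-1]

    def wrong_type(table, marker_cols, slide_id, image_id):
        return table[marker_cols].to_numpy()

    for bad in (drops_rows, wrong_type):
        with pytest.raises(sn.ContractViolationError):
            sn.normalize(minimal_dataset, "None", bad)
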