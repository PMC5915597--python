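import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxelfc.assoc import (
    ThresholdMode,
    apply_threshold,
    bh_fdr,
    cluster_filter,
    liptak_combine,
    ma_score,
    p_to_signed_z,
    region_cluster_table,
    site_link_test,
    voxel_signed_summary,
)
from voxelfc.fc import enumerate_pairs
from voxelfc.synth import RegionSpec, make_toy_atlas


def _phen(groups, **covs):
    df = pd.DataFrame({"group": groups})
    for k, v in covs.items():
        df[k] = v
    return df


# -- site_link_test -------------------------------------------------------


def test_no_covariates_equals_pooled_two_sample_t(rng):
    z = rng.standard_normal((14, 50))
    groups = ["control"] * 6 + ["patient"] * 8
    res = site_link_test(z, _phen(groups))
    t_ref, p_ref = stats.ttest_ind(z[6:], z[:6], equal_var=True)
    np.testing.assert_allclose(res.t, t_ref, atol=1e-10)
    np.testing.assert_allclose(res.p, p_ref, atol=1e-10)
    assert res.df == 12
    # group coefficient is the raw mean difference
    np.testing.assert_allclose(res.effect, z[6:].mean(0) - z[:6].mean(0), atol=1e-10)


def test_covariate_adjustment_changes_t_and_matches_ols(rng):
    import statsmodels.api as sm

    n = 24
    z = rng.standard_normal((n, 5))
    groups = ["control"] * 12 + ["patient"] * 12
    age = rng.uniform(18, 60, n)
    res = site_link_test(z, _phen(groups, age=age), covariates=("age",))
    x = sm.add_constant(np.column_stack([np.r_[np.zeros(12), np.ones(12)], age]))
    for j in range(5):
        fit = sm.OLS(z[:, j], x).fit()
        assert res.t[j] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert res.p[j] == pytest.approx(fit.pvalues[1], abs=1e-10)


def test_null_pvalues_uniform(rng):
    z = rng.standard_normal((40, 3000))
    groups = rng.permutation(["control"] * 20 + ["patient"] * 20)
    res = site_link_test(z, _phen(list(groups)))
    assert stats.kstest(res.p, "uniform").pvalue > 0.01


def test_collinear_covariate_rejected(rng):
    z = rng.standard_normal((10, 3))
    groups = ["control"] * 5 + ["patient"] * 5
    indicator = [0.0] * 5 + [1.0] * 5
    with pytest.raises(ValueError, match="rank deficient"):
        site_link_test(z, _phen(groups, dup=indicator), covariates=("dup",))


def test_missing_group_rejected(rng):
    z = rng.standard_normal((5, 3))
    with pytest.raises(ValueError, match=">= 2 subjects"):
        site_link_test(z, _phen(["control"] * 4 + ["patient"]))


def test_missing_pairs_excluded(rng):
    z = rng.standard_normal((10, 4))
    z[3, 2] = np.nan
    res = site_link_test(z, _phen(["control"] * 5 + ["patient"] * 5))
    assert np.isnan(res.t[2]) and np.isnan(res.p[2]) and np.isnan(res.z_signed[2])
    assert np.isfinite(res.t[[0, 1, 3]]).all()


# -- p_to_signed_z / liptak -----------------------------------------------


def test_signed_z_conversion():
    assert p_to_signed_z(np.array([1.0]), np.array([1.0]))[0] == 0.0
    assert p_to_signed_z(np.array([1.0]), np.array([-1.0]))[0] == 0.0
    z = p_to_signed_z(np.array([0.05, 0.05]), np.array([1.0, -1.0]))
    assert z[0] == pytest.approx(1.95996, abs=5e-6)
    assert z[1] == pytest.approx(-1.95996, abs=5e-6)
    assert np.isfinite(p_to_signed_z(np.array([1e-320]), np.array([1.0]))[0])
    with pytest.raises(ValueError):
        p_to_signed_z(np.array([0.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        p_to_signed_z(np.array([1.5]), np.array([1.0]))


def test_liptak_single_site_identity(rng):
    z = rng.standard_normal(20)
    combined, p = liptak_combine(z[None, :], np.array([57]))
    np.testing.assert_allclose(combined, z, atol=1e-12)
    np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(z)), atol=1e-12)


def test_liptak_worked_example():
    combined, _ = liptak_combine(np.array([[2.0], [1.0]]), np.array([100, 400]))
    assert combined[0] == pytest.approx(40.0 / np.sqrt(500.0), abs=1e-12)
    assert combined[0] == pytest.approx(1.78885, abs=5e-6)


def test_liptak_cancellation_and_missing_site():
    z = np.array([[1.7], [-1.7]])
    combined, p = liptak_combine(z, np.array([30, 30]))
    assert combined[0] == 0.0 and p[0] == 1.0
    z = np.array([[2.0], [np.nan]])
    combined, _ = liptak_combine(z, np.array([30, 30]))
    assert combined[0] == pytest.approx(2.0)  # missing site drops from both sums
    z = np.array([[np.nan], [np.nan]])
    combined, p = liptak_combine(z, np.array([30, 30]))
    assert np.isnan(combined[0]) and np.isnan(p[0])


def test_liptak_same_sign_site_behaviour(rng):
    """Adding an equal-weight site with same-sign z' preserves the sign, gives
    exactly (z1+z2)/sqrt(2), and increases |Z| precisely when the new site's
    evidence exceeds (sqrt(2)-1)|z1| (sharp condition for the normalized
    statistic)."""
    for _ in range(50):
        z1, extra = rng.standard_normal(2)
        z2 = np.sign(z1) * abs(extra)
        base, _ = liptak_combine(np.array([[z1]]), np.array([40]))
        both, _ = liptak_combine(np.array([[z1], [z2]]), np.array([40, 40]))
        assert both[0] == pytest.approx((z1 + z2) / np.sqrt(2.0), abs=1e-12)
        assert np.sign(both[0]) == np.sign(z1)
        grows = abs(z2) >= (np.sqrt(2.0) - 1.0) * abs(z1)
        assert (abs(both[0]) >= abs(base[0]) - 1e-12) == grows


# -- BH FDR ---------------------------------------------------------------


def test_bh_step_up_example():
    p = np.array([0.001, 0.01, 0.02, 0.04, 0.2])
    p_star, mask = bh_fdr(p, 0.05)
    assert p_star == 0.04
    np.testing.assert_array_equal(mask, [True, True, True, True, False])


def test_bh_edge_cases():
    p_star, mask = bh_fdr(np.ones(5), 0.05)
    assert p_star == 0.0 and not mask.any()
    p_star, mask = bh_fdr(np.array([0.04]), 0.05)
    assert mask[0] and p_star == 0.04
    with pytest.raises(ValueError):
        bh_fdr(np.array([np.nan]), 0.05)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=500) ** 2
    p_star, mask = bh_fdr(p, 0.05)
    reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
    np.testing.assert_array_equal(mask, reject)
    if reject.any():
        assert p_star == p[reject].max()


# -- voxel summaries ------------------------------------------------------


def _random_instance(rng):
    atlas = make_toy_atlas(
        (8, 6, 2),
        [
            RegionSpec(1, "seed", (0, 0, 0), (3, 1, 1)),
            RegionSpec(2, "a", (0, 2, 0), (4, 2, 1)),
            RegionSpec(3, "b", (5, 3, 1), (3, 3, 1)),
        ],
    )
    pi = enumerate_pairs(atlas, 1)
    z = rng.standard_normal(pi.n_pairs) * 3
    mask = rng.random(pi.n_pairs) < 0.3
    return atlas, pi, z, mask


def test_ma_score_cases_and_oracle(rng):
    atlas, pi, _, mask = _random_instance(rng)
    assert ma_score(np.zeros(pi.n_pairs, bool), pi).sum() == 0
    ma = ma_score(mask, pi)
    brute = np.zeros(atlas.n_voxels, int)
    for (i, j), m in zip(pi.pairs, mask):
        if m:
            brute[i] += 1
            brute[j] += 1
    np.testing.assert_array_equal(ma, brute)
    assert ma.sum() == 2 * mask.sum()


def test_voxel_signed_summary_cases_and_oracle(rng):
    atlas, pi, z, mask = _random_instance(rng)
    s, sign = voxel_signed_summary(z, mask, pi)
    s_brute = np.zeros(atlas.n_voxels)
    sum_brute = np.zeros(atlas.n_voxels)
    for (i, j), m, zz in zip(pi.pairs, mask, z):
        if m:
            for v in (i, j):
                s_brute[v] += abs(zz)
                sum_brute[v] += zz
    np.testing.assert_allclose(s, s_brute, atol=1e-10)
    nonzero = s_brute > 0
    np.testing.assert_array_equal(sign[nonzero], np.sign(sum_brute[nonzero]))
    assert (sign[~nonzero] == 0).all()


def test_voxel_signed_summary_mixed_links():
    atlas = make_toy_atlas(
        (6, 2, 1),
        [RegionSpec(1, "seed", (0, 0, 0), (2, 1, 1)), RegionSpec(2, "o", (3, 0, 0), (3, 1, 1))],
    )
    pi = enumerate_pairs(atlas, 1)
    z = np.zeros(pi.n_pairs)
    mask = np.zeros(pi.n_pairs, bool)
    # two significant links incident to brain voxel j0: Z = +3 and -2
    j0 = atlas.voxel_indices(2)[0]
    rows = np.flatnonzero(pi.pairs[:, 1] == j0)
    z[rows[0]], z[rows[1]] = 3.0, -2.0
    mask[rows[:2]] = True
    s, sign = voxel_signed_summary(z, mask, pi)
    assert s[j0] == pytest.approx(5.0)
    assert sign[j0] == 1.0


# -- cluster operations ---------------------------------------------------


def _cluster_atlas():
    # seed 27 voxels; one 27-voxel cuboid, one 15-voxel and one 25-voxel slab
    return make_toy_atlas(
        (16, 16, 4),
        [
            RegionSpec(1, "seed", (0, 0, 0), (3, 3, 3)),
            RegionSpec(2, "cuboid27", (6, 0, 0), (3, 3, 3)),
            RegionSpec(3, "slab15", (11, 0, 0), (5, 3, 1)),
            RegionSpec(4, "slab25", (0, 6, 0), (5, 5, 1)),
            RegionSpec(5, "lone", (12, 12, 3), (1, 1, 1)),
        ],
    )


def _links_to(atlas, pi, region_id):
    lb = atlas.voxel_labels[pi.pairs[:, 1]]
    return lb == region_id


def test_cluster_filter_small_components_removed():
    atlas = _cluster_atlas()
    pi = enumerate_pairs(atlas, 1)
    mask = _links_to(atlas, pi, 5)  # single isolated significant voxel
    out = cluster_filter(mask, pi, atlas, min_cluster_voxels=20)
    assert not out.any()

    mask = _links_to(atlas, pi, 2)  # 27-voxel component, kept (27 > 20)
    out = cluster_filter(mask, pi, atlas, min_cluster_voxels=20)
    np.testing.assert_array_equal(out, mask)

    mask = _links_to(atlas, pi, 3) | _links_to(atlas, pi, 4)  # 15 + 25 voxels
    out = cluster_filter(mask, pi, atlas, min_cluster_voxels=20)
    assert not out[_links_to(atlas, pi, 3)].any()
    np.testing.assert_array_equal(out[_links_to(atlas, pi, 4)],
                                  mask[_links_to(atlas, pi, 4)])


def test_cluster_filter_matches_component_oracle(rng):
    from scipy import ndimage

    atlas, pi, _, mask = _random_instance(rng)
    out = cluster_filter(mask, pi, atlas, min_cluster_voxels=3)
    # oracle: label incident voxels, keep links whose both endpoints are in
    # components of size > 3
    vol = np.zeros(atlas.labels.shape, bool)
    for (i, j), m in zip(pi.pairs, mask):
        if m:
            for v in (i, j):
                vol[tuple(atlas.voxel_coords[v])] = True
    lab, n = ndimage.label(vol, structure=np.ones((3, 3, 3)))
    sizes = np.bincount(lab.ravel())
    expected = np.zeros_like(mask)
    for k, ((i, j), m) in enumerate(zip(pi.pairs, mask)):
        if m:
            ci = lab[tuple(atlas.voxel_coords[i])]
            cj = lab[tuple(atlas.voxel_coords[j])]
            expected[k] = sizes[ci] > 3 and sizes[cj] > 3
    np.testing.assert_array_equal(out, expected)


def test_region_cluster_table_boundary_and_sums(rng):
    # 10-voxel component suppressed at min=10 ("more than 10"), 11 reported
    atlas = make_toy_atlas(
        (16, 8, 2),
        [
            RegionSpec(1, "seed", (0, 0, 0), (4, 3, 1)),  # 12 voxels, reported
            RegionSpec(2, "ten", (5, 0, 0), (5, 2, 1)),  # 10 voxels
            RegionSpec(3, "eleven", (5, 4, 0), (11, 1, 1)),  # 11 voxels
        ],
    )
    pi = enumerate_pairs(atlas, 1)
    z = rng.standard_normal(pi.n_pairs)
    mask = _links_to(atlas, pi, 2) | _links_to(atlas, pi, 3)
    res = region_cluster_table(mask, z, atlas, pi, min_cluster_voxels=10)
    assert list(res.table["regions"]) != []
    assert "ten" not in " ".join(res.table["regions"])
    row = res.table[res.table["regions"] == "eleven"].iloc[0]
    assert row["n_voxels"] == 11
    expected_sum = np.abs(z[mask & _links_to(atlas, pi, 3)]).sum()
    assert row["sum_abs_z"] == pytest.approx(expected_sum, abs=1e-10)
    # seed row present: every significant link touches the 12-voxel seed
    seed_row = res.table[res.table["regions"] == "seed"].iloc[0]
    assert seed_row["n_voxels"] == 12
    assert seed_row["sum_abs_z"] == pytest.approx(np.abs(z[mask]).sum(), abs=1e-10)
    # peak voxel is the component voxel with the largest per-voxel sum |Z|
    s, _ = voxel_signed_summary(z, mask, pi)
    vox3 = atlas.voxel_indices(3)
    peak = vox3[np.argmax(s[vox3])]
    np.testing.assert_allclose(
        [row["peak_x"], row["peak_y"], row["peak_z"]], atlas.voxel_to_world(peak)
    )


def test_empty_mask_gives_empty_table(tiny_atlas):
    pi = enumerate_pairs(tiny_atlas, 1)
    res = region_cluster_table(
        np.zeros(pi.n_pairs, bool), np.zeros(pi.n_pairs), tiny_atlas, pi
    )
    assert len(res.table) == 0 and res.row_links == []


# -- threshold modes ------------------------------------------------------


def test_threshold_mode_parse_round_trip():
    for text, kind in [
        ("fdr:0.05", "fdr"),
        ("unc:0.0001", "uncorrected"),
        ("unc-cluster:0.001:20", "uncorrected_cluster"),
    ]:
        mode = ThresholdMode.parse(text)
        assert mode.kind == kind
        assert ThresholdMode.parse(str(mode)) == mode
    with pytest.raises(ValueError):
        ThresholdMode.parse("bonferroni:0.05")
    with pytest.raises(ValueError):
        ThresholdMode("fdr", 1.5)


def test_apply_threshold_modes(rng):
    atlas, pi, z, _ = _random_instance(rng)
    p = rng.uniform(size=pi.n_pairs)
    p[:30] = 1e-6
    mask, p_star = apply_threshold(p, ThresholdMode("fdr", 0.05))
    ref_star, ref_mask = bh_fdr(p, 0.05)
    assert p_star == ref_star
    np.testing.assert_array_equal(mask, ref_mask)
    mask, p_star = apply_threshold(p, ThresholdMode("uncorrected", 1e-4))
    assert p_star is None
    np.testing.assert_array_equal(mask, p < 1e-4)
    mode = ThresholdMode("uncorrected_cluster", 1e-4, 2)
    mask_c, _ = apply_threshold(p, mode, pair_index=pi, atlas=atlas)
    np.testing.assert_array_equal(
        mask_c, cluster_filter(p < 1e-4, pi, atlas, 2)
    )
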