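"""Top-K target selection, overlap maps, peak distances, extraction,
outcome correlation."""

import numpy as np
import pandas as pd
import pytest

from cnmtarget.connectivity import TargetMap
from cnmtarget.targets import (
    TargetSet,
    adjusted_outcome_correlation,
    extract_at_coordinates,
    group_overlap_map,
    peak_distances,
    select_top_k,
    target_connectivity_strength,
)
from cnmtarget.seeds import split_hemispheres
from cnmtarget.volumes import BrainMask

from _oracles import overlap_counts_loop, pairwise_distances_loop, partial_corr_twostage


@pytest.fixture
def dlpfc_mask(small_grid):
    """A bilateral box away from the midline (left x<0, right x>0)."""
    mm = small_grid.mm_coordinates()
    vox = (np.abs(mm[..., 0]) >= 3) & (np.abs(mm[..., 0]) <= 12)
    return BrainMask(small_grid, vox, name="dlpfc")


def random_map(grid, rng):
    return TargetMap(grid, rng.uniform(-0.5, 0.5, grid.shape))


class TestSelectTopK:
    def test_exactly_k_maximal_voxels(self, small_grid, dlpfc_mask, rng):
        values = np.full(small_grid.shape, -1.0)
        left, _ = split_hemispheres(dlpfc_mask)
        chosen = left.indices()[:5]
        values[tuple(chosen.T)] = 1.0
        ts = select_top_k(TargetMap(small_grid, values), dlpfc_mask, "left", k=5)
        assert {tuple(v) for v in ts.voxel_indices} == {tuple(v) for v in chosen}

    def test_returns_exactly_k(self, small_grid, dlpfc_mask, rng):
        ts = select_top_k(random_map(small_grid, rng), dlpfc_mask, "left", k=100)
        assert ts.n_voxels == 100

    def test_ties_broken_by_linear_index(self, small_grid, dlpfc_mask):
        values = np.zeros(small_grid.shape)  # every voxel ties
        ts = select_top_k(TargetMap(small_grid, values), dlpfc_mask, "right", k=10)
        flat = np.flatnonzero(split_hemispheres(dlpfc_mask)[1].voxels.ravel())
        expected = flat[:10]  # full-sort oracle: value desc, linear index asc
        got = np.ravel_multi_index(tuple(ts.voxel_indices.T), small_grid.shape)
        assert sorted(got) == sorted(expected)

    def test_tie_selection_matches_full_sort_oracle(self, small_grid, dlpfc_mask, rng):
        values = rng.integers(0, 4, small_grid.shape).astype(float) / 10  # many ties
        tmap = TargetMap(small_grid, values)
        ts = select_top_k(tmap, dlpfc_mask, "left", k=30)
        hemi = split_hemispheres(dlpfc_mask)[0]
        flat = np.flatnonzero(hemi.voxels.ravel())
        order = sorted(flat, key=lambda i: (-values.ravel()[i], i))
        expected = set(order[:30])
        got = set(np.ravel_multi_index(tuple(ts.voxel_indices.T), small_grid.shape))
        assert got == expected

    def test_monotone_in_k(self, small_grid, dlpfc_mask, rng):
        tmap = random_map(small_grid, rng)
        small = select_top_k(tmap, dlpfc_mask, "left", k=20)
        big = select_top_k(tmap, dlpfc_mask, "left", k=60)
        small_set = {tuple(v) for v in small.voxel_indices}
        big_set = {tuple(v) for v in big.voxel_indices}
        assert small_set <= big_set

    def test_fewer_than_k_available(self, small_grid, dlpfc_mask, rng, caplog):
        tmap = random_map(small_grid, rng)
        n_left = split_hemispheres(dlpfc_mask)[0].n_voxels
        ts = select_top_k(tmap, dlpfc_mask, "left", k=n_left + 50)
        assert ts.n_voxels == n_left

    def test_all_selected_voxels_inside_hemisphere_mask(self, small_grid, dlpfc_mask, rng):
        ts = select_top_k(random_map(small_grid, rng), dlpfc_mask, "right", k=40)
        mm = ts.grid.voxel_to_mni(ts.voxel_indices.astype(float))
        assert np.all(mm[:, 0] > 0)
        assert np.all(dlpfc_mask.voxels[tuple(ts.voxel_indices.T)])


class TestConnectivityStrength:
    def _sets(self, small_grid, dlpfc_mask, tmap):
        return (select_top_k(tmap, dlpfc_mask, "left", k=20),
                select_top_k(tmap, dlpfc_mask, "right", k=20))

    def test_constant_map(self, small_grid, dlpfc_mask):
        tmap = TargetMap(small_grid, np.full(small_grid.shape, 0.42))
        left, right = self._sets(small_grid, dlpfc_mask, tmap)
        assert target_connectivity_strength(tmap, left, right) == pytest.approx(0.42)

    def test_pooled_is_mean_of_hemispheres(self, small_grid, dlpfc_mask, rng):
        tmap = random_map(small_grid, rng)
        left, right = self._sets(small_grid, dlpfc_mask, tmap)
        l, r = target_connectivity_strength(tmap, left, right, pool=False)
        pooled = target_connectivity_strength(tmap, left, right, pool=True)
        assert pooled == pytest.approx((l + r) / 2)

    def test_matches_loop_mean(self, small_grid, dlpfc_mask, rng):
        tmap = random_map(small_grid, rng)
        left, right = self._sets(small_grid, dlpfc_mask, tmap)
        manual = np.mean([tmap.values[tuple(v)] for v in left.voxel_indices])
        l, _ = target_connectivity_strength(tmap, left, right, pool=False)
        assert l == pytest.approx(manual, rel=1e-12)


class TestOverlapMap:
    def _ts(self, grid, vox_indices):
        return TargetSet(grid=grid, hemisphere="left",
                         voxel_indices=np.asarray(vox_indices), k=len(vox_indices),
                         mean_connectivity=0.0, peak_voxel=tuple(vox_indices[0]))

    def test_single_subject_values(self, small_grid):
        omap = group_overlap_map([self._ts(small_grid, [(0, 0, 0), (1, 1, 1)])])
        assert set(np.unique(omap.values)) == {0.0, 100.0}

    def test_two_disjoint_subjects(self, small_grid):
        a = self._ts(small_grid, [(0, 0, 0)])
        b = self._ts(small_grid, [(2, 2, 2)])
        omap = group_overlap_map([a, b])
        assert omap.values[0, 0, 0] == 50.0
        assert omap.values[2, 2, 2] == 50.0

    def test_matches_counting_oracle(self, small_grid, rng):
        sets = []
        for _ in range(7):
            n = rng.integers(5, 30)
            flat = rng.choice(small_grid.n_voxels, size=n, replace=False)
            sets.append(self._ts(small_grid,
                                 np.column_stack(np.unravel_index(flat, small_grid.shape))))
        omap = group_overlap_map(sets)
        counts = overlap_counts_loop([s.voxel_indices for s in sets], small_grid.shape)
        np.testing.assert_allclose(omap.values, 100.0 * counts / 7)

    def test_subject_order_invariance_and_mass(self, small_grid, rng):
        sets = []
        for _ in range(5):
            flat = rng.choice(small_grid.n_voxels, size=10, replace=False)
            sets.append(self._ts(small_grid,
                                 np.column_stack(np.unravel_index(flat, small_grid.shape))))
        a = group_overlap_map(sets)
        b = group_overlap_map(sets[::-1])
        np.testing.assert_array_equal(a.values, b.values)
        assert np.all((a.values >= 0) & (a.values <= 100))
        total = (a.values / 100).sum() * len(sets)
        assert total == pytest.approx(sum(s.n_voxels for s in sets))


class TestPeakDistances:
    def test_identical_maps_zero_distance(self, small_grid, full_mask, rng):
        tmap = random_map(small_grid, rng)
        res = peak_distances([tmap, tmap, tmap], full_mask)
        np.testing.assert_allclose(res["distances_mm"], 0)

    def test_known_peaks_known_distance(self, small_grid, full_mask):
        a = np.zeros(small_grid.shape)
        b = np.zeros(small_grid.shape)
        a[5, 6, 5] = 1.0
        b[6, 6, 5] = 1.0  # one voxel (3 mm) apart in x
        res = peak_distances([TargetMap(small_grid, a), TargetMap(small_grid, b)], full_mask)
        assert res["distances_mm"][0] == pytest.approx(3.0)

    def test_matches_pairwise_loop_oracle(self, small_grid, full_mask, rng):
        maps = [random_map(small_grid, rng) for _ in range(5)]
        res = peak_distances(maps, full_mask)
        expected = pairwise_distances_loop(res["peaks_mm"])
        np.testing.assert_allclose(np.sort(res["distances_mm"]), np.sort(expected))
        assert res["mean_mm"] == pytest.approx(expected.mean())


class TestExtractAtCoordinates:
    def test_single_map_voxel_center(self, small_grid, rng):
        tmap = random_map(small_grid, rng)
        c = small_grid.voxel_to_mni(np.array([4.0, 5.0, 6.0]))
        vals = extract_at_coordinates([tmap], [c])
        assert vals[0] == pytest.approx(tmap.values[4, 5, 6])

    def test_group_mean_of_two_maps(self, small_grid):
        a = TargetMap(small_grid, np.full(small_grid.shape, 0.1))
        b = TargetMap(small_grid, np.full(small_grid.shape, 0.3))
        c = small_grid.voxel_to_mni(np.array([1.0, 1.0, 1.0]))
        assert extract_at_coordinates([a, b], [c])[0] == pytest.approx(0.2)

    def test_off_center_uses_nearest_voxel(self, small_grid, rng):
        tmap = random_map(small_grid, rng)
        c = small_grid.voxel_to_mni(np.array([4.0, 5.0, 6.0])) + np.array([1.2, -1.1, 0.9])
        # brute-force nearest voxel by mm distance
        mm = small_grid.mm_coordinates().reshape(-1, 3)
        nearest = np.argmin(((mm - c) ** 2).sum(axis=1))
        expected = tmap.values.ravel()[nearest]
        assert extract_at_coordinates([tmap], [c])[0] == pytest.approx(expected)

    def test_out_of_bounds_coordinate_named(self, small_grid, rng):
        tmap = random_map(small_grid, rng)
        with pytest.raises(ValueError, match="999"):
            extract_at_coordinates([tmap], [(999.0, 0.0, 0.0)])


def make_records(rng, n, outcome):
    return pd.DataFrame({
        "subject": [f"s{i}" for i in range(n)],
        "outcome": outcome,
        "device": rng.choice(["A", "B"], n),
        "protocol": rng.choice(["10Hz", "20Hz"], n),
        "n_sessions": rng.integers(20, 33, n),
    })


class TestOutcomeCorrelation:
    def test_unadjusted_equals_plain_pearson(self, rng):
        from scipy import stats
        x = rng.standard_normal(20)
        y = x + rng.standard_normal(20)
        rec = make_records(rng, 20, y)
        res = adjusted_outcome_correlation(x, rec, adjust=False)
        r, p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p)
        assert res.partial_r is None

    def test_covariate_identical_to_strengths_errors(self, rng):
        x = np.linspace(0, 1, 12)
        rec = make_records(rng, 12, rng.standard_normal(12))
        rec["n_sessions"] = x  # covariate == strengths
        rec["device"] = "A"
        rec["protocol"] = "10Hz"
        with pytest.raises(ValueError, match="partial correlation undefined"):
            adjusted_outcome_correlation(x, rec, adjust=True)

    def test_matches_twostage_ols_oracle(self, rng):
        n = 30
        x = rng.standard_normal(n)
        rec = make_records(rng, n, 2 * x + rng.standard_normal(n))
        res = adjusted_outcome_correlation(x, rec, adjust=True)
        C = np.column_stack([
            (rec["device"] == "B").astype(float),
            (rec["protocol"] == "20Hz").astype(float),
            rec["n_sessions"].astype(float),
        ])
        expected = partial_corr_twostage(x, rec["outcome"].to_numpy(), C)
        assert res.partial_r == pytest.approx(expected, rel=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        x = rng.standard_normal(n)
        rec = make_records(rng, n, x + rng.standard_normal(n))
        res = adjusted_outcome_correlation(x, rec, adjust=True)
        df = pd.DataFrame({
            "x": x, "y": rec["outcome"],
            "dev": (rec["device"] == "B").astype(float),
            "prot": (rec["protocol"] == "20Hz").astype(float),
            "ses": rec["n_sessions"].astype(float),
        })
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["dev", "prot", "ses"])
        assert res.partial_r == pytest.approx(float(ref["r"].iloc[0]), rel=1e-9)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.partial_p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_constant_variable_rejected(self, rng):
        rec = make_records(rng, 10, rng.standard_normal(10))
        with pytest.raises(ValueError, match="constant"):
            adjusted_outcome_correlation(np.ones(10), rec)

    def test_recovers_positive_relation_as_noise_vanishes(self, rng):
        n = 40
        truth = rng.uniform(0, 0.5, n)
        rs = []
        for noise in (1.0, 0.1, 0.0):
            rec = make_records(rng, n, 10 * truth + noise * rng.standard_normal(n))
            res = adjusted_outcome_correlation(truth, rec, adjust=False)
            rs.append(res.r)
        assert rs[0] < rs[2]
        assert rs[2] == pytest.approx(1.0, abs=1e-12)
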