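"""KMD projection, window filtering, series chaining, collapsing, clouds."""

import math

import numpy as np
import pandas as pd
import pytest

import kmdmsi as K
from kmdmsi import kmd as kmdmod
from kmdmsi.kmd import (
    ADDUCT_ISOTOPE_SHIFTS,
    KMDWindow,
    chain_ch2_series,
    chain_vertical,
    collapse_adducts_isotopes,
    filter_window,
    flag_matrix_points,
    kmd_points_from_mz,
    select_cloud,
)

# printed experimental m/z of every identified ion in the published tables
TABLE_MZ = K.load_reference_tables()
TABLE_MZ = TABLE_MZ.loc[TABLE_MZ["best_match"] != "?", "mz_exp"].unique()


def points_from(mzs, intensities=None):
    return kmd_points_from_mz(mzs, intensities)


class TestKmdPoints:
    def test_base_unit_has_zero_defect(self):
        pts = points_from([14.01565])
        assert pts.kmd[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_equals_bin_count(self, default_run):
        res = default_run["result"]
        assert len(res.points) == res.matrix.n_bins

    def test_points_consistent_with_mass_core(self, default_run):
        res = default_run["result"]
        for _, row in res.points.head(20).iterrows():
            assert row["km"] == pytest.approx(K.kendrick_mass(row["mz"]), abs=1e-9)
            assert row["kmd"] == pytest.approx(K.kmd_of_mz(row["mz"]), abs=1e-9)

    def test_published_ions_have_lipid_like_defects(self):
        pts = points_from(TABLE_MZ)
        assert ((pts.kmd >= 0.10) & (pts.kmd <= 0.50)).all()


class TestFilterWindow:
    def test_bounds(self):
        pts = points_from([150.0, 400.0, 851.7103])
        pts.loc[1, "kmd"] = 0.05  # force below the KMD floor
        kept = filter_window(pts)
        assert list(kept["mz"]) == [851.7103]

    def test_idempotent(self, default_run):
        filt = filter_window(default_run["result"].points)
        again = filter_window(filt)
        pd.testing.assert_frame_equal(filt, again)

    def test_all_published_ions_survive_default_window(self):
        pts = points_from(TABLE_MZ)
        assert len(filter_window(pts)) == len(pts)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            KMDWindow(kmd_min=0.5, kmd_max=0.1)


from tests_support_oracle import brute_force_components


class TestCh2Chaining:
    def test_published_tg_series_chains_as_one(self):
        # TG 50:3 / 52:3 / 54:3 sodium adducts
        pts = points_from([851.7099, 879.7412, 907.7725])
        groups, singles = chain_ch2_series(pts)
        assert len(groups) == 1 and not singles
        assert groups[0].members == [0, 1, 2]
        assert groups[0].canonical == 0

    def test_isolated_ion_stays_singleton(self):
        pts = points_from([400.0, 851.7099])
        groups, singles = chain_ch2_series(pts)
        assert groups == [] and set(singles) == {0, 1}

    def test_inexact_step_not_chained(self):
        pts = points_from([700.0, 714.0300])  # ~1000 ppm off one CH2
        groups, _ = chain_ch2_series(pts)
        assert groups == []

    def test_matches_brute_force_on_random_subsets(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            base = rng.uniform(300, 900, size=12)
            series = np.concatenate(
                [b + 14.01565 * np.arange(rng.integers(2, 5)) for b in base[:4]]
            )
            mzs = np.sort(np.concatenate([base[4:], series]))[:50]
            mzs = mzs * (1 + rng.normal(0, 3e-7, size=mzs.size))
            pts = points_from(mzs)
            groups, singles = chain_ch2_series(pts, ppm_tolerance=2.0, k_max=6)
            ours = {frozenset(g.members) for g in groups} | {
                frozenset([s]) for s in singles
            }
            oracle = brute_force_components(list(mzs), 14.01565, 2.0, 6)
            assert ours == oracle

    def test_permutation_invariance(self):
        mzs = [851.7099, 879.7412, 907.7725, 723.4935, 737.5092]
        a, _ = chain_ch2_series(points_from(mzs))
        b, _ = chain_ch2_series(points_from(mzs[::-1]))
        sets_a = {frozenset(tuple(np.sort([mzs[m] for m in g.members]))) for g in a}
        sets_b = {frozenset(tuple(np.sort([mzs[::-1][m] for m in g.members]))) for g in b}
        assert sets_a == sets_b


class TestVerticalChaining:
    def test_unsaturation_ladder_groups_as_one(self):
        # sodiated TG 50:1 / 50:2 / 50:3: exact H2 steps
        top = K.ion_mz("C53H100O6", "[M+Na]+")
        pts = points_from([top, top - 2.01565, top - 2 * 2.01565])
        groups, _ = chain_vertical(pts, "H2")
        assert len(groups) == 1 and len(groups[0].members) == 3
        assert groups[0].orientation == "vertical-H2"

    def test_inexact_h2_step_not_grouped(self):
        pts = points_from([700.0, 702.0300])
        groups, _ = chain_vertical(pts, "H2")
        assert groups == []

    def test_oxygen_step_grouping(self):
        pts = points_from([700.0, 700.0 + 15.99491462])
        groups, _ = chain_vertical(pts, "O")
        assert len(groups) == 1

    def test_empty_input_empty_output(self):
        groups, singles = chain_vertical(points_from([]), "H2")
        assert groups == [] and singles == []

    def test_unknown_step_formula_rejected(self):
        with pytest.raises(ValueError):
            chain_vertical(points_from([700.0]), "CO2")

    def test_span_limit_restricts_ladder(self):
        mzs = [700.0 + k * 2.01565 for k in range(8)]
        groups, _ = chain_vertical(points_from(mzs), "H2", span_steps=3)
        for g in groups:
            lo = min(700.0 + 2.01565 * m for m in g.members)
            hi = max(700.0 + 2.01565 * m for m in g.members)
            assert hi - lo <= 3 * 2.01565 + 1e-6


class TestCollapse:
    def test_published_adduct_triplet_collapses_to_protonated(self):
        # PC 34:1 (or PE 37:1) as H / Na / K adducts
        pts = points_from([760.5851, 782.5670, 798.5410], [3.0, 2.0, 1.0])
        out = collapse_adducts_isotopes(pts)
        assert out["canonical"].nunique() == 1
        assert out["canonical_mz"].iloc[0] == pytest.approx(760.5851)
        assert out["collapsed_intensity"].iloc[0] == pytest.approx(6.0)

    def test_isotopologue_pair_collapses(self):
        pts = points_from([739.4675, 740.4709])
        out = collapse_adducts_isotopes(pts)
        assert out["canonical"].nunique() == 1

    def test_lone_protonated_ion_maps_to_itself(self):
        pts = points_from([760.5851])
        out = collapse_adducts_isotopes(pts)
        assert out["canonical"].iloc[0] == pts.index[0]

    def test_shift_masses_derive_from_atomic_constants(self):
        assert ADDUCT_ISOTOPE_SHIFTS["Na-H"] == pytest.approx(
            22.98976928 - 1.00782503, abs=1e-9
        )
        assert ADDUCT_ISOTOPE_SHIFTS["K-H"] == pytest.approx(37.95588146, abs=1e-7)
        assert ADDUCT_ISOTOPE_SHIFTS["13C"] == pytest.approx(1.00335484, abs=1e-8)

    def test_collapse_conserves_total_intensity(self):
        rng = np.random.default_rng(5)
        mzs = np.sort(rng.uniform(400, 900, 30))
        pts = points_from(mzs, rng.uniform(1e5, 1e9, 30))
        out = collapse_adducts_isotopes(pts)
        per_group = out.drop_duplicates("canonical")["collapsed_intensity"].sum()
        assert per_group == pytest.approx(pts["intensity"].sum(), rel=1e-12)


class TestCloudsAndFlags:
    def test_rectangle_covering_everything_selects_all(self):
        pts = points_from(TABLE_MZ)
        cloud = select_cloud(pts, (0.0, 2000.0, 0.0, 1.0))
        assert len(cloud.members) == len(pts)

    def test_empty_rectangle_selects_none(self):
        pts = points_from(TABLE_MZ)
        assert select_cloud(pts, (100.0, 150.0, 0.0, 0.05)).members == []

    def test_degenerate_geometry_rejected(self):
        pts = points_from([500.0])
        with pytest.raises(ValueError):
            select_cloud(pts, (500.0, 500.0, 0.1, 0.1))
        with pytest.raises(ValueError):
            select_cloud(pts, [(500.0, 0.1), (500.0, 0.1), (500.0, 0.1)])

    def test_rectangle_membership_matches_direct_kmd_arithmetic(self):
        # Cloud-1-like box over the published high-mass m/z values
        mzs = sorted(TABLE_MZ)
        pts = points_from(mzs)
        cloud = select_cloud(pts, (840.0, 910.0, 0.23, 0.25))
        expected = []
        for i, mz in enumerate(mzs):
            km = mz * 14.00000 / 14.01565
            kmd = math.ceil(km) - km
            if 840.0 <= mz <= 910.0 and 0.23 <= kmd <= 0.25:
                expected.append(i)
        assert cloud.members == expected
        assert expected  # the box is not trivially empty

    def test_polygon_selection_is_boundary_inclusive(self):
        pts = points_from([500.0])
        kmd = pts.kmd[0]
        tri = [(499.0, kmd - 0.01), (501.0, kmd - 0.01), (500.0, kmd)]  # apex on point
        assert select_cloud(pts, tri).members == [0]

    def test_matrix_flags(self):
        ions = K.matrix_ion_set()
        pts = points_from(list(ions) + [760.5851])
        flags = flag_matrix_points(pts, ions, 3.0)
        assert flags.sum() == len(ions)
        assert not flags.iloc[-1]
        assert flag_matrix_points(pts, [], 3.0).sum() == 0
        exact = flag_matrix_points(pts, [760.5851], 0.0)
        assert exact.sum() == 1 and exact.iloc[-1]
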