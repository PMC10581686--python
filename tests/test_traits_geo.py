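"""Geography statistics, IUCN regrouping and design construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biointerest as bi
from biointerest.traits_geo import (DOMAIN_LEVELS, IUCN_GROUPS, IUCN_LEVELS,
                                    RegionLookup, assign_region,
                                    dispersion_range, prepare_design,
                                    range_centroid, regroup_iucn)

EARTH_HALF_CIRCUMFERENCE = np.pi * 6371.0  # 20015.086... km


class TestDispersionRange:
    def test_single_point_is_zero(self):
        assert dispersion_range([(10.0, 45.0)]) == 0.0

    def test_antipodal_equatorial_pair(self):
        # mean pairwise distance of two antipodal points = half circumference
        d = dispersion_range([(0.0, 0.0), (180.0, 0.0)])
        assert d == pytest.approx(EARTH_HALF_CIRCUMFERENCE, rel=5e-5)
        assert round(d, 3) == pytest.approx(20015.087, abs=0.5)

    def test_three_equatorial_points(self):
        # hand haversine: (111.195 + 222.390 + 111.195) / 3 = 148.26 km
        d = dispersion_range([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        assert d == pytest.approx(148.26, rel=5e-4)

    @given(st.lists(st.tuples(st.floats(-180, 180), st.floats(-80, 80)),
                    min_size=2, max_size=8),
           st.floats(-180, 180))
    @settings(max_examples=60, deadline=None)
    def test_permutation_and_rotation_invariance(self, pts, rot):
        base = dispersion_range(pts)
        perm = dispersion_range(list(reversed(pts)))
        rotated = [(((lon + rot + 180) % 360) - 180, lat) for lon, lat in pts]
        assert perm == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert dispersion_range(rotated) == pytest.approx(base, rel=1e-6, abs=1e-6)

    def test_duplicates_kept_by_default(self):
        pts = [(0.0, 0.0), (3.0, 0.0)]
        doubled = pts + pts
        # duplicating every point leaves the pair-mean unchanged only under
        # the documented keep-duplicates convention (0-distance self pairs
        # enter the average)
        d1 = dispersion_range(pts)
        d2 = dispersion_range(doubled)
        assert d2 < d1  # self-pairs pull the mean down: duplicates were kept
        assert dispersion_range(doubled, dedupe=True) == pytest.approx(d1)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            dispersion_range([(0.0, 95.0), (1.0, 0.0)])

    def test_subsampled_mode_close_to_exact(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(-20, 20, 800), rng.uniform(-20, 20, 800)])
        exact = dispersion_range(pts)
        import biointerest.traits_geo as tg
        old = tg.EXACT_PAIRWISE_LIMIT
        tg.EXACT_PAIRWISE_LIMIT = 100
        try:
            approx = dispersion_range(pts, seed=0)
        finally:
            tg.EXACT_PAIRWISE_LIMIT = old
        assert approx == pytest.approx(exact, rel=0.01)


class TestRangeCentroid:
    def test_single_point(self):
        assert range_centroid([(12.0, 34.0)]) == pytest.approx((12.0, 34.0))

    def test_latitude_symmetry(self):
        lon, lat = range_centroid([(0.0, 10.0), (0.0, -10.0)])
        assert (lon, lat) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_antimeridian_safe(self):
        lon, lat = range_centroid([(-179.5, 0.0), (179.5, 0.0)])
        assert abs(lon) == pytest.approx(180.0, abs=1e-9)
        assert lat == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_pair_degenerate(self):
        with pytest.raises(ValueError, match="degenerate centroid"):
            range_centroid([(0.0, 0.0), (180.0, 0.0)])


class TestAssignRegion:
    @pytest.fixture()
    def lookup(self):
        grid = pd.DataFrame({
            "lon": [10.0, 20.0, 10.0, 20.0],
            "lat": [40.0, 40.0, 50.0, 50.0],
            "region": ["Palaearctic", "Palaearctic", "Nearctic", "Nearctic"],
        })
        return RegionLookup(grid)

    def test_cell_lookup(self, lookup):
        assert assign_region((11.0, 41.0), lookup) == "Palaearctic"
        assert assign_region((19.0, 51.0), lookup) == "Nearctic"

    def test_outside_coverage_is_unknown_with_warning(self, lookup):
        with pytest.warns(UserWarning, match="outside region lookup"):
            assert assign_region((-120.0, -40.0), lookup) == "Unknown"

    def test_deterministic(self, lookup):
        a = assign_region((14.9, 44.9), lookup)
        assert all(assign_region((14.9, 44.9), lookup) == a for _ in range(5))


class TestRegroupIucn:
    @pytest.mark.parametrize("code, group", sorted(IUCN_GROUPS.items()))
    def test_nine_code_mapping(self, code, group):
        assert regroup_iucn(code) == group

    def test_total_and_surjective(self):
        groups = {regroup_iucn(c) for c in IUCN_GROUPS}
        assert groups == {"Threatened", "NonThreatened", "Unknown"}

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="XX"):
            regroup_iucn("XX")


class TestPrepareDesign:
    def test_continuous_columns_standardized(self, profiles_small):
        prof, _ = profiles_small
        design, _ = prepare_design(prof, "eq1")
        for col in ("size", "range", "uniqueness", "phylo_dist"):
            assert design[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert design[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_baseline_species_all_dummies_zero(self, profiles_small):
        prof, _ = profiles_small
        design, _ = prepare_design(prof, "eq1")
        base = (prof["habitat_domain"] == DOMAIN_LEVELS[0]) & \
               (prof["iucn_group"] == IUCN_LEVELS[0])
        assert base.any()
        dummies = [c for c in design.columns
                   if c.startswith("domain_") or c.startswith("iucn_")]
        assert (design.loc[base, dummies].to_numpy() == 0).all()

    def test_transform_round_trip(self, profiles_small):
        prof, _ = profiles_small
        design, transform = prepare_design(prof, "eq1")
        again = transform.apply(prof)
        pd.testing.assert_frame_equal(again, design)

    def test_eq2_swaps_uniqueness_and_drops_divergence(self, profiles_small):
        prof, _ = profiles_small
        d1, _ = prepare_design(prof, "eq1")
        d2, _ = prepare_design(prof, "eq2")
        assert "phylo_dist" in d1.columns and "phylo_dist" not in d2.columns
        # eq2 uniqueness is genus-based, eq1 family-based
        assert not np.allclose(d1["uniqueness"], d2["uniqueness"])

    def test_zero_variance_column_rejected(self, profiles_small):
        prof, _ = profiles_small
        bad = prof.copy()
        bad["size_mm"] = 10.0
        with pytest.raises(ValueError, match="zero-variance"):
            prepare_design(bad, "eq1")

    def test_unknown_factor_level_rejected(self, profiles_small):
        prof, _ = profiles_small
        bad = prof.copy()
        bad.loc[bad.index[0], "habitat_domain"] = "lunar"
        with pytest.raises(ValueError, match="lunar"):
            prepare_design(bad, "eq1")
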