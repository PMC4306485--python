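"""En-face projection, useful mask, candidate detection, ducts, counting."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from octgland import (
    AnalysisParams,
    ConfigurationError,
    GlandCandidate,
    GlandSpec,
    PhantomConfig,
    ScanGeometry,
    SurfaceMap,
    UsefulSurfaceMask,
    count_glands,
    detect_duct,
    detect_gland_candidates,
    extract_cscan,
    flatten_volume,
    make_useful_mask,
    segment_surface,
    simulate_volume,
)
from octgland.preprocess import FlattenedVolume


def _flat_from_array(arr, geometry):
    surface = SurfaceMap(
        depth_index=np.zeros(arr.shape[:2], dtype=np.int32),
        valid=np.ones(arr.shape[:2], dtype=bool),
    )
    return FlattenedVolume(
        intensity=arr, spacing_um=geometry.spacing_um, geometry=geometry, surface=surface
    )


@pytest.fixture(scope="module")
def params():
    return AnalysisParams()


class TestExtractCscan:
    def test_constant_volume_gives_constant_cscan(self, small_geometry, params):
        arr = np.full(
            (small_geometry.n_slow, small_geometry.n_fast, small_geometry.n_depth),
            2.5,
            dtype=np.float32,
        )
        cs = extract_cscan(_flat_from_array(arr, small_geometry), params)
        np.testing.assert_allclose(cs.values, 2.5)

    def test_slab_beyond_depth_range_rejected(self, small_geometry, params):
        arr = np.zeros(
            (small_geometry.n_slow, small_geometry.n_fast, small_geometry.n_depth),
            dtype=np.float32,
        )
        deep = replace(params, cscan_depth_um=10 * small_geometry.depth_range_mm * 1e3)
        with pytest.raises(ValueError, match="slab"):
            extract_cscan(_flat_from_array(arr, small_geometry), deep)

    def test_gland_footprint_darker_by_contrast(self, clean_config, params):
        spec = GlandSpec((0.865, 0.865), 750.0, (600.0, 600.0, 400.0), has_duct=False)
        cfg = replace(clean_config, gland_specs=(spec,))
        vol, _ = simulate_volume(cfg)
        flat = flatten_volume(vol, segment_surface(vol))
        cs = extract_cscan(flat, params)
        g = cfg.geometry
        x = (np.arange(g.n_fast) + 0.5) * g.fov_lateral_cm / g.n_fast
        y = (np.arange(g.n_slow) + 0.5) * g.fov_lateral_cm / g.n_slow
        inside = ((x[None, :] - 0.865) * 1e4 / 600) ** 2 + (
            (y[:, None] - 0.865) * 1e4 / 600
        ) ** 2 <= 0.25
        far = ((x[None, :] - 0.865) ** 2 + (y[:, None] - 0.865) ** 2) > 0.09
        ratio = cs.values[inside].mean() / cs.values[far].mean()
        assert ratio < cfg.gland_contrast + 0.05


class TestUsefulMask:
    def test_full_field_area_saturates_mask(self, small_geometry, params):
        full = replace(params, useful_area_cm2=small_geometry.field_area_cm2)
        mask = make_useful_mask(small_geometry, full)
        assert mask.mask.all()

    @pytest.mark.parametrize("n", [100, 150, 256, 400])
    def test_default_area_within_one_pixel(self, n, params):
        g = ScanGeometry(n_fast=n, n_slow=n, n_depth=64)
        mask = make_useful_mask(g, params)
        achieved = mask.mask.sum() * g.pixel_area_cm2
        assert abs(achieved - 2.43) <= g.pixel_area_cm2

    def test_oversized_area_rejected(self, small_geometry, params):
        with pytest.raises(ConfigurationError):
            make_useful_mask(small_geometry, replace(params, useful_area_cm2=10.0))


class TestDetectCandidates:
    def test_ten_well_separated_glands_found_exactly(self, clean_config, params):
        g = clean_config.geometry
        centres = [
            (0.865 + ox, 0.865 + oy)
            for ox in (-0.45, 0.0, 0.45)
            for oy in (-0.45, 0.0, 0.45)
        ] + [(0.645, 0.645)]
        specs = tuple(
            GlandSpec(c, 750.0, (450.0, 450.0, 350.0), has_duct=True) for c in centres
        )
        vol, truth = simulate_volume(replace(clean_config, gland_specs=specs))
        flat = flatten_volume(vol, segment_surface(vol))
        cands = detect_gland_candidates(
            extract_cscan(flat, params), make_useful_mask(g, params), params
        )
        assert len(cands) == 10
        got = np.array([c.centroid_cm for c in cands])
        want = np.array(centres)
        for w in want:
            d = np.sqrt(((got - w) ** 2).sum(axis=1))
            assert d.min() * 1e4 <= max(g.dx_um, g.dy_um)  # within one lateral voxel

    def test_gland_outside_mask_not_reported(self, clean_config, params):
        spec = GlandSpec((0.10, 0.10), 750.0, (450.0, 450.0, 350.0), has_duct=True)
        vol, truth = simulate_volume(replace(clean_config, gland_specs=(spec,)))
        assert not truth.glands["visible"].iloc[0]
        flat = flatten_volume(vol, segment_surface(vol))
        cands = detect_gland_candidates(
            extract_cscan(flat, params),
            make_useful_mask(clean_config.geometry, params),
            params,
        )
        assert cands == []

    def test_uniform_cscan_gives_no_candidates(self, small_geometry, params):
        arr = np.full(
            (small_geometry.n_slow, small_geometry.n_fast, small_geometry.n_depth),
            1.0,
            dtype=np.float32,
        )
        cs = extract_cscan(_flat_from_array(arr, small_geometry), params)
        mask = make_useful_mask(small_geometry, params)
        assert detect_gland_candidates(cs, mask, params) == []

    def test_empty_mask_rejected(self, small_geometry, params):
        arr = np.ones(
            (small_geometry.n_slow, small_geometry.n_fast, small_geometry.n_depth),
            dtype=np.float32,
        )
        cs = extract_cscan(_flat_from_array(arr, small_geometry), params)
        empty = UsefulSurfaceMask(
            mask=np.zeros((small_geometry.n_slow, small_geometry.n_fast), dtype=bool),
            area_cm2=0.0,
            pixel_area_cm2=small_geometry.pixel_area_cm2,
        )
        with pytest.raises(ValueError, match="mask"):
            detect_gland_candidates(cs, empty, params)

    def test_border_gland_flagged_on_border(self, clean_config, params):
        from octgland.geometry import solve_useful_mask

        g = clean_config.geometry
        mask, _ = solve_useful_mask(g, params.useful_area_cm2)
        diag = int(np.flatnonzero(np.diagonal(mask))[-1])
        x_edge = (diag + 0.5) * g.fov_lateral_cm / g.n_fast
        y_edge = (diag + 0.5) * g.fov_lateral_cm / g.n_slow
        spec = GlandSpec((x_edge, y_edge), 750.0, (500.0, 500.0, 350.0), has_duct=False)
        vol, _ = simulate_volume(replace(clean_config, gland_specs=(spec,)))
        flat = flatten_volume(vol, segment_surface(vol))
        cands = detect_gland_candidates(
            extract_cscan(flat, params), make_useful_mask(g, params), params
        )
        assert len(cands) == 1
        assert cands[0].on_border


@pytest.fixture(scope="module")
def flat_and_candidates(clean_config, three_gland_specs, params):
    vol, truth = simulate_volume(
        replace(clean_config, gland_specs=three_gland_specs, seed=3)
    )
    flat = flatten_volume(vol, segment_surface(vol))
    cands = detect_gland_candidates(
        extract_cscan(flat, params),
        make_useful_mask(clean_config.geometry, params),
        params,
    )
    return flat, cands, truth


class TestDetectDuct:
    def test_duct_flags_match_generator_truth(self, flat_and_candidates, params):
        flat, cands, truth = flat_and_candidates
        assert len(cands) == 3
        for c in cands:
            d = np.sqrt(
                (truth.glands["x_cm"] - c.centroid_cm[0]) ** 2
                + (truth.glands["y_cm"] - c.centroid_cm[1]) ** 2
            )
            want = bool(truth.glands["has_duct"].iloc[int(d.idxmin())])
            assert detect_duct(flat, c, params) == want

    def test_centroid_outside_volume_rejected(self, flat_and_candidates, params):
        flat, cands, _ = flat_and_candidates
        bad = GlandCandidate(
            id=99,
            centroid_px=(-1.0, -1.0),
            centroid_cm=(-0.01, -0.01),
            area_mm2=1.0,
            mean_intensity=0.1,
            on_border=False,
        )
        with pytest.raises(ValueError, match="outside"):
            detect_duct(flat, bad, params)


class TestCountingRule:
    @staticmethod
    def _cand(i, duct, border):
        return GlandCandidate(
            id=i,
            centroid_px=(10.0, 10.0),
            centroid_cm=(0.2, 0.2),
            area_mm2=1.0,
            mean_intensity=0.1,
            on_border=border,
            has_duct=duct,
        )

    def test_interior_duct_matched_all_counted(self):
        cands = [self._cand(i, True, False) for i in range(3)]
        assert count_glands(cands) == 3

    def test_interior_without_duct_excluded(self):
        cands = [self._cand(0, True, False), self._cand(1, True, False),
                 self._cand(2, False, False)]
        assert count_glands(cands) == 2
        assert [c.accepted for c in cands] == [True, True, False]

    def test_border_exception_waives_duct(self):
        assert count_glands([self._cand(0, False, True)]) == 1

    def test_unset_flags_rejected(self):
        c = self._cand(0, True, False)
        c.has_duct = None
        with pytest.raises(ValueError, match="flags"):
            count_glands([c])

    @settings(max_examples=100, deadline=None)
    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=8
        )
    )
    def test_counting_rule_equals_set_builder_oracle(self, flags):
        cands = [self._cand(i, d, b) for i, (d, b) in enumerate(flags)]
        assert count_glands(cands) == sum(1 for d, b in flags if d or b)
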