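import numpy as np
import pytest

from hemosys import FrameStack, filter_stack, preprocess_stack
from hemosys.errors import StateError
from hemosys.propagation import (
    ACUTE,
    CHRONIC,
    NORMOXIC,
    extract_wavefronts,
    hypoxic_mask,
    mean_speed,
    ray_speed_profile,
    zone_scatter,
)


def _disc_stack(radii, shape=(120, 120), center=(60, 60), inside=20.0, outside=60.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dist = np.hypot(rr - center[0], cc - center[1])
    frames = np.where(dist[None] <= np.asarray(radii)[:, None, None], inside, outside)
    return FrameStack("HBSAT", frames, np.arange(len(radii), dtype=float))


class TestHypoxicMask:
    def test_above_threshold_everywhere_is_empty(self):
        assert not hypoxic_mask(np.full((5, 5), 50.0), 30.0).any()

    def test_below_threshold_everywhere_is_full(self):
        assert hypoxic_mask(np.full((5, 5), 10.0), 30.0).all()

    def test_half_plane_split(self):
        frame = np.where(np.arange(10)[None, :] < 5, 20.0, 40.0) * np.ones((6, 10))
        mask = hypoxic_mask(frame, 30.0)
        assert mask[:, :5].all() and not mask[:, 5:].any()

    def test_nan_pixels_excluded(self):
        frame = np.full((3, 3), 10.0)
        frame[1, 1] = np.nan
        mask = hypoxic_mask(frame, 30.0)
        assert not mask[1, 1] and mask.sum() == 8


class TestExtractWavefronts:
    def test_growing_disc_contour_tracks_radius(self):
        radii = [10 + 3 * t for t in range(10)]
        wf = extract_wavefronts(_disc_stack(radii), (60, 60), 30.0)
        assert wf.n_present == 10
        for t, contour in enumerate(wf.contours):
            extent = np.hypot(contour[:, 0] - 60, contour[:, 1] - 60).max()
            assert extent == pytest.approx(radii[t], abs=1.0)

    def test_area_nondecreasing_for_growing_front(self):
        radii = [5 + 2 * t for t in range(12)]
        wf = extract_wavefronts(_disc_stack(radii), (60, 60), 30.0)
        area = wf.area_px()
        assert (np.diff(area) >= 0).all()

    def test_absent_when_nothing_below_threshold(self):
        stack = _disc_stack([0, 5, 8], inside=20.0)  # radius 0: nothing hypoxic
        stack.frames[0] = 60.0
        wf = extract_wavefronts(stack, (60, 60), 30.0)
        assert wf.contours[0] is None and wf.contours[1] is not None

    def test_only_component_containing_origin_selected(self):
        frames = np.full((2, 60, 100), 60.0)
        frames[:, 10:20, 10:20] = 20.0  # blob 1, holds the origin
        frames[:, 40:50, 70:90] = 20.0  # blob 2, disjoint
        wf = extract_wavefronts(FrameStack("HBSAT", frames, [0.0, 1.0]), (15, 15), 30.0)
        assert all((c[:, 1] < 30).all() for c in wf.contours)

    def test_origin_outside_fov_rejected(self):
        with pytest.raises(ValueError):
            extract_wavefronts(_disc_stack([5, 6]), (500, 500), 30.0)


class TestRaySpeedProfile:
    def test_planar_front_speed(self):
        # front advances along +col at 3 px/min; 5 um px -> 15 um/min
        edges = [10 + 3 * t for t in range(12)]
        frames = np.stack(
            [np.where(np.arange(100)[None, :] < e, 20.0, 60.0) * np.ones((40, 100)) for e in edges]
        )
        stack = FrameStack("HBSAT", frames, np.arange(12, dtype=float), pixel_size_um=5.0)
        wf = extract_wavefronts(stack, (20, 2), 30.0)
        prof = ray_speed_profile(wf, (20, 90), direction_label="east")
        assert mean_speed(prof) == pytest.approx(15.0, abs=5.0)
        perp = ray_speed_profile(wf, (35, 2), direction_label="south")
        assert abs(mean_speed(perp)) <= 5.0  # no front motion along the rows

    def test_static_mask_zero_speed(self):
        wf = extract_wavefronts(_disc_stack([15] * 6), (60, 60), 30.0)
        prof = ray_speed_profile(wf, (60, 110))
        np.testing.assert_allclose(prof.speed_um_per_min, 0.0)

    def test_anchor_equal_origin_rejected(self):
        wf = extract_wavefronts(_disc_stack([10, 12]), (60, 60), 30.0)
        with pytest.raises(ValueError):
            ray_speed_profile(wf, (60, 60))


@pytest.fixture(scope="module")
def zones(short_wavefront_scene):
    trial, manifest = short_wavefront_scene
    wf = extract_wavefronts(
        filter_stack(trial.stacks["HBSAT"]), tuple(manifest["origin"]), 30.0
    )
    bf = preprocess_stack(trial.stacks["BF"])
    bv = preprocess_stack(trial.stacks["BV"])
    return zone_scatter(wf, bf, bv), manifest, bf


class TestZoneScatter:

    def test_partition_covers_every_cell_once(self, zones):
        table, _, bf = zones
        n_cells = (~bf.missing_mask).sum()
        assert len(table) == n_cells
        assert set(table["zone"]) <= {ACUTE, NORMOXIC, CHRONIC}
        assert not table.duplicated(subset=["row", "col"]).any()

    def test_acute_cells_show_planted_drops(self, zones):
        table, manifest, _ = zones
        acute = table[table["zone"] == ACUTE]
        assert len(acute) > 0
        assert acute["neg_delta_bf"].mean() == pytest.approx(
            manifest["neg_delta_bf"], rel=0.15
        )
        assert acute["neg_delta_bv"].mean() == pytest.approx(
            manifest["neg_delta_bv"], rel=0.15
        )

    def test_normoxic_cells_clear_of_the_front_show_no_drop(self, zones):
        # cells whose whole 50 px block lies beyond the final contour;
        # straddling cells legitimately average in part of the drop
        table, manifest, bf = zones
        origin = np.asarray(manifest["origin"], dtype=float)
        clear_radius = manifest["final_radius_px"] + bf.block_px / np.sqrt(2) + 1
        centers = np.array(
            [bf.cell_center_px(r, c) for r, c in zip(table["row"], table["col"])],
            dtype=float,
        )
        far = np.hypot(*(centers - origin).T) > clear_radius
        norm = table[(table["zone"] == NORMOXIC).to_numpy() & far]
        assert len(norm) > 0
        assert abs(norm["neg_delta_bf"].mean()) < 0.05 * manifest["neg_delta_bf"]
        assert abs(norm["neg_delta_bv"].mean()) < 0.05 * manifest["neg_delta_bv"]

    def test_missing_first_contour_raises(self):
        stack = _disc_stack([0, 5, 8])
        stack.frames[0] = 60.0
        wf = extract_wavefronts(stack, (60, 60), 30.0)
        grid = preprocess_stack(
            FrameStack("BV", np.ones((7, 100, 100)), np.arange(7.0)), kernel_min=3.0
        )
        with pytest.raises(StateError):
            zone_scatter(wf, grid, grid)
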