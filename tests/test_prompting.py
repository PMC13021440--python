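import numpy as np
import pytest

from perfmap.centerline import extract_centerlines
from perfmap.prompting import (
    OracleBackend,
    PromptParams,
    PromptSet,
    SlicePrompt,
    ThresholdRegionGrowBackend,
    build_prompts,
    generate_negative_points,
    refine_positive_point,
    run_prompted_segmentation,
)
from perfmap.volume_io import Mask, VoxelPoint

from conftest import make_mask, make_volume


class TestRefinePositivePoint:
    def test_uniform_ball_returns_original_point(self):
        v = make_volume(np.full((11, 11, 11), 7.0))
        p = VoxelPoint(5, 5, 5)
        assert refine_positive_point(v, p, 5) == p

    def test_finds_planted_maximum_at_ball_boundary(self):
        arr = np.zeros((11, 11, 11))
        arr[5, 8, 9] = 10.0  # offset (0, 3, 4), distance exactly 5
        v = make_volume(arr)
        assert refine_positive_point(v, VoxelPoint(5, 5, 5), 5) == VoxelPoint(5, 8, 9)

    def test_maximum_outside_ball_ignored(self):
        arr = np.zeros((3, 3, 13))
        arr[1, 1, 12] = 10.0  # offset (0, 0, 6): outside radius 5
        arr[1, 1, 8] = 5.0    # offset (0, 0, 2): best inside
        v = make_volume(arr)
        assert refine_positive_point(v, VoxelPoint(1, 1, 6), 5) == VoxelPoint(1, 1, 8)

    def test_radius_zero_is_identity(self):
        arr = np.zeros((3, 3, 3))
        arr[0, 0, 0] = 5.0
        assert refine_positive_point(make_volume(arr), VoxelPoint(1, 1, 1), 0) == VoxelPoint(1, 1, 1)

    def test_never_moves_farther_than_radius(self):
        rng = np.random.default_rng(4)
        v = make_volume(rng.random((12, 12, 12)))
        for _ in range(100):
            p = VoxelPoint(*(int(i) for i in rng.integers(0, 12, 3)))
            q = refine_positive_point(v, p, 5)
            d = np.linalg.norm(np.subtract(q.as_tuple(), p.as_tuple()))
            assert d <= 5.0 + 1e-12


class TestNegativePoints:
    def test_zero_points_requested(self):
        v = make_volume(np.zeros((3, 9, 9)))
        assert generate_negative_points(v, VoxelPoint(1, 4, 4), n_points=0) == []

    def test_negatives_avoid_bright_tube(self):
        yy, xx = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        tube = (yy - 10) ** 2 + (xx - 10) ** 2 <= 4
        arr = np.where(tube, 400.0, 50.0)[None]
        v = make_volume(arr)
        pts = generate_negative_points(v, VoxelPoint(0, 10, 10), 4, 6, 4, 0.6)
        assert len(pts) == 4
        for p in pts:
            assert not tube[p.y, p.x]
            assert np.hypot(p.y - 10, p.x - 10) >= 4.0

    def test_uniform_bright_slice_yields_nothing(self):
        v = make_volume(np.full((1, 21, 21), 300.0))
        assert generate_negative_points(v, VoxelPoint(0, 10, 10), 4, 6, 4, 0.5) == []


class TestBuildPrompts:
    def test_exact_slice_coverage(self, default_case):
        c = default_case.gt_centerlines[0]
        ps = build_prompts(default_case.image, c)
        expected = sorted({p.z for p in c.points})
        assert [sp.z for sp in ps.slice_prompts] == expected

    def test_positives_stay_within_refinement_radius(self, default_case):
        c = default_case.gt_centerlines[1]
        params = PromptParams()
        ps = build_prompts(default_case.image, c, params)
        by_slice = {}
        for p in c.points:
            by_slice.setdefault(p.z, []).append((p.y, p.x))
        for sp in ps.slice_prompts:
            for (y, x) in sp.positives:
                d = min(np.hypot(y - oy, x - ox) for oy, ox in by_slice[sp.z])
                assert d <= params.refine_radius_voxels + 1e-12

    def test_positives_mostly_inside_vessel(self, default_case, default_priors):
        priors, _ = default_priors
        cls = extract_centerlines(priors.candidates, 10.0)
        vm = default_case.vessel_mask.as_bool()
        total = inside = 0
        for c in cls:
            ps = build_prompts(default_case.image, c)
            for sp in ps.slice_prompts:
                for (y, x) in sp.positives:
                    total += 1
                    inside += bool(vm[sp.z, y, x])
        assert inside / total >= 0.95


class TestRunPromptedSegmentation:
    def test_all_zero_backend_gives_empty_mask(self, default_case):
        class Zero:
            def segment_slice(self, sl, prompt):
                return np.zeros_like(sl, dtype=np.uint8)

        c = default_case.gt_centerlines[0]
        ps = build_prompts(default_case.image, c)
        out = run_prompted_segmentation(Zero(), default_case.image, ps)
        assert out.values.sum() == 0

    def test_full_slice_oracle_identity(self, default_case):
        """A backend echoing the reference slice reproduces GT on prompted slices."""
        gt = default_case.vessel_mask

        class Echo:
            def segment_slice(self, sl, prompt):
                return gt.values[prompt.z]

        c = default_case.gt_centerlines[0]
        ps = build_prompts(default_case.image, c)
        out = run_prompted_segmentation(Echo(), default_case.image, ps)
        zs = {sp.z for sp in ps.slice_prompts}
        for z in range(gt.geometry.shape[0]):
            if z in zs:
                np.testing.assert_array_equal(out.values[z], gt.values[z])
            else:
                assert out.values[z].sum() == 0

    def test_oracle_backend_output_subset_of_reference(self, default_case):
        be = OracleBackend(default_case.vessel_mask)
        c = default_case.gt_centerlines[2]
        ps = build_prompts(default_case.image, c)
        out = run_prompted_segmentation(be, default_case.image, ps)
        assert not (out.as_bool() & ~default_case.vessel_mask.as_bool()).any()

    def test_backend_errors_carry_slice_context(self, default_case):
        class Boom:
            def segment_slice(self, sl, prompt):
                raise RuntimeError("nope")

        c = default_case.gt_centerlines[0]
        ps = build_prompts(default_case.image, c)
        with pytest.raises(RuntimeError, match="slice"):
            run_prompted_segmentation(Boom(), default_case.image, ps)

    def test_wrong_shape_rejected(self, default_case):
        class BadShape:
            def segment_slice(self, sl, prompt):
                return np.zeros((2, 2), dtype=np.uint8)

        c = default_case.gt_centerlines[0]
        ps = build_prompts(default_case.image, c)
        with pytest.raises(ValueError, match="shape"):
            run_prompted_segmentation(BadShape(), default_case.image, ps)

    def test_timing_recorded(self, default_case):
        be = OracleBackend(default_case.vessel_mask)
        c = default_case.gt_centerlines[0]
        ps = build_prompts(default_case.image, c)
        timings = []
        run_prompted_segmentation(be, default_case.image, ps, timings)
        assert len(timings) == 1 and timings[0][1] > 0

    def test_region_grow_dsc_on_noise_free_phantom(self, noise_free_case, noise_free_priors):
        from perfmap.evaluate import dsc

        priors, enhanced = noise_free_priors
        cls = extract_centerlines(priors.candidates, 10.0)
        be = ThresholdRegionGrowBackend(0.6)
        pred = np.zeros(enhanced.geometry.shape, dtype=np.uint8)
        for c in cls:
            ps = build_prompts(enhanced, c)
            pred |= run_prompted_segmentation(be, enhanced, ps).values
        pm = Mask(geometry=enhanced.geometry, values=pred)
        assert dsc(pm, noise_free_case.vessel_mask) >= 0.7


class TestPromptTypes:
    def test_slice_prompt_requires_positive_and_disjointness(self):
        with pytest.raises(ValueError):
            SlicePrompt(z=0, positives=[])
        with pytest.raises(ValueError):
            SlicePrompt(z=0, positives=[(1, 1)], negatives=[(1, 1)])

    def test_prompt_set_requires_increasing_slices(self):
        sp = SlicePrompt(z=3, positives=[(1, 1)])
        sp2 = SlicePrompt(z=2, positives=[(1, 1)])
        with pytest.raises(ValueError):
            PromptSet(centerline_id="c", slice_prompts=[sp, sp2])
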