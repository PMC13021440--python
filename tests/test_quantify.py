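import numpy as np
import pytest

from perfmap.anatomy import AnatomyPriors
from perfmap.centerline import Centerline, extract_centerlines, path_length_mm
from perfmap.quantify import (
    LENGTH_THRESHOLD_MM,
    build_report,
    fascial_emergence_point,
    intramuscular_path_length,
    umbilicus_distances,
)
from perfmap.volume_io import Geometry, Mask, VoxelPoint

from conftest import make_mask


def straight_centerline_x(n, y=5, z=1, shape=(3, 12, 40), spacing=(1.0, 1.0, 1.0)):
    g = Geometry(shape=shape, spacing=spacing)
    return Centerline(points=[VoxelPoint(z, y, x) for x in range(n)], geometry=g), g


class TestIntramuscularLength:
    def test_outside_muscle_is_zero(self):
        c, g = straight_centerline_x(11)
        muscle = Mask(geometry=g, values=np.zeros(g.shape, np.uint8))
        assert intramuscular_path_length(c, muscle) == 0.0

    def test_six_central_voxels_give_five_mm_in_literal_mode(self):
        c, g = straight_centerline_x(11)
        arr = np.zeros(g.shape, np.uint8)
        arr[:, :, 3:9] = 1  # 6 central points of the 11 survive
        muscle = Mask(geometry=g, values=arr)
        literal = intramuscular_path_length(
            c, muscle, chord_stride_points=1, boundary_extension=False
        )
        assert literal == pytest.approx(5.0)
        # default mode adds the half-voxel boundary extension at both faces
        assert intramuscular_path_length(c, muscle) == pytest.approx(6.0)

    def test_gap_bridging_vs_strict_mode(self):
        c, g = straight_centerline_x(11)
        arr = np.zeros(g.shape, np.uint8)
        arr[:, :, 2:5] = 1
        arr[:, :, 7:10] = 1  # two runs of 3, gap of 2
        muscle = Mask(geometry=g, values=arr)
        kw = dict(chord_stride_points=1, boundary_extension=False)
        bridged = intramuscular_path_length(c, muscle, **kw)
        strict = intramuscular_path_length(c, muscle, split_at_gaps=True, **kw)
        assert bridged == pytest.approx(7.0)  # spans the gap
        assert strict == pytest.approx(4.0)   # 2 + 2

    def test_never_exceeds_path_length(self, default_case, default_priors):
        priors, _ = default_priors
        muscle = priors.muscle_union()
        for c in default_case.gt_centerlines:
            assert intramuscular_path_length(c, muscle) <= path_length_mm(c) + 1e-9

    def test_phantom_recovery_mae(self, default_case, default_priors):
        """Centerline-based lengths track the analytic truth across 5 vessels."""
        from perfmap.pipeline import match_centerlines

        priors, _ = default_priors
        cls = extract_centerlines(priors.candidates, 10.0)
        muscle = priors.muscle_union()
        pairs = match_centerlines(cls, default_case.gt_centerlines)
        errors = [
            abs(
                intramuscular_path_length(cls[i], muscle)
                - default_case.gt_intramuscular_length_mm[j]
            )
            for i, j, _ in pairs
        ]
        assert np.mean(errors) < 2 * max(default_case.config.spacing)


class TestFascialEmergence:
    def _setup(self, fascia_y, cl_y, n=10):
        g = Geometry(shape=(3, 40, 20), spacing=(1, 1, 1))
        fascia = np.zeros(g.shape, np.uint8)
        fascia[1, fascia_y, 2 : 2 + n] = 1
        c = Centerline(points=[VoxelPoint(1, cl_y, 2 + i) for i in range(n)], geometry=g)
        return c, Mask(geometry=g, values=fascia)

    def test_direct_intersection_returns_most_superficial(self):
        g = Geometry(shape=(3, 40, 20), spacing=(1, 1, 1))
        fascia = np.zeros(g.shape, np.uint8)
        fascia[1, 10:12, :] = 1
        pts = [VoxelPoint(1, 13 - i, 5 + i) for i in range(4)]  # crosses y=11 then y=10
        c = Centerline(points=pts, geometry=g)
        e = fascial_emergence_point(c, Mask(geometry=g, values=fascia))
        assert e.y == 10

    def test_offset_exactly_20_qualifies(self):
        c, fascia = self._setup(fascia_y=5, cl_y=25)
        e = fascial_emergence_point(c, fascia, y_threshold_voxels=20)
        assert e is not None and e.y == 25

    def test_offset_21_is_absent(self):
        c, fascia = self._setup(fascia_y=5, cl_y=26)
        assert fascial_emergence_point(c, fascia, y_threshold_voxels=20) is None

    def test_empty_fascia_warns_and_returns_none(self):
        c, fascia = self._setup(fascia_y=5, cl_y=6)
        empty = Mask(geometry=fascia.geometry, values=np.zeros(fascia.geometry.shape, np.uint8))
        with pytest.warns(UserWarning):
            assert fascial_emergence_point(c, empty) is None


class TestUmbilicusDistances:
    g = Geometry(shape=(30, 30, 30), spacing=(2.0, 1.0, 1.0))

    def test_identical_points(self):
        p = VoxelPoint(5, 5, 5)
        assert umbilicus_distances(p, p, self.g) == (0.0, 0.0)

    def test_pure_vertical(self):
        assert umbilicus_distances(VoxelPoint(15, 5, 5), VoxelPoint(5, 5, 5), self.g) == (20.0, 0.0)

    def test_axis_differences_not_euclidean(self):
        g = Geometry(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))
        v, h = umbilicus_distances(VoxelPoint(3, 0, 4), VoxelPoint(0, 0, 0), g)
        assert (v, h) == (3.0, 4.0)  # not the 5.0 a Euclidean reading would give

    def test_components_bounded_by_3d_distance(self):
        rng = np.random.default_rng(6)
        g = Geometry(shape=(20, 20, 20), spacing=(1.7, 0.9, 1.1))
        for _ in range(50):
            a = VoxelPoint(*(int(i) for i in rng.integers(0, 20, 3)))
            b = VoxelPoint(*(int(i) for i in rng.integers(0, 20, 3)))
            v, h = umbilicus_distances(a, b, g)
            d3 = np.linalg.norm(
                (np.array(a.as_tuple()) - np.array(b.as_tuple())) * np.array(g.spacing)
            )
            assert v <= d3 + 1e-12 and h <= d3 + 1e-12

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            umbilicus_distances(VoxelPoint(99, 0, 0), VoxelPoint(0, 0, 0), self.g)


class TestBuildReport:
    def _priors_for(self, g, muscle_arr, fascia_arr=None, umbilicus=None):
        z = np.zeros(g.shape, np.uint8)
        return AnatomyPriors(
            geometry=g,
            muscle_left=Mask(geometry=g, values=muscle_arr),
            muscle_right=Mask(geometry=g, values=z.copy()),
            fascia=Mask(geometry=g, values=fascia_arr if fascia_arr is not None else z.copy()),
            umbilicus=umbilicus,
        )

    def test_length_threshold_flags(self):
        g = Geometry(shape=(3, 10, 60), spacing=(1, 1, 1))
        muscle = np.zeros(g.shape, np.uint8)
        muscle[:, :, :] = 1
        short = Centerline(points=[VoxelPoint(1, 5, x) for x in range(26)], geometry=g, id="s")
        long_ = Centerline(points=[VoxelPoint(1, 5, x) for x in range(56)], geometry=g, id="l")
        reports = build_report([short, long_], self._priors_for(g, muscle))
        by_id = {r.centerline_id: r for r in reports}
        assert by_id["s"].intramuscular_length_mm == pytest.approx(25.0, abs=0.5)
        assert by_id["s"].length_ok
        assert by_id["l"].intramuscular_length_mm == pytest.approx(55.0, abs=0.5)
        assert not by_id["l"].length_ok
        assert by_id["l"].intramuscular_length_mm > LENGTH_THRESHOLD_MM

    def test_absent_emergence_propagates(self):
        g = Geometry(shape=(3, 10, 30), spacing=(1, 1, 1))
        muscle = np.zeros(g.shape, np.uint8)
        c = Centerline(points=[VoxelPoint(1, 5, x) for x in range(10)], geometry=g, id="c")
        (r,) = build_report([c], self._priors_for(g, muscle, umbilicus=VoxelPoint(1, 1, 1)))
        assert r.emergence_point is None
        assert r.vertical_distance_mm is None and r.central_ok is None

    def test_phantom_report_per_vessel(self, default_case, default_priors):
        priors, _ = default_priors
        cls = extract_centerlines(priors.candidates, 10.0)
        reports = build_report(cls, priors)
        assert len(reports) == len(cls) == len(default_case.gt_centerlines)
        assert all(r.emergence_point is not None for r in reports)
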