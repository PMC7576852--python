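"""Kinematics: filtering, virtual frame, displacements, segmentation,
time normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from liftucm.datatypes import MarkerRecording
from liftucm.kin import (
    build_virtual_frame,
    compute_displacements,
    filter_markers,
    pair_repetitions,
    segment_phases,
    time_normalize,
    vertical_velocity,
)

FS = 250.0


def _markers(positions: dict[str, np.ndarray], n: int) -> MarkerRecording:
    labels = list(positions)
    pos = np.stack(
        [np.broadcast_to(np.asarray(p, dtype=float), (n, 3)).copy() for p in positions.values()],
        axis=1,
    )
    return MarkerRecording(pos, FS, labels)


FEET = {
    "LCAL": (-0.1, 0.0, 0.05),
    "RCAL": (0.1, 0.0, 0.05),
    "LMTP1": (-0.1, 0.2, 0.02),
    "RMTP1": (0.1, 0.2, 0.02),
}


def _filtfilt_gain(freq: float, cutoff: float = 6.0, order: int = 4) -> float:
    """Analytic forward-backward Butterworth magnitude: |H|^2."""
    b, a = sps.butter(order, cutoff, fs=FS)
    _, h = sps.freqz(b, a, worN=[freq], fs=FS)
    return float(np.abs(h[0]) ** 2)


class TestFilterMarkers:
    def _rec_with_z(self, z: np.ndarray) -> MarkerRecording:
        pos = np.zeros((len(z), 1, 3))
        pos[:, 0, 2] = z
        return MarkerRecording(pos, FS, ["M"])

    def test_constant_position_unchanged(self):
        rec = self._rec_with_z(np.full(500, 1.234))
        out = filter_markers(rec)
        assert np.max(np.abs(out.positions - rec.positions)) < 1e-9

    def test_passband_sine_matches_analytic_response(self):
        t = np.arange(2500) / FS
        rec = self._rec_with_z(np.sin(2 * np.pi * 1.0 * t))
        out = filter_markers(rec).positions[500:-500, 0, 2]
        gain = np.max(np.abs(out))
        assert gain >= 0.99 * _filtfilt_gain(1.0)

    def test_stopband_sine_attenuated(self):
        t = np.arange(2500) / FS
        rec = self._rec_with_z(np.sin(2 * np.pi * 50.0 * t))
        out = filter_markers(rec).positions[500:-500, 0, 2]
        assert np.max(np.abs(out)) < 0.01
        assert np.max(np.abs(out)) < 10 * _filtfilt_gain(50.0) + 1e-6

    def test_idempotent_in_passband(self):
        t = np.arange(2500) / FS
        rec = self._rec_with_z(0.5 * np.sin(2 * np.pi * 0.5 * t))
        once = filter_markers(rec)
        twice = filter_markers(once)
        mid = slice(300, -300)
        assert np.max(np.abs(twice.positions[mid] - once.positions[mid])) < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            filter_markers(self._rec_with_z(np.zeros(10)))


class TestVirtualFrame:
    def test_symmetric_geometry(self):
        frame = build_virtual_frame(_markers(FEET, 10))
        assert np.allclose(frame.origin, [0, 0, 0], atol=1e-12)
        assert np.allclose(frame.anterior, [0, 1, 0], atol=1e-12)
        assert np.allclose(frame.vertical, [0, 0, 1], atol=1e-12)

    def test_axes_orthonormal_right_handed(self, rng):
        feet = {k: np.asarray(v) + rng.normal(0, 0.02, 3) for k, v in FEET.items()}
        frame = build_virtual_frame(_markers(feet, 5))
        assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0)

    def test_translation_moves_origin_not_displacements(self):
        shift = np.array([0.3, -0.2, 0.0])
        m1 = dict(FEET, RACR=(0.0, 0.1, 1.4), PEL=(0.0, 0.05, 1.0))
        m2 = {k: np.asarray(v) + shift for k, v in m1.items()}
        f1 = build_virtual_frame(_markers(m1, 5))
        f2 = build_virtual_frame(_markers(m2, 5))
        assert np.allclose(f2.origin - f1.origin, shift, atol=1e-12)
        p1, t1 = compute_displacements(_markers(m1, 5), f1)
        p2, t2 = compute_displacements(_markers(m2, 5), f2)
        for a, b in ((p1, p2), (t1, t2)):
            assert np.allclose(a.ap, b.ap, atol=1e-12)
            assert np.allclose(a.v, b.v, atol=1e-12)

    def test_degenerate_geometry_raises(self):
        feet = dict(FEET)
        feet["LMTP1"] = (-0.1, 0.0, 0.02)
        feet["RMTP1"] = (0.1, 0.0, 0.02)
        with pytest.raises(ValueError, match="degenerate"):
            build_virtual_frame(_markers(feet, 5))

    def test_missing_marker_raises(self):
        with pytest.raises(KeyError, match="LCAL"):
            build_virtual_frame(_markers({k: v for k, v in FEET.items() if k != "LCAL"}, 5))


class TestDisplacements:
    def test_landmark_at_origin_is_zero(self):
        m = dict(FEET, RACR=(0.0, 0.0, 0.0), PEL=(0.0, 0.0, 0.0))
        rec = _markers(m, 8)
        frame = build_virtual_frame(rec)
        pelvis, trunk = compute_displacements(rec, frame)
        for d in (pelvis, trunk):
            assert np.allclose(d.ap, 0) and np.allclose(d.v, 0)

    def test_pure_vertical_motion(self):
        rec = _markers(dict(FEET, RACR=(0.0, 0.1, 0.0), PEL=(0.0, 0.1, 0.0)), 50)
        z = np.linspace(1.0, 1.5, 50)
        rec.positions[:, rec.labels.index("RACR"), 2] = z
        frame = build_virtual_frame(rec)
        _, trunk = compute_displacements(rec, frame)
        assert np.allclose(trunk.ap, 0.1, atol=1e-12)
        assert np.allclose(trunk.v, z, atol=1e-12)

    def test_missing_pelvis_falls_back_to_cluster(self):
        m = dict(FEET, RACR=(0.0, 0.1, 1.4))
        m.update({k: (0.05, 0.0, 1.0) for k in ("LASI", "RASI", "LPSI", "RPSI")})
        rec = _markers(m, 5)
        pelvis, _ = compute_displacements(rec, build_virtual_frame(rec))
        assert np.allclose(pelvis.v, 1.0)

    def test_missing_pelvis_everything_raises_naming_it(self):
        rec = _markers(dict(FEET, RACR=(0.0, 0.1, 1.4)), 5)
        with pytest.raises(KeyError, match="PEL"):
            compute_displacements(rec, build_virtual_frame(rec))


class TestSegmentPhases:
    def test_triangular_velocity_threshold_scan(self):
        # oracle: direct scan of v >= 0.1 * peak on the triangle
        i = np.arange(201)
        tri = (100 - np.abs(i - 100)) / 100.0  # exact 0.1 at samples 10/190
        v = np.concatenate([tri, -tri])
        segs = segment_phases(v, FS, min_duration_s=0.05)
        lift, lower = segs
        expect_on, expect_off = 10, 190  # first/last sample with tri >= 0.1
        assert lift.onsets.tolist() == [expect_on]
        assert lift.offsets.tolist() == [expect_off]
        assert lower.onsets.tolist() == [201 + expect_on]
        assert lower.offsets.tolist() == [201 + expect_off]

    def test_planted_bounds_recovered_exactly_from_raw_velocity(self, small_dataset):
        z = small_dataset.markers.get("RACR")[:, 2]
        v = np.empty_like(z)
        v[0] = 0.0
        v[1:] = np.diff(z) * small_dataset.markers.fs
        segs = segment_phases(v, small_dataset.markers.fs)
        for seg in segs:
            on_t, off_t = small_dataset.truth.cycle_bounds[seg.phase]
            assert np.array_equal(seg.onsets, on_t)
            assert np.array_equal(seg.offsets, off_t)

    def test_no_excursion_raises(self):
        with pytest.raises(ValueError, match="no repetition detected"):
            segment_phases(np.zeros(500), FS)

    def test_lift_precedes_lower_and_counts_match(self, small_dataset):
        segs = segment_phases(small_dataset.truth.acromion_velocity, FS)
        lift, lower = segs
        assert lift.n_reps == lower.n_reps == small_dataset.config.n_reps
        reps = pair_repetitions(segs)
        assert all(a < b for a, b in reps)

    def test_vertical_velocity_of_linear_ramp(self):
        d = np.linspace(0.0, 1.0, 251)
        v = vertical_velocity(d, FS)
        assert np.allclose(v[1:-1], 1.0)


class TestTimeNormalize:
    def test_linear_ramp_preserved_exactly(self):
        out = time_normalize(np.linspace(2.0, 5.0, 137), 100)
        assert np.allclose(out, np.linspace(2.0, 5.0, 100), atol=1e-12)

    def test_length_100_input_identity(self, rng):
        x = rng.standard_normal(100)
        assert np.array_equal(time_normalize(x, 100), x)

    def test_sine_matches_analytic_evaluation(self):
        n = 250
        t = np.arange(n) / (n - 1)
        out = time_normalize(np.sin(2 * np.pi * t), 100)
        expect = np.sin(2 * np.pi * np.linspace(0, 1, 100))
        assert np.max(np.abs(out - expect)) < 1e-3

    def test_2d_normalized_per_column(self, rng):
        x = rng.standard_normal((57, 3))
        out = time_normalize(x, 100)
        assert out.shape == (100, 3)
        assert np.allclose(out[0], x[0]) and np.allclose(out[-1], x[-1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            time_normalize(np.array([1.0]), 100)
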