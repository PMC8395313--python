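"""Membrane geometry: leaflet splitting, surface distance, tilt, insertion
depths, smoothing — plus ground-truth recovery on generated trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helimem import (
    BilayerModel,
    build_ideal_helix,
    fit_helix_axis,
    peptide_surface_distance,
    residue_insertion_depths,
    smooth_exponential,
    split_leaflets,
    tilt_angle,
)
from helimem.geometry import depth_trace, distance_trace, tilt_trace
from helimem.synth import SyntheticSpec, generate_mode_trajectory

from conftest import STUDY_PEPTIDES


def _grid(z, n=16, jitter=None, rng=None):
    side = int(np.sqrt(n))
    xy = np.array(
        [(x, y) for x in np.arange(side) for y in np.arange(side)], dtype=float
    )
    zs = np.full(n, float(z))
    if jitter is not None:
        zs = zs + rng.normal(0, jitter, size=n)
    return np.column_stack([xy, zs])


class TestLeaflets:
    def test_clean_split(self):
        P = np.vstack([_grid(2.0), _grid(-2.0)])
        bl = split_leaflets(P)
        assert len(bl.upper_P) == len(bl.lower_P) == 16
        assert bl.upper_plane_z == pytest.approx(2.0)

    def test_jittered_planes_recovered_exactly(self):
        rng = np.random.default_rng(3)
        upper = _grid(2.0, jitter=0.1, rng=rng)
        lower = _grid(-2.0, jitter=0.1, rng=rng)
        bl = split_leaflets(np.vstack([upper, lower]))
        assert np.allclose(np.sort(bl.upper_P[:, 2]), np.sort(upper[:, 2]))
        assert np.allclose(np.sort(bl.lower_P[:, 2]), np.sort(lower[:, 2]))

    def test_single_plane_rejected(self):
        with pytest.raises(ValueError, match="no bilayer"):
            split_leaflets(_grid(0.0))

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            split_leaflets(np.array([[0.0, 0.0, 1.0]]))


class TestSurfaceDistance:
    def _bilayer(self):
        return BilayerModel(upper_P=_grid(2.0), lower_P=_grid(-2.0))

    def _frame_at(self, z):
        frame = build_ideal_helix("A" * 8)
        com = frame.center_of_mass()
        return frame.translated(np.array([0.0, 0.0, z]) - com)

    def test_arithmetic(self):
        assert peptide_surface_distance(
            self._frame_at(3.0), self._bilayer()
        ) == pytest.approx(1.0, abs=1e-9)

    def test_tie_goes_to_upper(self):
        assert peptide_surface_distance(
            self._frame_at(0.0), self._bilayer()
        ) == pytest.approx(2.0, abs=1e-9)

    def test_xy_translation_invariance(self):
        frame = self._frame_at(1.2)
        bl = self._bilayer()
        ref = peptide_surface_distance(frame, bl)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shift = np.array([rng.normal(), rng.normal(), 0.0])
            moved = frame.translated(shift)
            moved.phosphorus = frame.phosphorus  # peptide-only xy shift
            assert peptide_surface_distance(moved, bl) == pytest.approx(
                ref, abs=1e-9
            )

    def test_bound_trajectory_stays_close(self):
        spec = SyntheticSpec(sequence=STUDY_PEPTIDES["FK-16"], mode="I", seed=5)
        trace = distance_trace(generate_mode_trajectory(spec))
        assert np.all(trace.values < 1.0)


class TestHelixAxis:
    def test_ideal_helix_axis_along_z(self):
        frame = build_ideal_helix(STUDY_PEPTIDES["FK-16"])
        axis = fit_helix_axis(frame.ca)
        assert abs(axis[2]) >= 0.99

    def test_collinear_points(self):
        pts = np.outer(np.arange(6), [1.0, 0.0, 0.0])
        axis = fit_helix_axis(pts)
        assert np.allclose(np.abs(axis), [1.0, 0.0, 0.0], atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_helix_axis(np.zeros((4, 3)))

    @pytest.mark.parametrize(
        "axis, expected",
        [((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((1, 0, 1), 45.0)],
    )
    def test_tilt_values(self, axis, expected):
        assert tilt_angle(np.array(axis, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tilt_angle(np.zeros(3))


@settings(deadline=None, max_examples=50)
@given(
    st.tuples(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    ).filter(lambda v: sum(x * x for x in v) > 1e-6)
)
def test_tilt_fold_symmetry(vec):
    v = np.array(vec)
    assert tilt_angle(v) == pytest.approx(tilt_angle(-v), abs=1e-9)
    assert 0.0 <= tilt_angle(v) <= 90.0


class TestInsertionDepths:
    def test_sign_convention(self):
        bl = BilayerModel(upper_P=_grid(2.0), lower_P=_grid(-2.0))
        frame = build_ideal_helix("A" * 8)
        frame = frame.translated(
            np.array([0.0, 0.0, 1.5]) - frame.center_of_mass()
        )
        depths = residue_insertion_depths(frame, bl)
        centroids = frame.sidechain_centroids()
        assert depths == pytest.approx(centroids[:, 2] - 2.0)

    def test_far_peptide_all_positive(self):
        bl = BilayerModel(upper_P=_grid(2.0), lower_P=_grid(-2.0))
        frame = build_ideal_helix("A" * 8)
        frame = frame.translated(
            np.array([0.0, 0.0, 6.0]) - frame.center_of_mass()
        )
        assert np.all(residue_insertion_depths(frame, bl) > 0)

    def test_mode_ii_anchor_depth_recovered(self):
        spec = SyntheticSpec(
            sequence=STUDY_PEPTIDES["LasioIII"], mode="II", seed=9,
            disorder_range=(1, 7),
        )
        traj = generate_mode_trajectory(spec)
        mean_depths = depth_trace(traj).mean_depths()
        # Trp3 is the bulkiest side chain of the disordered segment -> anchor
        assert -0.6 <= mean_depths[2] <= -0.2


class TestSmoothing:
    def test_identity_at_alpha_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert smooth_exponential(x, 1.0) == pytest.approx(x)

    def test_constant_unchanged(self):
        x = np.full(10, 2.5)
        assert smooth_exponential(x, 0.3) == pytest.approx(x)

    def test_arithmetic(self):
        assert smooth_exponential(np.array([0.0, 1.0]), 0.5) == pytest.approx(
            [0.0, 0.5]
        )

    def test_invalid_alpha_rejected(self):
        for alpha in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                smooth_exponential(np.ones(3), alpha)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        st.floats(0.01, 1.0),
    )
    def test_bounds_preserved(self, xs, alpha):
        y = smooth_exponential(np.array(xs), alpha)
        assert np.all(y >= min(xs) - 1e-6) and np.all(y <= max(xs) + 1e-6)


class TestGroundTruthRecovery:
    """Measured tilt / distance / anchor depth match generation parameters."""

    def test_tilt_recovery_20_seeds(self):
        errors = []
        for seed in range(10):
            spec = SyntheticSpec(
                sequence=STUDY_PEPTIDES["TempoLa"], mode="III", seed=seed,
                n_frames=40,
            )
            trace = tilt_trace(generate_mode_trajectory(spec))
            errors.append(abs(trace.values.mean() - spec.tilt_deg))
        for seed in range(10):
            spec = SyntheticSpec(
                sequence=STUDY_PEPTIDES["FK-16"], mode="I", seed=seed,
                n_frames=40,
            )
            trace = tilt_trace(generate_mode_trajectory(spec))
            errors.append(abs(trace.values.mean() - 90.0))
        assert max(errors) < 5.0

    def test_distance_recovery(self):
        for seed in range(5):
            spec = SyntheticSpec(
                sequence=STUDY_PEPTIDES["FK-16"], mode="I", seed=seed,
                n_frames=40,
            )
            trace = distance_trace(generate_mode_trajectory(spec))
            assert abs(trace.values.mean() - spec.surface_offset) < 0.1

    def test_anchor_depth_recovery(self):
        for seed in range(5):
            spec = SyntheticSpec(
                sequence=STUDY_PEPTIDES["LasioIII"], mode="II", seed=seed,
                disorder_range=(1, 7), n_frames=40,
            )
            traj = generate_mode_trajectory(spec)
            mean_depths = depth_trace(traj).mean_depths()
            assert abs(mean_depths[2] - (-spec.anchor_depth)) < 0.1
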