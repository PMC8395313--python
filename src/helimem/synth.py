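"""Seeded generation of peptide-bilayer trajectories with known ground truth.

This module fabricates geometry, not physics: no force field, water or
integrator.  It emulates, at toy scale, a simulation setup in which a helical
peptide starts near a planar bilayer whose phosphorus atoms define the two
leaflet planes, and produces trajectories whose helicity, surface distance,
tilt and anchoring are controlled inputs.  Each of the four target regimes
maps onto one binding mode:

* ``I``       — full helix lying in-plane ~0.3 nm above the upper phosphate
                plane (carpet-like);
* ``II``      — a partially disordered chain whose anchor residues sit below
                the phosphate plane while the helical remainder rests on the
                surface;
* ``III``     — full helix standing at a small tilt, tethered by its first
                residues at the plane, its azimuth performing a random walk
                (antenna-like swinging);
* ``unbound`` — full helix kept >= 3 nm above the surface.

Lipids are reduced to their phosphorus positions, the only bilayer atoms any
downstream metric reads.  All randomness flows from the single seed in the
spec, so identical specs give byte-identical trajectory files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .builder import build_ideal_helix, randomize_segment, SIDECHAIN_RADIUS
from .geometry import BilayerModel
from .structures import Frame, Trajectory

__all__ = ["SyntheticSpec", "make_bilayer", "generate_mode_trajectory"]

_MODES = ("I", "II", "III", "unbound")


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of one synthetic trajectory.

    Defaults encode the emulated setup: the peptide starts/stays near a
    bilayer with phosphate planes at +/- 2 nm, frames are 1 ns apart (100
    frames ~ a 100 ns trace), surface-bound peptides ride ~0.3 nm above the
    phosphate plane and anchors bury ~0.4 nm below it.
    """

    sequence: str
    mode: str
    seed: int
    n_frames: int = 100
    timestep: float = 1000.0  # ps between frames
    jitter_sigma: float = 0.03  # nm rigid-body positional jitter per frame
    bilayer_z: float = 2.0  # nm, +/- phosphate plane positions
    n_P_per_leaflet: int = 36
    composition: str = "PC/PS 80:20"
    surface_offset: float = 0.3  # nm COM height above the plane (mode I)
    anchor_depth: float = 0.4  # nm anchor burial below the plane (modes II/III)
    unbound_height: float = 3.2  # nm COM height (unbound)
    disorder_range: tuple[int, int] | None = None  # 1-based inclusive (mode II)
    anchor_residues: tuple[int, ...] | None = None  # 1-based (mode II)
    tilt_deg: float = 20.0  # generation tilt from the normal (mode III)
    azimuth_walk_sigma: float = 15.0  # degrees/frame (mode III)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mode == "II":
            if self.disorder_range is None:
                raise ValueError("mode II requires a disorder_range")
            lo, hi = self.disorder_range
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(
                    f"disorder_range {self.disorder_range} outside sequence"
                )
        if self.mode == "III" and not (0.0 < self.tilt_deg < 45.0):
            raise ValueError("mode III generation tilt must lie in (0, 45)")

    def to_dict(self) -> dict:
        return asdict(self)


def make_bilayer(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> BilayerModel:
    """Two phosphorus point-planes at +/- ``bilayer_z`` with Gaussian z-jitter.

    Phosphorus positions are laid out on a uniform xy grid (one point per
    lipid head group) wide enough to sit under the peptide; the composition
    label is carried through for bookkeeping only.
    """
    if spec.n_P_per_leaflet < 4:
        raise ValueError("need at least 4 phosphorus atoms per leaflet")
    rng = rng or np.random.default_rng(spec.seed)
    side = int(np.ceil(np.sqrt(spec.n_P_per_leaflet)))
    spacing = 0.8  # nm, approximately one lipid head group per grid cell
    offsets = (np.arange(side) - (side - 1) / 2.0) * spacing
    xy = np.array([(x, y) for x in offsets for y in offsets])[: spec.n_P_per_leaflet]

    def leaflet(z_plane: float) -> np.ndarray:
        z = z_plane + rng.normal(0.0, spec.jitter_sigma, size=len(xy))
        return np.column_stack([xy, z])

    return BilayerModel(
        upper_P=leaflet(+spec.bilayer_z),
        lower_P=leaflet(-spec.bilayer_z),
        composition=spec.composition,
    )


def _rot_y(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array(
        [[np.cos(a), 0.0, np.sin(a)], [0.0, 1.0, 0.0], [-np.sin(a), 0.0, np.cos(a)]]
    )


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


def _transform(frame: Frame, rot: np.ndarray, shift: np.ndarray) -> Frame:
    def tf(arr):
        return None if arr is None else arr @ rot.T + shift

    return Frame(
        sequence=frame.sequence,
        n=tf(frame.n),
        ca=tf(frame.ca),
        c=tf(frame.c),
        o=tf(frame.o),
        h=tf(frame.h),
        sidechain=tf(frame.sidechain),
        phosphorus=frame.phosphorus,
        time=frame.time,
    )


def _default_anchor(spec: SyntheticSpec) -> tuple[int, ...]:
    if spec.anchor_residues is not None:
        return spec.anchor_residues
    if spec.mode == "II":
        lo, hi = spec.disorder_range
        # bulkiest side chain in the disordered segment plays the anchor
        # (emulating an anchoring Trp)
        best = max(
            range(lo, hi + 1), key=lambda r: SIDECHAIN_RADIUS[spec.sequence[r - 1]]
        )
        return (best,)
    # mode III: tethered by its first three residues
    return (1, 2, 3)


def _base_conformation(spec: SyntheticSpec, rng: np.random.Generator) -> Frame:
    frame = build_ideal_helix(spec.sequence)
    if spec.mode == "II":
        frame = randomize_segment(
            frame, spec.disorder_range, seed=int(rng.integers(2**31))
        )
    return frame


def _oriented_base(spec: SyntheticSpec, bilayer: BilayerModel, rng) -> Frame:
    """Rotate/translate the base conformation into its mode geometry."""
    frame = _base_conformation(spec, rng)
    plane = bilayer.upper_plane_z

    def centroids_z(f: Frame) -> np.ndarray:
        return f.sidechain_centroids()[:, 2]

    if spec.mode == "I":
        frame = _transform(frame, _rot_y(90.0), np.zeros(3))
        dz = plane + spec.surface_offset - frame.center_of_mass()[2]
        frame = _transform(frame, np.eye(3), np.array([0.0, 0.0, dz]))
    elif spec.mode == "II":
        frame = _transform(frame, _rot_y(90.0), np.zeros(3))
        anchors = np.array(_default_anchor(spec)) - 1
        anchor_z = centroids_z(frame)[anchors].min()
        dz = plane - spec.anchor_depth - anchor_z
        frame = _transform(frame, np.eye(3), np.array([0.0, 0.0, dz]))
    elif spec.mode == "III":
        frame = _transform(frame, _rot_y(spec.tilt_deg), np.zeros(3))
        anchors = np.array(_default_anchor(spec)) - 1
        anchor_z = centroids_z(frame)[anchors].min()
        # tether just below the phosphate plane, helix body pointing up
        dz = plane - 0.6 * spec.anchor_depth - anchor_z
        frame = _transform(frame, np.eye(3), np.array([0.0, 0.0, dz]))
    else:  # unbound
        frame = _transform(frame, _rot_y(90.0), np.zeros(3))
        dz = plane + spec.unbound_height - frame.center_of_mass()[2]
        frame = _transform(frame, np.eye(3), np.array([0.0, 0.0, dz]))
    return frame


def generate_mode_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Generate a seeded trajectory realising the spec's binding mode.

    Every frame is a rigid placement of the (mode-dependent) base
    conformation: per-frame Gaussian rigid-body jitter of width
    ``jitter_sigma`` plus, for mode III, a cumulative random-walk rotation of
    the helix azimuth about the z axis through the anchor point.  The
    phosphorus planes are jittered once and held fixed.  The generating
    parameters are echoed in ``Trajectory.ground_truth``.
    """
    rng = np.random.default_rng(spec.seed)
    bilayer = make_bilayer(spec, rng)
    p_coords = np.vstack([bilayer.upper_P, bilayer.lower_P])
    base = _oriented_base(spec, bilayer, rng)

    if spec.mode == "III":
        anchors = np.array(_default_anchor(spec)) - 1
        pivot = base.ca[anchors].mean(axis=0)
        steps = rng.normal(0.0, spec.azimuth_walk_sigma, size=spec.n_frames)
        azimuth_angles = np.cumsum(steps)
    frames = []
    for t in range(spec.n_frames):
        jitter = rng.normal(0.0, spec.jitter_sigma, size=3)
        if spec.mode == "III":
            rot = _rot_z(azimuth_angles[t])
            shift = pivot - rot @ pivot + jitter
            frame = _transform(base, rot, shift)
        else:
            frame = _transform(base, np.eye(3), jitter)
        frame.phosphorus = p_coords
        frame.time = t * spec.timestep
        frames.append(frame)
    return Trajectory(
        frames=frames, timestep=spec.timestep, ground_truth=spec.to_dict()
    )
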