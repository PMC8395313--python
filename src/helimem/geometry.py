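"""Geometric trajectory metrics for a peptide at a planar bilayer.

The bilayer is represented by its phosphorus atoms only: the mass centre of
each leaflet's P atoms defines the phosphate plane of that leaflet, and the
membrane normal is fixed to the z axis (flat-bilayer assumption, matching
both the simulation convention these metrics mirror and the synthetic
generator).

Metrics:

* peptide-surface distance: |z_COM(peptide) - z_COM(nearer leaflet P)|;
* helix tilt: angle between the fitted helix axis and the z normal, folded to
  [0, 90] degrees (90 = lying flat on the surface, 0 = standing upright);
* per-residue insertion depth: signed z offset of the side-chain centroid
  from the nearer phosphate plane (negative = inserted below the phosphates);
* exponential smoothing, y_t = alpha*x_t + (1-alpha)*y_{t-1}, for all traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Frame, Trajectory

__all__ = [
    "DEFAULT_SMOOTHING_ALPHA",
    "BilayerModel",
    "DistanceTrace",
    "TiltTrace",
    "DepthTrace",
    "split_leaflets",
    "peptide_surface_distance",
    "com_height",
    "fit_helix_axis",
    "tilt_angle",
    "axis_azimuth",
    "residue_insertion_depths",
    "smooth_exponential",
    "distance_trace",
    "tilt_trace",
    "depth_trace",
]

#: Default exponential-smoothing weight for trace curves.
DEFAULT_SMOOTHING_ALPHA = 0.05


@dataclass
class BilayerModel:
    """Two leaflets of phosphorus positions (nm) with a z membrane normal."""

    upper_P: np.ndarray
    lower_P: np.ndarray
    composition: str = "PC"

    def __post_init__(self) -> None:
        self.upper_P = np.asarray(self.upper_P, float).reshape(-1, 3)
        self.lower_P = np.asarray(self.lower_P, float).reshape(-1, 3)
        if len(self.upper_P) == 0 or len(self.lower_P) == 0:
            raise ValueError("both leaflets must contain phosphorus atoms")
        if self.upper_P[:, 2].mean() <= self.lower_P[:, 2].mean():
            raise ValueError("upper leaflet must lie above lower leaflet")

    @property
    def upper_plane_z(self) -> float:
        """z of the upper-leaflet phosphate COM (equal P masses), nm."""
        return float(self.upper_P[:, 2].mean())

    @property
    def lower_plane_z(self) -> float:
        return float(self.lower_P[:, 2].mean())

    def nearer_plane_z(self, z: float) -> float:
        """Phosphate-plane z of the leaflet closer to ``z``; ties -> upper."""
        du = abs(z - self.upper_plane_z)
        dl = abs(z - self.lower_plane_z)
        return self.upper_plane_z if du <= dl else self.lower_plane_z


@dataclass
class DistanceTrace:
    """Peptide-surface distance (nm, >= 0) versus time (ps), plus the signed
    COM height above the nearer phosphate plane used by the classifier."""

    times: np.ndarray
    values: np.ndarray
    com_height: np.ndarray | None = None
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TiltTrace:
    """Helix tilt (degrees in [0, 90]) and in-plane azimuth versus time."""

    times: np.ndarray
    values: np.ndarray
    azimuths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if np.any((self.values < 0) | (self.values > 90)):
            raise ValueError("tilt must lie in [0, 90] degrees")


@dataclass
class DepthTrace:
    """Per-residue signed insertion depths (nm) versus time.

    ``per_residue[t, i]`` is the depth of residue i at frame t; negative
    means below the nearer phosphate plane.
    """

    times: np.ndarray
    per_residue: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.per_residue = np.asarray(self.per_residue, float)

    def mean_depths(self, window: slice = slice(None)) -> np.ndarray:
        return self.per_residue[window].mean(axis=0)


def split_leaflets(P_coords: np.ndarray, composition: str = "PC") -> BilayerModel:
    """Partition phosphorus atoms into leaflets about their median z.

    Atoms strictly above the median go to the upper leaflet; atoms at or
    below the median (ties) go to the lower leaflet.  Rejects point clouds
    with no bilayer gap (every P within 0.5 nm of the median).
    """
    P = np.asarray(P_coords, float).reshape(-1, 3)
    if len(P) < 2:
        raise ValueError("need at least 2 phosphorus atoms to split leaflets")
    med = np.median(P[:, 2])
    if np.all(np.abs(P[:, 2] - med) < 0.5):
        raise ValueError(
            "phosphorus atoms form a single plane (no bilayer separation)"
        )
    upper = P[P[:, 2] > med]
    lower = P[P[:, 2] <= med]
    return BilayerModel(upper_P=upper, lower_P=lower, composition=composition)


def com_height(
    frame: Frame, bilayer: BilayerModel, include_hydrogens: bool = True
) -> float:
    """Signed z offset of the peptide COM from the nearer phosphate plane."""
    z = frame.center_of_mass(include_hydrogens)[2]
    return float(z - bilayer.nearer_plane_z(z))


def peptide_surface_distance(
    frame: Frame, bilayer: BilayerModel, include_hydrogens: bool = True
) -> float:
    """|z_COM(peptide) - z_COM(P atoms of the nearer leaflet)| in nm.

    The nearer leaflet is the one minimising this same absolute difference;
    an exact tie resolves to the upper leaflet.
    """
    return abs(com_height(frame, bilayer, include_hydrogens))


def fit_helix_axis(CA_coords: np.ndarray) -> np.ndarray:
    """Principal axis of an ordered CA point cloud, unit norm, oriented N->C.

    For a helical segment the largest-variance direction of the CA positions
    is an accurate estimate of the helix axis.  At least 5 CA positions are
    required for the estimate to be meaningful.
    """
    ca = np.asarray(CA_coords, float).reshape(-1, 3)
    if len(ca) < 5:
        raise ValueError("helix-axis fit needs at least 5 CA positions")
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient from N-terminus towards C-terminus
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def tilt_angle(axis: np.ndarray) -> float:
    """Angle (degrees) between a helix axis and the z membrane normal.

    Folded to [0, 90]: 0 means the helix stands perpendicular to the surface
    (antenna-like), 90 means it lies in the membrane plane (carpet-like).
    The fold makes the angle independent of the axis sign.
    """
    axis = np.asarray(axis, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length axis")
    cos_to_normal = abs(axis[2]) / norm
    return float(np.degrees(np.arccos(np.clip(cos_to_normal, -1.0, 1.0))))


def axis_azimuth(axis: np.ndarray) -> float:
    """In-plane direction of the axis, degrees in [0, 360)."""
    return float(np.degrees(np.arctan2(axis[1], axis[0])) % 360.0)


def residue_insertion_depths(frame: Frame, bilayer: BilayerModel) -> np.ndarray:
    """Signed per-residue depth (nm) of side-chain centroids (CA for Gly)
    relative to the phosphate plane of the leaflet nearer the peptide COM;
    negative values are below the plane (inserted)."""
    plane_z = bilayer.nearer_plane_z(frame.center_of_mass()[2])
    centroids = frame.sidechain_centroids()
    depths = centroids[:, 2] - plane_z
    # depth is measured towards the membrane interior: for the lower leaflet
    # "inserted" means above the plane, so flip the sign there
    if plane_z == bilayer.lower_plane_z and plane_z != bilayer.upper_plane_z:
        depths = -depths
    return depths


def smooth_exponential(series: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average: y_0 = x_0; y_t = alpha*x_t + (1-alpha)*y_{t-1}."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    y = np.empty_like(x)
    y[0] = x[0]
    for t in range(1, len(x)):
        y[t] = alpha * x[t] + (1.0 - alpha) * y[t - 1]
    return y


def _frame_bilayer(frame: Frame, composition: str = "PC") -> BilayerModel:
    if len(frame.phosphorus) == 0:
        raise ValueError("frame carries no bilayer phosphorus atoms")
    return split_leaflets(frame.phosphorus, composition)


def distance_trace(
    traj: Trajectory,
    alpha: float | None = None,
    include_hydrogens: bool = True,
) -> DistanceTrace:
    """Per-frame peptide-surface distance; leaflets are re-split per frame."""
    values, heights = [], []
    for frame in traj:
        bilayer = _frame_bilayer(frame)
        h = com_height(frame, bilayer, include_hydrogens)
        heights.append(h)
        values.append(abs(h))
    trace = DistanceTrace(
        times=traj.times, values=np.array(values), com_height=np.array(heights)
    )
    if alpha is not None:
        trace.smoothed = smooth_exponential(trace.values, alpha)
    return trace


def tilt_trace(traj: Trajectory, helical_only: bool = True) -> TiltTrace:
    """Per-frame helix tilt and azimuth.

    With ``helical_only`` the axis is fitted to the CA atoms of the longest
    helical run (when it spans >= 5 residues, as assigned by the
    Kabsch-Sander module); otherwise, or when the helical run is too short,
    all CA atoms are used.
    """
    from .secondary import assign_helix

    tilts, azimuths = [], []
    for frame in traj:
        ca = frame.ca
        if helical_only:
            labels = str(assign_helix(frame))
            run = _longest_run(labels, "H")
            if run is not None and run[1] - run[0] >= 5:
                ca = frame.ca[run[0] : run[1]]
        axis = fit_helix_axis(ca)
        tilts.append(tilt_angle(axis))
        azimuths.append(axis_azimuth(axis))
    return TiltTrace(
        times=traj.times, values=np.array(tilts), azimuths=np.array(azimuths)
    )


def depth_trace(traj: Trajectory) -> DepthTrace:
    """Per-frame, per-residue signed insertion depths."""
    depths = []
    for frame in traj:
        bilayer = _frame_bilayer(frame)
        depths.append(residue_insertion_depths(frame, bilayer))
    return DepthTrace(times=traj.times, per_residue=np.array(depths))


def _longest_run(labels: str, code: str) -> tuple[int, int] | None:
    best = None
    start = None
    for i, ch in enumerate(labels + "\0"):
        if ch == code and start is None:
            start = i
        elif ch != code and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best
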