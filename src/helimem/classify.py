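"""Membrane binding-mode classification and flow-LD band-sign prediction.

Helical membrane-active peptides fall into three recurring association
geometries at a bilayer surface:

* **Mode I** (carpet-like): highly helical, lying flat on the phosphate
  plane with the helix axis in the membrane plane.
* **Mode II** (partial helix + anchor): only part of the chain is helical;
  a disordered segment buries an anchoring side chain below the phosphate
  plane while the rest sits on the surface.
* **Mode III** (antenna): a fully helical monomer standing roughly
  perpendicular to the surface, not inserted, tethered by its first few
  residues and free to swing its azimuth.

The classifier turns the helicity, distance, tilt and depth traces into one
of {I, II, III, unbound} by a small threshold table evaluated over the final
third of the trajectory (the equilibrated part).  The thresholds are
quantitative stand-ins for qualitative descriptors ("highly helical",
"perpendicular"), so they all live in one configurable block.

Flow linear dichroism reports the same orientation experimentally: LD =
A_par - A_perp of flow-aligned vesicles.  For an alpha-helix the ~210 nm
pi-pi* transition moment lies along the helix axis and the ~222 nm n-pi*
moment perpendicular to it, so the two band signs are opposite and change
together as the helix tilts through the magic angle (54.7 degrees, where the
orientation factor 3cos^2(gamma)-1 of both moments vanishes).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .geometry import DepthTrace, DistanceTrace, TiltTrace
from .secondary import HelicityTrace
from .structures import Frame

__all__ = [
    "MAGIC_ANGLE_DEG",
    "ClassifierThresholds",
    "BindingModeCall",
    "LDSignPrediction",
    "predict_ld_signs",
    "surface_footprint",
    "classify_binding_mode",
]

#: Angle at which 3cos^2 - 1 vanishes; LD bands null out within +/- 1 degree.
MAGIC_ANGLE_DEG = math.degrees(math.acos(math.sqrt(1.0 / 3.0)))


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds for the mode classifier.

    d_bind
        COM distance (nm) from the phosphate plane below which a frame counts
        as membrane-bound.
    helicity_high / helicity_low
        Mean helicity cuts separating "highly helical" (modes I/III) from
        "partially helical" (mode II) from unfolded.
    tilt_parallel / tilt_upright
        Median tilt cuts: above ``tilt_parallel`` the helix lies in-plane
        (mode I); below ``tilt_upright`` it stands (mode III).
    anchor_depth
        Mean side-chain depth (nm) below which a residue counts as an anchor
        buried under the phosphate plane.
    analysis_fraction
        Final fraction of the trajectory analysed (equilibrated window).
    """

    d_bind: float = 1.2
    helicity_high: float = 0.6
    helicity_low: float = 0.2
    tilt_parallel: float = 60.0
    tilt_upright: float = 45.0
    anchor_depth: float = -0.1
    bound_fraction_min: float = 0.5
    analysis_fraction: float = 1.0 / 3.0
    min_frames: int = 20


@dataclass
class LDSignPrediction:
    """Predicted signs of the two helix LD bands with orientation factors.

    ``orientation_factor`` per band is 3cos^2(gamma)-1 where gamma is the
    angle of that band's transition moment to the membrane normal; the band
    sign in the flow-cell geometry is the sign of minus that factor (a moment
    in the membrane plane absorbs preferentially parallel to the flow axis).
    """

    band_210_sign: str
    band_222_sign: str
    orientation_factor_210: float
    orientation_factor_222: float


@dataclass
class BindingModeCall:
    """A mode assignment plus the per-criterion evidence behind it."""

    mode: str
    evidence: dict = field(default_factory=dict)
    window_used: float = 1.0 / 3.0
    low_confidence: bool = False
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "evidence": {k: float(v) for k, v in self.evidence.items()},
            "window_used": self.window_used,
            "low_confidence": self.low_confidence,
            "thresholds": asdict(self.thresholds),
        }


def predict_ld_signs(tilt: float) -> LDSignPrediction:
    """Predict the ~210 nm and ~222 nm LD band signs from the helix tilt.

    ``tilt`` is the angle (degrees, [0, 90]) between the helix axis and the
    membrane normal.  The pi-pi* moment (~210 nm) lies along the helix axis,
    at gamma_210 = tilt to the normal; the n-pi* moment (~222 nm) is
    perpendicular to the axis.  Averaging the perpendicular moment over its
    rotation about the helix axis gives an effective orientation factor of
    -(3cos^2(tilt)-1)/2, always opposite in sign to the parallel band.  Both
    signs are '0' within one degree of the magic angle.
    """
    if not 0.0 <= tilt <= 90.0:
        raise ValueError(f"tilt must lie in [0, 90] degrees, got {tilt}")
    cos2 = math.cos(math.radians(tilt)) ** 2
    s_axis = 3.0 * cos2 - 1.0  # orientation factor of the helix axis
    factor_210 = s_axis
    factor_222 = -0.5 * s_axis
    if abs(tilt - MAGIC_ANGLE_DEG) <= 1.0:
        return LDSignPrediction("0", "0", factor_210, factor_222)

    def sign_of_band(factor: float) -> str:
        # a moment preferentially in the membrane plane (factor < 0) absorbs
        # parallel to the flow axis -> positive LD
        return "+" if factor < 0 else "-"

    return LDSignPrediction(
        band_210_sign=sign_of_band(factor_210),
        band_222_sign=sign_of_band(factor_222),
        orientation_factor_210=factor_210,
        orientation_factor_222=factor_222,
    )


def surface_footprint(frame: Frame) -> float:
    """Area (nm^2) of the convex hull of peptide atoms projected on xy.

    Quantifies how much membrane surface the peptide covers: a helix lying
    in-plane throws a long shadow, a standing (antenna) helix a compact one.
    Degenerate (collinear) projections return 0.
    """
    xy = frame.peptide_coords()[:, :2]
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # 2-D hull "volume" is the area
    except QhullError:
        return 0.0


def _analysis_window(n: int, fraction: float, min_frames: int) -> slice:
    start = min(n - min_frames, int(round(n * (1.0 - fraction))))
    return slice(max(0, start), n)


def classify_binding_mode(
    helicity: HelicityTrace,
    distance: DistanceTrace,
    tilt: TiltTrace,
    depths: DepthTrace,
    thresholds: ClassifierThresholds | None = None,
    footprint_area: float | None = None,
) -> BindingModeCall:
    """Assign one of {I, II, III, unbound} from the four aligned traces.

    Decision table over the analysis window (final third by default):

    * unbound: fewer than half the frames have distance < d_bind;
    * I: mean helicity >= helicity_high and median tilt >= tilt_parallel;
    * II: helicity_low <= mean helicity < helicity_high and at least one
      residue's mean depth < anchor_depth;
    * III: mean helicity >= helicity_high, median tilt < tilt_upright, the
      COM stays above the phosphate plane (mean signed height > 0) and at
      least one of the first three residues anchors below it;
    * otherwise the nearest rule by score margin, flagged low-confidence.

    Classification is total on valid input: the fallback never raises.
    """
    th = thresholds or ClassifierThresholds()
    n = len(helicity.values)
    for other in (distance, tilt, depths):
        if len(other.times) != n or not np.allclose(other.times, helicity.times):
            raise ValueError("traces are not time-aligned")
    if n < th.min_frames:
        raise ValueError(
            f"need at least {th.min_frames} frames to classify, got {n}"
        )
    win = _analysis_window(n, th.analysis_fraction, th.min_frames)

    mean_hel = float(helicity.values[win].mean())
    med_tilt = float(np.median(tilt.values[win]))
    bound_fraction = float((distance.values[win] < th.d_bind).mean())
    mean_depths = depths.mean_depths(win)
    anchor_depth_min = float(mean_depths.min())
    early_anchor = float(mean_depths[: min(3, len(mean_depths))].min())
    if distance.com_height is not None:
        mean_height = float(distance.com_height[win].mean())
    else:
        mean_height = float(distance.values[win].mean())
    evidence = {
        "bound_fraction": bound_fraction,
        "mean_helicity": mean_hel,
        "median_tilt": med_tilt,
        "anchor_depth_min": anchor_depth_min,
        "early_anchor_depth": early_anchor,
        "mean_com_height": mean_height,
    }
    if tilt.azimuths is not None:
        evidence["azimuth_circular_variance"] = _circular_variance(
            tilt.azimuths[win]
        )
    if footprint_area is not None:
        evidence["footprint_area"] = float(footprint_area)

    def call(mode, low=False):
        return BindingModeCall(
            mode=mode,
            evidence=evidence,
            window_used=th.analysis_fraction,
            low_confidence=low,
            thresholds=th,
        )

    if bound_fraction < th.bound_fraction_min:
        return call("unbound")
    if mean_hel >= th.helicity_high and med_tilt >= th.tilt_parallel:
        return call("I")
    if th.helicity_low <= mean_hel < th.helicity_high and anchor_depth_min < th.anchor_depth:
        return call("II")
    if (
        mean_hel >= th.helicity_high
        and med_tilt < th.tilt_upright
        and mean_height > 0.0
        and early_anchor < th.anchor_depth
    ):
        return call("III")

    # no rule fired cleanly: score each mode by its worst normalised margin
    # and return the closest one, flagged low-confidence
    scores = {
        "I": min(
            (mean_hel - th.helicity_high) / th.helicity_high,
            (med_tilt - th.tilt_parallel) / 90.0,
        ),
        "II": min(
            (mean_hel - th.helicity_low) / th.helicity_high,
            (th.helicity_high - mean_hel) / th.helicity_high,
            (th.anchor_depth - anchor_depth_min) / 0.5,
        ),
        "III": min(
            (mean_hel - th.helicity_high) / th.helicity_high,
            (th.tilt_upright - med_tilt) / 90.0,
            (th.anchor_depth - early_anchor) / 0.5,
            mean_height / 0.5,
        ),
    }
    best = max(scores, key=lambda m: scores[m])
    result = call(best, low=True)
    result.evidence["fallback_margins"] = scores[best]
    return result


def _circular_variance(angles_deg: np.ndarray) -> float:
    """1 - |mean resultant| of unit vectors at the given angles (degrees)."""
    a = np.radians(np.asarray(angles_deg, float))
    r = math.hypot(float(np.cos(a).mean()), float(np.sin(a).mean()))
    return 1.0 - r
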