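"""End-to-end analysis: trajectory -> traces -> binding-mode call."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    BindingModeCall,
    ClassifierThresholds,
    classify_binding_mode,
    surface_footprint,
)
from .geometry import (
    DEFAULT_SMOOTHING_ALPHA,
    DepthTrace,
    DistanceTrace,
    TiltTrace,
    depth_trace,
    distance_trace,
    tilt_trace,
)
from .secondary import HelicityTrace, helicity_trace
from .structures import Trajectory

__all__ = ["AnalysisResult", "analyze_trajectory"]


@dataclass
class AnalysisResult:
    """All traces plus the classification for one trajectory."""

    helicity: HelicityTrace
    distance: DistanceTrace
    tilt: TiltTrace
    depths: DepthTrace
    mean_footprint: float
    call: BindingModeCall


def analyze_trajectory(
    traj: Trajectory,
    thresholds: ClassifierThresholds | None = None,
    alpha: float = DEFAULT_SMOOTHING_ALPHA,
    include_hydrogens: bool = True,
) -> AnalysisResult:
    """Compute the four traces and classify the binding mode.

    ``alpha`` is the exponential-smoothing weight applied to the helicity and
    distance curves (the raw values feed the classifier; smoothing is for
    reporting/plotting).  Frames must carry bilayer phosphorus atoms.
    """
    th = thresholds or ClassifierThresholds()
    if len(traj.frames[0].phosphorus) == 0:
        raise ValueError("trajectory has no bilayer phosphorus atoms")
    hel = helicity_trace(traj, alpha=alpha)
    dist = distance_trace(traj, alpha=alpha, include_hydrogens=include_hydrogens)
    tilt = tilt_trace(traj)
    depths = depth_trace(traj)
    n = len(traj)
    win_start = max(0, min(n - th.min_frames, int(round(n * (1 - th.analysis_fraction)))))
    footprint = float(
        np.mean([surface_footprint(f) for f in traj.frames[win_start:]])
    )
    call = classify_binding_mode(
        hel, dist, tilt, depths, thresholds=th, footprint_area=footprint
    )
    return AnalysisResult(
        helicity=hel,
        distance=dist,
        tilt=tilt,
        depths=depths,
        mean_footprint=footprint,
        call=call,
    )
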