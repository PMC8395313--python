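import numpy as np
import pytest

from helimem import PeptideSequence, build_ideal_helix
from helimem.structures import Frame, Trajectory

# The five study peptides (all C-terminally amidated synthetic products).
STUDY_PEPTIDES = {
    "LasioIII": "VNWKKILGKIIKVVK",
    "Macro1": "GFGMALKLLKKVL",
    "TempoLa": "LLRHVVKILEKYL",
    "FK-16": "FKRIVQRIKDFLRNLV",
    "LL-37": "LLGDFFRKSKEKIGKEFKRIVQRIKDFLRNLVPRTES",
}


@pytest.fixture(scope="session")
def peptides():
    return {
        name: PeptideSequence(id=name, residues=seq, c_terminal_amidated=True)
        for name, seq in STUDY_PEPTIDES.items()
    }


@pytest.fixture(scope="session")
def ideal_helix_16():
    return build_ideal_helix(STUDY_PEPTIDES["FK-16"])


@pytest.fixture()
def flat_bilayer_frame(ideal_helix_16):
    """Helix lying in the xy plane 0.3 nm above an exact upper P plane."""
    from helimem.synth import SyntheticSpec, generate_mode_trajectory

    spec = SyntheticSpec(
        sequence=STUDY_PEPTIDES["FK-16"], mode="I", seed=0, n_frames=1,
        jitter_sigma=0.0,
    )
    return generate_mode_trajectory(spec).frames[0]


def constant_trajectory(frame: Frame, n_frames: int, timestep: float = 1000.0):
    """A trajectory repeating one frame at uniform times."""
    frames = []
    for t in range(n_frames):
        f = Frame(
            sequence=frame.sequence,
            n=frame.n.copy(),
            ca=frame.ca.copy(),
            c=frame.c.copy(),
            o=frame.o.copy(),
            h=None if frame.h is None else frame.h.copy(),
            sidechain=None if frame.sidechain is None else frame.sidechain.copy(),
            phosphorus=frame.phosphorus.copy(),
            time=t * timestep,
        )
        frames.append(f)
    return Trajectory(frames=frames, timestep=timestep)
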