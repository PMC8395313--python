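"""Alpha-helix assignment from backbone geometry (Kabsch-Sander criterion).

A backbone N-H...O=C hydrogen bond is called from the Kabsch-Sander
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with distances in Angstrom; the bond exists when E < -0.5 kcal/mol.  A
residue is assigned 'H' when it lies inside two consecutive i -> i+4
hydrogen-bonded turns, the standard alpha-helix rule.  Only the reduced
alphabet {H, T, C} is produced (helix, isolated turn, coil); 3_10/pi helices
and strands are not distinguished here because the downstream helicity
fraction counts alpha-helical residues only.

The helicity fraction divides the helical residue count by L - 2: the two
terminal residues can never satisfy the two-turn rule and are treated as
inherently coil.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structures import Frame, Trajectory

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "SSLabels",
    "HelicityTrace",
    "reconstruct_amide_hydrogen",
    "hbond_energy",
    "assign_helix",
    "helicity_fraction",
    "helicity_trace",
]

#: Kabsch-Sander coupling constant q1*q2*332, kcal/mol * Angstrom.
_KS_FACTOR = 0.084 * 332.0
#: Hydrogen bond called below this energy (kcal/mol).
HBOND_ENERGY_CUTOFF = -0.5
#: Geometry guard: atom pairs closer than this (Angstrom) signal a clash.
_MIN_DISTANCE = 0.5
#: Reconstructed N-H bond length (Angstrom).
_NH_LENGTH = 1.0

_NM_TO_ANGSTROM = 10.0


@dataclass(frozen=True)
class SSLabels:
    """Per-residue secondary structure in the reduced {H, T, C} alphabet."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - set("HTC")
        if bad:
            raise ValueError(f"invalid secondary-structure codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return self.labels

    @property
    def n_helical(self) -> int:
        return self.labels.count("H")


@dataclass
class HelicityTrace:
    """Helicity fraction versus time (ps); values in [0, 1]."""

    times: np.ndarray
    values: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("helicity values must lie in [0, 1]")


def reconstruct_amide_hydrogen(frame: Frame, trust_input: bool = False) -> Frame:
    """Place backbone amide hydrogens by the standard DSSP reconstruction.

    H sits 1.0 Angstrom from N along the previous residue's O->C unit vector
    (i.e. N-H anti-parallel to the preceding carbonyl C=O).  Residue 1 and
    prolines carry no amide hydrogen.  Existing hydrogens are replaced unless
    ``trust_input`` is set and a full H array is already present, keeping the
    assignment deterministic across input sources of varying quality.
    """
    if trust_input and frame.h is not None:
        return frame
    L = frame.n_residues
    h = np.full((L, 3), np.nan)
    co = frame.c - frame.o  # O -> C direction, per residue
    norms = np.linalg.norm(co, axis=1)
    if np.any(norms < 1e-9):
        bad = int(np.argmin(norms)) + 1
        raise ValueError(f"degenerate C=O geometry at residue {bad}")
    unit = co / norms[:, None]
    for i in range(1, L):
        if frame.sequence[i] == "P":
            continue
        h[i] = frame.n[i] + (_NH_LENGTH / _NM_TO_ANGSTROM) * unit[i - 1]
    return replace(frame, h=h)


def hbond_energy(c, o, n, h) -> float:
    """Kabsch-Sander electrostatic energy of one N-H...O=C contact, kcal/mol.

    Inputs are coordinates in nm; the formula is evaluated in Angstrom.
    Raises if any inter-atom distance falls below the 0.5 Angstrom clash
    guard, which signals malformed geometry rather than a strong bond.
    """
    c = np.asarray(c, float) * _NM_TO_ANGSTROM
    o = np.asarray(o, float) * _NM_TO_ANGSTROM
    n = np.asarray(n, float) * _NM_TO_ANGSTROM
    h = np.asarray(h, float) * _NM_TO_ANGSTROM
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DISTANCE:
        raise ValueError(
            "atoms closer than 0.5 Angstrom in hydrogen-bond evaluation "
            "(malformed geometry)"
        )
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _turn4(frame: Frame) -> np.ndarray:
    """turn4[i] is True when residue i's C=O accepts an H-bond from i+4."""
    L = frame.n_residues
    turns = np.zeros(L, dtype=bool)
    h = frame.h
    for i in range(L - 4):
        donor = i + 4
        if h is None or not np.all(np.isfinite(h[donor])):
            continue  # no amide H (proline or chain start)
        e = hbond_energy(frame.c[i], frame.o[i], frame.n[donor], h[donor])
        turns[i] = e < HBOND_ENERGY_CUTOFF
    return turns


def assign_helix(frame: Frame) -> SSLabels:
    """Label residues H/T/C from i -> i+4 backbone hydrogen bonds.

    Two consecutive hydrogen-bonded turns starting at i-1 and i promote
    residues i..i+3 to 'H'.  A turn that is not part of such a pair marks its
    spanned residues 'T'.  The first and last residues are always coil.
    """
    frame = reconstruct_amide_hydrogen(frame)
    L = frame.n_residues
    if L < 5:
        return SSLabels("C" * L)
    turns = _turn4(frame)
    labels = np.full(L, "C", dtype="U1")
    for i in range(1, L - 4):
        if turns[i - 1] and turns[i]:
            labels[i : i + 4] = "H"
    for i in np.flatnonzero(turns):
        for j in range(i + 1, i + 4):
            if labels[j] == "C":
                labels[j] = "T"
    # the two-turn rule can never reach the chain ends, but make the
    # terminal-coil guarantee explicit
    labels[0] = "C" if labels[0] == "H" else labels[0]
    labels[-1] = "C" if labels[-1] == "H" else labels[-1]
    return SSLabels("".join(labels))


def helicity_fraction(labels: SSLabels) -> float:
    """Helical residue count over L - 2 (terminal residues excluded), in [0,1]."""
    L = len(labels)
    if L < 3:
        raise ValueError("helicity fraction needs at least 3 residues")
    return min(1.0, labels.n_helical / (L - 2))


def helicity_trace(
    traj: Trajectory, alpha: float | None = None
) -> HelicityTrace:
    """Per-frame helicity fraction; optionally exponentially smoothed.

    ``alpha`` in (0, 1] enables smoothing with that weight (see
    :func:`helimem.geometry.smooth_exponential`).
    """
    values = []
    for idx, frame in enumerate(traj):
        try:
            values.append(helicity_fraction(assign_helix(frame)))
        except ValueError as err:
            raise ValueError(f"frame {idx}: {err}") from err
    trace = HelicityTrace(times=traj.times, values=np.array(values))
    if alpha is not None:
        from .geometry import smooth_exponential

        trace.smoothed = smooth_exponential(trace.values, alpha)
    return trace
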