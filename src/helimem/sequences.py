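"""Sequence-level amphipathicity profiling of helical membrane-active peptides.

Cationic anticancer/antimicrobial peptides are commonly characterised by three
numbers derived from their sequence alone: the net charge at neutral pH, the
mean residue hydrophobicity ``<H>`` and the Eisenberg mean hydrophobic moment
``<muH>``.  The moment treats the peptide as an ideal alpha-helix in which
successive residues are rotated by 100 degrees about the helix axis; the
vector sum of the per-residue hydrophobicities then measures how strongly the
hydrophobic residues segregate onto one helix face (amphipathicity).

Both windowed metrics follow the HELIQUEST convention: the metric is evaluated
on every contiguous 11-residue window and the window values are averaged.  The
default hydrophobicity scale is the Fauchere-Pliska octanol/water partition
scale.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "PeptideSequence",
    "HydrophobicityScale",
    "AmphipathicityResult",
    "WheelProjection",
    "get_scale",
    "parse_peptide",
    "read_fasta",
    "net_charge",
    "window_hydrophobicity",
    "window_hydrophobic_moment",
    "amphipathicity_profile",
    "segment_metrics",
    "helical_wheel",
    "metrics_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fauchere & Pliska octanol/water side-chain partition free energies
#: (unitless as tabulated, 2-decimal published precision; Gly defines zero).
_FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Default angular step per residue in an ideal alpha-helix (degrees).
DEFAULT_DELTA = 100.0

#: Default HELIQUEST window length (residues).
DEFAULT_WINDOW = 11


@dataclass(frozen=True)
class PeptideSequence:
    """A validated peptide with explicit terminal chemistry.

    Terminal flags are never inferred: synthetic peptides in this family are
    usually C-terminally amidated (removing the terminal carboxylate charge),
    and that choice changes the net charge by one.
    """

    id: str
    residues: str
    c_terminal_amidated: bool
    n_terminal_free: bool = True

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"peptide {self.id!r}: non-canonical residue {aa!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, stop: int) -> "PeptideSequence":
        """Extract residues ``start..stop`` (1-based, inclusive).

        The fragment keeps the parent's terminal flags only where the cut
        coincides with the parent terminus; an internal cut point is treated
        as a free terminus for bookkeeping but fragments are used for H/muH
        metrics only, which ignore termini.
        """
        if not (1 <= start <= stop <= len(self.residues)):
            raise ValueError(
                f"interval {start}-{stop} out of bounds for "
                f"{len(self.residues)}-residue peptide {self.id!r}"
            )
        return PeptideSequence(
            id=f"{self.id}[{start}-{stop}]",
            residues=self.residues[start - 1 : stop],
            c_terminal_amidated=self.c_terminal_amidated
            and stop == len(self.residues),
            n_terminal_free=self.n_terminal_free and start == 1,
        )


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity mapping covering all 20 codes."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


_SCALES = {
    "fauchere_pliska": HydrophobicityScale("fauchere_pliska", _FAUCHERE_PLISKA),
}


def get_scale(name: str = "fauchere_pliska") -> HydrophobicityScale:
    """Look up a registered hydrophobicity scale by name."""
    try:
        return _SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; registered: {sorted(_SCALES)}"
        ) from None


@dataclass
class AmphipathicityResult:
    """Windowed hydrophobicity / hydrophobic-moment profile of one peptide."""

    window_size: int
    delta: float
    per_window_H: list[float] = field(default_factory=list)
    per_window_muH: list[float] = field(default_factory=list)

    @property
    def mean_H(self) -> float:
        return sum(self.per_window_H) / len(self.per_window_H)

    @property
    def mean_muH(self) -> float:
        return sum(self.per_window_muH) / len(self.per_window_muH)


@dataclass
class WheelProjection:
    """Helical-wheel coordinates and the hydrophobic-face vector.

    ``face_azimuth`` is the direction of the per-residue-normalised vector sum
    of hydrophobicities in the wheel plane — the direction a drawn arrow for
    the hydrophobic face would point.  It is undefined (``None``) when the
    vector magnitude vanishes (e.g. poly-Gly).
    """

    per_residue_azimuth: list[float]
    face_azimuth: float | None
    face_magnitude: float


def parse_peptide(
    record: str,
    label: str = "peptide",
    amidated: bool = False,
    n_terminal_free: bool = True,
) -> PeptideSequence:
    """Validate labelled sequence text into a :class:`PeptideSequence`.

    Whitespace is stripped and case is ignored; any other non-canonical
    character is rejected with its (1-based) position in the cleaned string.
    """
    cleaned = "".join(record.split()).upper()
    return PeptideSequence(
        id=label,
        residues=cleaned,
        c_terminal_amidated=amidated,
        n_terminal_free=n_terminal_free,
    )


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    """Read peptides from FASTA; an ``amidated`` token in the description
    sets the C-terminal flag."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        amidated = "amidated" in rec.description.lower()
        peptides.append(parse_peptide(str(rec.seq), rec.id, amidated=amidated))
    if not peptides:
        raise ValueError(f"no FASTA records in {path}")
    return peptides


def net_charge(p: PeptideSequence) -> int:
    """Integer net charge at neutral pH.

    Counting convention: Lys/Arg +1, Asp/Glu -1, His 0, free N-terminus +1,
    free-acid C-terminus -1 (0 if amidated).
    """
    positive = sum(p.residues.count(aa) for aa in "KR")
    negative = sum(p.residues.count(aa) for aa in "DE")
    charge = positive - negative
    if p.n_terminal_free:
        charge += 1
    if not p.c_terminal_amidated:
        charge -= 1
    return charge


def _windows(residues: str, window: int) -> list[str]:
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(residues) < window:
        return [residues]
    return [residues[j : j + window] for j in range(len(residues) - window + 1)]


def _window_moment(win: str, scale: HydrophobicityScale, delta: float) -> float:
    step = math.radians(delta)
    vec = sum(scale[aa] * cmath.exp(1j * step * k) for k, aa in enumerate(win))
    return abs(vec) / len(win)


def amphipathicity_profile(
    p: PeptideSequence,
    scale: HydrophobicityScale | None = None,
    window: int = DEFAULT_WINDOW,
    delta: float = DEFAULT_DELTA,
) -> AmphipathicityResult:
    """Windowed ``<H>`` and ``<muH>`` profile (both metrics populated).

    Each contiguous ``window``-residue stretch contributes one window value;
    a sequence shorter than the window forms a single whole-sequence window.
    The per-window moment is the per-residue-normalised modulus of the
    complex sum ``sum_k H_k exp(i k delta)``.
    """
    scale = scale or get_scale()
    result = AmphipathicityResult(window_size=window, delta=delta)
    for win in _windows(p.residues, window):
        result.per_window_H.append(sum(scale[aa] for aa in win) / len(win))
        result.per_window_muH.append(_window_moment(win, scale, delta))
    return result


def window_hydrophobicity(
    p: PeptideSequence,
    scale: HydrophobicityScale | None = None,
    window: int = DEFAULT_WINDOW,
) -> AmphipathicityResult:
    """Window-averaged mean hydrophobicity ``<H>``."""
    return amphipathicity_profile(p, scale, window)


def window_hydrophobic_moment(
    p: PeptideSequence,
    scale: HydrophobicityScale | None = None,
    window: int = DEFAULT_WINDOW,
    delta: float = DEFAULT_DELTA,
) -> AmphipathicityResult:
    """Window-averaged Eisenberg hydrophobic moment ``<muH>``."""
    return amphipathicity_profile(p, scale, window, delta)


def segment_metrics(
    p: PeptideSequence,
    ranges: Iterable[tuple[int, int]],
    scale: HydrophobicityScale | None = None,
    window: int = DEFAULT_WINDOW,
    delta: float = DEFAULT_DELTA,
) -> list[AmphipathicityResult]:
    """Apply the windowed metrics independently to 1-based inclusive
    sub-sequence intervals (used for long peptides reported per segment)."""
    return [
        amphipathicity_profile(p.subsequence(start, stop), scale, window, delta)
        for start, stop in ranges
    ]


def helical_wheel(
    p: PeptideSequence,
    scale: HydrophobicityScale | None = None,
    delta: float = DEFAULT_DELTA,
) -> WheelProjection:
    """Project residues onto the helical wheel and locate the hydrophobic face.

    Residue ``k`` (0-based) sits at azimuth ``(k * delta) mod 360``.  The face
    vector is the whole-sequence moment, so its magnitude equals ``muH``
    recomputed with window = sequence length.
    """
    scale = scale or get_scale()
    azimuths = [(k * delta) % 360.0 for k in range(len(p.residues))]
    step = math.radians(delta)
    vec = sum(
        scale[aa] * cmath.exp(1j * step * k) for k, aa in enumerate(p.residues)
    )
    magnitude = abs(vec) / len(p.residues)
    if magnitude < 1e-9:
        azimuth = None
    else:
        azimuth = math.degrees(cmath.phase(vec)) % 360.0
    return WheelProjection(
        per_residue_azimuth=azimuths,
        face_azimuth=azimuth,
        face_magnitude=magnitude,
    )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, matching the 2-decimal published tables."""
    factor = 10**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * math.copysign(1, value)


def metrics_table(
    peptides: Sequence[PeptideSequence],
    scale: HydrophobicityScale | None = None,
    window: int = DEFAULT_WINDOW,
    delta: float = DEFAULT_DELTA,
):
    """Per-peptide summary table (pandas DataFrame) with the standard columns
    id, length, net_charge, mean_H, mean_muH, window, scale."""
    import pandas as pd

    scale = scale or get_scale()
    rows = []
    for p in peptides:
        prof = amphipathicity_profile(p, scale, window, delta)
        rows.append(
            {
                "id": p.id,
                "length": len(p),
                "net_charge": net_charge(p),
                "mean_H": round_half_up(prof.mean_H),
                "mean_muH": round_half_up(prof.mean_muH),
                "window": window,
                "scale": scale.name,
            }
        )
    return pd.DataFrame(rows)
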