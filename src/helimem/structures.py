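"""Coordinate containers shared by the structural analysis modules.

A :class:`Frame` holds one time point of a peptide near a planar lipid
bilayer: backbone coordinates per residue (N, CA, C, O, optionally the amide
H), one pseudo-atom per side chain placed at the side-chain centroid, and the
phosphorus atoms of the bilayer head groups.  Coordinates are in nanometres
throughout; the membrane normal is the z axis.

A :class:`Trajectory` is an ordered, time-stamped sequence of frames with a
constant atom layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Frame", "Trajectory", "BACKBONE_MASSES", "SIDECHAIN_MASSES"]

#: Standard atomic masses (u) for the explicitly represented backbone atoms.
BACKBONE_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999, "H": 1.008}

#: Average side-chain masses (u) lumped onto the per-residue pseudo-atom
#: (residue mass minus the Gly backbone); Gly has no pseudo-atom.
SIDECHAIN_MASSES = {
    "G": 1.008, "A": 15.035, "S": 31.034, "C": 47.095, "T": 45.061,
    "V": 43.089, "L": 57.116, "I": 57.116, "M": 75.149, "P": 41.073,
    "F": 91.133, "W": 130.170, "Y": 107.132, "D": 59.044, "E": 73.071,
    "N": 58.060, "Q": 72.086, "K": 72.129, "R": 100.143, "H": 81.097,
}


@dataclass
class Frame:
    """One snapshot of a peptide (plus optional bilayer phosphorus atoms).

    Arrays are ``(L, 3)`` in nm, indexed by 0-based residue.  ``h`` rows are
    NaN where no amide hydrogen exists (residue 1, prolines, or simply not yet
    reconstructed); ``sidechain`` rows are NaN for glycine.
    """

    sequence: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None
    sidechain: np.ndarray | None = None
    phosphorus: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L == 0:
            raise ValueError("empty peptide frame")
        for name in ("n", "ca", "c", "o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, 3):
                raise ValueError(
                    f"backbone array {name!r} has shape {arr.shape}, "
                    f"expected ({L}, 3)"
                )
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr).all(axis=1))[0, 0]) + 1
                raise ValueError(
                    f"non-finite {name.upper()} coordinate at residue {bad}"
                )
            setattr(self, name, arr)
        self.phosphorus = np.asarray(self.phosphorus, dtype=float).reshape(-1, 3)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def peptide_coords(self) -> np.ndarray:
        """All peptide atom coordinates, (n_atoms, 3) nm (NaN rows dropped)."""
        parts = [self.n, self.ca, self.c, self.o]
        if self.h is not None:
            parts.append(self.h)
        if self.sidechain is not None:
            parts.append(self.sidechain)
        coords = np.concatenate(parts, axis=0)
        return coords[np.isfinite(coords).all(axis=1)]

    def peptide_masses(self, include_hydrogens: bool = True) -> np.ndarray:
        """Masses aligned with :meth:`peptide_coords` (same NaN filtering)."""
        L = self.n_residues
        masses = [np.full(L, BACKBONE_MASSES[a]) for a in ("N", "CA", "C", "O")]
        keep = [np.ones(L, bool)] * 4
        if self.h is not None:
            h_mass = BACKBONE_MASSES["H"] if include_hydrogens else 0.0
            masses.append(np.full(L, h_mass))
            keep.append(np.isfinite(self.h).all(axis=1))
        if self.sidechain is not None:
            masses.append(
                np.array([SIDECHAIN_MASSES[aa] for aa in self.sequence])
            )
            keep.append(np.isfinite(self.sidechain).all(axis=1))
        return np.concatenate([m[k] for m, k in zip(masses, keep)])

    def center_of_mass(self, include_hydrogens: bool = True) -> np.ndarray:
        """Mass-weighted centre of the peptide atoms, nm."""
        coords = self.peptide_coords()
        masses = self.peptide_masses(include_hydrogens)
        return masses @ coords / masses.sum()

    def sidechain_centroids(self) -> np.ndarray:
        """Per-residue side-chain position (CA for glycine), (L, 3) nm."""
        if self.sidechain is None:
            return self.ca.copy()
        out = self.sidechain.copy()
        missing = ~np.isfinite(out).all(axis=1)
        out[missing] = self.ca[missing]
        return out

    def translated(self, shift: np.ndarray) -> "Frame":
        """Rigidly shift the peptide AND the bilayer by ``shift`` (nm)."""
        shift = np.asarray(shift, dtype=float)

        def mv(arr):
            return None if arr is None else arr + shift

        return replace(
            self,
            n=self.n + shift,
            ca=self.ca + shift,
            c=self.c + shift,
            o=self.o + shift,
            h=mv(self.h),
            sidechain=mv(self.sidechain),
            phosphorus=self.phosphorus + shift
            if len(self.phosphorus)
            else self.phosphorus,
        )


@dataclass
class Trajectory:
    """Ordered frames with uniform atom layout and strictly increasing times."""

    frames: list[Frame]
    timestep: float = 1000.0  # ps between frames
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        seqs = {f.sequence for f in self.frames}
        if len(seqs) > 1:
            raise ValueError("frames disagree on peptide sequence")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def sequence(self) -> str:
        return self.frames[0].sequence
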