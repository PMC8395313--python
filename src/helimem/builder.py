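"""Peptide backbone construction from internal coordinates.

Builds full N-CA-C-O backbones (plus one pseudo-atom per side chain at the
average side-chain centroid distance) by forward kinematics from standard
bond lengths/angles and per-residue (phi, psi) torsions.  An ideal
alpha-helix uses phi = -57, psi = -47 degrees, which yields the canonical
~1.5 Angstrom rise and ~100 degree twist per residue and i -> i+4 backbone
hydrogen bonds; segments can be re-sampled from extended/polyproline-II coil
torsion ranges to create partially folded states with a fixed seed.

All outputs are :class:`~helimem.structures.Frame` objects in nm with the
helix axis aligned to +z and the centroid at the origin.
"""

from __future__ import annotations

import numpy as np

from .structures import Frame

__all__ = [
    "ALPHA_PHI",
    "ALPHA_PSI",
    "build_ideal_helix",
    "build_from_torsions",
    "randomize_segment",
    "backbone_torsions",
]

# Engh-Huber-style standard backbone geometry (Angstrom / degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_OMEGA = 180.0

#: Ideal alpha-helix backbone torsions (degrees).
ALPHA_PHI = -57.0
ALPHA_PSI = -47.0

#: Uniform sampling ranges for coil-region torsions (degrees): the
#: extended/PPII basin, which cannot satisfy the alpha-helix H-bond pattern.
_COIL_PHI = (-160.0, -70.0)
_COIL_PSI = (90.0, 170.0)

#: Average distance (Angstrom) from CA to the side-chain centroid, used to
#: place the single side-chain pseudo-atom; Gly has no side chain.
SIDECHAIN_RADIUS = {
    "A": 1.5, "C": 2.1, "D": 2.5, "E": 3.1, "F": 3.4, "G": 0.0, "H": 3.2,
    "I": 2.3, "K": 3.5, "L": 2.6, "M": 3.2, "N": 2.5, "P": 1.9, "Q": 3.1,
    "R": 4.1, "S": 1.9, "T": 1.9, "V": 2.0, "W": 3.9, "Y": 3.8,
}

_NM = 0.1  # Angstrom -> nm


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom D given A-B-C, |C-D|, angle(B,C,D) and dihedral(A,B,C,D).

    The standard natural-extension-of-reference-frame construction; inputs in
    Angstrom/degrees, output in the same cartesian frame as a, b, c.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_from_torsions(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    align_z: bool = True,
) -> Frame:
    """Build a backbone frame from per-residue (phi, psi) torsions (degrees).

    ``phi[0]`` is unused (no preceding carbonyl) and ``psi[-1]`` only places
    the terminal carbonyl oxygen.  With ``align_z`` the chain is rotated so
    its CA principal axis points along +z (N- to C-terminus) and centred at
    the CA centroid.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("need at least 2 residues to build a backbone")
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if phi.shape != (L,) or psi.shape != (L,):
        raise ValueError("phi/psi must have one entry per residue")

    n = np.empty((L, 3))
    ca = np.empty((L, 3))
    c = np.empty((L, 3))
    o = np.empty((L, 3))

    # first residue in a canonical local frame
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    c[0] = ca[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(L - 1):
        n[i + 1] = _place_atom(n[i], ca[i], c[i], _B_C_N, _A_CA_C_N, psi[i])
        ca[i + 1] = _place_atom(ca[i], c[i], n[i + 1], _B_N_CA, _A_C_N_CA, _OMEGA)
        c[i + 1] = _place_atom(c[i], n[i + 1], ca[i + 1], _B_CA_C, _A_N_CA_C, phi[i + 1])
        # carbonyl O of residue i, trans to the next amide N about CA-C
        o[i] = _place_atom(n[i + 1], ca[i], c[i], _B_C_O, _A_CA_C_O, 180.0)
    # terminal carbonyl from psi of the last residue
    o[L - 1] = _place_atom(n[L - 1], ca[L - 1], c[L - 1], _B_C_O, _A_CA_C_O,
                           psi[L - 1] + 180.0)

    sidechain = _place_sidechains(sequence, n, ca, c)

    frame = Frame(
        sequence=sequence,
        n=n * _NM,
        ca=ca * _NM,
        c=c * _NM,
        o=o * _NM,
        sidechain=sidechain * _NM if sidechain is not None else None,
    )
    if align_z:
        frame = _align_to_z(frame)
    return frame


def _place_sidechains(sequence, n, ca, c) -> np.ndarray | None:
    """One pseudo-atom per residue along the idealised CA->CB direction,
    scaled to the residue's average centroid distance; NaN for Gly."""
    L = len(sequence)
    out = np.full((L, 3), np.nan)
    for i, aa in enumerate(sequence):
        r = SIDECHAIN_RADIUS[aa]
        if r == 0.0:
            continue
        b1 = ca[i] - n[i]
        b2 = ca[i] - c[i]
        bisector = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
        bisector /= np.linalg.norm(bisector)
        normal = np.cross(b1, b2)
        normal /= np.linalg.norm(normal)
        # tetrahedral split between the bisector and the N-CA-C plane normal
        direction = bisector * np.cos(np.radians(54.0)) - normal * np.sin(
            np.radians(54.0)
        )
        out[i] = ca[i] + r * direction / np.linalg.norm(direction)
    return out


def _align_to_z(frame: Frame) -> Frame:
    """Rotate so the CA principal axis (N->C oriented) is +z, centre at CA
    centroid."""
    ca = frame.ca
    center = ca.mean(axis=0)
    centered = ca - center
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))

    def tf(arr):
        if arr is None:
            return None
        out = (arr - center) @ rot.T
        return out

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


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    cross = np.cross(u, v)
    dot = float(np.dot(u, v))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # opposite vectors: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    axis = cross / np.linalg.norm(cross)
    return _axis_angle(axis, np.arccos(np.clip(dot, -1.0, 1.0)))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1.0 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def build_ideal_helix(sequence: str, peptide_id: str | None = None) -> Frame:
    """Fully alpha-helical conformation of ``sequence``, axis along +z.

    Consecutive CA-CA distances come out at ~3.8 Angstrom with ~100 degrees
    of twist per residue; the geometry satisfies the Kabsch-Sander i -> i+4
    hydrogen-bond pattern, so downstream assignment recovers near-complete
    helicity.
    """
    if len(sequence) < 4:
        raise ValueError(
            f"an alpha-helix needs at least 4 residues, got {len(sequence)}"
        )
    L = len(sequence)
    phi = np.full(L, ALPHA_PHI)
    psi = np.full(L, ALPHA_PSI)
    return build_from_torsions(sequence, phi, psi)


def backbone_torsions(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-residue (phi, psi) in degrees from backbone coordinates.

    phi[0] and psi[-1] are inferred where undefined: phi[0] is reported as
    the ideal-helix value placeholder and psi[-1] from the terminal carbonyl.
    """
    L = frame.n_residues
    phi = np.full(L, ALPHA_PHI)
    psi = np.full(L, ALPHA_PSI)
    n, ca, c, o = frame.n, frame.ca, frame.c, frame.o
    for i in range(L):
        if i > 0:
            phi[i] = _dihedral(c[i - 1], n[i], ca[i], c[i])
        if i < L - 1:
            psi[i] = _dihedral(n[i], ca[i], c[i], n[i + 1])
        else:
            psi[i] = _dihedral(n[i], ca[i], c[i], o[i]) - 180.0
    return phi, psi


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def randomize_segment(frame: Frame, interval: tuple[int, int], seed: int) -> Frame:
    """Re-sample backbone torsions in a 1-based inclusive residue interval
    from coil-region ranges and rebuild the chain by forward kinematics.

    Residues before the interval keep their exact conformation (the rebuilt
    chain is superposed onto the original over that prefix); residues after
    it keep their internal geometry up to a rigid attachment.  An empty
    interval (start > stop) returns the input unchanged.  Deterministic for a
    fixed seed.
    """
    start, stop = interval
    if start > stop:
        return frame
    L = frame.n_residues
    if not (1 <= start <= stop <= L):
        raise ValueError(f"interval {start}-{stop} out of bounds for L={L}")
    rng = np.random.default_rng(seed)
    phi, psi = backbone_torsions(frame)
    idx = np.arange(start - 1, stop)
    phi[idx] = rng.uniform(*_COIL_PHI, size=len(idx))
    psi[idx] = rng.uniform(*_COIL_PSI, size=len(idx))
    rebuilt = build_from_torsions(frame.sequence, phi, psi, align_z=False)
    rebuilt = _superpose_prefix(rebuilt, frame, n_fit=max(start - 1, 3))
    return rebuilt


def _superpose_prefix(mobile: Frame, reference: Frame, n_fit: int) -> Frame:
    """Rigidly superpose ``mobile`` onto ``reference`` using the first
    ``n_fit`` CA positions (Kabsch algorithm)."""
    n_fit = min(n_fit, mobile.n_residues)
    P = mobile.ca[:n_fit]
    Q = reference.ca[:n_fit]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    rot = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T

    def tf(arr):
        if arr is None:
            return None
        return (arr - pc) @ rot.T + qc

    return Frame(
        sequence=mobile.sequence,
        n=tf(mobile.n),
        ca=tf(mobile.ca),
        c=tf(mobile.c),
        o=tf(mobile.o),
        h=tf(mobile.h),
        sidechain=tf(mobile.sidechain),
        phosphorus=reference.phosphorus,
        time=reference.time,
    )
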