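"""Multi-model PDB input/output for peptide + bilayer-phosphorus trajectories.

One MODEL per frame, coordinates in Angstrom (converted to nm in memory).
Chain A carries the peptide as ATOM records (backbone N/CA/C/O, optional
amide H, and the side-chain pseudo-atom written with atom name ``CB``);
bilayer phosphorus atoms are HETATM records named ``P`` on chain B.  The
frame spacing in picoseconds is stored in a ``REMARK 250 TIMESTEP_PS`` line
so that write -> read round-trips the time axis.

Parsing and formatting are delegated to biotite's fixed-width PDB machinery.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .structures import Frame, Trajectory

__all__ = ["read_structures", "write_structures", "write_trace", "read_trace"]

_NM_TO_ANGSTROM = 10.0
_TIMESTEP_REMARK = "REMARK 250 TIMESTEP_PS"


def _one_to_three(aa: str) -> str:
    return ProteinSequence.convert_letter_1to3(aa).upper()


def _three_to_one(res: str) -> str:
    return ProteinSequence.convert_letter_3to1(res.upper())


def write_structures(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (Angstrom units)."""
    first = traj.frames[0]
    L = first.n_residues
    has_h = first.h is not None
    has_sc = first.sidechain is not None

    atom_names, res_ids, res_names, elements, hetero, chains = [], [], [], [], [], []
    row_sources = []  # (array-name, residue-index) per output atom
    for i, aa in enumerate(first.sequence):
        per_res = [("n", "N", "N"), ("ca", "CA", "C"), ("c", "C", "C"), ("o", "O", "O")]
        if has_h and np.all(np.isfinite(first.h[i])):
            per_res.append(("h", "H", "H"))
        if has_sc and np.all(np.isfinite(first.sidechain[i])):
            per_res.append(("sidechain", "CB", "C"))
        for source, name, element in per_res:
            row_sources.append((source, i))
            atom_names.append(name)
            res_ids.append(i + 1)
            res_names.append(_one_to_three(aa))
            elements.append(element)
            hetero.append(False)
            chains.append("A")
    n_p = len(first.phosphorus)
    for j in range(n_p):
        row_sources.append(("phosphorus", j))
        atom_names.append("P")
        res_ids.append(L + 1 + j)
        res_names.append("LIP")
        elements.append("P")
        hetero.append(True)
        chains.append("B")

    n_atoms = len(atom_names)
    template = struc.AtomArray(n_atoms)
    template.atom_name = np.array(atom_names)
    template.res_id = np.array(res_ids)
    template.res_name = np.array(res_names)
    template.element = np.array(elements)
    template.hetero = np.array(hetero)
    template.chain_id = np.array(chains)

    coords = np.empty((len(traj), n_atoms, 3))
    for t, frame in enumerate(traj):
        for k, (source, i) in enumerate(row_sources):
            coords[t, k] = getattr(frame, source)[i]
    stack = struc.AtomArrayStack(len(traj), n_atoms)
    for ann in ("atom_name", "res_id", "res_name", "element", "hetero", "chain_id"):
        stack.set_annotation(ann, getattr(template, ann))
    stack.coord = coords * _NM_TO_ANGSTROM

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.lines.insert(0, f"{_TIMESTEP_REMARK} {traj.timestep:.6f}")
    pdb.write(str(path))


def read_structures(path: str | Path, default_timestep: float = 1000.0) -> Trajectory:
    """Read a multi-model PDB trajectory written in the dialect above.

    Tolerates missing amide hydrogens and missing side-chain pseudo-atoms
    (their rows become NaN).  Files without any coordinate record are
    rejected.
    """
    path = Path(path)
    text = path.read_text() if path.exists() else None
    if text is None:
        raise FileNotFoundError(path)
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise ValueError(f"{path}: no coordinate records (empty or malformed PDB)")
    timestep = default_timestep
    for line in text.splitlines():
        if line.startswith(_TIMESTEP_REMARK):
            timestep = float(line.split()[-1])
            break
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as err:  # biotite raises format-specific errors
        raise ValueError(f"{path}: malformed PDB ({err})") from err
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    is_p = (stack.atom_name == "P") & (stack.element == "P")
    pep_mask = ~is_p
    res_ids = stack.res_id[pep_mask]
    res_names = stack.res_name[pep_mask]
    atom_names = stack.atom_name[pep_mask]

    unique_res = []
    seen = set()
    for rid in res_ids:
        if rid not in seen:
            seen.add(rid)
            unique_res.append(rid)
    sequence = ""
    for rid in unique_res:
        name = res_names[res_ids == rid][0]
        sequence += _three_to_one(name)
    L = len(sequence)
    rid_to_idx = {rid: i for i, rid in enumerate(unique_res)}

    frames = []
    pep_coords_all = stack.coord[:, pep_mask, :] / _NM_TO_ANGSTROM
    p_coords_all = stack.coord[:, is_p, :] / _NM_TO_ANGSTROM
    has_h = "H" in atom_names
    has_sc = "CB" in atom_names
    for t in range(stack.stack_depth()):
        arrays = {
            "N": np.full((L, 3), np.nan),
            "CA": np.full((L, 3), np.nan),
            "C": np.full((L, 3), np.nan),
            "O": np.full((L, 3), np.nan),
            "H": np.full((L, 3), np.nan),
            "CB": np.full((L, 3), np.nan),
        }
        for k, (rid, name) in enumerate(zip(res_ids, atom_names)):
            if name in arrays:
                arrays[name][rid_to_idx[rid]] = pep_coords_all[t, k]
        for name in ("N", "CA", "C", "O"):
            missing = ~np.isfinite(arrays[name]).all(axis=1)
            if np.any(missing):
                bad = int(np.flatnonzero(missing)[0]) + 1
                raise ValueError(
                    f"{path}: residue {bad} missing backbone atom {name}"
                )
        frames.append(
            Frame(
                sequence=sequence,
                n=arrays["N"],
                ca=arrays["CA"],
                c=arrays["C"],
                o=arrays["O"],
                h=arrays["H"] if has_h else None,
                sidechain=arrays["CB"] if has_sc else None,
                phosphorus=p_coords_all[t],
                time=t * timestep,
            )
        )
    return Trajectory(frames=frames, timestep=timestep)


def write_trace(
    path: str | Path,
    times: np.ndarray,
    values: np.ndarray,
    metric: str,
    units: str,
    alpha: float | None = None,
    config_hash: str | None = None,
    smoothed: np.ndarray | None = None,
) -> None:
    """Write a time/value table as TSV with a self-describing header."""
    import pandas as pd

    header = [f"# metric={metric}", f"# units={units}"]
    if alpha is not None:
        header.append(f"# smoothing_alpha={alpha}")
    if config_hash is not None:
        header.append(f"# config={config_hash}")
    data = {"time_ps": np.asarray(times), "value": np.asarray(values)}
    if smoothed is not None:
        data["smoothed"] = np.asarray(smoothed)
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_trace(path: str | Path):
    """Read a trace TSV back into a pandas DataFrame (header comments skipped)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
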