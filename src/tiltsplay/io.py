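"""File I/O: PDB topologies, DCD trajectories and CCP4/MRC density maps.

PDB/DCD reading and writing is delegated to MDAnalysis; density maps go
through gemmi.  Chain names longer than one character (the replica chains
``M1``, ``M2``, ... created by trajectory extension) are carried in the PDB
segid columns; on read the segid takes precedence over the single-character
chain ID when present.

Atom masses are not stored in PDB files, so they are resolved from a
built-in element table keyed by an element guessed from the atom name.  For
coarse-grained beads (or anything else the heuristic cannot know) pass
``mass_overrides``, a mapping from atom name to mass in amu, which always
wins.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import MolecularSystem, Trajectory, UnitCell

__all__ = [
    "ELEMENT_MASSES",
    "guess_element",
    "mass_of_atom",
    "load_system",
    "load_trajectory",
    "save_trajectory",
    "write_ccp4",
    "read_ccp4",
]

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
    "BR": 79.904, "I": 126.904, "SE": 78.971,
}

_TWO_LETTER = {"NA", "MG", "CL", "BR", "FE", "ZN", "SE"}

_DEFAULT_MASS = 12.011  # fall back to carbon for unrecognized names


def guess_element(atom_name: str) -> str:
    """Best-effort element symbol from a PDB-style atom name."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not stripped:
        return ""
    if stripped[:2] in _TWO_LETTER and stripped[:2] == stripped:
        return stripped[:2]
    return stripped[0]


def mass_of_atom(atom_name: str, mass_overrides: dict[str, float] | None = None) -> float:
    if mass_overrides and atom_name in mass_overrides:
        return float(mass_overrides[atom_name])
    elem = guess_element(atom_name)
    if elem in ELEMENT_MASSES:
        return ELEMENT_MASSES[elem]
    warnings.warn(f"unknown element for atom {atom_name!r}; using carbon mass")
    return _DEFAULT_MASS


# ---------------------------------------------------------------------------
# PDB / DCD via MDAnalysis
# ---------------------------------------------------------------------------


def _system_from_universe(u, mass_overrides: dict[str, float] | None) -> MolecularSystem:
    atoms = u.atoms
    n_res = len(u.residues)

    # chain name: segid if set, otherwise chainID, otherwise a placeholder
    res_chain_names = []
    for res in u.residues:
        segid = str(getattr(res.atoms[0], "segid", "") or "").strip()
        chain = str(getattr(res.atoms[0], "chainID", "") or "").strip()
        res_chain_names.append(segid or chain or "A")
    chain_names: list[str] = []
    res_chain = np.empty(n_res, dtype=np.intp)
    seen: dict[str, int] = {}
    for i, name in enumerate(res_chain_names):
        if name not in seen:
            seen[name] = len(chain_names)
            chain_names.append(name)
        res_chain[i] = seen[name]

    atom_names = np.array([str(a.name) for a in atoms], dtype=object)
    masses = np.array([mass_of_atom(str(a.name), mass_overrides) for a in atoms])
    return MolecularSystem(
        chain_names=chain_names,
        residue_names=np.array([str(r.resname) for r in u.residues], dtype=object),
        residue_chain=res_chain,
        residue_ids=np.array([int(r.resid) for r in u.residues]),
        atom_names=atom_names,
        atom_masses=masses,
        atom_residue=atoms.resindices.astype(np.intp),
    )


def _cell_from_dimensions(dimensions) -> np.ndarray | None:
    from MDAnalysis.lib.mdamath import triclinic_vectors

    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        return None
    return np.asarray(triclinic_vectors(dimensions), dtype=float)


def load_system(pdb_path, mass_overrides: dict[str, float] | None = None) -> MolecularSystem:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))
    return _system_from_universe(u, mass_overrides)


def load_trajectory(
    pdb_path,
    dcd_path=None,
    mass_overrides: dict[str, float] | None = None,
    cell: UnitCell | None = None,
) -> Trajectory:
    """Read a topology (PDB) plus optional coordinate trajectory (DCD).

    Without a DCD the PDB's own coordinates form a single-frame trajectory.
    ``cell`` overrides the unit cell stored in the files (required when the
    files carry none).
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path)) if dcd_path is None else mda.Universe(
            str(pdb_path), str(dcd_path)
        )
    system = _system_from_universe(u, mass_overrides)

    frames = []
    cells = []
    for ts in u.trajectory:
        frames.append(u.atoms.positions.astype(float).copy())
        vec = _cell_from_dimensions(ts.dimensions)
        if vec is None:
            if cell is None:
                raise ValueError("trajectory has no unit cell; pass cell=...")
            vec = cell.vectors
        cells.append(vec)
    return Trajectory(system, np.asarray(frames), np.asarray(cells))


def _universe_from_trajectory(traj: Trajectory):
    import MDAnalysis as mda
    from MDAnalysis.lib.mdamath import triclinic_box

    sys_ = traj.system
    u = mda.Universe.empty(
        sys_.n_atoms,
        n_residues=sys_.n_residues,
        n_segments=sys_.n_chains,
        atom_resindex=sys_.atom_residue,
        residue_segindex=sys_.residue_chain,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(sys_.atom_names))
    u.add_TopologyAttr("resnames", list(sys_.residue_names))
    u.add_TopologyAttr("resids", list(sys_.residue_ids))
    u.add_TopologyAttr("segids", list(sys_.chain_names))
    u.add_TopologyAttr("chainIDs", [sys_.chain_names[c][0] for c in sys_.atom_chain])
    u.add_TopologyAttr("masses", sys_.atom_masses)
    u.add_TopologyAttr("occupancies", np.ones(sys_.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(sys_.n_atoms))
    u.atoms.positions = traj.coords[0]
    u.dimensions = triclinic_box(*traj.cells[0])
    return u


def save_trajectory(traj: Trajectory, pdb_path=None, dcd_path=None) -> None:
    """Write frame 0 as PDB (topology) and all frames as DCD."""
    import MDAnalysis as mda
    from MDAnalysis.lib.mdamath import triclinic_box

    u = _universe_from_trajectory(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if pdb_path is not None:
            u.atoms.write(str(pdb_path))
        if dcd_path is not None:
            with mda.Writer(str(dcd_path), n_atoms=traj.n_atoms) as w:
                for f in range(traj.n_frames):
                    u.atoms.positions = traj.coords[f]
                    u.dimensions = triclinic_box(*traj.cells[f])
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# CCP4/MRC density maps via gemmi
# ---------------------------------------------------------------------------


def write_ccp4(density_map, path) -> None:
    """Write a DensityMap to CCP4/MRC; the origin goes into MRC2014 words 50-52."""
    import gemmi

    values = np.ascontiguousarray(density_map.values, dtype=np.float32)
    nx, ny, nz = values.shape
    sp = float(density_map.spacing)
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid, dtype=np.float32)[...] = values
    grid.set_unit_cell(gemmi.UnitCell(nx * sp, ny * sp, nz * sp, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, word in enumerate((50, 51, 52)):
        m.set_header_float(word, float(density_map.origin[i]))
    m.write_ccp4_map(str(path))


def read_ccp4(path):
    """Read a CCP4/MRC map back into a DensityMap."""
    import gemmi

    from .density import DensityMap

    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, dtype=float)
    nx = values.shape[0]
    spacing = m.grid.unit_cell.a / nx
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    return DensityMap(origin=origin, spacing=spacing, values=values)
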