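"""Periodic-boundary handling: extend to neighboring cells, wrap, translate.

The analysis pipeline never computes minimum-image distances.  Instead the
system is replicated into the neighboring unit cells of interest before any
other step, and boolean residue flags mark the (usually central-cell) lipids
whose tilts and splays are to be collected.  Replicated chains are renamed
with an integer suffix (``M`` -> ``M1``, ``M2``, ...), and all flags on
replicas are cleared.

Non-orthogonal cells are handled through fractional coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MolecularSystem, Trajectory

__all__ = [
    "ExtensionSpec",
    "extend_trajectory",
    "wrap_trajectory",
    "translate_frames",
]


@dataclass(frozen=True)
class ExtensionSpec:
    """Which neighboring cells to add, and the multipliers for the new cell.

    ``shifts`` are integer triplets (combinations of the cell vectors); the
    original cell ``(0, 0, 0)`` is implicit and must not be listed.
    ``multipliers`` scale the three cell vectors of the extended trajectory.
    """

    shifts: tuple[tuple[int, int, int], ...]
    multipliers: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        shifts = tuple(tuple(int(x) for x in s) for s in self.shifts)
        object.__setattr__(self, "shifts", shifts)
        mult = tuple(int(m) for m in self.multipliers)
        object.__setattr__(self, "multipliers", mult)
        if any(s == (0, 0, 0) for s in shifts):
            raise ValueError("shift (0,0,0) would duplicate the original cell")
        if len(set(shifts)) != len(shifts):
            raise ValueError("duplicate shifts")
        if any(m < 1 for m in mult):
            raise ValueError("multipliers must be >= 1")


def _replica_chain_names(original: list[str], n_shifts: int) -> list[str]:
    names = list(original)
    used = set(names)
    for k in range(1, n_shifts + 1):
        for cn in original:
            candidate = f"{cn}{k}"
            suffix = k
            while candidate in used:  # collision: take the next free integer
                suffix += 1
                candidate = f"{cn}{suffix}"
            used.add(candidate)
            names.append(candidate)
    return names


def extend_trajectory(traj: Trajectory, spec: ExtensionSpec) -> Trajectory:
    """Replicate the system into the neighboring cells given by ``spec``.

    The output holds the original atoms followed by one translated replica
    per shift; the atom count is multiplied by ``1 + len(shifts)`` exactly.
    Output cell vectors are the input vectors scaled by the multipliers.
    """
    sys_ = traj.system
    n_shifts = len(spec.shifts)
    chain_names = _replica_chain_names(sys_.chain_names, n_shifts)

    reps = 1 + n_shifts
    residue_names = np.tile(sys_.residue_names, reps)
    residue_ids = np.tile(sys_.residue_ids, reps)
    residue_chain = np.concatenate(
        [sys_.residue_chain + k * sys_.n_chains for k in range(reps)]
    )
    atom_names = np.tile(sys_.atom_names, reps)
    atom_masses = np.tile(sys_.atom_masses, reps)
    atom_residue = np.concatenate(
        [sys_.atom_residue + k * sys_.n_residues for k in range(reps)]
    )
    flags = {
        name: np.concatenate([arr, np.zeros(n_shifts * sys_.n_residues, dtype=bool)])
        for name, arr in sys_.flags.items()
    }
    new_system = MolecularSystem(
        chain_names, residue_names, residue_chain, residue_ids,
        atom_names, atom_masses, atom_residue, flags,
    )

    shifts = np.asarray(spec.shifts, dtype=float)  # (K, 3)
    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    coords = np.empty((n_frames, n_atoms * reps, 3))
    for f in range(n_frames):
        offsets = shifts @ traj.cells[f] if n_shifts else np.zeros((0, 3))
        coords[f, :n_atoms] = traj.coords[f]
        for k in range(n_shifts):
            block = slice((k + 1) * n_atoms, (k + 2) * n_atoms)
            coords[f, block] = traj.coords[f] + offsets[k]
    mult = np.asarray(spec.multipliers, dtype=float)
    cells = traj.cells * mult[None, :, None]
    return Trajectory(new_system, coords, cells)


def wrap_trajectory(
    traj: Trajectory,
    centers: np.ndarray,
    group_by_residue: bool = False,
) -> Trajectory:
    """Wrap every frame into the unit cell centered on that frame's center.

    With ``group_by_residue`` each residue is shifted as a whole (by the
    lattice shift of its center of mass), so residues are kept intact across
    the boundary.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (traj.n_frames, 3):
        raise ValueError("need one 3-vector center per frame")
    sys_ = traj.system
    coords = traj.coords.copy()
    for f in range(traj.n_frames):
        H = traj.cells[f].T  # columns are cell vectors
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise ValueError("non-invertible unit cell") from exc
        if group_by_residue:
            m = sys_.atom_masses
            mx = coords[f] * m[:, None]
            tot = np.zeros((sys_.n_residues, 3))
            np.add.at(tot, sys_.atom_residue, mx)
            msum = np.zeros(sys_.n_residues)
            np.add.at(msum, sys_.atom_residue, m)
            com = tot / msum[:, None]
            frac = (com - centers[f]) @ Hinv.T
            lattice = np.round(frac)
            coords[f] -= (lattice @ H.T)[sys_.atom_residue]
        else:
            frac = (coords[f] - centers[f]) @ Hinv.T
            lattice = np.round(frac)
            coords[f] -= lattice @ H.T
    return Trajectory(sys_, coords, traj.cells.copy())


def translate_frames(traj: Trajectory, offsets: np.ndarray) -> Trajectory:
    """Shift every frame by its own 3-vector offset (rigid translation)."""
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (traj.n_frames, 3):
        raise ValueError("need one 3-vector offset per frame")
    return Trajectory(traj.system, traj.coords + offsets[:, None, :], traj.cells.copy())
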