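"""Core domain types: unit cells, molecular systems, trajectories, selections.

The in-memory model is deliberately flat: atoms, residues and chains are
parallel numpy arrays on :class:`MolecularSystem`, and a
:class:`Trajectory` is a ``(n_frames, n_atoms, 3)`` coordinate array plus a
(possibly per-frame) unit cell.  Boolean analysis flags (``do_tilt`` /
``do_splay``) live on residues: whether a lipid participates in the
tilt/splay statistics is a property of the whole molecule, not of
individual atoms.

Coordinates are in Å throughout, axes are right-handed, and nothing is
wrapped implicitly on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionError",
    "UnitCell",
    "MolecularSystem",
    "Trajectory",
    "SelectionExpression",
    "LipidDefinitions",
    "select_atoms",
    "center_of_mass",
]


class SelectionError(ValueError):
    """Raised for malformed or invalid selection expressions."""


@dataclass(frozen=True)
class UnitCell:
    """Periodic unit cell given by three cell vectors (rows of ``vectors``, Å)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"cell vectors must be (3, 3), got {v.shape}")
        if abs(np.linalg.det(v)) < 1e-12:
            raise ValueError("cell vectors are linearly dependent (volume = 0)")
        object.__setattr__(self, "vectors", v)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with the cell vectors as columns (x = H @ frac)."""
        return self.vectors.T

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    @classmethod
    def orthorhombic(cls, lx: float, ly: float, lz: float) -> "UnitCell":
        return cls(np.diag([float(lx), float(ly), float(lz)]))


class MolecularSystem:
    """Topology: chains, residues and atoms with masses and residue flags.

    Atoms must be grouped contiguously by residue and residues are indexed in
    topology order.  ``flags`` maps a flag name to a per-residue boolean
    array; missing flags default to all-``False``.
    """

    def __init__(
        self,
        chain_names: list[str],
        residue_names: np.ndarray,
        residue_chain: np.ndarray,
        residue_ids: np.ndarray,
        atom_names: np.ndarray,
        atom_masses: np.ndarray,
        atom_residue: np.ndarray,
        flags: dict[str, np.ndarray] | None = None,
    ) -> None:
        self.chain_names = list(chain_names)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_chain = np.asarray(residue_chain, dtype=np.intp)
        self.residue_ids = np.asarray(residue_ids, dtype=np.intp)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.atom_masses = np.asarray(atom_masses, dtype=float)
        self.atom_residue = np.asarray(atom_residue, dtype=np.intp)
        self.flags = {k: np.asarray(v, dtype=bool) for k, v in (flags or {}).items()}
        self._validate()

    def _validate(self) -> None:
        n_res = len(self.residue_names)
        if len(self.residue_chain) != n_res or len(self.residue_ids) != n_res:
            raise ValueError("residue arrays must have equal length")
        if self.residue_chain.size and (
            self.residue_chain.min() < 0 or self.residue_chain.max() >= len(self.chain_names)
        ):
            raise ValueError("residue_chain index out of range")
        n_atoms = len(self.atom_names)
        if len(self.atom_masses) != n_atoms or len(self.atom_residue) != n_atoms:
            raise ValueError("atom arrays must have equal length")
        if n_atoms and (self.atom_residue.min() < 0 or self.atom_residue.max() >= n_res):
            raise ValueError("atom_residue index out of range")
        if np.any(np.diff(self.atom_residue) < 0):
            raise ValueError("atoms must be grouped contiguously by residue")
        if np.any(self.atom_masses <= 0):
            raise ValueError("atom masses must be > 0")
        for name, arr in self.flags.items():
            if arr.shape != (n_res,):
                raise ValueError(f"flag {name!r} must be per-residue boolean array")

    # -- sizes ---------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_chains(self) -> int:
        return len(self.chain_names)

    # -- derived lookups -----------------------------------------------------
    @property
    def atom_chain(self) -> np.ndarray:
        """Per-atom chain index."""
        return self.residue_chain[self.atom_residue]

    def residue_atom_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, stop) atom index per residue (atoms are residue-contiguous)."""
        starts = np.searchsorted(self.atom_residue, np.arange(self.n_residues), side="left")
        stops = np.searchsorted(self.atom_residue, np.arange(self.n_residues), side="right")
        return starts, stops

    # -- flags ---------------------------------------------------------------
    def get_flag(self, name: str) -> np.ndarray:
        if name in self.flags:
            return self.flags[name]
        return np.zeros(self.n_residues, dtype=bool)

    def set_flag(self, name: str, residue_mask: np.ndarray) -> None:
        mask = np.asarray(residue_mask, dtype=bool)
        if mask.shape != (self.n_residues,):
            raise ValueError("flag mask must be per-residue")
        self.flags[name] = mask.copy()

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            list(self.chain_names),
            self.residue_names.copy(),
            self.residue_chain.copy(),
            self.residue_ids.copy(),
            self.atom_names.copy(),
            self.atom_masses.copy(),
            self.atom_residue.copy(),
            {k: v.copy() for k, v in self.flags.items()},
        )


class Trajectory:
    """A molecular system plus per-frame coordinates and unit cell(s).

    ``cells`` is stored as an ``(n_frames, 3, 3)`` array of cell vectors; a
    single :class:`UnitCell` passed to the constructor is broadcast to all
    frames.
    """

    def __init__(
        self,
        system: MolecularSystem,
        coords: np.ndarray,
        cell: "UnitCell | np.ndarray",
    ) -> None:
        self.system = system
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if coords.shape[1] != system.n_atoms:
            raise ValueError("coords second axis must equal the atom count")
        self.coords = coords
        if isinstance(cell, UnitCell):
            cells = np.broadcast_to(cell.vectors, (coords.shape[0], 3, 3)).copy()
        else:
            cells = np.asarray(cell, dtype=float)
            if cells.shape == (3, 3):
                cells = np.broadcast_to(cells, (coords.shape[0], 3, 3)).copy()
            if cells.shape != (coords.shape[0], 3, 3):
                raise ValueError("cells must be (n_frames, 3, 3)")
        self.cells = cells

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def cell(self, frame: int = 0) -> UnitCell:
        return UnitCell(self.cells[frame])

    def copy(self) -> "Trajectory":
        return Trajectory(self.system.copy(), self.coords.copy(), self.cells.copy())


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^\s*(cname|rname|aname)\s*=\s*(.+?)\s*$")


@dataclass(frozen=True)
class SelectionExpression:
    """Minimal selection dialect: conjunction of chain / residue / atom names.

    String form: ``"rname=DPPC and aname=P,C2"`` or ``"cname=M"``.  Only
    name-membership conjunctions are supported; ``None`` for a field means
    "no constraint".
    """

    chain_names: frozenset[str] | None = None
    residue_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None

    @classmethod
    def parse(cls, text: str) -> "SelectionExpression":
        fields: dict[str, frozenset[str]] = {}
        for token in text.split(" and "):
            m = _TOKEN_RE.match(token)
            if m is None:
                raise SelectionError(f"cannot parse selection token {token!r}")
            key, values = m.groups()
            names = frozenset(v.strip() for v in values.split(",") if v.strip())
            if not names:
                raise SelectionError(f"empty name list in token {token!r}")
            attr = {"cname": "chain_names", "rname": "residue_names", "aname": "atom_names"}[key]
            if attr in fields:
                raise SelectionError(f"duplicate {key!r} constraint")
            fields[attr] = names
        if not fields:
            raise SelectionError("empty selection expression")
        return cls(**fields)

    def atom_mask(self, system: MolecularSystem) -> np.ndarray:
        mask = np.ones(system.n_atoms, dtype=bool)
        if self.chain_names is not None:
            chain_ok = np.array([c in self.chain_names for c in system.chain_names])
            mask &= chain_ok[system.atom_chain]
        if self.residue_names is not None:
            res_ok = np.isin(system.residue_names, list(self.residue_names))
            mask &= res_ok[system.atom_residue]
        if self.atom_names is not None:
            mask &= np.isin(system.atom_names, list(self.atom_names))
        return mask


def _as_expression(expr: "SelectionExpression | str") -> SelectionExpression:
    if isinstance(expr, SelectionExpression):
        return expr
    return SelectionExpression.parse(expr)


def select_atoms(system: MolecularSystem, expr: "SelectionExpression | str") -> np.ndarray:
    """Indices (topology order) of atoms matching ``expr``.

    An empty result is returned as an empty array, not raised.
    """
    return np.flatnonzero(_as_expression(expr).atom_mask(system))


def center_of_mass(
    system: MolecularSystem, atom_indices: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms in one frame."""
    idx = np.asarray(atom_indices, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("center of mass of an empty selection")
    m = system.atom_masses[idx]
    return (m[:, None] * positions[idx]).sum(axis=0) / m.sum()


@dataclass(frozen=True)
class LipidDefinitions:
    """Per-species selections for headgroup, tail and distance sites.

    Mirrors the dictionary interface used to declare lipids: one entry per
    species (residue name) in each of the three mappings, plus the residue
    names forming the solvent.
    """

    species: tuple[str, ...]
    head_group: dict[str, SelectionExpression] = field(default_factory=dict)
    tail: dict[str, SelectionExpression] = field(default_factory=dict)
    distance: dict[str, SelectionExpression] = field(default_factory=dict)
    solvent_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "solvent_names", tuple(self.solvent_names))
        for label, mapping in (
            ("head_group", self.head_group),
            ("tail", self.tail),
            ("distance", self.distance),
        ):
            parsed = {
                sp: (_as_expression(sel)) for sp, sel in mapping.items()
            }
            object.__setattr__(self, label, parsed)
            missing = [sp for sp in self.species if sp not in parsed]
            if missing:
                raise ValueError(f"{label} mapping is missing species {missing}")

    def solvent_selection(self) -> SelectionExpression:
        if not self.solvent_names:
            raise ValueError("no solvent residue names defined")
        return SelectionExpression(residue_names=frozenset(self.solvent_names))

    def lipid_selection(self) -> SelectionExpression:
        return SelectionExpression(residue_names=frozenset(self.species))
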