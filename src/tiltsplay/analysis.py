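"""Lipid directors, tilt angles and finite-difference splays.

The director of a lipid is the unit vector from the center of mass of its
tail selection to the center of mass of its headgroup selection.  The tilt
of a lipid in a frame is the angle between its director and the normal of
the interface point nearest to its headgroup, folded to [0, pi/2] via
theta = arccos(|n . N|): with solvent-oriented normals the directors of the
opposite leaflet anti-align with the normal field, and folding makes the
estimator leaflet-agnostic.

The splay of a pair of nearby lipids is the finite-difference directional
derivative combining director and normal differences,

    S = [ (n2 - n1) . e + (N2 - N1) . e ] / h ,

where e is the unit vector from lipid 1 toward lipid 2 orthogonalized
against N1, and h is the in-plane (tangential) distance between the two
lipids' distance sites.  The step of the finite difference is tangential, so
h is the tangential distance; the pair cutoff is applied to the full 3-D
distance between distance sites (which keeps leaflets apart on bilayers).
Pairs contribute when at least one member carries the ``do_splay`` flag, so
central-cell lipids keep their pairs with extended-cell replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    LipidDefinitions,
    MolecularSystem,
    SelectionExpression,
    Trajectory,
)
from .interface import InterfaceSurface, nearest_surface_points

__all__ = [
    "TiltSamples",
    "SplaySamples",
    "compute_director",
    "compute_tilt",
    "compute_splay",
    "analyze_tilts",
    "analyze_splays",
    "analyze_area_per_lipid",
    "partition_flags",
    "leaflet_masks",
]


@dataclass
class TiltSamples:
    """Per-species collection of tilt observations (columnar storage)."""

    species: str
    lipid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    frame: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    surface_point: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __len__(self) -> int:
        return self.theta.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame,
                "lipid": self.lipid,
                "species": self.species,
                "theta": self.theta,
                "surface_point": self.surface_point,
            }
        )


@dataclass
class SplaySamples:
    """Per species-pair collection of splay observations (columnar storage)."""

    species_pair: tuple[str, str]
    lipid_1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    lipid_2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    frame: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    splay: np.ndarray = field(default_factory=lambda: np.empty(0))
    h: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return self.splay.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame,
                "lipid_1": self.lipid_1,
                "lipid_2": self.lipid_2,
                "species_1": self.species_pair[0],
                "species_2": self.species_pair[1],
                "splay": self.splay,
                "h": self.h,
            }
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def compute_director(head_com: np.ndarray, tail_com: np.ndarray) -> np.ndarray:
    """Unit vector from the tail site to the head site."""
    d = np.asarray(head_com, dtype=float) - np.asarray(tail_com, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("head and tail sites coincide")
    return d / norm


def compute_tilt(director: np.ndarray, normal: np.ndarray) -> float:
    """Tilt angle in [0, pi/2]: arccos(|director . normal|)."""
    c = abs(float(np.dot(director, normal)))
    return float(np.arccos(np.clip(c, 0.0, 1.0)))


def compute_splay(
    n1: np.ndarray,
    n2: np.ndarray,
    N1: np.ndarray,
    N2: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    normal_term_sign: float = 1.0,
) -> tuple[float, float] | None:
    """Finite-difference splay for one lipid pair; returns (S, h).

    Returns ``None`` when the inter-lipid vector has no tangential component
    (p2 - p1 parallel to N1).  ``normal_term_sign`` switches between the
    printed "+" combination of the normal difference (default) and the "-"
    variant corresponding to the derivative of (n - N).
    """
    dp = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    tangential = dp - np.dot(dp, N1) * np.asarray(N1, dtype=float)
    h = float(np.linalg.norm(tangential))
    if h < 1e-10:
        return None
    e = tangential / h
    s = (np.dot(np.asarray(n2) - np.asarray(n1), e)
         + normal_term_sign * np.dot(np.asarray(N2) - np.asarray(N1), e)) / h
    return float(s), h


# ---------------------------------------------------------------------------
# per-species site machinery
# ---------------------------------------------------------------------------


class _SpeciesSites:
    """Atom-index matrices and mass weights for one species' site selection."""

    def __init__(
        self,
        system: MolecularSystem,
        species: str,
        expr: SelectionExpression,
        residues: np.ndarray,
        label: str,
    ) -> None:
        starts, stops = system.residue_atom_bounds()
        rows = []
        for r in residues:
            atoms = np.arange(starts[r], stops[r])
            names = system.atom_names[atoms]
            sel = atoms[np.isin(names, list(expr.atom_names))] if expr.atom_names \
                else atoms
            if sel.size == 0:
                raise ValueError(
                    f"{label} selection matches no atoms in a residue of species {species!r}"
                )
            rows.append(sel)
        counts = {len(r) for r in rows}
        if len(counts) == 1:
            self.idx = np.asarray(rows, dtype=np.intp)  # (n_res, k)
            m = system.atom_masses[self.idx]
            self.weights = m / m.sum(axis=1, keepdims=True)
            self._ragged = None
        else:  # unequal atom counts across residues: ragged fallback
            self.idx = None
            self.weights = None
            self._ragged = [(r, system.atom_masses[r]) for r in rows]

    def coms(self, positions: np.ndarray) -> np.ndarray:
        if self.idx is not None:
            return np.einsum("rk,rkd->rd", self.weights, positions[self.idx])
        out = np.empty((len(self._ragged), 3))
        for i, (atoms, m) in enumerate(self._ragged):
            out[i] = (m[:, None] * positions[atoms]).sum(axis=0) / m.sum()
        return out


class _LipidTable:
    """Per-species flagged residues and their head/tail/distance sites."""

    def __init__(
        self,
        system: MolecularSystem,
        defs: LipidDefinitions,
        flag: str,
        require_flag: bool,
    ) -> None:
        flag_arr = system.get_flag(flag)
        self.entries: dict[str, dict] = {}
        for sp in defs.species:
            res = np.flatnonzero(system.residue_names == sp)
            if require_flag:
                res = res[flag_arr[res]]
            if res.size == 0:
                continue
            for label, mapping in (
                ("head", defs.head_group),
                ("tail", defs.tail),
                ("distance", defs.distance),
            ):
                if sp not in mapping:
                    raise ValueError(f"species {sp!r} missing from {label} mapping")
            self.entries[sp] = {
                "residues": res,
                "flagged": flag_arr[res],
                "head": _SpeciesSites(system, sp, defs.head_group[sp], res, "head_group"),
                "tail": _SpeciesSites(system, sp, defs.tail[sp], res, "tail"),
                "distance": _SpeciesSites(system, sp, defs.distance[sp], res, "distance"),
            }


def _directors(head_coms: np.ndarray, tail_coms: np.ndarray) -> np.ndarray:
    d = head_coms - tail_coms
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("head and tail sites coincide for some lipid")
    return d / norms[:, None]


# ---------------------------------------------------------------------------
# trajectory-level analyses
# ---------------------------------------------------------------------------


def analyze_tilts(
    traj: Trajectory,
    defs: LipidDefinitions,
    surface: InterfaceSurface,
    flag: str = "do_tilt",
    frames: np.ndarray | None = None,
) -> dict[str, TiltSamples]:
    """Tilt samples for every flagged lipid in every frame, keyed by species."""
    if surface.normals is None:
        raise ValueError("surface has no normals; run compute_normals first")
    table = _LipidTable(traj.system, defs, flag, require_flag=True)
    if frames is None:
        frames = np.arange(traj.n_frames)
    out: dict[str, TiltSamples] = {}
    for sp, entry in table.entries.items():
        lip_all, frm_all, th_all, pt_all = [], [], [], []
        for f in frames:
            pos = traj.coords[f]
            heads = entry["head"].coms(pos)
            tails = entry["tail"].coms(pos)
            directors = _directors(heads, tails)
            nearest = nearest_surface_points(surface, heads)
            normals = surface.normals[nearest]
            cosines = np.abs(np.einsum("ij,ij->i", directors, normals))
            theta = np.arccos(np.clip(cosines, 0.0, 1.0))
            lip_all.append(entry["residues"])
            frm_all.append(np.full(len(theta), f, dtype=np.intp))
            th_all.append(theta)
            pt_all.append(nearest)
        out[sp] = TiltSamples(
            species=sp,
            lipid=np.concatenate(lip_all),
            frame=np.concatenate(frm_all),
            theta=np.concatenate(th_all),
            surface_point=np.concatenate(pt_all),
        )
    return out


def analyze_splays(
    traj: Trajectory,
    defs: LipidDefinitions,
    surface: InterfaceSurface,
    flag: str = "do_splay",
    cutoff: float = 10.0,
    frames: np.ndarray | None = None,
    normal_term_sign: float = 1.0,
) -> dict[tuple[str, str], SplaySamples]:
    """Splay samples for nearby lipid pairs, keyed by unordered species pair.

    A pair enters when the 3-D distance between the two distance sites is
    below ``cutoff`` and at least one member carries the flag.  Pairs whose
    separation is parallel to the local normal are skipped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if surface.normals is None:
        raise ValueError("surface has no normals; run compute_normals first")
    table = _LipidTable(traj.system, defs, flag, require_flag=False)
    if frames is None:
        frames = np.arange(traj.n_frames)

    species_list = list(table.entries)
    # concatenated arrays across species, fixed order
    res_concat = np.concatenate([table.entries[sp]["residues"] for sp in species_list])
    sp_index = np.concatenate(
        [np.full(len(table.entries[sp]["residues"]), i, dtype=np.intp)
         for i, sp in enumerate(species_list)]
    )
    flagged = np.concatenate([table.entries[sp]["flagged"] for sp in species_list])

    acc: dict[tuple[str, str], dict[str, list]] = {}
    for f in frames:
        pos = traj.coords[f]
        heads = np.concatenate([table.entries[sp]["head"].coms(pos) for sp in species_list])
        tails = np.concatenate([table.entries[sp]["tail"].coms(pos) for sp in species_list])
        dists = np.concatenate(
            [table.entries[sp]["distance"].coms(pos) for sp in species_list]
        )
        directors = _directors(heads, tails)
        nearest = nearest_surface_points(surface, heads)
        normals = surface.normals[nearest]

        pairs = cKDTree(dists).query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            continue
        use = flagged[pairs[:, 0]] | flagged[pairs[:, 1]]
        pairs = pairs[use]
        if pairs.size == 0:
            continue
        i1, i2 = pairs[:, 0], pairs[:, 1]
        dp = dists[i2] - dists[i1]
        N1 = normals[i1]
        tang = dp - np.einsum("ij,ij->i", dp, N1)[:, None] * N1
        h = np.linalg.norm(tang, axis=1)
        ok = h > 1e-10
        i1, i2, tang, h, N1 = i1[ok], i2[ok], tang[ok], h[ok], N1[ok]
        e = tang / h[:, None]
        dn = directors[i2] - directors[i1]
        dN = normals[i2] - N1
        s = (np.einsum("ij,ij->i", dn, e)
             + normal_term_sign * np.einsum("ij,ij->i", dN, e)) / h

        key_i = np.minimum(sp_index[i1], sp_index[i2])
        key_j = np.maximum(sp_index[i1], sp_index[i2])
        for a in range(len(species_list)):
            for b in range(a, len(species_list)):
                sel = (key_i == a) & (key_j == b)
                if not np.any(sel):
                    continue
                key = (species_list[a], species_list[b])
                bucket = acc.setdefault(
                    key, {"l1": [], "l2": [], "frame": [], "s": [], "h": []}
                )
                bucket["l1"].append(res_concat[i1[sel]])
                bucket["l2"].append(res_concat[i2[sel]])
                bucket["frame"].append(np.full(int(sel.sum()), f, dtype=np.intp))
                bucket["s"].append(s[sel])
                bucket["h"].append(h[sel])

    out: dict[tuple[str, str], SplaySamples] = {}
    for key, b in acc.items():
        out[key] = SplaySamples(
            species_pair=key,
            lipid_1=np.concatenate(b["l1"]),
            lipid_2=np.concatenate(b["l2"]),
            frame=np.concatenate(b["frame"]),
            splay=np.concatenate(b["s"]),
            h=np.concatenate(b["h"]),
        )
    return out


def analyze_area_per_lipid(
    traj: Trajectory,
    lipids_per_leaflet: int,
    plane: str = "xy",
) -> float:
    """Area per lipid: in-plane cell cross-section / lipids per leaflet, frame-averaged.

    Assumes a planar system; the membrane plane defaults to xy.
    """
    if lipids_per_leaflet <= 0:
        raise ValueError("need at least one lipid per leaflet")
    axes = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    areas = []
    for f in range(traj.n_frames):
        a = traj.cells[f][axes[0]][list(axes)]
        b = traj.cells[f][axes[1]][list(axes)]
        areas.append(abs(a[0] * b[1] - a[1] * b[0]))
    return float(np.mean(areas)) / lipids_per_leaflet


def leaflet_masks(
    traj: Trajectory,
    defs: LipidDefinitions,
    frame: int = 0,
    axis: int = 2,
) -> dict[str, np.ndarray]:
    """Residue masks splitting lipids into upper/lower leaflets.

    Uses the headgroup center of mass in one frame relative to the lipid
    midplane (mean head position along ``axis``).
    """
    sys_ = traj.system
    z = np.full(sys_.n_residues, np.nan)
    for sp in defs.species:
        res = np.flatnonzero(sys_.residue_names == sp)
        if res.size == 0:
            continue
        sites = _SpeciesSites(sys_, sp, defs.head_group[sp], res, "head_group")
        z[res] = sites.coms(traj.coords[frame])[:, axis]
    center = np.nanmean(z)
    is_lipid = ~np.isnan(z)
    return {
        "upper": is_lipid & (z > center),
        "lower": is_lipid & (z <= center),
    }


def partition_flags(
    system: MolecularSystem,
    parts: dict[str, "np.ndarray | SelectionExpression | str"],
    flag_names: tuple[str, ...] = ("do_tilt", "do_splay"),
) -> dict[str, MolecularSystem]:
    """One flagged copy of the system per named part, analyzed independently.

    Each part is either a per-residue boolean mask or a selection expression
    (a residue is in the part when it owns at least one matched atom).
    Parts need not cover the system; unmatched lipids are simply ignored.
    """
    out: dict[str, MolecularSystem] = {}
    for name, part in parts.items():
        if isinstance(part, (SelectionExpression, str)):
            expr = part if isinstance(part, SelectionExpression) else SelectionExpression.parse(part)
            atom_mask = expr.atom_mask(system)
            mask = np.zeros(system.n_residues, dtype=bool)
            mask[np.unique(system.atom_residue[atom_mask])] = True
        else:
            mask = np.asarray(part, dtype=bool)
        sys_copy = system.copy()
        for fname in flag_names:
            sys_copy.set_flag(fname, mask)
        out[name] = sys_copy
    return out
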