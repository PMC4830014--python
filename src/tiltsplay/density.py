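"""Gaussian-sum density maps and density-based rigid trajectory alignment.

Each frame of a trajectory is aligned onto a reference frame (frame 0) by
maximizing the overlap of the solvent atoms with the reference solvent
density while minimizing the overlap of the lipid atoms with that same
density.  The density of a set of atoms is a sum of mass-weighted isotropic
Gaussians on a regular grid,

    rho(y) = sum_i C m_i exp(-D ||y - x_i||^2),

with D = 1/(2 s^2), s = resolution/2 and C = (2 pi s^2)^(-3/2), so that each
atom integrates to its mass and the map is directly interpretable as a mass
density.  Gaussians are truncated beyond 3 s (per axis) for efficiency.

The optimizer is a derivative-free local search (Nelder-Mead) over three
intrinsic z-y-x Euler angles and three translations, warm-started from the
previous frame's solution; MD frames are temporally correlated, so a local
search suffices and keeps the procedure deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core import Trajectory, select_atoms

__all__ = [
    "DensityMap",
    "RigidTransform",
    "AlignResult",
    "build_density_map",
    "grid_covering",
    "smooth_density",
    "interpolate_density",
    "alignment_score",
    "align_frame",
    "align_trajectory_on_first_frame",
    "write_transforms",
    "read_transforms",
]


@dataclass
class DensityMap:
    """Regular 3-D scalar grid; ``origin`` is the center of voxel (0,0,0)."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.values.shape[axis])

    def copy(self) -> "DensityMap":
        return DensityMap(self.origin.copy(), self.spacing, self.values.copy())


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be (3,3), translation (3,)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        """Six parameters: intrinsic z-y-x Euler angles (rad) then translation."""
        params = np.asarray(params, dtype=float)
        R = Rotation.from_euler("zyx", params[:3]).as_matrix()
        return cls(R, params[3:6])

    def to_params(self) -> np.ndarray:
        angles = Rotation.from_matrix(self.rotation).as_euler("zyx")
        return np.concatenate([angles, self.translation])

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def grid_covering(
    positions: np.ndarray, margin: float = 5.0, spacing: float = 1.0
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Grid origin and shape covering the bounding box of ``positions`` plus margin."""
    positions = np.asarray(positions, dtype=float)
    lo = positions.min(axis=0) - margin
    hi = positions.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    shape = tuple(int(np.ceil((hi[i] - origin[i]) / spacing)) + 1 for i in range(3))
    return origin, shape


def build_density_map(
    positions: np.ndarray,
    masses: np.ndarray,
    resolution: float = 4.0,
    margin: float = 5.0,
    spacing: float = 1.0,
    grid: tuple[np.ndarray, tuple[int, int, int]] | None = None,
) -> DensityMap:
    """Gaussian-sum mass density of a set of atoms on a regular grid.

    ``resolution`` sets the Gaussian width (sigma = resolution / 2); each
    atom's Gaussian is mass-normalized and truncated at 3 sigma per axis.
    Pass ``grid=(origin, shape)`` to accumulate onto a predefined grid (used
    to put water and lipid maps on a common mesh).
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("need at least one atom")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    sigma = resolution / 2.0
    D = 1.0 / (2.0 * sigma * sigma)
    C = (2.0 * np.pi * sigma * sigma) ** -1.5

    if grid is None:
        origin, shape = grid_covering(positions, margin=margin, spacing=spacing)
    else:
        origin, shape = grid
        origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    values = np.zeros(shape, dtype=float)

    half = int(np.ceil(3.0 * sigma / spacing))  # truncation half-width in voxels
    w = 2 * half + 1
    offs = np.arange(-half, half + 1)

    # nearest voxel per atom
    ijk0 = np.rint((positions - origin) / spacing).astype(np.intp)
    flat = values.ravel()
    chunk = max(1, int(2e6 / w**3))
    for a0 in range(0, positions.shape[0], chunk):
        a1 = min(a0 + chunk, positions.shape[0])
        pos = positions[a0:a1]
        m = masses[a0:a1]
        base = ijk0[a0:a1]  # (n, 3)
        idx = base[:, :, None] + offs[None, None, :]  # (n, 3, w)
        centers = origin[None, :, None] + spacing * idx
        d2 = (centers - pos[:, :, None]) ** 2
        g = np.exp(-D * d2)  # (n, 3, w) separable factors
        # clip out-of-grid voxels by zeroing their weight
        for axis, nax in enumerate((nx, ny, nz)):
            bad = (idx[:, axis, :] < 0) | (idx[:, axis, :] >= nax)
            g[:, axis, :][bad] = 0.0
        idx = np.clip(idx, 0, np.array([nx - 1, ny - 1, nz - 1])[None, :, None])
        contrib = (
            (C * m)[:, None, None, None]
            * g[:, 0, :, None, None]
            * g[:, 1, None, :, None]
            * g[:, 2, None, None, :]
        )
        flat_idx = (
            idx[:, 0, :, None, None] * (ny * nz)
            + idx[:, 1, None, :, None] * nz
            + idx[:, 2, None, None, :]
        )
        np.add.at(flat, flat_idx.ravel(), contrib.ravel())
    return DensityMap(origin=origin, spacing=spacing, values=values)


def smooth_density(density_map: DensityMap, filter_width: float) -> DensityMap:
    """Gaussian low-pass filter of the stated width (sigma, Å); 0 is identity."""
    if filter_width < 0:
        raise ValueError("filter width must be >= 0")
    if filter_width == 0:
        return density_map.copy()
    sigma_vox = filter_width / density_map.spacing
    blurred = ndimage.gaussian_filter(density_map.values, sigma=sigma_vox, mode="constant")
    return DensityMap(density_map.origin.copy(), density_map.spacing, blurred)


def interpolate_density(density_map: DensityMap, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at one or more points; outside the grid -> 0."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = (pts - density_map.origin) / density_map.spacing
    out = ndimage.map_coordinates(
        density_map.values, coords.T, order=1, mode="constant", cval=0.0
    )
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def alignment_score(
    density_map: DensityMap, water_positions: np.ndarray, lipid_positions: np.ndarray
) -> float:
    """Sum of map values at water positions minus sum at lipid positions."""
    score = 0.0
    if len(water_positions):
        score += float(np.sum(interpolate_density(density_map, water_positions)))
    if len(lipid_positions):
        score -= float(np.sum(interpolate_density(density_map, lipid_positions)))
    return score


@dataclass
class AlignResult:
    transform: RigidTransform
    score: float
    converged: bool
    n_evaluations: int = 0


def align_frame(
    density_map: DensityMap,
    water_positions: np.ndarray,
    lipid_positions: np.ndarray,
    initial: RigidTransform | None = None,
    max_iterations: int = 4000,
) -> AlignResult:
    """Find the rigid transform locally maximizing the alignment score.

    Deterministic given its inputs.  On optimizer non-convergence the
    best-found transform is returned with ``converged=False`` and a warning.
    """
    water_positions = np.asarray(water_positions, dtype=float)
    lipid_positions = np.asarray(lipid_positions, dtype=float)
    x0 = (initial or RigidTransform.identity()).to_params()

    def objective(params: np.ndarray) -> float:
        tf = RigidTransform.from_params(params)
        return -alignment_score(
            density_map, tf.apply(water_positions), tf.apply(lipid_positions)
        )

    # initial simplex sized for the problem's natural scales (rad / Å);
    # scipy's default steps are far too small around a near-zero start
    steps = np.array([0.02, 0.02, 0.02, 0.5, 0.5, 0.5])
    simplex = np.vstack([x0, x0 + np.diag(steps)])
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-5,
            "fatol": 1e-4,
            "maxiter": max_iterations,
            "maxfev": max_iterations,
            "initial_simplex": simplex,
        },
    )
    # one polish pass from the found optimum tightens rotation/translation
    res2 = optimize.minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": max_iterations},
    )
    best = res2 if res2.fun <= res.fun else res
    converged = bool(res.success or res2.success)
    if not converged:
        warnings.warn("alignment optimizer did not converge; returning best found")
    return AlignResult(
        transform=RigidTransform.from_params(best.x),
        score=-float(best.fun),
        converged=converged,
        n_evaluations=int(res.nfev + res2.nfev),
    )


def align_trajectory_on_first_frame(
    traj: Trajectory,
    water_selection,
    lipid_selection,
    outdir=None,
    resolution: float = 4.0,
    filter_width: float = 4.0,
    margin: float = 5.0,
    spacing: float = 1.0,
) -> tuple[Trajectory, list[RigidTransform]]:
    """Align every frame onto the solvent density of frame 0.

    Builds the reference solvent map from frame 0, smooths it, then aligns
    frames sequentially, warm-starting each optimization from the previous
    frame's transform.  Returns the aligned trajectory and the per-frame
    transforms (frame 0 gets the identity).  When ``outdir`` is given, the
    reference density (CCP4), aligned trajectory (PDB+DCD) and the transform
    table are written there.
    """
    water_idx = select_atoms(traj.system, water_selection)
    lipid_idx = select_atoms(traj.system, lipid_selection)
    if water_idx.size == 0:
        raise ValueError("empty water selection")

    ref_map = build_density_map(
        traj.coords[0][water_idx],
        traj.system.atom_masses[water_idx],
        resolution=resolution,
        margin=margin,
        spacing=spacing,
    )
    ref_map = smooth_density(ref_map, filter_width)

    transforms: list[RigidTransform] = [RigidTransform.identity()]
    coords = traj.coords.copy()
    previous = RigidTransform.identity()
    for f in range(1, traj.n_frames):
        result = align_frame(
            ref_map, traj.coords[f][water_idx], traj.coords[f][lipid_idx], initial=previous
        )
        transforms.append(result.transform)
        coords[f] = result.transform.apply(traj.coords[f])
        previous = result.transform
    aligned = Trajectory(traj.system, coords, traj.cells.copy())

    if outdir is not None:
        from pathlib import Path

        from .io import save_trajectory, write_ccp4

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ccp4(ref_map, outdir / "reference_solvent_density.ccp4")
        save_trajectory(aligned, outdir / "aligned.pdb", outdir / "aligned.dcd")
        write_transforms(transforms, outdir / "transforms.txt")
    return aligned, transforms


def write_transforms(transforms: list[RigidTransform], path) -> None:
    """Plain-text table: frame index, 9 rotation entries row-major, 3 translations."""
    rows = []
    for f, tf in enumerate(transforms):
        rows.append(
            np.concatenate([[f], tf.rotation.ravel(), tf.translation])
        )
    header = "frame " + " ".join(f"r{i}{j}" for i in range(3) for j in range(3)) + " tx ty tz"
    np.savetxt(str(path), np.asarray(rows), header=header)


def read_transforms(path) -> list[RigidTransform]:
    data = np.atleast_2d(np.loadtxt(str(path)))
    out = []
    for row in data:
        out.append(RigidTransform(row[1:10].reshape(3, 3), row[10:13]))
    return out
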