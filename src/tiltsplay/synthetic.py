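"""Synthetic lipid systems with known elastic ground truth.

Two kinds of inputs are generated, both pure functions of their spec
(seed included):

* direct samplers for the tilt and splay distributions (rejection sampling
  of P(theta) ~ sin(theta) exp(-kappa theta^2/2) and Gaussian splays with
  variance 1/(K_c A_L) in kBT units), used to validate the fitting chain in
  isolation;

* full pseudo-trajectories — a planar two-leaflet bilayer of three-site
  lipids plus water slabs, and a cylindrical (inverted-hexagonal-like) water
  channel surrounded by radially oriented lipids — that exercise every
  pipeline stage (interface extraction, normal field, tilt/splay analysis,
  density alignment) without any external data.

Planar director construction.  Per frame, each leaflet carries a tangential
Gaussian random field t(x) with per-component variance v = 1/kappa_t and
Gaussian spatial covariance C(r) = v exp(-r^2 / 2 ell^2).  The magnitude
|t| (Rayleigh distributed) is pushed through a quantile map so that the
director polar angle follows the target tilt distribution EXACTLY at
kappa_t; the azimuth is the field direction.  The correlation length is set
to ell = sqrt(v K_c A_L) (below the 10 Å pair cutoff for the default
parameters), which makes nearest-neighbor finite-difference splays
approximately Gaussian with variance ~ 1/(K_c A_L).  Because the mapping is
mildly nonlinear and neighbor distances are finite, the generator records a
*calibrated* splay ground truth: a construction-side Monte Carlo over the
frozen pair geometry (using the field's known covariance, never the
analysis code) evaluates the exact pooled splay variance, and
K_c_calibrated = 1 / (A_L Var(S)).  The tilt ground truth is exact by
construction.

The cylindrical lattice carries frozen positional jitter; without it the
tube would be continuously symmetric under rotations about, and
translations along, its axis, and recovering the per-frame rigid transforms
would be ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import LipidDefinitions, MolecularSystem, Trajectory, UnitCell
from .density import RigidTransform

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "sample_tilt_angles",
    "sample_splays",
    "generate_planar_trajectory",
    "generate_cylindrical_trajectory",
    "default_lipid_definitions",
]

LIPID_BEAD_MASS = 72.0
WATER_BEAD_MASS = 18.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic lipid assembly.

    Moduli are in kBT (per monolayer), areas in Å².  ``seed`` fixes all
    randomness.  Planar geometry uses ``lipids_per_leaflet`` / ``A_L`` /
    ``water_thickness``; cylindrical geometry uses ``radius`` /
    ``lipids_per_ring`` / ``ring_spacing`` / ``length`` and the transform
    amplitudes.
    """

    geometry: str = "planar"
    lipids_per_leaflet: int = 200
    n_frames: int = 500
    kappa_t: float = 12.0
    K_c: float = 10.0
    A_L: float = 60.0
    temperature: float = 300.0
    seed: int = 0
    zero_noise: bool = False
    water_thickness: float = 8.0
    water_spacing: float = 3.0
    # cylindrical geometry
    radius: float = 15.0
    lipids_per_ring: int = 20
    ring_spacing: float = 3.0
    length: float = 60.0
    max_rotation_deg: float = 8.0
    max_translation: float = 3.0
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("planar", "cylindrical"):
            raise ValueError("geometry must be 'planar' or 'cylindrical'")
        if min(self.kappa_t, self.K_c, self.A_L) <= 0:
            raise ValueError("moduli and area per lipid must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually built, for comparing recovered moduli."""

    kappa_t: float
    K_c_nominal: float
    K_c_calibrated: float
    A_L: float
    seed: int
    correlation_length: float = 0.0
    interface_z: float | None = None
    interface_radius: float | None = None
    transforms: list[RigidTransform] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "kappa_t_kBT": self.kappa_t,
            "K_c_nominal_kBT": self.K_c_nominal,
            "K_c_calibrated_kBT": self.K_c_calibrated,
            "A_L_A2": self.A_L,
            "seed": self.seed,
            "correlation_length_A": self.correlation_length,
        }
        if self.interface_z is not None:
            d["interface_z_A"] = self.interface_z
        if self.interface_radius is not None:
            d["interface_radius_A"] = self.interface_radius
        if self.transforms:
            d["transforms"] = [
                {"rotation": t.rotation.tolist(), "translation": t.translation.tolist()}
                for t in self.transforms
            ]
        return d


def default_lipid_definitions() -> LipidDefinitions:
    """Selections for the synthetic species: LIP (sites HD/MD/TL), solvent SOL."""
    return LipidDefinitions(
        species=("LIP",),
        head_group={"LIP": "aname=HD"},
        tail={"LIP": "aname=TL"},
        distance={"LIP": "aname=MD"},
        solvent_names=("SOL",),
    )


# ---------------------------------------------------------------------------
# direct samplers
# ---------------------------------------------------------------------------


def sample_tilt_angles(kappa_t: float, n: int, seed: int) -> np.ndarray:
    """n draws of theta from P ~ sin(theta) exp(-kappa theta^2/2) on (0, pi/2].

    Rejection sampling: the proposal is the sin(theta) density (inverse-CDF
    theta = arccos(1 - u)) and the acceptance probability exp(-kappa
    theta^2 / 2).  Deterministic for a given seed.
    """
    if kappa_t <= 0:
        raise ValueError("kappa_t must be > 0")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        batch = max(4 * (n - out.size), 1000)
        theta = np.arccos(1.0 - rng.random(batch))
        accept = rng.random(batch) < np.exp(-0.5 * kappa_t * theta**2)
        out = np.concatenate([out, theta[accept]])
    return out[:n]


def sample_splays(K_c: float, A_L: float, n: int, seed: int) -> np.ndarray:
    """n Gaussian splay draws, mean 0, variance 1/(K_c A_L) (kBT units)."""
    if K_c <= 0 or A_L <= 0:
        raise ValueError("K_c and A_L must be > 0")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(K_c * A_L), n)


# ---------------------------------------------------------------------------
# director-field machinery (planar)
# ---------------------------------------------------------------------------


def _tilt_quantile_map(kappa_t: float, v: float, n_grid: int = 4096):
    """Map |t| (Rayleigh, per-component variance v) -> polar angle with the
    exact target tilt distribution at kappa_t."""
    theta = np.linspace(1e-6, np.pi / 2, n_grid)
    pdf = np.sin(theta) * np.exp(-0.5 * kappa_t * theta**2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]

    def g(r: np.ndarray) -> np.ndarray:
        u = 1.0 - np.exp(-np.asarray(r) ** 2 / (2.0 * v))
        return np.interp(u, cdf, theta)

    return g


def _directors_from_field(tx: np.ndarray, ty: np.ndarray, g, sign: float) -> np.ndarray:
    """Unit directors from tangential field components; ``sign`` is the leaflet
    normal direction (+1 upper, -1 lower; directors point toward the solvent)."""
    r = np.hypot(tx, ty)
    theta = g(r)
    n = np.empty(tx.shape + (3,))
    safe = np.where(r > 1e-300, r, 1.0)
    n[..., 0] = np.sin(theta) * tx / safe
    n[..., 1] = np.sin(theta) * ty / safe
    n[..., 2] = sign * np.cos(theta)
    return n


def _near_square_factors(n: int) -> tuple[int, int]:
    for d in range(int(np.sqrt(n)), 0, -1):
        if n % d == 0:
            return d, n // d
    return 1, n


def _calibrate_splay_variance(
    pair_h: np.ndarray, v: float, ell: float, g, rng: np.random.Generator,
    n_draws: int = 400,
) -> float:
    """Exact (Monte Carlo) pooled splay variance of the director construction
    over the frozen pair geometry; independent of the analysis code."""
    h = np.asarray(pair_h, dtype=float)
    rho = np.exp(-(h**2) / (2.0 * ell**2))[:, None]
    shape = (h.size, n_draws)
    sd = np.sqrt(v)
    a1 = sd * rng.standard_normal(shape)
    b1 = sd * rng.standard_normal(shape)
    mix = np.sqrt(np.maximum(0.0, 1.0 - rho**2))
    a2 = rho * a1 + mix * sd * rng.standard_normal(shape)
    b2 = rho * b1 + mix * sd * rng.standard_normal(shape)
    n1 = _directors_from_field(a1, b1, g, +1.0)
    n2 = _directors_from_field(a2, b2, g, +1.0)
    # e = in-plane unit vector along the pair; WLOG x (the field is isotropic)
    s = (n2[..., 0] - n1[..., 0]) / h[:, None]
    return float(np.mean(s**2))


def generate_planar_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Planar pseudo-bilayer: two leaflets of 3-site lipids plus water slabs.

    Species "LIP" (sites HD / MD / TL, the MD anchor is frozen so the pair
    geometry is constant), solvent "SOL" (site OW).  Directors follow the
    calibrated tangential field construction described in the module
    docstring; with ``zero_noise`` they are exactly +/- z.
    """
    if spec.geometry != "planar":
        raise ValueError("spec.geometry must be 'planar'")
    n_lip = spec.lipids_per_leaflet
    d_lat = np.sqrt(spec.A_L)
    m1, m2 = _near_square_factors(n_lip)
    box_x, box_y = m2 * d_lat, m1 * d_lat
    if m1 < 2 or box_x < 2 * d_lat:
        raise ValueError("box too small for the requested lipid count")

    rng = np.random.default_rng(spec.seed)
    z_mid, head_len, tail_len = 8.0, 6.0, 6.0
    water_lo = z_mid + head_len + 2.0  # 16 Å: slab face, 2 Å above the head plane
    interface_z = 0.5 * (z_mid + head_len + water_lo)  # midpoint head-plane/water-face
    box_z = 2.0 * (water_lo + spec.water_thickness + 4.0)

    # frozen in-plane lattice per leaflet (jittered)
    xy = {}
    for leaflet in (0, 1):
        gx, gy = np.meshgrid(np.arange(m2), np.arange(m1), indexing="ij")
        pos = np.column_stack(
            [(gx.ravel() + 0.5) * d_lat, (gy.ravel() + 0.5) * d_lat]
        )
        pos += rng.uniform(-0.15 * d_lat, 0.15 * d_lat, pos.shape)
        xy[leaflet] = pos - np.array([box_x / 2.0, box_y / 2.0])

    # frozen water slabs
    waters = []
    nwx = max(int(box_x / spec.water_spacing), 1)
    nwy = max(int(box_y / spec.water_spacing), 1)
    nwz = max(int(spec.water_thickness / spec.water_spacing), 1)
    wx, wy, wz = np.meshgrid(
        (np.arange(nwx) + 0.5) * box_x / nwx - box_x / 2.0,
        (np.arange(nwy) + 0.5) * box_y / nwy - box_y / 2.0,
        water_lo + (np.arange(nwz) + 0.5) * spec.water_thickness / nwz,
        indexing="ij",
    )
    slab = np.column_stack([wx.ravel(), wy.ravel(), wz.ravel()])
    slab += rng.uniform(-0.5, 0.5, slab.shape)
    waters = np.vstack([slab, slab * np.array([1.0, 1.0, -1.0])])
    n_wat = waters.shape[0]

    # director field setup
    v = 1.0 / spec.kappa_t
    ell = float(np.sqrt(v * spec.K_c * spec.A_L))
    g = _tilt_quantile_map(spec.kappa_t, v)
    chol = {}
    for leaflet in (0, 1):
        dx = xy[leaflet][:, None, :] - xy[leaflet][None, :, :]
        r2 = np.sum(dx**2, axis=-1)
        K = v * np.exp(-r2 / (2.0 * ell**2)) + 1e-10 * np.eye(n_lip)
        chol[leaflet] = np.linalg.cholesky(K)

    # assemble topology: lipids (chain M) then waters (chain W)
    n_lip_tot = 2 * n_lip
    system = MolecularSystem(
        chain_names=["M", "W"],
        residue_names=np.array(["LIP"] * n_lip_tot + ["SOL"] * n_wat, dtype=object),
        residue_chain=np.array([0] * n_lip_tot + [1] * n_wat),
        residue_ids=np.concatenate([np.arange(1, n_lip_tot + 1), np.arange(1, n_wat + 1)]),
        atom_names=np.array(
            ["HD", "MD", "TL"] * n_lip_tot + ["OW"] * n_wat, dtype=object
        ),
        atom_masses=np.array(
            [LIPID_BEAD_MASS] * (3 * n_lip_tot) + [WATER_BEAD_MASS] * n_wat
        ),
        atom_residue=np.concatenate(
            [np.repeat(np.arange(n_lip_tot), 3), n_lip_tot + np.arange(n_wat)]
        ),
    )
    lipid_mask = np.concatenate(
        [np.ones(n_lip_tot, dtype=bool), np.zeros(n_wat, dtype=bool)]
    )
    system.set_flag("do_tilt", lipid_mask)
    system.set_flag("do_splay", lipid_mask)

    n_atoms = 3 * n_lip_tot + n_wat
    coords = np.empty((spec.n_frames, n_atoms, 3))
    anchors = {
        0: np.column_stack([xy[0], np.full(n_lip, z_mid)]),
        1: np.column_stack([xy[1], np.full(n_lip, -z_mid)]),
    }
    for f in range(spec.n_frames):
        lipid_coords = []
        for leaflet, sign in ((0, 1.0), (1, -1.0)):
            if spec.zero_noise:
                directors = np.tile([0.0, 0.0, sign], (n_lip, 1))
            else:
                tx = chol[leaflet] @ rng.standard_normal(n_lip)
                ty = chol[leaflet] @ rng.standard_normal(n_lip)
                directors = _directors_from_field(tx, ty, g, sign)
            md = anchors[leaflet]
            hd = md + head_len * directors
            tl = md - tail_len * directors
            lipid_coords.append(np.stack([hd, md, tl], axis=1).reshape(-1, 3))
        coords[f, : 3 * n_lip_tot] = np.vstack(lipid_coords)
        coords[f, 3 * n_lip_tot :] = waters

    cell = UnitCell.orthorhombic(box_x, box_y, box_z)
    traj = Trajectory(system, coords, cell)

    # calibrated splay ground truth over the frozen pair geometry
    if spec.zero_noise:
        k_c_cal = float("inf")
    else:
        pair_h = []
        from scipy.spatial import cKDTree

        for leaflet in (0, 1):
            tree = cKDTree(xy[leaflet])
            pairs = tree.query_pairs(10.0, output_type="ndarray")
            dvec = xy[leaflet][pairs[:, 0]] - xy[leaflet][pairs[:, 1]]
            pair_h.append(np.linalg.norm(dvec, axis=1))
        pair_h = np.concatenate(pair_h)
        cal_rng = np.random.default_rng(spec.seed + 777_001)
        var_s = _calibrate_splay_variance(pair_h, v, ell, g, cal_rng)
        k_c_cal = 1.0 / (spec.A_L * var_s)

    truth = GroundTruth(
        kappa_t=spec.kappa_t,
        K_c_nominal=spec.K_c,
        K_c_calibrated=k_c_cal,
        A_L=spec.A_L,
        seed=spec.seed,
        correlation_length=ell,
        interface_z=interface_z,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# cylindrical geometry
# ---------------------------------------------------------------------------


def generate_cylindrical_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Water channel along z surrounded by radially oriented pseudo-lipids.

    Waters fill the cylinder r < radius - 1 on a jittered lattice; lipid
    rings sit outside with heads at radius + 3.5 and tails pointing outward
    (directors point inward, toward the solvent).  Frames 1.. are rigidly
    rotated/translated by known random transforms (frame 0 is the identity);
    the applied transforms are recorded in the ground truth.
    """
    if spec.geometry != "cylindrical":
        raise ValueError("spec.geometry must be 'cylindrical'")
    R = spec.radius
    head_r, mid_r, tail_r = R + 3.5, R + 7.0, R + 10.5
    if spec.box is not None:
        bx, by, bz = spec.box
        if R >= min(bx, by) / 2.0:
            raise ValueError("radius must be smaller than half the box")
    else:
        bx = by = 2.0 * (tail_r + 5.0)
        bz = spec.length

    rng = np.random.default_rng(spec.seed)

    # jittered water lattice inside the cylinder
    sp_w = spec.water_spacing
    n_side = int(np.floor(2.0 * R / sp_w))
    ax = (np.arange(n_side) + 0.5) * sp_w - R
    wx, wy, wz = np.meshgrid(
        ax, ax, (np.arange(int(bz / sp_w)) + 0.5) * sp_w - bz / 2.0, indexing="ij"
    )
    pts = np.column_stack([wx.ravel(), wy.ravel(), wz.ravel()])
    pts += rng.uniform(-0.8, 0.8, pts.shape)
    inside = np.hypot(pts[:, 0], pts[:, 1]) < (R - 1.0)
    waters = pts[inside]
    # dense off-axis, partial-length water column deep inside the channel:
    # breaks the tube's azimuthal and axial symmetry so that rigid-transform
    # recovery is well-posed; far from the wall, so the interface is untouched
    col_ax = np.arange(-bz / 2.0 + 0.9, bz / 4.0, 1.8)
    cx, cy, cr = R / 2.0, 0.0, 2.5
    gx, gy, gz = np.meshgrid(
        cx + np.arange(-cr, cr + 0.1, 1.8), cy + np.arange(-cr, cr + 0.1, 1.8),
        col_ax, indexing="ij",
    )
    col = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    col += rng.uniform(-0.4, 0.4, col.shape)
    col = col[np.hypot(col[:, 0] - cx, col[:, 1] - cy) < cr]
    waters = np.vstack([waters, col])
    n_wat = waters.shape[0]

    # lipid rings with frozen azimuthal offsets and jitter
    ring_z = np.arange(-bz / 2.0 + spec.ring_spacing / 2.0, bz / 2.0, spec.ring_spacing)
    lipids = []
    for z0 in ring_z:
        offset = rng.uniform(0.0, 2.0 * np.pi)
        phi = offset + 2.0 * np.pi * np.arange(spec.lipids_per_ring) / spec.lipids_per_ring
        phi = phi + rng.uniform(-0.05, 0.05, spec.lipids_per_ring)
        z = z0 + rng.uniform(-0.5, 0.5, spec.lipids_per_ring)
        for p, zz in zip(phi, z):
            radial = np.array([np.cos(p), np.sin(p), 0.0])
            hd = radial * head_r + np.array([0.0, 0.0, zz])
            md = radial * mid_r + np.array([0.0, 0.0, zz])
            tl = radial * tail_r + np.array([0.0, 0.0, zz])
            lipids.append((hd, md, tl))
    n_lip = len(lipids)
    lipid_coords = np.array(lipids).reshape(-1, 3)

    system = MolecularSystem(
        chain_names=["M", "W"],
        residue_names=np.array(["LIP"] * n_lip + ["SOL"] * n_wat, dtype=object),
        residue_chain=np.array([0] * n_lip + [1] * n_wat),
        residue_ids=np.concatenate([np.arange(1, n_lip + 1), np.arange(1, n_wat + 1)]),
        atom_names=np.array(["HD", "MD", "TL"] * n_lip + ["OW"] * n_wat, dtype=object),
        atom_masses=np.array([LIPID_BEAD_MASS] * (3 * n_lip) + [WATER_BEAD_MASS] * n_wat),
        atom_residue=np.concatenate(
            [np.repeat(np.arange(n_lip), 3), n_lip + np.arange(n_wat)]
        ),
    )
    lipid_mask = np.concatenate([np.ones(n_lip, dtype=bool), np.zeros(n_wat, dtype=bool)])
    system.set_flag("do_tilt", lipid_mask)
    system.set_flag("do_splay", lipid_mask)

    base = np.vstack([lipid_coords, waters])
    transforms = [RigidTransform.identity()]
    max_rot = np.deg2rad(spec.max_rotation_deg)
    for _ in range(1, spec.n_frames):
        angles = rng.uniform(-max_rot, max_rot, 3)
        trans = rng.uniform(-spec.max_translation, spec.max_translation, 3)
        transforms.append(RigidTransform.from_params(np.concatenate([angles, trans])))
    coords = np.stack([tf.apply(base) for tf in transforms])

    cell = UnitCell.orthorhombic(bx, by, bz)
    traj = Trajectory(system, coords, cell)
    truth = GroundTruth(
        kappa_t=spec.kappa_t,
        K_c_nominal=spec.K_c,
        K_c_calibrated=float("nan"),
        A_L=spec.A_L,
        seed=spec.seed,
        interface_radius=R,
        transforms=transforms,
    )
    return traj, truth
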