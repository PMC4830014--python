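"""High-level workflow: aligned trajectory -> interface -> tilts/splays -> moduli.

Glues the stage modules together the way a user would run them: build the
time-averaged solvent and lipid densities on a common 1 Å mesh, extract the
equal-density interface and its normal field, collect tilt and splay
samples, and fit the elastic moduli.
"""

from __future__ import annotations

import numpy as np

from .analysis import analyze_splays, analyze_tilts
from .core import LipidDefinitions, Trajectory
from .density import grid_covering
from .fitting import ModuliResult, extract_tilt_and_splay_moduli
from .interface import (
    InterfaceSurface,
    average_density,
    compute_normals,
    extract_interface,
)

__all__ = ["build_interface", "analyze_lipid_tilt_and_splay", "run_moduli_pipeline"]


def build_interface(
    traj: Trajectory,
    defs: LipidDefinitions,
    resolution: float = 4.0,
    spacing: float = 1.0,
    margin: float = 5.0,
    fit_radius: float = 10.0,
    interface_frames: np.ndarray | None = None,
) -> InterfaceSurface:
    """Equal-density water/lipid interface with normals, from averaged maps.

    ``interface_frames`` selects the frames used for the density averages
    (all frames by default; a stride is usually plenty for a converged
    average).
    """
    if interface_frames is None:
        interface_frames = np.arange(traj.n_frames)
    sel_w = defs.solvent_selection()
    sel_l = defs.lipid_selection()
    grid = grid_covering(
        traj.coords[interface_frames].reshape(-1, 3), margin=margin, spacing=spacing
    )
    water_map = average_density(
        traj, sel_w, resolution=resolution, spacing=spacing,
        frames=interface_frames, grid=grid,
    )
    lipid_map = average_density(
        traj, sel_l, resolution=resolution, spacing=spacing,
        frames=interface_frames, grid=grid,
    )
    surface = extract_interface(water_map, lipid_map)
    return compute_normals(surface, water_map, lipid_map, fit_radius=fit_radius)


def analyze_lipid_tilt_and_splay(
    traj: Trajectory,
    defs: LipidDefinitions,
    tilt_flag: str = "do_tilt",
    splay_flag: str = "do_splay",
    cutoff: float = 10.0,
    resolution: float = 4.0,
    interface_stride: int = 1,
    surface: InterfaceSurface | None = None,
):
    """Collect tilt and splay samples against the averaged interface.

    Returns ``(tilts, splays, surface)`` where the dictionaries are keyed by
    species and unordered species pair.  Pass ``surface`` to reuse a
    precomputed interface.
    """
    if surface is None:
        frames = np.arange(0, traj.n_frames, max(1, interface_stride))
        surface = build_interface(
            traj, defs, resolution=resolution, interface_frames=frames
        )
    tilts = analyze_tilts(traj, defs, surface, flag=tilt_flag)
    splays = analyze_splays(traj, defs, surface, flag=splay_flag, cutoff=cutoff)
    return tilts, splays, surface


def run_moduli_pipeline(
    traj: Trajectory,
    defs: LipidDefinitions,
    area_per_lipid: float,
    temperature: float = 300.0,
    cutoff: float = 10.0,
    resolution: float = 4.0,
    interface_stride: int = 1,
    outdir=None,
) -> tuple[ModuliResult, InterfaceSurface]:
    """Full chain from an aligned trajectory to a ModuliResult."""
    tilts, splays, surface = analyze_lipid_tilt_and_splay(
        traj, defs, cutoff=cutoff, resolution=resolution,
        interface_stride=interface_stride,
    )
    result = extract_tilt_and_splay_moduli(
        tilts, splays, area_per_lipid, temperature=temperature, outdir=outdir
    )
    return result, surface
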