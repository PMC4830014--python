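import numpy as np
import pytest

from tiltsplay.analysis import (
    analyze_area_per_lipid,
    analyze_splays,
    analyze_tilts,
    compute_director,
    compute_splay,
    compute_tilt,
    leaflet_masks,
    partition_flags,
)
from tiltsplay.core import LipidDefinitions, Trajectory, UnitCell
from tiltsplay.interface import InterfaceSurface

from conftest import make_system


DEFS = LipidDefinitions(
    species=("LIP",),
    head_group={"LIP": "aname=HD"},
    tail={"LIP": "aname=TL"},
    distance={"LIP": "aname=MD"},
    solvent_names=("SOL",),
)


def flat_surface(z=0.0, extent=40, normal_up=True):
    """Flat interface sheet at height z with +/-z normals."""
    ax = np.arange(-extent, extent + 1, 1.0)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    n = np.tile([0.0, 0.0, 1.0 if normal_up else -1.0], (len(pts), 1))
    return InterfaceSurface(points=pts, normals=n)


def lipid_traj(directors, anchors, flags=None):
    """One-frame trajectory of 3-site lipids from anchor points and directors."""
    n = len(anchors)
    residues = [("M", "LIP", [("HD", 72.0), ("MD", 72.0), ("TL", 72.0)]) for _ in range(n)]
    sys_ = make_system(residues)
    mask = np.ones(n, dtype=bool) if flags is None else np.asarray(flags)
    sys_.set_flag("do_tilt", mask)
    sys_.set_flag("do_splay", mask)
    coords = np.empty((1, 3 * n, 3))
    for i, (a, d) in enumerate(zip(anchors, directors)):
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        coords[0, 3 * i] = a + 6.0 * d      # HD
        coords[0, 3 * i + 1] = a           # MD
        coords[0, 3 * i + 2] = a - 6.0 * d  # TL
    return Trajectory(sys_, coords, UnitCell.orthorhombic(200, 200, 100))


class TestDirector:
    def test_along_z(self):
        assert np.allclose(compute_director([0, 0, 10], [0, 0, 0]), [0, 0, 1])

    def test_normalized(self):
        d = compute_director([1, 0, 1], [0, 0, 0])
        assert np.allclose(d, np.array([1, 0, 1]) / np.sqrt(2))

    def test_swap_negates(self):
        a, b = [1.0, 2, 3], [-1.0, 0, 5]
        assert np.allclose(compute_director(a, b), -compute_director(b, a))

    def test_coincident_sites_rejected(self):
        with pytest.raises(ValueError):
            compute_director([1, 1, 1], [1, 1, 1])


class TestTilt:
    @pytest.mark.parametrize(
        "director,normal,expected",
        [
            ([0, 0, 1], [0, 0, 1], 0.0),
            ([1, 0, 0], [0, 0, 1], np.pi / 2),
            (np.array([1, 0, 1]) / np.sqrt(2), [0, 0, 1], np.pi / 4),
            ([0, 0, -1], [0, 0, 1], 0.0),  # folded: anti-parallel is zero tilt
        ],
    )
    def test_angles(self, director, normal, expected):
        assert compute_tilt(director, normal) == pytest.approx(expected, abs=1e-12)

    def test_rotation_invariance(self):
        """Tilt unchanged when directors and normals rotate together."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        R = Rotation.random(random_state=7).as_matrix()
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            assert compute_tilt(R @ d, R @ n) == pytest.approx(compute_tilt(d, n), abs=1e-9)


class TestSplay:
    def test_identical_fields_zero(self):
        out = compute_splay([0, 0, 1], [0, 0, 1], [0, 0, 1], [0, 0, 1],
                            [0, 0, 0], [5, 0, 0])
        assert out is not None and out[0] == pytest.approx(0.0)

    def test_hand_value_flat_membrane(self):
        """S = sin(10 deg) / 5 for a 10-degree director difference at h = 5."""
        ten = np.deg2rad(10.0)
        n2 = [np.sin(ten), 0, np.cos(ten)]
        s, h = compute_splay([0, 0, 1], n2, [0, 0, 1], [0, 0, 1], [0, 0, 0], [5, 0, 0])
        assert h == pytest.approx(5.0)
        assert s == pytest.approx(np.sin(ten) / 5.0, rel=1e-12)

    def test_exchange_symmetric_on_flat_membrane(self):
        ten = np.deg2rad(10.0)
        n1, n2 = [0, 0, 1], [np.sin(ten), 0, np.cos(ten)]
        N = [0, 0, 1]
        s12, _ = compute_splay(n1, n2, N, N, [0, 0, 0], [5, 0, 0])
        s21, _ = compute_splay(n2, n1, N, N, [5, 0, 0], [0, 0, 0])
        assert s12 == pytest.approx(s21, rel=1e-12)

    def test_pair_parallel_to_normal_skipped(self):
        out = compute_splay([0, 0, 1], [0, 0, 1], [0, 0, 1], [0, 0, 1],
                            [0, 0, 0], [0, 0, 5])
        assert out is None

    def test_linear_director_field_exact_derivative(self):
        """For n_x = alpha * x on a flat interface, S equals alpha exactly."""
        alpha = 0.01
        N = [0.0, 0, 1]
        h = 6.0
        def director(x):
            nx = alpha * x
            return np.array([nx, 0.0, np.sqrt(1.0 - nx**2)])
        s, _ = compute_splay(director(0.0), director(h), N, N, [0, 0, 0], [h, 0, 0])
        assert s == pytest.approx(alpha, rel=1e-9)

    def test_normal_term_sign_switch(self):
        N1, N2 = [0.0, 0, 1], [0.1, 0, np.sqrt(1 - 0.01)]
        n = [0.0, 0, 1]
        plus, _ = compute_splay(n, n, N1, N2, [0, 0, 0], [5, 0, 0], normal_term_sign=1.0)
        minus, _ = compute_splay(n, n, N1, N2, [0, 0, 0], [5, 0, 0], normal_term_sign=-1.0)
        assert plus == pytest.approx(-minus, rel=1e-12)
        assert plus != 0.0


class TestAnalyzeTilts:
    def test_zero_tilt_construction(self):
        traj = lipid_traj([[0, 0, 1]] * 4, [[-10, 0, 0], [0, 0, 0], [10, 0, 0], [0, 10, 0]])
        tilts = analyze_tilts(traj, DEFS, flat_surface(z=8.0))
        assert np.allclose(tilts["LIP"].theta, 0.0, atol=1e-6)

    def test_thirty_degree_lipid(self):
        traj = lipid_traj([[np.sin(np.pi / 6), 0, np.cos(np.pi / 6)]], [[0, 0, 0]])
        tilts = analyze_tilts(traj, DEFS, flat_surface(z=8.0))
        assert len(tilts["LIP"]) == 1
        assert tilts["LIP"].theta[0] == pytest.approx(np.pi / 6, abs=1e-9)

    def test_all_flags_false_empty(self):
        traj = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [8, 0, 0]], flags=[False, False])
        tilts = analyze_tilts(traj, DEFS, flat_surface(z=8.0))
        assert sum(len(v) for v in tilts.values()) == 0

    def test_sample_count_contract(self):
        """Tilt sample count = frames x flagged lipids."""
        traj = lipid_traj([[0, 0, 1]] * 3, [[0, 0, 0], [8, 0, 0], [0, 8, 0]],
                          flags=[True, True, False])
        traj = Trajectory(traj.system, np.repeat(traj.coords, 4, axis=0), traj.cells[0])
        tilts = analyze_tilts(traj, DEFS, flat_surface(z=8.0))
        assert len(tilts["LIP"]) == 4 * 2

    def test_missing_species_mapping_raises(self):
        traj = lipid_traj([[0, 0, 1]], [[0, 0, 0]])
        bad = LipidDefinitions(
            species=("LIP",),
            head_group={"LIP": "aname=NOPE"},
            tail={"LIP": "aname=TL"},
            distance={"LIP": "aname=MD"},
        )
        with pytest.raises(ValueError, match="LIP"):
            analyze_tilts(traj, bad, flat_surface(z=8.0))


class TestAnalyzeSplays:
    def test_cutoff_excludes_far_pairs(self):
        traj = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [12, 0, 0]])
        splays = analyze_splays(traj, DEFS, flat_surface(z=8.0), cutoff=10.0)
        assert sum(len(v) for v in splays.values()) == 0

    def test_collinear_pair_enumeration(self):
        traj = lipid_traj([[0, 0, 1]] * 3, [[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        splays = analyze_splays(traj, DEFS, flat_surface(z=8.0), cutoff=6.0)
        assert len(splays[("LIP", "LIP")]) == 2

    def test_uniformly_tilted_field_zero_splay(self):
        d = [np.sin(0.3), 0, np.cos(0.3)]
        traj = lipid_traj([d] * 3, [[0, 0, 0], [6, 0, 0], [0, 6, 0]])
        splays = analyze_splays(traj, DEFS, flat_surface(z=8.0), cutoff=10.0)
        assert np.allclose(splays[("LIP", "LIP")].splay, 0.0, atol=1e-9)

    def test_pair_needs_one_flagged_member(self):
        traj = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [5, 0, 0]], flags=[True, False])
        splays = analyze_splays(traj, DEFS, flat_surface(z=8.0))
        assert len(splays[("LIP", "LIP")]) == 1
        both_off = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [5, 0, 0]], flags=[False, False])
        assert len(analyze_splays(both_off, DEFS, flat_surface(z=8.0))) == 0

    def test_bad_cutoff_rejected(self):
        traj = lipid_traj([[0, 0, 1]], [[0, 0, 0]])
        with pytest.raises(ValueError):
            analyze_splays(traj, DEFS, flat_surface(z=8.0), cutoff=0.0)


class TestAreaPerLipid:
    def test_hand_value(self):
        sys_ = make_system([("M", "LIP", [("HD", 72.0)])])
        traj = Trajectory(sys_, np.zeros((1, 1, 3)), UnitCell.orthorhombic(62, 62, 50))
        assert analyze_area_per_lipid(traj, 64) == pytest.approx(60.0625)

    def test_intensive_under_doubling(self):
        sys_ = make_system([("M", "LIP", [("HD", 72.0)])])
        small = Trajectory(sys_, np.zeros((1, 1, 3)), UnitCell.orthorhombic(62, 62, 50))
        big = Trajectory(sys_, np.zeros((1, 1, 3)), UnitCell.orthorhombic(124, 124, 50))
        assert analyze_area_per_lipid(small, 64) == pytest.approx(
            analyze_area_per_lipid(big, 256)
        )

    def test_zero_lipids_rejected(self):
        sys_ = make_system([("M", "LIP", [("HD", 72.0)])])
        traj = Trajectory(sys_, np.zeros((1, 1, 3)), UnitCell.orthorhombic(62, 62, 50))
        with pytest.raises(ValueError):
            analyze_area_per_lipid(traj, 0)


class TestPartition:
    def test_leaflet_partition_covers_each_lipid_once(self):
        anchors = [[0, 0, 8], [8, 0, 8], [0, 0, -8], [8, 0, -8]]
        dirs = [[0, 0, 1], [0, 0, 1], [0, 0, -1], [0, 0, -1]]
        traj = lipid_traj(dirs, anchors)
        masks = leaflet_masks(traj, DEFS)
        combined = masks["upper"].astype(int) + masks["lower"].astype(int)
        assert np.all(combined == 1)
        assert masks["upper"].sum() == 2

    def test_partition_flags_set_per_part(self):
        traj = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [8, 0, 0]])
        parts = partition_flags(
            traj.system, {"left": np.array([True, False]), "right": np.array([False, True])}
        )
        assert parts["left"].get_flag("do_tilt").tolist() == [True, False]
        assert parts["right"].get_flag("do_splay").tolist() == [False, True]

    def test_empty_part_gives_empty_samples(self):
        traj = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [8, 0, 0]])
        parts = partition_flags(traj.system, {"none": np.zeros(2, dtype=bool)})
        traj_part = Trajectory(parts["none"], traj.coords, traj.cells)
        tilts = analyze_tilts(traj_part, DEFS, flat_surface(z=8.0))
        assert sum(len(v) for v in tilts.values()) == 0

    def test_selection_expression_part(self):
        traj = lipid_traj([[0, 0, 1]] * 2, [[0, 0, 0], [8, 0, 0]])
        parts = partition_flags(traj.system, {"all": "rname=LIP"})
        assert parts["all"].get_flag("do_tilt").all()
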