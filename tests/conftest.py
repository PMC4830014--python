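import numpy as np
import pytest

from tiltsplay.core import MolecularSystem, Trajectory, UnitCell


def make_system(residues, chain_names=None):
    """Build a MolecularSystem from a list of (chain, resname, [(aname, mass), ...])."""
    chains = chain_names or []
    res_names, res_chain, res_ids = [], [], []
    at_names, at_mass, at_res = [], [], []
    for chain, resname, atoms in residues:
        if chain not in chains:
            chains.append(chain)
        res_idx = len(res_names)
        res_names.append(resname)
        res_chain.append(chains.index(chain))
        res_ids.append(res_idx + 1)
        for aname, mass in atoms:
            at_names.append(aname)
            at_mass.append(mass)
            at_res.append(res_idx)
    return MolecularSystem(
        chains,
        np.array(res_names, dtype=object),
        np.array(res_chain),
        np.array(res_ids),
        np.array(at_names, dtype=object),
        np.array(at_mass),
        np.array(at_res),
    )


@pytest.fixture
def two_chain_traj():
    """Scheme-1-like toy: chain M (one 3-site lipid) + chain W (two waters)."""
    sys_ = make_system(
        [
            ("M", "LIP", [("HD", 72.0), ("MD", 72.0), ("TL", 72.0)]),
            ("W", "SOL", [("OW", 18.0)]),
            ("W", "SOL", [("OW", 18.0)]),
        ]
    )
    sys_.set_flag("do_tilt", np.array([True, False, False]))
    sys_.set_flag("do_splay", np.array([True, False, False]))
    coords = np.array(
        [[[0.0, 0, 14], [0, 0, 8], [0, 0, 2], [3, 3, 20], [9, 1, -20]]]
    )
    return Trajectory(sys_, coords, UnitCell.orthorhombic(10, 10, 50))
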