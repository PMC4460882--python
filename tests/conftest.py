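"""Shared fixtures: a minimal test lipid registry and frame builders."""

from __future__ import annotations

import numpy as np
import pytest

from lamella import Frame, LipidDefinition, LipidRegistry, load_lipid_registry
from lamella.fixtures import FixtureSpec, build_bilayer
from lamella.leaflets import assign_leaflets, detect_layout


@pytest.fixture(scope="session")
def registry():
    return load_lipid_registry()


@pytest.fixture(scope="session")
def tiny_registry():
    """Hand-sized lipids for geometric unit tests.

    TSTA: atomistic, 6-carbon single tail, two hydrogens per carbon.
    TSTC: coarse-grained, 4-bead single tail.
    """
    defs = [
        LipidDefinition(
            residue_name="TSTA", flavour="atomistic", phosphorus_atom="P",
            headgroup_reference_atom="N",
            tails=(tuple(f"C{i}" for i in range(1, 7)),),
            tail_hydrogens={f"C{i}": (f"H{i}1", f"H{i}2") for i in range(1, 7)},
        ),
        LipidDefinition(
            residue_name="TSTC", flavour="coarse_grained", phosphorus_atom="PO4",
            headgroup_reference_atom="NC3",
            tails=(("B1", "B2", "B3", "B4"),), bond_step=0.47,
        ),
        LipidDefinition(
            residue_name="TSTU", flavour="united_atom", phosphorus_atom="P",
            headgroup_reference_atom="N",
            tails=(tuple(f"C{i}" for i in range(1, 7)),),
        ),
    ]
    return LipidRegistry(defs)


def make_frame(residues, box=(10.0, 10.0, 10.0), time=0.0) -> Frame:
    """Build a Frame from [(resname, [(atom, (x, y, z)), ...]), ...]."""
    names, resids, resnames, coords = [], [], [], []
    for rid, (resname, atoms) in enumerate(residues, start=1):
        for (name, xyz) in atoms:
            names.append(name)
            resids.append(rid)
            resnames.append(resname)
            coords.append(xyz)
    return Frame(
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        positions=np.array(coords, dtype=float),
        box=np.array(box, dtype=float),
        time=time,
    )


def cg_lipid(x, y, z_p, down=False, resname="TSTC", bond_dirs=None):
    """A 6-atom coarse-grained test lipid with its phosphorus at z_p.

    ``bond_dirs``: optional list of 3 unit vectors for the three tail bonds
    (default: straight toward the bilayer centre).
    """
    s = -1.0 if not down else 1.0        # tails run opposite the outward normal
    if bond_dirs is None:
        bond_dirs = [(0.0, 0.0, s)] * 3
    atoms = [("NC3", (x, y, z_p + (0.3 if not down else -0.3))),
             ("PO4", (x, y, z_p))]
    bz = z_p + (-0.4 if not down else 0.4)
    pos = np.array([x, y, bz])
    atoms.append(("B1", tuple(pos)))
    for i, d in enumerate(bond_dirs, start=2):
        pos = pos + 0.47 * np.asarray(d, dtype=float)
        atoms.append((f"B{i}", tuple(pos)))
    return (resname, atoms)


def flat_cg_bilayer(n_side=3, centre=5.0, half=2.0, box=(10.0, 10.0, 10.0),
                    types=None):
    """Small symmetric CG bilayer; phosphorus exactly at centre +/- half."""
    residues = []
    k = 0
    for down in (True, False):
        for iy in range(n_side):
            for ix in range(n_side):
                resname = "TSTC" if types is None else types[k % len(types)]
                x, y = 1.0 + 2.5 * ix, 1.0 + 2.5 * iy
                z_p = centre + (half if not down else -half)
                residues.append(cg_lipid(x, y, z_p, down=down, resname=resname))
                k += 1
    return make_frame(residues, box=box)


@pytest.fixture(scope="session")
def cg_gel_system(registry):
    """64-lipid/leaflet all-trans coarse-grained POPE/POPG bilayer."""
    spec = FixtureSpec(n_lipids=64, composition={"POPE": 0.75, "POPG": 0.25},
                       phase="all_trans_gel", seed=11)
    frames = build_bilayer(spec, registry)
    layout = detect_layout(frames[0], registry)
    assignment = assign_leaflets(frames, layout, registry)
    return frames, layout, assignment


@pytest.fixture(scope="session")
def atomistic_system(registry):
    """16-lipid/leaflet atomistic POPC bilayer, fluid tails."""
    spec = FixtureSpec(n_lipids=16, composition={"POPC": 1.0},
                       flavour="atomistic", phase="folded_fluid", seed=12)
    frames = build_bilayer(spec, registry)
    layout = detect_layout(frames[0], registry)
    assignment = assign_leaflets(frames, layout, registry)
    return frames, layout, assignment
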