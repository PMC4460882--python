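"""Order parameters: analytic limits, independent oracles and invariants."""

import numpy as np
import pytest

from lamella import (
    angle_histograms,
    p2_coarse,
    scd_atomistic,
    scd_united_atom,
)

from conftest import make_frame

MAGIC = np.degrees(np.arccos(np.sqrt(1.0 / 3.0)))       # 54.7356...


def atomistic_lipid(h_dir, x=2.0, y=2.0, n_c=6, resname="TSTA"):
    """One test lipid whose every C-H bond points along ``h_dir``."""
    h = 0.109 * np.asarray(h_dir) / np.linalg.norm(h_dir)
    atoms = [("N", (x, y, 8.0)), ("P", (x, y, 7.7))]
    for i in range(1, n_c + 1):
        c = np.array([x + 0.04 * (i % 2), y, 7.3 - 0.127 * i])
        atoms.append((f"C{i}", tuple(c)))
        atoms.append((f"H{i}1", tuple(c + h)))
        atoms.append((f"H{i}2", tuple(c + h)))
    return (resname, atoms)


def cg_lipid_with_bonds(bond_dirs, x=2.0, y=2.0):
    atoms = [("NC3", (x, y, 8.0)), ("PO4", (x, y, 7.7))]
    pos = np.array([x, y, 7.3])
    atoms.append(("B1", tuple(pos)))
    for i, d in enumerate(bond_dirs, start=2):
        pos = pos + 0.47 * np.asarray(d, dtype=float)
        atoms.append((f"B{i}", tuple(pos)))
    return ("TSTC", atoms)


class TestAtomisticLimits:
    @pytest.mark.parametrize("h_dir,expected", [
        ((1.0, 0.0, 0.0), 0.5),                 # C-H perpendicular to normal
        ((0.0, 0.0, 1.0), -1.0),                # C-H parallel to normal
    ])
    def test_printed_limits(self, tiny_registry, h_dir, expected):
        frame = make_frame([atomistic_lipid(h_dir)])
        profiles = scd_atomistic([frame], None, tiny_registry)
        values = profiles["TSTA:sn1"].values
        assert np.allclose(values, expected, atol=1e-12)

    def test_magic_angle_zero(self, tiny_registry):
        h_dir = (np.sin(np.radians(MAGIC)), 0.0, np.cos(np.radians(MAGIC)))
        frame = make_frame([atomistic_lipid(h_dir)])
        profiles = scd_atomistic([frame], None, tiny_registry)
        assert np.allclose(profiles["TSTA:sn1"].values, 0.0, atol=1e-12)

    def test_isotropic_orientations_average_to_zero(self, tiny_registry):
        rng = np.random.default_rng(42)
        lipids = []
        n_lip = 500                       # 500 lipids x 6 C x 2 H = 6000 bonds
        for k in range(n_lip):
            v = rng.normal(size=3)
            lipids.append(atomistic_lipid(v, x=float(k % 50), y=float(k // 50)))
        frame = make_frame(lipids, box=(60.0, 60.0, 10.0))
        profiles = scd_atomistic([frame], None, tiny_registry)
        vals = profiles["TSTA:sn1"].values
        # each carbon position pools n_lip samples (paired H double-counts)
        assert np.all(np.abs(vals) < 3.0 / np.sqrt(n_lip))

    def test_missing_hydrogen_is_definition_error(self, tiny_registry):
        lipid = atomistic_lipid((1, 0, 0))
        atoms = [a for a in lipid[1] if a[0] != "H31"]
        frame = make_frame([("TSTA", atoms)])
        with pytest.raises(Exception, match="H31|hydrogen"):
            scd_atomistic([frame], None, tiny_registry)


def united_atom_oracle(chain):
    """Brute-force -S_CD per carbon from explicit molecular axes."""
    chain = np.asarray(chain, dtype=float)
    out = np.full(len(chain), np.nan)
    for i in range(1, len(chain) - 1):
        z = chain[i + 1] - chain[i - 1]
        z = z / np.linalg.norm(z)
        v = chain[i] - 0.5 * (chain[i - 1] + chain[i + 1])
        v = v - np.dot(v, z) * z
        y = v / np.linalg.norm(v)
        x = np.cross(y, z)
        sxx = 0.5 * (3.0 * x[2] ** 2 - 1.0)
        syy = 0.5 * (3.0 * y[2] ** 2 - 1.0)
        out[i] = -((2.0 / 3.0) * sxx + (1.0 / 3.0) * syy)
    return out


class TestUnitedAtom:
    def test_zigzag_chain_matches_handbuilt_oracle(self, tiny_registry):
        # hand-specified planar zig-zag, 6 carbons, slightly tilted
        chain = []
        for k in range(6):
            chain.append((2.0 + 0.0855 * (k % 2) + 0.01 * k, 2.0, 7.0 - 0.127 * k))
        atoms = [("N", (2.0, 2.0, 8.0)), ("P", (2.0, 2.0, 7.7))]
        atoms += [(f"C{k+1}", c) for k, c in enumerate(chain)]
        frame = make_frame([("TSTU", atoms)])
        profiles = scd_united_atom([frame], None, tiny_registry)
        expected = united_atom_oracle(chain)
        got = profiles["TSTU:sn1"].values
        assert np.isnan(got[0]) and np.isnan(got[-1])   # terminals skipped
        assert np.allclose(got[1:-1], expected[1:-1], atol=1e-12)

    def test_collinear_carbons_skipped_and_tallied(self, tiny_registry):
        chain = [(2.0, 2.0, 7.0 - 0.127 * k) for k in range(6)]   # straight
        atoms = [("N", (2.0, 2.0, 8.0)), ("P", (2.0, 2.0, 7.7))]
        atoms += [(f"C{k+1}", c) for k, c in enumerate(chain)]
        frame = make_frame([("TSTU", atoms)])
        profiles = scd_united_atom([frame], None, tiny_registry)
        p = profiles["TSTU:sn1"]
        assert p.n_degenerate == 4                       # all interior carbons
        assert np.all(np.isnan(p.values))

    def test_matches_atomistic_with_ideal_tetrahedral_hydrogens(
            self, registry, atomistic_system):
        frames, layout, assignment = atomistic_system
        at = scd_atomistic(frames, assignment, registry)
        ua = scd_united_atom(frames, assignment, registry)
        for label in at:
            diff = np.abs(at[label].values[1:-1] - ua[label].values[1:-1])
            assert np.nanmax(diff) < 0.02


class TestCoarseGrained:
    @pytest.mark.parametrize("bond,expected", [
        ((0.0, 0.0, 1.0), 1.0),                 # bonds parallel to normal
        ((1.0, 0.0, 0.0), -0.5),                # perpendicular
    ])
    def test_printed_limits(self, tiny_registry, bond, expected):
        frame = make_frame([cg_lipid_with_bonds([bond] * 3)])
        profiles = p2_coarse([frame], None, tiny_registry)
        assert np.allclose(profiles["TSTC:sn1"].values, expected, atol=1e-12)

    def test_magic_angle_zero(self, tiny_registry):
        d = (np.sin(np.radians(MAGIC)), 0.0, np.cos(np.radians(MAGIC)))
        frame = make_frame([cg_lipid_with_bonds([d] * 3)])
        profiles = p2_coarse([frame], None, tiny_registry)
        assert np.allclose(profiles["TSTC:sn1"].values, 0.0, atol=1e-12)

    def test_mean_angle_inside_cosine_on_bimodal_distribution(self, tiny_registry):
        """P2 uses cos<theta>, not <P2(cos theta)>: a 30/90-degree bimodal
        sample distinguishes the two averaging orders."""
        d30 = (np.sin(np.radians(30)), 0.0, np.cos(np.radians(30)))
        d90 = (1.0, 0.0, 0.0)
        frame = make_frame([cg_lipid_with_bonds([d30] * 3, x=2.0),
                            cg_lipid_with_bonds([d90] * 3, x=6.0)])
        profiles = p2_coarse([frame], None, tiny_registry)
        mean_theta_inside = 0.5 * (3.0 * np.cos(np.radians(60.0)) ** 2 - 1.0)
        mean_of_p2 = 0.5 * (0.5 * (3 * np.cos(np.radians(30)) ** 2 - 1)
                            + 0.5 * (3 * np.cos(np.radians(90)) ** 2 - 1))
        assert np.allclose(profiles["TSTC:sn1"].values, mean_theta_inside,
                           atol=1e-12)
        assert not np.isclose(mean_theta_inside, mean_of_p2)

    def test_bounds_on_random_orientations(self, tiny_registry):
        rng = np.random.default_rng(7)
        lipids = [cg_lipid_with_bonds(rng.normal(size=(3, 3)),
                                      x=float(k % 20), y=float(k // 20))
                  for k in range(100)]
        frame = make_frame(lipids, box=(25.0, 25.0, 10.0))
        profiles = p2_coarse([frame], None, tiny_registry)
        assert np.all(profiles["TSTC:sn1"].values >= -0.5 - 1e-12)
        assert np.all(profiles["TSTC:sn1"].values <= 1.0 + 1e-12)


class TestLeafletDecomposition:
    def test_full_profile_is_sample_weighted_leaflet_mean(
            self, registry, cg_gel_system):
        frames, layout, assignment = cg_gel_system
        full = p2_coarse(frames, assignment, registry)
        per_leaflet = [p2_coarse(frames, assignment, registry, leaflet=l)
                       for l in (0, 1)]
        for label in full:
            n0 = per_leaflet[0][label].n_samples
            n1 = per_leaflet[1][label].n_samples
            # P2 averages theta before the Legendre term, so recombine thetas
            t0 = np.arccos(np.sqrt((2 * per_leaflet[0][label].values + 1) / 3))
            t1 = np.arccos(np.sqrt((2 * per_leaflet[1][label].values + 1) / 3))
            tfull = (n0 * t0 + n1 * t1) / (n0 + n1)
            expected = 0.5 * (3 * np.cos(tfull) ** 2 - 1)
            assert np.allclose(full[label].values, expected, atol=1e-9)

    def test_scd_decomposition_is_linear(self, registry, atomistic_system):
        frames, layout, assignment = atomistic_system
        full = scd_atomistic(frames, assignment, registry)
        parts = [scd_atomistic(frames, assignment, registry, leaflet=l)
                 for l in (0, 1)]
        for label in full:
            n0, n1 = parts[0][label].n_samples, parts[1][label].n_samples
            mix = (n0 * parts[0][label].values + n1 * parts[1][label].values) \
                / (n0 + n1)
            assert np.allclose(full[label].values, mix, atol=1e-12)


class TestAngleHistograms:
    def test_single_angle_occupies_one_bin(self, tiny_registry):
        frame = make_frame([cg_lipid_with_bonds([(1.0, 0.0, 0.0)] * 3)])
        hists = angle_histograms([frame], None, tiny_registry,
                                 flavour="coarse_grained")
        h = hists["TSTC:sn1"]
        assert h.counts.sum() == 3
        assert h.counts[90] == 3                 # the [90, 91) bin

    def test_uniform_orientations_follow_sine_density(self, tiny_registry):
        rng = np.random.default_rng(11)
        lipids = [cg_lipid_with_bonds(rng.normal(size=(3, 3)),
                                      x=float(k % 60), y=float(k // 60))
                  for k in range(3000)]
        frame = make_frame(lipids, box=(65.0, 65.0, 10.0))
        hists = angle_histograms([frame], None, tiny_registry,
                                 flavour="coarse_grained", bin_width=10.0)
        h = hists["TSTC:sn1"]
        n = h.counts.sum()
        edges = np.radians(h.bin_edges)
        expected = n * (np.cos(edges[:-1]) - np.cos(edges[1:])) / 2.0
        # solid-angle density: chi-square-ish agreement within 5 sigma
        sigma = np.sqrt(np.maximum(expected, 1.0))
        assert np.all(np.abs(h.counts - expected) < 5.0 * sigma)

    def test_empty_selection_gives_zero_histogram(self, tiny_registry):
        frame = make_frame([cg_lipid_with_bonds([(0, 0, 1.0)] * 3)])
        hists = angle_histograms([frame], None, tiny_registry,
                                 selection=set(), flavour="coarse_grained")
        assert hists and all(h.counts.sum() == 0 for h in hists.values())
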