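"""Charge density, Poisson double integral and TMV extraction."""

import numpy as np
import pytest

from lamella import (
    LamellaError,
    assign_leaflets,
    charge_density,
    detect_layout,
    potential_profile,
    tmv_series,
)
from lamella.fixtures import (
    FixtureSpec,
    ScriptedIonTransfer,
    build_bilayer,
    capacitor_frames,
    script_trajectory,
)
from lamella.model import Frame

E_OVER_EPS0_NM = 1.602176634e-19 / 8.8541878128e-12 * 1e9   # V nm^2 / e


def capacitor_analytic(sigma, d):
    """|dPsi| = sigma d / eps0 for sigma in e/nm^2, d in nm, volts."""
    return sigma * d * E_OVER_EPS0_NM


class TestChargeDensity:
    def test_neutral_system_sums_to_zero(self, registry):
        frames, cmap = capacitor_frames(sigma=0.5)
        profile = charge_density(frames, registry, cmap, n_slices=64)
        assert profile.total_charge == pytest.approx(0.0, abs=1e-9)

    def test_single_ion_slice_density(self, registry):
        frame = Frame(
            names=np.array(["NA"], dtype=object),
            resids=np.array([1]),
            resnames=np.array(["NA"], dtype=object),
            positions=np.array([[1.0, 1.0, 2.05]]),
            box=np.array([4.0, 4.0, 8.0]),
        )
        profile = charge_density([frame], registry, n_slices=80)
        dz = 8.0 / 80
        k = int(2.05 / dz)
        assert profile.rho[k] == pytest.approx(1.0 / (16.0 * dz))
        assert np.count_nonzero(profile.rho) == 1

    def test_imbalance_gives_opposite_compartment_charges(self, registry):
        spec = FixtureSpec(n_lipids=16, composition={"POPC": 1.0},
                           layout="double", ion_imbalance=20, seed=3)
        frame = build_bilayer(spec, registry)[0]
        layout = detect_layout(frame, registry)
        profile = charge_density([frame], registry, n_slices=200)
        dz = np.diff(profile.edges)
        q = profile.rho * dz * profile.box_area
        z = profile.centres
        inner = (z > layout.bilayer_centres[0]) & (z < layout.bilayer_centres[1])
        assert q[inner].sum() == pytest.approx(-10.0, abs=1e-9)
        assert q[~inner].sum() == pytest.approx(10.0, abs=1e-9)

    def test_uncharged_atom_is_hard_error(self, registry):
        frame = Frame(
            names=np.array(["XX"], dtype=object),
            resids=np.array([1]),
            resnames=np.array(["UNK"], dtype=object),
            positions=np.array([[1.0, 1.0, 1.0]]),
            box=np.array([4.0, 4.0, 8.0]),
        )
        with pytest.raises(LamellaError, match="UNK:XX"):
            charge_density([frame], registry, n_slices=16)


class TestPotential:
    def test_zero_density_zero_potential(self, registry):
        frames, cmap = capacitor_frames(sigma=0.0)
        profile = potential_profile(charge_density(frames, registry, cmap,
                                                   n_slices=50))
        assert np.allclose(profile.psi, 0.0)

    def test_anchored_at_box_bottom(self, registry):
        frames, cmap = capacitor_frames(sigma=0.4)
        profile = potential_profile(charge_density(frames, registry, cmap,
                                                   n_slices=200))
        assert profile.psi[0] == 0.0

    def test_capacitor_within_one_percent_and_first_order(self, registry):
        sigma, z1, z2 = 0.5, 2.0, 10.0
        frames, cmap = capacitor_frames(sigma=sigma, z_plates=(z1, z2),
                                        box=(4.0, 4.0, 12.0))
        analytic = capacitor_analytic(sigma, z2 - z1)
        errors = []
        for n_slices in (200, 400):
            profile = potential_profile(charge_density(frames, registry, cmap,
                                                       n_slices=n_slices))
            z = profile.centres
            below = profile.psi[z < z1 - 0.5].mean()
            above = profile.psi[z > z2 + 0.5].mean()
            errors.append(abs(abs(above - below) - analytic) / analytic)
        assert errors[0] < 0.01
        assert errors[1] == pytest.approx(errors[0] / 2.0, rel=0.2)

    def test_field_between_plates_is_sigma_over_eps0(self, registry):
        sigma = 0.5
        frames, cmap = capacitor_frames(sigma=sigma, z_plates=(2.0, 10.0),
                                        box=(4.0, 4.0, 12.0))
        profile = potential_profile(charge_density(frames, registry, cmap,
                                                   n_slices=200))
        z = profile.centres
        mid = (z > 4.0) & (z < 8.0)
        field = np.gradient(profile.psi, z)[mid]
        assert np.allclose(np.abs(field), sigma * E_OVER_EPS0_NM, rtol=1e-9)

    def test_even_density_gives_even_potential_up_to_linear(self, registry):
        frames, cmap = capacitor_frames(sigma=0.5, z_plates=(3.0, 9.0),
                                        box=(4.0, 4.0, 12.0))
        # plates symmetric about the box centre but opposite in sign; use
        # two like-signed sheets plus compensation for an even rho
        cmap = {"MINUS:Q": 0.5, "PLUS:Q": 0.5, "CL": -1.0}
        frame = frames[0].copy()
        # add a central compensating sheet (-16 e at z = 6) for neutrality;
        # rho is then even about the box centre
        n_cl = 16
        names = np.concatenate([frame.names,
                                np.array(["CL"] * n_cl, dtype=object)])
        resids = np.concatenate([frame.resids, np.arange(1000, 1000 + n_cl)])
        resnames = np.concatenate([frame.resnames,
                                   np.array(["CL"] * n_cl, dtype=object)])
        rng = np.random.default_rng(2)
        centre_sheet = np.column_stack([
            rng.uniform(0, 4, n_cl), rng.uniform(0, 4, n_cl),
            np.full(n_cl, 6.0)])
        positions = np.vstack([frame.positions, centre_sheet])
        even = Frame(names=names, resids=resids, resnames=resnames,
                     positions=positions, box=frame.box)
        profile = potential_profile(charge_density([even], registry, cmap,
                                                   n_slices=240))
        # Psi = even-about-axis + linear iff its odd part about the axis is
        # itself linear; the binned rho is even about slice index 120
        axis = 120
        k = np.arange(1, 120)
        odd = profile.psi[axis + k] - profile.psi[axis - k]
        slope = np.polyfit(k.astype(float), odd, 1)
        fit_resid = odd - np.polyval(slope, k)
        assert np.abs(fit_resid).max() < 1e-9 * np.abs(profile.psi).max()


@pytest.fixture(scope="module")
def double_system(registry):
    spec = FixtureSpec(n_lipids=16, composition={"POPC": 1.0},
                       layout="double", ion_imbalance=20,
                       n_frames=10, seed=4)
    frames = build_bilayer(spec, registry)
    layout = detect_layout(frames[0], registry)
    assignment = assign_leaflets(frames, layout, registry)
    return frames, layout, assignment


class TestTMV:
    def test_single_bilayer_unsupported(self, registry, cg_gel_system):
        frames, layout, assignment = cg_gel_system
        with pytest.raises(LamellaError, match="double"):
            tmv_series(frames, layout, registry)

    def test_static_trajectory_constant_tmv(self, registry, double_system):
        frames, layout, assignment = double_system
        series = tmv_series(frames, layout, registry, assignment=assignment,
                            window=2, n_slices=200)
        assert len(series.tmv) == 5
        assert np.allclose(series.tmv, series.tmv[0], atol=1e-9)
        assert series.tmv[0] < 0          # inner compartment holds the anions

    def test_charge_conjugation_flips_sign_exactly(self, registry, double_system):
        frames, layout, assignment = double_system
        base = tmv_series(frames, layout, registry, assignment=assignment,
                          window=5, n_slices=200)
        flipped = tmv_series(frames, layout, registry, assignment=assignment,
                             charge_map={"NA": -1.0, "CL": 1.0},
                             window=5, n_slices=200)
        assert np.allclose(flipped.tmv, -base.tmv, atol=1e-12)

    def test_embedded_capacitor_matches_analytic(self, registry):
        """Ion sheets flanking each bilayer turn the double bilayer into two
        series capacitors with flat compartments; TMV then equals the
        analytic plate-pair potential difference."""
        spec = FixtureSpec(n_lipids=16, composition={"POPC": 1.0},
                           layout="double", n_frames=2, seed=5)
        frames = build_bilayer(spec, registry)
        layout = detect_layout(frames[0], registry)
        zc = layout.bilayer_centres
        half = 2.6                        # sheets just outside the headgroups
        n_side = 16
        sheets = []
        for z, sign in ((zc[0] - half, +1), (zc[0] + half, -1),
                        (zc[1] - half, -1), (zc[1] + half, +1)):
            sheets.append((z, sign))
        base = frames[0]
        extra_pos, extra_rn = [], []
        for (z, sign) in sheets:
            for k in range(n_side):
                x = (k % 4 + 0.5) * base.box[0] / 4
                y = (k // 4 + 0.5) * base.box[1] / 4
                extra_pos.append([x, y, z])
                extra_rn.append("NA" if sign > 0 else "CL")
        n_extra = len(extra_pos)
        frame = Frame(
            names=np.concatenate([base.names,
                                  np.array(extra_rn, dtype=object)]),
            resids=np.concatenate([base.resids,
                                   np.arange(5000, 5000 + n_extra)]),
            resnames=np.concatenate([base.resnames,
                                     np.array(extra_rn, dtype=object)]),
            positions=np.vstack([base.positions, np.array(extra_pos)]),
            box=base.box, time=0.0,
        )
        frames10 = [frame] * 10
        series = tmv_series(frames10, layout, registry, window=1,
                            n_slices=400)
        sigma = n_side / (base.box[0] * base.box[1])
        analytic = -capacitor_analytic(sigma, 2 * half)
        assert np.allclose(series.tmv, series.tmv[0], atol=1e-12)
        assert series.tmv[0] == pytest.approx(analytic, rel=0.02)

    def test_stepwise_imbalance_decay_is_monotone(self, registry):
        spec = FixtureSpec(n_lipids=16, composition={"POPC": 1.0},
                           layout="double", ion_imbalance=20,
                           n_frames=8, seed=6)
        events = [ScriptedIonTransfer(time=200.0 * (k + 1), n_ions=2)
                  for k in range(3)]
        frames = script_trajectory(spec, events)
        layout = detect_layout(frames[0], registry)
        series = tmv_series(frames, layout, registry, window=1, n_slices=200)
        mags = np.abs(series.tmv)
        assert np.all(np.diff(mags) <= 1e-9)
        assert mags[-1] < mags[0]

    def test_zero_imbalance_zero_tmv(self, registry):
        spec = FixtureSpec(n_lipids=16, composition={"POPC": 1.0},
                           layout="double", n_frames=2, seed=7)
        frames = build_bilayer(spec, registry)
        layout = detect_layout(frames[0], registry)
        series = tmv_series(frames, layout, registry, window=1, n_slices=200)
        assert np.allclose(series.tmv, 0.0, atol=1e-12)
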