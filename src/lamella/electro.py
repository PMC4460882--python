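"""Charge-density profiles, electrostatic potential and TMV evolution.

The simulation box is cut into slices along z; the per-slice charge
density rho(z) (e nm^-3, window-averaged) feeds the double integral of
Poisson's equation,

    Psi(z) = -(1/eps0) int_0^z dz' int_0^z' rho(z'') dz'',

evaluated with cumulative trapezoids and converted to volts; the profile
is anchored so Psi(0) = 0 at the bottom of the box.  For stacked double
bilayers the transmembrane voltage is the potential of the inner water
compartment minus that of the outer one, each averaged over the central
50% of its compartment (a plateau average), one value per trajectory
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .leaflets import BilayerLayout, LeafletAssignment
from .model import Frame, LamellaError, ResidueTable
from .registry import LipidRegistry, resolve_charges

__all__ = ["ChargeDensityProfile", "TMVSeries", "charge_density",
           "potential_profile", "tmv_series"]

#: e / (V m): elementary charge over vacuum permittivity.
_E_OVER_EPS0 = 1.602176634e-19 / 8.8541878128e-12
#: conversion of (e nm^-3 integrated twice over nm) to volts.
_UNIT = _E_OVER_EPS0 * 1e-27 / (1e-9) ** 2 * (1e-9) ** 2 * 1e18
# rho [e nm^-3] -> C m^-3 multiplies by e * 1e27; each dz integral brings 1e-9 m,
# so Psi = (1/eps0) * e * 1e27 * 1e-18 * (value in e nm^-1) = _E_OVER_EPS0 * 1e9.
_PSI_SCALE = _E_OVER_EPS0 * 1e9


@dataclass
class ChargeDensityProfile:
    edges: np.ndarray            # (n_slices + 1,) nm
    centres: np.ndarray          # (n_slices,) nm
    rho: np.ndarray              # (n_slices,) e nm^-3, window mean
    box_area: float              # nm^2
    psi: Optional[np.ndarray] = None   # (n_slices,) volts, on slice centres

    @property
    def total_charge(self) -> float:
        dz = np.diff(self.edges)
        return float(np.sum(self.rho * dz * self.box_area))


@dataclass
class TMVSeries:
    times: np.ndarray            # ps, window centres
    tmv: np.ndarray              # volts


def charge_density(
    frames: Sequence[Frame],
    registry: LipidRegistry,
    charge_map: Optional[Mapping[str, float]] = None,
    n_slices: int = 200,
) -> ChargeDensityProfile:
    """Window-averaged charge density per z-slice.

    Every atom must resolve to a charge through the registry or the extra
    charge map; unresolvable atoms are a hard error.
    """
    if n_slices < 10:
        raise LamellaError("n_slices must be >= 10")
    if not frames:
        raise LamellaError("empty frame window")
    table = ResidueTable(frames[0])
    charges = resolve_charges(frames[0], registry, charge_map, table=table)
    lz = float(np.mean([f.box[2] for f in frames]))
    area = float(np.mean([f.box[0] * f.box[1] for f in frames]))
    edges = np.linspace(0.0, lz, n_slices + 1)
    dz = edges[1] - edges[0]
    acc = np.zeros(n_slices)
    for frame in frames:
        z = frame.positions[:, 2] % lz
        idx = np.minimum((z / dz).astype(int), n_slices - 1)
        np.add.at(acc, idx, charges)
    rho = acc / len(frames) / (area * dz)
    return ChargeDensityProfile(edges=edges,
                                centres=0.5 * (edges[:-1] + edges[1:]),
                                rho=rho, box_area=area)


def potential_profile(profile: ChargeDensityProfile) -> ChargeDensityProfile:
    """Attach Psi(z) in volts via the double cumulative trapezoid."""
    z = profile.centres
    inner = cumulative_trapezoid(profile.rho, z, initial=0.0)   # e nm^-2
    psi = -cumulative_trapezoid(inner, z, initial=0.0) * _PSI_SCALE
    profile.psi = psi - psi[0]          # Psi anchored to 0 at the box bottom
    return profile


def _compartment_windows(layout_zs: np.ndarray, lz: float):
    """Central-50% z masks for the inner and outer water compartments.

    ``layout_zs`` holds the four leaflet reference heights of a stacked
    double bilayer, bottom to top.  The inner compartment spans leaflet 1
    to leaflet 2; the outer one wraps from leaflet 3 through the periodic
    boundary to leaflet 0.
    """
    z1, z2 = layout_zs[1], layout_zs[2]
    inner_lo = z1 + 0.25 * (z2 - z1)
    inner_hi = z1 + 0.75 * (z2 - z1)
    width_out = layout_zs[0] + lz - layout_zs[3]
    out_lo = (layout_zs[3] + 0.25 * width_out) % lz
    out_hi = (layout_zs[3] + 0.75 * width_out) % lz
    return (inner_lo, inner_hi), (out_lo, out_hi)


def _mask_between(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if lo <= hi:
        return (z >= lo) & (z <= hi)
    return (z >= lo) | (z <= hi)        # wraps through the periodic boundary


def tmv_series(
    frames: Sequence[Frame],
    layout: BilayerLayout,
    registry: LipidRegistry,
    assignment: Optional[LeafletAssignment] = None,
    charge_map: Optional[Mapping[str, float]] = None,
    window: int = 10,
    n_slices: int = 200,
) -> TMVSeries:
    """TMV against time for a stacked double bilayer.

    The trajectory is split into consecutive windows of ``window`` frames;
    each window yields one potential profile and one TMV value (inner
    minus outer compartment plateau average), time-stamped at the window
    centre.  Positive TMV means the inner compartment sits at the higher
    potential.
    """
    if layout.n_bilayers != 2:
        raise LamellaError("TMV requires a double bilayer layout")
    if window < 1:
        raise LamellaError("window must be >= 1 frame")
    times, tmvs = [], []
    for start in range(0, len(frames) - window + 1, window):
        chunk = frames[start:start + window]
        profile = potential_profile(
            charge_density(chunk, registry, charge_map, n_slices=n_slices))
        leaf_z = _leaflet_reference_heights(chunk[0], layout, registry, assignment)
        lz = profile.edges[-1]
        (ilo, ihi), (olo, ohi) = _compartment_windows(leaf_z, lz)
        z = profile.centres
        inner = _mask_between(z, ilo, ihi)
        outer = _mask_between(z, olo, ohi)
        if not inner.any() or not outer.any():
            raise LamellaError("water compartment too thin for plateau averaging")
        tmvs.append(profile.psi[inner].mean() - profile.psi[outer].mean())
        times.append(0.5 * (chunk[0].time + chunk[-1].time))
    return TMVSeries(times=np.array(times), tmv=np.array(tmvs))


def _leaflet_reference_heights(
    frame: Frame,
    layout: BilayerLayout,
    registry: LipidRegistry,
    assignment: Optional[LeafletAssignment],
) -> np.ndarray:
    """Mean phosphorus z of the four leaflets, bottom to top."""
    from .leaflets import assign_leaflets

    if assignment is None:
        assignment = assign_leaflets([frame], layout, registry)
    table = ResidueTable(frame)
    p_idx = []
    for resid in assignment.resids:
        res = table.by_resid(int(resid))
        d = registry.match_residue(res)
        p_idx.append(res.index_of(d.phosphorus_atom))
    p_idx = np.array(p_idx)
    heights = []
    for l in range(4):
        sel = assignment.lipids_in_leaflet(0, l)
        heights.append(frame.positions[p_idx[sel], 2].mean())
    return np.sort(np.array(heights))
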