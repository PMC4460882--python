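"""Lateral and axial headgroup orientation analysis.

The headgroup vector runs from the phosphorus to a second reference atom on
the headgroup (choline/ethanolamine nitrogen for PC/PE, a glycerol oxygen
for PG by default).  The lateral angle is the elevation of that vector
above the membrane plane measured along the *outward* leaflet normal
(+z for upper leaflets, -z for lower), so 0 degrees means the headgroup
lies parallel to the surface and positive angles point away from the
membrane in both leaflets.  The axial angle is the polar angle of the
vector's projection onto the membrane (xy) plane, mapped to [0, 2 pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .leaflets import LeafletAssignment
from .model import Frame, LamellaError
from .order import _leaflet_mask, _selected_lipids
from .registry import LipidRegistry

__all__ = ["LateralAngleHistogram", "lateral_angles", "axial_angles"]


@dataclass
class LateralAngleHistogram:
    """Lateral-angle distribution for one lipid type, -90..90 degrees."""

    lipid_type: str
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_per_leaflet: dict[int, float]      # leaflet index -> mean angle, deg
    mean: float                             # all sampled angles, deg
    n_skipped: int = 0                      # zero-length headgroup vectors


def _headgroup_indices(frame0: Frame, registry: LipidRegistry,
                       selection: Optional[set[int]]):
    """Per lipid type: (lipid positions, P indices, reference indices)."""
    by_type: dict[str, dict] = {}
    for res, d, pos in _selected_lipids(frame0, registry, selection):
        if not res.has(d.headgroup_reference_atom):
            raise LamellaError(
                f"residue {res.resname}:{res.resid}: headgroup reference atom "
                f"{d.headgroup_reference_atom!r} not found"
            )
        g = by_type.setdefault(d.residue_name, {"pos": [], "p": [], "ref": []})
        g["pos"].append(pos)
        g["p"].append(res.index_of(d.phosphorus_atom))
        g["ref"].append(res.index_of(d.headgroup_reference_atom))
    for g in by_type.values():
        for k in g:
            g[k] = np.array(g[k], dtype=int)
    return by_type


def _outward_sign(assignment: LeafletAssignment, frame_idx: int,
                  lipid_pos: np.ndarray) -> np.ndarray:
    """+1 where the leaflet's outward normal is +z (upper leaflets), else -1."""
    leaf = assignment.leaflet_per_frame[frame_idx, lipid_pos]
    upper = np.array([assignment.layout.leaflets[l].side == "upper" for l in leaf])
    return np.where(upper, 1.0, -1.0)


def lateral_angles(
    frames: Sequence[Frame],
    assignment: LeafletAssignment,
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
    leaflet: Optional[int] = None,
    bin_width: float = 1.0,
) -> dict[str, LateralAngleHistogram]:
    """Out-of-plane headgroup angle histograms per lipid type.

    angle = arcsin(outward z component / |vector|), in [-90, 90] degrees.
    """
    by_type = _headgroup_indices(frames[0], registry, selection)
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    out: dict[str, LateralAngleHistogram] = {}
    for lipid_type, g in by_type.items():
        counts = np.zeros(len(edges) - 1, dtype=int)
        sums: dict[int, float] = {}
        ns: dict[int, int] = {}
        total_sum, total_n, skipped = 0.0, 0, 0
        for f, frame in enumerate(frames):
            mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
            if not mask.any():
                continue
            vec = frame.positions[g["ref"][mask]] - frame.positions[g["p"][mask]]
            norm = np.linalg.norm(vec, axis=-1)
            ok = norm > 1e-10
            skipped += int((~ok).sum())
            sign = _outward_sign(assignment, f, g["pos"][mask])
            ang = np.degrees(np.arcsin(
                np.clip(sign[ok] * vec[ok, 2] / norm[ok], -1.0, 1.0)))
            counts += np.histogram(ang, bins=edges)[0]
            total_sum += ang.sum()
            total_n += ang.size
            leaf_idx = assignment.leaflet_per_frame[f, g["pos"][mask]][ok]
            for l in np.unique(leaf_idx):
                sel = leaf_idx == l
                sums[int(l)] = sums.get(int(l), 0.0) + ang[sel].sum()
                ns[int(l)] = ns.get(int(l), 0) + int(sel.sum())
        means = {l: sums[l] / ns[l] for l in sums if ns[l] > 0}
        out[lipid_type] = LateralAngleHistogram(
            lipid_type=lipid_type, bin_edges=edges, counts=counts,
            mean_per_leaflet=means,
            mean=(total_sum / total_n) if total_n else float("nan"),
            n_skipped=skipped,
        )
    return out


def axial_angles(
    frames: Sequence[Frame],
    assignment: LeafletAssignment,
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
) -> dict[int, np.ndarray]:
    """Per-lipid time series of the radial (in-plane) headgroup angle.

    Returns resid -> array of angles in [0, 2 pi) radians, NaN where the
    in-plane projection vanishes.
    """
    by_type = _headgroup_indices(frames[0], registry, selection)
    series: dict[int, np.ndarray] = {}
    for g in by_type.values():
        resids = assignment.resids[g["pos"]]
        arr = np.full((len(frames), len(resids)), np.nan)
        for f, frame in enumerate(frames):
            vec = frame.positions[g["ref"]] - frame.positions[g["p"]]
            in_plane = np.hypot(vec[:, 0], vec[:, 1])
            ang = np.mod(np.arctan2(vec[:, 1], vec[:, 0]), 2.0 * np.pi)
            arr[f] = np.where(in_plane > 1e-10, ang, np.nan)
        for j, rid in enumerate(resids):
            series[int(rid)] = arr[:, j]
    return series
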