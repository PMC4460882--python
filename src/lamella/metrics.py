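"""Membrane/leaflet thickness, area per lipid and gel-fraction metrics.

Thickness uses a user-chosen reference atom (the phosphorus by default):
membrane thickness is the difference of the mean reference-atom heights of
two opposing leaflets, leaflet thickness the distance of a leaflet's mean
reference height from the bilayer's geometric centre.  APL divides the
lateral box area by the lipids per leaflet, recomputed per frame so
asymmetric bilayers and flip-flops yield distinct per-leaflet values.  A
lipid counts as gel when each of its tails is nearly fully extended: the
first-to-last tail-atom distance must reach ``tolerance`` times the tail's
all-trans (force-field) extension on every tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .leaflets import LeafletAssignment
from .model import Frame, LamellaError, ResidueTable
from .registry import LipidRegistry

__all__ = ["ThicknessSeries", "GelClassification", "membrane_thickness",
           "area_per_lipid", "gel_percentage"]


@dataclass
class ThicknessSeries:
    times: np.ndarray                       # (n_frames,) ps
    membrane: np.ndarray                    # (n_frames, n_bilayers) nm
    leaflet: dict[int, np.ndarray]          # leaflet index -> (n_frames,) nm
    reference_atom: str


@dataclass
class GelClassification:
    times: np.ndarray
    gel_flags: np.ndarray                   # (n_frames, n_lipids) bool
    excluded: np.ndarray                    # (n_lipids,) bool, missing tail atoms
    resids: np.ndarray
    percentage: np.ndarray                  # (n_frames,) overall %
    per_leaflet: dict[int, np.ndarray]      # leaflet -> (n_frames,) %
    tolerance: float


def _reference_indices(frame0: Frame, assignment: LeafletAssignment,
                       registry: LipidRegistry, reference_atom: Optional[str]):
    table = ResidueTable(frame0)
    idx = np.empty(assignment.n_lipids, dtype=int)
    for pos, resid in enumerate(assignment.resids):
        res = table.by_resid(int(resid))
        d = registry.match_residue(res)
        name = reference_atom or d.phosphorus_atom
        idx[pos] = res.index_of(name)
    return idx


def membrane_thickness(
    frames: Sequence[Frame],
    assignment: LeafletAssignment,
    registry: LipidRegistry,
    reference_atom: Optional[str] = None,
) -> ThicknessSeries:
    """Per-frame membrane and leaflet thickness from reference-atom heights."""
    ref_idx = _reference_indices(frames[0], assignment, registry, reference_atom)
    layout = assignment.layout
    n_frames = len(frames)
    membrane = np.full((n_frames, layout.n_bilayers), np.nan)
    leaflet = {l: np.full(n_frames, np.nan) for l in range(len(layout.leaflets))}
    times = np.array([f.time for f in frames])
    table = ResidueTable(frames[0])
    atoms_per_lipid = [table.by_resid(int(r)).atom_indices for r in assignment.resids]
    for f, frame in enumerate(frames):
        z_ref = frame.positions[ref_idx, 2]
        for b in range(layout.n_bilayers):
            lo = layout.leaflet_index(b, upper=False)
            hi = layout.leaflet_index(b, upper=True)
            sel_lo = assignment.lipids_in_leaflet(f, lo)
            sel_hi = assignment.lipids_in_leaflet(f, hi)
            if len(sel_lo) == 0 or len(sel_hi) == 0:
                raise LamellaError(
                    f"bilayer {b}: empty leaflet, thickness undefined"
                )
            membrane[f, b] = z_ref[sel_hi].mean() - z_ref[sel_lo].mean()
            atoms = np.concatenate(
                [atoms_per_lipid[i] for i in
                 np.flatnonzero(assignment.lipid_bilayer == b)])
            centre = frame.positions[atoms, 2].mean()
            leaflet[hi][f] = abs(z_ref[sel_hi].mean() - centre)
            leaflet[lo][f] = abs(z_ref[sel_lo].mean() - centre)
    return ThicknessSeries(times=times, membrane=membrane, leaflet=leaflet,
                           reference_atom=reference_atom or "phosphorus")


def area_per_lipid(
    frames: Sequence[Frame],
    assignment: LeafletAssignment,
) -> dict[int, np.ndarray]:
    """Per-leaflet APL series: lateral box area / lipids in the leaflet."""
    out = {l: np.full(len(frames), np.nan)
           for l in range(len(assignment.layout.leaflets))}
    for f, frame in enumerate(frames):
        area = frame.box[0] * frame.box[1]
        for l in out:
            n = len(assignment.lipids_in_leaflet(f, l))
            if n == 0:
                raise LamellaError(f"leaflet {l}: no lipids, APL undefined")
            out[l][f] = area / n
    return out


def gel_percentage(
    frames: Sequence[Frame],
    assignment: LeafletAssignment,
    registry: LipidRegistry,
    tolerance: float = 0.9,
) -> GelClassification:
    """Classify lipids as gel by tail end-to-end extension.

    Gel iff, on every tail, the distance between first and last tail atoms
    is at least ``tolerance`` x the tail's all-trans extension.  Lipids
    with missing tail atoms are excluded and tallied.
    """
    if not 0.0 < tolerance <= 1.0:
        raise LamellaError("tolerance must be in (0, 1]")
    table = ResidueTable(frames[0])
    ends, maxima = [], []
    excluded = np.zeros(assignment.n_lipids, dtype=bool)
    for pos, resid in enumerate(assignment.resids):
        res = table.by_resid(int(resid))
        d = registry.match_residue(res)
        try:
            ends.append([(res.index_of(t[0]), res.index_of(t[-1])) for t in d.tails])
            maxima.append(list(d.max_tail_extension))
        except LamellaError:
            excluded[pos] = True
            ends.append([(0, 0)] * len(d.tails))
            maxima.append([np.inf] * len(d.tails))
    ends = np.array(ends, dtype=int)            # (n_lipids, n_tails, 2)
    maxima = np.array(maxima)                   # (n_lipids, n_tails)

    n_frames = len(frames)
    flags = np.zeros((n_frames, assignment.n_lipids), dtype=bool)
    for f, frame in enumerate(frames):
        delta = frame.positions[ends[..., 1]] - frame.positions[ends[..., 0]]
        dist = np.linalg.norm(delta, axis=-1)
        flags[f] = np.all(dist >= tolerance * maxima, axis=-1) & ~excluded
    ok = ~excluded
    percentage = 100.0 * flags[:, ok].sum(axis=1) / max(ok.sum(), 1)
    per_leaflet = {}
    for l in range(len(assignment.layout.leaflets)):
        series = np.full(n_frames, np.nan)
        for f in range(n_frames):
            sel = assignment.lipids_in_leaflet(f, l)
            sel = sel[~excluded[sel]]
            if len(sel):
                series[f] = 100.0 * flags[f, sel].sum() / len(sel)
        per_leaflet[l] = series
    return GelClassification(
        times=np.array([f.time for f in frames]), gel_flags=flags,
        excluded=excluded, resids=assignment.resids.copy(),
        percentage=percentage, per_leaflet=per_leaflet, tolerance=tolerance,
    )
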