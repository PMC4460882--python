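"""Lipid mixing/demixing entropy from nearest-neighbour type statistics.

Within a leaflet, every lipid's single nearest neighbour is found by the
minimum-image phosphorus-phosphorus distance.  The (type, neighbour-type)
pairs are binned into a joint probability matrix p(x, nb) normalised to 1;
the mixing entropy is

    S = - sum_{x,nb} p(x, nb) ln p(x | nb)        (nats per lipid)

with the conditional p(x | nb) = p(x, nb) / p(nb).  The theoretical
maximum for the composition is S_max = - sum_x rho_x ln rho_x, attained by
a perfectly random mixture, and the scaled entropy S / S_max is 1 for an
ideally mixed system and tends to 0 as types segregate.

The neighbour search uses a periodic k-d tree for candidates but rescores
them with the same minimum-image arithmetic as the brute-force O(N^2)
oracle, breaking exact ties by lowest lipid index, so both routes agree
bit-for-bit even on unjittered lattices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .leaflets import LeafletAssignment
from .model import Frame, LamellaError, ResidueTable, wrap_minimum_image
from .registry import LipidRegistry

__all__ = ["NeighbourProbabilityMatrix", "EntropyResult", "nearest_neighbours",
           "neighbour_matrix", "entropy", "entropy_series", "NN_TIE_TOL"]

#: squared-distance slack (nm^2) below which neighbour candidates count as
#: tied; ~(3e-5 nm)^2, orders of magnitude below structure-file precision.
NN_TIE_TOL = 1e-9


@dataclass
class NeighbourProbabilityMatrix:
    types: tuple[str, ...]
    joint: np.ndarray          # p(x, nb), sums to 1
    conditional: np.ndarray    # p(x | nb), columns sum to 1 where defined
    n_lipids: int


@dataclass
class EntropyResult:
    S: float                   # nats per lipid
    S_max: float               # nats
    S_scaled: float            # S / S_max


def nearest_neighbours(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Index of each point's nearest neighbour under periodic boundaries.

    Candidates come from a periodic k-d tree; final distances are
    recomputed with explicit minimum-image arithmetic and ties broken by
    lowest index (np.argmin order), matching the brute-force oracle.
    """
    n = len(points)
    if n < 2:
        raise LamellaError("nearest-neighbour search needs >= 2 lipids")
    k = min(n, 13)                      # up to 12 candidates + self
    wrapped = points % box
    tree = cKDTree(wrapped, boxsize=box)
    _, cand = tree.query(wrapped, k=k)
    cand = np.atleast_2d(cand)
    out = np.empty(n, dtype=int)
    for i in range(n):
        ids = np.unique(cand[i])
        ids = ids[ids != i]
        delta = wrap_minimum_image(points[ids] - points[i], box)
        d2 = np.einsum("ij,ij->i", delta, delta)
        # squared distances within NN_TIE_TOL (far below coordinate precision)
        # count as tied; ids is sorted, so argmax picks the lowest index
        tied = d2 <= d2.min() + NN_TIE_TOL
        out[i] = ids[np.argmax(tied)]
    return out


def _phosphorus_xy(frame: Frame, assignment: LeafletAssignment,
                   registry: LipidRegistry, table: ResidueTable) -> np.ndarray:
    idx = np.empty(assignment.n_lipids, dtype=int)
    for pos, resid in enumerate(assignment.resids):
        res = table.by_resid(int(resid))
        d = registry.match_residue(res)
        idx[pos] = res.index_of(d.phosphorus_atom)
    return frame.positions[idx]


def neighbour_matrix(
    frame: Frame,
    assignment: LeafletAssignment,
    registry: LipidRegistry,
    leaflet: int,
    frame_idx: int = 0,
    table: Optional[ResidueTable] = None,
) -> NeighbourProbabilityMatrix:
    """Joint/conditional nearest-neighbour type probabilities for a leaflet."""
    table = table or ResidueTable(frame)
    sel = assignment.lipids_in_leaflet(frame_idx, leaflet)
    if len(sel) < 2:
        raise LamellaError(f"leaflet {leaflet}: needs >= 2 lipids for neighbours")
    pos = _phosphorus_xy(frame, assignment, registry, table)[sel]
    nn = nearest_neighbours(pos, frame.box)
    types = tuple(sorted({str(t) for t in assignment.resnames}))
    t_index = {t: i for i, t in enumerate(types)}
    labels = np.array([t_index[str(t)] for t in assignment.resnames[sel]])
    joint = np.zeros((len(types), len(types)))
    np.add.at(joint, (labels, labels[nn]), 1.0)
    joint /= joint.sum()
    p_nb = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        conditional = np.where(p_nb > 0, joint / p_nb, 0.0)
    return NeighbourProbabilityMatrix(types=types, joint=joint,
                                      conditional=conditional,
                                      n_lipids=len(sel))


def entropy(
    matrix: NeighbourProbabilityMatrix,
    densities: Optional[np.ndarray] = None,
) -> EntropyResult:
    """Mixing entropy, theoretical maximum and scaled value.

    ``densities`` are the per-type number fractions rho_x; by default the
    joint matrix's row marginal.  A single-type composition has S_max = 0
    and no defined scaled entropy.
    """
    if densities is None:
        densities = matrix.joint.sum(axis=1)
    densities = np.asarray(densities, dtype=float)
    if not np.isclose(densities.sum(), 1.0):
        raise LamellaError("type densities must sum to 1")
    pos = densities > 0
    s_max = float(-(densities[pos] * np.log(densities[pos])).sum())
    if s_max == 0.0:
        raise LamellaError(
            "degenerate composition (single lipid type): S_max = 0, "
            "scaled entropy undefined"
        )
    j = matrix.joint
    c = matrix.conditional
    mask = j > 0
    s = float(-(j[mask] * np.log(c[mask])).sum())
    return EntropyResult(S=s, S_max=s_max, S_scaled=s / s_max)


def entropy_series(
    frames: Sequence[Frame],
    assignment: LeafletAssignment,
    registry: LipidRegistry,
) -> tuple[np.ndarray, list[EntropyResult]]:
    """System mixing entropy per frame.

    Each leaflet with at least two lipids contributes its entropy and its
    composition's S_max, combined as lipid-count-weighted means; the
    scaled value is their ratio.
    """
    table = ResidueTable(frames[0])
    times = np.array([f.time for f in frames])
    results: list[EntropyResult] = []
    n_leaflets = len(assignment.layout.leaflets)
    for f, frame in enumerate(frames):
        s_sum = smax_sum = w_sum = 0.0
        for l in range(n_leaflets):
            sel = assignment.lipids_in_leaflet(f, l)
            if len(sel) < 2:
                continue
            m = neighbour_matrix(frame, assignment, registry, l,
                                 frame_idx=f, table=table)
            res = entropy(m)
            w = float(len(sel))
            s_sum += w * res.S
            smax_sum += w * res.S_max
            w_sum += w
        if w_sum == 0:
            raise LamellaError(f"frame {f}: no leaflet with >= 2 lipids")
        results.append(EntropyResult(S=s_sum / w_sum, S_max=smax_sum / w_sum,
                                     S_scaled=s_sum / smax_sum))
    return times, results
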