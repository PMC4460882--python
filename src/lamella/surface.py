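"""2D surface, density and thickness maps of bilayer leaflets.

Atom heights are binned into a periodic 2D lattice; each cell keeps the
height of its outermost atom (relative to the bilayer centre, measured
along the leaflet's outward normal).  Iterative Gauss-Seidel smoothing of
the lattice,

    phi[i,j] <- ( A[i,j] + phi[i-1,j] + phi[i+1,j] + phi[i,j-1] + phi[i,j+1] ) / 4,

spreads each cell's height into a smooth bump (a Laplace-smoothed height /
density field; the update treats A as the source term of a discrete Poisson
problem).  Sweeps are in-place and row-major with periodic neighbour
indexing; cells that received no atoms are holes — they are never updated,
contribute nothing to their neighbours' sums, and render black.  After
sweeping, phi is min-max normalised over non-hole cells to [0, 1] and
mapped onto a blue -> green -> red colour ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .leaflets import LeafletAssignment
from .model import Frame, LamellaError, ResidueTable
from .registry import LipidRegistry

__all__ = [
    "SurfaceLattice",
    "RenderedMap",
    "bin_leaflet",
    "gauss_seidel",
    "render_map",
    "thickness_map",
]


@dataclass
class SurfaceLattice:
    """Periodic 2D lattice of per-cell heights and the smoothed field."""

    nx: int
    ny: int
    cell_size: float                     # nm
    A: np.ndarray                        # (nx, ny) outermost-atom height, nm
    occupied: np.ndarray                 # (nx, ny) atom counts
    phi: np.ndarray = field(default=None)  # smoothed scalar field

    def __post_init__(self) -> None:
        if self.phi is None:
            self.phi = np.zeros((self.nx, self.ny))

    @property
    def holes(self) -> np.ndarray:
        return self.occupied == 0


@dataclass
class RenderedMap:
    """RGB pixel rendering of a smoothed lattice with optional overlays."""

    pixels: np.ndarray                   # (H, W, 3) uint8
    cell_size: float
    overlays: tuple = ()

    def save(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels).save(path)


def _bin_xy(frame: Frame, atom_idx: np.ndarray, cell_size: float):
    box = frame.box
    if cell_size >= min(box[0], box[1]):
        raise LamellaError(
            f"cell size {cell_size} nm must be smaller than the box edges "
            f"({box[0]} x {box[1]} nm)"
        )
    nx = max(1, int(round(box[0] / cell_size)))
    ny = max(1, int(round(box[1] / cell_size)))
    xy = frame.positions[atom_idx, :2] % box[:2]
    ix = np.minimum((xy[:, 0] / box[0] * nx).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / box[1] * ny).astype(int), ny - 1)
    return nx, ny, ix, iy


def _leaflet_atoms(frame: Frame, assignment: LeafletAssignment, leaflet: int,
                   frame_idx: int, registry: LipidRegistry,
                   reference_atom: Optional[str] = None) -> np.ndarray:
    table = ResidueTable(frame)
    lipid_pos = assignment.lipids_in_leaflet(frame_idx, leaflet)
    if len(lipid_pos) == 0:
        raise LamellaError(f"leaflet {leaflet} is empty")
    idx: list[np.ndarray] = []
    for pos in lipid_pos:
        res = table.by_resid(int(assignment.resids[pos]))
        if reference_atom is None:
            idx.append(res.atom_indices)
        else:
            idx.append(np.array([res.index_of(reference_atom)]))
    return np.concatenate(idx)


def bin_leaflet(
    frame: Frame,
    assignment: LeafletAssignment,
    leaflet: int,
    cell_size: float = 0.1,
    registry: Optional[LipidRegistry] = None,
    frame_idx: int = 0,
    reference_atom: Optional[str] = None,
) -> SurfaceLattice:
    """Bin one leaflet's atoms into a lattice of outward heights.

    Heights are measured from the bilayer centre along the leaflet's
    outward normal, so 'highest' means outermost for both leaflets; x,y
    are wrapped periodically into the box.
    """
    atom_idx = _leaflet_atoms(frame, assignment, leaflet, frame_idx,
                              registry, reference_atom)
    nx, ny, ix, iy = _bin_xy(frame, atom_idx, cell_size)
    leaf = assignment.layout.leaflets[leaflet]
    centre = frame.positions[
        np.concatenate([ResidueTable(frame).by_resid(int(r)).atom_indices
                        for r in assignment.resids[assignment.lipid_bilayer == leaf.bilayer]]),
        2].mean()
    sign = 1.0 if leaf.side == "upper" else -1.0
    height = sign * (frame.positions[atom_idx, 2] - centre)
    A = np.full((nx, ny), -np.inf)
    occupied = np.zeros((nx, ny), dtype=int)
    np.maximum.at(A, (ix, iy), height)
    np.add.at(occupied, (ix, iy), 1)
    A[occupied == 0] = 0.0
    return SurfaceLattice(nx=nx, ny=ny, cell_size=cell_size, A=A, occupied=occupied)


def gauss_seidel(lattice: SurfaceLattice, n_sweeps: int = 50,
                 normalise: bool = True, demean: bool = True) -> SurfaceLattice:
    """In-place row-major Gauss-Seidel sweeps over the lattice.

    Hole cells are skipped and contribute zero to neighbour sums.  With
    ``demean`` the source term A has its non-hole mean removed first: on a
    periodic lattice the discrete Poisson problem only has a solution for a
    zero-mean source, and without this a uniform height field would never
    settle (the min-max normalisation then just amplifies sweep-order
    noise).  With ``normalise`` the non-hole field is min-max scaled to
    [0, 1] after the final sweep (holes keep phi = 0 but stay flagged).
    """
    if n_sweeps < 1:
        raise LamellaError("n_sweeps must be >= 1")
    nx, ny = lattice.nx, lattice.ny
    phi = lattice.phi.copy()
    holes = lattice.holes
    A = lattice.A
    if demean and (~holes).any():
        A = np.where(holes, 0.0, A - A[~holes].mean())
    for _ in range(n_sweeps):
        for i in range(nx):
            im, ip = (i - 1) % nx, (i + 1) % nx
            for j in range(ny):
                if holes[i, j]:
                    continue
                jm, jp = (j - 1) % ny, (j + 1) % ny
                s = 0.0
                if not holes[im, j]:
                    s += phi[im, j]
                if not holes[ip, j]:
                    s += phi[ip, j]
                if not holes[i, jm]:
                    s += phi[i, jm]
                if not holes[i, jp]:
                    s += phi[i, jp]
                phi[i, j] = 0.25 * (A[i, j] + s)
    if normalise:
        vals = phi[~holes]
        lo, hi = vals.min(), vals.max()
        # degenerate (uniform) fields map to mid-scale instead of blowing
        # float noise up to the full colour range
        if hi - lo > 1e-9 * max(1.0, abs(hi), abs(lo)):
            phi = np.where(holes, 0.0, (phi - lo) / (hi - lo))
        else:
            phi = np.where(holes, 0.0, 0.5)
    return SurfaceLattice(nx=nx, ny=ny, cell_size=lattice.cell_size,
                          A=lattice.A.copy(), occupied=lattice.occupied.copy(),
                          phi=phi)


def _colour_ramp(phi: np.ndarray) -> np.ndarray:
    """Linear blue -> green -> red ramp on phi in [0, 1]."""
    t = np.clip(phi, 0.0, 1.0)
    r = np.clip(2.0 * t - 1.0, 0.0, 1.0)
    b = np.clip(1.0 - 2.0 * t, 0.0, 1.0)
    g = 1.0 - r - b
    return (np.stack([r, g, b], axis=-1) * 255).astype(np.uint8)


def render_map(
    lattice: SurfaceLattice,
    overlays: Sequence[tuple[float, float]] = (),
    box: Optional[np.ndarray] = None,
    pixels_per_cell: int = 1,
    marker_radius: int = 1,
) -> RenderedMap:
    """Render the smoothed field to RGB: blue (low) -> green -> red (high),
    black holes, white overlay markers drawn at periodically wrapped x,y."""
    phi = lattice.phi
    vals = phi[~lattice.holes]
    if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
        raise LamellaError("render_map expects a normalised field; "
                           "run gauss_seidel(..., normalise=True) first")
    rgb = _colour_ramp(phi)
    rgb[lattice.holes] = 0
    img = np.repeat(np.repeat(rgb.transpose(1, 0, 2)[::-1], pixels_per_cell, axis=0),
                    pixels_per_cell, axis=1)  # row 0 at top = max y
    H, W = img.shape[:2]
    if overlays:
        Lx = lattice.nx * lattice.cell_size if box is None else float(box[0])
        Ly = lattice.ny * lattice.cell_size if box is None else float(box[1])
        for (ox, oy) in overlays:
            px = (ox % Lx) / Lx * W
            py = (oy % Ly) / Ly * H
            for du in range(-marker_radius, marker_radius + 1):
                for dv in range(-marker_radius, marker_radius + 1):
                    if du * du + dv * dv > marker_radius * marker_radius:
                        continue
                    u = int(px + du) % W
                    v = int(H - 1 - py + dv) % H
                    img[v, u] = (255, 255, 255)
    return RenderedMap(pixels=img, cell_size=lattice.cell_size,
                       overlays=tuple(overlays))


def thickness_map(
    frame: Frame,
    assignment: LeafletAssignment,
    reference_atom: str,
    cell_size: float = 0.1,
    registry: Optional[LipidRegistry] = None,
    bilayer: int = 0,
    frame_idx: int = 0,
    n_sweeps: int = 50,
) -> RenderedMap:
    """Local membrane thickness map from reference-atom heights.

    Reference atoms of the two opposing leaflets are binned separately;
    each cell's A value is the mean upper height minus the mean lower
    height, cells lacking either leaflet are holes, and the same
    Gauss-Seidel pipeline renders the result.
    """
    lower = assignment.layout.leaflet_index(bilayer, upper=False)
    upper = assignment.layout.leaflet_index(bilayer, upper=True)
    sums, counts = [], []
    nx = ny = None
    for leaflet in (upper, lower):
        atom_idx = _leaflet_atoms(frame, assignment, leaflet, frame_idx,
                                  registry, reference_atom)
        nx, ny, ix, iy = _bin_xy(frame, atom_idx, cell_size)
        s = np.zeros((nx, ny))
        c = np.zeros((nx, ny), dtype=int)
        np.add.at(s, (ix, iy), frame.positions[atom_idx, 2])
        np.add.at(c, (ix, iy), 1)
        sums.append(s)
        counts.append(c)
    both = (counts[0] > 0) & (counts[1] > 0)
    A = np.zeros((nx, ny))
    A[both] = sums[0][both] / counts[0][both] - sums[1][both] / counts[1][both]
    lattice = SurfaceLattice(nx=nx, ny=ny, cell_size=cell_size, A=A,
                             occupied=both.astype(int))
    return render_map(gauss_seidel(lattice, n_sweeps=n_sweeps))
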