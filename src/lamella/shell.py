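"""Annular-shell analysis: lipids in contact with an embedded molecule.

A lipid belongs to the shell when the minimum-image distance between *any*
of its atoms and *any* atom of the molecule is within the cutoff radius.
The search is accelerated with a periodic k-d tree; an O(N*M) all-pairs
scan gives identical membership and serves as the test oracle.  Control
groups are drawn at random from lipids outside the shell with the same
per-leaflet composition as the shell, optionally excluding gel lipids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .leaflets import LeafletAssignment
from .metrics import GelClassification
from .model import Frame, LamellaError, ResidueTable
from .registry import LipidRegistry

__all__ = ["ShellSelection", "OccupancyRecord", "select_shell",
           "select_shell_series", "select_control", "shell_type_ratio",
           "occupancy"]


@dataclass
class ShellSelection:
    """Per-frame shell membership (lipid resids) at one cutoff radius."""

    radius: float
    times: np.ndarray
    members: list[frozenset[int]]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])


@dataclass
class OccupancyRecord:
    resids: np.ndarray
    frames_in_shell: np.ndarray             # per lipid
    events: dict[int, list[tuple[int, str]]]  # resid -> [(frame, "enter"/"exit")]
    shell_size: np.ndarray                  # per frame


def _lipid_atom_map(frame: Frame, registry: LipidRegistry,
                    exclude_resids: Optional[set[int]] = None):
    """Flat arrays of lipid atom indices and their owning resids."""
    table = ResidueTable(frame)
    atom_idx, owner = [], []
    for res in table:
        if registry.match_residue(res) is None:
            continue
        if exclude_resids and res.resid in exclude_resids:
            continue
        atom_idx.append(res.atom_indices)
        owner.append(np.full(res.n_atoms, res.resid))
    if not atom_idx:
        raise LamellaError("no recognised lipid atoms for shell selection")
    return np.concatenate(atom_idx), np.concatenate(owner)


def select_shell(
    frame: Frame,
    molecule_atoms: np.ndarray,
    registry: LipidRegistry,
    radius: float,
) -> frozenset[int]:
    """Resids of lipids with any atom within ``radius`` nm of the molecule."""
    if radius <= 0:
        raise LamellaError("shell radius must be > 0")
    molecule_atoms = np.asarray(molecule_atoms, dtype=int)
    if molecule_atoms.size == 0:
        raise LamellaError("molecule selection is empty")
    exclude = {int(r) for r in np.unique(frame.resids[molecule_atoms])}
    atom_idx, owner = _lipid_atom_map(frame, registry, exclude_resids=exclude)
    box = frame.box
    tree = cKDTree(frame.positions[atom_idx] % box, boxsize=box)
    hits = tree.query_ball_point(frame.positions[molecule_atoms] % box, r=radius)
    members = {int(owner[j]) for lst in hits for j in lst}
    return frozenset(members)


def select_shell_series(
    frames: Sequence[Frame],
    molecule_atoms: np.ndarray,
    registry: LipidRegistry,
    radius: float,
) -> ShellSelection:
    members = [select_shell(f, molecule_atoms, registry, radius) for f in frames]
    return ShellSelection(radius=radius,
                          times=np.array([f.time for f in frames]),
                          members=members)


def occupancy(selection: ShellSelection, all_resids: np.ndarray) -> OccupancyRecord:
    """Shell residency statistics: frames in shell and entry/exit events."""
    resids = np.asarray(all_resids)
    frames_in = np.zeros(len(resids), dtype=int)
    events: dict[int, list[tuple[int, str]]] = {}
    prev: frozenset[int] = frozenset()
    pos = {int(r): i for i, r in enumerate(resids)}
    for f, mem in enumerate(selection.members):
        for r in mem:
            if r in pos:
                frames_in[pos[r]] += 1
        for r in mem - prev:
            events.setdefault(int(r), []).append((f, "enter"))
        for r in prev - mem:
            events.setdefault(int(r), []).append((f, "exit"))
        prev = mem
    return OccupancyRecord(resids=resids, frames_in_shell=frames_in,
                           events=events, shell_size=selection.sizes)


def select_control(
    frame_idx: int,
    shell: frozenset[int],
    assignment: LeafletAssignment,
    mode: str = "match_count",
    n: Optional[int] = None,
    exclude_gel: bool = False,
    gel: Optional[GelClassification] = None,
    seed: int = 0,
) -> frozenset[int]:
    """Random control group outside the shell, leaflet-matched to it.

    ``mode`` is one of ``match_count`` (same number of lipids per leaflet
    as the shell), ``fixed_n`` (``n`` lipids, spread over the shell's
    leaflets proportionally) or ``all_outside`` (every eligible lipid in
    the shell's leaflets).  With ``exclude_gel`` a gel classification must
    be supplied and gel lipids are ineligible.  The draw is without
    replacement and reproducible for a given seed.
    """
    if mode not in ("match_count", "fixed_n", "all_outside"):
        raise LamellaError(f"unknown control mode {mode!r}")
    if exclude_gel and gel is None:
        raise LamellaError("exclude_gel requires a GelClassification")
    rng = np.random.default_rng(seed)
    leaf = assignment.leaflet_per_frame[frame_idx]
    in_shell = np.isin(assignment.resids, list(shell))
    shell_leaflets, shell_counts = np.unique(leaf[in_shell], return_counts=True)
    eligible = ~in_shell
    if exclude_gel:
        eligible &= ~gel.gel_flags[frame_idx]
    chosen: list[int] = []
    if mode == "fixed_n":
        if n is None or n <= 0:
            raise LamellaError("fixed_n mode needs n > 0")
        # largest-remainder apportioning over the shell's leaflets
        quota = shell_counts / shell_counts.sum() * n
        take = np.floor(quota).astype(int)
        rem = np.argsort(-(quota - take))
        for k in range(n - take.sum()):
            take[rem[k % len(take)]] += 1
        targets = dict(zip(shell_leaflets, take))
    elif mode == "match_count":
        targets = dict(zip(shell_leaflets, shell_counts))
    else:
        targets = {l: None for l in shell_leaflets}
    for l, want in targets.items():
        pool = np.flatnonzero(eligible & (leaf == l))
        if want is None:
            chosen.extend(int(assignment.resids[i]) for i in pool)
            continue
        if len(pool) < want:
            raise LamellaError(
                f"leaflet {l}: only {len(pool)} eligible control lipids, "
                f"{want} requested (pool exhausted)"
            )
        pick = rng.choice(pool, size=int(want), replace=False)
        chosen.extend(int(assignment.resids[i]) for i in pick)
    return frozenset(chosen)


def shell_type_ratio(
    selection: ShellSelection,
    assignment: LeafletAssignment,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-frame lipid-type fractions in the shell and time-averaged counts.

    Frames with an empty shell carry NaN fractions; the averaged counts are
    the mean per-frame occupancy per type, from which enrichment ratios
    (e.g. 2.6:1) follow directly.
    """
    type_of = {int(r): str(t) for r, t in
               zip(assignment.resids, assignment.resnames)}
    types = sorted(set(type_of.values()))
    n_frames = len(selection.members)
    fractions = {t: np.full(n_frames, np.nan) for t in types}
    counts = {t: np.zeros(n_frames) for t in types}
    for f, mem in enumerate(selection.members):
        if not mem:
            continue
        for r in mem:
            counts[type_of[int(r)]][f] += 1
        for t in types:
            fractions[t][f] = counts[t][f] / len(mem)
    mean_counts = {t: float(counts[t].mean()) for t in types}
    return fractions, mean_counts
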