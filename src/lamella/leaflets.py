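"""Leaflet assignment, bilayer layout detection, flip-flops and symmetry.

A lipid belongs to the upper leaflet of its bilayer iff the z of its
phosphorus (minimum image) lies above the bilayer's geometric centre, the
centre being the mean z of *all* atoms of the bilayer's lipids.  A
hysteresis margin suppresses jitter-induced false flip-flops: a lipid only
changes leaflet once its phosphorus has crossed the centre by more than
``hysteresis`` nm.

Single vs double bilayers are detected by gap-splitting the sorted
phosphorus z values: one significant gap means a single bilayer (two
leaflets), three mean a stacked double bilayer (four leaflets).  In double
bilayers the leaflets facing the compartment with net negative ion charge
are labelled anodic (the compartment cations were moved out of); with no
ions declared, positional inner/outer labels are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Frame, LamellaError, LipidDefinition, ResidueTable
from .registry import ION_CHARGES, LipidRegistry

__all__ = [
    "BilayerLayout",
    "LeafletInfo",
    "LeafletAssignment",
    "FlipFlopEvent",
    "detect_layout",
    "assign_leaflets",
    "leaflet_symmetry",
    "write_flip_flop_log",
]

#: Gaps in sorted phosphorus z larger than this (nm) separate leaflet bands.
SIGNIFICANT_GAP = 1.0


@dataclass(frozen=True)
class LeafletInfo:
    bilayer: int            # bilayer index, ordered by z
    side: str               # "lower" | "upper" within its bilayer
    label: str              # upper/lower, inner/outer or anodic/cathodic


@dataclass
class BilayerLayout:
    n_bilayers: int
    leaflets: tuple[LeafletInfo, ...]   # index 2*b (lower) and 2*b+1 (upper)
    bilayer_centres: np.ndarray         # (n_bilayers,) z in nm

    def leaflet_index(self, bilayer: int, upper: bool) -> int:
        return 2 * bilayer + (1 if upper else 0)

    def symmetry_groups(self) -> tuple[list[int], list[int], str, str]:
        """Leaflet indices of the (A, B) groups whose count difference is the
        leaflet symmetry: anodic-cathodic for double bilayers (inner-outer
        when no ions are declared), upper-lower for single bilayers."""
        if self.n_bilayers == 1:
            return [1], [0], "upper", "lower"
        by_label: dict[str, list[int]] = {}
        for i, leaf in enumerate(self.leaflets):
            by_label.setdefault(leaf.label, []).append(i)
        if "anodic" in by_label:
            return by_label["anodic"], by_label["cathodic"], "anodic", "cathodic"
        return by_label["inner"], by_label["outer"], "inner", "outer"


@dataclass(frozen=True)
class FlipFlopEvent:
    time: float             # ps
    resid: int
    resname: str
    from_leaflet: int
    to_leaflet: int


@dataclass
class LeafletAssignment:
    """Per-frame lipid -> leaflet mapping plus the flip-flop event log."""

    layout: BilayerLayout
    resids: np.ndarray                  # (n_lipids,)
    resnames: np.ndarray                # (n_lipids,)
    lipid_bilayer: np.ndarray           # (n_lipids,) bilayer index
    leaflet_per_frame: np.ndarray       # (n_frames, n_lipids) leaflet index
    times: np.ndarray                   # (n_frames,) ps
    flip_flop_events: list[FlipFlopEvent] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.leaflet_per_frame.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.leaflet_per_frame.shape[1]

    def lipids_in_leaflet(self, frame_idx: int, leaflet: int) -> np.ndarray:
        """Positions (into the lipid arrays) of that leaflet's lipids."""
        return np.flatnonzero(self.leaflet_per_frame[frame_idx] == leaflet)


def _lipid_records(
    frame: Frame, registry: LipidRegistry, table: Optional[ResidueTable] = None
) -> tuple[ResidueTable, list, list[LipidDefinition]]:
    table = table or ResidueTable(frame)
    residues, defs = [], []
    for res in table:
        d = registry.match_residue(res)
        if d is not None:
            residues.append(res)
            defs.append(d)
    return table, residues, defs


def detect_layout(
    frame: Frame,
    registry: LipidRegistry,
    table: Optional[ResidueTable] = None,
) -> BilayerLayout:
    """Detect single vs double bilayer from phosphorus z clustering."""
    table, residues, defs = _lipid_records(frame, registry, table)
    if len(residues) < 2:
        raise LamellaError("layout detection needs at least 2 recognised lipids")
    pz = np.array([frame.positions[r.index_of(d.phosphorus_atom), 2]
                   for r, d in zip(residues, defs)])
    order = np.argsort(pz)
    gaps = np.diff(pz[order])
    significant = np.flatnonzero(gaps > SIGNIFICANT_GAP)
    if len(significant) not in (1, 3):
        raise LamellaError(
            f"ambiguous bilayer layout: {len(significant)} phosphorus bands "
            f"split by gaps > {SIGNIFICANT_GAP} nm (expected 2 or 4 leaflet bands)"
        )
    n_bilayers = 1 if len(significant) == 1 else 2
    # groups of lipids per leaflet band, bottom to top
    bounds = [0, *(significant + 1), len(pz)]
    bands = [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    centres = []
    for b in range(n_bilayers):
        lipid_idx = np.concatenate([bands[2 * b], bands[2 * b + 1]])
        atoms = np.concatenate([residues[i].atom_indices for i in lipid_idx])
        centres.append(float(frame.positions[atoms, 2].mean()))
    centres = np.array(centres)
    if n_bilayers == 1:
        leaflets = (LeafletInfo(0, "lower", "lower"), LeafletInfo(0, "upper", "upper"))
    else:
        labels = _double_bilayer_labels(frame, table, registry, centres)
        leaflets = (
            LeafletInfo(0, "lower", labels["outer"]),
            LeafletInfo(0, "upper", labels["inner"]),
            LeafletInfo(1, "lower", labels["inner"]),
            LeafletInfo(1, "upper", labels["outer"]),
        )
    return BilayerLayout(n_bilayers=n_bilayers, leaflets=leaflets,
                         bilayer_centres=centres)


def _double_bilayer_labels(
    frame: Frame, table: ResidueTable, registry: LipidRegistry, centres: np.ndarray
) -> dict[str, str]:
    """Inner/outer labels, upgraded to anodic/cathodic when ions are present."""
    inner_q = outer_q = 0.0
    n_ions = 0
    for res in table:
        q = ION_CHARGES.get(res.resname.upper())
        if q is None or res.n_atoms != 1 or registry.is_lipid(res.resname):
            continue
        n_ions += 1
        z = frame.positions[res.atom_indices[0], 2]
        if centres[0] < z < centres[1]:
            inner_q += q
        else:
            outer_q += q
    if n_ions and inner_q != outer_q:
        if inner_q < outer_q:
            return {"inner": "anodic", "outer": "cathodic"}
        return {"inner": "cathodic", "outer": "anodic"}
    return {"inner": "inner", "outer": "outer"}


def assign_leaflets(
    frames: Sequence[Frame],
    layout: BilayerLayout,
    registry: LipidRegistry,
    hysteresis: float = 0.5,
) -> LeafletAssignment:
    """Assign every lipid to a leaflet in every frame, logging flip-flops.

    The bilayer a lipid belongs to is fixed by the initial layout (nearest
    centre); within its bilayer the lipid switches leaflet only when its
    phosphorus crosses the per-frame geometric centre by more than
    ``hysteresis`` nm.
    """
    if not frames:
        raise LamellaError("no frames to assign")
    table, residues, defs = _lipid_records(frames[0], registry)
    n_lipids = len(residues)
    if n_lipids == 0:
        raise LamellaError("no recognised lipids to assign")
    p_idx = np.array([r.index_of(d.phosphorus_atom) for r, d in zip(residues, defs)])
    atom_groups = [r.atom_indices for r in residues]
    resids = np.array([r.resid for r in residues])
    resnames = np.array([r.resname for r in residues], dtype=object)

    # fixed bilayer membership from the initial layout
    pz0 = frames[0].positions[p_idx, 2]
    dz0 = pz0[:, None] - layout.bilayer_centres[None, :]
    dz0 -= frames[0].box[2] * np.round(dz0 / frames[0].box[2])
    bilayer_of = np.argmin(np.abs(dz0), axis=1)
    bilayer_atoms = [
        np.concatenate([atom_groups[i] for i in np.flatnonzero(bilayer_of == b)])
        for b in range(layout.n_bilayers)
    ]

    state = np.full(n_lipids, -1, dtype=int)   # leaflet index per lipid
    out = np.empty((len(frames), n_lipids), dtype=int)
    times = np.empty(len(frames))
    events: list[FlipFlopEvent] = []
    for f, frame in enumerate(frames):
        times[f] = frame.time
        centres = np.array([frame.positions[a, 2].mean() for a in bilayer_atoms])
        dz = frame.positions[p_idx, 2] - centres[bilayer_of]
        dz -= frame.box[2] * np.round(dz / frame.box[2])
        for i in range(n_lipids):
            upper_now = dz[i] > 0
            target = layout.leaflet_index(int(bilayer_of[i]), upper_now)
            if state[i] == -1:
                state[i] = target
            elif target != state[i] and abs(dz[i]) > hysteresis:
                events.append(FlipFlopEvent(
                    time=float(frame.time), resid=int(resids[i]),
                    resname=str(resnames[i]),
                    from_leaflet=int(state[i]), to_leaflet=int(target),
                ))
                state[i] = target
        out[f] = state
    return LeafletAssignment(
        layout=layout, resids=resids, resnames=resnames,
        lipid_bilayer=bilayer_of, leaflet_per_frame=out, times=times,
        flip_flop_events=events,
    )


def leaflet_symmetry(
    assignment: LeafletAssignment, registry: LipidRegistry
) -> dict[str, np.ndarray]:
    """Per lipid type, the time series of (anodic - cathodic) leaflet counts
    (upper - lower for single bilayers).  A single flip-flop towards the
    cathodic leaflet shows up as a step of -2."""
    group_a, group_b, _, _ = assignment.layout.symmetry_groups()
    series: dict[str, np.ndarray] = {}
    types = sorted({str(t) for t in assignment.resnames})
    in_a = np.isin(assignment.leaflet_per_frame, group_a)
    in_b = np.isin(assignment.leaflet_per_frame, group_b)
    for t in types:
        mask = assignment.resnames == t
        series[t] = (in_a[:, mask].sum(axis=1) - in_b[:, mask].sum(axis=1)).astype(int)
    return series


def write_flip_flop_log(path, assignment: LeafletAssignment) -> None:
    """Flip-flop event log as TSV: time_ps, residue, name, from, to."""
    with open(path, "w") as fh:
        fh.write("time_ps\tresidue_id\tresidue_name\tfrom_leaflet\tto_leaflet\n")
        for ev in assignment.flip_flop_events:
            fh.write(f"{ev.time:.3f}\t{ev.resid}\t{ev.resname}\t"
                     f"{ev.from_leaflet}\t{ev.to_leaflet}\n")
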