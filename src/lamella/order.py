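"""Acyl-chain order parameters for all three force-field flavours.

Atomistic chains use the deuterium order parameter per carbon,

    S_CD = < (3 cos^2 theta - 1) / 2 >,

theta being the angle each C-H bond makes with the membrane normal (z for a
planar bilayer); profiles are reported as -S_CD, which reaches 0.5 at
maximum order (C-H perpendicular to the normal) and -1 at full alignment.

United-atom chains lack tail hydrogens, so S_CD is reconstructed from the
order tensor of molecular axes built on the carbon skeleton: for interior
carbon C_i the molecular z-axis runs along C_(i-1) -> C_(i+1), the y-axis
lies in the C_(i-1), C_i, C_(i+1) plane perpendicular to z, and x completes
the triad; then S_CD = (2/3) S_xx + (1/3) S_yy with S_xx, S_yy evaluated by
the atomistic formula on the x/y axis orientations.  Terminal carbons are
skipped.

Coarse-grained (Martini) tails use the second Legendre polynomial of the
*mean* bond angle per bond position,

    P2 = (3 cos^2<theta> - 1) / 2,

literally with <theta> inside the cosine — a different averaging order from
the atomistic formula, which averages the Legendre term itself.  Bond
angles are folded to [0, 90] degrees via |cos theta| so that the
antiparallel tails of opposing leaflets do not average to a spurious
<theta> of 90 degrees.  P2 = 1 at full alignment and -0.5 perpendicular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .leaflets import LeafletAssignment
from .model import Frame, LamellaError, ResidueTable
from .registry import LipidRegistry

__all__ = [
    "OrderProfile",
    "AngleHistogram",
    "scd_atomistic",
    "scd_united_atom",
    "p2_coarse",
    "angle_histograms",
]


@dataclass
class OrderProfile:
    """Per-position order parameter along one tail type.

    ``values`` holds -S_CD (atomistic/united-atom, range [-1, 0.5]) or P2
    (coarse-grained, range [-0.5, 1]); positions are 1-based from the
    carbonyl end.  Positions with no samples are NaN.
    """

    label: str
    values: np.ndarray
    n_samples: np.ndarray
    n_degenerate: int = 0

    @property
    def carbons(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)


@dataclass
class AngleHistogram:
    """Histogram of bond/axis angles to the membrane normal, degrees."""

    label: str
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_angles(self) -> int:
        return int(self.counts.sum())


def _selected_lipids(
    frame0: Frame,
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
):
    """(residue, definition, lipid position index) for recognised lipids."""
    table = ResidueTable(frame0)
    out = []
    pos = 0
    for res in table:
        d = registry.match_residue(res)
        if d is None:
            continue
        if selection is None or res.resid in selection:
            out.append((res, d, pos))
        pos += 1
    return out


def _leaflet_mask(
    assignment: Optional[LeafletAssignment], frame_idx: int, leaflet: Optional[int],
    lipid_pos: np.ndarray,
) -> np.ndarray:
    if leaflet is None or assignment is None:
        return np.ones(len(lipid_pos), dtype=bool)
    return assignment.leaflet_per_frame[frame_idx, lipid_pos] == leaflet


def _tail_index_arrays(lipids, want_hydrogens: bool):
    """Group selected lipids by (resname, tail) into index arrays."""
    groups: dict[str, dict] = {}
    for res, d, pos in lipids:
        for t, tail in enumerate(d.tails):
            label = f"{d.residue_name}:{d.tail_names[t]}"
            g = groups.setdefault(label, {"carbons": [], "hydrogens": [], "pos": []})
            g["carbons"].append([res.index_of(a) for a in tail])
            g["pos"].append(pos)
            if want_hydrogens:
                hyd = []
                for a in tail:
                    names = d.tail_hydrogens.get(a)
                    if not names:
                        raise LamellaError(
                            f"{d.residue_name}: no hydrogens defined for tail carbon {a}"
                        )
                    missing = [h for h in names if not res.has(h)]
                    if missing:
                        raise LamellaError(
                            f"residue {res.resname}:{res.resid}: hydrogen(s) "
                            f"{missing} of carbon {a} not found"
                        )
                    hyd.append([res.index_of(h) for h in names])
                g["hydrogens"].append(hyd)
    for g in groups.values():
        g["carbons"] = np.array(g["carbons"], dtype=int)        # (n_lip, n_c)
        g["pos"] = np.array(g["pos"], dtype=int)
        if want_hydrogens:
            g["hydrogens"] = np.array(g["hydrogens"], dtype=int)  # (n_lip, n_c, n_h)
    return groups


def _legendre2(cos_theta: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * cos_theta**2 - 1.0)


def scd_atomistic(
    frames: Sequence[Frame],
    assignment: Optional[LeafletAssignment],
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
    leaflet: Optional[int] = None,
) -> dict[str, OrderProfile]:
    """-S_CD per carbon from every individual C-H bond vector."""
    lipids = _selected_lipids(frames[0], registry, selection)
    groups = _tail_index_arrays(lipids, want_hydrogens=True)
    profiles: dict[str, OrderProfile] = {}
    for label, g in groups.items():
        n_c = g["carbons"].shape[1]
        acc = np.zeros(n_c)
        n = np.zeros(n_c, dtype=int)
        for f, frame in enumerate(frames):
            mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
            if not mask.any():
                continue
            c_pos = frame.positions[g["carbons"][mask]]        # (m, n_c, 3)
            h_pos = frame.positions[g["hydrogens"][mask]]      # (m, n_c, n_h, 3)
            vec = h_pos - c_pos[:, :, None, :]
            norm = np.linalg.norm(vec, axis=-1)
            cos = vec[..., 2] / norm
            acc += _legendre2(cos).sum(axis=(0, 2))
            n += cos.shape[0] * cos.shape[2]
        values = np.where(n > 0, -acc / np.maximum(n, 1), np.nan)
        profiles[label] = OrderProfile(label=label, values=values, n_samples=n)
    return profiles


def scd_united_atom(
    frames: Sequence[Frame],
    assignment: Optional[LeafletAssignment],
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
    leaflet: Optional[int] = None,
) -> dict[str, OrderProfile]:
    """-S_CD per interior carbon via the molecular-axes tensor relation."""
    lipids = _selected_lipids(frames[0], registry, selection)
    groups = _tail_index_arrays(lipids, want_hydrogens=False)
    profiles: dict[str, OrderProfile] = {}
    for label, g in groups.items():
        n_c = g["carbons"].shape[1]
        if n_c < 3:
            raise LamellaError(f"{label}: united-atom tails need >= 3 carbons")
        acc_xx = np.zeros(n_c)
        acc_yy = np.zeros(n_c)
        n = np.zeros(n_c, dtype=int)
        degenerate = 0
        for f, frame in enumerate(frames):
            mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
            if not mask.any():
                continue
            c = frame.positions[g["carbons"][mask]]            # (m, n_c, 3)
            prev, mid, nxt = c[:, :-2], c[:, 1:-1], c[:, 2:]
            z_mol = nxt - prev
            z_mol = z_mol / np.linalg.norm(z_mol, axis=-1, keepdims=True)
            v = mid - 0.5 * (prev + nxt)
            v -= np.sum(v * z_mol, axis=-1, keepdims=True) * z_mol
            v_norm = np.linalg.norm(v, axis=-1, keepdims=True)
            ok = v_norm[..., 0] > 1e-10                        # collinear -> skip
            degenerate += int((~ok).sum())
            y_mol = np.where(ok[..., None], v / np.where(v_norm > 0, v_norm, 1.0), 0.0)
            x_mol = np.cross(y_mol, z_mol)
            sxx = _legendre2(x_mol[..., 2])
            syy = _legendre2(y_mol[..., 2])
            acc_xx[1:-1] += np.where(ok, sxx, 0.0).sum(axis=0)
            acc_yy[1:-1] += np.where(ok, syy, 0.0).sum(axis=0)
            n[1:-1] += ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            scd = (2.0 / 3.0) * acc_xx / np.maximum(n, 1) \
                + (1.0 / 3.0) * acc_yy / np.maximum(n, 1)
        values = np.where(n > 0, -scd, np.nan)
        profiles[label] = OrderProfile(label=label, values=values, n_samples=n,
                                       n_degenerate=degenerate)
    return profiles


def p2_coarse(
    frames: Sequence[Frame],
    assignment: Optional[LeafletAssignment],
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
    leaflet: Optional[int] = None,
) -> dict[str, OrderProfile]:
    """P2 per bond position from the mean folded bond angle."""
    lipids = _selected_lipids(frames[0], registry, selection)
    groups = _tail_index_arrays(lipids, want_hydrogens=False)
    profiles: dict[str, OrderProfile] = {}
    for label, g in groups.items():
        n_bonds = g["carbons"].shape[1] - 1
        if n_bonds < 1:
            raise LamellaError(f"{label}: tails need >= 2 beads for bond vectors")
        theta_sum = np.zeros(n_bonds)
        n = np.zeros(n_bonds, dtype=int)
        for f, frame in enumerate(frames):
            mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
            if not mask.any():
                continue
            c = frame.positions[g["carbons"][mask]]
            vec = c[:, 1:] - c[:, :-1]
            cos = np.abs(vec[..., 2]) / np.linalg.norm(vec, axis=-1)
            theta_sum += np.arccos(np.clip(cos, -1.0, 1.0)).sum(axis=0)
            n += cos.shape[0]
        with np.errstate(invalid="ignore"):
            mean_theta = theta_sum / np.maximum(n, 1)
        values = np.where(n > 0, _legendre2(np.cos(mean_theta)), np.nan)
        profiles[label] = OrderProfile(label=label, values=values, n_samples=n)
    return profiles


def angle_histograms(
    frames: Sequence[Frame],
    assignment: Optional[LeafletAssignment],
    registry: LipidRegistry,
    selection: Optional[set[int]] = None,
    leaflet: Optional[int] = None,
    flavour: Optional[str] = None,
    bin_width: float = 1.0,
) -> dict[str, AngleHistogram]:
    """Histograms of the angles each technique measures, 1-degree bins in
    [0, 180): C-H bond angles (atomistic), molecular x/y-axis angles
    (united-atom) or bead-bond angles (coarse-grained)."""
    from .io import detect_force_field

    if flavour is None:
        flavour = detect_force_field(frames[0], registry)
    lipids = _selected_lipids(frames[0], registry, selection)
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    out: dict[str, AngleHistogram] = {}

    if selection is not None and not lipids:
        # empty selection: keep the tail labels, emit all-zero histograms
        groups = _tail_index_arrays(
            _selected_lipids(frames[0], registry, None),
            want_hydrogens=(flavour == "atomistic"),
        )
        zeros = np.zeros(len(edges) - 1, dtype=int)
        for label in groups:
            keys = [f"{label}|x-axis", f"{label}|y-axis"] \
                if flavour == "united_atom" else [label]
            for key in keys:
                out[key] = AngleHistogram(label=key, bin_edges=edges,
                                          counts=zeros.copy())
        return out

    def _hist(label: str, samples_per_frame) -> None:
        counts = np.zeros(len(edges) - 1, dtype=int)
        for arr in samples_per_frame:
            if arr.size:
                counts += np.histogram(arr, bins=edges)[0]
        out[label] = AngleHistogram(label=label, bin_edges=edges, counts=counts)

    if flavour == "atomistic":
        groups = _tail_index_arrays(lipids, want_hydrogens=True)
        for label, g in groups.items():
            def gen(g=g):
                for f, frame in enumerate(frames):
                    mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
                    if not mask.any():
                        yield np.empty(0)
                        continue
                    vec = frame.positions[g["hydrogens"][mask]] \
                        - frame.positions[g["carbons"][mask]][:, :, None, :]
                    cos = vec[..., 2] / np.linalg.norm(vec, axis=-1)
                    yield np.degrees(np.arccos(np.clip(cos, -1, 1))).ravel()
            _hist(label, gen())
    elif flavour == "united_atom":
        groups = _tail_index_arrays(lipids, want_hydrogens=False)
        for label, g in groups.items():
            for axis in ("x", "y"):
                def gen(g=g, axis=axis):
                    for f, frame in enumerate(frames):
                        mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
                        if not mask.any():
                            yield np.empty(0)
                            continue
                        c = frame.positions[g["carbons"][mask]]
                        prev, mid, nxt = c[:, :-2], c[:, 1:-1], c[:, 2:]
                        z_mol = nxt - prev
                        z_mol /= np.linalg.norm(z_mol, axis=-1, keepdims=True)
                        v = mid - 0.5 * (prev + nxt)
                        v -= np.sum(v * z_mol, axis=-1, keepdims=True) * z_mol
                        norm = np.linalg.norm(v, axis=-1, keepdims=True)
                        ok = norm[..., 0] > 1e-10
                        y_mol = v / np.where(norm > 0, norm, 1.0)
                        u = y_mol if axis == "y" else np.cross(y_mol, z_mol)
                        cos = u[..., 2][ok]
                        yield np.degrees(np.arccos(np.clip(cos, -1, 1))).ravel()
                _hist(f"{label}|{axis}-axis", gen())
    else:
        groups = _tail_index_arrays(lipids, want_hydrogens=False)
        for label, g in groups.items():
            def gen(g=g):
                for f, frame in enumerate(frames):
                    mask = _leaflet_mask(assignment, f, leaflet, g["pos"])
                    if not mask.any():
                        yield np.empty(0)
                        continue
                    c = frame.positions[g["carbons"][mask]]
                    vec = c[:, 1:] - c[:, :-1]
                    cos = vec[..., 2] / np.linalg.norm(vec, axis=-1)
                    yield np.degrees(np.arccos(np.clip(cos, -1, 1))).ravel()
            _hist(label, gen())
    return out
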