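"""Deterministic synthetic bilayer generator.

Builds planar single or stacked double bilayers of minimal but
registry-consistent lipids on jittered square lattices, with controllable
phase (all-trans gel vs folded fluid tails), composition and demixing
arrangement, headgroup tilt, compartment ions with a chosen imbalance, and
scripted events (flip-flops, mixing schedules, ion transfers).  The same
seed always yields bitwise-identical frames.

Fixture lipids are not chemically complete: a 4-atom headgroup/backbone
(reference atom, phosphorus, two glycerol linkers) plus two tails taken
from the lipid registry, with two ideal-tetrahedral hydrogens per carbon
in the atomistic flavour.  All-trans tails advance one registry bond step
per atom along z (so their end-to-end distance equals the registry's
all-trans extension exactly); folded tails advance half a step with a
lateral zig, reaching about half extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    ATOMISTIC,
    COARSE_GRAINED,
    UNITED_ATOM,
    Frame,
    LamellaError,
    LipidDefinition,
)
from .registry import LipidRegistry, load_lipid_registry

__all__ = [
    "FixtureSpec",
    "ScriptedFlipFlop",
    "ScriptedMixing",
    "ScriptedIonTransfer",
    "build_bilayer",
    "script_trajectory",
    "capacitor_frames",
]

_MIN_APL = 0.4          # nm^2, below this lipids cannot pack
_HEAD_LIFT = 0.45       # nm, phosphorus above the first tail atom
_GLYCEROL_LIFT = 0.15   # nm
_TAIL_GAP = 0.2         # nm, clearance of tail ends above the bilayer centre
_CH_BOND = 0.109        # nm


@dataclass(frozen=True)
class ScriptedFlipFlop:
    """Move one lipid across its bilayer centre, animated over 3 frames."""
    time: float
    lipid: int              # position index into the generator's lipid list


@dataclass(frozen=True)
class ScriptedMixing:
    """Swap n random cross-type lipid site pairs (per leaflet pool)."""
    time: float
    n_swaps: int


@dataclass(frozen=True)
class ScriptedIonTransfer:
    """Move cations from the outer to the inner compartment."""
    time: float
    n_ions: int = 1


@dataclass(frozen=True)
class FixtureSpec:
    n_lipids: int = 64                      # per leaflet
    composition: Mapping[str, float] = field(
        default_factory=lambda: {"POPC": 1.0})
    flavour: str = COARSE_GRAINED
    phase: str = "folded_fluid"             # all_trans_gel | folded_fluid | mixture
    p_gel: float = 0.0                      # gel fraction for phase="mixture"
    arrangement: str = "random"             # random | quadrant_demixed | slab_demixed | checker
    layout: str = "single"                  # single | double
    jitter: float = 0.05                    # nm, lateral lattice jitter (sigma)
    apl: float = 0.64                       # nm^2 lattice area per lipid
    head_angle_deg: float = 23.0            # lateral headgroup elevation
    ion_imbalance: int = 0                  # e, double layout only
    water_gap: float = 3.0                  # nm between stacked bilayers
    n_frames: int = 1
    dt: float = 100.0                       # ps between frames
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0):
            raise LamellaError(f"composition fractions must sum to 1, got {total}")
        if self.apl < _MIN_APL:
            raise LamellaError(
                f"APL {self.apl} nm^2 below {_MIN_APL}: infeasible packing")
        if self.layout not in ("single", "double"):
            raise LamellaError(f"unknown layout {self.layout!r}")
        if self.phase not in ("all_trans_gel", "folded_fluid", "mixture"):
            raise LamellaError(f"unknown phase {self.phase!r}")
        if self.arrangement not in ("random", "quadrant_demixed",
                                    "slab_demixed", "checker"):
            raise LamellaError(f"unknown arrangement {self.arrangement!r}")
        if self.ion_imbalance and self.layout != "double":
            raise LamellaError("ion imbalance needs the double layout")
        if self.ion_imbalance % 2:
            raise LamellaError("ion imbalance must be even")


def _lattice_dims(n: int) -> tuple[int, int]:
    """Near-square divisor pair (nx, ny) with nx * ny == n."""
    best = None
    for nx in range(1, int(np.sqrt(n)) + 1):
        if n % nx == 0:
            best = (n // nx, nx)
    if best is None or best[1] / best[0] < 0.5:
        raise LamellaError(
            f"{n} lipids per leaflet cannot tile a near-square lattice; "
            "choose a composite count (e.g. 64, 128, 1008)")
    return best


def _type_counts(composition: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding of fractions to lipid counts."""
    types = sorted(composition, key=lambda t: (-composition[t], t))
    quota = np.array([composition[t] * n for t in types])
    take = np.floor(quota).astype(int)
    order = np.argsort(-(quota - take))
    for k in range(n - take.sum()):
        take[order[k % len(take)]] += 1
    return {t: int(c) for t, c in zip(types, take)}


def _site_types(spec: FixtureSpec, nx: int, ny: int,
                rng: np.random.Generator) -> np.ndarray:
    """Type label per lattice site (row-major, index = iy * nx + ix)."""
    n = nx * ny
    counts = _type_counts(spec.composition, n)
    types = list(counts)
    labels = np.empty(n, dtype=object)
    if spec.arrangement == "random":
        pool = np.array(sum(([t] * c for t, c in counts.items()), []), dtype=object)
        labels[:] = rng.permutation(pool)
    elif spec.arrangement == "checker":
        # deterministic even interleave: minority every ~n/c_min-th site
        minority = types[-1]
        c_min = counts[minority]
        period = max(2, int(round(n / max(c_min, 1))))
        maj_iter = iter(sum(([t] * counts[t] for t in types[:-1]), []))
        placed = 0
        lab = []
        for i in range(n):
            if placed < c_min and i % period == period - 1:
                lab.append(minority)
                placed += 1
            else:
                lab.append(next(maj_iter, types[0]))
        labels[:] = lab
    else:
        minority = types[-1]
        c_min = counts[minority]
        ix = np.arange(n) % nx
        iy = np.arange(n) // nx
        if spec.arrangement == "quadrant_demixed":
            frac = np.sqrt(counts[minority] / n)
            wx, wy = int(round(nx * frac)), int(round(ny * frac))
            in_region = (ix < wx) & (iy < wy)
        else:  # slab_demixed
            wx = int(round(nx * c_min / n))
            in_region = ix < max(wx, 1)
        region = np.flatnonzero(in_region)[:c_min]
        rest = np.setdiff1d(np.arange(n), region)
        # overflow of the minority (rounding) continues outside the region
        extra = rest[:c_min - len(region)]
        minority_sites = np.concatenate([region, extra]).astype(int)
        maj_seq = sum(([t] * counts[t] for t in types[:-1]), [])
        labels[:] = ""
        labels[minority_sites] = minority
        fill = np.setdiff1d(np.arange(n), minority_sites)
        labels[fill] = np.array(maj_seq, dtype=object)[:len(fill)]
    return labels


def _hydrogen_pairs(chain: np.ndarray) -> np.ndarray:
    """Two ideal-tetrahedral hydrogens per chain atom, (n, 2, 3)."""
    n = len(chain)
    out = np.empty((n, 2, 3))
    s2, s1 = np.sqrt(2.0 / 3.0), np.sqrt(1.0 / 3.0)
    for i in range(n):
        prev = chain[max(i - 1, 0)]
        nxt = chain[min(i + 1, n - 1)]
        z_mol = nxt - prev
        z_mol = z_mol / np.linalg.norm(z_mol)
        mid = 0.5 * (prev + nxt)
        v = chain[i] - mid
        v = v - np.dot(v, z_mol) * z_mol
        if np.linalg.norm(v) < 1e-8:
            v = np.array([1.0, 0.0, 0.0])
            v = v - np.dot(v, z_mol) * z_mol
            if np.linalg.norm(v) < 1e-8:
                v = np.array([0.0, 1.0, 0.0])
                v = v - np.dot(v, z_mol) * z_mol
        y_mol = v / np.linalg.norm(v)
        x_mol = np.cross(y_mol, z_mol)
        for k, sign in enumerate((1.0, -1.0)):
            out[i, k] = chain[i] + _CH_BOND * (sign * s2 * x_mol - s1 * y_mol)
    return out


@dataclass
class _LipidState:
    site: int               # lattice site index within its leaflet
    leaflet_sign: float     # +1 upper, -1 lower (within its bilayer)
    bilayer: int
    lipid_type: str
    gel: bool
    azimuth: float
    jitter_xy: np.ndarray
    flip_progress: float = 0.0   # 0 = settled; (0,1) = mid-flip


@dataclass
class _SystemState:
    spec: FixtureSpec
    defs: dict[str, LipidDefinition]
    nx: int
    ny: int
    a: float                # lattice constant, nm
    box: np.ndarray
    centres: np.ndarray     # bilayer centres, z nm
    lipids: list            # _LipidState, file order
    cations: list           # z positions (x, y drawn at build)
    anions: list
    ion_xy: np.ndarray
    head_len: float
    tail_top: float         # first-tail-atom height above the centre


def _geometry(spec: FixtureSpec, registry: LipidRegistry) -> _SystemState:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    defs = {t: registry.get(t, spec.flavour) for t in spec.composition}
    nx, ny = _lattice_dims(spec.n_lipids)
    a = float(np.sqrt(spec.apl))
    tail_max = max(max(d.max_tail_extension) for d in defs.values())
    head_len = 0.47 if spec.flavour == COARSE_GRAINED else 0.35
    tail_top = _TAIL_GAP + tail_max
    half = tail_top + _HEAD_LIFT + head_len + 0.4
    if spec.layout == "single":
        lz = 2.0 * half + 2.0
        centres = np.array([lz / 2.0])
    else:
        w = spec.water_gap
        lz = 4.0 * half + 2.0 * w
        centres = np.array([w / 2.0 + half, w / 2.0 + 3.0 * half + w])
    box = np.array([nx * a, ny * a, lz])

    lipids: list[_LipidState] = []
    n_bilayers = len(centres)
    for b in range(n_bilayers):
        for sign in (-1.0, 1.0):                    # lower leaflet first
            labels = _site_types(spec, nx, ny, rng)
            for site in range(nx * ny):
                gel = (spec.phase == "all_trans_gel"
                       or (spec.phase == "mixture" and rng.random() < spec.p_gel))
                lipids.append(_LipidState(
                    site=site, leaflet_sign=sign, bilayer=b,
                    lipid_type=str(labels[site]), gel=gel,
                    azimuth=float(rng.uniform(0.0, 2.0 * np.pi)),
                    jitter_xy=rng.normal(0.0, spec.jitter, size=2),
                ))
    cations: list[float] = []
    anions: list[float] = []
    ion_xy = np.empty((0, 2))
    if spec.layout == "double" and spec.ion_imbalance:
        q = spec.ion_imbalance // 2
        inner_lo = centres[0] + half + 0.3
        inner_hi = centres[1] - half - 0.3
        outer_w = box[2] - (centres[1] + half) + (centres[0] - half) - 0.6
        anions = list(rng.uniform(inner_lo, inner_hi, size=q))
        cations = list((centres[1] + half + 0.3
                        + rng.uniform(0.0, outer_w, size=q)) % box[2])
        ion_xy = rng.uniform(0.0, 1.0, size=(2 * q, 2)) * box[:2]
    return _SystemState(spec=spec, defs=defs, nx=nx, ny=ny, a=a, box=box,
                        centres=centres, lipids=lipids, cations=cations,
                        anions=anions, ion_xy=ion_xy, head_len=head_len,
                        tail_top=tail_top)


def _lipid_atoms(state: _SystemState, lip: _LipidState) -> tuple[list[str], np.ndarray]:
    """Names and coordinates of one lipid, upper-leaflet frame mirrored by sign."""
    spec = state.spec
    d = state.defs[lip.lipid_type]
    ix, iy = lip.site % state.nx, lip.site // state.nx
    x0 = (ix + 0.5) * state.a + lip.jitter_xy[0]
    y0 = (iy + 0.5) * state.a + lip.jitter_xy[1]
    zc = state.centres[lip.bilayer]
    # flip animation: interpolate the leaflet sign through the centre
    sign = lip.leaflet_sign
    if lip.flip_progress > 0.0:
        sign = lip.leaflet_sign * (1.0 - 2.0 * lip.flip_progress)
    names: list[str] = []
    rel: list[np.ndarray] = []          # offsets in the upper-leaflet frame

    z_first = state.tail_top
    step0 = d.bond_step
    for t, tail in enumerate(d.tails):
        dx = (-0.16, 0.16)[t % 2]
        chain = np.empty((len(tail), 3))
        # all-trans acyl chains are planar zig-zags: 0.127 nm z-advance per
        # bond with a lateral alternation keeping the C-C bond at 0.153 nm
        # (coarse-grained bonds advance straight, amp = 0)
        bond = 0.47 if spec.flavour == COARSE_GRAINED else 0.153
        amp = float(np.sqrt(max(bond**2 - step0**2, 0.0)))
        if lip.gel:
            for k in range(len(tail)):
                chain[k] = (dx + amp * (k % 2), 0.0, z_first - k * step0)
        else:
            for k in range(len(tail)):
                zig = 0.08 * ((-1) ** k)
                chain[k] = (dx + zig, 0.0, z_first - k * (0.5 * step0))
        for k, atom in enumerate(tail):
            names.append(atom)
            rel.append(chain[k])
            if spec.flavour == ATOMISTIC:
                hyd = d.tail_hydrogens[atom]
                hpos = _hydrogen_pairs(chain)[k]
                for hname, hxyz in zip(hyd, hpos):
                    names.append(hname)
                    rel.append(hxyz)
    # glycerol linkers and phosphorus above the tail tops
    if spec.flavour != COARSE_GRAINED:
        names += ["G1", "G2"]
        rel += [np.array([-0.16, 0.05, z_first + _GLYCEROL_LIFT]),
                np.array([0.16, 0.05, z_first + _GLYCEROL_LIFT])]
    else:
        names += ["GL1", "GL2"]
        rel += [np.array([-0.16, 0.05, z_first + _GLYCEROL_LIFT]),
                np.array([0.16, 0.05, z_first + _GLYCEROL_LIFT])]
    p_rel = np.array([0.0, 0.0, z_first + _HEAD_LIFT])
    names.append(d.phosphorus_atom)
    rel.append(p_rel)
    alpha = np.radians(spec.head_angle_deg)
    head = p_rel + state.head_len * np.array([
        np.cos(alpha) * np.cos(lip.azimuth),
        np.cos(alpha) * np.sin(lip.azimuth),
        np.sin(alpha),
    ])
    names.append(d.headgroup_reference_atom)
    rel.append(head)

    rel_arr = np.array(rel)
    xyz = np.empty_like(rel_arr)
    xyz[:, 0] = x0 + rel_arr[:, 0]
    xyz[:, 1] = y0 + rel_arr[:, 1]
    xyz[:, 2] = zc + sign * rel_arr[:, 2]
    return names, xyz


def _emit_frame(state: _SystemState, time: float) -> Frame:
    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    coords: list[np.ndarray] = []
    resid = 1
    for lip in state.lipids:
        n, xyz = _lipid_atoms(state, lip)
        names += n
        resnames += [lip.lipid_type] * len(n)
        resids += [resid] * len(n)
        coords.append(xyz)
        resid += 1
    ion_row = 0
    for group, label in ((state.anions, "CL"), (state.cations, "NA")):
        for z in group:
            names.append(label)
            resnames.append(label)
            resids.append(resid)
            coords.append(np.array([[state.ion_xy[ion_row, 0],
                                     state.ion_xy[ion_row, 1], float(z)]]))
            resid += 1
            ion_row += 1
    return Frame(
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        positions=np.vstack(coords),
        box=state.box.copy(),
        time=time,
    )


def build_bilayer(
    spec: FixtureSpec,
    registry: Optional[LipidRegistry] = None,
) -> list[Frame]:
    """Static trajectory of ``spec.n_frames`` identical-geometry frames."""
    return script_trajectory(spec, (), registry=registry)


def script_trajectory(
    spec: FixtureSpec,
    events: Sequence = (),
    registry: Optional[LipidRegistry] = None,
) -> list[Frame]:
    """Trajectory whose frames realise the time-ordered scripted events."""
    registry = registry or load_lipid_registry()
    state = _geometry(spec, registry)
    events = sorted(events, key=lambda e: e.time)
    for ev in events:
        if isinstance(ev, ScriptedFlipFlop) and not (
                0 <= ev.lipid < len(state.lipids)):
            raise LamellaError(f"flip-flop event references absent lipid {ev.lipid}")
        if isinstance(ev, ScriptedIonTransfer) and spec.layout != "double":
            raise LamellaError("ion transfer events need the double layout")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    frames: list[Frame] = []
    pending = list(events)
    flipping: list[tuple[int, int]] = []     # (lipid index, steps completed)
    for f in range(spec.n_frames):
        t = f * spec.dt
        # advance ongoing flips by one frame
        still = []
        for (li, step) in flipping:
            lip = state.lipids[li]
            step += 1
            if step >= 3:
                lip.flip_progress = 0.0
                lip.leaflet_sign = -lip.leaflet_sign
            else:
                lip.flip_progress = step / 3.0
                still.append((li, step))
        flipping = still
        while pending and pending[0].time <= t:
            ev = pending.pop(0)
            if isinstance(ev, ScriptedFlipFlop):
                flipping.append((ev.lipid, 1))
                state.lipids[ev.lipid].flip_progress = 1.0 / 3.0
            elif isinstance(ev, ScriptedMixing):
                _apply_mixing(state, ev.n_swaps, rng)
            elif isinstance(ev, ScriptedIonTransfer):
                _apply_ion_transfer(state, ev.n_ions)
            else:
                raise LamellaError(f"unknown scripted event {ev!r}")
        frames.append(_emit_frame(state, time=t))
    return frames


def _apply_mixing(state: _SystemState, n_swaps: int,
                  rng: np.random.Generator) -> None:
    by_leaflet: dict[tuple[int, float], list[int]] = {}
    for i, lip in enumerate(state.lipids):
        by_leaflet.setdefault((lip.bilayer, lip.leaflet_sign), []).append(i)
    for _ in range(n_swaps):
        key = list(by_leaflet)[int(rng.integers(len(by_leaflet)))]
        pool = by_leaflet[key]
        types = {}
        for i in pool:
            types.setdefault(state.lipids[i].lipid_type, []).append(i)
        if len(types) < 2:
            continue
        tnames = sorted(types)
        ta, tb = tnames[0], tnames[-1]
        i = types[ta][int(rng.integers(len(types[ta])))]
        j = types[tb][int(rng.integers(len(types[tb])))]
        a, b = state.lipids[i], state.lipids[j]
        a.site, b.site = b.site, a.site
        a.jitter_xy, b.jitter_xy = b.jitter_xy, a.jitter_xy


def _apply_ion_transfer(state: _SystemState, n_ions: int) -> None:
    """Move cations from the outer to the inner compartment (reduces the
    compartment charge separation by 2 e per ion)."""
    inner_mid = 0.5 * (state.centres[0] + state.centres[1])
    moved = 0
    for i, z in enumerate(state.cations):
        if moved >= n_ions:
            break
        in_inner = state.centres[0] < z < state.centres[1]
        if not in_inner:
            state.cations[i] = inner_mid + 0.1 * i
            moved += 1


def capacitor_frames(
    sigma: float = 0.5,
    z_plates: tuple[float, float] = (3.0, 7.0),
    box: tuple[float, float, float] = (4.0, 4.0, 12.0),
    n_per_plate: int = 16,
    n_frames: int = 1,
) -> tuple[list[Frame], dict[str, float]]:
    """Parallel-plate capacitor of point charges: -sigma at z1, +sigma at z2.

    Returns the frames and the charge map resolving the plate residues
    (each plate carries ``n_per_plate`` equal point charges summing to
    ``sigma * Lx * Ly`` e).  The analytic potential difference between the
    plates is |sigma| * d / eps0.
    """
    lx, ly, lz = box
    grid = int(np.ceil(np.sqrt(n_per_plate)))
    xy = np.array([((i % grid + 0.5) * lx / grid, (i // grid + 0.5) * ly / grid)
                   for i in range(n_per_plate)])
    total = sigma * lx * ly
    q = total / n_per_plate
    names, resids, resnames, coords = [], [], [], []
    charge_map: dict[str, float] = {"MINUS:Q": -q, "PLUS:Q": q}
    resid = 1
    for z, rn in ((z_plates[0], "MINUS"), (z_plates[1], "PLUS")):
        for (x, y) in xy:
            names.append("Q")
            resnames.append(rn)
            resids.append(resid)
            coords.append([x, y, z])
            resid += 1
    frame = Frame(names=np.array(names, dtype=object),
                  resids=np.array(resids), resnames=np.array(resnames, dtype=object),
                  positions=np.array(coords), box=np.array(box), time=0.0)
    frames = [replace_time(frame, 100.0 * k) for k in range(n_frames)]
    return frames, charge_map


def replace_time(frame: Frame, time: float) -> Frame:
    out = frame.copy()
    out.time = time
    return out
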