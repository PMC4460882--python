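"""Reading and writing multi-frame structure files.

GRO and PDB are first-class (GRO in nm, PDB in Angstrom converted to nm on
read); compressed binary formats (xtc/trr) are available through the same
frame-sequence contract when a topology file is supplied.  Parsing is
delegated to mdtraj, which natively works in nm/ps; this module adapts its
containers to the :class:`~lamella.model.Frame` data model and enforces the
orthorhombic-box restriction that every planar-bilayer analysis here
assumes (z is the membrane normal).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    Frame,
    ForceFieldFlavour,
    LamellaError,
    ParseError,
    ResidueTable,
)
from .registry import LipidRegistry

__all__ = ["read_trajectory", "write_gro", "detect_force_field"]

_BINARY_FORMATS = {".xtc", ".trr"}


def _check_orthorhombic(angles: np.ndarray, path: Path) -> None:
    if angles is None or not np.allclose(angles, 90.0, atol=1e-3):
        raise ParseError(
            f"{path}: triclinic box (angles {angles}) not supported; "
            "analyses assume an orthorhombic box with z normal to the membrane"
        )


def _from_mdtraj(traj, path: Path) -> list[Frame]:
    if traj.n_frames == 0:
        raise ParseError(f"{path}: empty trajectory (zero frames)")
    if traj.unitcell_lengths is None:
        raise ParseError(
            f"{path}: no box information (GRO box line or PDB CRYST1 required)"
        )
    top = traj.topology
    names = np.array([a.name for a in top.atoms], dtype=object)
    resids = np.array([a.residue.resSeq for a in top.atoms], dtype=int)
    resnames = np.array([a.residue.name for a in top.atoms], dtype=object)
    frames = []
    for k in range(traj.n_frames):
        _check_orthorhombic(traj.unitcell_angles[k], path)
        frames.append(
            Frame(
                names=names,
                resids=resids,
                resnames=resnames,
                positions=np.array(traj.xyz[k], dtype=float),
                box=np.array(traj.unitcell_lengths[k], dtype=float),
                time=float(traj.time[k]) if traj.time is not None else float(k),
            )
        )
    return frames


def read_trajectory(
    path: str | Path,
    format_hint: Optional[str] = None,
    topology: Optional[str | Path] = None,
) -> list[Frame]:
    """Read a GRO/PDB (or xtc/trr + topology) file into a list of Frames.

    Coordinates are returned in nm regardless of dialect; multi-model PDB
    and concatenated multi-frame GRO files yield one Frame per model/frame,
    in file order.
    """
    import mdtraj as md

    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    suffix = ("." + format_hint.lower().lstrip(".")) if format_hint else path.suffix.lower()
    try:
        if suffix in _BINARY_FORMATS:
            if topology is None:
                raise ParseError(
                    f"{path}: binary format {suffix} needs a GRO/PDB topology file"
                )
            traj = md.load(str(path), top=str(topology))
        else:
            traj = md.load(str(path))
    except ParseError:
        raise
    except Exception as exc:  # mdtraj raises assorted exception types
        raise ParseError(f"{path}: malformed {suffix or 'structure'} file: {exc}") from exc
    frames = _from_mdtraj(traj, path)
    counts = {f.n_atoms for f in frames}
    if len(counts) != 1:
        raise ParseError(f"{path}: atom count changes across frames ({sorted(counts)})")
    return frames


def write_gro(path: str | Path, frames: Sequence[Frame] | Frame, title: str = "lamella") -> None:
    """Write frames as (concatenated multi-frame) GRO, nm, 3-decimal precision."""
    if isinstance(frames, Frame):
        frames = [frames]
    if not frames:
        raise LamellaError("cannot write an empty trajectory")
    path = Path(path)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{title} t= {frame.time:.3f}\n{frame.n_atoms}\n")
            for i in range(frame.n_atoms):
                resid = int(frame.resids[i]) % 100000
                x, y, z = frame.positions[i]
                fh.write(
                    f"{resid:>5d}{str(frame.resnames[i])[:5]:<5s}"
                    f"{str(frame.names[i])[:5]:>5s}{(i + 1) % 100000:>5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def detect_force_field(
    frame: Frame,
    registry: LipidRegistry,
    table: Optional[ResidueTable] = None,
) -> ForceFieldFlavour:
    """Detect the force-field flavour from one frame.

    Lipid residues with bead-level particle counts are coarse grained;
    atomistic when tail hydrogens are present; united-atom otherwise.
    Deterministic given the frame and registry.
    """
    table = table or ResidueTable(frame)
    flavours: set[str] = set()
    unmatched: set[str] = set()
    for res in table:
        if not registry.is_lipid(res.resname):
            continue
        definition = registry.match_residue(res)
        if definition is None:
            unmatched.add(res.resname)
        else:
            flavours.add(definition.flavour)
    if not flavours:
        names = sorted(unmatched) or sorted({str(r.resname) for r in table})
        raise LamellaError(
            "no recognised lipid residues; unmatched residue names: " + ", ".join(names)
        )
    if len(flavours) > 1:
        raise LamellaError(
            f"conflicting force-field flavours detected: {sorted(flavours)}"
        )
    return flavours.pop()
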