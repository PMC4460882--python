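"""Core data model for planar-bilayer trajectories.

All geometry is carried in nanometres and picoseconds regardless of the
input dialect.  A trajectory is a plain sequence of :class:`Frame` objects;
per-residue bookkeeping is derived lazily through :class:`ResidueTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "LamellaError",
    "ParseError",
    "Frame",
    "Residue",
    "ResidueTable",
    "LipidDefinition",
    "ForceFieldFlavour",
]


class LamellaError(Exception):
    """Base class for all package errors."""


class ParseError(LamellaError):
    """A structure/trajectory file could not be parsed."""


#: Recognised force-field flavours.
ATOMISTIC = "atomistic"
UNITED_ATOM = "united_atom"
COARSE_GRAINED = "coarse_grained"
ForceFieldFlavour = str
FLAVOURS = (ATOMISTIC, UNITED_ATOM, COARSE_GRAINED)

#: Lipid residues with at most this many particles are taken as coarse grained.
CG_BEAD_THRESHOLD = 15


@dataclass
class Frame:
    """One time point: atom labels, coordinates (nm) and an orthorhombic box."""

    names: np.ndarray          # (n,) atom names
    resids: np.ndarray         # (n,) integer residue ids
    resnames: np.ndarray       # (n,) residue names
    positions: np.ndarray      # (n, 3) nm
    box: np.ndarray            # (3,) orthorhombic edge lengths, nm
    time: float = 0.0          # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise LamellaError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise LamellaError("non-finite atom coordinate encountered")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise LamellaError("box must be three positive edge lengths (nm)")
        if np.any(self.resids < 0):
            raise LamellaError("residue ids must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "Frame":
        return Frame(
            names=self.names.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            positions=self.positions.copy(),
            box=self.box.copy(),
            time=self.time,
        )


@dataclass(frozen=True)
class Residue:
    resid: int
    resname: str
    atom_indices: np.ndarray            # global atom indices, frame order
    name_to_index: Mapping[str, int]    # atom name -> global index

    def index_of(self, atom_name: str) -> int:
        try:
            return self.name_to_index[atom_name]
        except KeyError:
            raise LamellaError(
                f"residue {self.resname}:{self.resid} has no atom {atom_name!r}"
            ) from None

    def has(self, atom_name: str) -> bool:
        return atom_name in self.name_to_index

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


class ResidueTable:
    """Groups a frame's atoms into residues, preserving file order.

    Atom counts and ordering are constant along a trajectory, so one table
    built from any frame serves all frames.
    """

    def __init__(self, frame: Frame):
        residues: list[Residue] = []
        start = 0
        resids = frame.resids
        n = len(resids)
        for i in range(1, n + 1):
            if i == n or resids[i] != resids[start] or frame.resnames[i] != frame.resnames[start]:
                idx = np.arange(start, i)
                names = {frame.names[j]: j for j in idx}
                residues.append(
                    Residue(
                        resid=int(resids[start]),
                        resname=str(frame.resnames[start]),
                        atom_indices=idx,
                        name_to_index=names,
                    )
                )
                start = i
        self.residues: Sequence[Residue] = residues
        self._by_resid = {r.resid: r for r in residues}

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def by_resid(self, resid: int) -> Residue:
        return self._by_resid[resid]


@dataclass(frozen=True)
class LipidDefinition:
    """Per-lipid-type metadata used by every analysis.

    ``tails`` are ordered carbon/bead atom-name chains, numbered from the
    glycerol (carbonyl) end.  ``tail_hydrogens`` maps each tail carbon to its
    hydrogen names (atomistic representations only).  ``max_tail_extension``
    is the all-trans first-to-last-carbon distance per tail in nm; when not
    given it defaults to 0.127 nm per C-C bond along the chain axis
    (``0.127 * (n_carbons - 1)``) for acyl chains, or the listed bond step for
    coarse-grained beads.
    """

    residue_name: str
    flavour: ForceFieldFlavour
    phosphorus_atom: str
    headgroup_reference_atom: str
    tails: tuple[tuple[str, ...], ...]
    tail_names: tuple[str, ...] = ()
    tail_hydrogens: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    max_tail_extension: tuple[float, ...] = ()
    charges: Mapping[str, float] = field(default_factory=dict)
    bond_step: float = 0.127  # nm, all-trans per-bond advance along the chain axis

    def __post_init__(self) -> None:
        if self.flavour not in FLAVOURS:
            raise LamellaError(f"unknown force-field flavour {self.flavour!r}")
        if not self.tails:
            raise LamellaError(f"{self.residue_name}: at least one tail required")
        for tail in self.tails:
            if len(tail) < 3:
                raise LamellaError(
                    f"{self.residue_name}: each tail needs >= 3 atoms, got {len(tail)}"
                )
        if not self.phosphorus_atom:
            raise LamellaError(f"{self.residue_name}: phosphorus atom required")
        if not self.tail_names:
            object.__setattr__(
                self, "tail_names", tuple(f"sn{i+1}" for i in range(len(self.tails)))
            )
        if not self.max_tail_extension:
            object.__setattr__(
                self,
                "max_tail_extension",
                tuple(self.bond_step * (len(t) - 1) for t in self.tails),
            )
        if any(x <= 0 for x in self.max_tail_extension):
            raise LamellaError(f"{self.residue_name}: max_tail_extension must be > 0")

    def matches(self, residue: Residue) -> bool:
        """True if the residue carries this definition's key atoms."""
        if residue.resname.upper() != self.residue_name.upper():
            return False
        if not residue.has(self.phosphorus_atom):
            return False
        return all(residue.has(a) for tail in self.tails for a in tail)


def wrap_minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors for an orthorhombic box."""
    return delta - box * np.round(delta / box)
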