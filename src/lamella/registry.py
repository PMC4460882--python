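"""Built-in lipid definitions and the user-extensible lipid registry.

The registry maps residue names (case-insensitive) to
:class:`~lamella.model.LipidDefinition` entries in up to three force-field
flavours.  POPC, POPE, POPG and DPPC ship as built-ins:

* atomistic — full acyl chains with two hydrogens per tail carbon,
  generic names ``C1A..C16A`` / ``H3A1`` etc.;
* united-atom — the same carbon skeleton without tail hydrogens;
* coarse-grained — Martini v2 bead names (``NC3 PO4 GL1 GL2 C1A..``).

A YAML/JSON config can override or extend the built-ins, e.g.::

    DOPC:
      flavour: atomistic
      phosphorus: P
      headgroup_ref: N
      tails: [[C1A, C2A, C3A, C4A, C5A], [C1B, C2B, C3B, C4B, C5B]]
      hydrogens: {C1A: [H1A1, H1A2]}
      max_extension: [0.51, 0.51]
      charges: {P: -1.0}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .model import (
    ATOMISTIC,
    CG_BEAD_THRESHOLD,
    COARSE_GRAINED,
    UNITED_ATOM,
    Frame,
    LamellaError,
    LipidDefinition,
    Residue,
    ResidueTable,
)

__all__ = ["LipidRegistry", "load_lipid_registry", "builtin_definitions",
           "resolve_charges", "ION_CHARGES"]

#: Default monatomic-ion charges (e), keyed by residue name.
ION_CHARGES: Mapping[str, float] = {
    "NA": 1.0, "K": 1.0, "CA": 2.0, "MG": 2.0, "CL": -1.0,
    "NA+": 1.0, "CL-": -1.0,
}


def _acyl_tail(n: int, suffix: str) -> tuple[str, ...]:
    return tuple(f"C{i}{suffix}" for i in range(1, n + 1))


def _acyl_hydrogens(tail: Iterable[str]) -> dict[str, tuple[str, ...]]:
    return {c: (f"H{c[1:]}1", f"H{c[1:]}2") for c in tail}


def _atomistic(resname: str, ref: str, n_sn1: int, n_sn2: int,
               tail_names: tuple[str, str]) -> LipidDefinition:
    tails = (_acyl_tail(n_sn1, "A"), _acyl_tail(n_sn2, "B"))
    hydrogens: dict[str, tuple[str, ...]] = {}
    for t in tails:
        hydrogens.update(_acyl_hydrogens(t))
    return LipidDefinition(
        residue_name=resname, flavour=ATOMISTIC, phosphorus_atom="P",
        headgroup_reference_atom=ref, tails=tails, tail_names=tail_names,
        tail_hydrogens=hydrogens,
    )


def _united(resname: str, ref: str, n_sn1: int, n_sn2: int,
            tail_names: tuple[str, str]) -> LipidDefinition:
    return LipidDefinition(
        residue_name=resname, flavour=UNITED_ATOM, phosphorus_atom="P",
        headgroup_reference_atom=ref,
        tails=(_acyl_tail(n_sn1, "A"), _acyl_tail(n_sn2, "B")),
        tail_names=tail_names,
    )


def _martini(resname: str, head: str, sn1: tuple[str, ...],
             sn2: tuple[str, ...]) -> LipidDefinition:
    return LipidDefinition(
        residue_name=resname, flavour=COARSE_GRAINED, phosphorus_atom="PO4",
        headgroup_reference_atom=head, tails=(sn1, sn2),
        tail_names=("sn1", "sn2"), bond_step=0.47,
    )


_SAT4 = ("C1A", "C2A", "C3A", "C4A")
_OLE4 = ("C1B", "D2B", "C3B", "C4B")


def builtin_definitions() -> list[LipidDefinition]:
    """POPC, POPE, POPG and DPPC in all three flavour variants."""
    defs = [
        # palmitoyl (16:0) sn1, oleoyl (18:1) sn2 for the POxx lipids
        _atomistic("POPC", "N", 16, 18, ("palmitoyl", "oleoyl")),
        _atomistic("POPE", "N", 16, 18, ("palmitoyl", "oleoyl")),
        _atomistic("POPG", "OG", 16, 18, ("palmitoyl", "oleoyl")),
        _atomistic("DPPC", "N", 16, 16, ("palmitoyl", "palmitoyl")),
        _united("POPC", "N", 16, 18, ("palmitoyl", "oleoyl")),
        _united("POPE", "N", 16, 18, ("palmitoyl", "oleoyl")),
        _united("POPG", "OG", 16, 18, ("palmitoyl", "oleoyl")),
        _united("DPPC", "N", 16, 16, ("palmitoyl", "palmitoyl")),
        _martini("POPC", "NC3", _SAT4, _OLE4),
        _martini("POPE", "NH3", _SAT4, _OLE4),
        _martini("POPG", "GL0", _SAT4, _OLE4),
        _martini("DPPC", "NC3", _SAT4, ("C1B", "C2B", "C3B", "C4B")),
    ]
    return defs


class LipidRegistry:
    """Lookup table resname (case-insensitive) x flavour -> LipidDefinition."""

    def __init__(self, definitions: Iterable[LipidDefinition]):
        self._defs: dict[tuple[str, str], LipidDefinition] = {}
        for d in definitions:
            self._defs[(d.residue_name.upper(), d.flavour)] = d

    def add(self, definition: LipidDefinition) -> None:
        self._defs[(definition.residue_name.upper(), definition.flavour)] = definition

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def definitions(self) -> list[LipidDefinition]:
        return list(self._defs.values())

    @property
    def lipid_resnames(self) -> set[str]:
        return {name for name, _ in self._defs}

    def is_lipid(self, resname: str) -> bool:
        return resname.upper() in self.lipid_resnames

    def get(self, resname: str, flavour: str) -> LipidDefinition:
        try:
            return self._defs[(resname.upper(), flavour)]
        except KeyError:
            raise LamellaError(
                f"no {flavour} definition registered for residue {resname!r}"
            ) from None

    def match_residue(self, residue: Residue) -> Optional[LipidDefinition]:
        """Best-matching definition for a residue, or None.

        Coarse-grained variants are preferred for bead-sized residues;
        otherwise the atomistic variant wins when its tail hydrogens are
        present and the united-atom variant when they are absent.
        """
        name = residue.resname.upper()
        candidates = [d for (n, _), d in self._defs.items() if n == name]
        if not candidates:
            return None
        if residue.n_atoms <= CG_BEAD_THRESHOLD:
            order = [COARSE_GRAINED, UNITED_ATOM, ATOMISTIC]
        else:
            has_h = any(
                residue.has(h)
                for d in candidates if d.flavour == ATOMISTIC
                for hs in d.tail_hydrogens.values() for h in hs
            )
            order = ([ATOMISTIC, UNITED_ATOM] if has_h else [UNITED_ATOM, ATOMISTIC])
            order.append(COARSE_GRAINED)
        for flavour in order:
            for d in candidates:
                if d.flavour == flavour and d.matches(residue):
                    return d
        return None


def _parse_definition(resname: str, entry: Mapping) -> LipidDefinition:
    try:
        tails = tuple(tuple(str(a) for a in t) for t in entry["tails"])
        phosphorus = str(entry["phosphorus"])
    except KeyError as exc:
        raise LamellaError(
            f"lipid config {resname!r}: missing required key {exc.args[0]!r}"
        ) from None
    hydrogens = {
        str(c): tuple(str(h) for h in hs)
        for c, hs in dict(entry.get("hydrogens", {})).items()
    }
    return LipidDefinition(
        residue_name=resname,
        flavour=str(entry.get("flavour", ATOMISTIC)),
        phosphorus_atom=phosphorus,
        headgroup_reference_atom=str(entry.get("headgroup_ref", phosphorus)),
        tails=tails,
        tail_names=tuple(entry.get("tail_names", ())),
        tail_hydrogens=hydrogens,
        max_tail_extension=tuple(entry.get("max_extension", ())),
        charges={str(k): float(v) for k, v in dict(entry.get("charges", {})).items()},
        bond_step=float(entry.get("bond_step", 0.127)),
    )


def load_lipid_registry(config_path: Optional[str | Path] = None) -> LipidRegistry:
    """Built-in registry, optionally overridden/extended by a YAML/JSON config."""
    registry = LipidRegistry(builtin_definitions())
    if config_path is None:
        return registry
    path = Path(config_path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise LamellaError(f"lipid config {path}: expected a mapping of residues")
    for resname, entry in data.items():
        registry.add(_parse_definition(str(resname).upper(), entry))
    return registry


def resolve_charges(
    frame: Frame,
    registry: LipidRegistry,
    extra_charges: Optional[Mapping[str, float]] = None,
    table: Optional[ResidueTable] = None,
) -> "np.ndarray":
    """Per-atom partial charges (e) from the registry plus an extra charge map.

    Lipid atoms default to their definition's charge (0 e when unlisted);
    monatomic ions use :data:`ION_CHARGES`.  ``extra_charges`` maps
    ``"RESNAME:ATOM"`` or plain atom names to charges and overrides both.
    Any atom that cannot be resolved raises a hard error listing every
    missing name, since a partial charge map silently biases Poisson
    integration.
    """
    import numpy as np

    table = table or ResidueTable(frame)
    extra = {str(k).upper(): float(v) for k, v in (extra_charges or {}).items()}
    charges = np.zeros(frame.n_atoms)
    missing: list[str] = []
    for res in table:
        definition = registry.match_residue(res)
        for i in res.atom_indices:
            name = str(frame.names[i]).upper()
            key = f"{res.resname.upper()}:{name}"
            if key in extra:
                charges[i] = extra[key]
            elif name in extra:
                charges[i] = extra[name]
            elif definition is not None:
                charges[i] = dict(definition.charges).get(str(frame.names[i]), 0.0)
            elif res.resname.upper() in ION_CHARGES and res.n_atoms == 1:
                charges[i] = ION_CHARGES[res.resname.upper()]
            else:
                missing.append(key)
    if missing:
        raise LamellaError(
            "atoms missing from charge map: " + ", ".join(sorted(set(missing)))
        )
    return charges
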