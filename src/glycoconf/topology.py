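"""Molecular bookkeeping: which atoms form each ring and each glycosidic torsion.

The PDB format carries no carbohydrate linkage record, so rings and
linkages are declared explicitly in a small YAML document keyed by
residue (``chain:resSeq``).  Torsion atom quadruples follow the IUPAC
conventions for glycosidic angles and can be overridden per linkage:

* (1→n):  φ = O5–C1–O–Cn,  ψ = C1–O–Cn–C(n−1), plus ω = O6–C6–C5–C4
  for (1→6) linkages;
* (2→3):  φ = O6–C2–O–C3,  ψ = C2–O–C3–C2 (donor C2, acceptor C2).

Coordinates are Å, axes right-handed, frames 0-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import MDAnalysis as mda
import yaml

__all__ = [
    "TopologyError",
    "AtomRef",
    "Atom",
    "RingDefinition",
    "LinkageDefinition",
    "GlycanTopology",
    "LINKAGE_KINDS",
    "default_linkage_quadruples",
    "load_topology",
    "topology_to_config",
]

LINKAGE_KINDS = ("1->2", "1->3", "1->4", "1->6", "2->3")


class TopologyError(ValueError):
    """Unresolvable or ill-formed ring/linkage declaration."""


@dataclass(frozen=True)
class AtomRef:
    """An atom named within a specific residue."""

    residue: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.residue}/{self.name}"


@dataclass(frozen=True)
class Atom:
    name: str
    residue: str
    element: str
    index: int  # 0-based index into the structure's atom order


@dataclass(frozen=True)
class RingDefinition:
    """A 6-atom puckering circuit within one residue.

    ``labels`` maps ring positions to the locants used in conformer
    names (e.g. ``("O","1","2","3","4","5")`` for O5–C1–…–C5).
    """

    residue_id: str
    atom_order: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.atom_order) != 6:
            raise TopologyError(
                f"ring in residue {self.residue_id} lists "
                f"{len(self.atom_order)} atoms; exactly 6 required"
            )
        if len(set(self.atom_order)) != 6:
            raise TopologyError(
                f"ring in residue {self.residue_id} repeats an atom name"
            )
        if len(self.labels) != 6:
            raise TopologyError("labels must cover all 6 ring positions")

    @property
    def atom_refs(self) -> tuple[AtomRef, ...]:
        return tuple(AtomRef(self.residue_id, a) for a in self.atom_order)


def _auto_labels(atom_order: Sequence[str]) -> tuple[str, ...]:
    """Derive name locants from atom names: C1 → "1", O5/O6 → "O"."""
    out = []
    for name in atom_order:
        if name.upper().startswith("O"):
            out.append("O")
        else:
            digits = "".join(ch for ch in name if ch.isdigit())
            out.append(digits or name)
    return tuple(out)


@dataclass(frozen=True)
class LinkageDefinition:
    """A glycosidic linkage with its torsion atom quadruples."""

    donor_residue: str
    acceptor_residue: str
    kind: str
    torsions: Mapping[str, tuple[AtomRef, AtomRef, AtomRef, AtomRef]]

    def __post_init__(self):
        if self.kind not in LINKAGE_KINDS:
            raise TopologyError(
                f"unsupported linkage kind {self.kind!r}; "
                f"expected one of {LINKAGE_KINDS}"
            )
        for name, quad in self.torsions.items():
            if len(quad) != 4 or len(set(quad)) != 4:
                raise TopologyError(
                    f"torsion {name} of {self.linkage_id} must list "
                    "4 distinct atoms"
                )
        if self.kind == "1->6" and "omega" not in self.torsions:
            raise TopologyError(
                f"(1->6) linkage {self.linkage_id} requires an omega torsion"
            )

    @property
    def linkage_id(self) -> str:
        return f"{self.donor_residue}({self.kind}){self.acceptor_residue}"


def default_linkage_quadruples(
    kind: str,
    donor_residue: str,
    acceptor_residue: str,
    omega_style: str = "C4",
) -> dict[str, tuple[AtomRef, AtomRef, AtomRef, AtomRef]]:
    """IUPAC torsion quadruples for a linkage kind.

    The glycosidic bridge oxygen ``On`` is taken to belong to the
    acceptor residue.  ``omega_style`` selects the last ω atom for
    (1→6) linkages: ``"C4"`` (O6–C6–C5–C4, the convention used
    throughout) or ``"O5"`` (the also-common O6–C6–C5–O5).
    """
    d = lambda name: AtomRef(donor_residue, name)  # noqa: E731
    a = lambda name: AtomRef(acceptor_residue, name)  # noqa: E731
    if kind == "2->3":
        return {
            "phi": (d("O6"), d("C2"), a("O3"), a("C3")),
            "psi": (d("C2"), a("O3"), a("C3"), a("C2")),
        }
    if kind in ("1->2", "1->3", "1->4", "1->6"):
        n = int(kind[-1])
        bridge = a(f"O{n}")
        quads = {
            "phi": (d("O5"), d("C1"), bridge, a(f"C{n}")),
            "psi": (d("C1"), bridge, a(f"C{n}"), a(f"C{n - 1}")),
        }
        if n == 6:
            if omega_style == "C4":
                quads["omega"] = (a("O6"), a("C6"), a("C5"), a("C4"))
            elif omega_style == "O5":
                quads["omega"] = (a("O6"), a("C6"), a("C5"), a("O5"))
            else:
                raise TopologyError(f"unknown omega_style {omega_style!r}")
        return quads
    raise TopologyError(f"unsupported linkage kind {kind!r}")


@dataclass
class GlycanTopology:
    """Resolved rings and linkages over a structure's atom list."""

    atoms: tuple[Atom, ...]
    rings: tuple[RingDefinition, ...] = ()
    linkages: tuple[LinkageDefinition, ...] = ()
    _index: dict[AtomRef, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {
                AtomRef(at.residue, at.name): at.index for at in self.atoms
            }
        self.validate()

    def validate(self) -> None:
        for ring in self.rings:
            for ref in ring.atom_refs:
                if ref not in self._index:
                    raise TopologyError(
                        f"ring atom {ref.name!r} not found in residue "
                        f"{ref.residue!r}"
                    )
        for link in self.linkages:
            for name, quad in link.torsions.items():
                for ref in quad:
                    if ref not in self._index:
                        raise TopologyError(
                            f"torsion {name} of {link.linkage_id}: atom "
                            f"{ref.name!r} not found in residue "
                            f"{ref.residue!r}"
                        )

    def atom_index(self, ref: AtomRef) -> int:
        try:
            return self._index[ref]
        except KeyError:
            raise TopologyError(
                f"atom {ref.name!r} not found in residue {ref.residue!r}"
            ) from None

    def ring_indices(self, ring: RingDefinition):
        return [self.atom_index(r) for r in ring.atom_refs]

    def torsion_indices(self, link: LinkageDefinition, torsion: str):
        return [self.atom_index(r) for r in link.torsions[torsion]]

    def ring_by_residue(self, residue_id: str) -> RingDefinition:
        for ring in self.rings:
            if ring.residue_id == residue_id:
                return ring
        raise TopologyError(f"no ring defined for residue {residue_id!r}")


def _residue_key(segid: str, resid: int) -> str:
    chain = (segid or "A").strip() or "A"
    return f"{chain}:{resid}"


def _atoms_from_universe(universe: mda.Universe) -> tuple[Atom, ...]:
    atoms = []
    has_chain = hasattr(universe.atoms, "chainIDs")
    for i, at in enumerate(universe.atoms):
        chain = at.chainID if has_chain else at.segid
        try:
            element = at.element or at.name[0]
        except (mda.exceptions.NoDataError, AttributeError):
            element = at.name[0]
        atoms.append(
            Atom(name=at.name, residue=_residue_key(chain, at.resid),
                 element=element, index=i)
        )
    return tuple(atoms)


def _parse_torsion_override(residue_map, raw) -> tuple[AtomRef, ...]:
    # entries look like "A:1/O5" or {residue: "A:1", atom: "O5"}
    out = []
    for item in raw:
        if isinstance(item, str):
            res, _, name = item.partition("/")
            if not name:
                raise TopologyError(
                    f"torsion atom {item!r} must be 'residue/atom'"
                )
            out.append(AtomRef(res, name))
        else:
            out.append(AtomRef(item["residue"], item["atom"]))
    return tuple(out)


def load_topology(
    structure_file: str | Path,
    definitions: str | Path | Mapping,
) -> GlycanTopology:
    """Resolve a ring/linkage config document against a PDB structure.

    ``definitions`` is a YAML path or an equivalent mapping with keys
    ``rings`` and ``linkages``; every referenced atom must exist in the
    structure or a :class:`TopologyError` naming it is raised.
    """
    if isinstance(definitions, (str, Path)):
        with open(definitions) as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(definitions)
    universe = mda.Universe(str(structure_file))
    atoms = _atoms_from_universe(universe)

    rings = []
    for entry in config.get("rings", []):
        atom_order = tuple(entry["atoms"])
        labels = tuple(entry["labels"]) if "labels" in entry \
            else _auto_labels(atom_order)
        rings.append(
            RingDefinition(
                residue_id=str(entry["residue"]),
                atom_order=atom_order,
                labels=labels,
            )
        )

    linkages = []
    for entry in config.get("linkages", []):
        donor = str(entry["donor"])
        acceptor = str(entry["acceptor"])
        kind = str(entry["kind"])
        quads = default_linkage_quadruples(
            kind, donor, acceptor,
            omega_style=entry.get("omega_style", "C4"),
        )
        for name, raw in (entry.get("torsions") or {}).items():
            quads[name] = _parse_torsion_override(None, raw)
        linkages.append(
            LinkageDefinition(
                donor_residue=donor, acceptor_residue=acceptor,
                kind=kind, torsions=quads,
            )
        )

    residue_ids = [r.residue_id for r in rings]
    if len(set(residue_ids)) != len(residue_ids):
        raise TopologyError("duplicate ring residue identifiers")
    return GlycanTopology(atoms=atoms, rings=tuple(rings),
                          linkages=tuple(linkages))


def topology_to_config(topology: GlycanTopology) -> dict:
    """Serialise rings/linkages back to the config mapping form.

    Round trip: ``load_topology(pdb, topology_to_config(t))`` compares
    equal to ``t`` field by field.
    """
    rings = [
        {
            "residue": r.residue_id,
            "atoms": list(r.atom_order),
            "labels": list(r.labels),
        }
        for r in topology.rings
    ]
    linkages = []
    for link in topology.linkages:
        entry = {
            "donor": link.donor_residue,
            "acceptor": link.acceptor_residue,
            "kind": link.kind,
            "torsions": {
                name: [f"{ref.residue}/{ref.name}" for ref in quad]
                for name, quad in link.torsions.items()
            },
        }
        linkages.append(entry)
    return {"rings": rings, "linkages": linkages}
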