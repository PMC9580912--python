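"""Reference database of compounds, reactions, atom mappings and pathways.

The reference database plays the role that a curated metabolic database plays
for a reconstruction pipeline: it is the universe of known biochemistry
against which each community member's annotation is resolved.  It is stored
as a single JSON document (see ``docs/refdb_schema.md``) holding

* compounds with elemental formulas (heavy-atom counts are derived from the
  formula; hydrogens are never tracked individually),
* reactions with stoichiometric slots, EC numbers, enzyme names, a
  directionality flag and a pre-computed atom mapping — a one-to-one partial
  matching of non-hydrogen atoms from reactant slots to product slots,
* pathways with an ontology class path, key reactions and an optional
  taxonomic range,
* a rooted pathway-class ontology, and
* an explicit list of currency metabolites (water, ATP and friends) that
  route search must not link through.

Atom mappings are input data: this module consumes them, it never computes
them from chemical structure.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

from .errors import IntegrityError, SchemaError, UsageError, ValidationError

SCHEMA_VERSION = 1

DIRECTIONS = ("LEFT-TO-RIGHT", "RIGHT-TO-LEFT", "REVERSIBLE")
REACTION_TYPES = ("SMALL-MOLECULE", "TRANSPORT", "MACROMOLECULE")

#: EC numbers are four dot-separated fields; trailing fields may be the
#: wildcard "-" to denote a partial classification.
EC_PATTERN = re.compile(r"^\d+(\.(\d+|-)){3}$")

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalize_name(name: str) -> str:
    """Normalize an enzyme or compound name for index lookup.

    Lowercase, punctuation stripped, whitespace collapsed.
    """
    return " ".join(name.lower().translate(_PUNCT_TABLE).split())


def validate_ec(ec: str) -> None:
    if not EC_PATTERN.match(ec):
        raise ValidationError(f"malformed EC number: {ec!r}")


def ec_prefixes(ec: str) -> list[str]:
    """All ancestor ECs of ``ec``, most specific first, e.g.
    ``2.7.1.40`` -> [``2.7.1.40``, ``2.7.1.-``, ``2.7.-.-``, ``2.-.-.-``]."""
    fields = ec.split(".")
    out = []
    for depth in range(4, 0, -1):
        head = fields[:depth]
        if head and head[-1] == "-":
            continue
        out.append(".".join(head + ["-"] * (4 - depth)))
    return out


@dataclass
class Compound:
    id: str
    name: str
    formula: dict[str, int] = field(default_factory=dict)
    is_currency: bool = False

    @property
    def heavy_atom_count(self) -> int:
        """Number of non-hydrogen atoms, derived from the formula."""
        return sum(n for el, n in self.formula.items() if el != "H")

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS.get(el, 0.0) * n for el, n in self.formula.items())

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "formula": dict(sorted(self.formula.items())),
            "is_currency": self.is_currency,
        }


#: Monoisotopic masses (Da) of the elements the toolkit's formulas may use.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Mg": 23.9850417,
    "Fe": 55.9349375,
    "Se": 73.9224764,
}


@dataclass(frozen=True)
class AtomMapping:
    """One-to-one partial matching of heavy atoms across a reaction.

    Each pair maps ``(reactant_slot_instance, atom_index)`` to
    ``(product_slot_instance, atom_index)``.  Slot instances index the
    *expanded* slot list: a slot with stoichiometric coefficient ``k``
    contributes ``k`` consecutive instances, each with its own 0-based atom
    index space bounded by the compound's heavy-atom count.
    """

    pairs: frozenset[tuple[tuple[int, int], tuple[int, int]]] = frozenset()

    def validate(self) -> None:
        lefts = [l for l, _ in self.pairs]
        rights = [r for _, r in self.pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise SchemaError("atom mapping is not one-to-one")

    def to_list(self) -> list:
        return sorted([list(l), list(r)] for l, r in self.pairs)

    @classmethod
    def from_list(cls, data: list) -> "AtomMapping":
        return cls(frozenset(((l[0], l[1]), (r[0], r[1])) for l, r in data))


@dataclass
class Reaction:
    id: str
    reactant_slots: list[tuple[str, int]]
    product_slots: list[tuple[str, int]]
    ec_numbers: set[str] = field(default_factory=set)
    enzyme_names: set[str] = field(default_factory=set)
    direction: str = "LEFT-TO-RIGHT"
    reaction_type: str = "SMALL-MOLECULE"
    atom_mapping: AtomMapping = field(default_factory=AtomMapping)

    def expanded_slots(self, side: str) -> list[str]:
        """Slot instances on ``side`` ('reactant' or 'product'): each slot is
        repeated once per unit of stoichiometry."""
        slots = self.reactant_slots if side == "reactant" else self.product_slots
        out: list[str] = []
        for cid, coef in slots:
            out.extend([cid] * coef)
        return out

    def compound_ids(self) -> set[str]:
        return {c for c, _ in self.reactant_slots} | {c for c, _ in self.product_slots}

    def transported_compounds(self) -> set[str]:
        return {c for c, _ in self.reactant_slots} & {c for c, _ in self.product_slots}

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "reactants": [[c, n] for c, n in self.reactant_slots],
            "products": [[c, n] for c, n in self.product_slots],
            "ec_numbers": sorted(self.ec_numbers),
            "enzyme_names": sorted(self.enzyme_names),
            "direction": self.direction,
            "reaction_type": self.reaction_type,
            "atom_mapping": self.atom_mapping.to_list(),
        }


@dataclass
class Pathway:
    id: str
    name: str
    class_path: list[str]
    reaction_ids: set[str]
    key_reaction_ids: set[str] = field(default_factory=set)
    taxonomic_range: set[str] = field(default_factory=set)
    is_superpathway: bool = False

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "class_path": list(self.class_path),
            "reactions": sorted(self.reaction_ids),
            "key_reactions": sorted(self.key_reaction_ids),
            "taxonomic_range": sorted(self.taxonomic_range),
            "is_superpathway": self.is_superpathway,
        }


@dataclass
class Ontology:
    """Rooted tree of pathway classes: id -> (name, parent id)."""

    root: str
    classes: dict[str, tuple[str, str | None]]

    def validate(self) -> None:
        roots = [cid for cid, (_, parent) in self.classes.items() if parent is None]
        if roots != [self.root] and set(roots) != {self.root}:
            raise SchemaError(f"ontology must have the single root {self.root!r}, got {roots}")
        for cid, (_, parent) in self.classes.items():
            seen = {cid}
            node = parent
            while node is not None:
                if node not in self.classes:
                    raise IntegrityError(f"ontology parent {node!r} of {cid!r} undefined")
                if node in seen:
                    raise SchemaError(f"ontology cycle through {node!r}")
                seen.add(node)
                node = self.classes[node][1]

    def path_to_root(self, class_id: str) -> list[str]:
        """Class ids from the root down to ``class_id`` inclusive."""
        if class_id not in self.classes:
            raise ValidationError(f"unknown ontology class {class_id!r}")
        path = [class_id]
        node = self.classes[class_id][1]
        while node is not None:
            if node in path:
                raise SchemaError(f"ontology cycle through {node!r}")
            path.append(node)
            node = self.classes[node][1]
        return path[::-1]

    def children(self, class_id: str) -> list[str]:
        return sorted(c for c, (_, p) in self.classes.items() if p == class_id)

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "classes": {
                cid: {"name": name, "parent": parent}
                for cid, (name, parent) in sorted(self.classes.items())
            },
        }


class ReferenceDB:
    """In-memory reference database with EC and enzyme-name indexes."""

    def __init__(
        self,
        compounds: dict[str, Compound],
        reactions: dict[str, Reaction],
        pathways: dict[str, Pathway],
        ontology: Ontology,
        currency_ids: set[str] | None = None,
    ):
        self.compounds = compounds
        self.reactions = reactions
        self.pathways = pathways
        self.ontology = ontology
        self.currency_ids = set(currency_ids or set())
        for cid in self.currency_ids:
            if cid in self.compounds:
                self.compounds[cid].is_currency = True
        self.ec_index: dict[str, set[str]] = {}
        self.name_index: dict[str, set[str]] = {}
        self._compound_name_index: dict[str, str] = {}
        self.validate()
        self._build_indexes()

    # -- construction ---------------------------------------------------

    def validate(self) -> None:
        self.ontology.validate()  # first: pathway checks walk the ontology
        for rxn in self.reactions.values():
            for cid in rxn.compound_ids():
                if cid not in self.compounds:
                    raise IntegrityError(
                        f"reaction {rxn.id!r} references missing compound {cid!r}"
                    )
            if rxn.direction not in DIRECTIONS:
                raise SchemaError(f"reaction {rxn.id!r}: bad direction {rxn.direction!r}")
            if rxn.reaction_type not in REACTION_TYPES:
                raise SchemaError(f"reaction {rxn.id!r}: bad type {rxn.reaction_type!r}")
            if rxn.reaction_type == "TRANSPORT" and not rxn.transported_compounds():
                raise SchemaError(
                    f"transport reaction {rxn.id!r} has no compound on both sides"
                )
            for ec in rxn.ec_numbers:
                validate_ec(ec)
            self._validate_mapping(rxn)
        for pwy in self.pathways.values():
            if not pwy.key_reaction_ids <= pwy.reaction_ids:
                raise SchemaError(f"pathway {pwy.id!r}: key reactions not a subset")
            for rid in pwy.reaction_ids:
                if rid not in self.reactions:
                    raise IntegrityError(
                        f"pathway {pwy.id!r} references missing reaction {rid!r}"
                    )
            if pwy.class_path:
                expected = self.ontology.path_to_root(pwy.class_path[-1])
                if list(pwy.class_path) != expected:
                    raise SchemaError(
                        f"pathway {pwy.id!r}: class_path {pwy.class_path} is not the "
                        f"root-to-class path {expected}"
                    )
        for cid in self.currency_ids:
            if cid not in self.compounds:
                raise IntegrityError(f"currency id {cid!r} is not a compound")
        self.ontology.validate()

    def _validate_mapping(self, rxn: Reaction) -> None:
        rxn.atom_mapping.validate()
        r_slots = rxn.expanded_slots("reactant")
        p_slots = rxn.expanded_slots("product")
        for (ri, ra), (pi, pa) in rxn.atom_mapping.pairs:
            if not (0 <= ri < len(r_slots)) or not (0 <= pi < len(p_slots)):
                raise SchemaError(f"reaction {rxn.id!r}: atom-mapping slot out of range")
            if ra >= self.compounds[r_slots[ri]].heavy_atom_count:
                raise SchemaError(
                    f"reaction {rxn.id!r}: atom index {ra} exceeds heavy atoms of "
                    f"{r_slots[ri]!r}"
                )
            if pa >= self.compounds[p_slots[pi]].heavy_atom_count:
                raise SchemaError(
                    f"reaction {rxn.id!r}: atom index {pa} exceeds heavy atoms of "
                    f"{p_slots[pi]!r}"
                )

    def _build_indexes(self) -> None:
        for rxn in self.reactions.values():
            for ec in rxn.ec_numbers:
                for key in ec_prefixes(ec):
                    self.ec_index.setdefault(key, set()).add(rxn.id)
                self.ec_index.setdefault(ec, set()).add(rxn.id)
            for name in rxn.enzyme_names:
                self.name_index.setdefault(normalize_name(name), set()).add(rxn.id)
        for cpd in self.compounds.values():
            self._compound_name_index[normalize_name(cpd.name)] = cpd.id

    # -- queries --------------------------------------------------------

    def ec_lookup(self, ec: str) -> set[str]:
        """Reaction ids annotated with ``ec``; a partial EC such as
        ``2.7.1.-`` matches every reaction whose EC has that prefix."""
        validate_ec(ec)
        return set(self.ec_index.get(ec, set()))

    def name_lookup(self, enzyme_name: str) -> set[str]:
        return set(self.name_index.get(normalize_name(enzyme_name), set()))

    def compound_by_name(self, name: str) -> str | None:
        return self._compound_name_index.get(normalize_name(name))

    def atoms_conserved_by_reaction(
        self,
        reaction_id: str,
        in_compound: str,
        in_atoms: set[int],
        out_compound: str,
        orientation: str = "forward",
    ) -> set[int]:
        """Image of ``in_atoms`` of ``in_compound`` under the reaction's atom
        mapping, landing on ``out_compound``.

        ``orientation`` orients the reaction: under ``forward`` the input
        side is the reactant side as written; under ``reverse`` it is the
        product side and the mapping is inverted.  When a compound occupies
        several slot instances the first matching instance on each side is
        used.
        """
        if orientation not in ("forward", "reverse"):
            raise UsageError(f"bad orientation {orientation!r}")
        rxn = self.reactions[reaction_id]
        if orientation == "forward":
            in_side, out_side = rxn.expanded_slots("reactant"), rxn.expanded_slots("product")
            pairs = rxn.atom_mapping.pairs
        else:
            in_side, out_side = rxn.expanded_slots("product"), rxn.expanded_slots("reactant")
            pairs = frozenset((r, l) for l, r in rxn.atom_mapping.pairs)
        if in_compound not in in_side:
            raise UsageError(
                f"{in_compound!r} is not on the input side of {reaction_id!r} "
                f"({orientation})"
            )
        if out_compound not in out_side:
            raise UsageError(
                f"{out_compound!r} is not on the output side of {reaction_id!r} "
                f"({orientation})"
            )
        in_slot = in_side.index(in_compound)
        out_slot = out_side.index(out_compound)
        return {
            oa for (islot, ia), (oslot, oa) in pairs
            if islot == in_slot and oslot == out_slot and ia in in_atoms
        }

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "compounds": [c.to_dict() for _, c in sorted(self.compounds.items())],
            "reactions": [r.to_dict() for _, r in sorted(self.reactions.items())],
            "pathways": [p.to_dict() for _, p in sorted(self.pathways.items())],
            "ontology": self.ontology.to_dict(),
            "currency": sorted(self.currency_ids),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "ReferenceDB":
        if not isinstance(doc, dict) or "schema_version" not in doc:
            raise SchemaError("not a reference DB document (no schema_version)")
        if doc["schema_version"] != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {doc['schema_version']!r}")
        compounds: dict[str, Compound] = {}
        for rec in doc.get("compounds", []):
            try:
                cpd = Compound(
                    id=rec["id"],
                    name=rec.get("name", rec["id"]),
                    formula={el: int(n) for el, n in rec.get("formula", {}).items()},
                    is_currency=bool(rec.get("is_currency", False)),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"bad compound record {rec!r}: {exc}") from exc
            if cpd.id in compounds:
                raise SchemaError(f"duplicate compound id {cpd.id!r}")
            if any(n < 0 for n in cpd.formula.values()):
                raise SchemaError(f"compound {cpd.id!r}: negative formula count")
            compounds[cpd.id] = cpd
        reactions: dict[str, Reaction] = {}
        for rec in doc.get("reactions", []):
            try:
                rxn = Reaction(
                    id=rec["id"],
                    reactant_slots=[(c, int(n)) for c, n in rec["reactants"]],
                    product_slots=[(c, int(n)) for c, n in rec["products"]],
                    ec_numbers=set(rec.get("ec_numbers", [])),
                    enzyme_names=set(rec.get("enzyme_names", [])),
                    direction=rec.get("direction", "LEFT-TO-RIGHT"),
                    reaction_type=rec.get("reaction_type", "SMALL-MOLECULE"),
                    atom_mapping=AtomMapping.from_list(rec.get("atom_mapping", [])),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"bad reaction record {rec!r}: {exc}") from exc
            if rxn.id in reactions:
                raise SchemaError(f"duplicate reaction id {rxn.id!r}")
            if any(n <= 0 for _, n in rxn.reactant_slots + rxn.product_slots):
                raise SchemaError(f"reaction {rxn.id!r}: non-positive stoichiometry")
            reactions[rxn.id] = rxn
        pathways: dict[str, Pathway] = {}
        for rec in doc.get("pathways", []):
            try:
                pwy = Pathway(
                    id=rec["id"],
                    name=rec.get("name", rec["id"]),
                    class_path=list(rec.get("class_path", [])),
                    reaction_ids=set(rec["reactions"]),
                    key_reaction_ids=set(rec.get("key_reactions", [])),
                    taxonomic_range=set(rec.get("taxonomic_range", [])),
                    is_superpathway=bool(rec.get("is_superpathway", False)),
                )
            except (KeyError, TypeError) as exc:
                raise SchemaError(f"bad pathway record {rec!r}: {exc}") from exc
            if pwy.id in pathways:
                raise SchemaError(f"duplicate pathway id {pwy.id!r}")
            pathways[pwy.id] = pwy
        ont = doc.get("ontology", {"root": "Pathways", "classes": {"Pathways": {"name": "Pathways", "parent": None}}})
        try:
            ontology = Ontology(
                root=ont["root"],
                classes={
                    cid: (rec.get("name", cid), rec.get("parent"))
                    for cid, rec in ont["classes"].items()
                },
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"bad ontology record: {exc}") from exc
        return cls(compounds, reactions, pathways, ontology, set(doc.get("currency", [])))


def load_refdb(path: str | Path) -> ReferenceDB:
    """Load a reference database from its JSON document."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    return ReferenceDB.from_dict(doc)


def save_refdb(db: ReferenceDB, path: str | Path) -> None:
    db.save(path)
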