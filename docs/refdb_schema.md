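# Reference database JSON schema

The reference database is a single JSON document with a top-level
`schema_version` field (currently `1`). It is the universe of known
biochemistry — compounds, reactions, pathways, the pathway-class ontology
and the currency-metabolite list — against which every organism is
reconstructed.

```json
{
  "schema_version": 1,
  "compounds": [
    {"id": "GLC", "name": "glucose",
     "formula": {"C": 6, "H": 12, "O": 6}, "is_currency": false}
  ],
  "reactions": [
    {"id": "RXN0001",
     "reactants": [["GLC", 1]], "products": [["PYR", 1]],
     "ec_numbers": ["2.7.1.40"], "enzyme_names": ["pyruvate kinase"],
     "direction": "LEFT-TO-RIGHT", "reaction_type": "SMALL-MOLECULE",
     "atom_mapping": [[[0, 0], [0, 0]], [[0, 1], [0, 2]]]}
  ],
  "pathways": [
    {"id": "PWY001", "name": "example pathway",
     "class_path": ["Pathways", "Biosynthesis", "Amino-Acid-Biosynthesis"],
     "reactions": ["RXN0001"], "key_reactions": ["RXN0001"],
     "taxonomic_range": [], "is_superpathway": false}
  ],
  "ontology": {
    "root": "Pathways",
    "classes": {
      "Pathways": {"name": "Pathways", "parent": null},
      "Biosynthesis": {"name": "Biosynthesis", "parent": "Pathways"},
      "Amino-Acid-Biosynthesis":
        {"name": "Amino Acid Biosynthesis", "parent": "Biosynthesis"}
    }
  },
  "currency": ["CUR-WATER", "CUR-ATP", "CUR-NAD"]
}
```

## Field notes

**compounds.** `formula` maps element symbols to non-negative counts.
The heavy-atom count (all non-hydrogen atoms) is derived from the formula,
never stored. Compound ids must be unique.

**reactions.** `reactants`/`products` are ordered slot lists of
`[compound_id, stoichiometric_coefficient]`; coefficients are positive
integers. `direction` is one of `LEFT-TO-RIGHT`, `RIGHT-TO-LEFT`,
`REVERSIBLE`; `reaction_type` one of `SMALL-MOLECULE`, `TRANSPORT`,
`MACROMOLECULE`. A `TRANSPORT` reaction must carry at least one compound
on both sides (the transported substrate). EC numbers are four
dot-separated fields, trailing fields may be `-` (partial classification).
`enzyme_names` feed the name index; lookup normalizes case, punctuation
and whitespace.

**atom_mapping.** A list of pairs
`[[reactant_slot, atom_index], [product_slot, atom_index]]` forming a
one-to-one partial matching of heavy atoms from the reactant side to the
product side. Slot indices address the *expanded* slot list: a slot with
coefficient *k* contributes *k* consecutive instances, each with its own
0-based atom index space bounded by the compound's heavy-atom count.
Mappings cover only non-hydrogen atoms by construction and are input data:
the toolkit never computes them from chemical structure.

**pathways.** `class_path` must be the exact root-to-class path in the
ontology. `key_reactions` ⊆ `reactions`. An empty `taxonomic_range` means
unrestricted; otherwise an organism qualifies when any taxon of its lineage
is in the range.

**ontology.** A rooted tree: exactly one class with `parent: null`, no
cycles.

**currency.** Explicit list of ubiquitous cofactor/carrier compounds
(water, ATP, NAD...). Route search refuses to link consecutive reactions
through these by default; the list is data, never inferred from network
degree.

Loading validates every cross-reference (integrity errors name the missing
id) and every structural constraint (schema errors name the offending
record). Saving re-serializes with sorted keys, so save→load→save is
byte-identical.
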