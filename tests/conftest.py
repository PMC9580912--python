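"""Shared fixtures: a tiny hand-built reference DB and a seeded synthetic
community used across the suite."""

from __future__ import annotations

import copy
import json

import pytest

from commkit.importer import Community, build_organism_db
from commkit.pathway_prediction import PredictorParams, predict_pathways
from commkit.refdb import AtomMapping, Compound, Ontology, Pathway, Reaction, ReferenceDB
from commkit.synthetic import SynthParams, generate_community, generate_omics, generate_refdb

SEED = 17


def make_tiny_db() -> ReferenceDB:
    """Hand-built reference DB with known atom mappings and indexes.

    Chain A -> B -> C with hand-traceable mappings:
      R-AB sends A atoms {0,1} to B atoms {1,0} and drops atom 2;
      R-BC keeps only B atom 1, landing on C atom 0;
      R-ID is an identity mapping A -> B on all three atoms.
    """
    compounds = {
        "A": Compound("A", "compound A", {"C": 3, "H": 4}),
        "B": Compound("B", "compound B", {"C": 3, "H": 6}),
        "C": Compound("C", "compound C", {"C": 2, "H": 2}),
        "D": Compound("D", "compound D", {"C": 2, "H": 4}),
        "GLC": Compound("GLC", "glucose", {"C": 6, "H": 12, "O": 6}),
        "PYR": Compound("PYR", "pyruvate", {"C": 3, "H": 4, "O": 3}),
        "ARS": Compound("ARS", "arsenite", {"O": 3, "S": 1, "H": 1}),
        "WAT": Compound("WAT", "water", {"O": 1, "H": 2}),
    }
    identity3 = AtomMapping(frozenset(((0, i), (0, i)) for i in range(3)))
    reactions = {
        "R-AB": Reaction(
            id="R-AB",
            reactant_slots=[("A", 1)],
            product_slots=[("B", 1)],
            ec_numbers={"4.1.1.1"},
            atom_mapping=AtomMapping(frozenset({((0, 0), (0, 1)), ((0, 1), (0, 0))})),
        ),
        "R-BC": Reaction(
            id="R-BC",
            reactant_slots=[("B", 1)],
            product_slots=[("C", 1)],
            ec_numbers={"4.1.1.2"},
            atom_mapping=AtomMapping(frozenset({((0, 1), (0, 0))})),
        ),
        "R-ID": Reaction(
            id="R-ID",
            reactant_slots=[("A", 1)],
            product_slots=[("B", 1)],
            direction="REVERSIBLE",
            atom_mapping=identity3,
        ),
        "R-PK": Reaction(
            id="R-PK",
            reactant_slots=[("GLC", 1)],
            product_slots=[("PYR", 1)],
            ec_numbers={"2.7.1.40"},
            enzyme_names={"pyruvate kinase"},
            atom_mapping=AtomMapping(frozenset(((0, i), (0, i)) for i in range(6))),
        ),
        "R-K1": Reaction(
            id="R-K1",
            reactant_slots=[("GLC", 1)],
            product_slots=[("D", 1)],
            ec_numbers={"2.7.1.1"},
            enzyme_names={"hexokinase"},
            atom_mapping=AtomMapping(frozenset({((0, 0), (0, 0))})),
        ),
        "R-K2": Reaction(
            id="R-K2",
            reactant_slots=[("PYR", 1)],
            product_slots=[("C", 1)],
            ec_numbers={"2.7.1.2"},
            atom_mapping=AtomMapping(frozenset({((0, 0), (0, 0))})),
        ),
        "R-TRANS": Reaction(
            id="R-TRANS",
            reactant_slots=[("GLC", 1)],
            product_slots=[("GLC", 1)],
            reaction_type="TRANSPORT",
            atom_mapping=AtomMapping(frozenset(((0, i), (0, i)) for i in range(12))),
        ),
    }
    ontology = Ontology(
        root="Pathways",
        classes={
            "Pathways": ("Pathways", None),
            "Biosynthesis": ("Biosynthesis", "Pathways"),
            "Amino-Acid-Biosynthesis": ("Amino Acid Biosynthesis", "Biosynthesis"),
            "Degradation": ("Degradation", "Pathways"),
        },
    )
    pathways = {
        "P-CHAIN": Pathway(
            id="P-CHAIN",
            name="A to C chain",
            class_path=["Pathways", "Biosynthesis", "Amino-Acid-Biosynthesis"],
            reaction_ids={"R-AB", "R-BC"},
            key_reaction_ids={"R-AB"},
        ),
        "P-GLYC": Pathway(
            id="P-GLYC",
            name="glucose breakdown",
            class_path=["Pathways", "Degradation"],
            reaction_ids={"R-PK", "R-K1", "R-K2", "R-BC"},
            key_reaction_ids={"R-PK"},
            taxonomic_range={"tax-phylum-A"},
        ),
    }
    return ReferenceDB(compounds, reactions, pathways, ontology, {"WAT"})


@pytest.fixture
def tiny_db() -> ReferenceDB:
    return make_tiny_db()


@pytest.fixture(scope="session")
def synth_setup(tmp_path_factory):
    """Seeded synthetic reference DB + community files + truth labels."""
    root = tmp_path_factory.mktemp("synth")
    params = SynthParams(seed=SEED)
    db, meta = generate_refdb(params)
    truth = generate_community(db, meta, params, root / "mags")
    generate_omics(truth, params, root / "omics")
    return {"params": params, "db": db, "meta": meta, "root": root, "truth": truth}


def build_members(setup, fmt: str = "genbank"):
    members = []
    for oid in sorted(setup["truth"]["organisms"]):
        org_dir = setup["root"] / "mags" / oid
        lineage = setup["truth"]["organisms"][oid]["lineage"]
        if fmt == "genbank":
            org = build_organism_db(
                setup["db"], oid, genbank_path=org_dir / f"{oid}.gbk", taxon_lineage=lineage
            )
        else:
            org = build_organism_db(
                setup["db"],
                oid,
                gff_path=org_dir / f"{oid}.gff",
                fasta_path=org_dir / f"{oid}.fna",
                taxon_lineage=lineage,
            )
        members.append(org)
    return members


@pytest.fixture(scope="session")
def _predicted_community(synth_setup):
    members = build_members(synth_setup)
    for m in members:
        predict_pathways(m, synth_setup["db"], PredictorParams())
    return Community(members=members, refdb=synth_setup["db"])


@pytest.fixture
def community(_predicted_community) -> Community:
    """Fresh deep copy of the predicted synthetic community."""
    return copy.deepcopy(_predicted_community)


@pytest.fixture(scope="session")
def truth(synth_setup) -> dict:
    return json.loads((synth_setup["root"] / "mags" / "truth.json").read_text())
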