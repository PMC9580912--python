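"""Self-consistent synthetic fixtures for the whole toolkit.

The generator builds a miniature reference database (compounds, reactions
with valid atom mappings, pathway chains with key reactions and taxonomic
ranges, decoy pathways, a small ontology), emits annotated genomes for a
community with known ground truth — in GenBank *and* GFF3+FASTA so format
equivalence is testable — and produces omics tables with designated
perturbed pathways.  Everything is driven by one integer seed and iterates
collections in sorted order, so a fixed seed yields byte-identical files.

Atom mappings are constructed by partitioning reactant atoms among
products, never matched after the fact, so validity is guaranteed rather
than checked.  Decoy pathways borrow most of their reactions from a true
pathway but own a key reaction that no organism's annotation ever
evidences: completion-ratio-only prediction accepts them, the key-reaction
gate rejects them.

Truth labels are written to a separate JSON file and never leak into the
annotation files.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .refdb import AtomMapping, Compound, Ontology, Pathway, Reaction, ReferenceDB

TAXA = ("tax-root", "tax-phylum-A", "tax-phylum-B")

_ELEMENTS = ("C", "N", "O", "S", "P")

_ENZYME_SUFFIXES = {
    "1": "dehydrogenase",
    "2": "transferase",
    "3": "hydrolase",
    "4": "lyase",
    "5": "isomerase",
    "6": "synthase",
}


@dataclass
class SynthParams:
    seed: int = 17
    n_compounds: int = 60
    n_reactions: int = 40
    n_pathways: int = 8
    n_organisms: int = 8
    pathway_presence_prob: float = 0.6
    annotation_noise: float = 0.0
    decoy_pathway_count: int = 2
    n_superpathways: int = 1
    operon_prob: float = 0.5
    omics_effect: float = 2.0
    omics_noise_sd: float = 0.3

    def __post_init__(self):
        for name in ("pathway_presence_prob", "annotation_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def _make_compound(rng: random.Random, idx: int) -> Compound:
    formula: dict[str, int] = {"C": rng.randint(2, 6)}
    for el in _ELEMENTS[1:]:
        if rng.random() < 0.5:
            formula[el] = rng.randint(1, 2)
    formula["H"] = rng.randint(3, 12)
    return Compound(id=f"C{idx:04d}", name=f"metabolite {idx}", formula=formula)


def _chain_mapping(rng: random.Random, n_in: int, n_out: int) -> AtomMapping:
    """Random injective mapping carrying min(n_in, n_out) reactant atoms of
    slot 0 onto product slot 0 — a valid atom partition by construction."""
    k = min(n_in, n_out)
    src = rng.sample(range(n_in), k)
    dst = rng.sample(range(n_out), k)
    return AtomMapping(frozenset(((0, a), (0, b)) for a, b in zip(src, dst)))


def generate_refdb(params: SynthParams) -> tuple[ReferenceDB, dict]:
    """Generate a reference database and its generation metadata.

    Metadata records which pathways are true versus decoy, and the donor
    pathway each decoy borrowed reactions from.
    """
    rng = random.Random(params.seed)
    compounds: dict[str, Compound] = {}
    reactions: dict[str, Reaction] = {}
    pathways: dict[str, Pathway] = {}

    # currency metabolites: explicit list, small formulas
    currency = {
        "CUR-WATER": Compound("CUR-WATER", "water", {"O": 1, "H": 2}, True),
        "CUR-ATP": Compound("CUR-ATP", "ATP", {"C": 10, "N": 5, "O": 13, "P": 3, "H": 16}, True),
        "CUR-NAD": Compound("CUR-NAD", "NAD", {"C": 21, "N": 7, "O": 14, "P": 2, "H": 27}, True),
    }
    compounds.update(currency)

    classes = {
        "Pathways": ("Pathways", None),
        "Biosynthesis": ("Biosynthesis", "Pathways"),
        "Energy-Metabolism": ("Energy-Metabolism", "Pathways"),
        "Degradation": ("Degradation", "Pathways"),
        "Amino-Acid-Biosynthesis": ("Amino Acid Biosynthesis", "Biosynthesis"),
        "Carbohydrate-Biosynthesis": ("Carbohydrate Biosynthesis", "Biosynthesis"),
        "Fermentation": ("Fermentation", "Energy-Metabolism"),
        "Carbohydrate-Degradation": ("Carbohydrate Degradation", "Degradation"),
        "Amine-Degradation": ("Amine Degradation", "Degradation"),
    }
    ontology = Ontology(root="Pathways", classes=classes)
    leaf_classes = [
        "Amino-Acid-Biosynthesis",
        "Carbohydrate-Biosynthesis",
        "Fermentation",
        "Carbohydrate-Degradation",
        "Amine-Degradation",
    ]

    cpd_counter = 0

    def new_compound() -> Compound:
        nonlocal cpd_counter
        cpd_counter += 1
        cpd = _make_compound(rng, cpd_counter)
        compounds[cpd.id] = cpd
        return cpd

    rxn_counter = 0
    ec_counter = 0

    def new_reaction(sub: Compound, prod: Compound, pathway_idx: int) -> Reaction:
        nonlocal rxn_counter, ec_counter
        rxn_counter += 1
        ec_counter += 1
        ec_class = str(rng.randint(1, 6))
        ec = f"{ec_class}.{rng.randint(1, 9)}.{rng.randint(1, 9)}.{ec_counter}"
        reactant_slots = [(sub.id, 1)]
        product_slots = [(prod.id, 1)]
        if rng.random() < 0.3:
            reactant_slots.append(("CUR-ATP", 1))
        if rng.random() < 0.3:
            product_slots.append(("CUR-WATER", 1))
        rxn = Reaction(
            id=f"RXN{rxn_counter:04d}",
            reactant_slots=reactant_slots,
            product_slots=product_slots,
            ec_numbers={ec},
            enzyme_names={f"{prod.name} {_ENZYME_SUFFIXES[ec_class]}"},
            direction="REVERSIBLE" if rng.random() < 0.25 else "LEFT-TO-RIGHT",
            atom_mapping=_chain_mapping(rng, sub.heavy_atom_count, prod.heavy_atom_count),
        )
        reactions[rxn.id] = rxn
        return rxn

    true_pathways: list[str] = []
    chain_heads: list[Compound] = []
    for p in range(params.n_pathways):
        length = rng.randint(3, 5)
        if chain_heads and rng.random() < 0.3:
            start = rng.choice(sorted(chain_heads, key=lambda c: c.id))
        else:
            start = new_compound()
        chain = [start]
        rxn_ids = []
        for _ in range(length):
            nxt = new_compound()
            rxn_ids.append(new_reaction(chain[-1], nxt, p).id)
            chain.append(nxt)
        chain_heads.append(chain[-1])
        leaf = leaf_classes[p % len(leaf_classes)]
        taxonomic_range: set[str] = set()
        if rng.random() < 0.25:
            taxonomic_range = {rng.choice(["tax-phylum-A", "tax-phylum-B"])}
        keys = set(rng.sample(rxn_ids, rng.randint(1, 2)))
        pid = f"PWY{p + 1:03d}"
        pathways[pid] = Pathway(
            id=pid,
            name=f"pathway {p + 1} ({classes[leaf][0].lower()})",
            class_path=ontology.path_to_root(leaf),
            reaction_ids=set(rxn_ids),
            key_reaction_ids=keys,
            taxonomic_range=taxonomic_range,
        )
        true_pathways.append(pid)

    # decoys: borrow a donor's reactions, add one never-evidenced key reaction
    decoys: dict[str, str] = {}
    for d in range(params.decoy_pathway_count):
        donor_id = true_pathways[d % len(true_pathways)]
        donor = pathways[donor_id]
        key_rxn = new_reaction(new_compound(), new_compound(), -1)
        pid = f"DECOY{d + 1:03d}"
        pathways[pid] = Pathway(
            id=pid,
            name=f"decoy pathway {d + 1}",
            class_path=ontology.path_to_root(leaf_classes[d % len(leaf_classes)]),
            reaction_ids=set(donor.reaction_ids) | {key_rxn.id},
            key_reaction_ids={key_rxn.id},
            taxonomic_range=set(),
        )
        decoys[pid] = donor_id

    superpathways: dict[str, list[str]] = {}
    for s in range(params.n_superpathways):
        if len(true_pathways) < 2:
            break
        a, b = true_pathways[2 * s % len(true_pathways)], true_pathways[(2 * s + 1) % len(true_pathways)]
        if a == b:
            break
        pid = f"SUPER{s + 1:03d}"
        pathways[pid] = Pathway(
            id=pid,
            name=f"superpathway {s + 1}",
            class_path=ontology.path_to_root("Biosynthesis"),
            reaction_ids=set(pathways[a].reaction_ids) | set(pathways[b].reaction_ids),
            key_reaction_ids=set(pathways[a].key_reaction_ids)
            | set(pathways[b].key_reaction_ids),
            is_superpathway=True,
        )
        superpathways[pid] = [a, b]

    # pad the compound pool to the requested size with unused compounds
    while cpd_counter < params.n_compounds:
        new_compound()
    # extra unaffiliated reactions up to the requested count
    free = [c for c in compounds.values() if not c.is_currency]
    while rxn_counter < params.n_reactions:
        sub, prod = rng.sample(sorted(free, key=lambda c: c.id), 2)
        new_reaction(sub, prod, -1)

    db = ReferenceDB(compounds, reactions, pathways, ontology, set(currency))
    meta = {
        "true_pathways": true_pathways,
        "decoys": decoys,
        "superpathways": superpathways,
    }
    return db, meta


# ---------------------------------------------------------------------------
# community generation


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def generate_community(
    refdb: ReferenceDB,
    meta: dict,
    params: SynthParams,
    out_dir: str | Path,
) -> dict:
    """Emit annotation files (GenBank and GFF3+FASTA) plus truth labels.

    Each organism receives each eligible true pathway with probability
    ``pathway_presence_prob`` (taxonomic ranges are respected, so recovery
    under the taxon gate is exact).  Pathway genes carry the reaction's EC
    numbers and enzyme name unless annotation noise hits, in which case the
    gene becomes an unannotated hypothetical protein.  Genes are laid out
    with 20 bp gaps inside operon-style runs and 400 bp between
    transcription units.  Truth labels go to ``truth.json``.
    """
    rng = random.Random(params.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": params.seed, "organisms": {}}

    for i in range(params.n_organisms):
        oid = f"org{i + 1:02d}"
        phylum = TAXA[1] if i % 2 == 0 else TAXA[2]
        lineage = ["tax-root", phylum]
        eligible = [
            pid
            for pid in meta["true_pathways"]
            if not refdb.pathways[pid].taxonomic_range
            or set(lineage) & refdb.pathways[pid].taxonomic_range
        ]
        assigned = [pid for pid in eligible if rng.random() < params.pathway_presence_prob]
        if not assigned:
            assigned = [rng.choice(eligible)]

        org_dir = out_dir / oid
        org_dir.mkdir(exist_ok=True)

        genes = []  # (gene_id, product, ec_list, pathway_id or None)
        pathway_genes: dict[str, list[str]] = {}
        gene_counter = 0
        for pid in assigned:
            pwy = refdb.pathways[pid]
            pathway_genes[pid] = []
            for rid in sorted(pwy.reaction_ids):
                gene_counter += 1
                gid = f"{oid}_g{gene_counter:04d}"
                rxn = refdb.reactions[rid]
                if rng.random() < params.annotation_noise:
                    product, ecs = "hypothetical protein", []
                else:
                    product = sorted(rxn.enzyme_names)[0]
                    ecs = sorted(rxn.ec_numbers)
                genes.append((gid, product, ecs, pid))
                pathway_genes[pid].append(gid)

        # transporter genes for a few chain compounds of the organism
        org_reactions = sorted({r for pid in assigned for r in refdb.pathways[pid].reaction_ids})
        org_compounds = sorted(
            {
                c
                for rid in org_reactions
                for c in refdb.reactions[rid].compound_ids()
                if c not in refdb.currency_ids
            }
        )
        transporters = []
        templates = ["{} uptake protein", "{} efflux protein", "{} permease"]
        directions = ["uptake", "efflux", "uptake"]
        for j, cid in enumerate(rng.sample(org_compounds, min(3, len(org_compounds)))):
            gene_counter += 1
            gid = f"{oid}_g{gene_counter:04d}"
            product = templates[j % 3].format(refdb.compounds[cid].name)
            genes.append((gid, product, [], None))
            transporters.append(
                {"gene_id": gid, "compound_id": cid, "direction": directions[j % 3]}
            )
        # unannotated filler genes
        for _ in range(2):
            gene_counter += 1
            genes.append((f"{oid}_g{gene_counter:04d}", "hypothetical protein", [], None))

        # genomic layout: operon-style runs (20 bp gaps) vs isolated genes
        layout = []  # (gene tuple, start, end, strand)
        truth_operons: list[list[str]] = []
        pos = 101
        idx = 0
        while idx < len(genes):
            run_len = 1
            if rng.random() < params.operon_prob and idx + 1 < len(genes):
                run_len = min(rng.randint(2, 4), len(genes) - idx)
            strand = rng.choice("+-")
            run_ids = []
            for k in range(run_len):
                gene_len = 3 * rng.randint(60, 220)
                layout.append((genes[idx], pos, pos + gene_len - 1, strand))
                run_ids.append(genes[idx][0])
                pos += gene_len + 21  # 20 bp intergenic gap within the run
                idx += 1
            pos += 380  # widen to a 400 bp gap between transcription units
            truth_operons.append(run_ids)

        replicon_id = f"{oid}_ctg1"
        replicon_len = pos + 100
        seq = _random_seq(rng, replicon_len)
        _write_genbank(org_dir / f"{oid}.gbk", replicon_id, seq, layout)
        _write_gff3_fasta(
            org_dir / f"{oid}.gff", org_dir / f"{oid}.fna", replicon_id, seq, layout
        )

        truth["organisms"][oid] = {
            "lineage": lineage,
            "pathways": sorted(assigned),
            "reactions": org_reactions,
            "pathway_genes": {pid: pathway_genes[pid] for pid in sorted(pathway_genes)},
            "operons": truth_operons,
            "transporters": transporters,
        }
        # superpathways whose components are all assigned are true positives too
        supers = [
            sid
            for sid, comps in meta.get("superpathways", {}).items()
            if all(c in assigned for c in comps)
        ]
        truth["organisms"][oid]["pathways"] = sorted(assigned + supers)

    truth["decoys"] = meta.get("decoys", {})
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return truth


def _write_genbank(path: Path, replicon_id: str, seq: str, layout: list) -> None:
    record = SeqRecord(
        Seq(seq),
        id=replicon_id,
        name=replicon_id[:16],
        description="synthetic MAG",
        annotations={"molecule_type": "DNA", "date": "01-JAN-2022", "topology": "linear"},
    )
    for (gid, product, ecs, _pid), start, end, strand in layout:
        quals = {"locus_tag": [gid]}
        if product:
            quals["product"] = [product]
        if ecs:
            quals["EC_number"] = list(ecs)
        record.features.append(
            SeqFeature(
                FeatureLocation(start - 1, end, strand=1 if strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")


def _write_gff3_fasta(
    gff_path: Path, fasta_path: Path, replicon_id: str, seq: str, layout: list
) -> None:
    lines = ["##gff-version 3"]
    for (gid, product, ecs, _pid), start, end, strand in layout:
        attrs = [f"ID={gid}"]
        if product:
            attrs.append(f"product={product}")
        if ecs:
            attrs.append("ec_number=" + ";".join(ecs))
        lines.append(
            "\t".join(
                [
                    replicon_id,
                    "synth",
                    "CDS",
                    str(start),
                    str(end),
                    ".",
                    strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    gff_path.write_text("\n".join(lines) + "\n")
    wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
    fasta_path.write_text(f">{replicon_id}\n{wrapped}\n")


# ---------------------------------------------------------------------------
# omics generation


def generate_omics(
    truth: dict, params: SynthParams, out_dir: str | Path
) -> dict:
    """Per-organism omics tables with designated perturbed pathways.

    Genes of perturbed pathways get log-ratios centred at +-omics_effect
    (one sign per pathway) plus Gaussian noise; all other genes are noise
    around zero.  Returns the perturbation truth (organism -> pathway ->
    sign), which is also appended to ``truth.json`` when present.
    """
    rng = random.Random(params.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    perturbed: dict[str, dict[str, int]] = {}
    for oid in sorted(truth["organisms"]):
        org = truth["organisms"][oid]
        pathway_genes = org.get("pathway_genes", {})
        pids = sorted(pathway_genes)
        chosen = {}
        if pids:
            n_pick = max(1, math.ceil(0.3 * len(pids)))
            for pid in rng.sample(pids, n_pick):
                chosen[pid] = rng.choice((-1, 1))
        perturbed[oid] = chosen
        lines = ["gene\tlog2_ratio\tnote"]
        all_genes: list[tuple[str, str | None]] = []
        for pid in pids:
            for gid in pathway_genes[pid]:
                all_genes.append((gid, pid))
        for rec in org.get("transporters", []):
            all_genes.append((rec["gene_id"], None))
        for gid, pid in sorted(all_genes):
            value = rng.gauss(0.0, params.omics_noise_sd)
            if pid in chosen:
                value += chosen[pid] * params.omics_effect
            lines.append(f"{gid}\t{value:.4f}\tsynthetic")
        (out_dir / f"{oid}.tsv").write_text("\n".join(lines) + "\n")
    truth_path = out_dir / "omics_truth.json"
    truth_path.write_text(json.dumps(perturbed, indent=1, sort_keys=True) + "\n")
    return perturbed


# ---------------------------------------------------------------------------
# random reaction networks for route-search oracles


def generate_random_network(
    seed: int,
    n_compounds: int = 12,
    n_reactions: int = 25,
    n_organisms: int = 3,
    reversible_prob: float = 0.2,
):
    """Small random reaction network with organism sets, for route search.

    Returns ``(refdb, organism_sets)`` ready for
    :class:`~commkit.route_search.UnionNetwork`.  Every reaction converts
    one compound into another with a random injective atom mapping, and is
    carried by a random nonempty organism subset.
    """
    rng = random.Random(seed)
    compounds = {}
    for i in range(n_compounds):
        heavy = rng.randint(2, 5)
        compounds[f"M{i:03d}"] = Compound(
            id=f"M{i:03d}", name=f"m{i}", formula={"C": heavy, "H": rng.randint(1, 6)}
        )
    cids = sorted(compounds)
    orgs = [f"org{j + 1}" for j in range(n_organisms)]
    reactions = {}
    organism_sets = {}
    for r in range(n_reactions):
        sub, prod = rng.sample(cids, 2)
        h_in = compounds[sub].heavy_atom_count
        h_out = compounds[prod].heavy_atom_count
        k = rng.randint(1, min(h_in, h_out))
        src = rng.sample(range(h_in), k)
        dst = rng.sample(range(h_out), k)
        rid = f"R{r:03d}"
        reactions[rid] = Reaction(
            id=rid,
            reactant_slots=[(sub, 1)],
            product_slots=[(prod, 1)],
            ec_numbers={f"1.1.1.{r + 1}"},
            direction="REVERSIBLE" if rng.random() < reversible_prob else "LEFT-TO-RIGHT",
            atom_mapping=AtomMapping(frozenset(((0, a), (0, b)) for a, b in zip(src, dst))),
        )
        organism_sets[rid] = frozenset(rng.sample(orgs, rng.randint(1, n_organisms)))
    ontology = Ontology(root="Pathways", classes={"Pathways": ("Pathways", None)})
    db = ReferenceDB(compounds, reactions, {}, ontology, set())
    return db, organism_sets
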