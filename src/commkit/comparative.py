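"""Multi-organism searches and comparative tables for a community.

Search operations answer "which members of the community contain X?"
questions over pathways, genes/proteins and metabolites, always reporting
every member — including members with zero hits, since absence is itself a
comparative result.

Comparison operations produce :class:`ComparisonTable` objects: members in
community order as columns, rows sorted by label, each cell optionally
carrying a drill-down key that resolves to a finer table (the pathway-class
rollup drills down to per-pathway presence rows).  Everything is plain set
algebra over the members' reactomes, pathway calls, compounds, transport
records and transcription units, so all tables can be cross-checked against
brute-force set computations.
"""

from __future__ import annotations

import csv
import html as _html
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .importer import Community, Gene, OrganismDB

#: average amino-acid residue mass (Da) used to approximate protein weight
#: from gene length when no protein sequence is available
AVERAGE_RESIDUE_MASS = 110.0


@dataclass
class Cell:
    value: object
    drill_key: str | None = None

    def __str__(self):
        return "" if self.value is None else str(self.value)


@dataclass
class ComparisonTable:
    title: str
    row_labels: list[str]
    column_labels: list[str]
    cells: list[list[Cell]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.cells) != len(self.row_labels) or any(
            len(row) != len(self.column_labels) for row in self.cells
        ):
            raise ValidationError(f"table {self.title!r}: cell matrix shape mismatch")

    def cell(self, row_label: str, column_label: str) -> Cell:
        return self.cells[self.row_labels.index(row_label)][
            self.column_labels.index(column_label)
        ]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow([self.title] + self.column_labels)
            for label, row in zip(self.row_labels, self.cells):
                writer.writerow([label] + [str(c) for c in row])

    def to_html(self, path: str | Path) -> None:
        parts = [f"<h2>{_html.escape(self.title)}</h2>", "<table border='1'>"]
        parts.append(
            "<tr><th></th>"
            + "".join(f"<th>{_html.escape(c)}</th>" for c in self.column_labels)
            + "</tr>"
        )
        for label, row in zip(self.row_labels, self.cells):
            parts.append(
                f"<tr><th>{_html.escape(label)}</th>"
                + "".join(f"<td>{_html.escape(str(c))}</td>" for c in row)
                + "</tr>"
            )
        parts.append("</table>")
        Path(path).write_text("\n".join(parts) + "\n")


def _member_ids(community: Community) -> list[str]:
    return [m.organism_id for m in community]


# ---------------------------------------------------------------------------
# searches


def search_pathways(community: Community, query: dict) -> dict[str, list[str]]:
    """Per-member present pathways matching the query.

    Query keys (all optional, conjunctive): ``name_substring``,
    ``ontology_class``, ``substrate_id``, ``min_length``, ``max_length``.
    Every member is reported, zero-hit members with an empty list.
    """
    db = community.refdb
    if "ontology_class" in query and query["ontology_class"] not in db.ontology.classes:
        raise ValidationError(f"unknown ontology class {query['ontology_class']!r}")
    if "substrate_id" in query and query["substrate_id"] not in db.compounds:
        raise ValidationError(f"unknown compound {query['substrate_id']!r}")
    out: dict[str, list[str]] = {}
    for member in community:
        hits = []
        for pid in sorted(member.present_pathways()):
            pwy = db.pathways[pid]
            if "name_substring" in query and (
                query["name_substring"].lower() not in pwy.name.lower()
            ):
                continue
            if "ontology_class" in query and query["ontology_class"] not in pwy.class_path:
                continue
            if "substrate_id" in query:
                compounds = set()
                for rid in pwy.reaction_ids:
                    compounds |= db.reactions[rid].compound_ids()
                if query["substrate_id"] not in compounds:
                    continue
            if "min_length" in query and len(pwy.reaction_ids) < query["min_length"]:
                continue
            if "max_length" in query and len(pwy.reaction_ids) > query["max_length"]:
                continue
            hits.append(pid)
        out[member.organism_id] = hits
    return out


def _approx_molecular_weight(gene: Gene) -> float:
    """Protein weight approximated as residue count x average residue mass;
    residues = codons minus the stop codon."""
    n_residues = max(gene.length // 3 - 1, 0)
    return n_residues * AVERAGE_RESIDUE_MASS


def search_genes_proteins(community: Community, query: dict) -> dict[str, list[str]]:
    """Per-member gene hits on name substring, sequence-length range,
    molecular-weight range or GO term."""
    out: dict[str, list[str]] = {}
    for member in community:
        hits = []
        for gid in sorted(member.genes):
            gene = member.genes[gid]
            if "name_substring" in query and (
                query["name_substring"].lower() not in gene.product_name.lower()
            ):
                continue
            if "min_length" in query and gene.length < query["min_length"]:
                continue
            if "max_length" in query and gene.length > query["max_length"]:
                continue
            mw = _approx_molecular_weight(gene)
            if "min_weight" in query and mw < query["min_weight"]:
                continue
            if "max_weight" in query and mw > query["max_weight"]:
                continue
            if "go_term" in query and query["go_term"] not in gene.go_terms:
                continue
            hits.append(gid)
        out[member.organism_id] = hits
    return out


def organism_compounds(member: OrganismDB, community: Community) -> set[str]:
    """Compounds of an organism: participants of any reaction in its
    reactome (enzyme-evidenced or pathway-imported)."""
    db = community.refdb
    out: set[str] = set()
    for rid in member.all_reaction_ids():
        out |= db.reactions[rid].compound_ids()
    return out


def search_compounds(community: Community, query: dict) -> dict[str, list[str]]:
    """Per-member compound hits on name substring, exact formula or a
    monoisotopic-mass window ``(center, half_width)``."""
    db = community.refdb
    out: dict[str, list[str]] = {}
    for member in community:
        hits = []
        for cid in sorted(organism_compounds(member, community)):
            cpd = db.compounds[cid]
            if "name_substring" in query and (
                query["name_substring"].lower() not in cpd.name.lower()
            ):
                continue
            if "formula" in query and dict(cpd.formula) != dict(query["formula"]):
                continue
            if "mass_window" in query:
                center, half = query["mass_window"]
                if abs(cpd.monoisotopic_mass - center) > half:
                    continue
            hits.append(cid)
        out[member.organism_id] = hits
    return out


# ---------------------------------------------------------------------------
# comparison tables


def db_summary_stats(community: Community) -> ComparisonTable:
    """Per-member counts of genes, reactions by evidence class, pathways,
    compounds, transporters and transcription units."""
    rows = [
        "Genes",
        "Reactions (enzyme-evidenced)",
        "Reactions (pathway-imported)",
        "Reactions (total)",
        "Pathways (present)",
        "Compounds",
        "Transport records",
        "Transcription units",
    ]
    cells = []
    values_per_member = []
    for member in community:
        values_per_member.append(
            {
                "Genes": len(member.genes),
                "Reactions (enzyme-evidenced)": len(member.reactome),
                "Reactions (pathway-imported)": len(member.pathway_imported),
                "Reactions (total)": len(member.all_reaction_ids()),
                "Pathways (present)": len(member.present_pathways()),
                "Compounds": len(organism_compounds(member, community)),
                "Transport records": len(member.transport_records),
                "Transcription units": len(member.operons),
            }
        )
    for row in rows:
        cells.append([Cell(vals[row]) for vals in values_per_member])
    return ComparisonTable(
        title="Database Summary Statistics",
        row_labels=rows,
        column_labels=_member_ids(community),
        cells=cells,
        provenance={"operation": "db_summary_stats"},
    )


def _shared_unique_tables(
    title_prefix: str, sets: dict[str, set[str]], order: list[str]
) -> dict[str, ComparisonTable]:
    shared_cells = [
        [Cell(len(sets[a] & sets[b])) for b in order] for a in order
    ]
    everyone = {x for s in sets.values() for x in s}
    unique = {
        a: sorted(x for x in sets[a] if not any(x in sets[b] for b in order if b != a))
        for a in order
    }
    unique_cells = [[Cell(len(unique[a])) for a in order]]
    return {
        "shared": ComparisonTable(
            title=f"Shared {title_prefix}",
            row_labels=list(order),
            column_labels=list(order),
            cells=shared_cells,
            provenance={"operation": f"shared_{title_prefix.lower()}"},
        ),
        "unique": ComparisonTable(
            title=f"Unique {title_prefix}",
            row_labels=["Unique count"],
            column_labels=list(order),
            cells=unique_cells,
            provenance={
                "operation": f"unique_{title_prefix.lower()}",
                "union_size": len(everyone),
                "unique_ids": unique,
            },
        ),
    }


def ec_top_level_category(ec: str) -> str:
    head = ec.split(".", 1)[0]
    return head if head in {"1", "2", "3", "4", "5", "6", "7"} else "unclassified"


def reaction_comparison(community: Community) -> dict[str, ComparisonTable]:
    """Reaction tables: breakdown by reaction type, top-level EC category
    counts (classes 1-7 plus unclassified), pairwise shared matrix and
    unique counts.  Reaction sets include pathway-imported reactions."""
    db = community.refdb
    order = _member_ids(community)
    sets = {m.organism_id: m.all_reaction_ids() for m in community}

    type_rows = ["SMALL-MOLECULE", "TRANSPORT", "MACROMOLECULE"]
    type_cells = [
        [
            Cell(sum(1 for rid in sets[oid] if db.reactions[rid].reaction_type == t))
            for oid in order
        ]
        for t in type_rows
    ]
    ec_rows = [str(i) for i in range(1, 8)] + ["unclassified"]

    def ec_counts(rids: set[str]) -> dict[str, int]:
        counts = {r: 0 for r in ec_rows}
        for rid in rids:
            ecs = db.reactions[rid].ec_numbers
            cats = {ec_top_level_category(ec) for ec in ecs} or {"unclassified"}
            for cat in cats:
                counts[cat] += 1
        return counts

    ec_cells = []
    per_member_counts = {oid: ec_counts(sets[oid]) for oid in order}
    for row in ec_rows:
        ec_cells.append([Cell(per_member_counts[oid][row]) for oid in order])

    tables = {
        "by_type": ComparisonTable(
            title="Breakdown of Reactions by Type",
            row_labels=type_rows,
            column_labels=order,
            cells=type_cells,
            provenance={"operation": "reaction_comparison"},
        ),
        "by_ec_category": ComparisonTable(
            title="Breakdown of Reactions by Top-Level EC Category",
            row_labels=ec_rows,
            column_labels=order,
            cells=ec_cells,
            provenance={"operation": "reaction_comparison"},
        ),
    }
    tables.update(_shared_unique_tables("Reactions", sets, order))
    return tables


def pathway_comparison(community: Community) -> dict[str, ComparisonTable]:
    """Pathway tables: ontology-class rollup (each present pathway counted
    once per ancestor class on its class path), pairwise shared matrix,
    unique counts and a pathway-holes summary."""
    db = community.refdb
    order = _member_ids(community)
    sets = {m.organism_id: set(m.present_pathways()) for m in community}

    class_counts: dict[str, dict[str, int]] = {}
    for oid in order:
        for pid in sets[oid]:
            for cls in db.pathways[pid].class_path:
                class_counts.setdefault(cls, {}).setdefault(oid, 0)
                class_counts[cls][oid] += 1
    row_labels = sorted(class_counts)
    rollup_cells = [
        [Cell(class_counts[cls].get(oid, 0), drill_key=cls) for oid in order]
        for cls in row_labels
    ]
    holes_cells = [
        [
            Cell(
                sum(
                    len(call.holes)
                    for call in community.member(oid).pathway_calls.values()
                    if call.present
                )
            )
            for oid in order
        ]
    ]
    tables = {
        "by_class": ComparisonTable(
            title="Breakdown of Pathways by Pathway Class",
            row_labels=row_labels,
            column_labels=order,
            cells=rollup_cells,
            provenance={"operation": "pathway_comparison"},
        ),
        "holes": ComparisonTable(
            title="Pathway Holes",
            row_labels=["Total holes in present pathways"],
            column_labels=order,
            cells=holes_cells,
            provenance={"operation": "pathway_comparison"},
        ),
    }
    tables.update(_shared_unique_tables("Pathways", sets, order))
    return tables


def pathway_class_drill_down(community: Community, class_id: str) -> ComparisonTable:
    """Per-pathway presence rows for one ontology class.

    Rows are every reference pathway under the class (so members lacking a
    pathway get an explicit empty cell — absence is displayed, not
    omitted); a cell shows '+' when the member's pathway call is present.
    """
    db = community.refdb
    if class_id not in db.ontology.classes:
        raise ValidationError(f"unknown ontology class {class_id!r}")
    order = _member_ids(community)
    pathway_ids = sorted(
        pid for pid, pwy in db.pathways.items() if class_id in pwy.class_path
    )
    cells = []
    for pid in pathway_ids:
        cells.append(
            [
                Cell("+" if pid in community.member(oid).present_pathways() else None)
                for oid in order
            ]
        )
    return ComparisonTable(
        title=f"Pathways of class {db.ontology.classes[class_id][0]}",
        row_labels=[db.pathways[pid].name for pid in pathway_ids],
        column_labels=order,
        cells=cells,
        provenance={"operation": "pathway_class_drill_down", "class": class_id},
    )


def compound_comparison(
    community: Community, exclude_currency: bool = False
) -> dict[str, ComparisonTable]:
    """Compound tables: per-member counts, shared/unique matrices and a
    role-frequency table (reactant / product / transported-substrate
    occurrences per compound across the whole community)."""
    db = community.refdb
    order = _member_ids(community)
    sets = {
        m.organism_id: {
            c
            for c in organism_compounds(m, community)
            if not (exclude_currency and c in db.currency_ids)
        }
        for m in community
    }
    count_cells = [[Cell(len(sets[oid])) for oid in order]]
    tables = {
        "all": ComparisonTable(
            title="All Compounds",
            row_labels=["Compound count"],
            column_labels=order,
            cells=count_cells,
            provenance={"operation": "compound_comparison"},
        ),
    }
    tables.update(_shared_unique_tables("Compounds", sets, order))

    union = sorted({c for s in sets.values() for c in s})
    union_reactions = set()
    for m in community:
        union_reactions |= m.all_reaction_ids()
    roles = {c: {"reactant": 0, "product": 0, "transported": 0} for c in union}
    for rid in sorted(union_reactions):
        rxn = db.reactions[rid]
        reversible = rxn.direction == "REVERSIBLE"
        for cid, _ in rxn.reactant_slots:
            if cid in roles:
                roles[cid]["reactant"] += 1
                if reversible:
                    roles[cid]["product"] += 1
        for cid, _ in rxn.product_slots:
            if cid in roles:
                roles[cid]["product"] += 1
                if reversible:
                    roles[cid]["reactant"] += 1
        if rxn.reaction_type == "TRANSPORT":
            for cid in rxn.transported_compounds():
                if cid in roles:
                    roles[cid]["transported"] += 1
    for m in community:
        for rec in m.transport_records:
            if rec.compound_id in roles:
                roles[rec.compound_id]["transported"] += 1
    role_cols = ["reactant", "product", "transported"]
    tables["roles"] = ComparisonTable(
        title="Compound Metabolic Role Frequencies",
        row_labels=union,
        column_labels=role_cols,
        cells=[[Cell(roles[c][r]) for r in role_cols] for c in union],
        provenance={"operation": "compound_comparison"},
    )
    return tables


def transporter_comparison(community: Community) -> dict[str, ComparisonTable]:
    """Transporter tables: per-member record counts, substrate uptake and
    efflux matrices, and substrates served by multiple transporter genes."""
    order = _member_ids(community)
    count_cells = [[Cell(len(community.member(oid).transport_records)) for oid in order]]

    def substrate_label(rec) -> str:
        if rec.compound_id is not None:
            return community.refdb.compounds[rec.compound_id].name
        return rec.substrate_text + " (unresolved)"

    def direction_table(direction: str, title: str) -> ComparisonTable:
        per_member: dict[str, dict[str, int]] = {oid: {} for oid in order}
        labels = set()
        for oid in order:
            for rec in community.member(oid).transport_records:
                if rec.direction != direction:
                    continue
                label = substrate_label(rec)
                labels.add(label)
                per_member[oid][label] = per_member[oid].get(label, 0) + 1
        rows = sorted(labels)
        cells = [
            [Cell(per_member[oid].get(label) or None) for oid in order] for label in rows
        ]
        return ComparisonTable(
            title=title,
            row_labels=rows,
            column_labels=order,
            cells=cells,
            provenance={"operation": "transporter_comparison"},
        )

    multi_rows = []
    multi_cells = []
    for oid in order:
        counts: dict[str, int] = {}
        for rec in community.member(oid).transport_records:
            label = substrate_label(rec)
            counts[label] = counts.get(label, 0) + 1
        multi_rows.append(
            {label: n for label, n in counts.items() if n > 1}
        )
    all_multi = sorted({label for d in multi_rows for label in d})
    multi_cells = [
        [Cell(multi_rows[j].get(label) or None) for j in range(len(order))]
        for label in all_multi
    ]
    return {
        "counts": ComparisonTable(
            title="Transporters",
            row_labels=["Transport records"],
            column_labels=order,
            cells=count_cells,
            provenance={"operation": "transporter_comparison"},
        ),
        "uptake": direction_table("uptake", "Substrate Uptake"),
        "efflux": direction_table("efflux", "Substrate Efflux"),
        "multiple": ComparisonTable(
            title="Substrates with Multiple Transporters",
            row_labels=all_multi,
            column_labels=order,
            cells=multi_cells,
            provenance={"operation": "transporter_comparison"},
        ),
    }


def transcription_unit_comparison(community: Community) -> ComparisonTable:
    """Distribution of genes per transcription unit, members as columns."""
    order = _member_ids(community)
    hists = {
        oid: {} for oid in order
    }
    sizes = set()
    for oid in order:
        for op in community.member(oid).operons:
            hists[oid][len(op)] = hists[oid].get(len(op), 0) + 1
            sizes.add(len(op))
    rows = sorted(sizes)
    cells = [[Cell(hists[oid].get(n, 0)) for oid in order] for n in rows]
    return ComparisonTable(
        title="Number of Genes per Transcription Unit",
        row_labels=[str(n) for n in rows],
        column_labels=order,
        cells=cells,
        provenance={"operation": "transcription_unit_comparison"},
    )


def all_comparisons(community: Community) -> dict[str, ComparisonTable]:
    """Every comparison table under namespaced keys, for bulk export."""
    out: dict[str, ComparisonTable] = {"summary": db_summary_stats(community)}
    for key, tbl in reaction_comparison(community).items():
        out[f"reactions_{key}"] = tbl
    for key, tbl in pathway_comparison(community).items():
        out[f"pathways_{key}"] = tbl
    for key, tbl in compound_comparison(community).items():
        out[f"compounds_{key}"] = tbl
    for key, tbl in transporter_comparison(community).items():
        out[f"transporters_{key}"] = tbl
    out["transcription_units"] = transcription_unit_comparison(community)
    return out
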