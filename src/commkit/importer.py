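"""Build per-organism databases from annotated MAG files.

Each metagenome-assembled genome arrives as a GenBank file or a GFF3+FASTA
pair whose CDS features already carry product names and (optionally) EC
numbers — ORF calling and function prediction happen upstream.  The import
pipeline mirrors the classic reconstruction sequence:

1. parse the annotation into genes on replicons,
2. predict the reactome by resolving EC numbers and enzyme names against
   the reference database,
3. infer transport reactions from transporter-style product names,
4. predict operons with a strand/intergenic-distance heuristic.

The result is an :class:`OrganismDB` — a lightweight pathway/genome
database for one community member — and a :class:`Community` groups the
members over one shared :class:`~commkit.refdb.ReferenceDB`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import IntegrityError, ParseError
from .refdb import ReferenceDB, normalize_name

logger = logging.getLogger(__name__)

DEFAULT_OPERON_MAX_GAP = 50  # bp of intergenic distance tolerated within an operon


@dataclass
class Gene:
    id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    product_name: str = ""
    ec_numbers: set[str] = field(default_factory=set)
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.start > self.end:
            raise ParseError(f"gene {self.id!r}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ParseError(f"gene {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "replicon_id": self.replicon_id,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "product_name": self.product_name,
            "ec_numbers": sorted(self.ec_numbers),
            "go_terms": sorted(self.go_terms),
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "Gene":
        return cls(
            id=rec["id"],
            replicon_id=rec["replicon_id"],
            start=rec["start"],
            end=rec["end"],
            strand=rec["strand"],
            product_name=rec.get("product_name", ""),
            ec_numbers=set(rec.get("ec_numbers", [])),
            go_terms=set(rec.get("go_terms", [])),
        )


@dataclass
class TransportRecord:
    """One inferred transport capability: a gene whose product name looks
    like a transporter, with the substrate resolved against compound names
    where possible."""

    gene_id: str
    substrate_text: str
    direction: str  # uptake | efflux | unknown
    compound_id: str | None = None

    @property
    def resolved(self) -> bool:
        return self.compound_id is not None

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "substrate_text": self.substrate_text,
            "direction": self.direction,
            "compound_id": self.compound_id,
        }


#: Transporter-name pattern table.  Each entry is (compiled regex with a
#: ``substrate`` group, direction).  Order matters: first match wins.
DEFAULT_TRANSPORT_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(r"^(?P<substrate>.+?)\s+uptake\s+(?:system|protein)$", re.I), "uptake"),
    (re.compile(r"^(?P<substrate>.+?)\s+efflux\s+(?:system|protein)$", re.I), "efflux"),
    (re.compile(r"^(?P<substrate>.+?)\s+ABC\s+transporter$", re.I), "unknown"),
    (re.compile(r"^(?P<substrate>.+?)\s+transporter$", re.I), "unknown"),
    (re.compile(r"^(?P<substrate>.+?)\s+permease$", re.I), "uptake"),
]


@dataclass
class OrganismDB:
    """Pathway/genome database for one community member."""

    organism_id: str
    name: str = ""
    taxon_lineage: list[str] = field(default_factory=list)
    replicons: dict[str, int] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    #: enzyme-evidenced reactome: reaction id -> evidence gene ids
    reactome: dict[str, set[str]] = field(default_factory=dict)
    #: reactions imported because a predicted-present pathway contains them
    pathway_imported: set[str] = field(default_factory=set)
    #: pathway id -> PathwayCall (populated by pathway prediction)
    pathway_calls: dict = field(default_factory=dict)
    transport_records: list[TransportRecord] = field(default_factory=list)
    operons: list[list[str]] = field(default_factory=list)
    build_report: dict = field(default_factory=dict)

    def all_reaction_ids(self) -> set[str]:
        """Enzyme-evidenced plus pathway-imported reactions."""
        return set(self.reactome) | set(self.pathway_imported)

    def present_pathways(self) -> set[str]:
        return {pid for pid, call in self.pathway_calls.items() if call.present}

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "organism_id": self.organism_id,
            "name": self.name,
            "taxon_lineage": list(self.taxon_lineage),
            "replicons": dict(sorted(self.replicons.items())),
            "genes": [g.to_dict() for _, g in sorted(self.genes.items())],
            "reactome": {rid: sorted(gs) for rid, gs in sorted(self.reactome.items())},
            "pathway_imported": sorted(self.pathway_imported),
            "pathway_calls": [c.to_dict() for _, c in sorted(self.pathway_calls.items())],
            "transport_records": [t.to_dict() for t in self.transport_records],
            "operons": [list(op) for op in self.operons],
            "build_report": self.build_report,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "OrganismDB":
        from .pathway_prediction import PathwayCall  # local import avoids a cycle

        org = cls(
            organism_id=doc["organism_id"],
            name=doc.get("name", ""),
            taxon_lineage=list(doc.get("taxon_lineage", [])),
            replicons=dict(doc.get("replicons", {})),
            genes={g["id"]: Gene.from_dict(g) for g in doc.get("genes", [])},
            reactome={rid: set(gs) for rid, gs in doc.get("reactome", {}).items()},
            pathway_imported=set(doc.get("pathway_imported", [])),
            transport_records=[
                TransportRecord(**t) for t in doc.get("transport_records", [])
            ],
            operons=[list(op) for op in doc.get("operons", [])],
            build_report=doc.get("build_report", {}),
        )
        org.pathway_calls = {
            c["pathway_id"]: PathwayCall.from_dict(c) for c in doc.get("pathway_calls", [])
        }
        return org

    @classmethod
    def load(cls, path: str | Path) -> "OrganismDB":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Community:
    """Ordered collection of organisms sharing one reference database."""

    members: list[OrganismDB]
    refdb: ReferenceDB

    def __post_init__(self):
        ids = [m.organism_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"duplicate organism ids in community: {ids}")

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    def member(self, organism_id: str) -> OrganismDB:
        for m in self.members:
            if m.organism_id == organism_id:
                return m
        raise KeyError(organism_id)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        order = []
        for m in self.members:
            m.save(directory / f"{m.organism_id}.json")
            order.append(m.organism_id)
        (directory / "community.json").write_text(
            json.dumps({"members": order}, indent=1) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path, refdb: ReferenceDB) -> "Community":
        directory = Path(directory)
        manifest = json.loads((directory / "community.json").read_text())
        members = [OrganismDB.load(directory / f"{oid}.json") for oid in manifest["members"]]
        return cls(members=members, refdb=refdb)


# ---------------------------------------------------------------------------
# parsing


def parse_genbank(path: str | Path) -> tuple[dict[str, int], dict[str, Gene]]:
    """Parse a GenBank file into replicon lengths and CDS-derived genes.

    Coordinates are converted to 1-based inclusive; ``complement()``
    locations become strand '-'.  A CDS without /product is retained with an
    empty product name and logged.
    """
    replicons: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise ParseError(f"{path}: unparseable GenBank: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no GenBank records")
    n_anon = 0
    for rec in records:
        replicons[rec.id] = len(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gid = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or quals.get("gene", [None])[0]
            )
            if gid is None:
                n_anon += 1
                gid = f"{rec.id}_cds{n_anon}"
            product = quals.get("product", [""])[0]
            if not product:
                logger.info("CDS %s has no /product; retained with empty name", gid)
            go_terms = {
                x for x in quals.get("db_xref", []) if x.startswith("GO:")
            }
            gene = Gene(
                id=gid,
                replicon_id=rec.id,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                product_name=product,
                ec_numbers=set(quals.get("EC_number", [])),
                go_terms=go_terms,
            )
            if gene.id in genes:
                raise ParseError(f"{path}: duplicate gene id {gene.id!r}")
            genes[gene.id] = gene
    return replicons, genes


def _parse_gff3_attributes(text: str) -> dict[str, list[str]]:
    """Parse a GFF3 column-9 attribute string.

    Tokens without '=' are treated as continuation values of the preceding
    key, which accommodates annotation exports that separate multiple EC
    numbers with ';' inside one ``ec_number`` attribute.  Comma-separated
    multi-values are also split.
    """
    attrs: dict[str, list[str]] = {}
    last_key = None
    for token in text.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" in token:
            key, _, value = token.partition("=")
            last_key = key.strip()
            attrs.setdefault(last_key, []).extend(v for v in value.split(",") if v)
        elif last_key is not None:
            attrs[last_key].extend(v for v in token.split(",") if v)
    return attrs


def parse_gff3(
    gff_path: str | Path, fasta_path: str | Path
) -> tuple[dict[str, int], dict[str, Gene]]:
    """Parse a GFF3 file plus its FASTA into replicon lengths and genes.

    GFF3 coordinates are already 1-based inclusive and are used as-is.
    Product comes from the ``product`` attribute, EC numbers from
    ``ec_number`` (semicolon- or comma-separated), GO terms from
    ``Ontology_term``.
    """
    replicons = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not replicons:
        raise ParseError(f"{fasta_path}: no FASTA records")
    genes: dict[str, Gene] = {}
    n_anon = 0
    for lineno, line in enumerate(Path(gff_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"{gff_path}:{lineno}: expected 9 columns, got {len(cols)}")
        seqid, _source, ftype, start, end, _score, strand, _phase, attr_text = cols
        if ftype != "CDS":
            continue
        if seqid not in replicons:
            raise IntegrityError(
                f"{gff_path}:{lineno}: CDS references absent seqid {seqid!r}"
            )
        attrs = _parse_gff3_attributes(attr_text)
        gid = attrs.get("ID", attrs.get("locus_tag", [None]))[0]
        if gid is None:
            n_anon += 1
            gid = f"{seqid}_cds{n_anon}"
        try:
            gene = Gene(
                id=gid,
                replicon_id=seqid,
                start=int(start),
                end=int(end),
                strand=strand,
                product_name=attrs.get("product", [""])[0],
                ec_numbers=set(attrs.get("ec_number", [])),
                go_terms=set(attrs.get("Ontology_term", [])),
            )
        except ValueError as exc:
            raise ParseError(f"{gff_path}:{lineno}: {exc}") from exc
        if gene.id in genes:
            raise ParseError(f"{gff_path}:{lineno}: duplicate gene id {gene.id!r}")
        genes[gene.id] = gene
    return replicons, genes


# ---------------------------------------------------------------------------
# inference steps


def predict_reactome(
    genes: dict[str, Gene], db: ReferenceDB
) -> tuple[dict[str, set[str]], dict]:
    """Predict the enzyme-evidenced reactome from gene annotations.

    Each gene contributes the union of the reactions matched by its EC
    numbers and by its normalized product name; evidence gene ids accumulate
    per reaction.  EC and name evidence are never arbitrated — both count.
    Returns (reactome, report) where the report records match statistics,
    including enzyme names that mapped to more than one reaction.
    """
    reactome: dict[str, set[str]] = {}
    multi_mapped_names: dict[str, int] = {}
    n_matched_genes = 0
    for gid in sorted(genes):
        gene = genes[gid]
        hits: set[str] = set()
        for ec in sorted(gene.ec_numbers):
            try:
                hits |= db.ec_lookup(ec)
            except Exception:
                logger.warning("gene %s: skipping malformed EC %r", gid, ec)
        if gene.product_name:
            name_hits = db.name_lookup(gene.product_name)
            if len(name_hits) > 1:
                multi_mapped_names[normalize_name(gene.product_name)] = len(name_hits)
            hits |= name_hits
        if hits:
            n_matched_genes += 1
        for rid in hits:
            reactome.setdefault(rid, set()).add(gid)
    report = {
        "n_genes": len(genes),
        "n_genes_with_reaction": n_matched_genes,
        "n_reactions": len(reactome),
        "multi_mapped_names": multi_mapped_names,
    }
    return reactome, report


def infer_transport(
    genes: dict[str, Gene],
    db: ReferenceDB,
    patterns: list[tuple[re.Pattern, str]] | None = None,
) -> list[TransportRecord]:
    """Infer transport capabilities from transporter-style product names.

    The substrate captured by the first matching pattern is resolved against
    compound names; unresolvable substrates are kept with
    ``compound_id=None`` and logged.
    """
    patterns = DEFAULT_TRANSPORT_PATTERNS if patterns is None else patterns
    records: list[TransportRecord] = []
    for gid in sorted(genes):
        gene = genes[gid]
        if not gene.product_name:
            continue
        for pattern, direction in patterns:
            m = pattern.match(gene.product_name.strip())
            if not m:
                continue
            substrate = m.group("substrate").strip()
            cid = db.compound_by_name(substrate)
            if cid is None:
                logger.info(
                    "gene %s: transporter substrate %r not resolvable", gid, substrate
                )
            records.append(
                TransportRecord(
                    gene_id=gid,
                    substrate_text=substrate,
                    direction=direction,
                    compound_id=cid,
                )
            )
            break
    return records


def predict_operons(
    genes: dict[str, Gene],
    max_gap: int = DEFAULT_OPERON_MAX_GAP,
    same_strand: bool = True,
) -> list[list[str]]:
    """Group genes into transcription units by strand and intergenic gap.

    Genes are coordinate-sorted per replicon; consecutive genes join one
    unit when they share a strand (if ``same_strand``) and the intergenic
    gap ``next.start - prev.end - 1`` is at most ``max_gap``.  Singletons
    become single-gene units.  The result is independent of input order.
    """
    operons: list[list[str]] = []
    by_replicon: dict[str, list[Gene]] = {}
    for gene in genes.values():
        by_replicon.setdefault(gene.replicon_id, []).append(gene)
    for replicon_id in sorted(by_replicon):
        ordered = sorted(by_replicon[replicon_id], key=lambda g: (g.start, g.end, g.id))
        current: list[Gene] = []
        for gene in ordered:
            if not current:
                current = [gene]
                continue
            prev = current[-1]
            gap = gene.start - prev.end - 1
            if (not same_strand or gene.strand == prev.strand) and gap <= max_gap:
                current.append(gene)
            else:
                operons.append([g.id for g in current])
                current = [gene]
        if current:
            operons.append([g.id for g in current])
    return operons


# ---------------------------------------------------------------------------
# orchestration


def build_organism_db(
    db: ReferenceDB,
    organism_id: str,
    genbank_path: str | Path | None = None,
    gff_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    name: str = "",
    taxon_lineage: list[str] | None = None,
    operon_max_gap: int = DEFAULT_OPERON_MAX_GAP,
    transport_patterns: list[tuple[re.Pattern, str]] | None = None,
) -> OrganismDB:
    """Run the full import pipeline for one MAG.

    Exactly one of ``genbank_path`` or (``gff_path``, ``fasta_path``) must
    be given.  Pathway calls are left empty for the pathway-prediction
    stage.  A build report with per-step counts is attached.
    """
    if genbank_path is not None:
        replicons, genes = parse_genbank(genbank_path)
    elif gff_path is not None and fasta_path is not None:
        replicons, genes = parse_gff3(gff_path, fasta_path)
    else:
        raise ParseError("need a GenBank path or a GFF3+FASTA pair")
    reactome, reactome_report = predict_reactome(genes, db)
    transport = infer_transport(genes, db, patterns=transport_patterns)
    operons = predict_operons(genes, max_gap=operon_max_gap)
    report = {
        "n_replicons": len(replicons),
        "n_genes": len(genes),
        "reactome": reactome_report,
        "n_transport_records": len(transport),
        "n_transport_unresolved": sum(1 for t in transport if not t.resolved),
        "n_transcription_units": len(operons),
    }
    return OrganismDB(
        organism_id=organism_id,
        name=name or organism_id,
        taxon_lineage=list(taxon_lineage or []),
        replicons=replicons,
        genes=genes,
        reactome=reactome,
        transport_records=transport,
        operons=operons,
        build_report=report,
    )
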