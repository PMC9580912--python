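"""Omics overlay on a community metabolic overview.

Per-organism omics tables (tab-delimited, identifier column plus one
numeric column) are parsed, gene values are attached to reactions through
the enzyme-evidence links, one display value per reaction is chosen by an
aggregation rule, and the whole community is rendered as a static SVG: one
panel per member arranged in a near-square grid, each panel showing its
pathways as glyph columns (biosynthesis on the left, energy metabolism in
the middle, degradation on the right), a grid of pathway-unassigned
reactions on the right, and transport records on the bounding membrane.
Up-regulation paints glyphs orange/red, down-regulation blue/purple,
no-data reactions stay neutral grey.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, ValidationError
from .importer import Community, OrganismDB

logger = logging.getLogger(__name__)

KINDS = ("gene", "metabolite")
SCALES = ("absolute", "ratio", "log-ratio")


@dataclass
class OmicsDataset:
    organism_id: str
    kind: str = "gene"
    scale: str = "log-ratio"
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"bad omics kind {self.kind!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"bad omics scale {self.scale!r}")
        for ident, v in self.values.items():
            if not ident:
                raise ValidationError("empty identifier in omics dataset")
            if not math.isfinite(v):
                raise ValidationError(f"non-finite value for {ident!r}")


#: display color classes, most-down to most-up
COLOR_CLASSES = ("purple", "blue", "neutral", "orange", "red")

COLOR_HEX = {
    "purple": "#9467bd",
    "blue": "#1f77b4",
    "neutral": "#c8c8c8",
    "orange": "#ff7f0e",
    "red": "#d62728",
}


@dataclass
class OverlaySpec:
    """Binning and aggregation specification.

    ``thresholds`` are the strictly increasing bin edges separating the
    five color classes (purple | blue | neutral | orange | red) on the
    log2-ratio scale.  ``aggregation`` chooses the per-reaction display
    value when several genes map to one reaction.
    """

    thresholds: tuple[float, float, float, float] = (-2.0, -0.5, 0.5, 2.0)
    aggregation: str = "max-magnitude"
    double_membrane: bool = False

    def __post_init__(self):
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValidationError("thresholds must be strictly increasing")
        if self.aggregation not in ("max-magnitude", "mean", "median"):
            raise ValidationError(f"unknown aggregation rule {self.aggregation!r}")

    def color_class(self, value: float | None) -> str:
        if value is None:
            return "neutral"
        lo2, lo1, hi1, hi2 = self.thresholds
        if value <= lo2:
            return "purple"
        if value <= lo1:
            return "blue"
        if value < hi1:
            return "neutral"
        if value < hi2:
            return "orange"
        return "red"


def parse_omics_file(path: str | Path, organism_id: str, kind: str = "gene",
                     scale: str = "log-ratio") -> OmicsDataset:
    """Parse a tab-delimited omics file.

    Column 1 is the identifier, column 2 the value; further columns are
    ignored.  A header row is auto-detected (non-numeric column 2 in the
    first row).  Rows with non-numeric values are skipped and counted; a
    duplicate identifier keeps the last value.  A file with no parseable
    rows is an error.
    """
    values: dict[str, float] = {}
    n_skipped = 0
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            n_skipped += 1
            continue
        ident, raw = cols[0].strip(), cols[1].strip()
        try:
            value = float(raw)
        except ValueError:
            if i == 0:
                continue  # header row
            n_skipped += 1
            continue
        if not math.isfinite(value):
            n_skipped += 1
            continue
        if ident in values:
            logger.warning("%s: duplicate identifier %r, keeping last value", path, ident)
        values[ident] = value
    if not values:
        raise InputError(f"{path}: no parseable data rows")
    if n_skipped:
        logger.info("%s: skipped %d non-numeric rows", path, n_skipped)
    return OmicsDataset(organism_id=organism_id, kind=kind, scale=scale, values=values)


def map_to_reactions(
    dataset: OmicsDataset, organism: OrganismDB
) -> tuple[dict[str, list[tuple[str, float]]], list[str]]:
    """Attach gene values to reactions via enzyme-evidence links.

    Returns ``(mapping, unmapped)``: mapping holds *all* values per
    reaction (not just an aggregate); unmapped lists identifiers with no
    evidenced reaction.
    """
    if dataset.kind != "gene":
        raise ValidationError("metabolite datasets map to compounds, not reactions")
    gene_to_reactions: dict[str, list[str]] = {}
    for rid in sorted(organism.reactome):
        for gid in organism.reactome[rid]:
            gene_to_reactions.setdefault(gid, []).append(rid)
    mapping: dict[str, list[tuple[str, float]]] = {}
    unmapped: list[str] = []
    for ident in sorted(dataset.values):
        rids = gene_to_reactions.get(ident)
        if not rids:
            unmapped.append(ident)
            continue
        for rid in rids:
            mapping.setdefault(rid, []).append((ident, dataset.values[ident]))
    return mapping, unmapped


def map_to_compounds(
    dataset: OmicsDataset, organism: OrganismDB, community: Community
) -> tuple[dict[str, float], list[str]]:
    """Resolve metabolite identifiers (compound ids or names) against the
    compounds participating in the organism's reactome."""
    if dataset.kind != "metabolite":
        raise ValidationError("gene datasets map to reactions, not compounds")
    from .comparative import organism_compounds

    db = community.refdb
    present = organism_compounds(organism, community)
    mapping: dict[str, float] = {}
    unmapped: list[str] = []
    for ident in sorted(dataset.values):
        cid = ident if ident in db.compounds else db.compound_by_name(ident)
        if cid is None or cid not in present:
            unmapped.append(ident)
        else:
            mapping[cid] = dataset.values[ident]
    return mapping, unmapped


def reaction_display_value(values: list[float], rule: str = "max-magnitude") -> float:
    """Collapse the values of a reaction's genes to one display value."""
    if not values:
        raise ValidationError("no values to aggregate")
    if rule == "max-magnitude":
        return max(values, key=lambda v: (abs(v), v))
    if rule == "mean":
        return sum(values) / len(values)
    if rule == "median":
        ordered = sorted(values)
        n = len(ordered)
        mid = n // 2
        return ordered[mid] if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2
    raise ValidationError(f"unknown aggregation rule {rule!r}")


def _to_log2_scale(dataset: OmicsDataset) -> dict[str, float]:
    """Convert a dataset to the log2-ratio scale the bin thresholds use.

    ratio values are log2-transformed (non-positive ratios are dropped);
    absolute values are rank-transformed within the organism onto a
    symmetric pseudo log-ratio in [-3, 3] so that within-organism extremes
    land in the extreme bins.
    """
    if dataset.scale == "log-ratio":
        return dict(dataset.values)
    if dataset.scale == "ratio":
        out = {}
        for ident, v in dataset.values.items():
            if v > 0:
                out[ident] = math.log2(v)
            else:
                logger.warning("dropping non-positive ratio for %r", ident)
        return out
    # absolute: quantile ranks mapped linearly onto [-3, 3]
    items = sorted(dataset.values.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if n == 1:
        return {items[0][0]: 0.0}
    return {ident: -3.0 + 6.0 * rank / (n - 1) for rank, (ident, _) in enumerate(items)}


# ---------------------------------------------------------------------------
# layout + rendering


def _ontology_section(community: Community, pathway_id: str) -> int:
    """0 = biosynthesis (left), 1 = energy (middle), 2 = degradation/other
    (right), decided by the top-level ontology branch of the pathway."""
    db = community.refdb
    path = db.pathways[pathway_id].class_path
    top = path[1] if len(path) > 1 else (path[0] if path else "")
    name = db.ontology.classes.get(top, (top, None))[0].lower()
    if "biosynthesis" in name:
        return 0
    if "energy" in name:
        return 1
    return 2


def panel_assignment(member: OrganismDB, community: Community) -> tuple[dict[str, str], list[str]]:
    """Assign every reactome reaction to exactly one pathway column or to
    the non-pathway grid.

    A reaction belonging to several present pathways is drawn under the
    first (sorted by pathway id); full membership stays queryable from the
    pathway calls.  Returns (reaction -> pathway id, unassigned reactions).
    """
    assignment: dict[str, str] = {}
    db = community.refdb
    for pid in sorted(member.present_pathways()):
        for rid in sorted(db.pathways[pid].reaction_ids):
            if rid in member.all_reaction_ids() and rid not in assignment:
                assignment[rid] = pid
    unassigned = sorted(member.all_reaction_ids() - set(assignment))
    return assignment, unassigned


def overlay_table(
    community: Community,
    overlays: dict[str, OmicsDataset],
    spec: OverlaySpec | None = None,
) -> list[dict]:
    """Rows (organism, reaction, display value, color class) for every
    reaction of every member — the testable core of the rendering."""
    spec = spec or OverlaySpec()
    rows = []
    for member in community:
        dataset = overlays.get(member.organism_id)
        per_reaction: dict[str, float] = {}
        if dataset is not None and dataset.kind == "gene":
            scaled = OmicsDataset(
                organism_id=dataset.organism_id,
                kind=dataset.kind,
                scale="log-ratio",
                values=_to_log2_scale(dataset),
            )
            mapping, _ = map_to_reactions(scaled, member)
            per_reaction = {
                rid: reaction_display_value([v for _, v in vals], spec.aggregation)
                for rid, vals in mapping.items()
            }
        for rid in sorted(member.all_reaction_ids()):
            value = per_reaction.get(rid)
            rows.append(
                {
                    "organism": member.organism_id,
                    "reaction": rid,
                    "display_value": value,
                    "color_class": spec.color_class(value),
                }
            )
    return rows


_PANEL_W = 300
_PANEL_H = 200
_GLYPH = 7
_GAP = 3


def _render_panel(
    svg: ET.Element,
    member: OrganismDB,
    community: Community,
    colors: dict[str, str],
    values: dict[str, float | None],
    x0: float,
    y0: float,
    double_membrane: bool,
) -> None:
    g = ET.SubElement(svg, "g", {"data-organism": member.organism_id})
    ET.SubElement(
        g,
        "rect",
        {
            "x": str(x0 + 4),
            "y": str(y0 + 4),
            "width": str(_PANEL_W - 8),
            "height": str(_PANEL_H - 8),
            "fill": "white",
            "stroke": "black",
            "stroke-width": "1.5",
        },
    )
    if double_membrane:
        ET.SubElement(
            g,
            "rect",
            {
                "x": str(x0 + 7),
                "y": str(y0 + 7),
                "width": str(_PANEL_W - 14),
                "height": str(_PANEL_H - 14),
                "fill": "none",
                "stroke": "black",
                "stroke-width": "0.7",
            },
        )
    label = ET.SubElement(
        g,
        "text",
        {"x": str(x0 + 10), "y": str(y0 + 18), "font-size": "10", "font-family": "sans-serif"},
    )
    label.text = member.name or member.organism_id

    assignment, unassigned = panel_assignment(member, community)
    by_pathway: dict[str, list[str]] = {}
    for rid, pid in assignment.items():
        by_pathway.setdefault(pid, []).append(rid)
    # pathway columns partitioned into ontology sections, left to right
    sections: list[list[str]] = [[], [], []]
    for pid in sorted(by_pathway):
        sections[_ontology_section(community, pid)].append(pid)

    pathway_area_w = _PANEL_W * 0.62
    col_x = x0 + 12
    top_y = y0 + 26
    max_rows = int((_PANEL_H - 40) // (_GLYPH + _GAP))
    for section in sections:
        for pid in section:
            glyph_y = top_y
            col = ET.SubElement(g, "g", {"data-pathway": pid})
            for i, rid in enumerate(sorted(by_pathway[pid])):
                if i and i % max_rows == 0:
                    col_x += _GLYPH + _GAP
                    glyph_y = top_y
                _glyph(col, col_x, glyph_y, rid, colors[rid], values.get(rid))
                glyph_y += _GLYPH + _GAP
            col_x += _GLYPH + _GAP
        col_x += 4  # section separator
        if col_x > x0 + pathway_area_w:
            col_x = x0 + pathway_area_w  # overflow guard: columns may overlap
    # non-pathway reaction grid on the right
    grid_x0 = x0 + pathway_area_w + 8
    grid_cols = max(int((_PANEL_W - pathway_area_w - 24) // (_GLYPH + _GAP)), 1)
    grid = ET.SubElement(g, "g", {"data-grid": "non-pathway"})
    for i, rid in enumerate(unassigned):
        gx = grid_x0 + (i % grid_cols) * (_GLYPH + _GAP)
        gy = top_y + (i // grid_cols) * (_GLYPH + _GAP)
        _glyph(grid, gx, gy, rid, colors[rid], values.get(rid))
    # transport records on the membrane border
    n_tr = len(member.transport_records)
    for j, rec in enumerate(member.transport_records):
        tx = x0 + 12 + (j * (_PANEL_W - 30) / max(n_tr, 1))
        t = ET.SubElement(
            g,
            "rect",
            {
                "x": f"{tx:.1f}",
                "y": str(y0 + _PANEL_H - 8),
                "width": "6",
                "height": "6",
                "fill": "#555555",
                "data-transport": rec.substrate_text,
                "data-direction": rec.direction,
            },
        )
        title = ET.SubElement(t, "title")
        title.text = f"{rec.substrate_text} ({rec.direction}) via {rec.gene_id}"


def _glyph(parent: ET.Element, x: float, y: float, rid: str, color_class: str,
           value: float | None) -> None:
    rect = ET.SubElement(
        parent,
        "rect",
        {
            "x": f"{x:.1f}",
            "y": f"{y:.1f}",
            "width": str(_GLYPH),
            "height": str(_GLYPH),
            "fill": COLOR_HEX[color_class],
            "data-reaction": rid,
            "data-color-class": color_class,
        },
    )
    title = ET.SubElement(rect, "title")
    title.text = rid if value is None else f"{rid}: {value:.3g}"


def render_community_overview(
    community: Community,
    overlays: dict[str, OmicsDataset],
    spec: OverlaySpec | None = None,
    out_path: str | Path | None = None,
) -> str:
    """Render the community overview SVG; returns the SVG text.

    One panel per member in a near-square grid.  Every reaction of a
    member's reactome appears exactly once in its panel — in a pathway
    column or in the non-pathway grid — colored by its binned display
    value, neutral when no data maps to it.
    """
    spec = spec or OverlaySpec()
    member_ids = {m.organism_id for m in community}
    for oid in overlays:
        if oid not in member_ids:
            raise ValidationError(f"overlay organism {oid!r} is not a community member")
    rows = overlay_table(community, overlays, spec)
    colors = {(r["organism"], r["reaction"]): r["color_class"] for r in rows}
    values = {(r["organism"], r["reaction"]): r["display_value"] for r in rows}

    n = len(community.members)
    ncols = max(math.ceil(math.sqrt(n)), 1)
    nrows = math.ceil(n / ncols) if n else 1
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": str(ncols * _PANEL_W),
            "height": str(nrows * _PANEL_H),
            "data-aggregation": spec.aggregation,
        },
    )
    for i, member in enumerate(community):
        x0 = (i % ncols) * _PANEL_W
        y0 = (i // ncols) * _PANEL_H
        _render_panel(
            svg,
            member,
            community,
            {rid: colors[(member.organism_id, rid)] for rid in member.all_reaction_ids()},
            {rid: values[(member.organism_id, rid)] for rid in member.all_reaction_ids()},
            x0,
            y0,
            spec.double_membrane,
        )
    text = ET.tostring(svg, encoding="unicode")
    if out_path is not None:
        Path(out_path).write_text(text + "\n")
    return text


def write_overlay_tsv(rows: list[dict], path: str | Path) -> None:
    """TSV companion of the SVG: organism, reaction, display value, color."""
    lines = ["organism\treaction\tdisplay_value\tcolor_class"]
    for r in rows:
        value = "" if r["display_value"] is None else f"{r['display_value']:.6g}"
        lines.append(f"{r['organism']}\t{r['reaction']}\t{value}\t{r['color_class']}")
    Path(path).write_text("\n".join(lines) + "\n")
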