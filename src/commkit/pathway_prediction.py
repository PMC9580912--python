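"""Pathway prediction from a predicted reactome.

Every reference pathway is scored against an organism's enzyme-evidenced
reactome.  The score is the *completion ratio* — the fraction of the
pathway's reactions with enzyme evidence — and a pathway is called present
when the score clears a threshold AND two hard gates pass:

* **key reactions**: reactions diagnostic for the pathway must all have
  enzyme evidence;
* **taxonomic range**: if the pathway is restricted to certain taxa, the
  organism's lineage must intersect that range.

A *baseline mode* disables both gates and tests only the completion ratio,
mimicking module-completion-ratio predictors; it is deliberately prone to
false positives on pathway collections with shared reactions, which the
gates exist to suppress.

Reactions of predicted-present pathways are merged into the organism as
*pathway-imported* reactions, kept distinct from enzyme-evidenced ones so
that downstream statistics can separate the two evidence classes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UsageError, ValidationError
from .importer import OrganismDB
from .refdb import Pathway, ReferenceDB


@dataclass
class PredictorParams:
    threshold: float = 0.5
    require_key_reactions: bool = True
    enforce_taxonomic_range: bool = True
    baseline_mode: bool = False

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError(f"threshold must be in [0,1], got {self.threshold}")


@dataclass
class PathwayCall:
    pathway_id: str
    score: float
    present: bool
    reasons: list[str] = field(default_factory=list)
    holes: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "score": self.score,
            "present": self.present,
            "reasons": list(self.reasons),
            "holes": sorted(self.holes),
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "PathwayCall":
        return cls(
            pathway_id=rec["pathway_id"],
            score=rec["score"],
            present=rec["present"],
            reasons=list(rec.get("reasons", [])),
            holes=set(rec.get("holes", [])),
        )


def completion_ratio(pathway: Pathway, reactome: set[str] | dict) -> float:
    """Fraction of the pathway's reactions present in the reactome."""
    if not pathway.reaction_ids:
        raise UsageError(f"pathway {pathway.id!r} has no reactions")
    present = pathway.reaction_ids & set(reactome)
    return len(present) / len(pathway.reaction_ids)


def score_pathway(
    pathway: Pathway, organism: OrganismDB, params: PredictorParams | None = None
) -> PathwayCall:
    """Score one pathway against one organism's enzyme-evidenced reactome.

    Superpathways are scored on their flat reaction set like any other
    pathway; they inherit no evidence from contained base pathways.
    """
    params = params or PredictorParams()
    reactome = set(organism.reactome)
    score = completion_ratio(pathway, reactome)
    holes = set(pathway.reaction_ids) - reactome
    reasons = [f"completion={score:.4g}"]

    present = score >= params.threshold
    if not present:
        reasons.append(f"below threshold {params.threshold}")
    if not params.baseline_mode:
        if params.require_key_reactions:
            missing_keys = sorted(pathway.key_reaction_ids - reactome)
            if missing_keys:
                present = False
                reasons.append("missing key reactions: " + ",".join(missing_keys))
            else:
                reasons.append("key reactions present")
        if params.enforce_taxonomic_range and pathway.taxonomic_range:
            if set(organism.taxon_lineage) & pathway.taxonomic_range:
                reasons.append("taxonomic range: in range")
            else:
                present = False
                reasons.append("taxonomic range: organism lineage outside range")
    else:
        reasons.append("baseline mode: completion ratio only")
    return PathwayCall(
        pathway_id=pathway.id, score=score, present=present, reasons=reasons, holes=holes
    )


def predict_pathways(
    organism: OrganismDB, db: ReferenceDB, params: PredictorParams | None = None
) -> OrganismDB:
    """Populate pathway calls and merge present pathways' reactions.

    A call is recorded for every pathway with score > 0.  Reactions of
    present pathways that lack enzyme evidence are added to the organism's
    ``pathway_imported`` set (flagged, never mixed into the enzyme-evidenced
    reactome).  Returns the same organism, updated in place.
    """
    params = params or PredictorParams()
    organism.pathway_calls = {}
    organism.pathway_imported = set()
    for pid in sorted(db.pathways):
        pathway = db.pathways[pid]
        if not pathway.reaction_ids:
            continue
        call = score_pathway(pathway, organism, params)
        if call.score > 0:
            organism.pathway_calls[pid] = call
        if call.present:
            organism.pathway_imported |= set(pathway.reaction_ids) - set(organism.reactome)
    return organism


def pathway_holes(organism: OrganismDB) -> list[tuple[str, list[str]]]:
    """Rows (pathway id, missing reaction ids) for present pathways with
    at least one reaction lacking enzyme evidence."""
    rows = []
    for pid in sorted(organism.pathway_calls):
        call = organism.pathway_calls[pid]
        if call.present and call.holes:
            rows.append((pid, sorted(call.holes)))
    return rows


def export_calls_tsv(organism: OrganismDB, db: ReferenceDB, path: str | Path) -> None:
    """Write pathway calls as TSV: pathway, score, present, missing keys, holes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pathway_id", "name", "score", "present", "missing_keys", "holes"])
        for pid in sorted(organism.pathway_calls):
            call = organism.pathway_calls[pid]
            pwy = db.pathways[pid]
            missing_keys = sorted(pwy.key_reaction_ids - set(organism.reactome))
            writer.writerow(
                [
                    pid,
                    pwy.name,
                    f"{call.score:.4f}",
                    "yes" if call.present else "no",
                    ",".join(missing_keys),
                    ",".join(sorted(call.holes)),
                ]
            )
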