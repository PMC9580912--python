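"""Comparative searches and tables: set algebra, rollups, drill-downs."""

import itertools

import pytest

from commkit.comparative import (
    all_comparisons,
    compound_comparison,
    db_summary_stats,
    ec_top_level_category,
    organism_compounds,
    pathway_class_drill_down,
    pathway_comparison,
    reaction_comparison,
    search_compounds,
    search_genes_proteins,
    search_pathways,
    transcription_unit_comparison,
    transporter_comparison,
)
from commkit.errors import ValidationError


def member_sets(community, attr="reactions"):
    if attr == "reactions":
        return {m.organism_id: m.all_reaction_ids() for m in community}
    if attr == "pathways":
        return {m.organism_id: set(m.present_pathways()) for m in community}
    return {m.organism_id: organism_compounds(m, community) for m in community}


class TestSearches:
    def test_every_member_reported_even_with_zero_hits(self, community):
        hits = search_pathways(community, {"name_substring": "no-such-pathway"})
        assert sorted(hits) == sorted(m.organism_id for m in community)
        assert all(v == [] for v in hits.values())

    def test_empty_substring_returns_all_present_pathways(self, community):
        hits = search_pathways(community, {"name_substring": ""})
        for member in community:
            assert set(hits[member.organism_id]) == member.present_pathways()

    def test_unknown_substrate_is_validation_error(self, community):
        with pytest.raises(ValidationError):
            search_pathways(community, {"substrate_id": "NOPE"})

    def test_ontology_class_filter(self, community):
        hits = search_pathways(community, {"ontology_class": "Biosynthesis"})
        db = community.refdb
        for member in community:
            expected = {
                pid
                for pid in member.present_pathways()
                if "Biosynthesis" in db.pathways[pid].class_path
            }
            assert set(hits[member.organism_id]) == expected

    def test_gene_search_substring_semantics(self, community):
        hits = search_genes_proteins(community, {"name_substring": "permease"})
        for member in community:
            expected = {
                gid
                for gid, g in member.genes.items()
                if "permease" in g.product_name.lower()
            }
            assert set(hits[member.organism_id]) == expected

    def test_gene_search_unbounded_length_returns_all(self, community):
        hits = search_genes_proteins(community, {"min_length": 0})
        for member in community:
            assert set(hits[member.organism_id]) == set(member.genes)

    def test_compound_exact_formula_match(self, community):
        db = community.refdb
        target = sorted(organism_compounds(community.members[0], community))[0]
        formula = db.compounds[target].formula
        hits = search_compounds(community, {"formula": formula})
        assert target in hits[community.members[0].organism_id]
        for oid, found in hits.items():
            for cid in found:
                assert dict(db.compounds[cid].formula) == dict(formula)

    def test_zero_width_mass_window_is_exact(self, community):
        db = community.refdb
        target = sorted(organism_compounds(community.members[0], community))[0]
        mass = db.compounds[target].monoisotopic_mass
        hits = search_compounds(community, {"mass_window": (mass, 0.0)})
        found = hits[community.members[0].organism_id]
        assert target in found
        assert all(db.compounds[c].monoisotopic_mass == mass for c in found)

    def test_compound_membership_means_reactome_participation(self, community):
        member = community.members[0]
        compounds = organism_compounds(member, community)
        db = community.refdb
        participants = set()
        for rid in member.all_reaction_ids():
            participants |= db.reactions[rid].compound_ids()
        assert compounds == participants


class TestSummaryStats:
    def test_counts_match_ground_truth(self, community, truth):
        table = db_summary_stats(community)
        for member in community:
            t = truth["organisms"][member.organism_id]
            col = member.organism_id
            assert table.cell("Genes", col).value == len(member.genes)
            assert table.cell("Transcription units", col).value == len(t["operons"])
            assert table.cell("Transport records", col).value == len(t["transporters"])
            assert table.cell("Pathways (present)", col).value == len(t["pathways"])

    def test_adding_a_member_adds_one_column(self, community):
        import copy

        before = db_summary_stats(community)
        extra = copy.deepcopy(community.members[0])
        extra.organism_id = "org99"
        community.members.append(extra)
        after = db_summary_stats(community)
        assert len(after.column_labels) == len(before.column_labels) + 1


def check_inclusion_exclusion(sets, unique_table):
    """Sum of unique counts + multi-member elements (once) == union size."""
    union = set().union(*sets.values())
    counts = {
        x: sum(1 for s in sets.values() if x in s) for x in union
    }
    brute_unique = {oid: sum(1 for x in sets[oid] if counts[x] == 1) for oid in sets}
    multi = sum(1 for x in union if counts[x] >= 2)
    for i, oid in enumerate(unique_table.column_labels):
        assert unique_table.cells[0][i].value == brute_unique[oid]
    assert sum(brute_unique.values()) + multi == len(union)


class TestSetAlgebra:
    @pytest.mark.parametrize("which", ["reactions", "pathways", "compounds"])
    def test_shared_matrix_symmetric_with_set_size_diagonal(self, community, which):
        tables = {
            "reactions": reaction_comparison,
            "pathways": pathway_comparison,
            "compounds": compound_comparison,
        }[which](community)
        shared = tables["shared"]
        sets = member_sets(community, which)
        n = len(shared.row_labels)
        for i, j in itertools.product(range(n), repeat=2):
            assert shared.cells[i][j].value == shared.cells[j][i].value
            if i == j:
                assert shared.cells[i][i].value == len(sets[shared.row_labels[i]])
            # brute-force intersection
            a, b = shared.row_labels[i], shared.column_labels[j]
            assert shared.cells[i][j].value == len(sets[a] & sets[b])

    @pytest.mark.parametrize("which", ["reactions", "pathways", "compounds"])
    def test_unique_counts_satisfy_inclusion_exclusion(self, community, which):
        tables = {
            "reactions": reaction_comparison,
            "pathways": pathway_comparison,
            "compounds": compound_comparison,
        }[which](community)
        check_inclusion_exclusion(member_sets(community, which), tables["unique"])

    def test_identical_members_share_everything(self, community):
        import copy

        twin = copy.deepcopy(community.members[0])
        twin.organism_id = "twin"
        community.members = [community.members[0], twin]
        tables = reaction_comparison(community)
        size = len(community.members[0].all_reaction_ids())
        assert tables["shared"].cells[0][1].value == size
        assert tables["unique"].cells[0][0].value == 0
        assert tables["unique"].cells[0][1].value == 0


class TestReactionBreakdowns:
    def test_ec_categories_cover_1_to_7_plus_unclassified(self, community):
        table = reaction_comparison(community)["by_ec_category"]
        assert table.row_labels == [str(i) for i in range(1, 8)] + ["unclassified"]

    @pytest.mark.parametrize(
        "ec,category", [("1.1.1.1", "1"), ("7.2.2.8", "7"), ("9.9.9.9", "unclassified")]
    )
    def test_top_level_category_assignment(self, ec, category):
        assert ec_top_level_category(ec) == category

    def test_type_breakdown_counts_total_to_reactome(self, community):
        table = reaction_comparison(community)["by_type"]
        for j, member in enumerate(community):
            total = sum(table.cells[i][j].value for i in range(len(table.row_labels)))
            assert total == len(member.all_reaction_ids())


class TestPathwayRollup:
    def test_class_path_increments_every_ancestor(self, community):
        db = community.refdb
        table = pathway_comparison(community)["by_class"]
        member = community.members[0]
        col = table.column_labels.index(member.organism_id)
        for cls in table.row_labels:
            expected = sum(
                1
                for pid in member.present_pathways()
                if cls in db.pathways[pid].class_path
            )
            assert table.cell(cls, member.organism_id).value == expected

    def test_parent_rows_are_supersets_of_child_rows(self, community):
        db = community.refdb
        table = pathway_comparison(community)["by_class"]
        for cls in table.row_labels:
            parent = db.ontology.classes[cls][1]
            if parent is None or parent not in table.row_labels:
                continue
            for j in range(len(table.column_labels)):
                assert (
                    table.cell(parent, table.column_labels[j]).value
                    >= table.cell(cls, table.column_labels[j]).value
                )

    def test_drill_down_keys_resolve_to_finer_table(self, community):
        table = pathway_comparison(community)["by_class"]
        for row in table.cells:
            for cell in row:
                if cell.drill_key is not None:
                    finer = pathway_class_drill_down(community, cell.drill_key)
                    assert finer.column_labels == table.column_labels

    def test_drill_down_shows_explicit_absence_cells(self, community):
        finer = pathway_class_drill_down(community, "Biosynthesis")
        db = community.refdb
        for i, pid in enumerate(
            sorted(p for p, pwy in db.pathways.items() if "Biosynthesis" in pwy.class_path)
        ):
            for j, oid in enumerate(finer.column_labels):
                present = pid in community.member(oid).present_pathways()
                assert (finer.cells[i][j].value == "+") == present


class TestCompoundRoles:
    def test_currency_exclusion_drops_currency_rows(self, community):
        with_cur = compound_comparison(community, exclude_currency=False)
        without = compound_comparison(community, exclude_currency=True)
        union_with = set(with_cur["roles"].row_labels)
        union_without = set(without["roles"].row_labels)
        dropped = union_with - union_without
        assert dropped == union_with & community.refdb.currency_ids

    def test_reversible_reaction_counts_compound_on_both_sides(self, community):
        db = community.refdb
        rev = [r for r in db.reactions.values() if r.direction == "REVERSIBLE"]
        assert rev, "synthetic DB should contain reversible reactions"
        table = compound_comparison(community)["roles"]
        rxn = next(
            r
            for r in rev
            if r.id in set().union(*(m.all_reaction_ids() for m in community))
        )
        sub = rxn.reactant_slots[0][0]
        if sub in table.row_labels:
            i = table.row_labels.index(sub)
            assert table.cells[i][0].value >= 1  # reactant
            assert table.cells[i][1].value >= 1  # also product


class TestTransporters:
    def test_uptake_table_matches_truth(self, community, truth):
        table = transporter_comparison(community)["uptake"]
        db = community.refdb
        for j, oid in enumerate(table.column_labels):
            expected = {
                db.compounds[t["compound_id"]].name
                for t in truth["organisms"][oid]["transporters"]
                if t["direction"] == "uptake"
            }
            got = {
                table.row_labels[i]
                for i in range(len(table.row_labels))
                if table.cells[i][j].value is not None
            }
            assert got == expected

    def test_counts_column_matches_record_count(self, community):
        table = transporter_comparison(community)["counts"]
        for j, oid in enumerate(table.column_labels):
            assert table.cells[0][j].value == len(
                community.member(oid).transport_records
            )


class TestTranscriptionUnits:
    def test_histogram_total_equals_number_of_units(self, community):
        table = transcription_unit_comparison(community)
        for j, oid in enumerate(table.column_labels):
            total = sum(table.cells[i][j].value for i in range(len(table.row_labels)))
            assert total == len(community.member(oid).operons)

    def test_histogram_matches_truth_operon_sizes(self, community, truth):
        table = transcription_unit_comparison(community)
        for j, oid in enumerate(table.column_labels):
            sizes = [len(op) for op in truth["organisms"][oid]["operons"]]
            for i, label in enumerate(table.row_labels):
                assert table.cells[i][j].value == sizes.count(int(label))


class TestExport:
    def test_all_tables_write_tsv(self, community, tmp_path):
        tables = all_comparisons(community)
        assert len(tables) >= 15
        for key, table in tables.items():
            path = tmp_path / f"{key}.tsv"
            table.to_tsv(path)
            lines = path.read_text().splitlines()
            assert len(lines) == len(table.row_labels) + 1
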