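"""Route search: switches, atom composition, cost, oracle equivalence."""

import itertools
import json

import pytest

from commkit.errors import GuardError, IntegrityError, ValidationError
from commkit.importer import Community, OrganismDB
from commkit.refdb import AtomMapping, Compound, Ontology, Reaction, ReferenceDB
from commkit.route_search import (
    Route,
    RouteParams,
    RouteStep,
    UnionNetwork,
    build_union_network,
    count_switches,
    enumerate_all_routes,
    pairwise_switch_count,
    report_route,
    route_conserved_atoms,
    route_cost,
    search_routes,
)
from commkit.synthetic import generate_random_network


def brute_min_switches(sets):
    """Independent dynamic-programming minimal segmentation."""
    n = len(sets)
    feasible = [[False] * n for _ in range(n)]
    for i in range(n):
        inter = frozenset(sets[i])
        for j in range(i, n):
            inter = inter & frozenset(sets[j]) if j > i else inter
            feasible[i][j] = bool(inter)
    INF = float("inf")
    best = [INF] * (n + 1)
    best[0] = 0
    for j in range(1, n + 1):
        for i in range(j):
            if feasible[i][j - 1] and best[i] + 1 < best[j]:
                best[j] = best[i] + 1
    return best[n] - 1


def chain_db(n_compounds=5, heavy=3, organisms=None):
    """Linear chain M0 -> M1 -> ... with identity atom mappings."""
    compounds = {
        f"M{i}": Compound(f"M{i}", f"m{i}", {"C": heavy, "H": 2})
        for i in range(n_compounds)
    }
    reactions = {}
    organism_sets = {}
    for i in range(n_compounds - 1):
        rid = f"R{i}"
        reactions[rid] = Reaction(
            id=rid,
            reactant_slots=[(f"M{i}", 1)],
            product_slots=[(f"M{i+1}", 1)],
            atom_mapping=AtomMapping(frozenset(((0, a), (0, a)) for a in range(heavy))),
        )
        organism_sets[rid] = frozenset((organisms or {"R0": ["X"]}).get(rid, ["X"]))
    ontology = Ontology(root="Pathways", classes={"Pathways": ("Pathways", None)})
    db = ReferenceDB(compounds, reactions, {}, ontology, set())
    return db, organism_sets


class TestCountSwitches:
    def test_common_organism_means_no_switch(self):
        assert count_switches([frozenset("X"), frozenset("X")])[0] == 0

    def test_disjoint_pair_is_one_switch(self):
        assert count_switches([frozenset("X"), frozenset("Y")])[0] == 1

    def test_pairwise_overlap_without_common_organism(self):
        """Three consecutive sets that pairwise overlap but share no common
        organism: the pairwise rule says 0, the minimal segmentation says 1."""
        sets = [frozenset("XY"), frozenset("YZ"), frozenset("ZX")]
        n, segments = count_switches(sets)
        assert n == 1
        assert segments == [[0, 1], [2]]
        assert pairwise_switch_count(sets) == 0
        assert brute_min_switches(sets) == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            count_switches([frozenset("X"), frozenset()])

    def test_greedy_equals_dp_minimum_exhaustively(self):
        subsets = [
            frozenset(c)
            for n in (1, 2, 3)
            for c in itertools.combinations("XYZ", n)
        ]
        for length in range(1, 5):
            for seq in itertools.product(subsets, repeat=length):
                seq = list(seq)
                greedy, _ = count_switches(seq)
                assert greedy == brute_min_switches(seq)
                # every disjoint adjacent pair forces a segment boundary
                assert greedy >= pairwise_switch_count(seq)


class TestAtomComposition:
    def test_identity_chain_conserves_all_atoms(self):
        db, orgsets = chain_db(4)
        net = UnionNetwork(db, orgsets, set())
        (route,) = enumerate_all_routes("M0", "M3", net, max_len=5)
        assert route.conserved_atoms == 3
        assert route_conserved_atoms(route, db) == 3

    def test_hand_composed_two_step_trace(self, tiny_db):
        """A->B keeps {0,1} as {1,0}; B->C keeps only B atom 1 -> exactly
        the A atom that landed on B atom 1 survives."""
        steps = [
            RouteStep("R-AB", "forward", "A", "B", frozenset(["X"])),
            RouteStep("R-BC", "forward", "B", "C", frozenset(["X"])),
        ]
        route = Route(steps, "A", "C", 0, [[0, 1]], 0, 0, 0.0)
        assert route_conserved_atoms(route, tiny_db) == 1

    def test_three_step_manual_trace(self, tiny_db):
        """Identity A->B, then hand-traced B->C keeps one atom; a final
        identity-like step cannot regain it."""
        steps = [
            RouteStep("R-ID", "forward", "A", "B", frozenset(["X"])),
            RouteStep("R-BC", "forward", "B", "C", frozenset(["X"])),
        ]
        route = Route(steps, "A", "C", 0, [[0, 1]], 0, 0, 0.0)
        assert route_conserved_atoms(route, tiny_db) == 1

    def test_zero_length_route_keeps_all_heavy_atoms(self, tiny_db):
        route = Route([], "A", "A", 0, [], 0, 0, 0.0)
        assert route_conserved_atoms(route, tiny_db) == 3

    def test_broken_linkage_is_integrity_error(self, tiny_db):
        steps = [
            RouteStep("R-AB", "forward", "A", "B", frozenset(["X"])),
            RouteStep("R-PK", "forward", "GLC", "PYR", frozenset(["X"])),
        ]
        route = Route(steps, "A", "PYR", 0, [[0, 1]], 0, 0, 0.0)
        with pytest.raises(IntegrityError):
            route_conserved_atoms(route, tiny_db)

    def test_conservation_non_increasing_along_routes(self):
        db, orgsets = generate_random_network(5, n_compounds=10, n_reactions=20)
        net = UnionNetwork(db, orgsets, set())
        cids = sorted(db.compounds)
        for goal in cids[1:5]:
            for route in enumerate_all_routes(cids[0], goal, net, max_len=5):
                atoms = set(range(db.compounds[route.start_compound].heavy_atom_count))
                sizes = [len(atoms)]
                current = route.start_compound
                for step in route.steps:
                    atoms = db.atoms_conserved_by_reaction(
                        step.reaction_id, current, atoms, step.out_compound,
                        step.orientation,
                    )
                    sizes.append(len(atoms))
                    current = step.out_compound
                assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestRouteCost:
    def make_route(self, n_steps, conserved, switches, heavy=3):
        steps = [
            RouteStep(f"R{i}", "forward", f"M{i}", f"M{i+1}", frozenset(["X"]))
            for i in range(n_steps)
        ]
        return Route(steps, "M0", f"M{n_steps}", conserved, [[i] for i in range(n_steps)],
                     switches, switches, 0.0)

    def test_two_step_all_atoms_no_switch(self):
        db, _ = chain_db(3)
        route = self.make_route(2, conserved=3, switches=0)
        assert route_cost(route, RouteParams(), db) == 2.0

    def test_switch_adds_its_weight(self):
        db, _ = chain_db(3)
        route = self.make_route(2, conserved=3, switches=1)
        assert route_cost(route, RouteParams(), db) == 4.0

    def test_degenerate_zero_weights(self):
        db, _ = chain_db(3)
        route = self.make_route(2, conserved=1, switches=2)
        assert route_cost(route, RouteParams(w_len=0, w_atom=0, w_switch=0), db) == 0.0

    def test_cost_strictly_decreasing_in_conserved_atoms(self):
        db, _ = chain_db(3)
        costs = [
            route_cost(self.make_route(2, conserved=c, switches=0), RouteParams(), db)
            for c in range(4)
        ]
        assert costs == sorted(costs, reverse=True)
        assert len(set(costs)) == 4


class TestUnionNetwork:
    def test_single_organism_owns_every_reaction(self, tiny_db):
        org = OrganismDB(organism_id="solo", reactome={"R-AB": {"g"}, "R-BC": {"g"}})
        community = Community(members=[org], refdb=tiny_db)
        net = build_union_network(community)
        assert all(s == frozenset(["solo"]) for s in net.organism_sets.values())

    def test_organism_set_is_exactly_the_carriers(self, tiny_db):
        orgs = [
            OrganismDB(organism_id=f"o{i}", reactome={"R-AB": {"g"}})
            for i in range(3)
        ]
        orgs[0].reactome["R-BC"] = {"g"}
        community = Community(members=orgs, refdb=tiny_db)
        net = build_union_network(community)
        assert net.organism_sets["R-AB"] == frozenset(["o0", "o1", "o2"])
        assert net.organism_sets["R-BC"] == frozenset(["o0"])

    def test_blocking_a_compound_removes_routes_through_it(self):
        db, orgsets = chain_db(4)
        open_net = UnionNetwork(db, orgsets, set())
        assert enumerate_all_routes("M0", "M3", open_net, max_len=5)
        blocked_net = UnionNetwork(db, orgsets, {"M1"})
        assert enumerate_all_routes("M0", "M3", blocked_net, max_len=5) == []


class TestEnumerateAllRoutes:
    def test_linear_chain_has_exactly_one_route(self):
        db, orgsets = chain_db(4)
        net = UnionNetwork(db, orgsets, set())
        assert len(enumerate_all_routes("M0", "M3", net, max_len=5)) == 1

    def diamond_net(self):
        compounds = {
            x: Compound(x, x.lower(), {"C": 2, "H": 2}) for x in "ABCD"
        }
        identity = AtomMapping(frozenset(((0, i), (0, i)) for i in range(2)))
        edges = [("R1", "A", "B"), ("R2", "A", "C"), ("R3", "B", "D"), ("R4", "C", "D")]
        reactions = {
            rid: Reaction(id=rid, reactant_slots=[(s, 1)], product_slots=[(t, 1)],
                          atom_mapping=identity)
            for rid, s, t in edges
        }
        ontology = Ontology(root="P", classes={"P": ("P", None)})
        db = ReferenceDB(compounds, reactions, {}, ontology, set())
        orgsets = {rid: frozenset(["X"]) for rid in reactions}
        return UnionNetwork(db, orgsets, set())

    def test_diamond_has_exactly_two_routes(self):
        routes = enumerate_all_routes("A", "D", self.diamond_net(), max_len=4)
        assert sorted(r.reaction_sequence for r in routes) == [
            ("R1", "R3"),
            ("R2", "R4"),
        ]

    def test_route_count_matches_dag_path_dp(self):
        """On a random DAG the number of enumerated simple routes equals an
        independent dynamic-programming path count."""
        import random

        rng = random.Random(11)
        n = 8
        compounds = {
            f"M{i}": Compound(f"M{i}", f"m{i}", {"C": 2, "H": 1}) for i in range(n)
        }
        identity = AtomMapping(frozenset({((0, 0), (0, 0)), ((0, 1), (0, 1))}))
        reactions = {}
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    rid = f"R{i}_{j}"
                    reactions[rid] = Reaction(
                        id=rid, reactant_slots=[(f"M{i}", 1)],
                        product_slots=[(f"M{j}", 1)], atom_mapping=identity,
                    )
                    edges.append((i, j))
        ontology = Ontology(root="P", classes={"P": ("P", None)})
        db = ReferenceDB(compounds, reactions, {}, ontology, set())
        net = UnionNetwork(db, {rid: frozenset(["X"]) for rid in reactions}, set())
        # DP path count on the DAG (paths in a DAG are simple by construction)
        paths = [0] * n
        paths[0] = 1
        for j in range(1, n):
            paths[j] = sum(paths[i] for i, jj in edges if jj == j)
        routes = enumerate_all_routes("M0", f"M{n-1}", net, max_len=n)
        assert len(routes) == paths[n - 1]

    def test_guard_refuses_oversized_enumeration(self):
        db, orgsets = generate_random_network(3, n_compounds=12, n_reactions=28)
        net = UnionNetwork(db, orgsets, set())
        cids = sorted(db.compounds)
        with pytest.raises(GuardError):
            enumerate_all_routes(cids[0], cids[1], net, max_len=8, guard=5)


class TestSearchRoutes:
    def test_start_without_outgoing_reactions_gives_empty_list(self):
        db, orgsets = chain_db(3)
        net = UnionNetwork(db, orgsets, set())
        assert search_routes("M2", "M0", net) == []

    def test_short_single_organism_route_ranks_first(self):
        """A 2-step single-organism route beats a 4-step two-organism
        alternative with a switch."""
        compounds = {
            x: Compound(x, x.lower(), {"C": 3, "H": 2}) for x in "SABCG"
        }
        identity = AtomMapping(frozenset(((0, i), (0, i)) for i in range(3)))
        spec = [
            ("R1", "S", "A", ["one"]),
            ("R2", "A", "G", ["one"]),
            ("R3", "S", "B", ["two"]),
            ("R4", "B", "C", ["two"]),
            ("R5", "C", "G", ["three"]),
        ]
        reactions = {
            rid: Reaction(id=rid, reactant_slots=[(s, 1)], product_slots=[(t, 1)],
                          atom_mapping=identity)
            for rid, s, t, _ in spec
        }
        ontology = Ontology(root="P", classes={"P": ("P", None)})
        db = ReferenceDB(compounds, reactions, {}, ontology, set())
        orgsets = {rid: frozenset(orgs) for rid, _, _, orgs in spec}
        net = UnionNetwork(db, orgsets, set())
        routes = search_routes("S", "G", net, RouteParams(k=3))
        assert routes[0].reaction_sequence == ("R1", "R2")
        assert routes[0].n_switches == 0
        assert routes[1].reaction_sequence == ("R3", "R4", "R5")
        assert routes[1].n_switches == 1

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_topk_equals_exhaustive_enumeration(self, seed):
        db, orgsets = generate_random_network(seed, n_compounds=12, n_reactions=25)
        net = UnionNetwork(db, orgsets, set())
        params = RouteParams(k=3, max_len=6)
        cids = sorted(db.compounds)
        for start, goal in [(cids[0], cids[5]), (cids[2], cids[9])]:
            found = search_routes(start, goal, net, params)
            oracle = enumerate_all_routes(start, goal, net, max_len=6, params=params)
            assert [r.cost for r in found] == [r.cost for r in oracle[:3]]
            assert [r.reaction_sequence for r in found] == [
                r.reaction_sequence for r in oracle[:3]
            ]

    def test_returned_routes_satisfy_invariants(self):
        db, orgsets = generate_random_network(7, n_compounds=12, n_reactions=25)
        net = UnionNetwork(db, orgsets, set())
        cids = sorted(db.compounds)
        routes = search_routes(cids[0], cids[5], net, RouteParams(k=5, max_len=6))
        costs = [r.cost for r in routes]
        assert costs == sorted(costs)
        for r in routes:
            r.validate(db)
            assert r.conserved_atoms == route_conserved_atoms(r, db)

    def test_single_organism_routes_never_switch(self):
        db, orgsets = generate_random_network(9, n_compounds=10, n_reactions=20,
                                              n_organisms=1)
        net = UnionNetwork(db, orgsets, set())
        cids = sorted(db.compounds)
        for r in search_routes(cids[0], cids[4], net, RouteParams(k=5, max_len=6)):
            assert r.n_switches == 0

    def test_huge_switch_cost_prefers_switchless_routes(self):
        db, orgsets = generate_random_network(13, n_compounds=12, n_reactions=25)
        net = UnionNetwork(db, orgsets, set())
        cids = sorted(db.compounds)
        params = RouteParams(k=1, max_len=6, w_switch=10_000.0)
        for goal in cids[1:6]:
            oracle = enumerate_all_routes(cids[0], goal, net, max_len=6,
                                          params=params)
            if any(r.n_switches == 0 for r in oracle):
                best = search_routes(cids[0], goal, net, params)[0]
                assert best.n_switches == 0

    def test_unknown_compound_is_validation_error(self):
        db, orgsets = chain_db(3)
        net = UnionNetwork(db, orgsets, set())
        with pytest.raises(ValidationError, match="NOPE"):
            search_routes("NOPE", "M1", net)


class TestReportRoute:
    def test_switchless_route_has_no_markers(self):
        db, orgsets = chain_db(4)
        net = UnionNetwork(db, orgsets, set())
        (route,) = enumerate_all_routes("M0", "M3", net, max_len=5)
        rec = report_route(route, db)
        assert all(not row["switch_after"] for row in rec["steps"])

    def test_marker_at_segment_boundary(self):
        db, orgsets = chain_db(
            4, organisms={"R0": ["X"], "R1": ["X"], "R2": ["Y"]}
        )
        net = UnionNetwork(db, orgsets, set())
        (route,) = enumerate_all_routes("M0", "M3", net, max_len=5)
        rec = report_route(route, db)
        assert [row["switch_after"] for row in rec["steps"]] == [False, True, False]

    def test_report_json_round_trips(self, tmp_path):
        db, orgsets = chain_db(4)
        net = UnionNetwork(db, orgsets, set())
        (route,) = enumerate_all_routes("M0", "M3", net, max_len=5)
        rec = report_route(route, db)
        path = tmp_path / "route.json"
        path.write_text(json.dumps(rec))
        assert json.loads(path.read_text()) == rec
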