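"""Single- and multi-organism metabolic route search.

A *route* is a linear sequence of oriented reactions transforming a start
compound into a goal compound through non-currency linking compounds.  For
a community, the search runs over the **union** of the members' reaction
networks; each reaction carries the set of organisms that contain it, and a
route must *switch organisms* wherever no single organism covers two
consecutive reactions — operationally, wherever the running intersection of
organism sets along the current segment becomes empty.

The cost of a route is a weighted sum of three terms::

    cost = w_len * n_steps + w_atom * (heavy_atoms(start) - conserved_atoms)
         + w_switch * n_switches

Conserved atoms are tracked as explicit index sets composed through each
reaction's pre-computed atom mapping, so conservation is exact even when
alternative routes keep different atom subsets.  More conserved atoms means
a more efficient transformation and a lower cost.

``search_routes`` is exact for this cost function: it expands partial
routes best-first on a lower bound that only ever grows along a route
(steps and switches accumulate, atom sets only shrink), so the first k goal
states popped are the k minimal-cost routes.  ``enumerate_all_routes`` is
the guarded exhaustive oracle.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import GuardError, IntegrityError, ValidationError
from .importer import Community
from .refdb import ReferenceDB


@dataclass
class RouteParams:
    w_len: float = 1.0
    w_atom: float = 1.0
    w_switch: float = 2.0
    k: int = 3
    max_len: int = 8
    blocked_compounds: set[str] | None = None  # None -> refdb currency list

    def __post_init__(self):
        for name in ("w_len", "w_atom", "w_switch"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValidationError(f"{name} must be finite and non-negative, got {v}")
        if self.k < 1 or self.max_len < 1:
            raise ValidationError("k and max_len must be positive")


@dataclass(frozen=True)
class RouteStep:
    reaction_id: str
    orientation: str  # forward | reverse
    in_compound: str
    out_compound: str
    organism_set: frozenset[str]


@dataclass
class Route:
    steps: list[RouteStep]
    start_compound: str
    goal_compound: str
    conserved_atoms: int
    segments: list[list[int]]        # step indices per organism segment
    n_switches: int                  # minimal-segmentation count (used in cost)
    n_pairwise_switches: int         # count of adjacent disjoint pairs (reported)
    cost: float

    @property
    def reaction_sequence(self) -> tuple[str, ...]:
        return tuple(s.reaction_id for s in self.steps)

    def validate(self, refdb: ReferenceDB) -> None:
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if prev.out_compound != nxt.in_compound:
                raise IntegrityError(
                    f"broken linkage {prev.out_compound!r} -> {nxt.in_compound!r}"
                )
        compounds = [self.start_compound] + [s.out_compound for s in self.steps]
        if len(set(compounds)) != len(compounds):
            raise IntegrityError("route revisits a compound")
        if self.conserved_atoms > refdb.compounds[self.start_compound].heavy_atom_count:
            raise IntegrityError("conserved atoms exceed start compound heavy atoms")
        for seg in self.segments:
            common = frozenset.intersection(*(self.steps[i].organism_set for i in seg))
            if not common:
                raise IntegrityError("segment has no common organism")


class UnionNetwork:
    """Union of the community members' reaction networks, oriented.

    A reaction is included when at least one member contains it (enzyme
    evidence or pathway import); its ``organism_set`` is exactly the members
    that do.  Reversible reactions contribute both orientations; blocked
    compounds (currency metabolites by default) generate no adjacency
    edges.
    """

    def __init__(
        self,
        refdb: ReferenceDB,
        organism_sets: dict[str, frozenset[str]],
        blocked_compounds: set[str],
    ):
        self.refdb = refdb
        self.organism_sets = organism_sets
        self.blocked = set(blocked_compounds)
        #: oriented reaction instances present in the network
        self.instances: list[tuple[str, str]] = []
        #: compound -> outgoing oriented reactions
        self.adjacency: dict[str, list[tuple[str, str]]] = {}
        for rid in sorted(organism_sets):
            rxn = refdb.reactions[rid]
            orientations = {
                "LEFT-TO-RIGHT": ("forward",),
                "RIGHT-TO-LEFT": ("reverse",),
                "REVERSIBLE": ("forward", "reverse"),
            }[rxn.direction]
            for orient in orientations:
                self.instances.append((rid, orient))
                for cid in set(self.inputs(rid, orient)):
                    if cid in self.blocked:
                        continue
                    self.adjacency.setdefault(cid, []).append((rid, orient))
        for edges in self.adjacency.values():
            edges.sort()

    def inputs(self, rid: str, orientation: str) -> list[str]:
        side = "reactant" if orientation == "forward" else "product"
        return self.refdb.reactions[rid].expanded_slots(side)

    def outputs(self, rid: str, orientation: str) -> list[str]:
        side = "product" if orientation == "forward" else "reactant"
        return self.refdb.reactions[rid].expanded_slots(side)


def build_union_network(
    community: Community, refdb: ReferenceDB | None = None, params: RouteParams | None = None
) -> UnionNetwork:
    """Build the community union network for route search."""
    refdb = refdb or community.refdb
    params = params or RouteParams()
    organism_sets: dict[str, frozenset[str]] = {}
    acc: dict[str, set[str]] = {}
    for member in community:
        for rid in member.all_reaction_ids():
            acc.setdefault(rid, set()).add(member.organism_id)
    organism_sets = {rid: frozenset(orgs) for rid, orgs in acc.items()}
    blocked = (
        set(refdb.currency_ids)
        if params.blocked_compounds is None
        else set(params.blocked_compounds)
    )
    return UnionNetwork(refdb, organism_sets, blocked)


# ---------------------------------------------------------------------------
# switches


def count_switches(
    organism_sets: list[frozenset[str] | set[str]],
) -> tuple[int, list[list[int]]]:
    """Minimal number of organism switches along a sequence of reactions.

    Returns ``(n_switches, segments)`` where segments partition the step
    indices into maximal runs whose organism sets share a common organism.
    The greedy rule — extend the current segment while the running
    intersection stays nonempty — yields the minimum number of segments:
    any segmentation must cut wherever the greedy one does, because the
    greedy segment is the longest feasible extension at each point.
    """
    if any(not s for s in organism_sets):
        raise ValidationError("organism sets must be nonempty")
    if not organism_sets:
        return 0, []
    segments: list[list[int]] = [[0]]
    running = frozenset(organism_sets[0])
    for i, orgs in enumerate(organism_sets[1:], start=1):
        nxt = running & frozenset(orgs)
        if nxt:
            segments[-1].append(i)
            running = nxt
        else:
            segments.append([i])
            running = frozenset(orgs)
    return len(segments) - 1, segments


def pairwise_switch_count(organism_sets: list[frozenset[str] | set[str]]) -> int:
    """Number of adjacent pairs with disjoint organism sets (the literal
    pairwise rule; can undercount the minimal segmentation)."""
    return sum(
        1
        for a, b in zip(organism_sets, organism_sets[1:])
        if not (frozenset(a) & frozenset(b))
    )


# ---------------------------------------------------------------------------
# atoms and cost


def route_conserved_atoms(route: Route, refdb: ReferenceDB) -> int:
    """Recompute conserved heavy atoms by composing atom mappings.

    Starts from every heavy atom of the start compound and pushes the set
    through each step's mapping restricted to the linking compounds.
    """
    atoms = set(range(refdb.compounds[route.start_compound].heavy_atom_count))
    current = route.start_compound
    for step in route.steps:
        if step.in_compound != current:
            raise IntegrityError(
                f"broken linkage at {step.reaction_id!r}: expected {current!r}"
            )
        atoms = refdb.atoms_conserved_by_reaction(
            step.reaction_id, step.in_compound, atoms, step.out_compound, step.orientation
        )
        current = step.out_compound
    return len(atoms)


def route_cost(route: Route, params: RouteParams, refdb: ReferenceDB) -> float:
    """Weighted route cost: length + atoms lost + organism switches."""
    heavy = refdb.compounds[route.start_compound].heavy_atom_count
    return (
        params.w_len * len(route.steps)
        + params.w_atom * (heavy - route.conserved_atoms)
        + params.w_switch * route.n_switches
    )


def _finish_route(
    steps: list[RouteStep],
    start: str,
    goal: str,
    atoms: frozenset[int],
    params: RouteParams,
    refdb: ReferenceDB,
) -> Route:
    n_switch, segments = count_switches([s.organism_set for s in steps])
    route = Route(
        steps=list(steps),
        start_compound=start,
        goal_compound=goal,
        conserved_atoms=len(atoms),
        segments=segments,
        n_switches=n_switch,
        n_pairwise_switches=pairwise_switch_count([s.organism_set for s in steps]),
        cost=0.0,
    )
    route.cost = route_cost(route, params, refdb)
    return route


# ---------------------------------------------------------------------------
# search


def _expansions(
    network: UnionNetwork,
    compound: str,
    atoms: frozenset[int],
    visited: frozenset[str],
    used_orients: dict[str, str],
):
    """Yield (step, new_atoms) for every legal one-step extension."""
    refdb = network.refdb
    for rid, orient in network.adjacency.get(compound, ()):
        if used_orients.get(rid, orient) != orient:
            continue  # both orientations of one reaction are forbidden
        orgs = network.organism_sets[rid]
        for out in sorted(set(network.outputs(rid, orient))):
            if out in network.blocked or out in visited:
                continue
            new_atoms = frozenset(
                refdb.atoms_conserved_by_reaction(rid, compound, set(atoms), out, orient)
            )
            yield RouteStep(rid, orient, compound, out, orgs), new_atoms


def search_routes(
    start: str,
    goal: str,
    network: UnionNetwork,
    params: RouteParams | None = None,
) -> list[Route]:
    """Exact k-minimal-cost simple routes from ``start`` to ``goal``.

    Best-first expansion on the accumulated cost lower bound
    ``w_len*steps + w_atom*atoms_lost_so_far + w_switch*switches_so_far``;
    every term is non-decreasing under extension, so goal states pop in
    final-cost order.  Ties break on the lexicographic reaction-id
    sequence.  Routes are simple (no compound revisited) and at most
    ``max_len`` steps; an empty list (no route) is not an error.
    """
    params = params or RouteParams()
    refdb = network.refdb
    for cid in (start, goal):
        if cid not in refdb.compounds:
            raise ValidationError(f"unknown compound {cid!r}")
    if start == goal:
        raise ValidationError("start and goal must differ")
    heavy = refdb.compounds[start].heavy_atom_count
    init_atoms = frozenset(range(heavy))
    results: list[Route] = []
    counter = 0  # heap tie-breaker of last resort
    # entry: (bound, rxn_seq, counter, compound, atoms, running_orgs, n_switch,
    #         visited, used_orients, steps)
    heap: list = [
        (0.0, (), 0, start, init_atoms, None, 0, frozenset([start]), {}, [])
    ]
    while heap and len(results) < params.k:
        bound, seq, _, compound, atoms, running, n_switch, visited, used, steps = (
            heapq.heappop(heap)
        )
        if compound == goal and steps:
            results.append(_finish_route(steps, start, goal, atoms, params, refdb))
            continue
        if len(steps) >= params.max_len:
            continue
        for step, new_atoms in _expansions(network, compound, atoms, visited, used):
            if running is None:
                new_running, new_switch = step.organism_set, 0
            else:
                inter = running & step.organism_set
                if inter:
                    new_running, new_switch = inter, n_switch
                else:
                    new_running, new_switch = step.organism_set, n_switch + 1
            new_steps = steps + [step]
            new_bound = (
                params.w_len * len(new_steps)
                + params.w_atom * (heavy - len(new_atoms))
                + params.w_switch * new_switch
            )
            counter += 1
            heapq.heappush(
                heap,
                (
                    new_bound,
                    seq + (step.reaction_id,),
                    counter,
                    step.out_compound,
                    new_atoms,
                    new_running,
                    new_switch,
                    visited | {step.out_compound},
                    {**used, step.reaction_id: step.orientation},
                    new_steps,
                ),
            )
    return results


def enumerate_all_routes(
    start: str,
    goal: str,
    network: UnionNetwork,
    max_len: int = 8,
    params: RouteParams | None = None,
    guard: int = 10**6,
) -> list[Route]:
    """Exhaustively enumerate all simple routes up to ``max_len`` steps.

    Independent depth-first oracle for :func:`search_routes`; refuses to
    run past ``guard`` partial-path expansions.  Routes come back sorted by
    (cost, reaction-id sequence).
    """
    params = params or RouteParams(max_len=max_len)
    refdb = network.refdb
    for cid in (start, goal):
        if cid not in refdb.compounds:
            raise ValidationError(f"unknown compound {cid!r}")
    if start == goal:
        raise ValidationError("start and goal must differ")
    heavy = refdb.compounds[start].heavy_atom_count
    routes: list[Route] = []
    expansions = 0

    def dfs(compound, atoms, visited, used, steps):
        nonlocal expansions
        if compound == goal and steps:
            routes.append(_finish_route(steps, start, goal, atoms, params, refdb))
            return
        if len(steps) >= max_len:
            return
        for step, new_atoms in _expansions(network, compound, atoms, visited, used):
            expansions += 1
            if expansions > guard:
                raise GuardError(f"exhaustive enumeration exceeded {guard} partial paths")
            used2 = {**used, step.reaction_id: step.orientation}
            dfs(
                step.out_compound,
                new_atoms,
                visited | {step.out_compound},
                used2,
                steps + [step],
            )

    dfs(start, frozenset(range(heavy)), frozenset([start]), {}, [])
    routes.sort(key=lambda r: (r.cost, r.reaction_sequence))
    return routes


# ---------------------------------------------------------------------------
# reporting


def report_route(route: Route, refdb: ReferenceDB, community: Community | None = None) -> dict:
    """Serializable per-step record of a route, with switch markers.

    ``switch_after`` is True on the last step of every organism segment but
    the final one — the position a display would mark with a vertical
    separator.
    """
    segment_of = {}
    for seg_idx, seg in enumerate(route.segments):
        for i in seg:
            segment_of[i] = seg_idx
    rows = []
    for i, step in enumerate(route.steps):
        rows.append(
            {
                "step": i + 1,
                "reaction_id": step.reaction_id,
                "orientation": step.orientation,
                "in_compound": step.in_compound,
                "in_compound_name": refdb.compounds[step.in_compound].name,
                "out_compound": step.out_compound,
                "out_compound_name": refdb.compounds[step.out_compound].name,
                "organisms": sorted(step.organism_set),
                "segment": segment_of[i],
                "switch_after": (
                    i + 1 < len(route.steps) and segment_of[i + 1] != segment_of[i]
                ),
            }
        )
    return {
        "start_compound": route.start_compound,
        "goal_compound": route.goal_compound,
        "n_steps": len(route.steps),
        "conserved_atoms": route.conserved_atoms,
        "n_switches": route.n_switches,
        "n_pairwise_switches": route.n_pairwise_switches,
        "cost": route.cost,
        "steps": rows,
    }


def save_routes(routes: list[Route], refdb: ReferenceDB, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([report_route(r, refdb) for r in routes], indent=1) + "\n"
    )
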