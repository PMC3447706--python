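"""Statistical-parsimony haplotype network: connection limit, minimum
spanning construction retaining tied alternatives (loops), frequency /
interiority / geography loop resolution, and the deep-split lineage
bipartition."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io_model import (
    CodedMatrix,
    DistanceMatrix,
    FormatError,
    GroupingScheme,
    PopulationTable,
)
from .haplotyping import pairwise_step_distances

__all__ = [
    "HaplotypeNetwork",
    "LoopResolution",
    "parsimony_connection_limit",
    "parsimony_probability",
    "build_network",
    "resolve_loops",
    "lineage_bipartition",
    "population_lineages",
]


class AmbiguityError(ValueError):
    """Raised when the deep-split bipartition is not unique."""


@dataclass(frozen=True)
class LoopResolution:
    """Provenance of one loop-breaking edge removal."""

    cycle: tuple[str, ...]
    removed: tuple[str, str]
    alternatives: tuple[tuple[str, str], ...]
    criterion: str


@dataclass
class HaplotypeNetwork:
    """Weighted haplotype graph with construction provenance.

    ``graph`` is an undirected :class:`networkx.Graph`; node attributes are
    ``frequency`` (individuals carrying the haplotype) and ``regions``
    (population codes or region labels carrying it), edge attribute
    ``steps`` is the mutational distance.
    """

    graph: nx.Graph
    connection_limit: int
    components_before: int
    components_after: int
    loops: list[LoopResolution] = field(default_factory=list)

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def copy(self) -> "HaplotypeNetwork":
        return HaplotypeNetwork(
            self.graph.copy(),
            self.connection_limit,
            self.components_before,
            self.components_after,
            list(self.loops),
        )


# ---------------------------------------------------------------------------
# Connection limit
# ---------------------------------------------------------------------------

def parsimony_probability(steps: int, n_characters: int) -> float:
    """Probability that a ``steps``-mutation connection over ``n_characters``
    sites is parsimonious, i.e. that independently, uniformly placed
    mutations all hit distinct sites (no hidden multiple hits).

    This is the birthday-problem product ``prod_{i<steps} (1 - i/m)``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if steps > n_characters:
        return 0.0
    p = 1.0
    for i in range(1, steps):
        p *= 1.0 - i / n_characters
    return p


def parsimony_connection_limit(n_characters: int, alpha: float = 0.05) -> int:
    """Largest step count whose parsimony probability meets the confidence
    level.

    ``alpha`` below 0.5 is read as a significance level (confidence
    ``1 - alpha``, the conventional 95% limit at the default); ``alpha``
    of 0.5 and above is read as the confidence level itself, so values
    approaching 1 admit only the always-certain single-step connections.
    """
    if n_characters < 1:
        raise ValueError("n_characters must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    confidence = 1.0 - alpha if alpha < 0.5 else alpha
    limit = 1
    for j in range(2, n_characters + 1):
        if parsimony_probability(j, n_characters) >= confidence:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(
    matrix: CodedMatrix,
    frequencies: dict[str, int] | None = None,
    limit: int | None = None,
    *,
    populations: PopulationTable | None = None,
    alpha: float = 0.05,
) -> HaplotypeNetwork:
    """Agglomerative minimum-spanning haplotype network.

    Components are joined in increasing order of step distance; at each
    distance level every minimal inter-component edge is retained, so tied
    alternative connections form loops.  Edges longer than the connection
    limit are excluded (possibly leaving the network disconnected).
    """
    if matrix.n_rows == 0:
        raise FormatError("empty haplotype matrix")
    distances = pairwise_step_distances(matrix)
    labels = distances.labels
    if limit is None:
        sites = matrix.total_sites or matrix.n_characters
        limit = parsimony_connection_limit(sites, alpha)

    graph = nx.Graph()
    freq = frequencies or {}
    regions: dict[str, tuple[str, ...]] = {}
    if populations is not None:
        for h in labels:
            regions[h] = tuple(
                r.code for r in populations.records if r.counts.get(h, 0) > 0
            )
        if frequencies is None:
            counts = populations.counts_matrix(labels)
            freq = {h: int(counts[:, i].sum()) for i, h in enumerate(labels)}
    for h in labels:
        graph.add_node(h, frequency=int(freq.get(h, 0)), regions=regions.get(h, ()))

    n = len(labels)
    components_before = n
    values = distances.values
    levels = sorted({int(values[i, j]) for i in range(n) for j in range(i + 1, n) if values[i, j] > 0})
    for level in levels:
        if level > limit:
            break
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(graph)):
            for node in comp:
                comp_of[node] = ci
        new_edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if int(values[i, j]) == level and comp_of[labels[i]] != comp_of[labels[j]]:
                    new_edges.append((labels[i], labels[j]))
        graph.add_edges_from(new_edges, steps=level)
    components_after = nx.number_connected_components(graph)
    return HaplotypeNetwork(graph, int(limit), components_before, components_after)


# ---------------------------------------------------------------------------
# Loop resolution (frequency > interiority > geography)
# ---------------------------------------------------------------------------

def _edge_rank(
    graph: nx.Graph,
    edge: tuple[str, str],
    populations: PopulationTable | None,
) -> tuple:
    u, v = edge
    freq = max(graph.nodes[u].get("frequency", 0), graph.nodes[v].get("frequency", 0))
    interior = max(graph.degree[u], graph.degree[v])
    geo = 0.0
    if populations is not None:
        du = _carrier_coords(populations, u)
        dv = _carrier_coords(populations, v)
        if du and dv:
            from .ibd_geo import haversine_km

            geo = min(haversine_km(a[0], a[1], b[0], b[1]) for a in du for b in dv)
    # Higher tuples are better (kept); the final lexicographic term breaks ties
    # deterministically in favour of earlier haplotype labels.
    return (freq, interior, -geo, tuple(sorted((u, v), reverse=True)))


def _carrier_coords(populations: PopulationTable, hap: str) -> list[tuple[float, float]]:
    return [
        (r.latitude, r.longitude)
        for r in populations.records
        if r.counts.get(hap, 0) > 0
    ]


def resolve_loops(
    network: HaplotypeNetwork, populations: PopulationTable | None = None
) -> HaplotypeNetwork:
    """Break ambiguous alternative connections until the network is a forest.

    Within each cycle only the longest (tied alternative) edges are
    candidates for removal; they are ranked by connection to the
    higher-frequency haplotype, then to the more interior (higher-degree)
    haplotype, then by smaller geographic distance between carrying
    populations, and the lowest-ranked edge is removed.  Each removal is
    recorded with its deciding criterion.
    """
    out = network.copy()
    graph = out.graph
    while True:
        cycles = nx.cycle_basis(graph)
        if not cycles:
            break
        cycle = min(cycles, key=len)
        edges = [
            (cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))
        ]
        max_steps = max(graph.edges[e]["steps"] for e in edges)
        candidates = [e for e in edges if graph.edges[e]["steps"] == max_steps]
        ranked = sorted(candidates, key=lambda e: _edge_rank(graph, e, populations))
        loser = ranked[0]
        ranks = {e: _edge_rank(graph, e, populations) for e in candidates}
        best = ranks[ranked[-1]]
        worst = ranks[loser]
        if best[0] != worst[0]:
            criterion = "frequency"
        elif best[1] != worst[1]:
            criterion = "interiority"
        elif best[2] != worst[2]:
            criterion = "geography"
        else:
            criterion = "label"
        graph.remove_edge(*loser)
        out.loops.append(
            LoopResolution(
                cycle=tuple(cycle),
                removed=tuple(sorted(loser)),
                alternatives=tuple(tuple(sorted(e)) for e in candidates),
                criterion=criterion,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Lineage bipartition
# ---------------------------------------------------------------------------

def lineage_bipartition(network: HaplotypeNetwork, name: str = "two_lineages") -> GroupingScheme:
    """Split the network into two lineages at the deepest edge class.

    All edges of maximal step count are removed; the result must have
    exactly two connected components, otherwise an :class:`AmbiguityError`
    lists the candidate edges.
    """
    graph = network.graph
    if graph.number_of_edges() == 0:
        raise FormatError("network has no edges")
    if not nx.is_connected(graph):
        raise FormatError("network is disconnected; bipartition undefined")
    max_steps = max(d["steps"] for _, _, d in graph.edges(data=True))
    pruned = graph.copy()
    deep = [(u, v) for u, v, d in graph.edges(data=True) if d["steps"] == max_steps]
    pruned.remove_edges_from(deep)
    comps = list(nx.connected_components(pruned))
    if len(comps) != 2:
        raise AmbiguityError(
            f"removing the {max_steps}-step edge class {sorted(deep)} yields "
            f"{len(comps)} components, not 2"
        )
    comps.sort(key=lambda c: sorted(c)[0])
    assignment = {}
    for label, comp in zip(("lineage_A", "lineage_B"), comps):
        for node in comp:
            assignment[node] = label
    return GroupingScheme(name, assignment)


def population_lineages(
    bipartition: GroupingScheme,
    populations: PopulationTable,
    *,
    on_mixed: str = "error",
) -> GroupingScheme:
    """Propagate a haplotype-level bipartition to populations.

    Populations carrying haplotypes from both lineages are flagged: with
    ``on_mixed="error"`` this raises, with ``"majority"`` the lineage of the
    majority of individuals is used.
    """
    assignment = {}
    for rec in populations.records:
        lineages = {
            bipartition.assignment[h] for h, c in rec.counts.items() if c > 0
        }
        if len(lineages) == 1:
            assignment[rec.code] = lineages.pop()
        elif on_mixed == "majority":
            tally: dict[str, int] = {}
            for h, c in rec.counts.items():
                if c > 0:
                    tally[bipartition.assignment[h]] = tally.get(
                        bipartition.assignment[h], 0
                    ) + c
            assignment[rec.code] = max(tally, key=lambda g: (tally[g], g))
        else:
            raise FormatError(
                f"population {rec.code} carries haplotypes from both lineages"
            )
    return GroupingScheme(bipartition.name, assignment)
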