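"""Typed signaling networks and their reduction to integer-capacity flow networks.

A signaling network is a list of molecule-molecule edges, each carrying one
of three relationship classes — ``interaction`` (binding, typically
undirected), ``direct`` control, or ``indirect`` control — mirroring how
curated pathway databases annotate relationships. A capacity scheme maps
each class to a nonnegative integer flow capacity; because the relative
weighting of the classes is a modeling choice, the prioritization stage
sweeps a family of schemes rather than committing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError

RELATIONS = ("interaction", "direct", "indirect")

__all__ = [
    "RELATIONS",
    "Edge",
    "SignalingNetwork",
    "CapacityScheme",
    "DEFAULT_SCHEMES",
    "FlowNetwork",
    "build_flow_network",
]


@dataclass(frozen=True)
class Edge:
    """One typed edge. ``directed=False`` means signal may pass either way."""

    source: str
    target: str
    relation: str
    directed: bool = True

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValidationError(
                f"unknown relation {self.relation!r}; expected one of {RELATIONS}"
            )


@dataclass
class SignalingNetwork:
    """Molecules plus typed edges, cleaned on construction.

    Self-loops are dropped and duplicate (source, target, relation, directed)
    edges collapsed; the dropped counts are kept for logging.
    """

    edges: list[Edge]
    nodes: set[str] = field(default_factory=set)
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    def __post_init__(self):
        cleaned: list[Edge] = []
        seen: set[tuple] = set()
        loops = dupes = 0
        for e in self.edges:
            if e.source == e.target:
                loops += 1
                continue
            key = (e.source, e.target, e.relation, e.directed)
            if key in seen:
                dupes += 1
                continue
            seen.add(key)
            cleaned.append(e)
        self.edges = cleaned
        self.n_self_loops_dropped = loops
        self.n_duplicates_dropped = dupes
        self.nodes = set(self.nodes)
        for e in self.edges:
            self.nodes.add(e.source)
            self.nodes.add(e.target)

    def out_degree(self, node: str) -> int:
        """Number of edges along which signal can leave ``node``."""
        return sum(
            1
            for e in self.edges
            if e.source == node or (not e.directed and e.target == node)
        )

    def relations_present(self) -> set[str]:
        return {e.relation for e in self.edges}


@dataclass(frozen=True)
class CapacityScheme:
    """Relationship class -> nonnegative integer capacity.

    Integer capacities guarantee termination of Ford-Fulkerson and keep all
    flow values integral.
    """

    scheme_id: str
    interaction: int
    direct: int
    indirect: int

    def __post_init__(self):
        for name in ("interaction", "direct", "indirect"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(
                    f"scheme {self.scheme_id!r}: capacity for {name} must be a "
                    f"nonnegative integer, got {v!r}"
                )

    def capacity(self, relation: str) -> int:
        if relation not in RELATIONS:
            raise ConfigurationError(f"relation class {relation!r} absent from scheme")
        return getattr(self, relation)

    def as_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "interaction": self.interaction,
            "direct": self.direct,
            "indirect": self.indirect,
        }


def _default_schemes() -> list[CapacityScheme]:
    # Ten (interaction, indirect, direct) triples spanning relative weightings
    # of relationship strength, all with direct >= indirect >= interaction.
    triples = [
        (1, 1, 1), (1, 1, 2), (1, 2, 2), (1, 2, 3), (1, 2, 4),
        (1, 3, 5), (2, 2, 3), (2, 3, 4), (1, 4, 4), (2, 3, 5),
    ]
    return [
        CapacityScheme(
            scheme_id=f"S{i + 1:02d}", interaction=a, indirect=b, direct=c
        )
        for i, (a, b, c) in enumerate(triples)
    ]


DEFAULT_SCHEMES: list[CapacityScheme] = _default_schemes()


@dataclass
class FlowNetwork:
    """Directed arcs with integer capacities, keyed (u, v) -> c(u, v).

    Adjacency lists are kept lexicographically sorted so breadth-first
    augmenting-path search is platform-reproducible.
    """

    capacities: dict[tuple[str, str], int]
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self):
        for (u, v), c in self.capacities.items():
            if c < 0:
                raise ValidationError(f"negative capacity on arc {u}->{v}")
            self.nodes.add(u)
            self.nodes.add(v)
        self._adjacency: dict[str, list[str]] = {n: [] for n in self.nodes}
        neighbor_sets: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.capacities:
            neighbor_sets[u].add(v)
            neighbor_sets[v].add(u)  # residual arcs may run backwards
        for n, s in neighbor_sets.items():
            self._adjacency[n] = sorted(s)

    def neighbors(self, node: str) -> list[str]:
        return self._adjacency.get(node, [])

    @property
    def n_arcs(self) -> int:
        return len(self.capacities)


def build_flow_network(network: SignalingNetwork, scheme: CapacityScheme) -> FlowNetwork:
    """Instantiate a signaling network as a capacitated flow network.

    Directed control edges become single arcs u->v at the class capacity;
    undirected interaction edges expand to antiparallel arcs u->v and v->u,
    each at the interaction capacity. Parallel arcs between the same ordered
    pair are merged by summing capacities; zero-capacity arcs are dropped.
    """
    missing = network.relations_present() - set(RELATIONS)
    if missing:
        raise ConfigurationError(f"relation classes not covered by scheme: {sorted(missing)}")
    caps: dict[tuple[str, str], int] = {}
    for e in network.edges:
        c = scheme.capacity(e.relation)
        if c == 0:
            continue
        pairs = [(e.source, e.target)]
        if not e.directed:
            pairs.append((e.target, e.source))
        for pair in pairs:
            caps[pair] = caps.get(pair, 0) + c
    return FlowNetwork(capacities=caps, nodes=set(network.nodes))
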