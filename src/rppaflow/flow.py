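"""Maximum flow and upstream-regulator prioritization.

The max-flow solver is Ford-Fulkerson with breadth-first augmenting-path
search (Edmonds-Karp): repeatedly find the shortest augmenting path in the
residual graph, push its bottleneck capacity, and stop when source and sink
are disconnected in the residual graph. With integer capacities the flow
value and every arc flow are integers and the algorithm terminates after at
most |V|·|E| augmentations. Neighbors are explored in lexicographic order,
so the augmenting-path log is reproducible across platforms.

The prioritization sweep runs max-flow for every (capacity scheme, sink,
candidate source) triple. Each (scheme, sink) pair identifies its upstream
regulator(s) and pathway molecules once: a molecule earns *source credit*
when it attains the maximal flow value among all candidate sources (ties
all credited; all-zero pairs credit nobody), and *path credit* when it lies
on a flow-carrying arc of a maximal run without being that run's source or
the sink. Molecules are ranked by the total credit over all pairs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .errors import ValidationError
from .network import CapacityScheme, FlowNetwork, SignalingNetwork, build_flow_network

__all__ = [
    "FlowResult",
    "max_flow",
    "flow_carrying_nodes",
    "CandidateScore",
    "score_candidates",
    "rank_report",
    "default_sources",
]


@dataclass
class FlowResult:
    """Outcome of one max-flow computation.

    ``flow`` maps each original arc to its final (nonnegative) flow;
    ``augmenting_paths`` records every augmenting path as (node sequence,
    bottleneck) in discovery order; ``min_cut_arcs`` are the saturated arcs
    from the residual-reachable set to its complement, whose capacities sum
    to the flow value by the max-flow min-cut theorem.
    """

    source: str
    sink: str
    value: int
    flow: dict[tuple[str, str], int] = field(default_factory=dict)
    augmenting_paths: list[tuple[list[str], int]] = field(default_factory=list)
    min_cut_arcs: set[tuple[str, str]] = field(default_factory=set)
    residual_reachable: set[str] = field(default_factory=set)


def _bfs_augmenting_path(
    flownet: FlowNetwork,
    residual: dict[tuple[str, str], int],
    source: str,
    sink: str,
) -> list[str] | None:
    """Shortest augmenting path in the residual graph, or None.

    Neighbors are scanned in lexicographic order (FlowNetwork keeps its
    adjacency sorted), so the chosen path is deterministic.
    """
    parent: dict[str, str] = {source: source}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in flownet.neighbors(u):
            if v in parent or residual.get((u, v), 0) <= 0:
                continue
            parent[v] = u
            if v == sink:
                path = [v]
                while path[-1] != source:
                    path.append(parent[path[-1]])
                return path[::-1]
            queue.append(v)
    return None


def _residual_reachable(
    flownet: FlowNetwork, residual: dict[tuple[str, str], int], source: str
) -> set[str]:
    seen = {source}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in flownet.neighbors(u):
            if v not in seen and residual.get((u, v), 0) > 0:
                seen.add(v)
                queue.append(v)
    return seen


def max_flow(flownet: FlowNetwork, source: str, sink: str) -> FlowResult:
    """Edmonds-Karp maximum flow from ``source`` to ``sink``.

    A source or sink absent from the network yields a zero-flow result (the
    molecule simply cannot route signal) rather than an error; identical
    source and sink is an error.
    """
    if source == sink:
        raise ValidationError("source and sink must differ")
    if source not in flownet.nodes or sink not in flownet.nodes:
        return FlowResult(source=source, sink=sink, value=0, residual_reachable={source})

    # Net-flow formulation: residual(u,v) = c(u,v) - net(u,v), with
    # net(v,u) = -net(u,v). Antiparallel original arcs cancel naturally.
    residual: dict[tuple[str, str], int] = dict(flownet.capacities)
    net: dict[tuple[str, str], int] = {}
    paths: list[tuple[list[str], int]] = []
    value = 0
    while True:
        path = _bfs_augmenting_path(flownet, residual, source, sink)
        if path is None:
            break
        arcs = list(zip(path[:-1], path[1:]))
        bottleneck = min(residual[(u, v)] for u, v in arcs)
        for u, v in arcs:
            residual[(u, v)] -= bottleneck
            residual[(v, u)] = residual.get((v, u), 0) + bottleneck
            net[(u, v)] = net.get((u, v), 0) + bottleneck
            net[(v, u)] = net.get((v, u), 0) - bottleneck
        value += bottleneck
        paths.append((path, bottleneck))

    flow = {
        arc: net.get(arc, 0)
        for arc in flownet.capacities
        if net.get(arc, 0) > 0
    }
    reachable = _residual_reachable(flownet, residual, source)
    cut = {
        (u, v)
        for (u, v) in flownet.capacities
        if u in reachable and v not in reachable
    }
    return FlowResult(
        source=source,
        sink=sink,
        value=value,
        flow=flow,
        augmenting_paths=paths,
        min_cut_arcs=cut,
        residual_reachable=reachable,
    )


def flow_carrying_nodes(result: FlowResult) -> set[str]:
    """Molecules lying on the final flow, excluding the run's source and sink."""
    nodes: set[str] = set()
    for (u, v), f in result.flow.items():
        if f > 0:
            nodes.add(u)
            nodes.add(v)
    return nodes - {result.source, result.sink}


@dataclass
class CandidateScore:
    """Credit tally for one molecule across the prioritization sweep."""

    molecule: str
    source_credit: int = 0
    path_credit: int = 0
    rank: int = 0

    @property
    def total(self) -> int:
        return self.source_credit + self.path_credit


def default_sources(network: SignalingNetwork, sinks: list[str]) -> list[str]:
    """Default candidate sources: non-sink molecules that can emit signal."""
    return sorted(
        n for n in network.nodes if n not in sinks and network.out_degree(n) >= 1
    )


def score_candidates(
    network: SignalingNetwork,
    schemes: list[CapacityScheme],
    sinks: list[str],
    sources: list[str] | None = None,
    flow_log: list[dict] | None = None,
) -> list[CandidateScore]:
    """Run the full (scheme x sink x source) sweep and tally credits.

    Per (scheme, sink) pair: every source attaining the maximal flow value
    gains one source credit, and every molecule lying on the flow-carrying
    arcs of a maximal run (other than that run's source and the sink) gains
    one path credit — at most one of each per pair, so credits count the
    number of parameter-set/sink combinations in which a molecule was
    identified, not the number of raw runs.

    Parameters
    ----------
    sources : list of str, optional
        Candidate upstream regulators; defaults to every non-sink molecule
        with out-degree >= 1 (a curated regulator whitelist can be passed
        instead).
    flow_log : list, optional
        If supplied, one dict per run (scheme_id, sink, source, F) is
        appended — the raw material of the per-run flow log file.

    Returns
    -------
    list of CandidateScore, sorted by descending total with lexicographic
    tie-break, dense 1-based ranks assigned.
    """
    if not schemes:
        raise ValidationError("need at least one capacity scheme")
    if not sinks:
        raise ValidationError("need at least one sink")
    if sources is None:
        sources = default_sources(network, sinks)
    if not sources:
        raise ValidationError("candidate source list is empty")
    overlap = set(sources) & set(sinks)
    if overlap:
        raise ValidationError(f"sinks may not be candidate sources: {sorted(overlap)}")

    scores: dict[str, CandidateScore] = {
        m: CandidateScore(molecule=m) for m in sorted(network.nodes)
    }
    for scheme in schemes:
        flownet = build_flow_network(network, scheme)
        for sink in sinks:
            results: dict[str, FlowResult] = {}
            for src in sources:
                res = max_flow(flownet, src, sink)
                results[src] = res
                if flow_log is not None:
                    flow_log.append(
                        {
                            "scheme_id": scheme.scheme_id,
                            "sink": sink,
                            "source": src,
                            "max_flow": res.value,
                        }
                    )
            best = max((r.value for r in results.values()), default=0)
            if best > 0:
                pathway: set[str] = set()
                for src, res in results.items():
                    if res.value == best:
                        scores[src].source_credit += 1
                        pathway |= flow_carrying_nodes(res)
                for mol in pathway:
                    scores[mol].path_credit += 1

    ranked = sorted(scores.values(), key=lambda s: (-s.total, s.molecule))
    rank = 0
    last_total: int | None = None
    for s in ranked:
        if s.total != last_total:
            rank += 1
            last_total = s.total
        s.rank = rank
    return ranked


def rank_report(
    scores: list[CandidateScore], regulator_whitelist: list[str] | None = None
):
    """Ranked candidate table as a DataFrame.

    A regulator whitelist (e.g. an upstream-regulator list from an external
    pathway tool) adds an ``in_whitelist`` column marking molecules present
    in both — the intersection that nominates final candidates.
    """
    import pandas as pd

    rows = {
        "molecule": [s.molecule for s in scores],
        "source_credit": [s.source_credit for s in scores],
        "path_credit": [s.path_credit for s in scores],
        "total": [s.total for s in scores],
        "rank": [s.rank for s in scores],
    }
    table = pd.DataFrame(rows)
    if regulator_whitelist is not None:
        wl = set(regulator_whitelist)
        table["in_whitelist"] = table["molecule"].isin(wl)
    return table
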