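"""Seeded synthetic benchmarks with planted ground truth.

Three generators make every pipeline stage testable without any download:

* :func:`generate_rppa_timeseries` — paired RPPA-style matrices for two cell
  lines over a shared time grid (default six points, baseline-normalized to
  1), with a planted subset of proteins whose trajectories are affinely
  related between the cell lines amid uncorrelated decoys;
* :func:`generate_signaling_network` — a typed signaling network with a
  planted high-connectivity regulator feeding every sink;
* :func:`generate_flow_fixture` — tiny flow networks whose maximum flow is
  known from exhaustive s-t cut enumeration (the independent oracle for the
  max-flow solver).

One global integer seed fans out to per-stage substreams via
``numpy.random.SeedSequence``, so stages re-run in isolation reproduce the
same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidDesignError, ValidationError
from .matrix import RppaMatrix
from .network import Edge, FlowNetwork, SignalingNetwork

__all__ = [
    "SyntheticRppaTruth",
    "SyntheticNetworkTruth",
    "FlowFixture",
    "generate_rppa_timeseries",
    "generate_signaling_network",
    "generate_flow_fixture",
    "min_cut_by_enumeration",
    "DEFAULT_EDGE_CLASS_PROBABILITIES",
]

DEFAULT_EDGE_CLASS_PROBABILITIES = {"interaction": 0.5, "direct": 0.3, "indirect": 0.2}

#: Random-walk step standard deviation for latent and decoy trajectories, on
#: the fold-change scale. 0.3 yields excursions comparable to the 0.5-2x
#: fold-change range typical of RPPA time courses.
WALK_STEP_SD = 0.3

#: Fold-change floor keeping synthetic linear-scale intensities positive.
FLOOR = 0.05


@dataclass
class SyntheticRppaTruth:
    """Ground truth of a planted-correlation RPPA benchmark."""

    seed: int
    n_proteins: int
    n_timepoints: int
    planted_ids: list[str]
    latent_trajectories: dict[str, list[float]]
    slopes: dict[str, float]
    intercepts: dict[str, float]
    noise_sd: float
    decoy_model: str = "iid-noise"

    @property
    def decoy_ids(self) -> list[str]:
        planted = set(self.planted_ids)
        return [f"P{i:04d}" for i in range(self.n_proteins) if f"P{i:04d}" not in planted]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_walk(rng: np.random.Generator, n: int, start: float) -> np.ndarray:
    """Baseline-anchored random walk on the fold-change scale, floored > 0."""
    steps = rng.normal(0.0, WALK_STEP_SD, size=n - 1)
    series = start + np.concatenate([[0.0], np.cumsum(steps)])
    return np.maximum(series, FLOOR)


def generate_rppa_timeseries(
    seed: int,
    n_proteins: int = 100,
    n_planted: int = 20,
    n_timepoints: int = 6,
    noise_sd: float = 0.05,
    baseline_value: float = 1.0,
    decoy_model: str = "iid-noise",
) -> tuple[RppaMatrix, RppaMatrix, SyntheticRppaTruth]:
    """Paired synthetic RPPA matrices with a planted correlated subset.

    Planted proteins share a latent trajectory (a baseline-anchored random
    walk): cell line A carries it directly, cell line B an affine transform
    of it (slope drawn uniformly in [0.5, 2]; the intercept is fixed at
    baseline_value*(1 - slope) so the affine map carries the baseline to the
    baseline and both series start at exactly ``baseline_value``) plus
    Gaussian noise of sd ``noise_sd`` at the non-baseline points.

    Decoys are generated independently in the two cell lines under
    ``decoy_model``: ``"iid-noise"`` (default) scatters independent Gaussian
    fluctuations around the baseline, giving uniform null p-values so the
    BH filter's false-discovery guarantee applies;
    ``"independent-random-walk"`` draws autocorrelated baseline-anchored
    walks, a harder regime in which independent trajectories can show
    spurious linear trends.

    Returns
    -------
    (cellA, cellB, truth) — two :class:`RppaMatrix` sharing protein list and
    time grid, plus the ground truth.
    """
    if decoy_model not in ("iid-noise", "independent-random-walk"):
        raise ValidationError(f"unknown decoy_model {decoy_model!r}")
    if n_planted > n_proteins:
        raise InvalidDesignError(
            f"n_planted ({n_planted}) exceeds n_proteins ({n_proteins})"
        )
    if n_timepoints < 3:
        raise ValidationError("need n_timepoints >= 3 (regression df = n-2 >= 1)")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if baseline_value <= 0:
        raise ValidationError("baseline_value must be positive (linear scale)")

    rng_assign, rng_latent, rng_noise, rng_decoy = _substreams(seed, 4)
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    planted = sorted(rng_assign.choice(ids, size=n_planted, replace=False).tolist())
    planted_set = set(planted)

    timepoints = [f"T{t + 1}" for t in range(n_timepoints)]
    a = np.empty((n_proteins, n_timepoints))
    b = np.empty((n_proteins, n_timepoints))
    latents: dict[str, list[float]] = {}
    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}

    for i, pid in enumerate(ids):
        if pid in planted_set:
            steps = rng_latent.normal(0.0, WALK_STEP_SD, size=n_timepoints - 1)
            walk = baseline_value + np.concatenate([[0.0], np.cumsum(steps)])
            slope = float(rng_latent.uniform(0.5, 2.0))
            intercept = baseline_value * (1.0 - slope)
            # shrink walk amplitude just enough that the latent and its affine
            # image both stay positive — keeps the relation exactly affine
            # instead of clamping it
            deepest = max(baseline_value - walk.min(), 0.0)
            if deepest > 0:
                allowed = (baseline_value - 2 * FLOOR) / (max(slope, 1.0) * deepest)
                scale = min(1.0, allowed)
            else:
                scale = 1.0
            latent = baseline_value + scale * (walk - baseline_value)
            latent[0] = baseline_value
            noisy = slope * latent + intercept
            noisy[1:] += rng_noise.normal(0.0, noise_sd, size=n_timepoints - 1)
            a[i] = latent
            b[i] = np.maximum(noisy, FLOOR)
            b[i, 0] = baseline_value
            latents[pid] = latent.tolist()
            slopes[pid] = slope
            intercepts[pid] = intercept
        else:
            if decoy_model == "independent-random-walk":
                a[i] = _random_walk(rng_decoy, n_timepoints, baseline_value)
                b[i] = _random_walk(rng_decoy, n_timepoints, baseline_value)
            else:
                a[i] = np.maximum(
                    baseline_value
                    + rng_decoy.normal(0.0, WALK_STEP_SD, size=n_timepoints),
                    FLOOR,
                )
                b[i] = np.maximum(
                    baseline_value
                    + rng_decoy.normal(0.0, WALK_STEP_SD, size=n_timepoints),
                    FLOOR,
                )
            a[i, 0] = baseline_value
            b[i, 0] = baseline_value

    hours = {tp: float(6 * t) for t, tp in enumerate(timepoints)}
    cell_a = RppaMatrix(
        cell_line="SYN-A",
        values=pd.DataFrame(a, index=ids, columns=timepoints),
        baseline=timepoints[0],
        scale="linear",
        hours=hours,
    )
    cell_b = RppaMatrix(
        cell_line="SYN-B",
        values=pd.DataFrame(b, index=ids, columns=timepoints),
        baseline=timepoints[0],
        scale="linear",
        hours=hours,
    )
    truth = SyntheticRppaTruth(
        seed=seed,
        n_proteins=n_proteins,
        n_timepoints=n_timepoints,
        planted_ids=planted,
        latent_trajectories=latents,
        slopes=slopes,
        intercepts=intercepts,
        noise_sd=noise_sd,
        decoy_model=decoy_model,
    )
    return cell_a, cell_b, truth


@dataclass
class SyntheticNetworkTruth:
    """Ground truth of a planted-hub network benchmark."""

    seed: int
    hub_id: str
    sink_ids: list[str]
    n_nodes: int
    hub_out_degree: int
    edge_class_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_CLASS_PROBABILITIES)
    )


def generate_signaling_network(
    seed: int,
    n_nodes: int = 50,
    sink_ids: tuple[str, ...] = ("CCNB1", "CCND1"),
    hub_out_degree: int = 6,
    max_decoy_out_degree: int = 2,
    edge_class_probabilities: dict[str, float] | None = None,
    max_retries: int = 5,
) -> tuple[SignalingNetwork, SyntheticNetworkTruth]:
    """Typed signaling network with a planted high-connectivity regulator.

    The hub sends ``hub_out_degree`` direct-control edges to distinct
    intermediates, and each intermediate sends a direct-control edge to every
    sink, so every sink is reachable from the hub with high capacity.
    Every other non-sink node ("decoy") emits at most
    ``max_decoy_out_degree`` random edges with the given relationship-class
    probabilities (interaction edges are undirected, control edges directed).
    No self-loops are generated.
    """
    sink_ids = list(sink_ids)
    probs = dict(edge_class_probabilities or DEFAULT_EDGE_CLASS_PROBABILITIES)
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValidationError("edge class probabilities must sum to 1")
    if n_nodes < hub_out_degree + len(sink_ids) + 1:
        raise ValidationError(
            "need n_nodes >= hub_out_degree + len(sink_ids) + 1 "
            f"({n_nodes} < {hub_out_degree + len(sink_ids) + 1})"
        )

    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(attempt + 1)[-1]
        )
        hub = "HUB"
        n_other = n_nodes - 1 - len(sink_ids)
        others = [f"M{i:03d}" for i in range(n_other)]
        nodes = [hub] + others + sink_ids
        intermediates = others[:hub_out_degree]
        edges: list[Edge] = [
            Edge(hub, mid, "direct", directed=True) for mid in intermediates
        ]
        for mid in intermediates:
            for sink in sink_ids:
                edges.append(Edge(mid, sink, "direct", directed=True))
        classes = sorted(probs)
        weights = np.array([probs[c] for c in classes])
        for node in others:
            k = int(rng.integers(0, max_decoy_out_degree + 1))
            if k == 0:
                continue
            candidates = [n for n in nodes if n != node]
            targets = rng.choice(candidates, size=k, replace=False)
            for tgt in targets:
                rel = classes[int(rng.choice(len(classes), p=weights))]
                edges.append(Edge(node, str(tgt), rel, directed=rel != "interaction"))
        net = SignalingNetwork(edges=edges, nodes=set(nodes))
        if all(_reachable(net, hub, sink) for sink in sink_ids):
            truth = SyntheticNetworkTruth(
                seed=seed,
                hub_id=hub,
                sink_ids=sink_ids,
                n_nodes=n_nodes,
                hub_out_degree=hub_out_degree,
                edge_class_probabilities=probs,
            )
            return net, truth
    raise GenerationError(
        f"could not generate a network with every sink reachable from the hub "
        f"after {max_retries} attempts"
    )


def _reachable(net: SignalingNetwork, source: str, target: str) -> bool:
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for e in net.edges:
        adj[e.source].add(e.target)
        if not e.directed:
            adj[e.target].add(e.source)
    seen, stack = {source}, [source]
    while stack:
        u = stack.pop()
        if u == target:
            return True
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


@dataclass
class FlowFixture:
    """A tiny flow network with an independently known maximum flow."""

    kind: str
    flownet: FlowNetwork
    source: str
    sink: str
    true_max_flow: int


def min_cut_by_enumeration(flownet: FlowNetwork, source: str, sink: str) -> int:
    """Minimum s-t cut capacity by exhaustive enumeration of node bipartitions.

    Independent oracle for the max-flow solver: every subset S with
    source in S, sink not in S is a cut whose capacity is the sum of arc
    capacities leaving S; the minimum over all 2^(|V|-2) subsets equals the
    maximum flow. Intended for networks of at most ~12 nodes.
    """
    if source == sink:
        raise ValidationError("source and sink must differ")
    if source not in flownet.nodes or sink not in flownet.nodes:
        return 0
    middle = sorted(flownet.nodes - {source, sink})
    if len(middle) > 12:
        raise ValidationError("enumeration oracle limited to 12 intermediate nodes")
    best = None
    for k in range(len(middle) + 1):
        for chosen in combinations(middle, k):
            s_side = {source, *chosen}
            cap = sum(
                c
                for (u, v), c in flownet.capacities.items()
                if u in s_side and v not in s_side
            )
            if best is None or cap < best:
                best = cap
    return int(best)


def generate_flow_fixture(kind: str, seed: int = 0) -> FlowFixture:
    """Named flow-network fixtures whose max flow the cut oracle certifies.

    ``kind`` is one of ``single-edge`` (one arc s->t of capacity 5),
    ``disconnected`` (no s-t path, flow 0), ``diamond`` (two 2-hop routes
    with a cross arc), or ``random-small`` (a seeded random DAG-ish graph of
    at most 8 nodes with integer capacities at most 9). ``true_max_flow`` is
    always computed by :func:`min_cut_by_enumeration`, never assumed.
    """
    if kind == "single-edge":
        net = FlowNetwork(capacities={("s", "t"): 5})
    elif kind == "disconnected":
        net = FlowNetwork(capacities={("s", "a"): 3, ("b", "t"): 2})
    elif kind == "diamond":
        net = FlowNetwork(
            capacities={
                ("s", "a"): 3,
                ("s", "b"): 2,
                ("a", "t"): 2,
                ("b", "t"): 3,
                ("a", "b"): 1,
            }
        )
    elif kind == "random-small":
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))  # total nodes <= 8
        names = ["s"] + [f"n{i}" for i in range(1, n - 1)] + ["t"]
        caps: dict[tuple[str, str], int] = {}
        for u in names:
            for v in names:
                if u != v and rng.random() < 0.35:
                    caps[(u, v)] = int(rng.integers(1, 10))
        net = FlowNetwork(capacities=caps, nodes=set(names))
    else:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; expected single-edge, disconnected, "
            "diamond, or random-small"
        )
    true_value = min_cut_by_enumeration(net, "s", "t")
    return FlowFixture(
        kind=kind, flownet=net, source="s", sink="t", true_max_flow=true_value
    )
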