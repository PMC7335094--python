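"""Stage 3: mutational distances and the statistical-parsimony network.

Haplotypes are compared event-by-event under three indel treatments
(missing / fifth state / single event) and joined into a haplotype network
in which every edge is one mutational step and multi-step links pass through
inferred (unsampled) intermediate nodes.  Links are only drawn up to a
*connection limit*: the largest number of steps that can still be
interpreted without homoplasy at a chosen confidence (0.95 by default),
following the statistical-parsimony rationale of Templeton, Crandall & Sing
(1992) that underlies the TCS program.

The parsimony probability is computed from an explicit model rather than a
reprinted formula (see :func:`parsimony_probability`); ``fixed_limit``
bypasses it entirely when a curated limit is preferred.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_model import (
    GAP,
    MISSING,
    CpnetError,
    HaplotypeMatrix,
    IndelMode,
    REGION_LENGTHS,
)

logger = logging.getLogger("cpnet")


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def pairwise_distance(v1, v2, mode: IndelMode) -> int:
    """Number of mutational steps between two equal-length state vectors.

    ``missing``: events where either vector carries the gap/absent or
    missing token are excluded; remaining mismatches are counted.
    ``fifth_state`` / ``single_event``: the gap state is an ordinary state;
    only missing tokens are excluded.  Each event contributes at most one
    step regardless of span length, so merged indels and inversions count
    one mutation apiece.
    """
    if len(v1) != len(v2):
        raise CpnetError(
            f"state vectors of different length ({len(v1)} vs {len(v2)})")
    mode = IndelMode(mode)
    d = 0
    for a, b in zip(v1, v2):
        if a == MISSING or b == MISSING:
            continue
        if mode is IndelMode.missing and (a == GAP or b == GAP):
            continue
        if a != b:
            d += 1
    return d


@dataclass
class DistanceMatrix:
    """Symmetric integer matrix of mutational steps between haplotypes."""

    labels: list[str]
    steps: np.ndarray
    mode: IndelMode

    def __post_init__(self):
        n = len(self.labels)
        if self.steps.shape != (n, n):
            raise CpnetError("distance matrix shape mismatch")
        if (self.steps.diagonal() != 0).any():
            raise CpnetError("distance matrix diagonal must be zero")
        if (self.steps != self.steps.T).any():
            raise CpnetError("distance matrix must be symmetric")
        if (self.steps < 0).any():
            raise CpnetError("distances must be non-negative")

    def get(self, a: str, b: str) -> int:
        return int(self.steps[self.labels.index(a), self.labels.index(b)])


def distance_matrix(matrix: HaplotypeMatrix,
                    mode: IndelMode) -> DistanceMatrix:
    labels = list(matrix.haplotypes)
    n = len(labels)
    steps = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_distance(matrix.haplotypes[labels[i]],
                              matrix.haplotypes[labels[j]], mode)
        steps[i, j] = steps[j, i] = d
    return DistanceMatrix(labels, steps, IndelMode(mode))


# ---------------------------------------------------------------------------
# Parsimony probability and connection limit
# ---------------------------------------------------------------------------

def _partitions_raw(n: int, max_part: int | None = None):
    """Integer partitions of n as non-increasing tuples ((),) for n=0."""
    if n == 0:
        yield ()
        return
    if max_part is None or max_part > n:
        max_part = n
    for first in range(max_part, 0, -1):
        for rest in _partitions_raw(n - first, first):
            yield (first,) + rest


_PARTITION_CACHE: dict[int, tuple[tuple[int, ...], ...]] = {}


def _partitions(n: int) -> tuple[tuple[int, ...], ...]:
    if n not in _PARTITION_CACHE:
        _PARTITION_CACHE[n] = tuple(_partitions_raw(n))
    return _PARTITION_CACHE[n]


def _visible_given_m(m_sites: int, n_mut: int, j: int) -> float:
    """P(exactly j sites look different | n_mut mutations on m_sites).

    Mutations strike sites independently and uniformly; per site the state
    follows the symmetric four-state (Jukes-Cantor) chain, so a site hit
    ``k`` times still shows a difference with probability
    ``(3/4)(1 - (-1/3)^k)`` (1 for a single hit).  Exact enumeration over
    hit-count partitions; feasible because the excess ``n_mut - j`` is
    small wherever the probability matters.
    """
    if j > n_mut:
        return 0.0
    total = 0.0
    for d in range(j, n_mut + 1):  # d = number of distinct sites hit
        excess = n_mut - d
        for part in _partitions(excess):
            t = len(part)              # multi-hit sites
            singles = d - t
            if singles < 0:
                continue
            counts = [p + 1 for p in part]  # hits at multi-hit sites
            # multinomial-occupancy weight of this hit-count multiset
            logw = 0.0
            for i in range(d):
                logw += math.log(m_sites - i) - math.log(m_sites)
            logw -= excess * math.log(m_sites)
            logw += math.lgamma(n_mut + 1)
            for k in counts:
                logw -= math.lgamma(k + 1)
            # sites with equal hit counts are interchangeable (singles too)
            mult: dict[int, int] = {1: singles}
            for k in counts:
                mult[k] = mult.get(k, 0) + 1
            for c in mult.values():
                logw -= math.lgamma(c + 1)
            w = math.exp(logw)
            # singles are always visible; multi-hit sites visible w.p. v_k
            need = j - singles
            if need < 0 or need > t:
                continue
            prob = [1.0] + [0.0] * t
            for k in counts:
                v = 0.75 * (1.0 - (-1.0 / 3.0) ** k)
                nxt = [0.0] * (t + 1)
                for got, p in enumerate(prob):
                    if p == 0.0:
                        continue
                    nxt[got] += p * (1.0 - v)
                    if got + 1 <= t:
                        nxt[got + 1] += p * v
                prob = nxt
            total += w * prob[need]
    return total


def parsimony_probability(length: int, j: int,
                          tail: float = 1e-12) -> float:
    """P(no homoplasy | two sequences of ``length`` sites differ at j sites).

    Model: the total number of mutations separating the pair is Poisson with
    mean fitted to the observed divergence by the Jukes-Cantor multiple-hit
    correction; mutations land uniformly on sites.  The pair is parsimonious
    when every observed difference reflects exactly one mutation and no
    mutation is hidden, i.e. when the mutation count equals j and all hits
    are distinct.  The returned value is the posterior probability of that
    outcome given that exactly j sites differ.
    """
    if not 0 < j:
        raise CpnetError("j must be >= 1")
    if not math.isfinite(length) or length <= 0:
        raise CpnetError("length must be a positive finite integer")
    p_obs = j / length
    if p_obs >= 0.75:
        return 0.0
    lam = -0.75 * length * math.log1p(-4.0 * p_obs / 3.0)

    def pois(k: int) -> float:
        return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))

    # numerator: exactly j mutations, all on distinct sites
    log_distinct = sum(math.log(length - i) - math.log(length)
                       for i in range(j))
    numerator = pois(j) * math.exp(log_distinct)
    denominator = 0.0
    for k in range(j, j + 31):
        term = pois(k) * _visible_given_m(length, k, j)
        denominator += term
        # extra mutations must hide in collisions, so terms decay
        # geometrically (~j^2/length per step); stop once negligible
        if k > j + 2 and term < tail * denominator:
            break
    if denominator <= 0.0:
        return 0.0
    return min(1.0, numerator / denominator)


def connection_limit(length: int, confidence: float = 0.95,
                     max_steps: int = 200) -> int:
    """Largest number of steps joinable at the given parsimony confidence.

    Walks j = 1, 2, ... while the parsimony probability stays above
    ``confidence``; the limit is the last j that does.
    """
    if not 0.0 < confidence < 1.0:
        raise CpnetError("confidence must lie in (0, 1)")
    if not math.isfinite(length):
        raise CpnetError("length must be finite")
    limit = 0
    for j in range(1, max_steps + 1):
        if parsimony_probability(length, j) > confidence:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Unit-step haplotype graph with inferred intermediates.

    Sampled nodes carry ``labels`` (all haplotype labels merged into the
    node at distance zero), ``frequency`` (number of samples) and
    ``sampled=True``; inferred intermediates are unlabelled with frequency
    zero.  Every edge is exactly one mutational step.
    """

    graph: nx.Graph
    connection_limit: int
    mode: IndelMode
    #: direct links drawn between sampled nodes: (node_a, node_b, steps)
    links: list[tuple[str, str, int]] = None  # type: ignore[assignment]

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["sampled"]]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if not d["sampled"]]

    def merged_labels(self, node: str) -> tuple[str, ...]:
        return tuple(self.graph.nodes[node]["labels"].split("+"))

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def _alignment_length_for(matrix: HaplotypeMatrix) -> int:
    regions = {ev.region_name for ev in matrix.events}
    if regions and regions <= set(REGION_LENGTHS):
        return sum(REGION_LENGTHS[r] for r in regions)
    return max(len(matrix.events), 1)


def build_network(matrix: HaplotypeMatrix,
                  mode: IndelMode = IndelMode.missing,
                  confidence: float = 0.95,
                  fixed_limit: int | None = None,
                  alignment_length: int | None = None) -> HaplotypeNetwork:
    """Statistical-parsimony haplotype network.

    Haplotypes at distance zero under ``mode`` merge into one node carrying
    all their labels and summed sample frequency.  Remaining pairs are
    linked in order of increasing distance (lexicographic label tie-break)
    up to the connection limit, inserting ``d - 1`` inferred nodes on a
    link of length ``d``.  A link between already-connected nodes is added
    only when the existing network path between them is longer than their
    mutational distance (reticulation); equal-length paths already account
    for the distance.  Components farther apart than the limit stay
    disconnected and are reported via :meth:`HaplotypeNetwork.components`.
    """
    mode = IndelMode(mode)
    if not matrix.haplotypes:
        raise CpnetError("cannot build a network from zero haplotypes")
    if fixed_limit is not None:
        limit = int(fixed_limit)
    else:
        length = alignment_length or _alignment_length_for(matrix)
        limit = connection_limit(length, confidence)
        logger.info("connection limit at %.2f confidence over %d bp: %d",
                    confidence, length, limit)

    dm = distance_matrix(matrix, mode)
    labels = dm.labels

    # distance-zero merging
    merged: dict[str, list[str]] = {}
    assigned: dict[str, str] = {}
    for lab in sorted(labels):
        home = None
        for rep in merged:
            if dm.get(rep, lab) == 0:
                home = rep
                break
        if home is None:
            merged[lab] = [lab]
            assigned[lab] = lab
        else:
            merged[home].append(lab)
            assigned[lab] = home

    def frequency(rep: str) -> int:
        if not matrix.sample_assignment:
            return len(merged[rep])
        return sum(matrix.frequency(lab) for lab in merged[rep])

    graph = nx.Graph()
    for rep, members in merged.items():
        graph.add_node(rep, labels="+".join(sorted(members)),
                       frequency=frequency(rep), sampled=True)

    # distance between merged nodes: minimum over member pairs
    # (indels-as-missing distances are not metric, so a convention is needed)
    reps = sorted(merged)
    pair_d = {}
    for a, b in itertools.combinations(reps, 2):
        pair_d[(a, b)] = min(dm.get(x, y)
                             for x in merged[a] for y in merged[b])

    counter = itertools.count(1)
    skipped: list[tuple[str, str, int]] = []
    links: list[tuple[str, str, int]] = []
    for (a, b), d in sorted(pair_d.items(), key=lambda kv: (kv[1], kv[0])):
        if d > limit:
            if not nx.has_path(graph, a, b):
                skipped.append((a, b, d))
            continue
        if nx.has_path(graph, a, b):
            if nx.shortest_path_length(graph, a, b) <= d:
                continue
        links.append((a, b, d))
        prev = a
        for _ in range(d - 1):
            node = f"x{next(counter)}"
            graph.add_node(node, labels="", frequency=0, sampled=False)
            graph.add_edge(prev, node)
            prev = node
        graph.add_edge(prev, b)
    if skipped:
        logger.warning(
            "%d haplotype pairs beyond the %d-step connection limit left "
            "unjoined (e.g. %s-%s at %d steps)",
            len(skipped), limit, *skipped[0])
    return HaplotypeNetwork(graph, limit, mode, links)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(net: HaplotypeNetwork, path,
                   format: str = "graphml") -> None:
    """Write the network as GraphML or as an edge list + node sidecar."""
    if format == "graphml":
        g = net.graph.copy()
        g.graph["connection_limit"] = net.connection_limit
        g.graph["mode"] = net.mode.value
        nx.write_graphml(g, path)
    elif format == "edge_list":
        with open(path, "w") as fh:
            fh.write(f"# connection_limit={net.connection_limit} "
                     f"mode={net.mode.value}\n")
            for a, b in sorted(map(sorted, net.graph.edges())):
                fh.write(f"{a}\t{b}\n")
        side = str(path) + ".nodes.tsv"
        with open(side, "w") as fh:
            fh.write("node\tlabels\tfrequency\tsampled\n")
            for n, d in sorted(net.graph.nodes(data=True)):
                fh.write(f"{n}\t{d['labels']}\t{d['frequency']}\t"
                         f"{int(d['sampled'])}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> HaplotypeNetwork:
    """Read back a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(path)
    graph = nx.Graph()
    for n, d in g.nodes(data=True):
        graph.add_node(n, labels=d.get("labels", ""),
                       frequency=int(d.get("frequency", 0)),
                       sampled=bool(d.get("sampled", False)))
    graph.add_edges_from(g.edges())
    return HaplotypeNetwork(graph,
                            int(g.graph.get("connection_limit", 0)),
                            IndelMode(g.graph.get("mode", "missing")),
                            links=None)
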