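"""Weighted bipartite plant-pollinator networks and specialization indices.

The network is a ``p x a`` matrix whose cell ``n_ij`` is the interaction
frequency of pollinator *j* on plant *i*, measured as visits per flower per
minute.  Pooling across repeated censuses of the same pair uses the pooled
ratio — total visits divided by total flower-minutes — so the frequency
equals what one would compute from the summed field totals.

Species-level specialization is summarized by three indices:

* **L** — linkage level, the number of pollinator species with a positive
  frequency on the plant (its degree);
* **H** — Shannon-Wiener diversity of the plant's interaction frequencies,
  ``H = -sum p_j ln p_j`` in nats, with ``p_j`` the frequency on pollinator
  *j* relative to the plant's row total;
* **CC** — closeness centrality of the plant in the unipartite plant-plant
  projection, where two plants are adjacent when they share at least one
  pollinator: ``CC = (p - 1) / sum_k d(i, k)`` with unweighted shortest-path
  distances.  A plant with any unreachable peer gets CC = 0 (the usual
  social-network convention; observed community networks are connected, so
  the convention only matters for degenerate inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from pollindep.io import CensusRecord

logger = logging.getLogger(__name__)


@dataclass
class BipartiteNetwork:
    """Weighted plant x pollinator interaction matrix."""

    plant_labels: list[str]
    pollinator_labels: list[str]
    weights: np.ndarray  # shape (p, a), visits per flower per minute

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p, a = len(self.plant_labels), len(self.pollinator_labels)
        if self.weights.shape != (p, a):
            raise ValueError(f"weights shape {self.weights.shape} != ({p}, {a})")
        if len(set(self.plant_labels)) != p or len(set(self.pollinator_labels)) != a:
            raise ValueError("duplicate species labels")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_labels)

    def plant_index(self, plant: str) -> int:
        try:
            return self.plant_labels.index(plant)
        except ValueError:
            raise KeyError(f"plant {plant!r} not in network") from None

    def to_frame(self):
        """Long-format export: plant_id, pollinator_id, frequency (links only)."""
        import pandas as pd

        rows = [
            (pl, po, self.weights[i, j])
            for i, pl in enumerate(self.plant_labels)
            for j, po in enumerate(self.pollinator_labels)
            if self.weights[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["plant_id", "pollinator_id", "frequency"])


@dataclass(frozen=True)
class NetworkDescriptors:
    """Whole-network summary statistics.

    S = p * a (network size); links_total = number of realized links;
    I = links_total / (p + a); H2 = Shannon diversity of link weights in
    nats; E2 = H2 / ln(links_total), the evenness of interaction
    frequencies (1 = uniform).  E2 is None when fewer than two links exist.
    """

    n_plants: int
    n_pollinators: int
    S: int
    links_total: int
    I: float
    H2: float
    E2: float | None


@dataclass
class UnipartiteProjection:
    """Binary plant-plant graph: adjacency iff the plants share a pollinator."""

    plant_labels: list[str]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        p = len(self.plant_labels)
        if self.adjacency.shape != (p, p):
            raise ValueError("adjacency must be p x p")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-edges are not allowed")

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(self.plant_labels)
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        graph.add_edges_from(
            (self.plant_labels[i], self.plant_labels[k]) for i, k in idx
        )
        return graph

    def edge_list(self):
        import pandas as pd

        idx = np.argwhere(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            [(self.plant_labels[i], self.plant_labels[k]) for i, k in idx],
            columns=["plant_a", "plant_b"],
        )


def build_network(records: list[CensusRecord]) -> BipartiteNetwork:
    """Aggregate census records into a weighted bipartite network.

    For each (plant, pollinator) pair, ``n_ij = sum(visits) /
    sum(flowers_observed * census_minutes)`` over every census of the pair.
    Labels keep first-appearance order.  Raises if no interaction was
    observed at all.
    """
    if not records:
        raise ValueError("no census records given")
    plants: dict[str, int] = {}
    pollinators: dict[str, int] = {}
    for r in records:
        plants.setdefault(r.plant_id, len(plants))
        pollinators.setdefault(r.pollinator_id, len(pollinators))
    visits = np.zeros((len(plants), len(pollinators)))
    effort = np.zeros_like(visits)
    for r in records:
        i, j = plants[r.plant_id], pollinators[r.pollinator_id]
        visits[i, j] += r.visits
        effort[i, j] += r.flowers_observed * r.census_minutes
    weights = np.divide(visits, effort, out=np.zeros_like(visits), where=effort > 0)
    if not np.any(weights > 0):
        raise ValueError("no interactions observed: all frequencies are zero")
    return BipartiteNetwork(list(plants), list(pollinators), weights)


def descriptors(net: BipartiteNetwork) -> NetworkDescriptors:
    """Network-level descriptors S, links_total, I, H2, E2."""
    p, a = net.n_plants, net.n_pollinators
    links = int(np.count_nonzero(net.weights))
    total = net.weights.sum()
    q = net.weights[net.weights > 0] / total
    h2 = float(-(q * np.log(q)).sum())
    e2 = h2 / np.log(links) if links >= 2 else None
    if e2 is None:
        logger.warning("fewer than 2 links: evenness E2 undefined")
    return NetworkDescriptors(
        n_plants=p,
        n_pollinators=a,
        S=p * a,
        links_total=links,
        I=links / (p + a),
        H2=h2,
        E2=e2,
    )


def linkage_level(net: BipartiteNetwork, plant: str) -> int:
    """Number of pollinator species with positive frequency on the plant."""
    row = net.weights[net.plant_index(plant)]
    level = int(np.count_nonzero(row))
    if level == 0:
        logger.warning("plant %r has no interactions (L = 0)", plant)
    return level


def interaction_diversity(net: BipartiteNetwork, plant: str) -> float:
    """Shannon diversity (nats) of the plant's interaction frequencies."""
    row = net.weights[net.plant_index(plant)]
    total = row.sum()
    if total <= 0:
        raise ValueError(f"plant {plant!r} has zero total interaction frequency")
    p_j = row[row > 0] / total
    return float(-(p_j * np.log(p_j)).sum())


def project_unipartite(net: BipartiteNetwork) -> UnipartiteProjection:
    """Unweighted plant-plant graph linking plants that share a pollinator."""
    present = net.weights > 0
    adjacency = (present @ present.T) > 0
    np.fill_diagonal(adjacency, False)
    return UnipartiteProjection(list(net.plant_labels), adjacency)


def closeness_centrality(proj: UnipartiteProjection, plant: str) -> float:
    """Closeness of a plant in the projection; 0 if any peer is unreachable."""
    if plant not in proj.plant_labels:
        raise KeyError(f"plant {plant!r} not in projection")
    p = len(proj.plant_labels)
    if p == 1:
        raise ValueError("closeness undefined for a single-plant projection")
    lengths = nx.single_source_shortest_path_length(proj.to_graph(), plant)
    if len(lengths) < p:  # some peer unreachable
        return 0.0
    return (p - 1) / sum(d for node, d in lengths.items() if node != plant)


def specialization_table(net: BipartiteNetwork, plants: list[str] | None = None):
    """Per-plant L, H, CC for ``plants`` (default: every plant in the network).

    H is reported as 0 for single-partner plants (a sum over one term).
    """
    import pandas as pd

    proj = project_unipartite(net)
    plants = list(net.plant_labels) if plants is None else plants
    rows = []
    for plant in plants:
        rows.append(
            {
                "plant_id": plant,
                "L": linkage_level(net, plant),
                "H": interaction_diversity(net, plant),
                "CC": closeness_centrality(proj, plant),
            }
        )
    return pd.DataFrame(rows)
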