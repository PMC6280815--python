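"""Network topology panel and G(n, m) random-graph baselines.

Computes the standard descriptive panel for a directed interaction network
-- density, average clustering, diameter, radius, mean degree, Louvain
modularity and community count, and hub nodes at maximum in-/out-degree --
and compares it against an ensemble of uniform random simple digraphs with
the same node and edge counts (the G(n, m) null model, 100 replicates by
default).  Clustering, diameter, radius, modularity and communities are
evaluated on the undirected projection, with eccentricities restricted to
the largest connected component when the graph is disconnected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .glv import InteractionNetwork

__all__ = [
    "TopologyReport",
    "RandomEnsemble",
    "topology_metrics",
    "communities_modularity",
    "find_hubs",
    "random_ensemble",
    "compare_to_null",
    "top_fraction_edges",
]

_METRICS = (
    "density", "clustering", "diameter", "radius", "mean_degree",
    "modularity", "n_communities",
)


def _digraph(net) -> nx.DiGraph:
    if isinstance(net, InteractionNetwork):
        return net.graph
    if isinstance(net, nx.DiGraph):
        return net
    raise TypeError("expected an InteractionNetwork or networkx DiGraph")


@dataclass
class TopologyReport:
    """Topology metric panel, optionally with a random-ensemble baseline."""

    density: float
    clustering: float
    diameter: int
    radius: int
    mean_degree: float
    modularity: float
    n_communities: int
    hubs_in: list = field(default_factory=list)
    hubs_out: list = field(default_factory=list)
    max_in_degree: int = 0
    max_out_degree: int = 0
    disconnected: bool = False
    random_mean: dict[str, float] | None = None
    random_std: dict[str, float] | None = None

    def metric(self, name: str) -> float:
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        """Metric table in the real vs random-baseline layout."""
        rows = []
        for m in _METRICS:
            row = {"metric": m, "real": self.metric(m)}
            if self.random_mean is not None:
                row["random_mean"] = self.random_mean.get(m)
                row["random_std"] = self.random_std.get(m)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {m: self.metric(m) for m in _METRICS}
        d.update(
            hubs_in=list(map(str, self.hubs_in)),
            hubs_out=list(map(str, self.hubs_out)),
            max_in_degree=self.max_in_degree,
            max_out_degree=self.max_out_degree,
            disconnected=self.disconnected,
        )
        if self.random_mean is not None:
            d["random_mean"] = self.random_mean
            d["random_std"] = self.random_std
        return d


def communities_modularity(net, seed: int = 0, resolution: float = 1.0):
    """Louvain partition and Newman-Girvan modularity Q.

    Detection runs on the undirected unweighted projection with a fixed
    seed for reproducibility.  A single-node graph is one community with
    Q = 0.
    """
    g = _digraph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    u = nx.Graph(g.to_undirected())
    if u.number_of_edges() == 0:
        parts = [{n} for n in u.nodes]
        return parts, 0.0
    parts = nx.community.louvain_communities(u, seed=seed, resolution=resolution)
    q = nx.community.modularity(u, parts, resolution=resolution)
    return parts, float(q)


def find_hubs(net) -> tuple[list, list, int, int]:
    """Nodes attaining the maximum in-degree and out-degree.

    All tied nodes are returned (a tie yields multiple hubs).  Returns
    (hubs_in, hubs_out, max_in_degree, max_out_degree).
    """
    g = _digraph(net)
    if g.number_of_edges() == 0:
        raise ValueError("hub detection requires at least one edge")
    in_deg = dict(g.in_degree())
    out_deg = dict(g.out_degree())
    max_in = max(in_deg.values())
    max_out = max(out_deg.values())
    hubs_in = sorted([n for n, d in in_deg.items() if d == max_in], key=str)
    hubs_out = sorted([n for n, d in out_deg.items() if d == max_out], key=str)
    return hubs_in, hubs_out, max_in, max_out


def topology_metrics(net, louvain_seed: int = 0) -> TopologyReport:
    """Compute the full topology panel for one network."""
    g = _digraph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("topology metrics require at least 2 nodes")
    m = g.number_of_edges()
    density = m / (n * (n - 1))
    mean_degree = (sum(d for _, d in g.in_degree())
                   + sum(d for _, d in g.out_degree())) / n
    u = nx.Graph(g.to_undirected())
    clustering = nx.average_clustering(u) if u.number_of_edges() else 0.0
    disconnected = not nx.is_connected(u) if n else True
    if u.number_of_edges() == 0:
        diameter = radius = 0
        disconnected = True
    else:
        comp = max(nx.connected_components(u), key=len)
        sub = u.subgraph(comp)
        diameter = nx.diameter(sub)
        radius = nx.radius(sub)
    parts, q = communities_modularity(g, seed=louvain_seed)
    hubs_in: list = []
    hubs_out: list = []
    max_in = max_out = 0
    if m:
        hubs_in, hubs_out, max_in, max_out = find_hubs(g)
    return TopologyReport(
        density=float(density), clustering=float(clustering),
        diameter=int(diameter), radius=int(radius),
        mean_degree=float(mean_degree), modularity=float(q),
        n_communities=len(parts), hubs_in=hubs_in, hubs_out=hubs_out,
        max_in_degree=int(max_in), max_out_degree=int(max_out),
        disconnected=bool(disconnected),
    )


@dataclass
class RandomEnsemble:
    """G(n, m) replicate ensemble with per-replicate metric values."""

    n: int
    m: int
    reps: int
    seed: int | None
    values: pd.DataFrame  # reps x metrics

    def mean(self) -> dict[str, float]:
        return self.values.mean().to_dict()

    def std(self) -> dict[str, float]:
        return self.values.std(ddof=0).to_dict()


def random_ensemble(
    n: int, m: int, reps: int = 100, seed: int | None = None
) -> RandomEnsemble:
    """Uniform simple digraphs with exactly n nodes and m edges.

    Every replicate's topology panel is computed so a real network can be
    compared metric-by-metric against the ensemble mean +/- std.
    """
    if m > n * (n - 1):
        raise ValueError(f"m = {m} exceeds the simple-digraph maximum {n * (n - 1)}")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)), directed=True)
        rep = topology_metrics(g) if m else None
        if rep is None:
            rows.append({k: 0.0 for k in _METRICS})
        else:
            rows.append({k: rep.metric(k) for k in _METRICS})
    return RandomEnsemble(n, m, reps, seed, pd.DataFrame(rows))


def compare_to_null(net, ensemble: RandomEnsemble | None = None,
                    reps: int = 100, seed: int | None = None) -> TopologyReport:
    """Topology panel of ``net`` annotated with its G(n, m) baseline."""
    g = _digraph(net)
    if ensemble is None:
        ensemble = random_ensemble(
            g.number_of_nodes(), g.number_of_edges(), reps=reps, seed=seed
        )
    if (ensemble.n, ensemble.m) != (g.number_of_nodes(), g.number_of_edges()):
        raise ValueError("ensemble (n, m) does not match the network")
    report = topology_metrics(g)
    report.random_mean = ensemble.mean()
    report.random_std = ensemble.std()
    return report


def top_fraction_edges(net: InteractionNetwork, f: float) -> InteractionNetwork:
    """Display filter: keep the floor(f * m) edges of largest |weight|.

    Ties are broken by the stable ordering (|weight| descending, source id,
    target id); the node set shrinks to the endpoints of retained edges.
    With f = 0.0005 this reproduces "top 0.05% of relationships" displays
    (e.g. 61 of 122,841 edges).
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("f must be in (0, 1]")
    g = net.graph
    m = g.number_of_edges()
    keep_n = math.floor(f * m)
    edges = sorted(
        g.edges(data=True),
        key=lambda e: (-abs(e[2].get("weight", 1.0)), str(e[0]), str(e[1])),
    )[:keep_n]
    if keep_n == 0:
        warnings.warn(
            f"top fraction f = {f} of {m} edges retains no edge", stacklevel=2
        )
    out = nx.DiGraph()
    for u, v, d in edges:
        out.add_edge(u, v, **d)
    return InteractionNetwork(out, kind=net.kind, rank=net.rank, sites=net.sites)
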