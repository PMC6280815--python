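"""Directed network motif analysis.

Motif classes are isomorphism classes of weakly connected directed graphs
without self-loops.  Each class is named by its canonical integer ID: the
adjacency matrix is read row-major (diagonal included, always zero) as a
binary number, and the ID is the minimum of that number over all node
permutations.  For 3-node motifs this is a 9-bit encoding and reproduces the
IDs conventionally used by Mfinder (e.g. 38 = feed-forward loop, 98 =
feedback loop / 3-cycle, 238 = fully bidirectional triangle).

The census counts every *induced* connected 3-node subgraph once.
Significance is assessed against degree-preserving randomizations of the
network (directed double-edge swaps).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MotifClass",
    "MotifCensus",
    "MOTIF_LABELS",
    "TRIAD_IDS",
    "canonical_id",
    "enumerate_motif_classes",
    "motif_census",
    "motif_significance",
    "normalize_across_ranks",
]

#: Ecological / regulatory readings of particular 3-node motif IDs.
MOTIF_LABELS: dict[int, str] = {
    6: "exploitative competition",
    36: "apparent competition",
    38: "feed-forward loop (FFL)",
    74: "cross-feeding / Black Queen",
    98: "feedback loop (FBL, 3-cycle)",
    110: "tri-trophic chain with mutual pair",
    238: "fully mutual triangle",
}


@dataclass(frozen=True)
class MotifClass:
    """One isomorphism class of connected digraphs on ``n`` nodes."""

    motif_id: int
    adjacency: np.ndarray  # representative whose encoding equals motif_id
    label: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class MotifCensus:
    """Per-class counts (and optionally significance) of 3-node motifs."""

    counts: dict[int, int]
    n_nodes: int
    p_values: dict[int, float] | None = None
    random_counts: dict[int, np.ndarray] | None = field(default=None, repr=False)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def significant(self, p_cut: float = 0.05) -> list[int]:
        """Motif IDs present in the network with empirical p <= p_cut."""
        if self.p_values is None:
            raise ValueError("census carries no p-values; run motif_significance")
        return [
            m
            for m, p in self.p_values.items()
            if self.counts.get(m, 0) > 0 and p <= p_cut
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.counts):
            row = {"motif_id": m, "count": self.counts[m]}
            if self.p_values is not None:
                row["p_value"] = self.p_values[m]
            rows.append(row)
        return pd.DataFrame(rows)


def _offdiag_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def _encode(adj: np.ndarray) -> int:
    """Row-major binary reading of the full n*n adjacency matrix."""
    code = 0
    for b in adj.ravel():
        code = (code << 1) | int(b)
    return code


def _is_weakly_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    und = (adj | adj.T).astype(bool)
    reach = np.zeros(n, dtype=bool)
    reach[0] = True
    for _ in range(n):
        new = reach | und[reach].any(axis=0)
        if (new == reach).all():
            break
        reach = new
    return bool(reach.all())


def canonical_id(adjacency) -> int:
    """Canonical motif ID of a connected digraph given as a 0/1 matrix.

    The ID is the minimum, over all node permutations, of the row-major
    binary encoding of the permuted adjacency matrix.
    """
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    n = adj.shape[0]
    if not 2 <= n <= 5:
        raise ValueError(f"motif size must be between 2 and 5 nodes, got {n}")
    adj = (adj != 0).astype(np.uint8)
    if np.diag(adj).any():
        raise ValueError("self-loops are not allowed in motifs")
    if not _is_weakly_connected(adj):
        raise ValueError("motif adjacency must be weakly connected")
    best = None
    for perm in itertools.permutations(range(n)):
        # entry (perm[i], perm[j]) of the relabeled matrix is adj[i, j]
        p = np.asarray(perm)
        new = np.zeros_like(adj)
        new[np.ix_(p, p)] = adj
        code = _encode(new)
        if best is None or code < best:
            best = code
    return int(best)


def _decode(code: int, n: int) -> np.ndarray:
    bits = [(code >> (n * n - 1 - k)) & 1 for k in range(n * n)]
    return np.asarray(bits, dtype=np.uint8).reshape(n, n)


def enumerate_motif_classes(n: int) -> list[MotifClass]:
    """Exhaustively enumerate all connected n-node motif classes.

    Every labeled digraph on ``n`` nodes without self-loops is generated,
    weakly disconnected ones are discarded, and the remainder are grouped by
    permutation isomorphism.  Returns one :class:`MotifClass` per class in
    ascending canonical-ID order: 13 classes for n=3, 199 for n=4, 9364
    for n=5.
    """
    if not 2 <= n <= 5:
        raise ValueError(f"motif size must be between 2 and 5 nodes, got {n}")
    pairs = _offdiag_pairs(n)
    npos = len(pairs)
    codes = np.arange(1, 2**npos, dtype=np.int64)  # 0 is never connected
    bits = [((codes >> (npos - 1 - b)) & 1).astype(np.uint8) for b in range(npos)]

    # weak connectivity on the undirected union, vectorized over all graphs
    nbr = np.zeros((n, codes.size), dtype=np.uint8)  # bitmask of neighbours
    for b, (i, j) in enumerate(pairs):
        nbr[i] |= bits[b] << j
        nbr[j] |= bits[b] << i
    reach = np.full(codes.size, 1, dtype=np.uint8)  # node 0
    for _ in range(n - 1):
        acc = reach.copy()
        for i in range(n):
            acc |= np.where((reach >> i) & 1, nbr[i], 0)
        reach = acc
    connected = reach == (1 << n) - 1
    keep = np.flatnonzero(connected)
    bits = [b[keep] for b in bits]

    # canonical form: minimum full-matrix encoding over all permutations
    def full_weight(i: int, j: int) -> int:
        return 1 << (n * n - 1 - (i * n + j))

    min_code = np.full(keep.size, np.iinfo(np.int64).max, dtype=np.int64)
    for perm in itertools.permutations(range(n)):
        code = np.zeros(keep.size, dtype=np.int64)
        for b, (i, j) in enumerate(pairs):
            w = full_weight(perm[i], perm[j])
            code += bits[b].astype(np.int64) * w
        np.minimum(min_code, code, out=min_code)

    ids = np.unique(min_code)
    return [
        MotifClass(int(m), _decode(int(m), n), MOTIF_LABELS.get(int(m)))
        for m in ids
    ]


def _triad_lookup() -> np.ndarray:
    """Map a 6-bit off-diagonal triple encoding to its canonical ID (-1 if
    disconnected).  Bit order, MSB first: (0,1),(0,2),(1,0),(1,2),(2,0),(2,1)."""
    pairs = _offdiag_pairs(3)
    table = np.full(64, -1, dtype=np.int16)
    for code in range(1, 64):
        adj = np.zeros((3, 3), dtype=np.uint8)
        for b, (i, j) in enumerate(pairs):
            adj[i, j] = (code >> (5 - b)) & 1
        if _is_weakly_connected(adj):
            table[code] = canonical_id(adj)
    return table


_TRIAD_TABLE: np.ndarray | None = None

#: Canonical IDs of the 13 connected 3-node motif classes.
TRIAD_IDS: tuple[int, ...] = (6, 12, 14, 36, 38, 46, 74, 78, 98, 102, 108, 110, 238)


def _as_adjacency(net) -> np.ndarray:
    from .glv import InteractionNetwork  # local import, avoids cycle

    if isinstance(net, InteractionNetwork):
        g = net.graph
    elif isinstance(net, nx.DiGraph):
        g = net
    else:
        return (np.asarray(net) != 0).astype(np.uint8)
    nodes = sorted(g.nodes)
    return (nx.to_numpy_array(g, nodelist=nodes, weight=None) != 0).astype(np.uint8)


def motif_census(net) -> MotifCensus:
    """Count every connected induced 3-node subgraph, by motif class.

    Accepts an :class:`~tsen.glv.InteractionNetwork`, a networkx DiGraph, or
    an adjacency matrix.  Triples are streamed one anchor node at a time, so
    dense networks are counted without materializing subgraphs.
    """
    global _TRIAD_TABLE
    if _TRIAD_TABLE is None:
        _TRIAD_TABLE = _triad_lookup()
    adj = _as_adjacency(net)
    n = adj.shape[0]
    counts = {m: 0 for m in TRIAD_IDS}
    if n < 3:
        return MotifCensus(counts, n)
    acc = np.zeros(64, dtype=np.int64)
    for i in range(n - 2):
        rest = np.arange(i + 1, n)
        jj, kk = np.triu_indices(rest.size, k=1)
        J, K = rest[jj], rest[kk]
        idx = (
            (adj[i, J].astype(np.int64) << 5)
            | (adj[i, K].astype(np.int64) << 4)
            | (adj[J, i].astype(np.int64) << 3)
            | (adj[J, K].astype(np.int64) << 2)
            | (adj[K, i].astype(np.int64) << 1)
            | adj[K, J].astype(np.int64)
        )
        acc += np.bincount(idx, minlength=64)
    for code in range(64):
        m = int(_TRIAD_TABLE[code])
        if m >= 0:
            counts[m] += int(acc[code])
    return MotifCensus(counts, n)


def motif_significance(
    net, n_rand: int = 100, seed: int | None = None, swaps_per_edge: int = 10
) -> MotifCensus:
    """Empirical motif significance against degree-preserving randomizations.

    ``n_rand`` randomized networks are produced by directed double-edge
    swaps preserving the in- and out-degree sequences; the p-value of a
    motif class is the fraction of randomized networks whose count is >= the
    observed count (so an absent motif has p = 1).
    """
    from .glv import InteractionNetwork

    if isinstance(net, InteractionNetwork):
        g = net.graph
    elif isinstance(net, nx.DiGraph):
        g = net
    else:
        g = nx.from_numpy_array(np.asarray(net), create_using=nx.DiGraph)
    m = g.number_of_edges()
    if m < 1:
        raise ValueError("motif significance requires a network with >= 1 edge")
    obs = motif_census(g)
    rng = np.random.default_rng(seed)
    rand_counts = {mid: np.zeros(n_rand, dtype=np.int64) for mid in TRIAD_IDS}
    moved = False
    for rep in range(n_rand):
        h = g.copy()
        try:
            nx.directed_edge_swap(
                h,
                nswap=swaps_per_edge * m,
                max_tries=swaps_per_edge * m * 20 + 100,
                seed=int(rng.integers(2**31)),
            )
        except (nx.NetworkXError, nx.NetworkXAlgorithmError, nx.NetworkXUnfeasible):
            pass  # keep whatever swaps succeeded (possibly none)
        if not moved and set(h.edges) != set(g.edges):
            moved = True
        rc = motif_census(h)
        for mid in TRIAD_IDS:
            rand_counts[mid][rep] = rc.counts[mid]
    if not moved:
        warnings.warn(
            "degree-preserving swap chain could not move; motif p-values are "
            "uninformative (all 1.0)",
            stacklevel=2,
        )
        p = {mid: 1.0 for mid in TRIAD_IDS}
    else:
        p = {
            mid: float(np.mean(rand_counts[mid] >= obs.counts[mid]))
            for mid in TRIAD_IDS
        }
    return MotifCensus(obs.counts, obs.n_nodes, p_values=p, random_counts=rand_counts)


def normalize_across_ranks(censuses: Mapping[str, MotifCensus]) -> pd.DataFrame:
    """Normalize each motif's abundance by its summed count across ranks.

    Returns a motifs x ranks frame; each row sums to 1 across the ranks where
    the motif occurs (a value of 1 means the motif is found at only that
    taxonomic rank), or is all-zero if the motif is absent everywhere.
    """
    if not censuses:
        raise ValueError("at least one rank-level census is required")
    ranks = list(censuses)
    mat = pd.DataFrame(
        {r: pd.Series(censuses[r].counts, dtype=float) for r in ranks}
    ).fillna(0.0)
    totals = mat.sum(axis=1)
    nonzero = totals > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(totals[nonzero], axis=0)
    return mat.sort_index()
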