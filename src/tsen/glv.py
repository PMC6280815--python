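"""Generalized Lotka-Volterra simulation and network inference.

The forward model is dx_i/dt = x_i * (r_i + sum_j a_ij * x_j), with a_ij
the per-capita effect of taxon j on taxon i (positive = promotion, negative
= inhibition).  Interactions are inferred from short abundance time series
by the candidate-ensemble procedure: many candidate (r, A) models are fit
by ridge-regularized least squares on the log-difference discretization

    (ln x_i(t+1) - ln x_i(t)) / dt  ~  r_i + sum_j a_ij * xbar_j(t),

each under a sampled (ridge strength, leave-one-interval subset,
sparsification threshold) configuration.  Candidates are scored by the mean
Bray-Curtis dissimilarity (BCD) between the observed profiles and the
profiles regenerated by forward simulation of the candidate, and the
best-scoring candidates are merged into a consensus network that keeps an
edge only when a sign-consistent coefficient appears in at least an
agreement fraction of them.  Consensus networks are split into
positive-only / negative-only views, and site networks are pooled into a
"global" network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp

from .diversity import bray_curtis

__all__ = [
    "GLVModel",
    "TimeSeries",
    "CandidateNetwork",
    "InteractionNetwork",
    "simulate_glv",
    "infer_candidates",
    "score_candidate",
    "consensus_network",
    "save_candidates",
    "split_by_sign",
    "global_network",
    "interaction_fractions",
    "mean_interaction_fractions",
]


@dataclass
class GLVModel:
    """Intrinsic growth rates r and interaction matrix A of a gLV system."""

    taxa: list
    r: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.taxa)
        if self.r.shape != (n,) or self.A.shape != (n, n):
            raise ValueError(
                f"model dimensions inconsistent: {n} taxa, r {self.r.shape}, "
                f"A {self.A.shape}"
            )
        if not (np.isfinite(self.r).all() and np.isfinite(self.A).all()):
            raise ValueError("model parameters must be finite")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def fixed_point(self) -> np.ndarray:
        """Interior equilibrium x* = -A^{-1} r (may have negative entries)."""
        return np.linalg.solve(self.A, -self.r)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"taxa": list(map(str, self.taxa)), "r": self.r.tolist(),
                 "A": self.A.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GLVModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["taxa"], np.asarray(d["r"]), np.asarray(d["A"]))


@dataclass
class TimeSeries:
    """Abundance trajectories x_i(t) for one community."""

    taxa: list
    times: np.ndarray
    values: np.ndarray  # shape (n_taxa, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("a time series needs at least 2 ordered time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.taxa), self.times.size):
            raise ValueError("values must have shape (n_taxa, n_times)")
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


class GLVDivergenceError(RuntimeError):
    """Forward simulation left the admissible abundance range."""


def simulate_glv(
    model: GLVModel,
    x0,
    times,
    method: str = "LSODA",
    floor: float = 0.0,
    overflow: float = 1e12,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeSeries:
    """Integrate the gLV ODE from x0 and sample it at ``times``.

    Abundances are clipped below at ``floor``; a trajectory exceeding
    ``overflow`` raises :class:`GLVDivergenceError` naming the first bad
    time point.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if (x0 < 0).any():
        raise ValueError("initial abundances must be non-negative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    r, A = model.r, model.A

    def rhs(_t, x):
        x = np.maximum(x, floor)
        return x * (r + A @ x)

    def blow_up(_t, x):
        m = np.max(np.abs(x))
        if not np.isfinite(m):
            return -1.0
        return float(overflow - m)

    blow_up.terminal = True

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(
                rhs, (times[0], times[-1]), x0, t_eval=times, method=method,
                rtol=rtol, atol=atol, events=blow_up,
            )
    except (ValueError, FloatingPointError) as exc:
        # overflow inside the step interpolant breaks event root-finding
        raise GLVDivergenceError(f"gLV trajectory diverged: {exc}") from exc
    if sol.status == 1:  # overflow event fired
        t_bad = float(sol.t_events[0][0])
        raise GLVDivergenceError(f"gLV trajectory diverged near t = {t_bad:.4g}")
    if not sol.success:
        raise GLVDivergenceError(f"gLV integration failed: {sol.message}")
    values = np.clip(sol.y, floor, None)
    return TimeSeries(list(model.taxa), times, values)


@dataclass
class CandidateNetwork:
    """One fitted candidate gLV model together with its BCD score."""

    model: GLVModel
    bcd_score: float = np.nan
    config: dict = field(default_factory=dict)

    @property
    def A(self) -> np.ndarray:
        return self.model.A


def _log_difference_design(ts: TimeSeries, eps_frac: float = 1e-6):
    """Response and design matrices of the discretized gLV regression.

    Abundances are floored at ``eps_frac`` of the per-time-point total
    before taking logs; the regressor abundances are interval midpoints.
    """
    x = ts.values.copy()
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    x = np.maximum(x, eps_frac * totals[None, :])
    dt = np.diff(ts.times)
    y = np.diff(np.log(x), axis=1) / dt[None, :]  # (n, T-1)
    xbar = 0.5 * (x[:, :-1] + x[:, 1:])  # (n, T-1)
    return y, xbar


def _fit_ridge(y: np.ndarray, xbar: np.ndarray, lam: float,
               intervals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve per-taxon ridge regressions; returns (r, A).

    Regressor abundances are standardized (centered, unit variance) before
    penalization so the ridge acts uniformly across taxa spanning orders of
    magnitude in abundance; the intercept (growth rate) is unpenalized and
    recovered on the original scale.
    """
    n = y.shape[0]
    x = xbar[:, intervals]  # (n, k)
    mu = x.mean(axis=1)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    z = (x - mu[:, None]) / sd[:, None]
    phi = np.vstack([np.ones(intervals.size), z]).T  # (k, n+1)
    gram = phi.T @ phi + lam * np.eye(n + 1)
    gram[0, 0] -= lam  # do not penalize the intercept
    rhs = phi.T @ y[:, intervals].T
    beta = np.linalg.solve(gram, rhs)  # (n+1, n) standardized coefficients
    A = (beta[1:] / sd[:, None]).T  # A[i, j] = effect of j on i
    r = beta[0] - A @ mu
    return r, A


def _as_series_list(ts) -> list[TimeSeries]:
    series = [ts] if isinstance(ts, TimeSeries) else list(ts)
    if not series:
        raise ValueError("at least one time series is required")
    taxa = series[0].taxa
    for s in series[1:]:
        if list(s.taxa) != list(taxa):
            raise ValueError("all replicate series must share the same taxa")
    return series


def infer_candidates(
    ts,
    n_candidates: int = 1600,
    ridge_grid=None,
    sparsify_grid=(0.0, 0.01, 0.05, 0.1),
    seed: int | None = None,
    eps_frac: float = 1e-6,
    score: bool = True,
) -> list[CandidateNetwork]:
    """Fit an ensemble of candidate gLV models from time-series data.

    ``ts`` is a single :class:`TimeSeries` or a list of replicate series
    over the same taxa (e.g. one per site); replicates are pooled in the
    regression, which greatly improves identifiability from short series.
    Each candidate uses a configuration sampled from the ridge-strength
    grid, the leave-one-interval subsets (only when enough intervals
    remain), and the sparsification-threshold grid (coefficients below the
    threshold fraction of the largest |a_ij| are zeroed).  The first
    candidate is always the plain fit (smallest ridge, all intervals, no
    sparsification).  Candidates carry their BCD score unless ``score`` is
    disabled.
    """
    series = _as_series_list(ts)
    if any(s.times.size < 3 for s in series) and len(series) == 1:
        raise ValueError("inference requires at least 3 time points")
    if sum(s.times.size - 1 for s in series) < 2:
        raise ValueError("inference requires at least 2 intervals in total")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    keep = ~np.all([np.all(s.values == 0, axis=1) for s in series], axis=0)
    if not keep.all():
        taxa0 = series[0].taxa
        dropped = [t for t, k in zip(taxa0, keep) if not k]
        warnings.warn(f"dropping all-zero taxa: {dropped}", stacklevel=2)
        series = [
            TimeSeries([t for t, k in zip(s.taxa, keep) if k],
                       s.times, s.values[keep])
            for s in series
        ]
    taxa = series[0].taxa
    if ridge_grid is None:
        ridge_grid = np.geomspace(1e-4, 1.0, 9)
    ridge_grid = np.asarray(ridge_grid, dtype=float)
    designs = [_log_difference_design(s, eps_frac) for s in series]
    y = np.hstack([d[0] for d in designs])
    xbar = np.hstack([d[1] for d in designs])
    n_int = y.shape[1]
    rng = np.random.default_rng(seed)

    configs = [(float(ridge_grid.min()), None, 0.0)]
    while len(configs) < n_candidates:
        lam = float(rng.choice(ridge_grid))
        drop = int(rng.integers(n_int)) if n_int > 3 and rng.random() < 0.5 else None
        tau = float(rng.choice(np.asarray(sparsify_grid)))
        configs.append((lam, drop, tau))

    candidates: list[CandidateNetwork] = []
    all_int = np.arange(n_int)
    for lam, drop, tau in configs[:n_candidates]:
        intervals = all_int if drop is None else np.delete(all_int, drop)
        r, A = _fit_ridge(y, xbar, lam, intervals)
        if tau > 0:
            off = ~np.eye(A.shape[0], dtype=bool)
            cut = tau * np.max(np.abs(A[off])) if off.any() else 0.0
            A = np.where((np.abs(A) < cut) & off, 0.0, A)
        cand = CandidateNetwork(
            GLVModel(taxa, r, A),
            config={"ridge": lam, "dropped_interval": drop, "sparsify": tau},
        )
        if score:
            cand.bcd_score = score_candidate(series, cand)
        candidates.append(cand)
    return candidates


def score_candidate(ts, candidate: CandidateNetwork) -> float:
    """Mean BCD between observed and candidate-regenerated profiles.

    The candidate model is forward-simulated from the first observed time
    point; the score is the mean Bray-Curtis dissimilarity between observed
    and regenerated relative-abundance columns over time points 2..T.
    With replicate series the scores are averaged.  A diverging
    regeneration scores 1 (worst).
    """
    series = _as_series_list(ts)
    model = candidate.model
    scores = []
    for s in series:
        if model.n != s.n_taxa:
            raise ValueError("candidate dimension does not match the time series")
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                regen = simulate_glv(model, s.values[:, 0], s.times)
        except GLVDivergenceError:
            scores.extend([1.0] * (s.times.size - 1))
            continue
        for k in range(1, s.times.size):
            obs, sim = s.values[:, k], regen.values[:, k]
            if obs.sum() == 0 or sim.sum() == 0:
                scores.append(1.0)
                continue
            scores.append(bray_curtis(obs / obs.sum(), sim / sim.sum()))
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def save_candidates(candidates: list[CandidateNetwork], out_dir) -> None:
    """Persist a candidate ensemble: per-candidate edge lists + scores TSV."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, cand in enumerate(candidates):
        taxa = cand.model.taxa
        edges = [
            {"source": taxa[j], "target": taxa[i], "weight": cand.A[i, j]}
            for i in range(len(taxa)) for j in range(len(taxa))
            if i != j and cand.A[i, j] != 0
        ]
        pd.DataFrame(edges, columns=["source", "target", "weight"]).to_csv(
            out / f"candidate_{k:04d}.tsv", sep="\t", index=False
        )
        rows.append({"candidate": k, "bcd_score": cand.bcd_score,
                     **cand.config})
    pd.DataFrame(rows).to_csv(out / "scores.tsv", sep="\t", index=False)


@dataclass
class InteractionNetwork:
    """Directed, signed, weighted taxon interaction network.

    ``kind`` is one of consensus / positive / negative / global (or the
    global sign-split variants); edge attributes are ``weight`` (signed
    interaction strength) and ``sign`` (+1 / -1).  Self-loops are never
    exported.
    """

    graph: nx.DiGraph
    kind: str = "consensus"
    rank: str = "family"
    sites: tuple = ()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
                for u, v, d in self.graph.edges(data=True)
            ]
        )

    def to_tsv(self, path) -> None:
        self.edges_frame().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def consensus_network(
    candidates: list[CandidateNetwork],
    top_k: int = 100,
    agreement: float = 0.5,
    rank: str = "family",
    site: str | None = None,
) -> InteractionNetwork:
    """Merge the best-scoring candidates into a consensus network.

    Candidates are ranked by ascending BCD score and the best ``top_k``
    kept.  A directed edge u -> v (u's effect on v, i.e. coefficient
    a_{vu}) enters the consensus iff a nonzero coefficient of consistent
    sign occurs in at least ``agreement`` of those candidates; its weight is
    the mean coefficient over the agreeing candidates.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if top_k > len(candidates):
        raise ValueError(f"top_k = {top_k} exceeds {len(candidates)} candidates")
    ranked = sorted(candidates, key=lambda c: c.bcd_score)[:top_k]
    taxa = ranked[0].model.taxa
    n = len(taxa)
    stack = np.stack([c.A for c in ranked])  # (k, n, n)
    g = nx.DiGraph()
    g.add_nodes_from(taxa)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue  # self-interactions fitted but never exported
            coeffs = stack[:, i, j]
            pos_frac = float(np.mean(coeffs > 0))
            neg_frac = float(np.mean(coeffs < 0))
            if pos_frac >= agreement:
                agree = coeffs[coeffs > 0]
            elif neg_frac >= agreement:
                agree = coeffs[coeffs < 0]
            else:
                continue
            w = float(agree.mean())
            # edge direction: j acts on i (a_ij = effect of j on i)
            g.add_edge(taxa[j], taxa[i], weight=w, sign=int(np.sign(w)))
    return InteractionNetwork(
        g, kind="consensus", rank=rank, sites=(site,) if site else ()
    )


def split_by_sign(net: InteractionNetwork) -> tuple[InteractionNetwork, InteractionNetwork]:
    """Partition a network into positive-only and negative-only views.

    The two edge sets are disjoint and, when no zero-weight edge exists,
    exhaustive: |E_pos| + |E_neg| = |E|.
    """
    pos, neg = nx.DiGraph(), nx.DiGraph()
    for u, v, d in net.graph.edges(data=True):
        if d["weight"] > 0:
            pos.add_edge(u, v, **d)
        elif d["weight"] < 0:
            neg.add_edge(u, v, **d)
    prefix = "global-" if net.kind.startswith("global") else ""
    return (
        InteractionNetwork(pos, kind=f"{prefix}positive", rank=net.rank,
                           sites=net.sites),
        InteractionNetwork(neg, kind=f"{prefix}negative", rank=net.rank,
                           sites=net.sites),
    )


def global_network(site_nets: list[InteractionNetwork]) -> InteractionNetwork:
    """Pool site-level networks at one rank into a single global network.

    Nodes are unioned; an ordered pair occurring in several sites is merged
    to the mean weight (sign of the mean).  Pairs whose mean weight is
    exactly zero are sign-indeterminate and dropped with a warning.
    """
    if not site_nets:
        raise ValueError("at least one site network is required")
    ranks = {n.rank for n in site_nets}
    if len(ranks) > 1:
        raise ValueError(f"cannot pool networks across ranks: {sorted(ranks)}")
    g = nx.DiGraph()
    weights: dict[tuple, list[float]] = {}
    for net in site_nets:
        g.add_nodes_from(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            weights.setdefault((u, v), []).append(d["weight"])
    dropped = 0
    for (u, v), ws in weights.items():
        w = float(np.mean(ws))
        if w == 0:
            dropped += 1
            continue
        g.add_edge(u, v, weight=w, sign=int(np.sign(w)))
    if dropped:
        warnings.warn(
            f"{dropped} edge(s) with mean weight exactly 0 dropped from the "
            "global network (sign-indeterminate)",
            stacklevel=2,
        )
    sites = tuple(s for net in site_nets for s in net.sites)
    return InteractionNetwork(g, kind="global", rank=ranks.pop(), sites=sites)


def interaction_fractions(net: InteractionNetwork) -> tuple[float, float]:
    """(fraction of positive edges, fraction of negative edges); sums to 1."""
    signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
    if not signs:
        raise ValueError("network has no edges")
    pos = sum(1 for s in signs if s > 0)
    return pos / len(signs), (len(signs) - pos) / len(signs)


def mean_interaction_fractions(nets: list[InteractionNetwork]) -> tuple[float, float, float, float]:
    """Mean and std of the positive/negative fractions across networks.

    Returns (mean_pos, std_pos, mean_neg, std_neg), the per-network
    fractions averaged e.g. across taxonomic ranks.
    """
    fracs = np.asarray([interaction_fractions(n) for n in nets])
    return (
        float(fracs[:, 0].mean()), float(fracs[:, 0].std()),
        float(fracs[:, 1].mean()), float(fracs[:, 1].std()),
    )
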