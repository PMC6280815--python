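"""Synthetic multi-site time-series metagenomic studies.

Generates communities with the statistical structure the downstream network
analysis assumes: a known generalized Lotka-Volterra (gLV) model drives the
dynamics, per-taxon abundance scales are heavy-tailed (lognormal) so that a
target fraction of taxa stays below the rare-biosphere threshold in every
sample, a configurable core of taxa is present in all samples, genera carry
complete five-rank lineages, and each sample gets a protein-domain content
table for pathway-completeness profiling.

The default study design mirrors a 3-site x 4-time-point field campaign
(12 samples) with the first time point sampled under dry conditions and the
rest wet.  Because the ground-truth model is known, interaction inference
can be validated by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glv import GLVDivergenceError, GLVModel, TimeSeries, simulate_glv
from .tables import RANKS, AbundanceTable, TaxonomyMap, aggregate_to_rank

__all__ = [
    "StudyDesign",
    "SyntheticStudy",
    "PathwayDefinition",
    "generate_taxonomy",
    "generate_glv_model",
    "generate_study",
    "generate_pathways",
]

#: default ratio of distinct taxa at each rank relative to genus count,
#: loosely following observed metagenome rank cardinalities
_RANK_RATIOS = {"family": 0.38, "order": 0.21, "class": 0.12, "phylum": 0.07}


@dataclass
class StudyDesign:
    """Sampling layout: sites x time points, with per-sample conditions."""

    n_sites: int = 3
    n_timepoints: int = 4
    site_labels: tuple = ()
    conditions: dict = field(default_factory=dict)  # sample_id -> dry/wet
    t_end: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not self.site_labels:
            self.site_labels = tuple(
                chr(ord("A") + k) for k in range(self.n_sites)
            )
        if len(self.site_labels) != self.n_sites:
            raise ValueError("site_labels length must equal n_sites")
        if not self.conditions:
            # first time point dry, the rest wet
            self.conditions = {
                sid: ("dry" if t == 1 else "wet")
                for sid, t in self._sample_iter()
            }

    def _sample_iter(self):
        for site in self.site_labels:
            for t in range(1, self.n_timepoints + 1):
                yield f"{site}{t}", t

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self._sample_iter()]

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_timepoints

    def metadata(self) -> pd.DataFrame:
        rows = []
        for site in self.site_labels:
            for t in range(1, self.n_timepoints + 1):
                sid = f"{site}{t}"
                rows.append(
                    {"sample_id": sid, "site": site, "time": t,
                     "condition": self.conditions[sid]}
                )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class PathwayDefinition:
    """A named metabolic pathway defined by its protein-domain repertoire."""

    pathway_id: str
    domains: frozenset

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty domain set")


@dataclass
class SyntheticStudy:
    """A complete generated study: truth model, tables, taxonomy, pathways."""

    design: StudyDesign
    truth_model: GLVModel
    tables_by_rank: dict[str, AbundanceTable]
    taxonomy: TaxonomyMap
    pathways: list[PathwayDefinition] = field(default_factory=list)
    domain_table: dict[str, set] = field(default_factory=dict)
    fine_series: dict[str, TimeSeries] = field(default_factory=dict)
    observed_series: dict[str, TimeSeries] = field(default_factory=dict)

    @property
    def genus_table(self) -> AbundanceTable:
        return self.tables_by_rank["genus"]


def generate_taxonomy(
    n_genera: int, shape: float = 2.0, seed: int | None = None
) -> TaxonomyMap:
    """Random five-rank taxonomy for ``n_genera`` genera.

    Parent assignment at each rank uses Dirichlet(shape) weights, producing
    unevenly sized clades; distinct-taxon counts are non-increasing from
    genus up to phylum by construction.
    """
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    rng = np.random.default_rng(seed)
    genera = [f"g{k:04d}" for k in range(n_genera)]
    lineage = pd.DataFrame(index=pd.Index(genera, name="taxon_id"))
    lineage["genus"] = genera
    child_labels = genera
    for rank in ("family", "order", "class", "phylum"):
        n_parents = max(1, round(len(set(child_labels)) * _RANK_RATIOS[rank]
                                 / (_RANK_RATIOS.get(_below(rank), 1.0))))
        n_parents = min(n_parents, len(set(child_labels)))
        weights = rng.dirichlet(np.full(n_parents, shape))
        parents = [f"{rank[0]}{k:04d}" for k in range(n_parents)]
        # assign each distinct child clade to one parent
        child_ids = sorted(set(child_labels))
        assignment = {
            c: parents[int(rng.choice(n_parents, p=weights))] for c in child_ids
        }
        col = [assignment[c] for c in lineage[_below(rank)]]
        lineage[rank] = col
        child_labels = col
    return TaxonomyMap(lineage[list(RANKS)])


def _below(rank: str) -> str:
    return RANKS[RANKS.index(rank) + 1]


def generate_glv_model(
    equilibrium: np.ndarray,
    taxa: list,
    connectance: float = 0.3,
    interaction_scale: float = 0.5,
    seed: int | None = None,
) -> GLVModel:
    """Random stable gLV model with a prescribed interior equilibrium.

    Self-limitation sets a_ii = -d_i / x*_i; off-diagonal interactions are
    sparse Gaussian, row-rescaled so the community Jacobian at x* is
    strictly diagonally dominant (hence stable); r = -A x* makes x* an
    exact fixed point.
    """
    x_star = np.asarray(equilibrium, dtype=float)
    n = x_star.size
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.5, 1.5, n)
    A = np.zeros((n, n))
    mask = rng.random((n, n)) < connectance
    np.fill_diagonal(mask, False)
    A[mask] = rng.normal(0.0, 1.0, int(mask.sum()))
    # Gershgorin: row i of the Jacobian diag(x*) A has center -d_i and
    # radius x*_i * sum_j |a_ij|; keep the radius at most interaction_scale*d_i
    for i in range(n):
        rad = x_star[i] * np.abs(A[i]).sum()
        if rad > 0:
            A[i] *= interaction_scale * d[i] / rad
    np.fill_diagonal(A, -d / x_star)
    r = -A @ x_star
    return GLVModel(list(taxa), r, A)


def _equilibrium_profile(
    n_genera: int, rb_target: float, rb_threshold: float, rng: np.random.Generator,
    tail_sigma: float = 1.5,
) -> np.ndarray:
    """Heavy-tailed relative-abundance equilibrium hitting the RB target.

    Lognormal draws are split into an abundant block (floored well above the
    rare-biosphere threshold) and a rare tail (capped well below it), so the
    realized fraction of sub-threshold taxa tracks ``rb_target`` even after
    the dynamics perturb abundances.
    """
    n_ab = int(round((1.0 - rb_target) * n_genera))
    if n_ab == 0:
        if n_genera * rb_threshold / 2.0 <= 1.0:
            raise ValueError(
                f"rb_target={rb_target} with n_genera={n_genera} is impossible: "
                "all-rare taxa cannot sum to a full community"
            )
        raw = np.sort(rng.lognormal(0.0, tail_sigma, n_genera))[::-1]
        x = raw / raw.sum()
        return np.minimum(x, rb_threshold / 2.0) / np.minimum(
            x, rb_threshold / 2.0
        ).sum()
    raw = np.sort(rng.lognormal(0.0, tail_sigma, n_genera))[::-1]
    abundant_raw, rare_raw = raw[:n_ab], raw[n_ab:]
    x = np.empty(n_genera)
    if rare_raw.size:
        # rare tail: keep every value at most half the threshold
        budget = min(0.2, 0.45 * rb_threshold * rare_raw.size)
        scale = min(budget / rare_raw.sum(), 0.4 * rb_threshold / rare_raw.max())
        x[n_ab:] = rare_raw * scale
        rare_mass = float(x[n_ab:].sum())
    else:
        rare_mass = 0.0
    mass = 1.0 - rare_mass
    floor = min(2.0 * rb_threshold, 0.5 * mass / n_ab)
    x[:n_ab] = floor + abundant_raw / abundant_raw.sum() * (mass - floor * n_ab)
    return x / x.sum()


def generate_study(
    design: StudyDesign,
    n_genera: int = 200,
    rb_target: float = 0.97,
    core_fraction: float = 0.25,
    noise_sd: float = 0.0,
    depth: int = 100_000,
    rb_threshold: float = 0.01,
    n_internal_steps: int = 40,
    x0_jitter: float = 0.3,
    seed: int | None = None,
) -> SyntheticStudy:
    """Generate a full synthetic study driven by a known gLV model.

    Per site, abundances follow a forward-simulated gLV trajectory started
    near the model's equilibrium, observed at ``design.n_timepoints`` points
    subsampled from a finer internal grid.  Counts are Poisson draws at
    fixed ``depth`` with multiplicative lognormal noise ``noise_sd`` (with
    ``noise_sd=0`` counts are deterministic roundings, so a system started
    exactly at equilibrium yields identical time points).  At least
    ``core_fraction`` of genera are present in every sample; the fraction
    of genera below ``rb_threshold`` relative abundance in every sample
    approximates ``rb_target``.
    """
    if not 0.0 <= rb_target <= 1.0:
        raise ValueError("rb_target must be in [0, 1]")
    if not 0.0 <= core_fraction <= 1.0:
        raise ValueError("core_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(seed, np.random.SeedSequence):
        master = seed
    else:
        master = np.random.SeedSequence(design.seed if seed is None else seed)
    s_tax, s_eq, s_model, s_dyn, s_obs, s_path = master.spawn(6)

    taxonomy = generate_taxonomy(n_genera, seed=s_tax)
    genera = list(taxonomy.lineage.index)
    rng_eq = np.random.default_rng(s_eq)
    x_star = _equilibrium_profile(n_genera, rb_target, rb_threshold, rng_eq)
    model = generate_glv_model(x_star, genera, seed=s_model)

    times_fine = np.linspace(0.0, design.t_end, n_internal_steps + 1)
    obs_idx = np.linspace(0, n_internal_steps, design.n_timepoints).round().astype(int)
    rng_dyn = np.random.default_rng(s_dyn)
    rng_obs = np.random.default_rng(s_obs)

    fine, observed = {}, {}
    counts = pd.DataFrame(0, index=pd.Index(genera, name="taxon_id"),
                          columns=design.sample_ids, dtype=int)
    n_core = int(np.ceil(core_fraction * n_genera))
    core_set = genera[:n_core]  # most abundant block first (sorted profile)

    for site in design.site_labels:
        x0 = x_star * np.exp(rng_dyn.uniform(-x0_jitter, x0_jitter, n_genera))
        traj = _simulate_with_damping(model, x0, times_fine)
        fine[site] = traj
        obs_times = times_fine[obs_idx]
        obs_values = traj.values[:, obs_idx]
        observed[site] = TimeSeries(genera, obs_times, obs_values)
        for k, t in enumerate(range(1, design.n_timepoints + 1)):
            sid = f"{site}{t}"
            col = obs_values[:, k]
            rel = col / col.sum()
            expected = depth * rel
            if noise_sd > 0:
                lam = expected * rng_obs.lognormal(0.0, noise_sd, n_genera)
                c = rng_obs.poisson(lam)
            else:
                c = np.round(expected).astype(int)
            counts[sid] = c
    counts.loc[core_set] = counts.loc[core_set].clip(lower=1)

    meta = design.metadata()
    genus_table = AbundanceTable(counts, rank="genus", meta=meta)
    tables = {"genus": genus_table}
    for rank in ("family", "order", "class", "phylum"):
        tables[rank] = aggregate_to_rank(genus_table, taxonomy, rank)

    pathways, domain_table = generate_pathways(
        n_pathways=8, domains_per_pathway=6, seed=s_path,
        samples=design.sample_ids,
    )
    return SyntheticStudy(
        design=design, truth_model=model, tables_by_rank=tables,
        taxonomy=taxonomy, pathways=pathways, domain_table=domain_table,
        fine_series=fine, observed_series=observed,
    )


def _simulate_with_damping(model: GLVModel, x0, times, max_retries: int = 5):
    """Forward-simulate; on divergence, damp interactions and retry."""
    current = model
    for attempt in range(max_retries):
        try:
            return simulate_glv(current, x0, times)
        except GLVDivergenceError:
            warnings.warn(
                "gLV trajectory diverged; damping off-diagonal interactions "
                f"(attempt {attempt + 1})",
                stacklevel=2,
            )
            A = current.A.copy()
            diag = np.diag(A).copy()
            A *= 0.5
            np.fill_diagonal(A, diag)
            current = GLVModel(current.taxa, current.r, A)
    raise GLVDivergenceError("gLV trajectory diverged even after damping")


def generate_pathways(
    n_pathways: int,
    domains_per_pathway: int,
    seed: int | None = None,
    samples: list[str] | None = None,
    presence_prob: float = 0.7,
) -> tuple[list[PathwayDefinition], dict[str, set]]:
    """Random pathway -> protein-domain definitions plus per-sample domains.

    Each pathway is a named set of distinct Pfam-style domain identifiers;
    the domain table assigns each sample a random subset of the full domain
    universe (each domain present independently with ``presence_prob``).
    """
    if n_pathways < 1 or domains_per_pathway < 1:
        raise ValueError("n_pathways and domains_per_pathway must be >= 1")
    rng = np.random.default_rng(seed)
    universe = [
        f"PF{k:05d}" for k in range(1, n_pathways * domains_per_pathway + 1)
    ]
    pathways = []
    for p in range(n_pathways):
        dom = universe[p * domains_per_pathway:(p + 1) * domains_per_pathway]
        pathways.append(PathwayDefinition(f"pathway_{p:02d}", frozenset(dom)))
    domain_table: dict[str, set] = {}
    for sid in samples or []:
        keep = rng.random(len(universe)) < presence_prob
        domain_table[sid] = {d for d, k in zip(universe, keep) if k}
    return pathways, domain_table
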