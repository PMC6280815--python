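"""End-to-end orchestration: synthetic (or user) data -> report bundle.

A single :class:`PipelineConfig` drives every stage in dependency order:
abundance tables at each taxonomic rank, per-sample diversity, dry-vs-wet
Welch differential proportions, per-site interaction inference and
consensus / positive / negative networks at every rank, a pooled global
network (plus its sign-split views) per rank, topology panels against
G(n, m) baselines, 3-node motif censuses with randomization significance,
keystone reports, and pathway completeness.  For a design with S sites and
R ranks the network inventory always holds S*R*3 + R*3 networks (three
site-level variants per site and rank, plus three global variants per
rank); the field design of 3 sites and 4 ranks yields 48.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import glv, motifs, topology
from .keystone import keystone_frame, keystone_report
from .completeness import pathway_completeness
from .synthetic import StudyDesign, SyntheticStudy, generate_study
from .tables import core_and_rare, relative_abundance

log = logging.getLogger("tsen.pipeline")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_network_tsv"]


@dataclass
class PipelineConfig:
    """All thresholds and sizes of one pipeline run.

    The analysis constants default to the standard study settings: rare-
    biosphere threshold 0.01, top-0.05% display filter, 1600 candidate
    models, 100 random networks and 100 motif randomizations, motif p cut
    0.05, Welch p cut 0.005, ranks phylum through family.
    """

    rb_threshold: float = 0.01
    top_display_fraction: float = 0.0005
    n_candidates: int = 1600
    top_k: int = 100
    agreement: float = 0.5
    n_random_networks: int = 100
    n_motif_randomizations: int = 100
    motif_p_cut: float = 0.05
    welch_p_cut: float = 0.005
    ranks: tuple = ("phylum", "class", "order", "family")
    seed: int = 0
    # synthetic-study knobs
    n_sites: int = 3
    n_timepoints: int = 4
    n_genera: int = 200
    rb_target: float = 0.97
    core_fraction: float = 0.25
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rb_threshold", "top_display_fraction", "agreement",
                     "motif_p_cut", "welch_p_cut"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("n_candidates", "top_k", "n_random_networks",
                     "n_motif_randomizations", "n_sites", "n_timepoints",
                     "n_genera"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.top_k > self.n_candidates:
            raise ValueError("top_k cannot exceed n_candidates")
        self.ranks = tuple(self.ranks)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranks"] = list(self.ranks)
        return d


@dataclass
class RunManifest:
    """Record of one pipeline run: config, outputs with content hashes,
    and the network inventory."""

    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    networks: list[dict] = field(default_factory=list)
    hashes: dict[str, str] = field(default_factory=dict)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def hash_outputs(self) -> None:
        import hashlib

        for key, path in self.outputs.items():
            p = Path(path)
            if p.is_file():
                self.hashes[key] = hashlib.sha256(p.read_bytes()).hexdigest()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "outputs": self.outputs,
                 "networks": self.networks, "hashes": self.hashes},
                fh, indent=2, sort_keys=True,
            )


def read_network_tsv(path, kind: str = "consensus",
                     rank: str = "family") -> glv.InteractionNetwork:
    """Load an interaction network from an edge-list TSV."""
    import networkx as nx

    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight),
                   sign=int(np.sign(row.weight)))
    return glv.InteractionNetwork(g, kind=kind, rank=rank)


def _site_series(study: SyntheticStudy, site: str, rank: str) -> glv.TimeSeries:
    """Observed counts of one site at one rank as a TimeSeries."""
    table = study.tables_by_rank[rank]
    cols = [f"{site}{t}" for t in range(1, study.design.n_timepoints + 1)]
    times = np.linspace(0.0, study.design.t_end, study.design.n_timepoints)
    values = table.data[cols].to_numpy(dtype=float)
    return glv.TimeSeries(list(table.data.index), times, values)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # abort with stage name and cause
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    study: SyntheticStudy | None = None,
) -> RunManifest:
    """Execute every stage and write a deterministic report bundle.

    With ``study=None`` a synthetic study is generated from the config's
    design knobs and master seed; re-running with the same config and seed
    reproduces every numeric output exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    master = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("study", "infer", "topology", "motifs"), master.spawn(4))}

    if study is None:
        design = StudyDesign(n_sites=config.n_sites,
                             n_timepoints=config.n_timepoints,
                             seed=config.seed)
        study = generate_study(
            design, n_genera=config.n_genera, rb_target=config.rb_target,
            core_fraction=config.core_fraction, noise_sd=config.noise_sd,
            rb_threshold=config.rb_threshold, seed=seeds["study"],
        )

    try:
        _write_tables(study, out, manifest)
        _diversity_stage(config, study, out, manifest)
        nets = _network_stage(config, study, out, manifest, seeds["infer"])
        _topology_stage(config, nets, out, manifest, seeds["topology"])
        _motif_stage(config, nets, out, manifest, seeds["motifs"])
        _keystone_stage(config, study, nets, out, manifest)
        _completeness_stage(study, out, manifest)
    except Exception:
        _quarantine_partial_outputs(out)
        raise

    expected = (config.n_sites * len(config.ranks) * 3
                + len(config.ranks) * 3)
    if manifest.n_networks != expected:
        raise RuntimeError(
            f"network inventory has {manifest.n_networks} entries, "
            f"expected {expected}"
        )
    manifest.hash_outputs()
    manifest.to_json(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def _quarantine_partial_outputs(out: Path) -> None:
    """Move whatever a failed run already wrote under a failed/ prefix."""
    failed = out / "failed"
    failed.mkdir(exist_ok=True)
    for child in list(out.iterdir()):
        if child.name == "failed":
            continue
        child.rename(failed / child.name)


@_stage("tables")
def _write_tables(study: SyntheticStudy, out: Path, manifest: RunManifest):
    tdir = out / "tables"
    tdir.mkdir(exist_ok=True)
    for rank, table in study.tables_by_rank.items():
        p = tdir / f"abundance_{rank}.tsv"
        table.to_tsv(p)
        manifest.outputs[f"table_{rank}"] = str(p)
    study.taxonomy.to_tsv(tdir / "taxonomy.tsv")
    meta = study.design.metadata()
    meta.to_csv(tdir / "metadata.tsv", sep="\t")
    study.truth_model.to_json(tdir / "truth_model.json")
    manifest.outputs["taxonomy"] = str(tdir / "taxonomy.tsv")
    manifest.outputs["metadata"] = str(tdir / "metadata.tsv")
    manifest.outputs["truth_model"] = str(tdir / "truth_model.json")


@_stage("diversity")
def _diversity_stage(config, study, out: Path, manifest: RunManifest):
    table = study.genus_table
    rows = []
    for sid in table.samples:
        rep = dv.alpha_diversity(table.data[sid].to_numpy())
        rows.append({"sample_id": sid, **rep.to_dict()})
    p = out / "diversity.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    manifest.outputs["diversity"] = str(p)

    rel = relative_abundance(table).data
    meta = study.design.metadata()
    dry = [s for s in table.samples if meta.loc[s, "condition"] == "dry"]
    wet = [s for s in table.samples if meta.loc[s, "condition"] == "wet"]
    if dry and wet:
        res = dv.welch_differential(rel[dry], rel[wet],
                                    p_cut=config.welch_p_cut)
        p = out / "differential_dry_vs_wet.tsv"
        dv.differential_to_frame(res).to_csv(p, sep="\t", index=False)
        manifest.outputs["differential"] = str(p)

    flags = core_and_rare(table, rb_threshold=config.rb_threshold)
    p = out / "core_rare_flags.tsv"
    flags.to_frame().to_csv(p, sep="\t")
    manifest.outputs["core_rare"] = str(p)


@_stage("networks")
def _network_stage(config, study, out: Path, manifest: RunManifest, seed):
    ndir = out / "networks"
    ndir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    nets: dict[tuple, glv.InteractionNetwork] = {}
    frac_rows = []
    for rank in config.ranks:
        site_nets = []
        for site in study.design.site_labels:
            ts = _site_series(study, site, rank)
            cands = glv.infer_candidates(
                ts, n_candidates=config.n_candidates,
                seed=int(rng.integers(2**31)),
            )
            cons = glv.consensus_network(
                cands, top_k=config.top_k, agreement=config.agreement,
                rank=rank, site=site,
            )
            pos, neg = glv.split_by_sign(cons)
            site_nets.append(cons)
            for net, kind in ((cons, "consensus"), (pos, "positive"),
                              (neg, "negative")):
                _register(net, f"{site}_{rank}_{kind}", ndir, manifest, nets,
                          key=(site, rank, kind))
            if cons.n_edges:
                fp, fn = glv.interaction_fractions(cons)
                frac_rows.append({"site": site, "rank": rank,
                                  "positive": fp, "negative": fn})
        gl = glv.global_network(site_nets)
        gpos, gneg = glv.split_by_sign(gl)
        for net, kind in ((gl, "global"), (gpos, "global-positive"),
                          (gneg, "global-negative")):
            _register(net, f"global_{rank}_{kind}", ndir, manifest, nets,
                      key=("global", rank, kind))
    if frac_rows:
        p = out / "interaction_fractions.tsv"
        pd.DataFrame(frac_rows).to_csv(p, sep="\t", index=False)
        manifest.outputs["interaction_fractions"] = str(p)
    return nets


def _register(net, name, ndir: Path, manifest: RunManifest, nets, key):
    p = ndir / f"{name}.tsv"
    net.to_tsv(p)
    nets[key] = net
    manifest.networks.append(
        {"name": name, "site": key[0], "rank": key[1], "kind": key[2],
         "n_nodes": net.n_nodes, "n_edges": net.n_edges, "path": str(p)}
    )


@_stage("topology")
def _topology_stage(config, nets, out: Path, manifest: RunManifest, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for (site, rank, kind), net in nets.items():
        if net.n_nodes < 2:
            continue
        rep = topology.compare_to_null(
            net, reps=config.n_random_networks, seed=int(rng.integers(2**31))
        )
        frame = rep.to_frame()
        frame.insert(0, "site", site)
        frame.insert(1, "rank", rank)
        frame.insert(2, "kind", kind)
        rows.append(frame)
    p = out / "topology.tsv"
    pd.concat(rows, ignore_index=True).to_csv(p, sep="\t", index=False)
    manifest.outputs["topology"] = str(p)


@_stage("motifs")
def _motif_stage(config, nets, out: Path, manifest: RunManifest, seed):
    rng = np.random.default_rng(seed)
    rows = []
    by_group: dict[tuple, dict[str, motifs.MotifCensus]] = {}
    for (site, rank, kind), net in nets.items():
        if net.n_edges == 0 or net.n_nodes < 3:
            census = motifs.motif_census(net)
            pvals = None
        else:
            census = motifs.motif_significance(
                net, n_rand=config.n_motif_randomizations,
                seed=int(rng.integers(2**31)),
            )
            pvals = census.p_values
        by_group.setdefault((site, kind), {})[rank] = census
        for mid in motifs.TRIAD_IDS:
            rows.append({
                "site": site, "rank": rank, "kind": kind, "motif_id": mid,
                "count": census.counts[mid],
                "p_value": None if pvals is None else pvals[mid],
            })
    df = pd.DataFrame(rows)
    norm_rows = []
    for (site, kind), censuses in by_group.items():
        norm = motifs.normalize_across_ranks(censuses)
        for mid, row in norm.iterrows():
            for rank, v in row.items():
                norm_rows.append({"site": site, "kind": kind, "rank": rank,
                                  "motif_id": mid, "normalized": v})
    df = df.merge(pd.DataFrame(norm_rows),
                  on=["site", "kind", "rank", "motif_id"], how="left")
    p = out / "motifs.tsv"
    df.to_csv(p, sep="\t", index=False)
    manifest.outputs["motifs"] = str(p)


@_stage("keystones")
def _keystone_stage(config, study, nets, out: Path, manifest: RunManifest):
    rank = config.ranks[-1]  # finest analyzed rank (family by default)
    flags = core_and_rare(study.tables_by_rank[rank],
                          rb_threshold=config.rb_threshold)
    frames = []
    sites = list(study.design.site_labels) + ["global"]
    for site in sites:
        kinds = {
            kind: net for (s, r, kind), net in nets.items()
            if s == site and r == rank
        }
        recs = keystone_report(kinds, flags=flags)
        frame = keystone_frame(recs)
        if not frame.empty:
            frame.insert(0, "site", site)
            frames.append(frame)
    p = out / "keystones.tsv"
    pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False)
    manifest.outputs["keystones"] = str(p)


@_stage("completeness")
def _completeness_stage(study, out: Path, manifest: RunManifest):
    if not study.pathways:
        return
    prof = pathway_completeness(study.domain_table, study.pathways)
    p = out / "completeness.tsv"
    prof.to_csv(p, sep="\t")
    manifest.outputs["completeness"] = str(p)
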