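"""Pathway completeness: percent of a pathway's domain repertoire detected.

Metabolic completeness of a pathway in a sample is the percentage of the
pathway's defining protein-domain set (e.g. Pfam accessions) present in
that sample: 100 * |pathway ∩ sample| / |pathway|.  Presence is binary
(at least one occurrence); completeness is a property of the repertoire,
not of domain abundance.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import pandas as pd

from .synthetic import PathwayDefinition

__all__ = ["pathway_completeness", "load_pathways", "load_domain_table"]


def pathway_completeness(
    sample_domains: Mapping[str, Iterable],
    pathways: Iterable[PathwayDefinition],
) -> pd.DataFrame:
    """Samples x pathways completeness matrix, in percent [0, 100].

    100% iff every domain of the pathway is present in the sample; 0% iff
    none is.  Adding domains to a sample can never decrease a value.
    """
    pathways = list(pathways)
    if not pathways:
        raise ValueError("at least one pathway definition is required")
    for p in pathways:
        if not p.domains:
            raise ValueError(f"pathway {p.pathway_id!r} has an empty domain set")
    rows = {}
    for sid, domains in sample_domains.items():
        present = set(domains)
        rows[sid] = {
            p.pathway_id: 100.0 * len(p.domains & present) / len(p.domains)
            for p in pathways
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out.sort_index()


def load_pathways(path) -> list[PathwayDefinition]:
    """Pathway definitions from JSON ({id: [domains]}) or 2-column TSV."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        return [PathwayDefinition(k, frozenset(v)) for k, v in raw.items()]
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("pathway TSV needs columns (pathway_id, domain)")
    pid, dom = df.columns[:2]
    return [
        PathwayDefinition(str(k), frozenset(g[dom].astype(str)))
        for k, g in df.groupby(pid)
    ]


def load_domain_table(path) -> dict[str, set]:
    """Per-sample domain sets from a (sample_id, domain[, count]) TSV.

    Rows with a count column equal to 0 are treated as absent.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("domain TSV needs columns (sample_id, domain[, count])")
    sid, dom = df.columns[:2]
    if df.shape[1] > 2:
        df = df[df[df.columns[2]] > 0]
    return {str(k): set(g[dom].astype(str)) for k, g in df.groupby(sid)}
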