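"""Keystone-taxon reporting: network hubs annotated with ecology flags.

A hub is a node attaining the maximum in-degree (affected by n others) or
maximum out-degree (affecting n others) in a network.  The report joins
each hub, per network kind and direction, with its core / rare-biosphere
membership and user-supplied trait labels (e.g. "PG" for public-goods
providers).  Annotation is a pure join -- traits are an input, never
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .glv import InteractionNetwork
from .tables import CoreRBFlags
from .topology import find_hubs

__all__ = ["KeystoneRecord", "keystone_report", "keystone_frame"]


@dataclass
class KeystoneRecord:
    """One hub in one network, with membership flags and trait labels."""

    taxon: object
    kind: str  # consensus / positive / negative / global ...
    direction: str  # "max_in" (affected by n) or "max_out" (affecting n)
    degree: int
    is_core: bool | None  # None = taxon missing from the flags (unknown)
    is_rare: bool | None
    traits: frozenset = field(default_factory=frozenset)


def _flag(flags: CoreRBFlags | None, series_name: str, taxon) -> bool | None:
    if flags is None:
        return None
    series = getattr(flags, series_name)
    if taxon in series.index:
        return bool(series[taxon])
    return None


def keystone_report(
    nets: Mapping[str, InteractionNetwork],
    flags: CoreRBFlags | None = None,
    traits: Mapping[object, set] | None = None,
) -> list[KeystoneRecord]:
    """Hubs of each network kind, annotated with core/RB flags and traits.

    One record per hub per (kind, direction); ties at the maximum degree
    yield multiple records.  Taxa missing from ``flags`` get unknown (None)
    flags rather than being dropped; taxa missing from ``traits`` get an
    empty trait set.
    """
    traits = traits or {}
    records: list[KeystoneRecord] = []
    for kind, net in nets.items():
        if net.n_edges == 0:
            continue
        hubs_in, hubs_out, max_in, max_out = find_hubs(net)
        for direction, hubs, deg in (
            ("max_in", hubs_in, max_in),
            ("max_out", hubs_out, max_out),
        ):
            for taxon in hubs:
                records.append(
                    KeystoneRecord(
                        taxon=taxon, kind=kind, direction=direction, degree=deg,
                        is_core=_flag(flags, "is_core", taxon),
                        is_rare=_flag(flags, "is_rare", taxon),
                        traits=frozenset(traits.get(taxon, ())),
                    )
                )
    return records


def keystone_frame(records: list[KeystoneRecord]) -> pd.DataFrame:
    """TSV-ready table: (kind, direction, taxon, n, flags, traits)."""
    return pd.DataFrame(
        [
            {
                "kind": r.kind, "direction": r.direction, "taxon": r.taxon,
                "n": r.degree, "is_core": r.is_core, "is_rare": r.is_rare,
                "traits": ",".join(sorted(r.traits)),
            }
            for r in records
        ]
    )
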