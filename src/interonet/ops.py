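"""Orthologous protein sets (OPS): the nodes of the conserved network.

An OPS contains exactly one protein per analysis species, all pairwise
reciprocal best hits — a one-per-species k-clique of the k-partite RBH
graph.  Because RBH gives every protein at most one partner per other
species, the cliques are pairwise disjoint and can be enumerated by
following partner links from the first species and verifying closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .orthology import OrthologyMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OPS:
    """One conserved node: species -> member accession."""

    ops_id: str
    members: Mapping[str, str]

    def member_pair(self, species_id: str) -> str:
        return self.members[species_id]


def _pair_key(s: str, t: str) -> tuple[str, str]:
    return (s, t) if s <= t else (t, s)


def index_maps(
    maps: Sequence[OrthologyMap] | Mapping[tuple[str, str], OrthologyMap],
) -> dict[tuple[str, str], OrthologyMap]:
    if isinstance(maps, Mapping):
        return {_pair_key(*k): v for k, v in maps.items()}
    return {_pair_key(m.species_a, m.species_b): m for m in maps}


def build_ops(
    orthology_maps: Sequence[OrthologyMap] | Mapping[tuple[str, str], OrthologyMap],
    species: Sequence[str],
) -> list[OPS]:
    """Every one-per-species k-clique of the RBH graph, as OPS nodes.

    Requires one orthology map per unordered species pair.  Node IDs
    ``OPS1..OPSn`` are assigned after sorting cliques by the first
    species' member accession, so runs are diffable.
    """
    species = list(species)
    k = len(species)
    if k < 2:
        raise ValueError("need at least two species")
    by_pair = index_maps(orthology_maps)
    for s, t in combinations(species, 2):
        if _pair_key(s, t) not in by_pair:
            raise ValueError(f"missing orthology map for species pair ({s}, {t})")

    partner: dict[tuple[str, str], dict[str, str]] = {}
    for s, t in combinations(species, 2):
        omap = by_pair[_pair_key(s, t)]
        partner[(s, t)] = omap.partner_of(s)
        partner[(t, s)] = omap.partner_of(t)

    anchor = species[0]
    cliques: list[dict[str, str]] = []
    for acc in sorted(partner[(anchor, species[1])]) if k > 1 else []:
        members = {anchor: acc}
        for t in species[1:]:
            p = partner[(anchor, t)].get(acc)
            if p is None:
                break
            members[t] = p
        if len(members) < k:
            continue
        # closure: every non-anchor pair must also be an RBH pair
        closed = all(
            partner[(s, t)].get(members[s]) == members[t]
            for s, t in combinations(species[1:], 2)
        )
        if closed:
            cliques.append(members)

    cliques.sort(key=lambda m: m[anchor])
    ops_list = [OPS(f"OPS{i + 1}", members) for i, members in enumerate(cliques)]
    log.info("built %d OPS across %d species", len(ops_list), k)
    return ops_list


def ops_members(ops_list: Sequence[OPS], species_id: str) -> set[str]:
    """All member accessions of one species across the OPS list."""
    return {ops.members[species_id] for ops in ops_list}
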