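"""Conserved-network extraction: the interolog protein network (IPN).

For every pair of OPS nodes the *coverage* is the number of species in
which the two member proteins interact in that species' filtered,
OPS-restricted network.  An IPN edge is drawn when coverage reaches the
coverage cutoff (inclusive, so requiring conservation in all k species
remains satisfiable).  Isolated OPS nodes are kept: they are legitimate
conserved proteins even when none of their interactions is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .ops import OPS
from .ppin import SpeciesNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IPNEdge:
    """A conserved interaction between two OPS nodes."""

    ops_i: str
    ops_j: str
    coverage: int
    supporting_species: frozenset[str]


@dataclass
class IPN:
    """The conserved network: OPS nodes, covered edges, and the run knobs."""

    nodes: list[OPS]
    edges: list[IPNEdge]
    params: dict = field(default_factory=dict)

    @property
    def node_ids(self) -> list[str]:
        return [ops.ops_id for ops in self.nodes]


def coverage(
    ops_i: OPS,
    ops_j: OPS,
    networks: Mapping[str, SpeciesNetwork],
) -> tuple[int, set[str]]:
    """How many species support the interaction between two OPS nodes."""
    supporting: set[str] = set()
    for species_id in ops_i.members:
        if species_id not in networks:
            raise ValueError(f"no network provided for species {species_id!r}")
        net = networks[species_id]
        if net.has_edge(ops_i.members[species_id], ops_j.members[species_id]):
            supporting.add(species_id)
    return len(supporting), supporting


def build_ipn(
    ops_list: Sequence[OPS],
    networks: Mapping[str, SpeciesNetwork],
    coverage_cutoff: int,
    params: dict | None = None,
) -> IPN:
    """Examine all OPS pairs and keep those with coverage >= cutoff."""
    k = len(networks)
    if ops_list:
        k = len(ops_list[0].members)
    if not 1 <= coverage_cutoff <= k:
        raise ValueError(
            f"coverage cutoff {coverage_cutoff} outside [1, {k}] for {k} species"
        )
    edges: list[IPNEdge] = []
    for ops_i, ops_j in combinations(ops_list, 2):
        count, supporting = coverage(ops_i, ops_j, networks)
        if count >= coverage_cutoff:
            edges.append(
                IPNEdge(ops_i.ops_id, ops_j.ops_id, count, frozenset(supporting))
            )
    run_params = dict(params or {})
    run_params["coverage_cutoff"] = coverage_cutoff
    log.info(
        "IPN: %d nodes, %d edges at coverage cutoff %d",
        len(ops_list), len(edges), coverage_cutoff,
    )
    return IPN(list(ops_list), edges, run_params)
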