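"""Stable serialization of the conserved network and run metadata.

Node and edge lists are TSV with fixed column orders, rows sorted by
node ID so diffs between runs are meaningful.  The graph itself is
exported as GraphML (interoperable with Cytoscape/igraph/Gephi) and DOT
(for GraphViz rendering).  A JSON run manifest records the tool version,
every parameter, input checksums, and per-stage counts; it contains no
timestamps so identical runs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .ipn import IPN, IPNEdge
from .ops import OPS
from .orthology import BestHit, OrthologyMap


def _ops_sort_key(ops_id: str):
    return (len(ops_id), ops_id)  # OPS2 before OPS10


def _edge_sort_key(edge: IPNEdge):
    return (_ops_sort_key(edge.ops_i), _ops_sort_key(edge.ops_j))


def write_node_list(ipn: IPN, path: str | Path, species: Sequence[str]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ops_id\t" + "\t".join(species) + "\n")
        for ops in sorted(ipn.nodes, key=lambda o: _ops_sort_key(o.ops_id)):
            fh.write(ops.ops_id + "\t" + "\t".join(ops.members[s] for s in species) + "\n")
    return path


def write_edge_list(ipn: IPN, path: str | Path, species: Sequence[str]) -> Path:
    path = Path(path)
    members = {ops.ops_id: ops.members for ops in ipn.nodes}
    with open(path, "w") as fh:
        fh.write(
            "ops_i\tops_j\tcoverage\tsupporting_species\t"
            + "\t".join(f"pair_{s}" for s in species)
            + "\n"
        )
        for e in sorted(ipn.edges, key=_edge_sort_key):
            pairs = [
                f"{members[e.ops_i][s]}--{members[e.ops_j][s]}" for s in species
            ]
            fh.write(
                f"{e.ops_i}\t{e.ops_j}\t{e.coverage}\t"
                + ",".join(sorted(e.supporting_species))
                + "\t"
                + "\t".join(pairs)
                + "\n"
            )
    return path


def read_ipn(nodes_path: str | Path, edges_path: str | Path) -> IPN:
    """Round-trip reader for the TSV pair written by this module."""
    node_lines = Path(nodes_path).read_text().splitlines()
    species = node_lines[0].split("\t")[1:]
    nodes = []
    for line in node_lines[1:]:
        fields = line.split("\t")
        nodes.append(OPS(fields[0], dict(zip(species, fields[1:]))))
    edges = []
    for line in Path(edges_path).read_text().splitlines()[1:]:
        fields = line.split("\t")
        support = frozenset(fields[3].split(",")) if fields[3] else frozenset()
        edges.append(IPNEdge(fields[0], fields[1], int(fields[2]), support))
    return IPN(nodes, edges)


def to_networkx(ipn: IPN, species: Sequence[str]) -> nx.Graph:
    g = nx.Graph()
    for ops in ipn.nodes:
        g.add_node(ops.ops_id, **{s: ops.members[s] for s in species})
    for e in ipn.edges:
        g.add_edge(
            e.ops_i,
            e.ops_j,
            coverage=e.coverage,
            supporting_species=",".join(sorted(e.supporting_species)),
        )
    return g


def write_graphml(ipn: IPN, path: str | Path, species: Sequence[str]) -> Path:
    path = Path(path)
    nx.write_graphml(to_networkx(ipn, species), str(path))
    return path


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_dot(ipn: IPN, path: str | Path, species: Sequence[str]) -> Path:
    """Undirected DOT graph; node labels list the member accessions."""
    path = Path(path)
    lines = ["graph IPN {", "  node [shape=ellipse];"]
    for ops in sorted(ipn.nodes, key=lambda o: _ops_sort_key(o.ops_id)):
        label = ops.ops_id + "\\n" + "\\n".join(
            f"{s}:{ops.members[s]}" for s in species
        )
        lines.append(f'  {_dot_quote(ops.ops_id)} [label="{label}"];')
    for e in sorted(ipn.edges, key=_edge_sort_key):
        lines.append(
            f"  {_dot_quote(e.ops_i)} -- {_dot_quote(e.ops_j)} "
            f'[label="{e.coverage}", weight={e.coverage}];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ipn(ipn: IPN, out_dir: str | Path, species: Sequence[str]) -> dict[str, Path]:
    """Write node TSV, edge TSV, GraphML, and DOT; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "nodes": write_node_list(ipn, out_dir / "ipn_nodes.tsv", species),
        "edges": write_edge_list(ipn, out_dir / "ipn_edges.tsv", species),
        "graphml": write_graphml(ipn, out_dir / "ipn.graphml", species),
        "dot": write_dot(ipn, out_dir / "ipn.dot", species),
    }


def write_best_hits(
    hits: Iterable[BestHit], species_a: str, species_b: str, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("species_a\taccession_a\tspecies_b\taccession_b\tsimilarity\ttie\n")
        for h in sorted(hits, key=lambda h: h.query):
            fh.write(
                f"{species_a}\t{h.query}\t{species_b}\t{h.subject}\t"
                f"{h.similarity:.4f}\t{int(h.tie_flag)}\n"
            )
    return path


def write_rbh(omap: OrthologyMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("species_a\taccession_a\tspecies_b\taccession_b\n")
        for a, b in sorted(omap.pairs):
            fh.write(f"{omap.species_a}\t{a}\t{omap.species_b}\t{b}\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
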