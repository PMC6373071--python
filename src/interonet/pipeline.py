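"""End-to-end orchestration: sequences in, conserved network out.

The pipeline is deterministic — same config, same outputs byte for byte.
Stages: load proteomes; all-vs-all alignment and reciprocal best hits per
species pair; assemble orthologous protein sets; load, confidence-filter
and restrict each species' interaction network; extract the conserved
network at the coverage cutoff; write all artifacts plus a run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import yaml

from . import __version__
from .alignment import AlignmentParams
from .ipn import IPN, build_ipn
from .ops import build_ops
from .orthology import best_hits, all_vs_all, reciprocal_best_hits
from .ppin import filter_by_score, read_edge_list, read_mapping, restrict_to_ops
from .seqio import read_accession_list, read_proteome
from . import writers

log = logging.getLogger(__name__)


@dataclass
class SpeciesInput:
    species_id: str
    accession_list: Path
    fasta: Path
    edges: Path
    mapping: Path | None = None


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    similarity_cutoff: float = 30.0
    similarity_mode: str = "identity"
    score_cutoff: int = 400
    coverage_cutoff: int | None = None  # None -> all species
    out_dir: Path = Path("results")
    strict: bool = False
    drop_isolated: bool = False

    def __post_init__(self) -> None:
        if not 2 <= len(self.species) <= 4:
            raise ValueError(
                f"analysis requires 2-4 species, got {len(self.species)}"
            )
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate species IDs: {ids}")
        if not 0 <= self.similarity_cutoff <= 100:
            raise ValueError("similarity cutoff must be in [0, 100]")
        if not 0 <= self.score_cutoff <= 1000:
            raise ValueError("score cutoff must be in [0, 1000]")
        if self.similarity_mode not in ("identity", "similarity"):
            raise ValueError(f"unknown similarity mode {self.similarity_mode!r}")
        k = len(self.species)
        if self.coverage_cutoff is not None and not 1 <= self.coverage_cutoff <= k:
            raise ValueError(
                f"coverage cutoff {self.coverage_cutoff} outside [1, {k}]"
            )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; relative paths resolve against the file."""
    path = Path(path)
    base = path.parent
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "species" not in raw:
        raise ValueError(f"{path}: config must be a mapping with a 'species' list")

    def _resolve(p):
        return (base / p).resolve() if p else None

    species = [
        SpeciesInput(
            species_id=str(entry["id"]),
            accession_list=_resolve(entry["accessions"]),
            fasta=_resolve(entry["fasta"]),
            edges=_resolve(entry["edges"]),
            mapping=_resolve(entry.get("mapping")),
        )
        for entry in raw["species"]
    ]
    align_raw = raw.get("alignment", {}) or {}
    params = AlignmentParams(
        matrix=align_raw.get("matrix", "BLOSUM62"),
        gap_open=float(align_raw.get("gap_open", -10)),
        gap_extend=float(align_raw.get("gap_extend", -1)),
    )
    return RunConfig(
        species=species,
        alignment=params,
        similarity_cutoff=float(raw.get("similarity_cutoff", 30)),
        similarity_mode=str(raw.get("similarity_mode", "identity")),
        score_cutoff=int(raw.get("score_cutoff", 400)),
        coverage_cutoff=raw.get("coverage_cutoff"),
        out_dir=(base / raw.get("out_dir", "results")).resolve(),
        strict=bool(raw.get("strict", False)),
    )


def run(config: RunConfig, coverage_sweep: bool = False) -> IPN:
    """Execute the full pipeline and write all outputs.

    With ``coverage_sweep`` an extra edge list is written for every
    coverage cutoff from 1 to k, showing how conservation stringency
    thins the network.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species_ids = [s.species_id for s in config.species]
    k = len(species_ids)
    cov_cut = config.coverage_cutoff if config.coverage_cutoff is not None else k
    counts: dict[str, object] = {}

    log.info("=== stage 1: sequences ===")
    proteomes = {}
    for sp in config.species:
        accs = read_accession_list(sp.accession_list)
        proteomes[sp.species_id] = read_proteome(
            sp.fasta, accs, sp.species_id, strict=config.strict
        )
        log.info("%s: %d proteins", sp.species_id, len(proteomes[sp.species_id]))
    counts["proteins"] = {s: len(p) for s, p in proteomes.items()}

    log.info("=== stage 2: orthology ===")
    omaps = {}
    n_alignments = 0
    for sa, sb in combinations(species_ids, 2):
        matrix = all_vs_all(
            proteomes[sa], proteomes[sb], config.alignment, config.similarity_mode
        )
        n_alignments += len(matrix.values)
        hits_ab = best_hits(matrix, "ab")
        hits_ba = best_hits(matrix, "ba")
        omap = reciprocal_best_hits(
            hits_ab, hits_ba, config.similarity_cutoff, sa, sb
        )
        omaps[(sa, sb)] = omap
        writers.write_best_hits(hits_ab, sa, sb, out_dir / f"best_hits_{sa}_{sb}.tsv")
        writers.write_best_hits(hits_ba, sb, sa, out_dir / f"best_hits_{sb}_{sa}.tsv")
        writers.write_rbh(omap, out_dir / f"rbh_{sa}_{sb}.tsv")
    counts["alignments"] = n_alignments
    counts["rbh_pairs"] = {f"{a}-{b}": len(m.pairs) for (a, b), m in omaps.items()}

    log.info("=== stage 3: conserved nodes ===")
    ops_list = build_ops(omaps, species_ids)
    counts["ops"] = len(ops_list)

    log.info("=== stage 4: interaction networks ===")
    networks = {}
    for sp in config.species:
        mapping = read_mapping(sp.mapping) if sp.mapping else None
        net = read_edge_list(sp.edges, sp.species_id, mapping)
        net = filter_by_score(net, config.score_cutoff)
        net = restrict_to_ops(net, ops_list)
        networks[sp.species_id] = net
        log.info("%s: %d edges after filtering/restriction", sp.species_id, len(net))
    counts["restricted_edges"] = {s: len(n) for s, n in networks.items()}

    log.info("=== stage 5: conserved edges ===")
    run_params = {
        "matrix": str(config.alignment.matrix),
        "gap_open": config.alignment.gap_open,
        "gap_extend": config.alignment.gap_extend,
        "similarity_cutoff": config.similarity_cutoff,
        "similarity_mode": config.similarity_mode,
        "score_cutoff": config.score_cutoff,
    }
    ipn = build_ipn(ops_list, networks, cov_cut, run_params)
    if config.drop_isolated:
        connected = {e.ops_i for e in ipn.edges} | {e.ops_j for e in ipn.edges}
        ipn.nodes = [o for o in ipn.nodes if o.ops_id in connected]
    counts["ipn_edges"] = len(ipn.edges)

    writers.write_ipn(ipn, out_dir, species_ids)
    if coverage_sweep:
        sweep_counts = {}
        for c in range(1, k + 1):
            swept = build_ipn(ops_list, networks, c, run_params)
            writers.write_edge_list(swept, out_dir / f"ipn_edges_cov{c}.tsv", species_ids)
            sweep_counts[c] = len(swept.edges)
        counts["coverage_sweep"] = sweep_counts

    manifest = {
        "tool": "interonet",
        "version": __version__,
        "species": species_ids,
        "parameters": {**run_params, "coverage_cutoff": cov_cut},
        "inputs": {
            sp.species_id: {
                "accessions": writers.sha256_file(sp.accession_list),
                "fasta": writers.sha256_file(sp.fasta),
                "edges": writers.sha256_file(sp.edges),
                **(
                    {"mapping": writers.sha256_file(sp.mapping)}
                    if sp.mapping
                    else {}
                ),
            }
            for sp in config.species
        },
        "counts": counts,
    }
    writers.write_manifest(manifest, out_dir / "manifest.json")
    return ipn
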