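"""Synthetic multi-species data with known orthology and conserved edges.

The generator emulates a star phylogeny: ancestral proteins (i.i.d.
uniform amino-acid sequences, length 60-120) diverge independently into
each species by per-site substitution at ``sub_rate``; each species also
carries unrelated decoy proteins, length-matched to the ancestors so the
similarity cutoff — not sequence length — drives their rejection.  An
ancestral interaction network (edge probability ``ancestral_edge_p``) is
inherited per species with probability ``retention_p`` per edge, and each
species gains species-private spurious edges.  Edges conserved in *all*
species form the ground-truth conserved set.

The model deliberately omits indels, duplications, and rate
heterogeneity: its only job is to give every pipeline stage a knowable
truth.  Identical seeds yield byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .seqio import AA20

log = logging.getLogger(__name__)

_AA = np.frombuffer(AA20.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study."""

    n_ancestral: int = 20
    k: int = 3
    sub_rate: float = 0.05
    decoys_per_species: int = 5
    ancestral_edge_p: float = 0.3
    retention_p: float = 1.0
    spurious_edges_per_species: int = 10
    score_floor: int = 700
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 4:
            raise ValueError(f"k must be 2-4, got {self.k}")
        for name in ("sub_rate", "ancestral_edge_p", "retention_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sub_rate > 0.5:
            raise ValueError("sub_rate above 0.5 leaves no orthology signal")
        if min(self.n_ancestral, self.decoys_per_species, self.spurious_edges_per_species) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.score_floor <= 1000:
            raise ValueError("score_floor must be in [0, 1000]")

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.k)]


@dataclass
class FixtureTruth:
    """What the generator planted: ortholog groups and conserved edges."""

    species_ids: list[str]
    # ancestral index -> species -> accession
    groups: dict[int, dict[str, str]] = field(default_factory=dict)
    # ancestral index pairs (i < j) retained in every species
    conserved_edges: set[tuple[int, int]] = field(default_factory=set)

    def conserved_accession_edges(self, species_id: str) -> set[tuple[str, str]]:
        out = set()
        for i, j in self.conserved_edges:
            p, q = self.groups[i][species_id], self.groups[j][species_id]
            out.add((p, q) if p <= q else (q, p))
        return out


def _ortholog_acc(species_id: str, idx: int) -> str:
    return f"{species_id.upper()}A{idx:03d}"


def _decoy_acc(species_id: str, idx: int) -> str:
    return f"{species_id.upper()}D{idx:03d}"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _AA[rng.integers(0, len(_AA), size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        # replace by one of the 19 other residues
        current = np.where(_AA == arr[pos])[0][0]
        arr[pos] = _AA[(current + 1 + rng.integers(0, len(_AA) - 1)) % len(_AA)]
    return arr.tobytes().decode()


def generate(spec: FixtureSpec, out_dir: str | Path) -> FixtureTruth:
    """Write FASTA, edge lists, accession lists, truth tables, and a
    ready-to-run pipeline config under ``out_dir``; return the truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    species = spec.species_ids

    lengths = rng.integers(60, 121, size=spec.n_ancestral)
    ancestors = [_random_seq(rng, int(n)) for n in lengths]

    truth = FixtureTruth(species_ids=list(species))
    sequences: dict[str, dict[str, str]] = {s: {} for s in species}
    for s in species:
        for i, anc in enumerate(ancestors):
            acc = _ortholog_acc(s, i)
            sequences[s][acc] = _mutate(rng, anc, spec.sub_rate)
            truth.groups.setdefault(i, {})[s] = acc
        for d in range(spec.decoys_per_species):
            length = int(lengths[rng.integers(0, len(lengths))]) if len(lengths) else int(rng.integers(60, 121))
            sequences[s][_decoy_acc(s, d)] = _random_seq(rng, length)

    # ancestral interactions over ancestral protein indices
    ancestral_edges = [
        (i, j)
        for i, j in combinations(range(spec.n_ancestral), 2)
        if rng.random() < spec.ancestral_edge_p
    ]

    retained: dict[str, set[tuple[int, int]]] = {}
    networks: dict[str, dict[tuple[str, str], int]] = {}
    for s in species:
        retained[s] = {e for e in ancestral_edges if rng.random() < spec.retention_p}
        edges: dict[tuple[str, str], int] = {}
        for i, j in sorted(retained[s]):
            p, q = truth.groups[i][s], truth.groups[j][s]
            key = (p, q) if p <= q else (q, p)
            edges[key] = int(rng.integers(spec.score_floor, 1001))
        # species-private spurious edges among any proteins, never reusing
        # an ancestral interaction or an existing pair
        all_accs = sorted(sequences[s])
        anc_pairs = {
            tuple(sorted((truth.groups[i][s], truth.groups[j][s])))
            for i, j in ancestral_edges
        }
        candidates = [
            (p, q)
            for p, q in combinations(all_accs, 2)
            if (p, q) not in anc_pairs
        ]
        if spec.spurious_edges_per_species > len(candidates):
            raise ValueError(
                f"cannot place {spec.spurious_edges_per_species} spurious edges: "
                f"only {len(candidates)} free pairs in species {s}"
            )
        picks = rng.choice(len(candidates), size=spec.spurious_edges_per_species, replace=False)
        for idx in sorted(picks):
            p, q = candidates[idx]
            edges[(p, q)] = int(rng.integers(spec.score_floor, 1001))
        networks[s] = edges

    truth.conserved_edges = set.intersection(*retained.values()) if species else set()

    # ---- files -----------------------------------------------------------
    for s in species:
        with open(out_dir / f"{s}.fasta", "w") as fh:
            for acc in sorted(sequences[s]):
                fh.write(f">{acc}\n{sequences[s][acc]}\n")
        with open(out_dir / f"{s}_accessions.txt", "w") as fh:
            fh.write("\n".join(sorted(sequences[s])) + "\n")
        with open(out_dir / f"{s}_edges.tsv", "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for (p, q), score in sorted(networks[s].items()):
                fh.write(f"{p}\t{q}\t{score}\n")

    with open(out_dir / "truth_groups.tsv", "w") as fh:
        fh.write("ancestral\t" + "\t".join(species) + "\n")
        for i in range(spec.n_ancestral):
            fh.write(f"{i}\t" + "\t".join(truth.groups[i][s] for s in species) + "\n")
    with open(out_dir / "truth_conserved_edges.tsv", "w") as fh:
        fh.write("ancestral_i\tancestral_j\n")
        for i, j in sorted(truth.conserved_edges):
            fh.write(f"{i}\t{j}\n")

    _write_config(spec, out_dir)
    log.info(
        "fixture: %d species, %d ancestral proteins, %d ancestral edges, "
        "%d conserved",
        spec.k, spec.n_ancestral, len(ancestral_edges), len(truth.conserved_edges),
    )
    return truth


def _write_config(spec: FixtureSpec, out_dir: Path) -> None:
    lines = ["species:"]
    for s in spec.species_ids:
        lines += [
            f"  - id: {s}",
            f"    accessions: {s}_accessions.txt",
            f"    fasta: {s}.fasta",
            f"    edges: {s}_edges.tsv",
        ]
    lines += [
        "alignment:",
        "  matrix: BLOSUM62",
        "  gap_open: -10",
        "  gap_extend: -1",
        "similarity_cutoff: 30",
        "similarity_mode: identity",
        "score_cutoff: 400",
        f"coverage_cutoff: {spec.k}",
        "out_dir: results",
        "",
    ]
    (out_dir / "config.yaml").write_text("\n".join(lines))


def load_truth(out_dir: str | Path) -> FixtureTruth:
    """Re-read the truth tables written by :func:`generate`."""
    out_dir = Path(out_dir)
    group_lines = (out_dir / "truth_groups.tsv").read_text().splitlines()
    species = group_lines[0].split("\t")[1:]
    truth = FixtureTruth(species_ids=species)
    for line in group_lines[1:]:
        fields = line.split("\t")
        idx = int(fields[0])
        truth.groups[idx] = dict(zip(species, fields[1:]))
    edge_lines = (out_dir / "truth_conserved_edges.tsv").read_text().splitlines()
    for line in edge_lines[1:]:
        i, j = map(int, line.split("\t"))
        truth.conserved_edges.add((i, j))
    return truth
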