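"""Reciprocal-best-hit orthology between species pairs.

For a species pair the full cross-proteome similarity matrix is computed
once and reused for both best-hit directions, which guarantees the two
directions agree on every pairwise value.  A reciprocal best hit (RBH) is
a pair in which each protein is the other's highest-similarity match and
the similarity reaches the cutoff (inclusive).  Ties on the maximum are
broken by subject accession lexicographic order and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import AlignmentParams, global_align
from .seqio import SpeciesProteome

log = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """All cross-species pairwise similarities for one species pair."""

    species_a: str
    species_b: str
    values: dict[tuple[str, str], float]  # keyed (accession_a, accession_b)
    a_accessions: list[str]
    b_accessions: list[str]

    def value(self, acc_a: str, acc_b: str) -> float:
        return self.values[(acc_a, acc_b)]


@dataclass(frozen=True)
class BestHit:
    """The highest-similarity subject for one query protein."""

    query: str
    subject: str
    similarity: float
    tie_flag: bool = False


@dataclass
class OrthologyMap:
    """RBH pairs of one species pair at a given similarity cutoff."""

    species_a: str
    species_b: str
    cutoff: float
    pairs: set[tuple[str, str]] = field(default_factory=set)  # (acc_a, acc_b)

    @property
    def species_pair(self) -> tuple[str, str]:
        return (self.species_a, self.species_b)

    def partner_of(self, species_id: str) -> dict[str, str]:
        """accession -> RBH partner accession, looking from ``species_id``."""
        if species_id == self.species_a:
            return {a: b for a, b in self.pairs}
        if species_id == self.species_b:
            return {b: a for a, b in self.pairs}
        raise KeyError(species_id)


def all_vs_all(
    proteome_a: SpeciesProteome,
    proteome_b: SpeciesProteome,
    params: AlignmentParams | None = None,
    mode: str = "identity",
) -> SimilarityMatrix:
    """Align every protein of one species against every protein of the other.

    Each cross pair is aligned exactly once; both best-hit directions later
    read the same matrix, so symmetry holds by construction.
    """
    params = params or AlignmentParams()
    if mode not in ("identity", "similarity"):
        raise ValueError(f"mode must be 'identity' or 'similarity', got {mode!r}")
    if len(proteome_a) == 0 or len(proteome_b) == 0:
        raise ValueError("all_vs_all requires two non-empty proteomes")
    values: dict[tuple[str, str], float] = {}
    for rec_a in proteome_a:
        for rec_b in proteome_b:
            res = global_align(rec_a.sequence, rec_b.sequence, params)
            pct = res.identity_pct if mode == "identity" else res.similarity_pct
            values[(rec_a.accession, rec_b.accession)] = pct
    log.info(
        "all-vs-all %s/%s: %d alignments",
        proteome_a.species_id, proteome_b.species_id, len(values),
    )
    return SimilarityMatrix(
        proteome_a.species_id,
        proteome_b.species_id,
        values,
        proteome_a.accessions,
        proteome_b.accessions,
    )


def best_hits(matrix: SimilarityMatrix, direction: str = "ab") -> list[BestHit]:
    """One best hit per query protein in the chosen direction.

    ``direction`` is ``"ab"`` (queries from species_a) or ``"ba"``.  Tied
    maxima take the lexicographically smallest subject accession, with
    ``tie_flag`` set.
    """
    if direction not in ("ab", "ba"):
        raise ValueError(f"direction must be 'ab' or 'ba', got {direction!r}")
    if direction == "ab":
        queries, subjects = matrix.a_accessions, matrix.b_accessions
        get = lambda q, s: matrix.values[(q, s)]
    else:
        queries, subjects = matrix.b_accessions, matrix.a_accessions
        get = lambda q, s: matrix.values[(s, q)]
    hits = []
    subjects_sorted = sorted(subjects)
    for q in queries:
        best_s = None
        best_v = None
        tie = False
        for s in subjects_sorted:
            v = get(q, s)
            if best_v is None or v > best_v:
                best_s, best_v, tie = s, v, False
            elif v == best_v:
                tie = True
        hits.append(BestHit(q, best_s, best_v, tie))
    return hits


def reciprocal_best_hits(
    hits_ab: list[BestHit],
    hits_ba: list[BestHit],
    cutoff: float,
    species_a: str = "a",
    species_b: str = "b",
) -> OrthologyMap:
    """Mutual best hits passing the similarity cutoff (inclusive)."""
    back = {h.query: h.subject for h in hits_ba}
    omap = OrthologyMap(species_a, species_b, cutoff)
    for h in hits_ab:
        if back.get(h.subject) == h.query and h.similarity >= cutoff:
            omap.pairs.add((h.query, h.subject))
    return omap


def pairwise_orthology(
    proteome_a: SpeciesProteome,
    proteome_b: SpeciesProteome,
    cutoff: float,
    params: AlignmentParams | None = None,
    mode: str = "identity",
) -> tuple[SimilarityMatrix, OrthologyMap]:
    """Convenience wrapper: matrix, both directions, RBH in one call."""
    matrix = all_vs_all(proteome_a, proteome_b, params, mode)
    omap = reciprocal_best_hits(
        best_hits(matrix, "ab"),
        best_hits(matrix, "ba"),
        cutoff,
        proteome_a.species_id,
        proteome_b.species_id,
    )
    log.info(
        "RBH %s/%s at cutoff %.1f: %d pairs",
        proteome_a.species_id, proteome_b.species_id, cutoff, len(omap.pairs),
    )
    return matrix, omap
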