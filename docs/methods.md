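# Methods

## The model

`interonet` extracts the evolutionarily conserved core shared by the
protein–protein interaction networks (PPINs) of two to four species. The
premise is the *interolog*: if proteins p and q interact in one species
and their orthologs p′ and q′ interact in another, the interaction is
likely ancestral and therefore a higher-confidence, lower-false-positive
observation than either single-species report. The output — here called
the interolog protein network (IPN) — has orthologous protein sets (OPS)
as nodes and interactions conserved in at least a chosen number of
species as edges.

The procedure has five stages:

1. **Sequences.** Protein lists (accessions) and amino-acid sequences are
   supplied locally: a plain-text accession list and a FASTA file per
   species. Accessions absent from the FASTA are dropped with a warning
   by default (`--strict` makes them fatal): a local run should degrade
   gracefully when a sequence source is incomplete.
2. **Orthology.** Every cross-species protein pair is globally aligned
   (Needleman–Wunsch with affine gaps, Gotoh's three-state recurrence)
   and scored as percent identity or percent similarity over the full
   gapped alignment length. Orthologs are *reciprocal best hits* (RBH):
   each protein is the other's highest-similarity match and the
   similarity reaches the cutoff. RBH is strict one-to-one; no inparalog
   clustering is attempted.
3. **Nodes.** An OPS is one protein per analysis species, *all pairwise*
   RBH — a one-per-species k-clique of the k-partite RBH graph. This is
   the strictest reading of "mutually orthologous": a relaxed
   star/connected-component mode was considered and rejected so that
   node semantics stay unambiguous. Because RBH gives each protein at
   most one partner per other species, OPS are automatically disjoint.
4. **Networks.** Each species' PPIN is read from a local STRING-style
   edge list (id1, id2, combined score 0–1000), optionally through an
   ID→accession mapping table. Edges below the confidence cutoff are
   removed, and the network is restricted to OPS member proteins.
5. **Edges.** For each OPS pair, the *coverage* is the number of species
   whose member proteins interact in that species' filtered, restricted
   network. An IPN edge is drawn when coverage ≥ the coverage cutoff.

## Parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| substitution matrix | BLOSUM62 | — | standard general-purpose protein matrix; BLOSUM/PAM family and NCBI-format custom files accepted |
| gap_open | −10 | matrix units | common practice for BLOSUM62; first residue of a gap run |
| gap_extend | −1 | matrix units | each further gap residue; `gap_open ≤ gap_extend < 0` |
| similarity cutoff | 30 | % of alignment columns | below ~30 % identity, alignment-based orthology is unreliable ("twilight zone"); inclusive (≥) |
| similarity mode | identity | identity \| similarity | identity over full gapped length is the most conservative, reproducible convention; positive-substitution "similarity" is selectable |
| confidence cutoff | 400 | STRING combined score, 0–1000 | STRING's "medium confidence" convention; inclusive |
| coverage cutoff | k (all species) | 1..k | full conservation by default — the IPN as a gold-standard core; inclusive so that the maximum-stringency setting is satisfiable |

All cutoffs are inclusive (≥). "Exceeds the coverage cutoff" is read
inclusively on purpose: a strict `>` would make the
conservation-in-all-species setting permanently empty.

## Numerical and determinism choices

* **Gap model.** A gap of length L costs `gap_open + (L−1)·gap_extend`,
  terminal gaps included (true global alignment). With
  `gap_open == gap_extend` the recurrence provably collapses to classical
  linear-gap Needleman–Wunsch (tested).
* **Traceback ties.** Resolved deterministically: substitution state
  first, then gap-in-second-sequence, then gap-in-first. The optimal
  score is tie-invariant; the reported alignment strings are therefore
  bit-reproducible across runs and platforms.
* **Percent similarity** counts columns whose residues are identical *or*
  score positively, which guarantees identity ≤ similarity for any
  matrix, including custom matrices with non-positive diagonal entries.
* **Best-hit ties** keep the lexicographically smallest subject accession
  and set a flag, rather than discarding tied queries — reproducible
  without silently losing data.
* **Duplicate network edges** (STRING exports repeat pairs in both
  orientations) collapse keeping the maximum score; self-loops are
  dropped; scores must be integers in 0–1000 — probabilities in [0, 1]
  are rejected rather than rescaled to avoid unit confusion.
* Each cross-proteome similarity matrix is computed once and reused for
  both best-hit directions, so symmetry cannot be violated by
  recomputation.
* The whole pipeline is seed-free and deterministic: identical configs
  yield byte-identical node/edge tables and manifests (the manifest
  carries no timestamps).
* The inner DP is JIT-compiled (numba) over integer-encoded sequences;
  a 25-protein × 25-protein proteome pair (~625 alignments of length
  60–120) aligns in well under a second.

## The synthetic benchmark

The generator (`interonet.fixtures`) emulates a star phylogeny with a
known truth: ancestral proteins are i.i.d. uniform sequences of length
60–120; each of k species receives a copy mutated by per-site
substitution at `sub_rate` (uniform replacement, no matrix weighting —
enough to separate orthologs from decoys while keeping the truth
trivial); decoys are fresh random sequences, length-matched to the
ancestors so that the similarity cutoff, not length artifacts, drives
their rejection. An ancestral interaction network (edge probability
`ancestral_edge_p`) is inherited per species with probability
`retention_p` per edge; each species gains `spurious_edges_per_species`
private edges drawn from pairs that are not ancestral interactions (so a
spurious edge can never silently raise a planted edge's coverage). True
edge scores are uniform on [`score_floor`, 1000] with `score_floor` 700,
safely above the default confidence cutoff so the benchmark exercises
coverage filtering rather than score filtering.

What it deliberately does **not** model: insertions/deletions, gene
duplication and loss (in- and out-paralogs), rate heterogeneity, biased
amino-acid composition, many-to-many orthology, and database-style
incompleteness of the input networks. Passing the benchmark therefore
demonstrates that the machinery is correct — not that RBH orthology or
interolog transfer is biologically sufficient for any particular real
dataset, where paralogy and network false negatives dominate the error
budget.

Default benchmark conditions (used by `scripts/acceptance.py` and the
end-to-end test): 20 ancestral proteins, 4 species, 5 % substitution per
site, 5 decoys and 10 spurious edges per species, full retention. At
these settings the planted orthology is recovered exactly and the IPN at
full coverage equals the planted conserved edge set; the problem size
(3 750 alignments, ≤ 300 candidate pairs per species) keeps a full run
around two seconds.

## Known limitations and edge cases

* The size bound "IPN edges ≤ smallest restricted species network" is a
  theorem only at coverage cutoff = k (each IPN edge then maps
  injectively into every species' restricted edge set). At lower
  cutoffs species-private support can add up: two OPS pairs each
  supported in a different single species already violate the bound at
  cutoff 1. Tests assert the exact bound at full coverage and the
  counting bound Σ_s|E_s|/c otherwise.
* Growing the species set can only shrink (or keep) the OPS node set
  derived from the same proteomes — conservation is intersective; this
  monotonicity is asserted on the benchmark.
* Selenocysteine (U) passes sequence validation but BLOSUM/PAM matrices
  do not score it; alignment then fails loudly naming the residue.
  Characters outside the 20 + BZXU alphabet are rejected at load time,
  because silently mis-scoring them would corrupt orthology.
* Empty similarity cutoff edge cases: with cutoff 0 every mutual best
  hit is an "ortholog", including decoy–decoy matches; the benchmark's
  defaults (30 %) are the tested regime.
* Live UniProt/STRING retrieval is out of scope; the file contracts are
  written so a fetcher could be added behind the same interfaces.
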