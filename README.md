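# interonet

Extraction of the evolutionarily conserved core shared by the
protein–protein interaction networks (PPINs) of two to four species.

Single-species PPINs are noisy: high-throughput interaction screens carry
substantial false-positive and false-negative rates, and no two databases
agree. An *interolog* — an interaction observed between orthologs in more
than one species — is far more likely to be real than any single report.
`interonet` turns that idea into a pipeline: given protein lists, amino-acid
sequences (FASTA) and STRING-style weighted edge lists for k ∈ {2, 3, 4}
species, it

1. infers orthology by **reciprocal best hits** (RBH) under
   Needleman–Wunsch global alignment with affine gaps (Gotoh),
   `sim(p, q) ≥ c_sim` with percent identity/similarity measured over the
   full gapped alignment length;
2. assembles **orthologous protein sets** (OPS): one protein per species,
   all pairwise RBH — the one-per-species k-cliques of the k-partite RBH
   graph;
3. filters each species' network by STRING combined score
   (`w ≥ c_conf`, integer scale 0–1000) and restricts it to OPS members;
4. draws an edge between OPS i and OPS j when their member proteins
   interact in at least `c_cov` species (the **coverage cutoff**):
   `|{s : (p_is, p_js) ∈ E_s}| ≥ c_cov`.

The result — the interolog protein network (IPN) — is a conserved,
low-false-positive network usable as a benchmark or gold standard for
downstream network biology. Who this is for: anyone integrating
cross-species interactome data who wants the conserved core under
explicit, tunable similarity/confidence/coverage cutoffs, with
deterministic, diffable outputs.

## Worked example

Generate a synthetic three-species study with known ground truth, then
run the pipeline:

```
$ interonet fixtures demo --n-ancestral 8 --species 3 --decoys 3 --spurious 5 --seed 4
fixture: 3 species, 8 ortholog groups, 7 conserved edges -> demo
$ interonet build demo/config.yaml
...
INFO interonet.ipn: IPN: 8 nodes, 7 edges at coverage cutoff 3
IPN: 8 nodes, 7 edges -> demo/results
```

All 8 planted ortholog groups come back as OPS nodes, and exactly the 7
ancestral interactions retained in every species survive at full
coverage — the 5 species-private spurious edges per species are gone.
The node table maps each OPS to its member accession per species, and
the edge table records each conserved interaction's coverage and the
per-species protein pairs supporting it:

```
$ head -3 demo/results/ipn_nodes.tsv
ops_id  sp1      sp2      sp3
OPS1    SP1A000  SP2A000  SP3A000
OPS2    SP1A001  SP2A001  SP3A001
$ head -3 demo/results/ipn_edges.tsv
ops_i   ops_j   coverage  supporting_species  pair_sp1          pair_sp2          pair_sp3
OPS1    OPS3    3         sp1,sp2,sp3         SP1A000--SP1A002  SP2A000--SP2A002  SP3A000--SP3A002
OPS2    OPS3    3         sp1,sp2,sp3         SP1A001--SP1A002  SP2A001--SP2A002  SP3A001--SP3A002
```

`results/` also contains GraphML and DOT exports of the IPN, best-hit and
RBH tables per species pair, and `manifest.json` (version, parameters,
input checksums, per-stage counts). `interonet build --coverage-sweep`
additionally writes one edge list per coverage cutoff 1..k;
`interonet align-orthologs` stops after the orthology stage. Real data
go in through the same config: per species an accession list, a FASTA
file, a STRING-style edge list, and optionally a network-ID→accession
mapping table.

The same pipeline is available as a library:

```python
from interonet import FixtureSpec, generate
from interonet.pipeline import load_config, run

generate(FixtureSpec(n_ancestral=8, k=3, seed=4), "demo")
ipn = run(load_config("demo/config.yaml"))
len(ipn.nodes), len(ipn.edges)   # (8, 6) under the generator's defaults
```

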