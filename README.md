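# otunet

Community analysis of OTU (operational taxonomic unit) count tables, built
for amplicon surveys of microbial guilds — for example ammonia-oxidizing
archaea and bacteria profiled via the *amoA* marker gene across treatment
groups of an agricultural field experiment. The package takes an integer
OTU × sample count table plus a sample-to-treatment map and provides, as
both a Python library and a CLI:

- **Rarefaction and alpha diversity** — seeded subsampling of every sample
  to even depth (multivariate hypergeometric), Shannon entropy
  *H* = −Σ pᵢ ln pᵢ and the Chao1 richness estimator
  *S*₁ = *S*obs + F₁²/(2F₂) (bias-corrected when F₂ = 0).
- **Beta ordination** — Bray–Curtis dissimilarity
  *d*(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), classical PCoA (Gower double-centering
  B = −½ J D² J with negative eigenvalues reported, not hidden), and the
  ANOSIM permutation test R = (r̄ᴮ − r̄ᵂ) / (n(n−1)/4) on ranked distances.
- **Co-occurrence networks** (the core) — all-pairs Spearman correlation
  with t-approximation p-values; an edge where |ρ| > 0.7 and P < 0.01
  (both strict); the standard topology vector (average degree 2E/N, edge
  density 2E/(N(N−1)), average path length over connected pairs, mean
  local clustering, linkage density E/N, Newman modularity Q); seeded
  Louvain module detection; and Guimerà–Amaral node roles from
  Zᵢ = (k_is − k̄ₛ)/σₛ and Pᵢ = 1 − Σₛ(k_is/kᵢ)², cut at Zᵢ = 2.5 and
  Pᵢ = 0.62 (peripheral / connector / module hub / network hub).
- **Synthetic communities with ground truth** — negative-binomial counts
  through a Gaussian copula with planted equicorrelated OTU modules, so
  network inference can be scored against known edges and known module
  membership.

## Worked example

Simulate a 40-OTU, 3-treatment × 10-replicate community with three planted
correlation modules of 6 OTUs each (latent intra-correlation 0.9) and a
group effect, then analyze it:

```bash
otunet simulate --config sim.yaml --out-table otus.tsv \
    --out-meta meta.tsv --out-truth truth.json
# wrote 40 OTUs x 30 samples

otunet alpha --table otus.tsv --depth min --seed 42 --out alpha.tsv
# rarefied to 14941; wrote alpha.tsv

otunet ordinate --table otus.tsv --meta meta.tsv --permutations 999 \
    --seed 42 --out-coords coords.tsv --out-report ord.json
# ANOSIM R = 0.6632, p = 0.0010 (999 permutations)

otunet network --table otus.tsv --seed 42 --out-graphml net.graphml \
    --out-edges edges.csv --out-roles roles.tsv --out-report net.json
# network: 23 nodes, 33 edges, modularity 0.635
```

The ANOSIM line says between-treatment Bray–Curtis distances rank well
above within-treatment ones (R = 0.66 of a maximum 1) and that no random
relabeling among 999 reached the observed R (p = 1/1000, the smallest
value the inclusive estimator allows). The network line reports the OTUs
kept after thresholding (23 of 40; isolated OTUs are excluded), the 33
edges with |ρ| > 0.7 and P < 0.01, and the modularity of the Louvain
partition. `roles.tsv` then lists each node's module, Zᵢ, Pᵢ and role —
in this run all nodes are peripheral, as expected for small tight modules:

```
otu     module  degree  zi      pi      role
OTU1    4       1       0.0     0.0     peripheral
```

The same operations are importable directly
(`otunet.spearman_matrix`, `otunet.build_network`, `otunet.topology`,
`otunet.zi_pi`, `otunet.anosim`, ...), each consuming and returning plain
numpy/pandas/networkx objects.

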