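# woodweb

Quantitative bipartite network analysis for colonizer–resource systems
observed through amplicon sequencing — typically fungal or prokaryotic
OTU tables from deadwood of multiple tree species, sampled in replicate
and by wood compartment (sapwood vs heartwood). The package is aimed at
microbial ecologists who want to quantify how specialized a community of
colonizers is on its resources, and whether that structure exceeds what
chance assembly would produce.

## What it computes

From a samples × OTUs count table with (tree species, compartment,
replicate) metadata, the pipeline:

1. **Rarefies** every sample to a common depth (multivariate
   hypergeometric subsampling) and repeats this for an ensemble of
   seed-controlled versions, since a single rarefaction is an arbitrary
   draw. The ACE richness estimator provides a depth diagnostic
   (share of estimated richness a depth retains).
2. **Builds the network**: cell *a<sub>ij</sub>* is the median over tree
   *i*'s replicates of OTU *j*'s relative abundance. Rows are resources
   (trees), columns colonizers (OTUs).
3. **Scores topology** (natural logs throughout; *m* = Σ*a<sub>ij</sub>*,
   *p<sub>ij</sub>* = *a<sub>ij</sub>*/*m*):
   - Shannon diversity of entries *H* = −Σ *p<sub>ij</sub>* ln *p<sub>ij</sub>*
     and interaction evenness *H*/ln(*IJ*);
   - generality per side: abundance-weighted mean effective partner
     number Σ<sub>i</sub> (*A<sub>i</sub>*/*m*) · exp(*H<sub>i</sub>*);
   - two-dimensional specialization
     *H₂′* = (*H₂max* − *H*) / (*H₂max* − *H₂min*), rescaling the entry
     entropy between its marginal-constrained extremes (0 = no
     specialization, 1 = perfect);
   - species-level *d′*: Kullback–Leibler divergence of a species'
     partner distribution from partner availability, normalized by
     ln(*m*/*A<sub>i</sub>*);
   - Barber bipartite modularity
     *Q* = (1/*m*) Σ [*a<sub>ij</sub>* − *A<sub>i</sub>A<sub>j</sub>*/*m*] δ(*g<sub>i</sub>*, *g<sub>j</sub>*),
     maximized by a seeded multi-start optimizer with iterated local
     search (exhaustive enumeration doubles as a test oracle on small
     matrices).
4. **Benchmarks against three null models**: Patefield (fixed marginal
   sums), Vazquez (fixed link count and total, abundance-weighted link
   placement), and shuffle (fixed weight multiset and connectance).
5. **Aggregates the ensemble**: per-index mean/variance/min/median/max,
   a consensus module partition (modal tree-side grouping), per-OTU
   support statistics (present, inBestModule, percInBestModule), paired
   *t* tests of observed vs null indices, and module-wise wood-trait
   medians (min–max scaled).

A synthetic-data generator plants known tree–OTU module structure behind
a specialization dial *s*, so the whole pipeline can be validated by
parameter recovery (adjusted Rand index against the planted truth).

## Worked example

```python
import numpy as np
from woodweb import InteractionMatrix, h2prime, null_ensemble, shannon_entries

rng = np.random.default_rng(0)
W = np.kron(np.eye(4), np.ones((1, 3))) * 15 + (rng.random((4, 12)) < 0.4)
M = InteractionMatrix(W)   # 4 trees, 12 OTUs, strong diagonal blocks

print(h2prime(M), shannon_entries(M))
for method in ("patefield", "vazquez", "shuffle"):
    d = null_ensemble(M, method, n=50, seed=1).index_distributions
    print(method, d["h2prime"].mean(), d["shannon"].std())
```

prints (rounded)

```
observed: H2' = 0.834, Shannon = 2.713
patefield: H2' = 0.064 (sd 0.017)
vazquez  : H2' = 0.450 (sd 0.035)
shuffle  : H2' = 0.562 (sd 0.080), Shannon sd = 0.000
```

The observed *H₂′* of 0.83 sits far above both abundance-constrained
null distributions — the block structure is genuine specialization, not
an artifact of the marginal abundances. The shuffle null's Shannon
standard deviation of exactly 0 shows why diversity indices cannot be
tested against a null that only permutes the existing weights.

The `examples/` directory contains one short script per capability
(network + indices, rarefaction + ACE, null models, modules + consensus,
end-to-end recovery with paired tests); each prints its results with a
note on what they mean.

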