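# interbench

Characterization and comparison of gene-centered interaction networks
("interactomes"): nodes are genes, edges are physical or functional
interactions between their products.  Because no consensus reference
interactome exists, network-based analyses — disease-gene prioritization,
pathway analysis, module discovery — can depend heavily on which interactome
they run on.  `interbench` provides the measurement machinery to quantify
that dependence, aimed at computational biologists choosing or combining
interactomes.

## What it computes

* **Topology** — degree, betweenness, closeness and spectral centrality;
  diameter, mean distance, mean clustering coefficient; hubs (top degree
  percentiles) with a permutation null for cross-network hub sharing;
  size/density-matched Barabási–Albert reference ensembles.
* **Scale-freeness** — joint discrete power-law MLE of the exponent α and
  onset degree k_min (KS scan over candidate onsets), a semi-parametric
  bootstrap goodness-of-fit p-value, likelihood comparison against discrete
  exponential and lognormal tails, and a four-level plausibility taxonomy:
  *none* (p < 0.1 or tail < 200 genes), *weak* (p ≥ 0.1 and tail ≥ 200),
  *medium* (weak plus 2 < α < 3 **or** power law out-fits both alternatives),
  *strong* (weak plus both).
* **Gene-set coverage** — the connected component fraction
  CCF = |S_C| / |S|, where S_C are the members of gene set S with at least
  one within-set edge; CCF matrices across networks and coverage counts.
* **Network diffusion** — steady state of
  X_{t+1} = αWX_t + (1−α)X_0 with W = D^{−1/2}AD^{−1/2} (default α = 0.7),
  as a scikit-learn style transformer over sparse matrices.
* **Pathway cross-talk** — PCT(P1, P2) = (S12 + S21)/2, where S12 is the mean
  normalized diffusion mass received by P2's genes when P1 seeds the
  diffusion; plus cross-network conservation (mean, SD, SNR) of each pair.
* **Disease-gene prioritization** — genome-wide diffusion ranking from known
  disease genes, evaluated by 5-fold cross-validated partial AUC at 20%
  false-positive rate (unnormalized; perfect = 0.2, random ≈ 0.02).
* **Comparison** — per-analysis-type Spearman correlation matrices averaged
  into C_t, summed into C_I, a directed top-k similarity network with
  fast-greedy communities, and the aggregate reproducibility index
  R_i = Σ_t Σ_{j≠i} c_ijt / (n−1).
* **Synthetic data** — BA / Erdős–Rényi / duplication-divergence networks,
  planted complexes (dense modules), proximal pathway sets, cohesive disease
  modules and degree-preserving rewiring families, all seeded and
  bit-reproducible, so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from interbench import GeneSet
from interbench.synthetic_data import SyntheticSpec, gen_network, plant_disease_module
from interbench.prioritization import cross_validate
from interbench.topology import assess_scale_freeness

net = gen_network(SyntheticSpec(n_genes=2000, n_edges=6000, model="ba", rng_seed=17))
module = plant_disease_module(net, size=50, cohesiveness=1.0, rng_seed=3)
cv = cross_validate(net, GeneSet("toy_disease", "disease", module.members),
                    k=5, alpha=0.7, rng_seed=1)
print(f"mean pAUC(0.2) = {cv.mean_pauc:.3f}")

sf = assess_scale_freeness(net.degrees(), n_boot=100, seed=1)
print(f"alpha = {sf.alpha:.2f}, k_min = {sf.k_min}, p = {sf.gof_pvalue:.2f}, "
      f"level = {sf.level}")
```

Output:

```
mean pAUC(0.2) = 0.131
alpha = 2.78, k_min = 5, p = 0.96, level = medium
```

The planted cohesive module is recovered far above the random-ranking
expectation of 0.02.  The BA degree sequence is graded *medium*: the
bootstrap cannot reject the power law, the fitted tail holds over 200 genes
and the exponent lies in (2, 3) — but the lognormal fits the tail at least
as well, so the *strong* grade is withheld.

A CLI mirrors the library (`interbench ingest | topology | ccf | pct |
prioritize | simulate | compare`); run `interbench --help`.

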