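# Methods

This note documents the models, conventions and numerical choices behind
`interbench`, and what the synthetic-data validation does and does not show
about real interactomes.

## Network model and harmonization

An interactome is a named simple undirected graph over opaque gene-identifier
strings.  Edge identity is the unordered pair, canonicalized by sorting
endpoints lexicographically, so reversed duplicate rows collapse
deterministically.  Self-loops, duplicate rows, unmapped identifiers and
edges that collapse onto self-loops after identifier mapping are dropped and
counted through the module logger — sanitization is never fatal.  When
duplicate rows or identifier mapping bring several confidence scores onto
the same gene pair, the highest score is kept as representative of the
interaction.  Confidence filtering (inclusive: score ≥ threshold) is applied
after identifier mapping, i.e. after the max-score merge, so the threshold
acts on the representative score.

All analyses operate on the largest connected component (LCC); size ties —
which never arise in practice but must not break determinism — go to the
component containing the lexicographically smallest gene.  Multi-protein
complexes expand to binary edges by the spoke model (bait to every other
member) when a bait is designated, otherwise by the matrix model (all
unordered pairs).  Default size filters keep pathways with 10–500 members
and complexes with 3–500, bounds inclusive.

## Topology

Centralities: degree; betweenness as unnormalized pair counts with endpoints
excluded (only ranks are consumed downstream, so normalization is
irrelevant); closeness as (n−1)/Σd; and spectral centrality, defined here as
the node-removal deformation of the graph-Laplacian spectrum (sum of
absolute differences between the full spectrum with its structural zero
dropped and the spectrum of the graph minus the node).  The spectral
definition sits behind a `spectral_strategy` name so an alternative can be
swapped in; it costs one dense eigendecomposition per node (O(n⁴) overall),
so the large-scale correlation analyses select the
degree/betweenness/closeness subset via the `measures` argument.

Global measures: diameter, mean distance over unordered pairs, and
transitivity as the **mean local clustering coefficient** over genes (genes
of degree < 2 contribute 0), not the global triangle ratio.

Hubs are the genes in the top percentile band (default top 2%) of the degree
distribution; the cut is inclusive (degree ≥ threshold) and ties straddling
it are kept, so the set may exceed the nominal count.  The hub-sharing null
reassigns each network's hub label to a uniform random subset of the same
size within that network's own gene universe; for two networks with h hubs
on a shared universe of n genes the null mean shared count is h²/n
(hypergeometric).

Barabási–Albert references use attachment parameter m = round(edges/genes),
clamped to ≥ 1; exact edge-count matching is impossible in the BA
construction, so the mismatch is logged.

## Scale-freeness

The degree distribution is fitted with a discrete power law whose exponent α
and onset k_min are estimated jointly: for each candidate onset (an observed
degree value; at most 50 candidates, evenly subsampled) the exponent is
fitted by maximizing the Hurwitz-zeta likelihood on the inclusive tail
{degree ≥ k_min}, and the onset minimizing the Kolmogorov–Smirnov distance
between empirical and model tail CDFs wins.  The tail convention is
inclusive — k_min is itself a fitted data point, and the onset can never
precede the support minimum.

Goodness of fit uses a semi-parametric bootstrap (default 100 replicates,
configurable): each replicate resamples the body (degrees < k_min)
empirically, draws the tail from the fitted power law by inverse-CDF
sampling, and is refitted jointly; the p-value is the fraction of replicate
KS statistics ≥ the observed one, so low p rejects the power law.

The alternative-fit comparison fits a discrete exponential
(shifted-geometric, closed-form MLE) and a discretized lognormal on the same
tail and declares the power law "better" by the sign of the log-likelihood
difference, without a significance gate.  The lognormal parameters are
constrained to μ ∈ [−20, 20], σ ∈ (0, 5]: the unconstrained MLE drifts to
the degenerate μ → −∞, σ → ∞ limit in which the lognormal reproduces any
pure power law exactly and the comparison becomes vacuous.

The plausibility taxonomy is a pure function of (p, tail size, α, the two
comparisons): *none* if p < 0.1 or the fitted tail holds fewer than 200
genes (the conservative reading — a tiny tail supports no claim either
way); *weak* otherwise; *medium* if additionally 2 < α < 3 **or** the power
law out-fits both alternatives; *strong* if both.

## Connected component fraction

CCF(S) = |S_C|/|S| with S_C the members of S having at least one edge to
another member — a direct edge, not a path.  Members absent from the network
stay in the denominator: they cannot be connected, and keeping them makes
CCF comparable across networks of different gene coverage.  CCF is monotone
non-decreasing under edge addition, so a union network dominates its
members.  Coverage counts use the strict inequality CCF > threshold.

## Diffusion

W = D^{−1/2}AD^{−1/2}; the steady state of X_{t+1} = αWX_t + (1−α)X_0 is
computed by sparse fixed-point iteration (default tol 1e−8 on the max
absolute change, max 10,000 iterations; both configurable — no natural
stopping rule exists, so the tolerance is simply set well below every
downstream decision margin).  Since ‖W‖ ≤ 1, the iteration contracts at rate
α and equals the closed form (1−α)(I−αW)^{−1}X_0, which serves as the dense
test oracle on graphs up to ~2,000 genes.  α defaults to 0.7 and is exposed
everywhere.  The normalized profile X*′ = X*/ΣX* sums to one and enables
comparison between seeds of different sizes.

## Pathway cross-talk

S12 is the mean normalized steady-state mass on P2's genes when P1∩network
(binary) seeds the diffusion; PCT = (S12+S21)/2, symmetric by construction
(bitwise, being an explicit average).  One diffusion is run per pathway, not
per pair.  Genes shared by both pathways contribute to both seed and target;
excluding them would break the unit-mass normalization identity
Σ_{P2 ∈ partition} S12·|P2| = 1.  Set members absent from the network are
dropped from both the numerator and |P2| (diffusion is undefined off the
network); a `count_absent` flag switches to the full set size.  Note the
deliberate asymmetry with CCF's denominator: PCT is a within-network
proximity, CCF a coverage measure.  Self-PCT is computed but excluded from
conservation summaries; conservation reports per-pair mean, sample SD and
SNR = mean/SD across networks (flagged infinite where SD = 0).

## Disease-gene prioritization

Known disease genes present in the network seed a binary X_0; every network
gene is ranked by decreasing steady-state score with a lexicographic
tie-break, making the pipeline deterministic given the RNG seed.
Performance is the partial AUC of the ROC up to a false-positive rate of 0.2,
unnormalized (maximum 0.2; random expectation fpr²/2 = 0.02), averaged over
the five folds of one seeded 5-fold partition (five folds = five trials).
Negatives exclude **all** known disease genes, training and held-out alike:
training genes trivially receive top scores, and letting them act as
negatives would distort the ROC.  Top-rank overlap between prioritizations
uses |top-k ∩ top-k|/k with k defaulting to 100.

## Comparison machinery

Spearman correlations (average ranks for ties) are computed per network pair
on the positions where both vectors are defined — per-pair intersection,
not the global one (a global-intersection variant is available by
restricting the input vectors).  Per-type matrices average into C_t with the
diagonal reset to 1 (self-correlations by definition); C_I = Σ_t C_t; missing
analysis types reduce the sums rather than aborting, with a logged warning.
The similarity network points each network to its k (default 4) most similar
by C_I, ties broken lexicographically by target name; communities come from
Clauset–Newman–Moore fast-greedy modularity optimization (igraph) on the
undirected simple projection.  R_i sums, over types, the mean off-diagonal
correlation of row i of C_t.

## Synthetic data: what it emulates, and what it does not

Generators produce BA, Erdős–Rényi and duplication-divergence graphs
(heterogeneous density, optionally heavy-tailed), planted dense complexes
(edges only added, never removed), snowball-sampled pathway/disease modules
with a cohesiveness dial interpolating between a connected neighborhood (1)
and a uniform random set (0), and degree-preserving rewiring families
(double-edge swaps touching a stated fraction of edges; LCC retained
afterwards).  Default scale is 1,000–2,000 genes: large enough for the
200-gene tail rule and stable Spearman estimates, small enough for the dense
diffusion oracle.  Degree-preserving (rather than uniform) rewiring is used
so that topology-correlation experiments isolate structural change from
degree-sequence change.

These generators reproduce the statistical mechanisms the analyses rely on —
heavy tails, planted modularity, guilt-by-association signal, controlled
structural divergence.  They deliberately do **not** reproduce literature
bias, realistic gene symbols, confidence-score distributions, study-specific
false-negative patterns, or the size (~10⁴ genes, 10⁵–10⁶ edges) of real
interactomes.  Passing tests therefore certify the correctness and
calibration of the measurement machinery, not any empirical claim about
real interactome resources.

## Known limitations

* Spectral centrality is one defensible reading of "Laplacian deformation"
  importance; other definitions exist, and its O(n⁴) cost limits it to
  networks of a few thousand genes.
* The power-law/lognormal comparison is decided by the likelihood sign
  alone; near-ties (common, since the constrained lognormal still
  approximates power laws well) carry no significance statement.
* The bootstrap p-value has granularity 1/n_boot (default 1/100); the
  taxonomy's p = 0.1 gate is therefore coarse at the default setting.
* Cross-validation uses one seeded partition; fold-to-fold variance is
  reported but no across-partition variance is estimated.
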