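# Methods

## Network model

The package builds an undirected, signed gene co-expression graph from a
gene × sample FPKM matrix.  Pearson's correlation (PCC) is computed between
every pair of usable genes over all replicate samples — raw FPKM, no
transform, by default; a `log2(FPKM+1)` option and a tissue-median option
exist for users who prefer variance-stabilized or replicate-collapsed
profiles, but both are off by default.  Each gene then ranks all partners
by descending |PCC|, and the mutual rank MR(A,B) = √(Rank(A→B)·Rank(B→A))
scores each pair symmetrically.  Using |PCC| for ranking is a deliberate
choice: ranking by signed PCC would push strongly anti-correlated pairs to
the bottom of every list and make a negative co-expression network
unreachable through the same MR machinery.

Edge admission is the conjunction of a correlation floor with a union of
two MR routes:

* |PCC| ≥ `pcc_cutoff` (default 0.7, applied to the absolute value so the
  negative network is reachable), **and**
* MR ≤ `mr_cutoff` (default 30) **or** the pair is in either endpoint's
  `top_k` (default 3) partners by MR.

The top-k route guarantees each well-correlated gene a minimum
connectivity even when its neighborhood is sparse; reading the two routes
as an intersection instead would strand most genes and is not how the
thresholds are used here.  Edge sign is the sign of the PCC; positive and
negative edges live in one graph with per-sign subgraph accessors.

Ties — in |PCC| during ranking and in MR during top-k selection — are
broken by ascending gene id.  This matters in the zero-noise limit of the
simulator, where whole modules tie at |PCC| = 1, and makes every construct
byte-reproducible.  Correlations are clipped to [−1, 1] to absorb
floating-point excursions; an all-pairs naive reference implementation
agrees with the vectorized path to 1e−12 and the rank/edge structures agree
exactly (see the test suite).

Zero-variance genes have no defined correlation; they are flagged and
excluded from ranking rather than being assigned 0.  Genes expressed in
fewer than `min_expressed_tissues` tissues (default 1) are dropped before
correlation — unexpressed genes carry no usable signal and would otherwise
contribute noise-only edges.  This is why network coverage of the input
gene list is below 100%.

## Expression calling

Replicates are collapsed to the per-tissue **median** (midpoint of the two
central values for even counts) — robust to a single discrepant replicate,
and the same summary is used everywhere for consistency.  A gene is called
expressed in a tissue when its median FPKM is **strictly greater than
0.3**; 0.3 itself is not expressed.  The 0.3 floor is a widely used
lower bound for calling a transcript present in FPKM units.  Whether the
call should be made on tissue medians or per-sample values is genuinely
ambiguous in practice; this package applies it to medians and exposes a
per-sample variant (`per_sample_expressed`).

Differential-expression classes are consumed, not computed: a table of
log2 fold changes and BH-adjusted p-values (as produced by DESeq-style
tools) is classified up / down / ns with strict inequalities
(padj < 0.05 and |log2FC| > 1 by default; a stricter |log2FC| > 2 variant is a
parameter away).  Boundary values are ns.

## Enrichment statistics

The hypergeometric point probability P(X = k) = C(K,k)·C(N−K,n−k)/C(N,n)
is evaluated in log-gamma space, so transcriptome-scale counts (N in the
hundreds of thousands) cannot overflow.  Significance is the one-sided
upper tail P(X ≥ k) — Fisher's exact test for over-representation — since a
point probability is not a significance level.  BH FDR follows the
step-up definition; when sets carry category labels the adjustment is
applied within each category, mirroring the common practice of separate GO
and pathway FDR tracks.  The universe N defaults to the union of set
members when reading a GMT and is configurable; for synthetic data it is
the full simulated gene complement.

## The synthetic generator

`simulate_expression` emulates a multi-tissue RNA-seq design (defaults: 10
tissues × 3 replicates, matching the tissue panels typical of de novo
transcriptome studies) with planted structure:

* **Modules** (20 × 25 genes): each module draws a latent per-tissue
  activity archetype, uniform on [0, 1] per tissue.  A member's tissue mean
  is `expression_scale × latent` (sign +1) or
  `expression_scale × (max(latent) − latent)` (sign −1); the reflection
  makes opposite-sign pairs exactly anti-correlated at zero noise, giving
  analytic anchors for tests.  10% of each module is anti-correlated —
  negative co-expression is the minority mode in real networks.
* **Background** (300 genes): independent latent profiles, so background
  genes correlate with modules only by chance.
* **Silent** (50 genes): uniform on [0, 0.3] in every sample — never called
  expressed, and therefore excluded from the network; they exist so that
  coverage below 100% is exercised.
* **Noise**: replicate values are `tissue_mean × 2^ε`, ε ~ Normal(0,
  `noise_sd`) with default 0.2 — multiplicative log-normal dispersion keeps
  FPKM non-negative without clipping and roughly matches the replicate
  scatter of abundance estimates.

Archetypes are rejection-sampled (greedy, batched, with restarts) so that
no two modules' profiles exceed |corr| = 0.45.  The cap is the generator's
separability contract: planted membership is only usable as ground truth if
between-module gene correlations stay clearly below the within-module
range.  With ~30 samples a PCC estimate fluctuates by ~0.12 (one s.e.), so
a cap at 0.45 keeps realized cross-module correlations below ~0.6, safely
under the 0.7 edge floor; much tighter caps approach the packing limit of
20 profiles in the 9-dimensional centered tissue space and stall the
sampler.  Consequences of this design worth knowing:

* Real tissue programs can be far more correlated than 0.45, and real
  modules overlap hierarchically; module recovery numbers on this
  generator say the pipeline is correct, not that real-data modules are
  this clean.
* Within-module correlations at the default noise are ~0.94 — stronger
  than typical co-expression signal.  The generator is a correctness
  harness, not a difficulty benchmark.
* Gene expression here has no library-size variation, no count-level
  (Poisson/NB) noise at low abundance, no batch structure, and no
  correlation between modules and DEG status.

Each operation (expression, gene sets, DEG truth, DEG table) draws from its
own RNG stream keyed by (seed, operation), so adding operations never
perturbs existing seeded outputs.  The DEG table gives planted genes their
true fold change (|log2FC| ≥ 1.5) with padj < 0.01 and null genes
|log2FC| < 0.5 with padj uniform on (0.05, 1), so default thresholds
recover exactly the planted set — again an anchor, not a realism claim.

## Numerical and design choices

* **Problem sizes**: tests and the acceptance script run the default
  850-gene design (≤ 5 seeds) and smaller; the all-pairs reference
  comparisons use ≤ 200 genes, where the naive O(n²) oracle is fast.
* **Degenerate inputs**: empty matrices, constant genes/samples, unknown
  query genes, out-of-range p-values and malformed hypergeometric counts
  all raise informative errors rather than propagating NaN.
* **Degree distribution**: the log-log slope/R² is a least-squares fit over
  degrees with count ≥ 1; isolated nodes are reported separately since they
  have no log-degree.  Planted near-clique modules concentrate degrees
  around the module size, so the simulator's slope is *not* negative — the
  scale-free shape is a property of real transcriptome networks that this
  generator does not emulate.
* **Neighborhoods** apply the query's MR bound uniformly, to query–neighbor
  spokes and to induced neighbor–neighbor edges alike.
* **Determinism**: run manifests record parameters and input checksums but
  no timestamps; repeated runs with a fixed seed are byte-identical.

## Known limitations

* FPKM computation, DE model fitting, and annotation transfer are out of
  scope; the package consumes their outputs.
* MR computation holds the full n × n correlation matrix in memory —
  appropriate up to a few tens of thousands of genes, not for the
  hundreds of thousands of transcripts of a raw de novo assembly without
  pre-filtering.
* The Fisher test treats genes as exchangeable; no correction for gene
  length, GC bias or annotation redundancy.
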