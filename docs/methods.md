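# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data do and do not establish about real cohorts.

## Attribute weighting by phi-correlation

Binary functional attributes are weighted by the magnitude of their
phi-coefficient against a binary cancer-gene label, computed from the 2×2
contingency table as |ad − bc|/√((a+b)(c+d)(a+c)(b+d)), which is identical
to √(χ²/N) for the uncorrected 1-df chi-square. The package reports the
unsigned magnitude as the weight (the scoring model needs a non-negative
quantity) and the enrichment direction separately; p-values come from the
uncorrected chi-square. Any zero margin leaves phi undefined and raises
with the offending margin named, rather than returning 0 or NaN.

The packaged reference weight table (`data/reference_weights.tsv`) ships the
seven published weights as data: the underlying contingency counts are not
distributed with them, and back-solving N = χ²/r_φ² from the published
p-values gives mutually inconsistent values (roughly 5,800–6,700), so the
table cannot be re-derived and is treated as input.

## Boolean root decomposition and the bit order

A gene's 7-bit pattern with k set bits has 2^k − 1 roots (non-empty subsets
of the present attributes). "Probability of a root" is implemented as the
arithmetic mean of the root's attribute weights; the gene score is the sum
over roots. Since an attribute appears in C(k−1, j−1) of the size-j roots,
the sum collapses exactly to ((2^k − 1)/k)·Σw, and the root-enumeration
implementation is tested against this closed form at 1e-12 for all 127
non-empty patterns.

The assignment of attributes to bit positions is not arbitrary: an
exhaustive search over all 7! assignments (kept as a test oracle) shows
that only the order (Meth, SP, PK, TS, PTM, TF, Hub) — with PK and TS
interchangeable, as they are always jointly present in the reference
patterns — reproduces the four published non-methylation pattern scores at
1e-4. That tolerance reflects the 6-dp rounding of the published weights.
The two methylation-containing patterns (1011001, 1011010) do not
reproduce under the pinned order: the package computes 0.643031 and
0.552127 against the published 0.697808 and 0.584684. No single assignment
fixes this — an assignment chosen per pattern can come within ~7e-4 of
either published value individually, but it contradicts the assignment the
other four patterns pin — so `reference_score_report()` surfaces both the
computed and the published value with a `reproduced` flag instead of
guessing at the cause.

The shortlist uses a strict inequality at the 0.5 cutoff, and genes with an
all-zero pattern score 0 by convention (they have no roots).

## Rank-product differential expression

The unpaired two-class design forms all K = n₁·n₂ tumor-minus-normal log2
ratio lists. Genes are ranked per list (descending ratio for the
up-regulation statistic, ascending for down; ties by average rank) and
RP = ∏ rᵢ/nᵢ is accumulated in log space to avoid underflow at large K.

pfp(g) = E[#{null RP ≤ RP(g)}]/rank(g), with the expectation over a
permutation null. Two nulls are provided:

- **sample_labels (default).** Tumor/normal labels are reassigned across
  samples and the full rank product is recomputed per permutation. This is
  the appropriate null here: the K pairwise lists share samples, so a null
  gene's noise persists across lists and list-wise ranks are strongly
  dependent. Because each gene's own expression shift survives label
  mixing, truly differential genes contaminate this null and depress
  power; genes detected at pfp ≤ 0.05 are therefore excluded from the null
  pool and the counts recomputed, iterating to a fixpoint (≤5 rounds). On
  data with no signal nothing is excluded, keeping the null-data
  calibration intact (measured false-call rate 0 at pfp ≤ 0.05; 93% of
  planted 2-log2-unit shifts recovered at 10 vs 10 samples, 1000 genes,
  100 permutations).
- **rank_uniform.** Each list's rank vector permuted independently — the
  classic null for K independent replicate comparisons. It is exact in
  that setting (and is verified against full enumeration on a 3-gene,
  2-list instance) but anti-conservative for pairwise two-class lists
  (~24% false calls in the same null-data experiment), so it is not the
  default.

A gene significant in both directions (possible at permissive cutoffs) is
assigned the direction with the smaller RP and flagged.

## Interactome rules and hubs

The four high-confidence criteria (≥2 source databases, ≥2 detection-method
classes, domain–domain support, ≥2 PMIDs) are combined disjunctively: they
are parallel evidence channels, and OR maximizes coverage while the
recorded per-edge provenance lets a user re-filter conjunctively. Detection
methods are taken at the granularity of four classes (biochemical,
biophysical, imaging, protein complementation assay), with raw terms mapped
by configuration. Hubs are nodes of degree ≥ 5 in the filtered network
(strict ≥, so degree 4 is excluded), and hub calls can be written back into
the Hub bit of the attribute table.

## Co-expression and centralities

Probe-level validation data are log2-transformed first; probes without a
gene assignment or mapping to several genes are dropped, and per gene the
probe with the highest log2 variance is retained, so correlations are
computed on the same scale as the preprocessing. Co-expression edges
require signed Pearson r strictly greater than 0.5 — anti-correlated pairs
never form edges; sub-threshold correlation bands are visualization
annotations, not edges. Zero-variance genes are excluded with a warning
(their correlation is undefined).

Betweenness uses raw shortest-path bridge counts with each unordered pair
counted once (a star centre with m leaves scores C(m,2)); no
per-component pair normalization is applied. Eigenvector centrality is
computed per connected component and max-normalized to 1 within the
component; components of one or two nodes are symmetric and score 1. The
residual column is from the ordinary least-squares fit of betweenness on
eigenvector over all nodes (residuals sum to 0); it highlights nodes whose
bridging role exceeds what their influence predicts. Curated signalling
networks are accepted as plain edge lists, with a labelled filter to drop
non-protein nodes before analysis.

## Clinical layer

The signature score is Σ up-gene − Σ down-gene expression per sample,
computed on whatever scale the caller provides (the scale is recorded by
the caller, not coerced); signature genes absent from a matrix are skipped
with a warning, mirroring validation sets that lack some genes. Tumor vs
normal separation uses the Welch unequal-variance t with
Welch–Satterthwaite df (scipy).

Median splits sort stably by (value, sample ID) and send the lower
⌈n/2⌉ samples — including the median sample at odd n — to "low", making tie
handling deterministic. Kaplan–Meier estimation and the Cox–Mantel log-rank
test (hypergeometric variance, simultaneous risk-set accounting at ties)
are delegated to lifelines behind the module interface; the test suite
checks them against hand-computed product-limit tables and an independent
permutation oracle. No multiple-testing correction is applied across
per-gene log-rank tests; the stratification layer instead uses the
deliberately less conservative α = 0.1 appropriate to small cohorts. The
combined three-gene score (default CHEK1 + AR − LYN) is scored, split and
tested identically.

## Synthetic data: what it emulates and what it does not

Defaults define a desk-scale study: 1000 genes, 10 tumor vs 10 normal
samples, 5% planted up- and 5% down-regulated genes shifted ±2 log2 units,
per-gene Gaussian noise SD 1 on the log2 scale, baselines N(8, 2²). Values
are simulated on the log2 scale but exported linear with a scale flag so
every consumer exercises the log2 preprocessing path. Attribute generation
is an independent Bernoulli per attribute at class-conditional prevalences;
the defaults encode weak associations with hub status the strongest, in
line with the ordering of the published weights, and the expected phi of
any configuration is available in closed form
(`analytic_phi`: (p₁−p₀)·√(π(1−π))/√(p̄(1−p̄))). Interaction evidence draws
each support channel independently at profile probabilities, so per-rule
pass rates are binomial. Survival times are exponential with the "poor"
group's hazard a configurable multiple (default 5) of the baseline 1/365
per day; censoring is an independent exponential clock with rate
baseline·c/(1−c), giving an expected censored fraction ≈ c in the baseline
group.

These generators validate the *machinery*: calibration, power under planted
effects, closed-form recovery, determinism. They do not emulate probe-level
artifacts, correlated attributes, batch effects, non-exponential hazards or
informative censoring, so passing tests demonstrate correctness of the
methods, not performance guarantees on real cohorts.

## Problem sizes and determinism

Test and acceptance runs use 1000-gene cohorts with 100 permutations, 100
survival replicates at n = 200, and a 10⁴-permutation log-rank oracle —
sizes at which every statistical check has comfortable Monte-Carlo margins
while the whole suite stays fast. All randomness flows through
`numpy.random.default_rng` seeds held in the configuration objects; a fixed
seed gives bit-identical matrices, TSVs and pipeline manifests.
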