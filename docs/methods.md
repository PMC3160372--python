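# Methods

## Causal graph model

The graph distinguishes *forms* of a biological entity: a protein, its
kinase or transcriptional activity, and a site-modified variant are separate
nodes joined by unsigned non-causal edges (`has-activity`,
`has-modified-form`, `has-member`, `has-component`).  Causal edges are
signed (+1 increases, −1 decreases), keyed by `(source, target, sign)`, and
carry one or more evidence records (citation id, quoted sentence, species,
tissue).  Re-asserting an existing edge merges evidences rather than
duplicating the edge, so a file with repeated evidence rows and its merged
in-memory form serialize to the same fixed point.  Cycles are legal
(biological feedback is common); self-edges are not, since a signed
self-assertion has no use in the scoring below.

Species augmentation translates a donor graph's causal edges through an
ortholog map into a base graph, keeping donor-species evidence.  The
operation is idempotent; many-to-many ortholog maps default to
*expand-all* (assert every combination), with *skip-ambiguous* and *error*
policies available because no principled resolution exists without curation.

`downstream_mrna_targets` is the reasoning primitive: the mRNA-class genes
reachable from a node within `depth` causal edges, each with the product of
edge signs along its path; genes reachable with both signs are *ambiguous*
(0).  The default depth is 1 — the scoring evaluates a controller against
its directly asserted RNA expressions; deeper propagation is an explicit
opt-in because sign products over long paths dilute causal specificity.
The search runs breadth-first over (node, sign) states, so it is polynomial
even in cyclic graphs.  A node's own gene symbol is always excluded: a
transcript does not explain its own change.

## State-Change chain

* **Background correction** models each column as background N(μ, σ²) plus
  exponential(θ) signal and replaces x with E[signal | x] (positive,
  monotone).  μ is the kernel-density mode, σ the RMS of sub-mode
  intensities, θ the mean exceedance above the mode.
* **Quantile normalization** maps every column onto the mean order-statistic
  distribution (stable-sort rank assignment, hence idempotent and
  rank-preserving).
* **Summarization** median-polishes each probe set's log2 probes × samples
  block; the per-sample value is overall + column effect.  Single-probe
  sets pass through unchanged.
* **Contrast**: per probe, log2 FC = mean(treated) − mean(control) and a
  pooled-variance t.  With `moderation="empirical-bayes"` (default) the
  per-probe variances s² are shrunk to (d₀s₀² + d·s²)/(d₀ + d) with
  (d₀, s₀²) fitted by moment matching on log s² (digamma/trigamma
  identities; trigamma inverted by Newton), and the t gets d + d₀ degrees of
  freedom.  When the observed spread of log-variances does not exceed the
  χ²-sampling expectation, d₀ = ∞ and the prior is the arithmetic mean
  variance.  This matches Bioconductor limma's eBayes to machine precision
  (cross-checked in the test suite with an Rscript oracle).
  `moderation="none"` gives the textbook pooled t; zero-variance probes are
  then flagged degenerate with NaN p.
* **FDR**: Benjamini–Hochberg step-up via statsmodels; NaNs propagate with
  a warning and do not count toward the number of tests.
* **Calling**: a probe passes at adjusted p ≤ 0.05 *and* |log2 FC| >
  log2(1.3) ≈ 0.3785 *and* (if configured) linear mean intensity above the
  abundance floor in at least one group.  The fold-change gate is evaluated
  on the log2 scale against the linear 1.3 threshold, and the abundance
  floor on linear group means, before the log transform.  A gene changes if
  ≥1 probe passes; probes passing in opposite directions drop the gene
  (counted as a conflict) because a directionless change cannot enter
  directional scoring.  The measured universe is every gene with ≥1 mapped
  probe; unmapped probes are excluded and counted.

Default thresholds (p 0.05, FC 1.3, floors 250/250/none/10 per platform)
are configuration, not code; the ≤/≥ conventions are inclusive at the
cutoff, and "above the floor" is strict.

## RCR scoring

With universe size N, K State Changes, a node's n measured targets, k of
them changed and, among the direction-carrying ones (m = k − ambiguous),
ℓ agreeing with *direction × edge sign*:

* richness = P(X ≥ k), X ~ Hypergeom(N, K, n),
* concordance = P(X ≥ ℓ), X ~ Bin(m, q), q = 0.5 by default.

Significance requires richness ≤ 0.1, concordance ≤ 0.1 and ℓ ≥ 4.  The
minimum-of-four rule is enforced twice and independently: candidacy needs
≥ 4 *measured* downstream targets, significance needs ≥ 4 *consistent*
changes — the looser reading alone would admit nodes that can never reach
significance, and the stricter alone would score nodes with no meaningful
null.  No multiple-testing correction is applied across hypotheses; the
0.1/0.1 cutoffs are raw by design, since the output is a ranked worklist
for human evaluation rather than a family of confirmatory tests.

Open-design choices, each exposed as configuration with the stated default:

* **Richness universe** = all platform-measured genes (`universe_mode=
  "platform"`); the alternative `"kb-covered"` restricts to genes downstream
  of some graph node.  The platform universe matches the universe the
  State-Change chain actually filtered.
* **Concordance null q** = 0.5 (a changed gene is equally likely up or
  down); `q="empirical"` uses the observed up-fraction for data with strong
  global asymmetry.
* **Ambiguous-sign targets** count in richness overlap but not in
  concordance trials: they attest connectivity but carry no direction.
* Output ordering is (concordance, richness, node id, direction) so results
  are byte-reproducible.

## Verification

A consistency cell is the pure sign rule
`predicted × expected == observed` applied to the best-scoring significant
hypothesis per node and dataset (lowest concordance, then richness, then
+1 before −1 — the scores themselves essentially never tie).  Expected
directions are curated inputs, never inferred.  Coverage counts *possible*
nodes — network nodes with ≥ min_targets measured downstream mRNA targets
in the reasoning substrate (which may be a much larger knowledgebase than
the network itself) in at least one dataset universe — and the subset
actually predicted; an alternative `consistent-changes` mode counts nodes
with ≥ min_consistent direction-consistent observed changes instead, since
the eligibility criterion can be read either way.  Expansion candidates are
significant hypotheses for out-of-network nodes, grouped by (node,
direction) with supporting datasets: a curation worklist, never
auto-merged.

## Synthetic benchmark

The generator emulates exactly the structure the method consumes, not
microarray physics: controller (activity) nodes with signed edges to mRNA
nodes, and log2-Gaussian expression in which genes downstream of planted
active controllers shift by `delta × direction × edge sign`.  Defaults —
200 controllers × 10 targets inside a 5000-gene pool, 20 planted, δ = 2.0
log2 units, σ = 0.5, 3 vs 3 replicates, baseline 2⁸ ≈ 256 linear — describe
a well-powered two-group microarray study on a genome-scale platform; the
baseline is placed near the scale where real abundance floors (10–250
linear units) operate.  Controllers' target sets are disjoint by default
(`overlap_allowed` enables the conflict pathway, where opposite implied
signs on a shared gene sum and may cancel, flagged in the truth record).
Each stage draws from its own seeded stream (seed, seed+1, seed+2) so
stages regenerate independently.

What passing the harness shows — and does not: the generator has no
probe-set structure, no intensity-dependent variance, no correlated genes
and no batch effects, so recovery there demonstrates the *logic* of the
chain (filtering, counting, tail probabilities, direction bookkeeping), not
robustness to real microarray artifacts.  The probe-set and background
steps are instead tested against hand-computable oracles and limma.

The recovery harness reports sensitivity (planted pairs found significant),
direction accuracy (best direction per recovered controller vs truth),
precision, and the significant fraction in a matched zero-effect run.  At
the defaults above the expected operating point is sensitivity ≈ 1 and a
null fraction ≈ 0: a 2.0 log2-unit shift at σ = 0.5 with 3v3 replicates
gives per-gene power near 1, and 10/10 concordant targets yields
concordance 2⁻¹⁰ ≪ 0.1.

## Numerical notes and limitations

* Hypergeometric/binomial tails come from scipy survival functions
  (`sf(k−1, …)`); both are verified against exhaustive enumeration for all
  instances with universe ≤ 12 in the tests.
* Median polish runs ≤ 10 iterations to a 1% absolute-residual change;
  exact for additive tables.
* The trigamma inversion uses the asymptotic branches 1/√y (y > 10⁷) and
  1/y (y < 10⁻⁶) around the Newton iteration.
* Only two-group contrasts are supported; multi-factor designs are out of
  scope, as is parsing binary CEL files (the package accepts extracted
  intensity tables).
* Richness and concordance are marginal scores per hypothesis: overlapping
  target sets between related nodes make neighboring hypotheses correlated,
  and no correction is attempted — matching the intended use as a ranked
  candidate list for expert review.
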