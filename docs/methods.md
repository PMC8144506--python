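# Methods

`spongenet` infers lncRNA-driven competing-endogenous-RNA (ceRNA)
networks from a gene × sample expression matrix and tables of validated
miRNA–target interactions. The procedure has four stages, mirroring the
construction used for the 22-sample tetralogy-of-Fallot heart cohort it
was built to reproduce in miniature:

1. **Evidence integration.** miRNA–lncRNA and miRNA–mRNA interaction
   tables are merged and deduplicated on the
   `(miRNA, target, target class)` triple. Identifier matching is exact
   string equality after whitespace trimming — no case folding, no
   miRBase-version harmonization; integration across database releases is
   assumed to have happened upstream. The miRNA universe for the
   enrichment test is pooled over both target classes, because a sponge
   pair's overlap is judged against all miRNAs with any evidence.
   A `(miRNA, target)` pair annotated with two different target classes
   is rejected rather than resolved silently, since the class drives pair
   enumeration.

2. **Candidate sponge pairs.** For each lncRNA–mRNA pair sharing at
   least `min_shared` (default 1) evidence miRNAs, the overlap `k` of the
   lncRNA's `n` and the mRNA's `K` regulators within the universe of `N`
   is scored by the hypergeometric upper tail P(X ≥ k). The tail is
   accumulated in log space (gammaln + logsumexp), so deep tails retain
   ≥ 10 significant digits instead of collapsing through `1 − cdf`
   cancellation, and an exactly-zero p is never produced for k < n.
   P-values are Benjamini–Hochberg adjusted across the whole candidate
   family (one family, not per lncRNA) and pairs with adjusted p < 0.05
   (configurable) are kept. Whether the original analysis thresholded
   raw or adjusted p at this stage is unknown; adjusted is the package's
   choice, matching the BH < 0.05 convention of the final stage.

3. **Causal effects (PC-stable + local IDA).** Over the union of
   candidate-pair genes (not the full transcriptome — effects are only
   needed for candidates, and transcriptome-wide constraint search is not
   desk-scale), a CPDAG is estimated with the order-independent PC-stable
   algorithm: Gaussian conditional-independence tests via the Fisher
   z-transform of partial correlations (z = √(n−|S|−3)·atanh ρ, two-sided
   normal p), per-test level α = 0.01, conditioning sets capped at 3 by
   default. Partial correlations are computed by sub-inverting the
   gene–gene correlation matrix. Adjacency sets are frozen per level;
   unordered pairs are processed in lexicographic order so separating-set
   choices are canonical, which makes the output invariant to the input
   gene ordering (property-tested). V-structures are oriented from the
   recorded separating sets; conflicting orientation demands leave the
   edge undirected (a deterministic, order-independent resolution); Meek
   rules R1–R4 are applied to closure. The Meek/orientation machinery is
   validated against orientation consensus over exhaustively enumerated
   Markov equivalence classes (all DAGs on ≤ 5 nodes).

   Local IDA then estimates, per pair (x = lncRNA, y = mRNA), the
   multiset of total causal effects compatible with the CPDAG: for every
   subset S of x's undirected neighbors whose promotion to parents
   creates no new v-structure at x (every member of S pairwise adjacent
   to the rest of S and to x's directed parents), the effect is x's
   coefficient in the least-squares regression of y on {x} ∪ parents(x)
   ∪ S, and 0 when y itself falls in the adjustment set. The summary is
   the conventional IDA lower bound: the minimum-absolute element,
   carrying its sign; ties break toward the smaller, lexicographically
   earlier parent set. The multiset is tested to coincide exactly with
   enumeration over all consistent DAG extensions for every CPDAG on
   ≤ 4 nodes. Causal sufficiency is assumed, as IDA requires; in
   rRNA-depleted long-RNA data the shared miRNAs are *latent*
   confounders, so summaries are screening annotations, not unbiased
   effect estimates — faithful to the original procedure, not a claim of
   its correctness.

4. **Edge calling and hubs.** Each candidate's Pearson correlation r on
   the shared transformed matrix gets the Fisher-transform p-value
   (the `corPvalueFisher` convention), BH-adjusted jointly across
   candidates; edges require adjusted p < 0.05 and, by default, r > 0
   (ceRNA co-regulation predicts positive correlation; the reported
   exemplar correlations are all positive). Hub lncRNAs are the top
   max(1, ⌊0.2·L⌋) by degree, ties broken lexicographically; with the
   published network's 24 lncRNAs this yields 4 hubs.

## The causal-effect gate

A cutoff on the IDA summary (`effect_min`, strict >) is available but
**disabled by default**, deliberately. The minimum-absolute summary is
exactly 0 whenever the pair's edge is undirected in the CPDAG (the
target then enters one valid adjustment set), and an undirected edge is
precisely what latent shared-miRNA confounding produces for an isolated
pair. A strict positive-effect gate would therefore discard the sponge
signal itself. The published construction gates only on the BH-adjusted
correlation p; effects are computed and reported as edge annotations
here, and the gate can be enabled for sensitivity analyses.

## Expression handling

The low-expression filter removes genes whose row total is strictly
below `min_total` (default 100 counts across samples; a row summing
exactly to the threshold is kept). In the pipeline, `min_total = 0`
disables the filter — on Gaussian-scale simulated data a literal
row-sum cut would be meaningless. The default transform for the
correlation and causal stages is log2(v+1): the upstream unit (raw vs
normalized counts) is not prescribed, Gaussian CI tests and Pearson
correlation behave better on log scale, and both stages always consume
the same transformed matrix. No library-size normalization is performed;
callers may pre-normalize. `ExpressionMatrix` admits any finite reals;
non-negativity is enforced only by the log transform, so simulated
Gaussian-scale matrices flow through with transform `none`.

## Synthetic sponge systems

The generator builds a linear-Gaussian structural equation model of the
ceRNA mechanism: exogenous miRNA nodes, each planted (lncRNA, mRNA) pair
sharing a planned number of common miRNA parents with negative
coefficients drawn around `repression_strength`, optional direct
lncRNA→mRNA edges, unit-variance Gaussian noise, and every node equal to
the weighted sum of its parents plus noise. miRNA rows are withheld from
the emitted matrix — as in rRNA-depleted long-RNA sequencing, the
confounders are unobserved. Evidence tables contain one record per true
miRNA→target edge, thinned by a false-negative rate and padded with
spurious non-edge records at a false-positive rate; all draws are pure
functions of the spec seed.

Defaults: 30 miRNAs, 12 lncRNAs, 20 mRNAs, 22 samples (the study's
cohort size), repression −0.8, noise sd 1, fp = fn = 0.05, and a sharing
plan of exactly three pairs with 5 shared miRNAs each. Planted-pair
genes are purely shared-regulated — maximal regulator overlap is the
sponge signal itself (population correlation s·b²/(s·b²+1) ≈ 0.76 at
s = 5, b = −0.8), and at n = 22 a pair diluted by private regulators
(r ≈ 0.66) would sit near the detection boundary rather than being
"strong". All other genes draw one private miRNA parent from a
class-specific pool; the pair-common, lncRNA-private and mRNA-private
pools are disjoint, so the planned pairs are exactly the true sponge
pairs and precision/recall scoring against the truth file is exact.
Accidental within-class regulator sharing is allowed (it creates
realistic lncRNA–lncRNA correlation but no spurious sponge pair).

What the simulator does **not** emulate: count noise (expression is
delivered on the Gaussian scale; a log-normal/negative-binomial count
layer is a non-goal), library-size effects, miRNA titration kinetics,
and the identifier heterogeneity of real databases. Passing tests
therefore demonstrate correctness of the statistics and estimators under
the model's own assumptions, not performance on real RNA-seq.

## Benchmark designs

`spongenet.benchmarks` fixes two estimation benchmarks. CPDAG recovery
uses a 5-node diamond-with-tail DAG (fork v1→{v2,v3}, collider
v2→v4←v3, tail v4→v5; coefficients 0.7–1.0, n = 5000, α = 0.01) whose
equivalence class mixes forced and unforced orientations. At α = 0.01
any sparse design carries an irreducible ≈α-per-separable-non-edge
false-positive floor (CI tests at the same pair are strongly
correlated, so multiple separators barely multiply protection), which
is what limits the recovery rate to ~96–99%; denser 5-node designs fare
far worse because conditioning near colliders suppresses the partial
correlations that power the tests. IDA recovery gives x three mutually
nonadjacent collider parents, so x's orientation (and then x→y via Meek
R1) survives a single false parent–parent edge; the whole estimation
path — PC-stable, then local IDA — is exercised per seed.

## Numerical and degenerate-case conventions

- Fisher tests saturate at |ρ| = 1: p = 0, dependence asserted.
- Hypergeometric arguments are validated against the named inequalities
  (0 ≤ k ≤ min(n, K) ≤ max(n, K) ≤ N, N ≥ 1).
- Regressions with conditioning/adjustment condition number > 1e10 are
  treated as rank-deficient: a conditioning set raises an error in the
  CI test; an adjustment set is skipped in IDA (error only if all sets
  fail).
- All tables are written deterministically sorted with fixed float
  formats; manifests omit timestamps, so identical inputs and config
  give byte-identical outputs.
- Empty candidate lists, empty networks and hub selection on empty
  networks are respectively: allowed, allowed, an error.

## Problem sizes

The shipped experiments use n = 5000 samples for the graph benchmarks
(100 replicates for CPDAG recovery, 50 seeds per effect size for IDA),
20 seeds each for null calibration and sponge recovery at the 22-sample
study design, and exhaustive enumeration up to 4 nodes (IDA oracle) /
N = 12 (hypergeometric oracle). These sizes characterize the estimators
well while keeping a full run in the tens of seconds.

## Known limitations

- Causal sufficiency is knowingly violated by design (latent miRNAs);
  IDA summaries are screening scores.
- PC-stable's false-positive floor at fixed α bounds equivalence-class
  recovery regardless of sample size.
- The pipeline's CPDAG spans only candidate-pair genes; effects are not
  adjusted for genes outside that set.
- No count-scale noise model; no identifier harmonization; no
  differential-expression or enrichment downstream analyses.
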