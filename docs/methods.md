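# Methods

This note records the models behind `suscape`, the defaults that matter,
what the synthetic cohorts do and do not emulate, and the choices made
where the design was genuinely open.  Nothing here states a result the
test suite or `scripts/acceptance.py` does not itself compute.

## Read-depth copy-number estimation

The read-depth (RD) method assumes mean sequencing depth in a window is
proportional to the copy number of the underlying sequence.  The pipeline
operates on fixed 1 kb bins over the repeat-masked genome; a bin enters
the analysis only if ≥ 300 of its bases are unmasked (`min_unmasked`),
since depth over a handful of unmasked bases is too noisy to scale.
Coordinates are 0-based half-open throughout; on disk everything is BED or
plain TSV.  Sex chromosomes are handled by a configurable chromosome
blacklist.

Individuals of a population are pooled by summing raw bin depths before
any correction — CN is then inferred once per population from the pooled
signal, which raises sensitivity at the cost of conflating within-
population variation (an accepted property of the design; individual-level
tracks can be run as one-member "populations").

**GC correction.** Short-read coverage is biased at extreme GC.  The
correction is multiplicative per GC stratum (width 0.01 over [0, 1]):
factor(s) = mean reference depth / mean reference depth in stratum s,
computed over a reference bin set.  Strata with fewer than 100 reference
bins inherit the nearest populated stratum's factor; if *no* stratum is
populated (tiny demo genomes with a sparse seed set) the correction
degrades to factors of 1 with a warning rather than amplifying noise.
Factors are finally rescaled so the reference-set mean depth is exactly
unchanged, which makes "correction does not move the reference mean" an
identity rather than an approximation.

The reference set is an open choice; the default ("diploid") fits
provisional factors on the seed regions, calibrates, then refits on the
stage-2 diploid bin set and recalibrates, so the final factors come from
genome-wide diploid sequence rather than genic seed regions whose GC runs
high.  "seed" and "all" are available.

**Diploid calibration.** Stage 1 takes the mean corrected depth over bins
overlapping the assumed-diploid seed regions (orthology-derived gene
regions in the real analysis; simulated windows here), requiring ≥ 50
bins.  Stage 2 assigns provisional CN = 2·d/d₂⁽¹⁾, re-classifies every
bin with provisional CN ∈ [1.5, 2.5) as diploid, and recomputes d₂ once
from that set.  The window is symmetric around 2 on the left and open at
2.5 to dovetail with the MCR seeding threshold; exactly one recalculation
is performed.  Contamination of the seed set by non-diploid sequence is
expected and absorbed by stage 2 (tested explicitly).

**CN.** CN_bin = 2 · corrected depth / d₂, real-valued and ≥ 0.  CN
estimation is invariant to global depth rescaling by construction.

## MCRs and CNVRs

Per population, retained bins with CN ≥ 2.5 are chained into maximal runs;
runs of ≥ 6 consecutive bins become multi-copy regions (MCRs).  "Consecutive"
is defined on the retained grid: a dropped (masked) bin breaks the run, so
repeats fragment large regions — a known resolution limit.  MCRs from all
populations are merged transitively by ≥ 1 bp overlap; book-ended
intervals do not merge.  Each merged region is scored as the mean CN over
its retained bins in every population (a population with no scorable bin
is recorded as CN 0 plus a missing flag, keeping vectors rectangular for
the tree stages), and regions whose per-population CN vector has sample
standard deviation (n−1 denominator) ≥ 0.7 are ascertained as CNVRs.  The
s.d. is taken across the seven population-level values, not the fourteen
individuals, matching the pooled-track workflow; both the denominator
convention and the threshold are configurable.  Raising the s.d.
threshold can only shrink the set (tested as a property).

Deletions are not a separate call class: MCR seeding uses CN ≥ 2.5 only,
and low-CN sequence remains visible in the scored vectors.
Population-specific CNVRs are those with CN ≥ 2.5 in exactly one
population; group ascertainment re-runs the entire chain within a
population subset (≥ 2 members), and two groups' sets are compared by
≥ 1 bp overlap into shared/unique partitions, with k-of-n resampling
helpers for taxon-sampling robustness.

## Gene annotation

A gene qualifies when its total overlap with the union of CNVRs reaches
70% of the gene's length (the union reading: two adjacent CNVRs covering
40% and 35% qualify a gene).  Its CN is copied from the single CNVR with
the largest overlap.  Partitions: CNVR-OR (≥ 1 qualifying OR gene),
CNVR-nonOR (≥ 1 qualifying gene, none OR), CNVR-ALL (everything).  Mixed
OR/non-OR regions go to CNVR-OR so the partitions stay disjoint; the tie
rule is ours — the partitions are treated as disjoint downstream, and OR
precedence is the reading that keeps "CNVR-nonOR" free of OR signal.

## Rates

The copy-number difference (CND) between two samples at a locus is
|CN_a − CN_b|, binarised at ≥ 2.  The threshold makes the scale
deliberately conservative — 2 → 10 copies is at least three duplication
events but counts once — and robust to ±0.3-copy estimation noise, which
would otherwise flip a |Δ| ≥ 1 indicator constantly.  Pair rates divide
the count by the partition's locus total; SNP rates divide observed
allelic differences by the callable-site total.  The rate ratio is the
mean over pairs of CND rate / SNP rate (min and max reported alongside,
since the spread across pairs is informative); it errors on any zero SNP
denominator rather than silently dropping pairs.

## Trees

**Neighbour joining** is the standard Saitou–Nei agglomeration with the
Q-criterion.  Ties in Q are broken toward the lexicographically smallest
label pair (clusters labelled by their smallest leaf), making output
independent of input order.  A negative branch length is clamped to zero
and the deficit moved to the sibling branch, preserving the pair distance.
On additive matrices NJ provably recovers topology and branch lengths
exactly; the tests check this against brute-force topology enumeration
with least-squares branch fitting.

**Hierarchical clustering** of per-sample CN vectors uses Euclidean
distance and complete linkage (scipy's implementation; the linkage is a
flag).  The dendrogram is emitted as an ultrametric tree (branch = half
the merge-height difference).

## Discretisation and the Mkv model

CN vectors per locus rescale to k = 10 integer states:
state = round((CN − CN_min)/(CN_max − CN_min) · 9), rounding half away
from zero (pinned; "round" alone is ambiguous), so each locus's minimum
maps to 0 and maximum to 9.  The transform is invariant to per-locus
affine rescaling.  Invariant loci (CN_max = CN_min) carry no signal and
are skipped with a warning — which is exactly why the likelihood must be
conditioned on variability.

Characters evolve under the symmetric k-state model, one rate class
(the cited default hyper-prior "implies little variation among rates";
a single class is the faithful simplification), branch lengths in expected
substitutions per character.  Site likelihoods come from Felsenstein
pruning with uniform root frequencies; the ascertainment correction
divides each site likelihood by 1 − Σ_c L(all taxa constant at c).  The
pruning is validated against full pattern enumeration (tolerance 1e−10)
and both Σ(all patterns) = 1 and Σ(corrected variable patterns) = 1 hold.
A variable site on an all-zero-length tree has probability 0; the log
likelihood is reported as −inf.

**MCMC.** Metropolis–Hastings over unrooted topologies and branch
lengths: NNI proposals (edge, exchanged subtrees chosen uniformly — a
symmetric kernel) rejected outright when they break a constrained clade,
and branch-length multiplier proposals (scale 1.0) against an
Exponential(10) prior (mean 0.1 substitutions — weak but proper, scaled
to the discretised data's typical tree lengths).  The prior is uniform
over constraint-compatible topologies.  A likelihood-free run recovers
the prior mean branch length (tested), and hard constraints hold in every
sample by construction.

**Stepping stone.** Inverse temperatures follow quantiles of Beta(0.3, 1)
(β_j = (j/K)^(1/0.3)), crowding the ladder near the prior where the
integrand varies fastest; the chain runs from the posterior end toward
the prior, reusing state.  ln m̂ = Σ_j [logsumexp((β_{j+1}−β_j)·lnL_i) −
ln n] with lnL_i sampled at β_j.  Monte Carlo error is estimated by batch
means (4–20 batches per step), which is honest under the strong
autocorrelation of single-branch updates; a `thin` parameter trades
compute for effective sample size.  The estimator recovers the
closed-form Beta(2,2) integral within 0.05 on the toy model.  Model
comparison reports delta-lnL = best − model (best = 0), invariant to
constant shifts.

The five predefined constraint models: null (the scrofa-like triple —
equivalently the island quadruple — monophyletic), m1 Sver+Sumatra,
m2 Scel+Sumatra, m3 Sbar+Sumatra, m4 Sceb+China.

## The synthetic cohort

The generator states the world the analysis assumes; its defaults are the
emulated study conditions.

* **Genome:** 20 Mb single chromosome (desk-scale stand-in for a 2.5 Gb
  genome), mask density 0.35 with ~800 bp masked runs (mammalian repeat
  content), GC mean 0.42, s.d. 0.05, AR(1) autocorrelation 0.8 across
  bins.
* **Populations:** Sbar, Sceb, Scel, Sver (island clade), Sumatra, China,
  Europe (scrofa-like clade); two individuals each with per-individual
  coverages 7–18× taken from the emulated cohort's table.
* **Species history:** fixed rooted tree with unit-scale branches and two
  admixture edges, Sbar→Sumatra (0.3) and Sceb→China (0.2) — pairings the
  admixture-scenario models test.  Admixture is applied at the tips
  (recipient copies donor state with the edge proportion), a shortcut
  that captures the distance distortion without per-lineage migration
  bookkeeping.
* **CN evolution:** root CN uniform on {2..6}; events Poisson per branch;
  default event magnitude ±1 (floored at 0, clipping applied per branch).
  Non-OR loci are perturbed two ways by default: event rate ×4 (fast
  random drift, which saturates binarised distances and erodes tree
  signal) and admixture eligibility.  A single 30% introgression edge
  alone barely moves NJ — distance methods resist a minority signal until
  roughly half the loci are introgressed — so the drift term is what makes
  the OR/nonOR contrast observable, and it is the stated mechanism, not a
  tuning knob.  For rate-matched cohorts the `block` event kind moves CN
  by ±(2 + Poisson(1)): multi-copy arrays gain or lose whole blocks, so a
  single event is visible on the |ΔCN| ≥ 2 binary scale.  Under ±1 events
  a single event is invisible at that threshold and the binary CND rate is
  quadratic in the event rate, so no ±1 world can measure a ratio near the
  generating one — a limitation worth knowing when interpreting binary CND
  rates generally.
* **Depth:** per-bin read counts are negative binomial (size 60 — var
  2–4× Poisson at typical bin counts) with mean coverage·(CN/2)·g(GC)·
  unmasked/read length; depth = reads·read length/unmasked, so the depth
  mean is exactly coverage·(CN/2)·g(GC).  The noise model is our choice;
  the emulated study states none.  Default bias g(GC) =
  exp(−4(GC−0.45)²), rescaled to mean 1 over the genome.
* **Genotypes:** per-branch Bernoulli flips (XOR accumulation) give
  pairwise difference fractions ≈ path length × SNP rate.
* **Planted landscapes** (for recovery benchmarks): 60 non-overlapping,
  bin-aligned regions of 8–20 retained bins, amplifying a random proper
  subset of populations to CN 3–6, rejection-sampled to cross-population
  s.d. ≥ 1.0 — "variable region" is part of the plant, so recovery rates
  measure the pipeline, not the plant.

What the generator does not emulate: read-level artefacts (mapping
ambiguity, duplicates, insert-size effects), assembly gaps, within-
population allele frequency structure, deletions as a planted class, and
linked selection.  A green recovery test therefore establishes that the
binning/correction/calibration/ascertainment chain measures what it
claims under its stated noise; it does not establish robustness to
mapping artefacts.

## Numerical and degenerate-input choices

Sample (n−1) standard deviations everywhere a dispersion is thresholded.
NJ tie-breaks are lexicographic; region scoring uses only finite bin
values.  Constant characters are an error inside `CharacterMatrix` (the
Mkv likelihood is undefined for them) but only a warning inside
`discretize`, which drops them.  Stepping-stone ladders must have ≥ 2
steps; the marginal-likelihood container rejects non-finite estimates.
Every stochastic function takes an explicit seed and is reproducible
bit-for-bit under it; pipeline reruns with identical config+seed produce
byte-identical artifacts (tested).

## Known limitations

Single rate class and no gamma heterogeneity in the Mkv stage; no
bootstrap support on NJ trees; breakpoints are bin-resolution; the
stepping-stone MC error at demo sample counts (hundreds per step) is a
few tenths of a log unit, so delta-lnL below ~1 should not be
over-read — the analysis-scale gaps here are tens of units.
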