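# suscape

Read-depth copy-number landscapes and copy-number phylogenetics for small
multi-population cohorts of closely related species — the setting of the
genus *Sus* (pigs), where seven populations diverged only a few million
years ago and repeatedly hybridised, and where copy-number variation of
olfactory-receptor (OR) genes is a candidate barrier to gene flow.

## What it computes

**Copy number from read depth.** The genome is cut into 1 kb bins over the
repeat-masked reference; a bin is retained if ≥ 300 bases are unmasked.
Per population, the two individuals' depths are pooled, corrected by
per-GC-stratum factors (factor = reference mean / stratum mean, 0.01-wide
strata, < 100-bin strata inherit a neighbour), and calibrated in two
stages against assumed-diploid seed regions: bins with provisional
CN ∈ [1.5, 2.5) are re-classified as diploid and the mean diploid depth
d₂ recomputed once.  Then CN = 2·depth/d₂ per bin.

**CNVR ascertainment.** Runs of ≥ 6 consecutive retained bins with
CN ≥ 2.5 form multi-copy regions (MCRs); MCRs are merged across
populations by ≥ 1 bp overlap (transitively); each merged region is scored
in every population and kept as a copy-number variable region (CNVR) when
the sample s.d. of the per-population CN vector is ≥ 0.7.  Group-restricted
ascertainment and population-specific flagging follow the same rules.

**Annotation.** Genes overlapping the CNVR union by ≥ 70% of their length
inherit the CN of their largest-overlap CNVR; CNVRs partition into
CNVR-OR, CNVR-nonOR and CNVR-ALL (mixed → OR).

**Rates and trees.** Copy-number differences binarise at |ΔCN| ≥ 2 (a jump
from 2 to 10 copies counts once); pairwise rates divide difference counts
by the locus/site totals, and the mean CND/SNP rate ratio measures how
much faster copy number evolves than single nucleotides.  Trees come from
an exact Saitou–Nei neighbour joining (recovers any additive matrix) and
complete-linkage hierarchical clustering.

**Bayesian model comparison.** Per-locus CN rescales to ten states via
`round((CN − CN_min)/(CN_max − CN_min) · 9)` and is analysed under the
symmetric k-state Markov model conditioned on variable characters (Mkv):
`P_same(t) = 1/k + (k−1)/k · e^(−kt/(k−1))`, pruning likelihood, uniform
root, ascertainment divisor `1 − Σ_c L(constant at c)`.  MCMC samples
topology (NNI, constraint-respecting) and branch lengths (multiplier,
Exp(10) prior); marginal likelihoods come from stepping-stone sampling on
a Beta(0.3, 1)-quantile ladder, and constrained models (null = species
clades monophyletic; m1–m4 = hybridisation pairings) are ranked by
delta-lnL.

A synthetic-cohort generator (masked genome, tree-structured CN evolution
with drift/admixture-perturbed nonOR loci, GC-biased negative-binomial
depth, diploid-site genotypes) provides ground truth for every stage.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # 20 Mb cohort under results/cohort/
python analysis/02_call_cnvrs.py
python analysis/04_rates_and_trees.py
python analysis/05_bayes_models.py
```

`02_call_cnvrs.py` prints, for the default seed:

```
ascertained CNVRs: 60; total span 0.60 Mb
planted regions recovered: 60/60 (60 with boundary error <= 1 bin)
scored CN entries within +-0.5 of truth: 416/420 (99.0%)
CNVRs not overlapping any planted region: 0 (FDR 0.0%)
```

i.e. every planted variable region is found at bin resolution with
accurate per-population CN and no false calls.  `04_rates_and_trees.py`
measures the binarised copy-number rate against the SNP rate on a cohort
generated with CN events at 2.5× the SNP rate:

```
CND/SNP rate ratio: mean 2.35 (min 2.06, max 3.37; generating ratio 2.5)
species-tree recovery (RF=0) over 20 replicate cohorts: OR 20/20 vs nonOR 2/20
```

— the binary scale is slightly conservative (multi-step changes count
once), and OR loci recover the species tree while the drift/admixture-
perturbed nonOR loci rarely do.  `05_bayes_models.py` repeats that
contrast with marginal likelihoods:

```
partition OR    : best model = null  (delta-lnL of null = 0.00)
partition nonOR : best model = m3  (delta-lnL of null = 55.31)
```

the nonOR partition rejects the species-tree null in favour of the
Sbar→Sumatra hybridisation scenario — exactly the admixture edge the
cohort was simulated with.

A console script mirrors the stages
(`suscape run -c config.yaml`, or `simulate | cn | cnvr | annotate | dist |
tree | bayes` individually); see `suscape --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole analysis from scratch under the given seed — cohort
simulation, CN estimation, CNVR ascertainment, annotation, trees, the
Bayesian model table and the matched-rate CND/SNP comparison — prints a
one-line run summary and writes the result JSON to `--out`.
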