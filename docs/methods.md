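# Methods

## The analysis model

The package treats a multi-locus MHC IIB exon 2 amplicon dataset as draws
from the following process: an ancestral class IIB locus underwent a small
number of duplications tens of millions of years before the sampled species
radiated; each duplicate founded an *allelic lineage* whose descendants are
carried by every descendant species; balancing selection maintains divergent
alleles within lineages and elevates the nonsynonymous substitution rate at
peptide-binding-region (PBR) codons.  Sequencing samples diploid individuals
twice (two independent PCRs) with point errors and PCR-chimera artifacts.

The statistical machinery makes the matching assumptions: equal-length,
gap-free 248 nt fragments (82 complete codons at frame offset 0; the 2 nt
remainder is carried but ignored by codon statistics); K2 distances for
trees; HKY+Γ₄ for dating; modified Nei–Gojobori counting for selection.

## Codon counting conventions

Synonymous/nonsynonymous *sites* weight the single transition target of a
position by R and the two transversion targets by 1 (modified
Nei–Gojobori); R defaults to the mean K2-implied transition/transversion
distance ratio across sequence pairs and can be overridden.  Changes that
would create a stop codon are excluded from site counting, with the
remaining changes renormalised so every position still contributes one
site, and substitution pathways through stop codons are dropped from the
pathway average.  This makes the estimator consistent with the sequence
simulator, which forbids stop-creating substitutions.  Both proportions are
Jukes–Cantor corrected; p ≥ 3/4 raises a saturation error rather than
returning a number.

The codon Z-test uses Z = (d̄_N − d̄_S)/SE with means over all sequence
pairs and the SE from bootstrap resampling of codon columns (default 1000
replicates; the test refuses fewer than 100).  Under the neutral simulator
the one-tailed rejection rate at α = 0.05 is close to, and slightly below,
nominal (the bootstrap SE is mildly conservative for means of
Jukes–Cantor-corrected pair statistics).

The saturation index is the mean per-site entropy of the alignment divided
by the Monte-Carlo mean site entropy of uniform-random alignments of the
same dimensions; its p-value is a one-sample t-test of the per-site entropy
ratios against the saturated mean.  It is a deliberately simple entropy
index in the spirit of the classical test of substitution saturation, not a
re-implementation of any particular program.

## Trees

Neighbor joining uses the Studier–Keppler Q criterion with all ties broken
by lexicographic label order, so trees are bit-reproducible; negative
branch lengths are clamped to zero with the deficit shifted to the sister
branch (pair sum preserved).  NJ on K2 distances stands in for a full
likelihood search: for the deep, well-separated bipartitions that define
allelic lineages the two approaches recover the same clades, and the
distance engine is fast enough to bootstrap thousands of replicates.  An
NNI refinement under a K2 likelihood was considered and omitted — the
bootstrap/lineage machinery never needed it on simulated data.  Bootstrap
support is the fraction of column-resampled replicates whose NJ tree
contains each original bipartition; replicates with saturated distances are
dropped (more than 10% dropped is an error).

Lineage detection midpoint-roots the supported tree and reports maximal
clades with support ≥ 0.75 spanning ≥ 4 genera, outermost first, with one
aggregation guard: when a qualifying clade decomposes exactly into two or
more qualifying units (which happens to the complement of a lineage that
shares its stem bipartition with the root), the units are reported instead
of the aggregate.  Multi-genus clusters at support ≥ 0.50 are emitted in a
secondary table flagged non-significant.

## Adjusted substitution rates

Coding MHC fragments do not evolve at the neutral genomic rate.  For each
lineage, pairwise synonymous distance (modified NG + JC) is regressed
through the origin on pairwise total distance (JC); the slope estimates the
fraction of total divergence that is synonymous and multiplies a neutral
genomic rate — zebra finch 2.21 × 10⁻⁹ or chicken 1.91 × 10⁻⁹
subs·site⁻¹·yr⁻¹ — to give the lineage's clock rate in subs·site⁻¹·My⁻¹.
The origin constraint is forced by the model: a pair with zero divergence
has zero synonymous divergence.  Note the procedure's known limitation,
reproduced faithfully here: when positive selection makes d_N exceed d_S,
the fragment's overall substitution rate *exceeds* the neutral rate while
the adjusted rate stays below it, so absolute ages of strongly selected
fragments are overestimated.  The simulator makes this visible: lineages
founded 53 My ago date to noticeably older values under the adjusted rate.

## Bayesian dating

`ClockDating` fixes the topology to the input supported tree (the clades
being dated are established by the bootstrap analysis; topology moves would
add cost without changing clade TMRCAs) and samples: internal node ages
(uniform sliding moves within parent/child bounds, a multiplier on the root
age, and a whole-tree age scaling move), HKY κ (LogNormal(1, 1.25) prior),
Γ shape (Exponential(1), four median-method categories), the Yule birth
rate (Exponential hyperprior with mean 0.05 My⁻¹, or fixed by config), and
the clock:

* `strict` — single fixed rate from the adjusted-rate stage;
* `random_local` — per-branch change indicators (Bernoulli prior with
  expected ln 2 changes per tree) and LogNormal(0, 0.7) multipliers that
  compound root-to-tip;
* `relaxed_exponential` — iid exponential branch rates with mean equal to
  the fixed rate.

The likelihood is Felsenstein pruning over site patterns with an analytic
HKY transition-probability kernel (verified against the matrix exponential
to machine precision), empirical base frequencies with a single
pseudocount, and branch lengths rate × duration.  The Yule prior density on
a fixed labeled topology is λ^(n−1) exp(−λL) with L the total tree duration;
prior-only sampling reproduces its analytic moments (the 2-leaf root age is
Exponential(2λ)).  Proposal scales adapt toward 0.2–0.5 acceptance during
burn-in (default 10% of the chain) and are then frozen; the default chain
is 10⁵ generations thinned to ~2000 samples, with longer chains available
via config.  Summaries report mean, SD, SE = SD/√ESS, Geyer
initial-monotone-sequence ESS, and the shortest interval containing 95% of
the samples (HPD); any parameter with ESS < 100 flags the whole result
unreliable, and that flag propagates to the pipeline report.

On simulated pairs the 95% HPD covers the true divergence time at close to
nominal frequency, and random-local-clock HPDs are systematically narrower
than relaxed-exponential ones on the same data — the same qualitative
contrast the adjusted-rate analyses show on real data.

Ancestral lineage relationships are reconstructed with Fitch two-pass
parsimony (exact for binary trees; verified against exhaustive search);
a Jukes–Cantor-style equal-rates marginal ML reconstruction at the root is
provided as a secondary method, since categorical parsimony and JC models
answer slightly different questions.

## The synthetic-data generator

Defaults encode the study scenario: duplications at (53, 53, 53, 49.1) My
joined as a budding caterpillar (oldest outermost); a fixed ultrametric
7-species, 4-genus species tree with a 20 My root and a recent crow
radiation; 2 alleles per species per lineage; neutral rate 2.21 × 10⁻³
subs·site⁻¹·My⁻¹; HKY κ = 4 with Γ₄ shape 1; PBR nonsynonymous multiplier
ω = 3 over 22 of 82 codons, which puts the realized whole-fragment dN/dS
(counted substitutions over mutational-opportunity sites) near 1.5 — inside
the 1.3–1.6 band typical of positively selected class IIB fragments; 3
diploid individuals per species; Poisson read depth (mean 60 per allele per
replicate), 0.3% per-base error, 10% PCR chimeras with a single uniform
breakpoint between two same-individual parents.

Within a lineage the gene tree follows the species tree topology exactly
(species are conditioned to be monophyletic within each lineage), with two
deliberate departures from a plain neutral coalescent, both reflecting
balancing selection: no coalescence younger than `allele_floor_my` (6 My) —
MHC alleles are maintained as divergent lineages far longer than drift
would allow, which also keeps same-species alleles ≥ ~3 substitutions apart
so the genotyping collapse rule rarely removes a real allele — and forced
completion of lineage coalescence by 0.8 × the founding time, guaranteeing
the invariant TMRCA < duplication time and a positive lineage stem.
Between-species joins happen at the species split or as soon after it as
the allele lines allow (exponential waiting, mean 1.5 My).

Substitutions are simulated codon-wise as an exact jump process: per-site
HKY rates times a per-site Γ₄ category, zero rate for stop-creating
changes, and ω multiplying nonsynonymous changes at PBR codons.  True
substitution events are tallied, so "realized dN/dS" is measured from
counts rather than estimated from end states; a neutral control run is
calibrated to 1 by construction.

What the generator does **not** emulate: 454 homopolymer indel errors and
base qualities (reads differ from templates only by substitutions), read
length variation (the length filter is exercised by constructed fixtures,
not by the generator), gene conversion by default (available as an option),
unequal base composition, and locus-specific primer bias.  Passing tests
therefore demonstrate the pipeline's behaviour under the assumed
evolutionary model with realistic substitution noise — not robustness to
platform-specific artifact spectra.

## Problem sizes used in validation

The packaged validation runs are sized for a single core: the exhaustive
codon-pair oracle covers all 61 × 61 pairs; NJ recovery uses 200 random
additive trees of up to 12 taxa; genotyping recovery and lineage recovery
each use 20 simulated datasets (56 alleles, ~15,000 reads; 100 bootstrap
replicates); Z-test calibration uses 1000 neutral simulations; dating
coverage uses 100 pairwise runs of 10⁵ generations; the clock-width
contrast uses 20 datasets × 2 clocks at 2 × 10⁴ generations.  The
acceptance script reruns the same pipeline at slightly reduced replicate
counts and reports every quantity it computes.
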