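# transpoly

Trans-species polymorphism (TSP) analysis of MHC class IIB exon 2 amplicons.

MHC allelic lineages can persist through speciation events for tens of
millions of years, so that alleles sampled from different genera cluster by
ancestral gene lineage rather than by species.  `transpoly` implements an
end-to-end pipeline for detecting and dating such lineages in corvid-style
multi-locus amplicon data:

1. **Genotyping** — demultiplex MID-tagged reads, filter short/indel/stop
   reads, validate variants that appear as ≥ 3 identical reads in **both**
   of two independent PCR replicates (which makes repeated validation of a
   PCR chimera vanishingly unlikely), and collapse variants within 3
   substitutions of a more-supported variant.
2. **Selection statistics** — per-species nucleotide diversity π, synonymous
   and nonsynonymous diversity (modified Nei–Gojobori with Jukes–Cantor
   correction, transition/transversion weight *R* estimated from the data),
   the one-tailed codon Z-test for positive selection
   (Z = (d̄_N − d̄_S)/SE, bootstrap SE over codon columns) on the full
   fragment and the peptide-binding-region (PBR) partition, Tajima's D, and
   an entropy-based substitution-saturation index.
3. **Phylogeny** — neighbor joining on Kimura 2-parameter distances with
   nonparametric bootstrap bipartition supports; midpoint rooting.
4. **Lineage detection** — maximal clades with ≥ 75% bootstrap support whose
   members span ≥ 4 genera; per-lineage amino-acid motif summaries.
5. **Adjusted substitution rates** — for each lineage, pairwise dS is
   regressed through the origin on total pairwise distance; the slope (an
   estimate of functional constraint) multiplies a neutral genomic rate
   (zebra finch 2.21 × 10⁻⁹ or chicken 1.91 × 10⁻⁹ subs·site⁻¹·yr⁻¹):

   μ_adj = slope × μ_neutral

6. **Bayesian divergence dating** — `ClockDating(alignment, tree, config)`
   with `.fit()` returning a `DatingResults` object: Metropolis–Hastings
   sampling of node ages under HKY+Γ₄ (Felsenstein pruning), a Yule tree
   prior, and a strict, random-local or relaxed-exponential clock with the
   rate fixed to μ_adj; posterior means, 95% HPD intervals and
   autocorrelation-corrected ESS per parameter.

A ground-truthed synthetic-data generator (`transpoly.simulate`) emulates
the assumed process end to end — four deep gene-duplication events
(53, 53, 53 and 49.1 My) shared across a 7-species, 4-genus corvid-like
species set, HKY+Γ₄ sequence evolution with an elevated nonsynonymous rate
at PBR codons, optional short-tract gene conversion, and replicated noisy
amplicon reads — so the whole pipeline runs and is validated without any
external data.

## Worked example

```python
from transpoly.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo", seed=1, boot_reps=100,
                     z_boot_reps=200, generations=20000)
result = run_pipeline(cfg)
print(open(result["report"]).read())
```

The run simulates 56 alleles (4 lineages × 7 species × 2 alleles), emits
~15,000 replicated reads, genotypes them, and prints a report containing a
per-species statistics table, e.g.

```
species  n  variants_total variants_individual    pi  pi_dS  pi_dN  dn_ds ...
   Cobr  3               8                 6-7 0.210  0.222  0.262    1.2
   ...
## Trans-species allelic lineages
L1: 14 alleles, 4 genera (Corvus, Cyanopica, Garrulus, Pica), support 1.00
L2: 14 alleles, 4 genera (Corvus, Cyanopica, Garrulus, Pica), support 1.00
...
## Constraint slopes and adjusted rates
lineage  slope  neutral_rate_per_year  adjusted_rate_per_my
     L1 0.8551           2.210000e-09              0.001890
```

π ≈ 0.20 is the pooled within-species nucleotide diversity (most allele
pairs straddle two ancient lineages); the four detected lineages each
contain all four genera at full bootstrap support — the TSP signature; the
constraint slopes below 1 scale the neutral rates down to per-lineage
adjusted rates near 1.7–2.2 × 10⁻³ subs·site⁻¹·My⁻¹, which the dating stage
then uses.  A command-line interface mirrors the stages
(`transpoly simulate|genotype|stats|tree|lineages|rates|date|run-all`).

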