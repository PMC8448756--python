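# clonetrace

Parental-origin tracing for clonal triploid lineages from whole-genome
variant profiles.

Some freshwater animals — the marbled crayfish is the best-known case —
reproduce by apomictic parthenogenesis: every offspring is a genetic copy of
a single triploid founder with an **AAB** genotype (two near-identical
haplotypes A plus one divergent haplotype B). `clonetrace` implements the
inference chain that reconstructs where such a founder came from, given
short-read variant profiles of candidate diploid parent populations:

1. **Ploidy classification.** Genotyping every sample under a diploid model,
   the alternative-allele read fraction at a heterozygous site is
   Binomial(depth, 1/2)/depth for a true diploid but mixes
   Binomial(depth, 1/3) and Binomial(depth, 2/3) for a triploid. Samples are
   classified by comparing the spectrum mass *M₃* inside windows
   1/3 ± w and 2/3 ± w against the mass *M₂* inside 1/2 ± w
   (*w* = 0.08): triploid iff *M₃* > *M₂*. Bi-/triallelic site composition is
   reported alongside (an AAB genome is overwhelmingly biallelic).
2. **A/B haplotype ancestry tracing.** At each biallelic heterozygous site of
   the triploid reference individual, the majority-read allele ("A",
   expected fraction 2/3) and minority allele ("B", expected 1/3) are
   separated. Because the clonal genome is unrecombined, the A alleles spell
   out one parental haplotype and the B alleles the other. Each allele's
   presence (1) or absence (0) in every candidate sample forms a binary
   matrix per haplotype; normalized Hamming distances over jointly scored
   columns feed Saitou–Nei neighbor-joining trees, which place each parental
   haplotype inside its source population.
3. **Mitochondrial phylogeny.** Plurality-consensus sequences, p-distances,
   an NJ tree, and nonparametric bootstrap branch supports (column
   resampling, percentage of replicates containing the same bipartition)
   recover the maternal lineage structure.
4. **Population structure.** Alternate-allele dosages are LD-pruned
   (r² > 0.1 within 50 kb windows) and fed to a genotype PCA
   (mean imputation, centering, 1/√(2p(1−p)) scaling).

A synthetic cohort generator provides ground truth for all of this:
structured diploid subpopulations built from small pools of ancestral
haplotypes, one triploid AAB founder whose A and B haplotypes segregate in a
designated source subpopulation, non-founder triploids, Poisson read depth
with per-base error, and one mitochondrial genome per maternal lineage. The
pipeline combines the four lines of evidence into a single origin verdict.

## Worked example

Run the full chain on a default synthetic cohort (4 subpopulations, 28
samples, 2 planted non-founder triploids, 50,000 sites, depth 30):

```python
from clonetrace import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7), "run7")
print("verdict:", report.verdict)
t = report.ploidy_table
print(t[t.classification == "triploid"].to_string(index=False))
print(report.mito_clades.to_string(index=False))
```

prints

```
verdict: concordant(Everglades)
      sample classification  modal_peak  n_het  triallelic_fraction
Everglades-1       triploid        0.65    234                  0.0
Everglades-2       triploid        0.63    271                  0.0
    subpop  n  monophyletic  support
Everglades  8          True    100.0
 Southwest  7          True    100.0
   StJohns  7          True    100.0
  Suwannee  7          True    100.0
```

Reading this: the two planted triploids are detected (their heterozygous
spectra peak at 1/3 and 2/3 instead of 1/2 — here the reported modal bin
sits on the 2/3 peak), all four subpopulations come out monophyletic in the
mitochondrial tree with 100% bootstrap support, and the verdict says that
the founder's mitochondrial lineage, its A haplotype, its B haplotype and
its PCA position all point at the same source subpopulation — the cohort's
"Everglades" analog, where the founder was planted. Simulating instead with
`SimConfig(hybrid_B_subpop=0)` plants the B haplotype in a different
subpopulation and the verdict becomes `discordant(...)`, i.e. a hybrid
origin would be detectable.

Each stage is also exposed as a CLI for file-based use
(`clonetrace simulate | genotype | ploidy | haplotrace | mito-tree |
popstruct | pipeline`); stage outputs are plain VCF/FASTA/TSV/Newick/JSON.

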