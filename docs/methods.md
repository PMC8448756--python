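# Methods

## Problem setting

A clonal triploid lineage with an AAB genotype descends from a single
founder. Given whole-genome variant profiles of individuals sampled from the
candidate (diploid, sexual) parent populations, we want to (i) detect
triploid individuals from read-level allele balance, (ii) trace each of the
founder's two parental haplotypes to a source subpopulation, and (iii)
corroborate the placement with mitochondrial phylogeny and nuclear
population structure. `clonetrace` implements this chain together with a
synthetic cohort generator that supplies ground truth for every stage.

## Synthetic cohort model (`simulate`)

**Nuclear genome.** `n_sites` polymorphic positions (default 50,000) are
placed uniformly without replacement on a single linkage group of
`genome_length` bp (default 5 Mb); there is no recombination within the
simulated window. A root sequence over {A,C,G,T} is mutated independently
per subpopulation at rate `subpop_divergence` (default 0.02 per site) to
give one ancestor per subpopulation; mutations pick a uniformly random
different letter (infinite-sites-flavored biallelic substitutions, so
truly triallelic sites essentially never arise in the truth).

**Standing variation.** Each subpopulation carries a small *pool* of
ancestral haplotypes (default 3), each derived from the subpop ancestor at
rate `within_subpop_diversity`/2 (default 0.005/2, giving pairwise
within-pool diversity ≈ 0.005). A sampled diploid copies two pool
haplotypes uniformly at random and adds private mutations at
`private_mutation_rate` (default 5 × 10⁻⁴). The pool is the load-bearing
choice: presence/absence ancestry tracing can only work if the founder's
haplotypes *segregate* among sampled relatives. A small pool keeps each
pool haplotype's sampling frequency high enough (≈ 1 − (2/3)² per diploid
at pool size 3) that a 7-sample subpopulation almost surely contains
carriers of both parental haplotypes; with independent per-individual
mutations instead, the founder's alleles would be private and the method
would have nothing to detect.

**Founder and triploids.** The founder's A and B haplotypes are each
derived from the source-subpop ancestor at rate `founder_AB_divergence`/2,
so their pairwise difference is d − d²/3 ≈ d (default 0.004, ≈ 200
heterozygous sites at 50,000 positions) and the het-site count is
Binomial(n_sites, ≈d). Both are members of the source subpop's pool.
The founder genome is [A, A, B]; the reference sequence *is* the A
haplotype (emulating a reference assembled from the clonal lineage), which
orients triploid het sites toward alternative-allele fraction 1/3.
Founder haplotypes carry no extra private mutations (clonal archetype).
Non-founder triploids copy one pool haplotype twice (the AA pair, with one
shared private-mutation pass so the two copies stay identical) plus a
distinct pool draw as B; they are placed in the founder's subpopulation
and share its maternal lineage. Setting `hybrid_B_subpop` plants B in a
different subpopulation's pool — the hybrid-origin scenario.

**Reads.** Per site, total depth ~ Poisson(`read_depth_mean`, default 30);
reads split uniformly across the genome's haplotypes (exact multinomial);
each read is corrupted to a uniformly chosen different allele with
probability `base_error` (default 0.002).

**Mitochondria.** A root mitogenome (default 15 kb) is mutated per
subpopulation at `mito_divergence` (0.02), per maternal lineage at
`mito_lineage_divergence` (0.002), and per sample at `mito_private_rate`
(2 × 10⁻⁴). Sequences are emitted pre-aligned (equal length, positionally
homologous); real-data users must supply an external alignment.

**Determinism.** One master seed; every stream (population, per-sample
reads, per-sample mito, bootstrap) is derived by stable hashing of the seed
with a purpose tag and the sample id, so results are independent of
iteration order and bit-identical across runs.

**What the generator does not emulate:** recombination and linkage maps,
coalescent genealogies, migration/admixture, selection, indels and
structural variation, mapping artifacts, batch effects, contamination.
Passing tests therefore show that the *inference chain* is correct under
its stated model, not that the thresholds are optimal for any particular
real dataset.

## Genotype calling (`genotype`)

A deliberate threshold caller replaces a full Bayesian caller so that its
behavior is exactly specifiable: a site is callable at depth ≥ `min_depth`
(10); heterozygous iff the second-best allele's fraction lies in
[`het_min`, 1 − `het_min`] ([0.10, 0.90]); homozygous iff the top allele
exceeds 1 − `het_min`; otherwise no-call. `alt_fraction` is non-reference
reads / depth. An allele is *supported* at fraction > 0.05 and ≥ 3 reads;
≥ 3 supported alleles ⇒ triallelic; exactly 2, or a single supported
non-reference allele (a fixed substitution), ⇒ biallelic; a pure-reference
site is neither. Triploid samples are intentionally genotyped under this
diploid model — their het alt-fractions then cluster at 1/3 and 2/3, which
is the ploidy signal. Marker-amplicon comparison
(`count_marker_polymorphisms`) assumes pre-aligned sequences and skips
gaps/ambiguity codes.

## Ploidy classification (`ploidy`)

Spectra use biallelic het calls whose called pair includes the reference
allele (their alt-fraction is strictly inside (0,1)); homozygous variants
are excluded from the spectrum but counted separately as a divergence
statistic. Classification is bin-free: with window half-width `w` = 0.08,
M₃ = mass in [1/3 ± w] ∪ [2/3 ± w] versus M₂ = mass in [1/2 ± w];
triploid iff M₃ > M₂. At depth ≥ 20 this separates the binomial mixtures by
several standard deviations once a few hundred het sites are available;
below `min_het_sites` (200) the call is *indeterminate*. The displayed
histogram uses 0.02-wide bins, and the reported modal peak is the highest
bin's midpoint rounded to two decimals. A power note on the modal bin: with
Poisson(30) depths the expected lead of the bin containing 1/3 over its
left neighbor is ≈ 0.85 SD at 1,500 het sites and ≈ 3 SD at 20,000, so
headline modal-peak computations are sized at ~20,000 het sites; the
window-mass classifier is far less size-sensitive than the modal bin.

## A/B tracing (`haplotrace`)

The reference individual must not classify as diploid (it is refused
outright); if its het-site count is below the confident floor the
decomposition still proceeds when the window masses are triploid-shaped
(M₃ > M₂), with a warning — the floor guards ploidy *reporting*, while the
decomposition degrades gracefully with fewer sites. Sites whose
minority-of-pair read fraction falls in [0.45, 0.55] are excluded
(majority/minority cannot be distinguished; misassignment would mix the
haplotypes). Presence matrices score 1 when a sample's called genotype
contains the designated allele, 0 when called without it, and missing on
no-calls. Distances are normalized Hamming over jointly non-missing
columns (Jaccard available via `metric=`); missing cells are excluded
pairwise rather than imputed, avoiding coverage-driven bias; a pair with no
jointly scored column is an error, not a guess. The founder enters each
per-haplotype tree as a pseudo-sample (`founder-A` / `founder-B`, an
all-present row for its own haplotype); its raw diploid-model row is
excluded.

## Trees (`trees`, `phylo`)

Neighbor joining is classic Saitou–Nei with two pinned determinism rules:
Q-criterion ties break toward the smallest active (i, j) pair (original
label order, merged nodes keeping the first child's position), and negative
branch lengths are clamped to zero with the deficit moved to the sibling
branch. On additive matrices the algorithm is exact, which the tests verify
against topology enumeration (5 taxa) and patristic round-trips (≤ 8 taxa),
plus an independent NJ implementation. Mitochondrial distances are
p-distances (mismatches over unambiguous shared sites; N excluded from
numerator and denominator; a pair with no comparable site is an error).
Bootstrap: columns resampled with replacement, NJ rebuilt per replicate,
each internal branch of the full tree labeled with the percentage of
*completed* replicates containing its bipartition; degenerate replicates
(undefined distances) are skipped, counted and logged. Zero-length internal
branches of the full tree are collapsed into polytomies first, so
unresolved splits are shown as unresolved instead of arbitrarily resolved
(an alignment of identical sequences yields a star tree with no supported
branch). Default 100 replicates; supports attach only to internal branches.

## Population structure (`popstruct`)

Dosage = number of non-reference alleles in the called pair (0/1/2, missing
on no-call). LD pruning scans sites in position order and drops any site
with r² above `r2_threshold` (0.1) against an already-retained site within
`window_bp` (50,000); the published contract is the postcondition — no
retained pair within one window span exceeds the threshold — which a
brute-force checker verifies independently of the greedy trace. r² is the
squared Pearson correlation over jointly non-missing samples, 0 by
convention for constant vectors. Implementation note: complete columns go
through a standardized-dot-product fast path; any column containing missing
values is recomputed exactly with pairwise-complete moments. PCA
mean-imputes missing dosages per site, centers, scales by √(2p(1−p)) with
p the alternate-allele frequency (monomorphic and zero-variance sites
dropped), and takes the SVD; sign convention: each component's
largest-magnitude loading is positive, which makes results invariant to
sample order.

## Pipeline and verdict (`pipeline`)

The origin verdict combines four evidence lines for the founder: nearest
mitochondrial neighbor's subpopulation, nearest non-founder leaf to
`founder-A` and to `founder-B` in the per-haplotype trees (patristic
distance), and nearest subpopulation centroid in the top ≤ 3 PCs.
`concordant(<subpop>)` requires all four to name the same subpopulation;
any disagreement is surfaced as `discordant(...)` rather than resolved;
degenerate inputs (no heterozygous sites, zero mitochondrial diversity,
monomorphic dosage matrix) drop the affected evidence line and yield
`indeterminate`. Genuine stage errors abort with the stage name. Every run
writes a manifest (package version, seed, full parameter set, stage
counts) sufficient to re-run any stage; with a fixed seed the report is
byte-identical across runs.

## Problem sizes used in the test suite

Unit tests run on a reduced cohort (12,000 sites over 1.2 Mb, 12 samples,
pool size 2, A/B divergence 0.01) chosen to preserve expected het-site
counts of order 10²; full-scale checks (50,000 sites, 28 samples + founder,
20 replicate cohorts for ploidy recovery, 10 seeds for origin and
hybrid-detection rates) live in the acceptance tests. The LD-prune
brute-force verification runs at 5,000 sites over 500 kb — the same site
density as the default cohort — because the all-pairs oracle is quadratic
in window occupancy while the contract itself is size-independent.

## Known limitations

* The threshold caller has no genotype likelihoods; at depths ≪ 20 its het
  band misclassifies sites faster than a Bayesian caller would.
* Ploidy classification assumes the 1/3–2/3 versus 1/2 geometry of AAB
  triploids at roughly uniform coverage; aneuploidy, contamination or
  strong reference bias would need dedicated modeling.
* A/B tracing presumes an unrecombined clonal genome; with recombination
  the A and B matrices would mix ancestry blocks.
* NJ replaces likelihood-based phylogenetics throughout; at the simulated
  divergence levels topology is robust to this substitution, but branch
  lengths are distance-based, not model-based.
* The "10 bp" LD window step is honored in spirit by the greedy
  position-order scan (every pair closer than one window span is tested);
  `step`/`step_unit` are exposed for explicit window stepping semantics.
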