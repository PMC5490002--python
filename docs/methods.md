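# Methods

`isodrift` quantifies how genetic isolation reshapes functional variation in
a small, drifted population (the *isolate*) relative to its closest large
*general* population. This note records the statistical definitions, the
synthetic-data model that provides ground truth, the numerical choices, and
the known limitations.

## Statistics

### Drifted variants and DVxy

A **drifted variant (DV)** has derived-allele frequency (DAF) in the
inclusive band [2%, 5%] in one population of the pair and at least
three-fold lower in the other (a DAF of exactly 0 in the comparison
population satisfies the fold rule: absence is the extreme drift case).
Both band endpoints are inclusive; the band is applied to the DAF of the
focal population, not the folded MAF.

**DVxy-coding** corrects the functional (missense + loss-of-function) DV
count in each direction by the intergenic DV count:

    DVxy = (n_func_x / n_intergenic_x) / (n_func_y / n_intergenic_y)

1 means no enrichment; > 1 means the isolate carries proportionally more
functional drifted variants than drift alone (intergenic baseline) would
produce. **DVxy-wg** applies the same ratio-of-fractions genome-wide per
CADD stratum — half-open bins [0,5), [5,10), [10,20), [20,∞) — with the
0–5 bin as the neutral reference. Any zero denominator yields an explicit
NA (never 0 or ∞). Exact antisymmetry holds by construction:
DVyx = 1/DVxy.

95% confidence intervals come from resampling 20 chromosome blocks without
replacement, 100 times, re-computing the statistic per replicate and taking
the 2.5/97.5 percentiles. On small synthetic genomes with fewer than 20
chromosomes, blocks are equal-variant chromosome *segments* (each
chromosome split until ≥ 20 blocks exist) so the resampling unit still
respects linkage; with ≥ 20 real chromosomes the blocks are whole
chromosomes. A leave-one-block-out jackknife z-test on log(DVxy) is
provided for significance.

### Singleton statistics (SVgene, SVpop, SVxy, G_SV)

A **singleton** carries exactly one copy of the alternative allele within a
population's own 36-individual subset — no cross-population exclusivity is
required. Per gene, `SVgene` = missense/synonymous singleton ratio; a gene
with missense but no synonymous singletons is classified "SVgene > 1" but
excluded from ratio averaging (no infinities). `SVpop` pools counts over
all genes with at least one singleton in either population of the pair
(the shared gene universe); `SVxy` = SVpop(isolate)/SVpop(general), > 1
under relaxed purifying selection in the isolate. `G_SV` is the ratio of
the share of essential genes with SVgene > 1 to the same share among
non-essential genes. CIs subsample 80% of the gene universe without
replacement, 100 times (a classical with-replacement bootstrap would be a
one-line change).

### Rxy genetic load

For a variant class C and populations x, y:

    L(x¬y) = Σ_{i∈C} daf_x,i (1 − daf_y,i),   L(y¬x) symmetric
    R(C)   = L(x¬y) / L(y¬x),   Rxy = R(class) / R(control)

Controls are synonymous sites (for missense/LoF) or CADD < 5 sites (for
CADD > 10 / > 20 classes); intragenic-as-control is deliberately not
offered. Sites with daf_x = daf_y = 0 are skipped. The raw ratio is
exactly antisymmetric (R(x,y)·R(y,x) = 1). Dispersion: chromosome blocks
are resampled **with** replacement (100 replicates) using per-block load
sums, preserving LD structure; both the raw and normalized values are
reported because normalization by the control is what removes pure-drift
inflation.

### Rare-variant sharing and deltaDAF

**f2** variants carry exactly two alternative-allele copies in the pooled
minimum-size sample: each increments the cell of its unordered carrier
pair (a single homozygous carrier increments its own diagonal cell, which
preserves the conservation identity: matrix total = number of f2
variants). **f3–10** variants (3–10 copies) contribute one uniformly
drawn pair of their allele copies (seeded; both copies of one homozygote
land on the diagonal). **deltaDAF** is the signed per-variant difference
daf_isolate − daf_general.

### Standard isolation measures

* **FST**: Hudson ratio-of-sums over polymorphic sites (per-site
  numerators/denominators also emitted); Weir–Cockerham available behind a
  flag. The two-deme symmetric island equilibrium expectation used as a
  simulation oracle is 1/(1 + 8Nm) (from T_within = 4N,
  T_between = 4N + 1/(2m)).
* **Inbreeding F**: method of moments, 1 − observed/expected
  heterozygosity per individual, expectation from that population's allele
  frequencies.
* **ROH**: sliding-window scan — a site is run-compatible when some
  50-site window covering it holds ≤ 1 heterozygote; maximal compatible
  runs ≥ 1 Mb (defaults; PLINK-like, not taken from any study) are
  reported per individual. The pipeline uses a 250 kb threshold on the
  small synthetic genomes.
* **LD decay length**: mean r² per physical-distance bin; the reported
  length is the midpoint of the first bin whose mean falls below r² = 0.1.
  r² uses phased haplotype correlation when haplotypes are available,
  otherwise the composite (Rogers–Huff) dosage correlation. A PLINK-style
  Gabriel haplotype-block statistic is deliberately replaced by this decay
  proxy.

### LD-based demography, Delta Ancestry, Isx

With the finite-sample correction (1/n_haplotypes phased; 1/(2n)
dosage-based):

    r²_adj = mean r² − correction
    Ne(t)  = (1/(4c)) · (1/r²_adj − 2),    t = 1/(2c)

per recombination-distance bin c (Morgans; constant cM/Mb map). Default
bins: 0.025–1.0 cM, 16 log-spaced, indexing t ≈ 2,000 down to 50
generations — chosen because isolate divergence times of interest
(≲ 5,000 years ≈ 170 generations at 29 y/generation) and the recent-Ne
component of Isx live below t = 200; a grid stopping at 0.25 cM
(t ≥ 200) cannot see them. Within a bin, locus pairs form seeded blocks
of ~75 pairs; the trajectory reports the median and the 5–95% percentiles
*across blocks* — an across-loci envelope describing locus-level
heterogeneity, not the standard error of the bin mean. Bins whose
adjusted r² carries no drift signal, or with fewer than half their blocks
valid, are dropped.

**Tdg** is read off the two trajectories scanning from the oldest shared
bin to the present: the oldest time from which the trajectories stay
separated, where "separated" means each population's median lies outside
the other's 5–95% envelope. Requiring full envelope–envelope disjointness
never fires (the across-loci envelopes are intrinsically wide), while
narrow median-sampling intervals fire at all depths because a recent
bottleneck depresses the window-harmonic Ne at every time depth; the
median-outside-envelope rule sits between the two and recovers a
150-generation split within a factor of two at the median in simulation.
Always-overlapping trajectories return Tdg = 0 with a flag.

**Delta Ancestry (M)**: a two-component admixture model
(dosage ~ Binomial(2, q·f1 + (1−q)·f2)) is fitted by block-relaxation EM
(monotone log-likelihood; label-agnostic random initialization, because
seeding q from the population labels projects spurious structure onto
them and inflates M on weakly diverged pairs). M is the isolate-minus-
general difference in the mean of the component with the higher isolate
mean (relabeling-invariant), clipped to [0, 1]. Externally computed
ADMIXTURE-dialect .Q files are read directly.

**Isx** = Tdg · M / Ne, with Ne the harmonic mean of the isolate's
trajectory over bins within the most recent 50 generations (the youngest
bin stands in if the grid has none). This is the simplest form satisfying
the required monotonicities — increasing in divergence time and private
ancestry, decreasing in effective size; it lives behind a single function
so an alternative form is a one-line change. Note the sign convention: M
is *Delta Ancestry*, an inverse-migration proxy, so more private ancestry
(less gene flow) raises Isx. Generation-time conversions default to 29
years.

### Correlation report

Pearson r and two-sided p for every pair of cohort-level measures across
≥ 3 cohort pairs; constant columns are flagged NA.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions for every calibration and recovery property.

**Demography.** An ancestral population of (diploid) size 2,000 expands to
10,000 at 600 generations before present (the recent-growth excess of
ultra-rare variation characteristic of European cohorts), then splits
`tdg_gens` generations ago into the general population (Ne 10,000) and the
isolate. The isolate preset passes through a severe founder event
(2N = 400 for 25 generations) before settling at Ne 1,500; symmetric
migration (5×10⁻⁴ per generation) continues after the split. The neutral
null preset uses identical sizes (5,000) on both sides with no selection.

**Two coupled engines.**

* *Intergenic* sites come from an msprime coalescent simulation of this
  demography with recombination (1 cM/Mb), so LD-based statistics see
  realistic linkage.
* *Genic* sites (missense 65%, LoF 5%, synonymous 30% of coding
  mutations) are independent loci propagated forward through the
  post-split generations: deterministic additive selection (heterozygote
  fitness 1 − s/2), symmetric migration, binomial Wright–Fisher drift
  with the per-epoch 2N. Ancestral standing variation is drawn from an
  x⁻² frequency spectrum (the growth-skewed analogue of the equilibrium
  1/x) and reweighted toward mutation–selection balance by accepting a
  site with probability exp(−2·N_anc·s·x₀). New mutations enter each
  population per post-split generation at Poisson rate 2N(t)·μ·L_coding,
  starting from a single copy — without this input an isolate can only
  lose rare functional variation and the relaxation regime never
  appears. Final genotypes are Hardy–Weinberg draws from the terminal
  frequencies, stored as phased haplotypes.

The spectrum exponent (2.0) and mutation-input scale (1.0) were calibrated
for *internal consistency between the two engines*: under a selection-off
bottleneck, neutral forward genic sites and coalescent intergenic sites
must show the same 2–5%-band retention (DVxy-coding = 1), so that any
DVxy signal under selection is attributable to selection rather than to a
mismatch between the engines.

**Selection coefficients** are gamma-distributed per site: missense shape
0.25, mean 0.03; LoF shape 0.5, mean 0.2 (literature-strength
distributions of fitness effects); sites in the 20% of genes labelled
essential get twice the coefficient (capped at 0.5).

**Pseudo-CADD.** Sites with a selection signal score
12·log₁₀(1 + s/10⁻⁴) + N(0, 2), clipped to [0, 50] — monotone in s up to
noise (Spearman ρ > 0.5 with |s| among deleterious classes by
construction). All other sites draw from a genome-like baseline mixture
(70% in 0–5, 15% in 5–10, 10% in 10–20, 5% above 20): a deleteriousness
score assigns high values to some neutral sites too, and the mixture keeps
every CADD stratum populated so DVxy-wg is defined even under a fully
neutral genome. This means "neutral" classes are *centred* in the 0–5
band rather than confined to it.

**Bookkeeping.** 10% of sites are written with REF/ALT swapped (ancestral
allele = ALT) and 2% with unknown ancestral state, exercising the DAF
folding and undefined-DAF paths. Allele-count bookkeeping, the AA INFO
tag, annotation TSV, sample map, essential-gene list and a truth Q matrix
round-trip byte-stably through the writers and readers. Everything is
deterministic given the config seed.

**Scale.** Default genomes are 2 chromosomes × 5 Mb with 40 genes of
20 kb per chromosome and a deliberately inflated coding variant density
(12,000 candidate genic loci per chromosome), so per-pair statistics are
well populated while a full pair simulates in ~1–2 s and the complete
pipeline battery runs in minutes on one CPU. Recovery scenarios
(constant-Ne, 150-generation split, equilibrium island) switch the genic
machinery off and use only the coalescent engine.

**Cohort panels.** `make_cohort_panel` generates cohorts whose split
time, isolate Ne, founder severity and migration all vary monotonically,
spanning *barely isolated* (Ne 8,000, founder 6,000, migration 5×10⁻³ —
DVxy ≈ 1) to *severely isolated* (Ne 800, founder 150, migration 10⁻⁴).
Two points are deliberate: the mild end sits near panmixia because
DVxy-coding conditions on drifted variants and its per-variant enrichment
saturates once any genuine isolation exists — a gradient confined to
strong isolates shows no DVxy trend at all; and split times span a
narrow 100–250 generations because with much older splits continued
purifying selection re-purges the founder-promoted functional variants,
reversing the DVxy-versus-isolation relationship. Panel cohorts use
larger (8-chromosome) genomes and average DVxy/SVxy over several
36-individual subsamples so that eight cohorts suffice for stable
correlation signs.

**What the generator does not emulate**, and hence what passing tests do
not certify on real data: sequencing error and genotype-likelihood
uncertainty of low-depth calls, LD between genic sites (they are
independent loci; LD statistics therefore run on non-coding sites in the
pipeline), dominance (h fixed at ½), linked selection/background
selection, realistic human mutation spectra and gene structure, and
cryptic relatedness within cohorts.

## Subsetting schemes

Three standard subsets mirror common practice: `whole` (all samples),
`matched` (every population downsampled to the smallest's size), and
`minimum` (36 per population). The pipeline runs DVxy, SVxy and sharing
on the minimum set; Rxy and deltaDAF on the matched set; LD-based
demography on the minimum set restricted to non-coding sites. Missing
genotypes (sentinel −1 after loading) are excluded from the
called-chromosome denominator, so per-site denominators vary as they do in
low-depth call sets.

## Numerical conventions

* Coordinates 1-based inclusive (VCF convention); MAF folded at 0.5 per
  population; printed MAF thresholds to one decimal (allele count 4 of 72
  chromosomes → 5.6%, count 1 → 1.4%).
* All sampling flows from a single seed per run; subsampling preserves
  input sample order; every undefined ratio is an explicit NA with its
  offending zero count.
* Half-open conventions: MAF bins (lo, hi]; CADD bins [lo, hi); the DAF
  band of the DV rule is closed on both ends.
* EM convergence: relative log-likelihood change < 10⁻⁶, max 500
  iterations; non-convergence returns a flag, not an error.

## Known limitations

* The Isx functional form is a documented surrogate (the constraints fix
  only its monotonicities); comparisons of Isx *values* across studies are
  not meaningful, rankings are.
* The Tdg envelope scan is biased upward for severe bottlenecks (recent
  drift depresses the isolate's window-harmonic Ne at all depths); it is
  validated for moderate contrasts (Ne ratio ≲ 3). Severe-founder cohorts
  rank correctly but their absolute Tdg is overestimated.
* The K=2 admixture EM on strongly diverged pairs saturates M near 1
  regardless of migration differences; M discriminates best among weakly
  to moderately isolated cohorts.
* Rxy on few chromosome blocks (2-chromosome synthetic genomes split into
  segments) underestimates long-range LD effects on its bootstrap s.d.
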