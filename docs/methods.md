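# Methods

`minkgs` simulates a closed fur-farm breeding population forward in time
and evaluates pedigree and genomic prediction on it.  This note records
the model, the defaults and why they were chosen, the numerical choices,
and what the simulator does and does not emulate.

## Demographic model

The population history has three phases.

1. **Historical.** Random union of gametes with separate sexes at
   constant size N = 1000 for 1000 generations, followed by a linear
   decline to N = 100 over 50 generations.  The long constant phase
   builds short-range linkage disequilibrium (LD) toward mutation–drift
   balance; the bottleneck raises LD at all scales and sets the small
   effective size typical of domesticated fur-animal populations.
   Founder haplotypes start at allele frequency 1/2 (uniform over
   alleles at multi-allelic loci); 1050 generations of drift and
   recurrent mutation then shape the frequency spectrum.  The decline is
   linear because nothing in the emulated design argues for a specific
   curvature; the trajectory function is configurable.

2. **Expansion.** 50 males and 50 females are sampled from the last
   bottleneck generation and bred as a *constant nucleus*: each of the
   30 generations, 50 random dams of the current cohort are mated to
   random sires of the cohort and produce litters of five, so each
   cohort has 250 kits while non-breeding offspring accumulate.  The
   recent phase recruits its founders from the youngest ~3000
   accumulated animals (`expand_final`).  This structure was chosen over
   exponential or linear census growth after comparing the LD it
   produces: only a breeding pool that *stays small* through the
   expansion keeps the effective size in the tens-to-low-hundreds that
   the emulated breeding program targets, and only then does pairwise r²
   at 0.9–1 Mb plateau near 0.12 instead of collapsing toward the
   1/(sample) floor.  Fast census growth erases long-range LD within a
   few generations.

3. **Recent.** 260 sires × 1250 dams, litters of exactly five kits
   (Poisson litters available by flag), sex ratio 1/2, ten generations.
   Each generation, 50% of dams and 80% of sires are replaced by the
   top-ranked kits of the current generation; retained parents are the
   top-ranked among current parents.  The ranking criterion is either
   own phenotype or EBV from a pedigree BLUP refit each generation on
   all phenotypes recorded so far (true variance components).  Mating is
   random, dams dealt round-robin over shuffled sires (~4.8 dams/sire).
   Pedigree recording and phenotyping start at the 1510 recent-phase
   founders; earlier animals are treated as unknown-parent founders
   because they carry no records and would only add empty equations.

## Genome, panel and trait

* 14 autosomal chromosomes of equal genetic length summing to 1192 cM;
  1 cM ≡ 1 Mb wherever physical distance is needed.
* Candidate loci: 40 000 biallelic marker candidates and 10 000 QTL
  candidates (allele count uniform on {2, 3, 4}), placed uniformly at
  random.  These pool sizes give ~3× headroom over the recruited panel
  after 1050 generations of drift.
* Recruitment at the end of the historical phase: 5000 QTL from
  candidates with MAF > 0.01, and the marker panel (default 10 000) from
  biallelic candidates with MAF ≥ 0.05.  The marker threshold is the
  common simulator default and reproduces observed heterozygosity near
  0.35 in the recent generations.  QTL are drawn before markers so that
  the trait architecture is identical across panel densities.
* Meiosis: crossover count per chromosome ~ Poisson(length in Morgans),
  positions uniform, no interference.  Recurrent mutation at 10⁻⁵ per
  allele per transmission, to a uniformly chosen other allele; mutation
  events are drawn over the full candidate-locus domain so that the
  random stream (and hence the simulation) is identical whichever panel
  was recruited.
* Trait: one gamma(shape 0.40) magnitude with random sign per
  (QTL, allele); effects jointly rescaled so that Var(TBV) = h² in the
  expansion pool that founds the recent phase (phenotypic variance 1, so
  σ²ₑ = 1 − h²).  Phenotype = TBV + N(0, σ²ₑ).
* Observation model: each (animal, marker) call missing with
  probability 0.05; each surviving allele call flips with probability
  0.005 (per-allele, so a homozygote is read as a heterozygote with
  probability ≈ 1%).  A per-genotype resampling variant is available.

## Evaluation models

All three evaluators solve the single-trait animal model
y = 1μ + Za + e with known variance components (σ²ₐ = h², σ²ₑ = 1 − h²)
and differ in the relationship kernel:

* **BLUP** – Henderson's MME with the sparse A⁻¹ (Henderson's rules,
  Meuwissen–Luo inbreeding).
* **GBLUP** – VanRaden G = (M−P)(M−P)′ / 2Σpⱼ(1−pⱼ) over the genotyped
  set, allele frequencies from the same set, missing dosages imputed to
  2pⱼ; G blended with 5% of A₂₂ for invertibility.  Solved in the
  equivalent variance-component form (Cholesky of the training-block
  covariance), which avoids inverting G at every training-set size.
* **ssGBLUP** – the MME with H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹] on the
  genotyped block (τ = ω = 1).  A₂₂ comes from the tabular method for
  small pedigrees and from Colleau's indirect method (two triangular
  sweeps per genotyped column) for large ones.

Prediction experiment (one replicate): training sets of 1000–5000
animals drawn (nested) from generations 7–9; 500 prediction animals
drawn from generation 10 and masked in the genomic evaluations.  All
methods see the training-set phenotypes; the pedigree BLUP baseline
additionally keeps the prediction animals' own phenotypes — it plays
the role of the evaluation a breeder can already run without
genotyping, which is the baseline the genomic methods must beat.  Note
that when every phenotyped animal is genotyped, ssGBLUP's prediction
for genotyped animals coincides with GBLUP exactly (the genotyped block
of H is G*); differences between the two methods appear only when
non-genotyped phenotypes contribute.

Accuracy is Pearson r(TBV, prediction) on the 500 masked animals; bias
is the OLS slope of TBV on prediction (1 = unbiased, < 1 = inflated).

## Numerical choices

* Sparse MME solved by SuperLU up to 3000 equations and by
  Jacobi-preconditioned conjugate gradients (rtol 1e-10, hard failure
  above residual 1e-6) beyond; the dense-vs-iterative paths are tested
  against each other and against dense oracles.
* Meiosis copies haplotype segments through an int64-aliased view of the
  int8 haplotype store (8-byte word copies with byte edges); the byte
  and word paths are tested for exact agreement.
* Ties in truncation selection are broken by animal id (birth order).
* G* = 0.95 G + 0.05 A₂₂ by default (β configurable, β = 0 allowed).
* Same seed ⇒ bit-identical populations; every pipeline stage consumes
  its own child stream (numpy spawning), so changing the marker density
  leaves demography, trait and training-set draws untouched (common
  random numbers across scenario cells).

## Population-genetic summaries

Diversity statistics (pedigree inbreeding F_PED, excess-homozygosity
inbreeding F_HOM, observed heterozygosity Ho, effective size Ne) are
computed over generations 7–10; LD decay (mean r² in 0.1 Mb bins to
1 Mb) from true haplotypes of a generation-10 sample (1250 animals by
default).  Markers failing a sample MAF ≥ 0.05 filter are excluded
first, as standard SNP QC would; with this filter the per-bin pair
counts of a 10k panel (~6400 at 0–0.1 Mb) match the counts such breeding
programs report.

F_HOM per individual is (O_hom − E_hom)/(L − E_hom) with
E_hom = Σⱼ(1 − 2pⱼ(1−pⱼ)) over non-missing loci.  Ne is estimated from
the binned LD by inverting Sved's expectation per bin,
Ne_bin = (1/r²_adj − 1)/(4c) with the phased-sample correction
r²_adj = r² − 1/(2n) and c from Haldane's map function at the bin
midpoint, summarised as the pair-count-weighted harmonic mean; a
ΔF-based alternative (Ne = 1/(2ΔF)) is provided.  LD-based Ne from
0–1 Mb bins reflects the effective size tens to hundreds of
generations ago, so in this design it reports values well above the
recent breeding Ne; treat it as a long-horizon summary, not as the
current-generation effective size (see Limitations).

## What the simulator does and does not emulate

The generator reproduces the *structure* of a mink-style breeding
program: three-phase demography, litter sizes, replacement rates,
two selection designs, panel densities, genotyping noise.  It does not
model sex chromosomes, dominance or epistasis, maternal effects,
overlapping-generation age structure beyond the replacement scheme,
genotyping ascertainment bias, or real mink karyotype heterogeneity
(equal chromosome lengths are assumed).  Passing tests therefore shows
that the methods behave correctly under this idealised architecture,
not that their absolute accuracies transfer to any particular real
population.

## Problem sizes used in the bundled experiments

The test suite exercises micro-scale configurations (tens of animals,
hundreds of loci) chosen so every structural feature is still present.
`scripts/acceptance.py` runs the full-scale design (10k panel, 5000
QTL, full demography) with three replicates, sharing one
history/expansion per replicate across the heritability × design
branches — the historical population is independent of trait and
design, so sharing introduces correlation between cells but no bias.

## Known limitations

* The LD-based Ne estimator applied to 0–1 Mb bins cannot recover the
  recent breeding Ne of this design (see above); the ΔF route is more
  appropriate for the recent phase.
* F_HOM here measures departure from Hardy–Weinberg expectation in the
  analysis sample; its magnitude is sensitive to the reference allele
  frequencies and genotyping error model, and is reported as a
  method-of-moments summary only.
* With known variance components and a single fixed effect, the
  evaluators are exact BLUP solvers; no REML/Gibbs machinery is
  provided or planned.
* A sizeable share of QTL are 3–4-allelic; biallelic markers tag their
  allelic contrasts imperfectly, so genomic accuracies under this
  architecture run somewhat below what an all-biallelic architecture
  with the same LD would give.  The allele-count mix is configurable
  through the genome-map builder.
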