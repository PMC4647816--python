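# Methods

## The data model

The substrate for every analysis is a diploid insertion-dosage matrix:
individuals × polyTE loci, entries in {0, 1, 2} counting the insertion
alleles carried at each locus. Phasing is discarded on input because all
statistics here are phase-free, and multi-allelic mobile-element records
collapse to presence/absence of any insertion allele. A sample panel
assigns each individual to one population and each population to one
continental group; groups partition the samples. The default packaged map
assigns 26 populations to five groups (African, Asian — meaning East
Asian — European, Indian — meaning South Asian — and American, which
collects the recently admixed populations of the Americas, including the
African-American ones).

Missing genotypes are a hard error by default; an opt-in policy treats
them as dosage 0, defensible only because the ancestral state of a polyTE
locus is absence. Coordinates are kept verbatim (1-based).

## Per-locus statistics

Allele frequency is f = TEi / 2n per stratum: the number of present
insertion alleles over total allele copies (2 per diploid). Frequency
spectra use half-open bins [lo, hi), except the final bin, which is
closed so a locus at the last edge is counted and bin totals always equal
the locus count. Sharing/exclusivity summaries use a *strict* threshold
(frequency > 0.05, not ≥), as do the δ AIM-threshold counts.

δ for two groups is |f₁ − f₂|; for three or more it is the maximum
pairwise absolute difference, which reduces to the two-group definition,
is invariant under group permutation and duplication, and matches how
multi-group δ is used in the ancestry-informative-marker literature.

F_ST is the Weir & Cockerham (1984) θ̂ per locus: variance components
a (among populations), b (among individuals within populations) and
c (within individuals), with the heterozygosity terms taken from observed
heterozygote counts rather than Hardy–Weinberg expectations, and
θ̂ = a/(a+b+c). Negative estimates are retained (they are informative
about sampling noise near zero differentiation); loci with a+b+c = 0
(monomorphic across all strata) are flagged undefined and excluded from
rankings. The implementation is vectorised over loci; the test suite pins
it to a literal, loop-based transcription of the component formulas on
exhaustive tiny configurations and 1,000 random ones at 1e-12.

Three-way "continental" differentiation (for AIM ranking and the
prediction analyses) uses the African/Asian/European groups only; admixed
groups (American, Indian) are excluded from differentiation statistics.

## Distances, diversity, embedding, trees

The allele-sharing distance between individuals is the L1 distance on
dosage vectors — the number of presence/absence alleles that differ. It
is a true metric; a normalised variant divides by 2 × (number of loci)
for comparability across marker subsets (analyses default to raw
distances). Population-average distances take the mean over cross-pairs
only; within-population pairs never enter the between average, and the
diagonal is zero as NJ/MDS input conventions require. Group diversity is
the distribution of within-group pairwise distances; contrasts between
groups use the two-sided Wilcoxon rank-sum test (normal approximation).

Because absence is ancestral, an all-zero pseudo-genome ("ANCESTOR") can
be appended; its distance to any individual is that individual's total
insertion load.

Classical (Torgerson) MDS double-centres −½ d² and keeps the top-k
eigenvectors scaled by √λ; on Euclidean-realisable input the embedding
reproduces the distances exactly (tested at 1e-9). Axis signs are fixed
by orienting each axis so a designated reference entity (by default the
first label) has a nonpositive coordinate. Negative trailing eigenvalues
are reported, never used.

Neighbor joining follows Saitou–Nei: Q-criterion agglomeration with ties
broken at the lowest (row, col) index pair for determinism, standard limb
lengths, and clamp-and-transfer for negative limbs (the limb is set to 0
and the deficit moved to its sibling) so all output branch lengths are
nonnegative. The algorithm is consistent: on additive matrices the
recovered path lengths equal the input (tested on random trees up to 12
taxa at 1e-9). Trees serialise to Newick and round-trip through standard
parsers.

The ancestor's position is reported two ways: its nearest neighbours in
the MDS plane (exact ties in the source distances are reported as ties,
never broken by the k-truncated embedding, which is degenerate for
equidistant configurations) and the leaf bipartition across its
attachment node in the NJ tree.

## Supervised admixture

The model: dosage g_l ~ Binomial(2, p_l) with p_l = Σ_k q_k f_kl, where
f are K ancestral-cluster insertion frequencies and q is the individual's
ancestry vector on the simplex. Estimation is two-phase:

1. **F from labelled references, closed form** — f_kl = TEi_k / 2n_k,
   clamped to [ε, 1−ε] with ε = 1e-4 so the likelihood stays finite.
   Target individuals never inform F.
2. **q per target by EM** — multiplicative update
   q_k ← q_k/(2L) Σ_l [g_l f_kl/p_l + (2−g_l)(1−f_kl)/(1−p_l)],
   uniform initialisation, convergence when the log-likelihood improves
   by less than 1e-7 (max 2,000 sweeps). The update never decreases the
   log-likelihood (asserted at every iteration), and the whole procedure
   is deterministic — no random seed exists anywhere in it.

The two-phase design was chosen over joint block relaxation because with
fixed references it optimises the identical target likelihood, is simpler
and reproducible. EM optima are verified in tests against brute-force
grid search over the simplex at 0.001 resolution; because EM approaches
boundary optima (q_k → 0) asymptotically, agreement is asserted at 2e-3
in q and 1e-6 in log-likelihood. Identical reference clusters make q
unidentifiable between them; this is detected and warned about, not
silently tolerated.

A practical property worth knowing: with genome-wide, mostly-rare marker
sets and finite reference panels, sampling noise in F̂ attenuates q̂
toward the uniform vector. Estimates remain strongly rank-correlated with
the truth; exact recovery (mean |q̂ − q| < 0.05) is a property of
informative, well-separated marker sets, and the tests state both claims
separately.

## Marker subsets and prediction

Loci are ranked by descending multi-group F_ST with ties broken by
(chrom, pos) and undefined estimates excluded; top-n prefixes give nested
subsets (the sweep grid 500, 490, …, 10 is packaged as the default).

Ancestry cross-validation, per replicate: a stratified 80/20 split within
each group; cluster frequencies from the training fold (full locus set
and each top-n subset); q for each test individual; a call to the argmax
group only when max q ≥ 0.9. Accuracy is correct calls over calls made —
no-calls are excluded from numerator and denominator, with the call rate
reported alongside so no information is lost. Error is the RMSD between
the subset-based q and the q computed from the complete locus set with
the same training fold, averaged over all test individuals; this "distance
to the genome-wide answer" reading keeps the error well-defined even
where group labels are arguable. Replicate streams derive
deterministically from (seed, replicate index), so reports are
bit-reproducible given (seed, replicates). The locus ranking is computed
once on the full data; note that ranking loci by F_ST measured on data
that include the test individuals can act as an anti-informative selector
when markers carry no true signal, which is why the chance-floor test
supplies a fixed marker list instead.

Admixture prediction error trains on reference groups, estimates q for an
admixed cohort from the full locus set and from each subset, and reports
the RMSD over the reference components (averaged over individuals) plus
the Pearson correlation of pooled component fractions. The procedure is
fully deterministic, so it takes no seed.

## The synthetic-data generator

The generator produces datasets with the statistical structure the
analyses assume, with complete ground truth (true frequencies at every
level, true q for admixed individuals), so every stage is testable
without external downloads.

- **Ancestral frequency law**: a mixture of a Beta(0.5, 50) truncated
  below at 0.003 (the rare class) and a Uniform(0.05, 0.6) component for
  common loci. The truncation models ascertainment — catalogued polyTE
  loci were discovered segregating in a sequenced cohort, so frequencies
  far below one carrier per cohort are never observed. The mixture weight
  is derived analytically from the target fraction of sub-5 % loci
  (default 0.935), so the drawn spectrum hits the target in expectation.
- **Demography**: frequencies drift root → clade → group → population.
  Each step is Balding–Nichols (f′ ~ Beta with mean f and variance
  F·f(1−f)); clade and group steps may add **founder loss** — an allele
  at frequency f is lost outright with probability (1−f)^(2·founders).
  Loss is deliberately not mean-preserving: it is what makes a
  bottlenecked lineage segregate fewer loci. Without it, mean-preserving
  drift alone cannot reproduce the robust diversity excess of the
  African-like group over an admixed cohort that is itself 80 %
  African-like.
- **Exclusive loci**: a per-group fraction of loci is private to one
  group (zeroed in the others before the group's drift step).
- **Admixed cohorts**: each individual draws q ~ Dirichlet(α) over source
  groups and genotypes Binomial(2, Σ_k q_k f_k,l) against group-level
  frequencies.
- **Families**: loci are labelled ALU/L1/SVA in proportions 0.79 / 0.16 /
  0.05 (Alu dominates real polyTE catalogues); family labels matter only
  for per-family masking.
- Everything derives from a single generator seeded by the config;
  outputs (VCF with `<INS:ME:…>` records, panel TSV, ground-truth TSVs,
  config echo) are byte-identical across runs with the same seed.

`serial_founder_preset()` packages the study design used throughout the
tests and the acceptance script: an African-like group (2 populations ×
50, divergence 0.01, within-group drift 0.03, 15 % private loci), an
out-of-Africa clade (F = 0.08, 8 diploid founders) from which a
European-like group (divergence 0.05) and an Asian-like group
(divergence 0.12 with a second founder event of 15) descend, plus a
two-way African/European cohort (α = (8, 2)) and a three-way mostly
Asian/European cohort, both 30 individuals, 2,000 loci in total. The
parameters were chosen so the serial-founder signatures are structural
rather than seed-dependent: diversity medians order African > admixed
American > European > Asian, the ancestor attaches between the
African-like and non-African-like clades, and the admixed cohorts fall
between their source poles in MDS.

**What the generator does not emulate**: linkage (loci are independent,
as every statistic here is locus-independent), selection, insertion-site
biology, realistic chromosome structure, or sequencing/genotyping error.
Passing tests therefore demonstrate correctness of the estimators and the
qualitative demographic signatures under the stated generative model, not
performance on real genotype panels.

## Problem sizes and numerical choices

The preset runs 360 individuals × 2,000 loci — large enough that the
group contrasts are decisively significant and the cross-validation
sweeps are stable at 10 replicates, while keeping the full test suite and
the acceptance script in the minutes range on a single CPU. Tolerances:
F_ST vs oracle 1e-12; NJ and MDS exactness 1e-9; EM ε = 1e-4, tol = 1e-7,
max 2,000 iterations (tests that probe invariance to locus duplication
tighten tol, since the likelihood scale doubles). Degenerate inputs have
defined behaviour throughout: monomorphic loci (undefined F_ST flag),
empty strata and clusters (errors), equidistant ancestors (reported
ties), identical clusters (warnings), groups too small to stratify or to
have within-group pairs (errors).

## Known limitations

- The supervised model ignores linkage and treats reference labels as
  error-free; it is a global, not local, ancestry method.
- q̂ attenuation on rare-marker panels (above) means absolute admixture
  fractions from small or rare-heavy panels should be read as
  conservative, pulled toward uniform.
- The raw allele-sharing distance conflates diversity with divergence: a
  highly diverse group has large internal distances, which dominates
  low-dimensional embeddings of population averages when group-private
  polymorphism is abundant. Individual-level embeddings are the more
  interpretable view in that regime.
- VCF ingestion recognises `<INS:ME:FAMILY>`-style symbolic ALT alleles
  (configurable regex); other MEI encodings need a custom pattern.
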