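# polyte

Population-genetic analysis of **polymorphic transposable element (polyTE)
genotypes** — genomic sites at which individuals differ in the
presence/absence of an Alu, L1 or SVA insertion.

PolyTE loci are attractive ancestry markers: a shared insertion almost
always reflects identity by descent (homoplasy-free), insertions are
stable once fixed in a lineage, and the ancestral state of every locus is
known to be *absence* of the insertion. `polyte` provides the complete
analysis chain for diploid presence/absence dosage matrices (dosage ∈
{0, 1, 2}), for researchers studying human population structure, ancestry
and admixture with TE markers — or any biallelic presence/absence marker
system with a known ancestral state.

## What it computes

- **Allele frequencies and spectra** — per locus and stratum,
  f = TEi / 2n (insertion alleles over total alleles); unfolded frequency
  spectra; counts of loci above a frequency threshold that are shared
  among or exclusive to continental groups.
- **Per-locus differentiation** — δ (maximum pairwise absolute frequency
  difference between groups, the classical AIM statistic) and the Weir &
  Cockerham (1984) F<sub>ST</sub> estimator
  θ̂ = a / (a + b + c) from the among-population (a), among-individual (b)
  and within-individual (c) variance components, with observed
  heterozygote counts; negative estimates retained, monomorphic loci
  flagged undefined.
- **Allele-sharing distances** — d(i, j) = Σ<sub>l</sub> |g<sub>il</sub> −
  g<sub>jl</sub>|, the number of presence/absence alleles differing
  between two individuals; population-averaged matrices; within-group
  diversity distributions with Wilcoxon rank-sum contrasts; a hypothetical
  ancestral genome (all dosages zero) as a pseudo-sample.
- **Embedding and trees** — classical (Torgerson) MDS and Saitou–Nei
  neighbor joining with Newick output; placement of the ancestor in both.
- **Supervised admixture** — the binomial likelihood model
  g<sub>l</sub> ~ Bin(2, Σ<sub>k</sub> q<sub>k</sub> f<sub>kl</sub>):
  cluster frequencies f from labelled reference individuals in closed
  form, per-individual ancestry fractions q by EM on the simplex
  (deterministic, monotone in log-likelihood).
- **Marker-subset prediction** — loci ranked by F<sub>ST</sub>; nested
  top-n panels evaluated by stratified 80/20 cross-validation (calls
  require max q ≥ 0.9; accuracy over calls; error = RMSD to the
  full-locus-set q) and by admixture-prediction error for admixed cohorts.
- **Synthetic data** — a generator with full ground truth: ascertained
  low-frequency-skewed spectra, group-exclusive loci, Balding–Nichols
  drift with founder loss along a serial-founder demography, and
  Dirichlet-admixed cohorts. `serial_founder_preset()` packages an
  African-like / European-like / Asian-like design with two admixed
  cohorts.

Input formats: VCF with mobile-element-insertion records
(`<INS:ME:ALU>`-style symbolic ALT alleles, via cyvcf2) and a sample panel
TSV (`sample`, `pop`[, `super_pop`]); a 26-population → 5-group
continental assignment ships as the default map.

## Worked example

```python
import numpy as np
from polyte import (simulate, serial_founder_preset, allele_sharing_distance,
                    diversity_distributions, ancestry_cv)

res = simulate(serial_founder_preset(seed=7))   # 360 individuals, 2000 loci
m, panel = res.matrix, res.panel

d = allele_sharing_distance(m)
dists, contrasts = diversity_distributions(d, panel, level="group")
for g, v in sorted(dists.items(), key=lambda kv: -np.median(kv[1])):
    print(f"{g:<10} median within-group distance {np.median(v):6.1f}")

cv = ancestry_cv(m, panel, ["African", "Asian", "European"],
                 subset_sizes=[500, 100, 50, 10], replicates=5, seed=7)
print(cv[["size", "accuracy", "error", "call_rate"]].round(3))
```

prints

```
African    median within-group distance  125.0
American   median within-group distance   94.0
European   median within-group distance   44.0
Asian      median within-group distance   38.0
 size  accuracy  error  call_rate
  500       1.0  0.010      0.927
  100       1.0  0.022      0.883
   50       1.0  0.030      0.847
   10       1.0  0.057      0.763
```

The African-like group is the most diverse (every pairwise rank-sum
contrast is significant), the admixed American cohorts sit second, and the
bottlenecked groups follow — the serial-founder signature. Ancestry calls
from the top-500 F<sub>ST</sub>-ranked markers are essentially perfect;
as the panel shrinks to 10 markers the calls that are made stay accurate
but fewer individuals clear the 90 % call threshold and the deviation from
the genome-wide ancestry fractions (error) grows.

The scripts in `examples/` walk through each capability: spectra and
AIM counts, diversity/MDS/NJ with the ancestral genome, supervised
admixture against simulated truth, and marker-subset prediction.

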