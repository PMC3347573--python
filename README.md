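# strpopgen

Population-genetic and forensic statistics for autosomal STR panels.

Forensic DNA identification rests on reference databases of short-tandem-repeat
(STR) allele frequencies: a match between a crime-scene profile and a suspect is
weighed by how probable that profile is in a reference population.  Building and
validating such a database for a large, genetically structured country requires
the full population-genetics toolchain — diversity summaries, exact
Hardy–Weinberg testing, identification indices, among-population differentiation,
distance/tree/ordination analysis, and gene-geographic mapping.  `strpopgen`
implements that pipeline for multiallelic STR panels such as PowerPlex 16
(the 13 CODIS loci plus PentaD/PentaE and amelogenin), together with a
synthetic-cohort generator so every stage is testable without access to
restricted genotype data.

It is written for forensic geneticists and population geneticists who work with
diploid STR genotype tables (GenePop or CSV) and per-population allele-frequency
reference tables.

## What it computes

**Diversity** (`strpopgen.diversity`) — expected heterozygosity
*He = 1 − Σᵢpᵢ²* (unbiased form *n/(n−1)·(1 − Σpᵢ²)* over *n* gene copies by
default), observed heterozygosity, allele counts, and the repeat-number
dispersion (max − min allele, in repeat units), per (population, locus) and
aggregated.

**Hardy–Weinberg exact test** (`strpopgen.hwe`) — the conditional probability
of a genotype table given its allele counts,

> P(table | m) = [n! / Π n<sub>ij</sub>!] · [Π mᵢ! / (2n)!] · 2^H,

with p-value by complete enumeration of the fixed-margin table set (small
loci) or by a Markov chain over gene-copy arrangements (many-allele loci),
with batch-means standard errors; Bonferroni and Šidák multiplicity
thresholds.

**Forensic indices** (`strpopgen.forensic`) — matching probability
*MP = Σ g²* over genotype frequencies, power of discrimination *PD = 1 − MP*,
power of exclusion *PE = h²(1 − 2hH²)*, typical paternity index *PI = 1/(2H)*;
panel-wide combination (MP multiplies; the reciprocal is the "1 out of N"
headline figure) and Balding–Nichols θ-corrected conditional genotype
probabilities for casework against structured reference populations.

**Differentiation** (`strpopgen.differentiation`) — two-level AMOVA over gene
copies with an allele-identity metric (Fst) or squared repeat-number
differences (Rst), multilocus indices, pairwise matrices and two-group
locus-wise tables, all with permutation significance.

**Structure** (`strpopgen.popstruct`) — Nei standard genetic distance
*D = −ln(J_XY/√(J_X·J_Y))*, UPGMA dendrograms (ultrametric, Newick output),
classical and SMACOF-refined multidimensional scaling.

**Gene geography** (`strpopgen.geomap`) — generalized Shepard interpolation of
a population statistic onto a uniform lon/lat grid: inverse-distance-cube
weights, 3,000 km cutoff, great-circle distances, legend statistics
(K reference points, N nodes, min/max/aver/std), ESRI ASCII export.

**Synthetic cohorts** (`strpopgen.synthdata`) — Balding–Nichols simulation:
subpopulation frequencies ~ Dirichlet(p(1−θ)/θ) around an ancestral vector,
genotypes drawn as two i.i.d. gametes (optional inbreeding *f*).  A bundled
15-locus panel emulation matches the PowerPlex 16 allele counts and per-locus
heterozygosity of a 17-population, 1,156-individual North-Eurasian cohort.

## Worked example

```python
import strpopgen as sp

# six urban-style populations, 50 individuals each, mild divergence
cfg = sp.make_paperlike_panel(seed=42, n_populations=6, n_per_population=50, theta=0.01)
gt, truth = sp.simulate_genotypes(cfg)

res = sp.amova(gt, permutations=999, seed=42)
print(f"multilocus Fst = {res.fst:.4f} (permutation p = {res.p_value:.4f})")

summary = sp.diversity_summary(gt)
print(summary.per_locus[["locus", "pooled_He", "pooled_A", "pooled_R"]].head(4).to_string(index=False))

per_locus, combined = sp.forensic_summary(gt, populations=["pop1"])
row = combined.iloc[0]
print(f"combined 15-locus MP = {row.MP_total:.3e}  (1 out of {row.reciprocal_str})")
```

prints

```
multilocus Fst = 0.0091 (permutation p = 0.0010)
  locus  pooled_He  pooled_A  pooled_R
D3S1358   0.759750         8       7.0
   TH01   0.762905         8       6.0
 D21S11   0.847986        17       9.0
 D18S51   0.871820        17      15.0
combined 15-locus MP = 3.951e-16  (1 out of 2.53e+15)
```

The simulated cohort recovers its configured divergence (θ = 0.01 → Fst ≈
0.009, highly significant under permutation), the per-locus diversity mirrors
the panel it emulates (TH01-like loci around He ≈ 0.76, D18S51-like around
0.87), and a 15-locus profile match is expected about once in 2.5 quadrillion
genotypes — the order of magnitude that makes such panels decisive in
identification casework.

The same stages are available from the shell:

```sh
strpopgen simulate --populations 6 --size 50 --theta 0.01 --seed 42 --out cohort.csv
strpopgen fst cohort.csv --permutations 999 --seed 42
strpopgen run --genotypes cohort.csv --out-dir results/
```

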