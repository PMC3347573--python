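# Methods

This note documents the statistical models behind `strpopgen`, the defaults
and the reasoning for them, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make results reproducible.

## Data model

STR alleles are repeat numbers with single-digit microvariants (TH01 9.3,
PentaD 2.2, FGA 22.2 …).  They are stored as integer tenths of a repeat
(9.3 → 93), never as binary floats, so microvariants survive arithmetic and
round-trips exactly; `"9.30"` normalizes to `"9.3"`.  A genotype is an
unordered diploid pair, missing only as a whole (half-calls are rejected —
multiplex STR typing fails per locus, not per allele).  Amelogenin is carried
as an optional per-individual metadata field and excluded from all
statistics; it determines sex, not identity.

GenePop files are supported with 2- and 3-digit allele codes.  GenePop cannot
natively encode microvariants, so reading or writing them requires an
explicit `{label: code}` map; writing a microvariant without one is an error
rather than a silent truncation.

## Diversity statistics

Expected heterozygosity is the gene diversity `He = 1 − Σ pᵢ²`, by default
with the `n/(n−1)` gene-copy correction (the unbiased Nei estimator, which
is what the mainstream population-genetics packages report for diploid
data).  Whether a given published table used the corrected or the plain form
is often unknowable from the table alone; both forms are exposed
(`unbiased=False`), and downstream consumers should state which they used.
"Repeat-number dispersion" is the allele-label range (max − min, in repeat
units) — for a PentaE-like locus with alleles 5…23 that is an 18-repeat
span.  A variance-based dispersion was deliberately not used: the range is
what makes published per-locus dispersion columns reproducible from allele
lists alone.  All table averages are arithmetic means over the cells
present; every emitted summary re-derives its own averages from its own
cells and fails loudly on mismatch.

## Exact Hardy–Weinberg test

Conditional on the allele counts `mᵢ`, a genotype table has probability

    P(table | m) = [n! / Π n_ij!] · [Π mᵢ! / (2n)!] · 2^H

(H = heterozygote count), computed in log space.  The p-value is the total
probability of tables with `P ≤ P_observed`, ties included (tolerance 1e-12
in log space).

*Enumeration* walks the full fixed-margin table set by depth-first recursion
and asserts that the probabilities sum to 1 (to 1e-8) on every call.  It is
used automatically where the table count stays in the tens of thousands
(k ≤ 2 at any n; k = 3 up to n = 60; k = 4 up to n = 25; k = 5 up to
n = 12) and refuses, rather than hangs, beyond a configurable budget.

*Markov chain*: the conditional distribution above is exactly the
push-forward of the uniform distribution over arrangements of the 2n gene
copies into n ordered pairs.  The chain therefore swaps two gene copies
between two random individuals and always accepts — a symmetric proposal
with uniform stationary law — and estimates the p-value as the long-run
fraction of steps whose (incrementally updated) log-probability is at or
below the observed one.  Defaults: 100,000 steps, 10,000 burn-in, standard
error by 50-batch means; the incremental log-probability uses a looser
1e-7 tie tolerance to absorb float accumulation over long chains.  The
kernel is numba-compiled; a fixed seed gives bit-identical results.

Degenerate inputs: a monomorphic locus returns p = 1 with method
`"degenerate"`.

Multiplicity: Bonferroni `α/m` is the default threshold; the Šidák variant
`1 − (1−α)^(1/m)` is a flag.  For α = 0.05 and m = 15 these give 0.00333
and 0.00341 — note that published analyses sometimes quote a rounded
"0.0035" for this setting, which matches neither exactly; both variants are
provided and the choice is reported with the results.

## Forensic indices

Per locus: `MP = Σ g_k²` over genotype frequencies, `PD = 1 − MP`,
`PE = h²(1 − 2hH²)`, `PI = 1/(2H)` (the *typical* paternity index of a
population summary, not a case-specific trio likelihood ratio; `H = 0`
yields an unbounded-PI flag).  The default genotype-frequency mode is
**observed** (empirical genotype proportions, the PowerStats convention for
cohort summary tables); an **expected** mode derives HWE genotype
frequencies from alleles, usable with frequency-only reference databases.
Across a panel of unlinked loci MP and PI multiply, `PE_total =
1 − Π(1 − PE_l)`, and the reciprocal `1/MP_total` is displayed at 3
significant figures.

Published identification tables are not always internally consistent: in
the bundled reference table several rows' printed MP and "1 out of N"
columns disagree at 3 significant figures, and the text-level headline
reciprocal matches a different row than the pooled one.  The Orel row is
self-consistent (1/2.53×10⁻¹⁶ = 3.95×10¹⁵) and is the one used for
validation.

θ-correction (Balding–Nichols conditional genotype probabilities):

    P(AA) = [2θ + (1−θ)p_A][3θ + (1−θ)p_A] / [(1+θ)(1+2θ)]
    P(AB) = 2[θ + (1−θ)p_A][θ + (1−θ)p_B] / [(1+θ)(1+2θ)]

At θ = 0 these reduce to `p²` and `2pq`; for θ > 0 the homozygote
probability strictly exceeds `p²`, which is the conservative direction when
the suspect's subpopulation may differ from the reference — the reason the
correction exists.  θ should be set to the largest plausible among-
subpopulation Fst for the reference group (order 0.01–0.03 for
continental-scale human structure).

## AMOVA differentiation

Gene copies are the analysis units (two per individual); sums of squared
inter-copy distances are partitioned among/within populations.  Identity
metric (d² = 0/1) gives Fst; squared repeat-number difference gives Rst,
which up-weights distant alleles under stepwise mutation.  Closed-form
count identities (`identity`: (|S| − Σc²/|S|)/2; `repeat²`: |S|·variance)
replace explicit O(|S|²) pair sums; a brute-force pair-sum oracle verifies
them to 1e-10 in the test suite.  Components follow the standard two-level
decomposition with `n′ = (N − Σn_g²/N)/(G−1)`; the multilocus index sums
among- and total-components over loci before taking the ratio (weighted
aggregation, not a mean of per-locus ratios).  Negative variance components
are reported as computed, with a flag; pairwise displays may clamp at zero
by option.  A within-individual level is not modelled: the quantities of
interest here are among/within-population only.

Significance: permutation of individuals across populations,
`p = (hits + 1)/(perms + 1)`, default 10,000 permutations, fixed seed.
Permutations that reproduce the observed partition are genuine ties and are
counted.  Two-group locus-wise tables report the Monte-Carlo standard error
`√(p(1−p)/perms)`.

Frequency-only mode: when only per-population frequencies and gene-copy
counts are available (published reference data), the same sums of squares
are reconstructed from counts.  Given counts identical to a genotype
table's, the estimate is identical; what is lost is the permutation test,
so frequency-only results carry a point estimate only.

## Distances, trees, ordination

Nei standard distance `D = −ln I`, `I = J_XY/√(J_X J_Y)` with J-terms
summed over shared loci.  Populations sharing no alleles anywhere have
infinite distance — flagged, and rejected by UPGMA rather than propagated.

UPGMA merges the closest pair of clusters; inter-cluster distance is the
unweighted average over member pairs (sizes weight the update), node height
is half the merge distance, so trees are ultrametric by construction (an
exactness check runs at build time).  Ties break on the lowest-index pair
in the current cluster ordering, making trees reproducible across runs and
platforms.  Both Nei and pairwise-AMOVA matrices are accepted as input.

Classical MDS (principal coordinates) double-centers the squared distances
and keeps the top positive eigenvalues; negative eigenvalues (non-Euclidean
input, common for genetic distances) are dropped with their share of
absolute eigenvalue mass reported, and eigenvalues below 1e-12 of the
leading one are treated as zero so duplicate populations map to coincident
points instead of acquiring noise axes.  An optional metric SMACOF
refinement starts from the classical solution with a fixed seed.  Stress is
Kruskal's stress-1 against the input distances.  Nonmetric scaling is not
implemented; for the near-Euclidean matrices typical of allele-frequency
data the classical solution is already a good metric embedding.

## Gene geography

Values known at reference points (population coordinates + statistic) are
interpolated to a uniform lon/lat grid by inverse-distance-power weighting
with a hard cutoff: `w = 1/d³` by default, points beyond 3,000 km ignored,
nodes with no point in radius set to no-data.  "Generalized Shepard" here
means exactly this cutoff-windowed power weighting; the Franke–Nielson
local-polynomial variant is not implemented.  Distances are great-circle
(haversine, R = 6371.0 km): at a 3,000 km radius across a continent planar
distances would be badly wrong.  Weights form a convex combination, so
interpolated values are bounded by the reference range; a node within
1e-9 km of a reference point takes its value exactly, and duplicate
reference coordinates with conflicting values are rejected as ambiguous.
Default grid: 881 × 381 nodes (335,661) over lon 10°E–180°E, lat
35°N–75°N — a North-Eurasian window chosen as configuration, not a claim
about any particular published map's bounds.  A land/water mask is optional
and user-supplied; no coastline data is bundled, so masked node counts are
configuration-dependent.

## Synthetic cohorts

The generator draws subpopulation frequencies from the Balding–Nichols
model, `q ~ Dirichlet(p(1−θ)/θ)`, so `E[q] = p` and
`Var[q] = θp(1−p)`: θ is simultaneously the simulation truth for Fst
recovery and the θ of the forensic correction.  θ = 0 returns the ancestral
vector analytically.  Genotypes are two i.i.d. gametes per individual;
inbreeding `f` replaces the second gamete with an identical-by-descent copy
at rate f.  Ancestral frequencies come from a uniform Dirichlet(1) law, a
triangular (unimodal, stepwise-mutation-like) law, or are fixed per locus.

`make_paperlike_panel` builds a 15-locus panel whose per-locus allele
counts (8, 8, 17, 18, 18, 9, 10, 12, 9, 8, 13, 10, 11, 8, 20) and
heterozygosities (0.61 at the least polymorphic, TPOX-like, locus to 0.91
at the PentaE-like locus) match a published 17-population North-Eurasian
PowerPlex 16 cohort; ancestral frequencies use an exponential-decay family
`p_j ∝ exp(−λ|j − center|)` with λ solved by bisection so `1 − Σp²` hits
each target exactly.  `make_study_cohort` adds the study's design scale:
17 named populations with their sample sizes (60, 50, 51, 50, 50, 185, 50,
52, 92, 70, 61, 53, 48, 50, 50, 138, 46 — 1,156 individuals) and a default
θ of 0.0267, the cohort's overall fixation index.

Randomness: one global seed feeds `SeedSequence` spawn keys per
(role, population, locus), so adding loci or populations never perturbs
earlier draws, and a fixed seed reproduces cohorts byte-identically.

What the generator does **not** emulate: linkage, mutation processes over
genealogies (no coalescent), genotyping dropout/missingness, allelic
ladders and binning artifacts, sex markers, and real geographic clines
(population coordinates are user-supplied, not simulated).  Passing tests
on synthetic cohorts therefore validate the estimators under their own
model assumptions — correct counting, variance decomposition, calibration
— not robustness to the artifacts of real capillary-electrophoresis data.

## Problem sizes and calibration checks

The test suite and the acceptance script choose sizes that make the checks
statistically meaningful at desk scale: exact-test chain-vs-enumeration
agreement on ≤4-allele tables of up to 20 individuals at 3 batch-means
standard errors; type-I calibration on 6-allele, 100-individual HWE-true
replicates (10,000 in the suite, 5,000 in the script) expecting 5% ± 1%
rejections at α = 0.05 — a many-allele design, because few-allele exact
tests are conservative through sheer discreteness of the null support, a
property of the test rather than a defect of the implementation; Fst
recovery at θ = 0.02 with 6 populations × 100 individuals × 15 loci,
expecting the multilocus estimate in [0.01, 0.03] in ≥95% of runs (the
multilocus SE at this design is ≈0.003, so the band is ≈3 SE); forensic MP
against a brute-force ordered-pair count on tables up to 200 individuals;
and full-cohort simulations at the 17 × 1,156 study scale in the
acceptance script.

## Known limitations

- Two-level AMOVA only (no group/population/individual hierarchy, no
  within-individual component, no Weir–Cockerham per-allele variants).
- Exact-test enumeration is exponential in allele count; the auto policy
  hands large loci to the chain, whose p-values carry Monte-Carlo error
  (reported as SE).
- Frequency-only differentiation has no significance test.
- Nonmetric MDS, neighbor-joining, bootstrap supports, and kriging-style
  interpolation are out of scope.
- The CSV/GenePop readers validate structure and allele syntax but do not
  re-bin alleles; calls are taken as given.
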