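# Methods

## Genotype I/O and dosage coding

Genotypes enter and leave the package as PLINK text PED/MAP (whitespace
tokens, allele "0" = missing; a half-missing genotype counts as missing) and
live in memory as counted-allele dosages {0, 1, 2, −1}. The counted allele
at each variant is the first non-missing allele in file order, with the
lexicographically smaller allele winning when both alleles first appear in
the same heterozygote. r² is invariant to this choice; fixing it makes the
sign of D and every output byte reproducible. Datasets written by the
package are coding-normalized first so a write → read cycle is the identity.
Positions are 1-based; `pos_bp = 0` is the unmapped sentinel, removed by QC.
Distances are simple differences `pos_b − pos_a` in bp.

## Marker QC

Rules run in a fixed order — autosome/mapped → call rate → MAF → HWE — and
each failing marker is attributed to the *first* rule it fails, so the
report's counts add up to the input count. Thresholds are inclusive
(call rate ≥ 0.90, MAF ≥ 0.05, HWE p ≥ 10⁻⁵ retained by default; cattle
autosomes "1"–"29"). The HWE test is the exact conditional test: given the
observed allele counts, heterozygote counts with the same parity are
enumerated, and the p-value sums the probabilities of configurations no more
probable than the observed one (no mid-p). Probabilities are computed with
log-gamma arithmetic; the test suite checks every table with ≤ 30 alleles
against an exact rational-arithmetic enumeration. No sample-level QC is
applied: the pipeline implements marker-level criteria only.

## Pairwise LD

The primary r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples — the estimator PLINK applies to unphased data,
and the one the downstream Ne machinery expects. Missingness is handled by
pairwise deletion with the per-pair sample count recorded; pairs that become
monomorphic after deletion, or retain fewer than two complete observations,
are skipped with a reason code rather than zero-filled. The windowed scan
emits every same-chromosome pair with 0 < distance ≤ 500 kb (cap inclusive)
exactly once, ordered by (chromosome, left index, right index), so outputs
are byte-stable.

Gamete frequencies for D and |D′| come from an EM fit: every genotype
combination except the double heterozygote resolves to gametes directly, and
EM splits the AB/ab vs Ab/aB ambiguity, starting from linkage equilibrium,
to a fixed point within 10⁻¹⁰ or 1000 iterations (non-convergence is
flagged, and the last iterate returned). A caution borne out by a concrete
counterexample in the test suite: the dosage-correlation r² and the
gamete-frequency r² are different statistics and coincide exactly only in
special cases (e.g. a panel of double homozygotes); with no double
heterozygotes it is the EM *frequencies* that are exactly the gamete tally,
not the dosage correlation.

## LD decay, useful-LD crossing and panel sizing

Distance bins are half-open intervals (lo, hi] — the conventional
0/10/25/50/100/200/500 kb edges by default — each with pair count, mean and
SD of r², and mean pair distance; an "overall" row aggregates the window.
The useful-LD crossing is found by linear interpolation between consecutive
bin (mean distance, mean r²) points, the threshold defaulting to r² = 0.2
(the level associated with ≈ 0.85 genomic-selection accuracy); a companion
figure snapped down to 10 kb granularity matches how such distances are
usually quoted. Bin inspection and interpolation can disagree slightly, so
both are reported. Panel size is `floor(genome kb / spacing kb)`: a
fractional marker is meaningless, and at 40 kb over the 2,510,605 kb cattle
autosomal genome the floor gives 62,765 markers.

## LD-based historical Ne

For each of `n_bins` equal-width distance bins between `min_dist_bp` and
`max_dist_bp` (defaults 10 kb – 4 Mb, 30 bins; widening the window toward
several Mb reaches more recent generations), the arithmetic mean pair
distance δ maps to d = kδ Morgans (k = 10⁻⁸ by default) and then to a
recombination fraction via Sved–Feldman, c = d(1 − d/2) — monotone on
[0, 1] with the free-recombination ceiling c(1) = 0.5. The bin mean r² is
corrected for finite sample size, r²_adj = r² − 1/(βn) with β = 1 for
unphased data (2 if phase were known) and n the number of genotyped
individuals (a single panel-wide value, as the correction's formula has a
single n), then inverted:

    Ne(t) = (1 / (4 f(c))) · (1 / r²_adj − α),    t = 1/(2c),

with f the identity (the mapping is kept as a config hook) and α = 1, the
appropriate mutation correction when drift and recombination dominate —
which is exact for the mutation-free simulator used in validation. Bins
whose corrected r² leaves (0, 1/α) are dropped with a reason
("over-corrected" / "saturated"), never clamped: clamping would fabricate
Ne values. Generations are reported as floats; rounding is presentation.
Raw (t, Ne) points are emitted with no interpolation onto integer
generations — a nearest-t lookup is the caller's choice.

## Pedigree-based Ne

Kinship uses the tabular method in topological order,
C(x,x) = (1 + C(sire, dam))/2 and C(x,y) = (C(sire,y) + C(dam,y))/2 with
unknown parents contributing zero; the test suite checks it against an
independent Wright path-counting oracle to 10⁻¹². Inbreeding is parental
coancestry, and pedigree depth is equivalent complete generations via
t_i = Σ over known parents of (1 + t_parent)/2 (equal to Σ(½)^g over known
ancestors). Per-generation increases follow Cervantes et al. (ΔC) and
Gutiérrez et al. (ΔF); ΔF needs t > 1 and such exclusions are counted.
NeC averages ΔC over unordered pairs (self-pairs excluded, founder pairs
with t_i + t_j = 0 excluded and counted) and NeF averages ΔF; each inverts
as 1/(2·mean), with the standard error of the pair mean reported. A zero
mean yields a reasoned "undefined" rather than an infinite estimate.

The default reference set is all non-founders; a birth-year cohort is
selectable. The recovery experiments use the last-born cohort: ΔC measures
the drift accumulated between contemporaries, and mixing cohorts of
different depths inflates NeC (≈ 67 vs the true 50 in the 25 × 25 design)
while the cohort reference recovers it (median 50.0). S = NeC/NeF compares
two views of the same drift process; S ≈ 1 signals panmixia.

## Simulators and what they do (not) emulate

The genotype simulator is forward-in-time diploid Wright–Fisher: discrete
generations, two uniformly drawn parents per offspring (selfing allowed, as
classical WF theory assumes), gametes built with Poisson crossovers at a
per-bp rate (10⁻⁸ by default), loci initialized independently at frequencies
uniform on [0.05, 0.5], and no mutation afterwards — which is exactly the
drift–recombination regime the Corbin/Sved inversion assumes, making α = 1
correct and recovery tests clean. A size schedule supports multi-epoch
histories; multi-chromosome panels are independent replicate populations
concatenated under distinct chromosome labels. Monomorphic loci are retained
for QC to remove. The pedigree simulator is two-sex hierarchical random
mating (no selfing) with known sire/dam counts and theoretical
Ne = 4·Nm·Nf/(Nm + Nf). Both are byte-reproducible from their seed.

What the simulators do *not* emulate: mutation, selection, migration and
admixture, age structure and overlapping generations, genotyping error, and
the deep, large-Ne ancestral history that gives real cattle their moderate
short-range LD. Passing recovery tests therefore demonstrate estimator
correctness under the estimators' own model, not robustness to those
realities — notably, at simulated Ne ≈ 50 the useful-LD crossing lies beyond
500 kb, unlike real panels.

## Validation designs and problem sizes

- **LD-based Ne recovery**: constant N = 50, all 50 individuals sampled
  (the sampling correction forbids sampling more individuals than exist),
  3 independent 10 Mb chromosomes × 1200 loci per replicate, 200 generations
  (≥ 4N, enough for quasi-equilibrium at the probed c), 20 replicates.
  Pairs spanning 0.4–5.5 Mb are split into 20 bins (t ≈ 9–120 generations);
  bin estimates with t ∈ [10, 100] are pooled and their median compared to
  truth. A single 10 Mb chromosome is only ≈ 0.1 Morgan and shares one
  genealogy, so replicate variance would be huge without the independent
  chromosomes. Runs in ≈ 12 s on one CPU.
- **Pedigree Ne recovery**: 25 sires × 25 dams × 100 offspring ×
  10 generations, 10 replicates, last cohort as reference. Runs in ≈ 2 s.
- **Sved-equilibrium check**: mean r² at c ≈ 0.01 across 10 replicates
  compared with 1/(1 + 4Nc) + 1/n within 3 replicate-level Monte-Carlo SEs —
  pair-level SEs would understate the error because pairs on one chromosome
  are correlated.
- **Drift law**: tested in its coding-invariant heterozygosity form
  E[p_t q_t] = p₀q₀(1 − 1/(2N))^t, since dosage coding normalization can
  flip which allele is counted.

## Numerical choices and degenerate inputs

EM tolerance 10⁻¹⁰ (max 1000 iterations); bin edges strictly increasing and
right-closed; the pair scan's monomorphic guard uses an absolute 10⁻¹²
threshold on sums of squared deviations (exact zeros in practice); the
weighted overall bin mean agrees with the pooled mean to 10⁻⁹; kinship and
HWE oracles agree to 10⁻¹² and 10⁻⁹ respectively. Empty QC output is a
warning, not an error; an empty Ne trajectory (all bins dropped) is returned
with its diagnostics. Cycles, duplicate ids and malformed rows are rejected
at parse time with the offending line or cycle named.

## Known limitations

- The LD arm estimates a single pooled trajectory; per-chromosome decay and
  jackknife confidence intervals are future work.
- Integer-generation Ne tables (e.g. "Ne at generation 5") require a
  nearest-t lookup on the emitted points; none is applied silently.
- NeC on mixed-depth reference sets is biased upward (see above); prefer a
  cohort when the pedigree has birth years.
- The dosage r² is a genotype-level approximation to gametic r²; at HWE the
  two are close, but they are not interchangeable statistics.
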