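# Methods

This note documents the models, conventions and numerical choices
behind `ssrkit`, in the order the pipeline runs.

## Perfect-microsatellite mining

A perfect SSR is a maximal uninterrupted tandem run of a *primitive*
motif of length 1–6 (primitive: not itself a whole-number repetition of
a shorter word, so `AT` qualifies but `ATAT` does not). The miner scans
each period `p` = 1..6 and, at each left-maximal anchor, extends the
run while `s[j] == s[j - p]`. Conventions:

* **Shortest-primitive-period uniqueness.** A run is reported exactly
  once. If the candidate motif at period `p` is primitive and at least
  two full copies are present, `p` is provably the minimal period of
  the run (Fine–Wilf), so a poly-A tract is `A`×n only, never also
  `AA`×(n/2). This is what makes frequency tables partition counts
  disjointly by repeat type.
* **Partial trailing copies** are truncated: a 13-base `(AT)` tract is
  `AT`×6 spanning 12 bases. Repeat counts in reports are whole numbers.
* **Ambiguity codes break runs.** Any character outside `{A,C,G,T}`
  (including `N`) terminates a run; the segments on either side are
  scored independently. Assembled transcripts do contain `N`s and a
  repeat spanning one is not perfect.
* **Single-strand scanning.** Transcripts are single-stranded; the
  reverse-complement relationship is handled at classification, not
  detection.
* **Coordinates** are 1-based inclusive in all reports.
* Default thresholds are 12, 6, 5, 5, 4, 4 minimum full copies for
  motif lengths 1–6 — the criteria used in transcriptome SSR surveys of
  this kind — and are overridable per run.

Adjacent runs of different motifs are reported as separate loci;
compound/interrupted SSR merging is deliberately out of scope.

## Canonical motif classes

Two motifs belong to one class iff one is a cyclic rotation of the
other or of its reverse complement. The class key is the smallest word
in the union of both rotation sets; the display label is `m/r` with `m`
and `r` the minimal rotations of the two strand sets in lexicographic
order (`AAG/CTT`, `ACG/CGT`). When the class is its own reverse
complement the two minima coincide, and the right-hand part falls back
to the second-smallest rotation, producing the conventional `AT/TA`.
Classification happens at display/tabulation time; detection stays
strand-literal.

Frequency matrices bin loci at 4–11 and ≥12 full copies. Percentages
are shares of the grand total rounded **half-up** to two decimals,
matching how printed survey tables round. Repeat counts below 4 are an
error rather than a silent extra bin, because such loci are never
tabulated in this table layout.

## Primer screening

The screen enumerates forward primers entirely within the left flank
and reverse primers within the right flank, so every amplicon contains
the full repeat run. Hard constraints (defaults): product 100–400 bp,
primer length 18–28 bp, GC fraction 0.30–0.70, Tm 50–65 °C, pairwise
Tm difference ≤ 5 °C, and rejection of any candidate with a contiguous
self- or cross-complementary stretch of ≥ 8 bases. Survivors are
ranked by

    penalty = |len_f − 23| + |len_r − 23|
            + 1.0 × |Tm_f − Tm_r|
            + 10.0 × (distance of each GC fraction outside [0.45, 0.55])

with deterministic tie-breaking (leftmost forward start, then shortest
product). The penalty is an explicit, reproducible scorer of the
package's own design; commercial design suites use unpublished scoring
models, and no attempt is made to imitate any of them. Melting
temperatures use the nearest-neighbor model with the SantaLucia (1998)
unified parameter set at fixed conditions (50 mM Na⁺, 250 nM each
oligo, entropic salt correction), so identical inputs always give
identical rankings.

Mononucleotide-repeat loci are excluded from screening by default:
homopolymer length variation is not reliably scorable as a
fragment-length polymorphism. The pre-filter can be disabled.

Screening cost is kept linear in practice by applying the
complementarity screen lazily along the penalty ranking: it only runs
until `top_k` survivors are found.

## Marker statistics

For each locus and population, with missing calls dropped per locus
(pairwise deletion) and `n` the remaining diploid count:

* `NA` — distinct observed alleles.
* `Ho` — heterozygous individuals / n.
* `He` — Nei's **unbiased** estimator `(2n/(2n−1)) (1 − Σ pᵢ²)`. The
  unbiased form, not the plug-in, is the one that reproduces reference
  marker tables from integer genotype configurations at small n.
* `PIC` — Botstein's `1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²`, computed via
  `Σ_{i<j} pᵢ²pⱼ² = ((Σp²)² − Σp⁴)/2`.

A monomorphic locus reports `Ho = He = PIC = 0` and a not-applicable
Hardy–Weinberg result; published tables occasionally print small
nonzero PIC values for fixed loci, which this package treats as display
artifacts — arithmetically PIC is 0 when one allele is fixed. Values
are held at full precision internally and rounded half-up to three
decimals only in reports.

Panel summaries report per-population arithmetic means of `NA` and
`PIC` across loci, plus a pooled `NA` over the union of alleles across
populations.

**Reconstruction oracle.** Because published marker tables rarely ship
raw genotypes, `reconstruct_genotype_configuration` exhaustively
enumerates all genotype-count vectors over `NA ≤ 4` alleles and
`n ≤ 50` individuals whose heterozygote count matches the printed `Ho`
and whose unbiased `He` lies within a tolerance (default 5e-4, half a
unit in the last printed digit). Configurations equivalent under allele
relabelling are reported once. This turns printed `(n, NA, Ho, He)`
rows into verifiable inputs: for the bundled reference panel the
matching configurations are unique and their implied PIC agrees with
the printed column.

## Hardy–Weinberg exact tests

Conditioning on the observed allele counts gives Levene's distribution
over genotype-count configurations:

    P(config) = n! · Π mᵢ! · 2^h / ((2n)! · Π n_ij!)

with `h` the heterozygote count. The probability-test p-value sums `P`
over configurations with `P ≤ P(observed)`; ties (equal within 1e-12
relative) are included, the standard exact-test convention. One-sided
deficit/excess p-values are tail sums over configurations with
`h ≤ h_obs` / `h ≥ h_obs`. The enumerator asserts that the
probabilities sum to 1 (tolerance 1e-9) on every call — an internal
consistency proof of the recursion.

Complete enumeration is used while the configuration count is ≤ 10⁵
(any two-population small-panel dataset enumerates); beyond that, the
conditional distribution is sampled by uniform random re-pairing of the
2n allele copies (default 10⁶ draws), with seed, sample count and the
Monte-Carlo standard error recorded in the result. Exact conditional
tests are conservative: the empirical type-I error at α = 0.05 over
simulated HWE data sits below nominal, which the test suite checks over
2000 simulated loci at n = 12.

## Genotypic linkage disequilibrium

Phase is unknown in codominant SSR data, so association is tested on
the genotype × genotype contingency table of complete cases with the
log-likelihood-ratio statistic `G = 2 Σ O ln(O/E)`. The null
distribution is built by permuting one locus's genotype column;
`p = (1 + #{G_perm ≥ G_obs}) / (1 + B)` (add-one rule, so p is never
0). Loci monomorphic among complete cases yield a structured
not-applicable result. Ties with `G_obs` count toward the numerator,
which makes the test slightly conservative on heavily tied small
tables.

Multiple-testing adjustment offers Bonferroni, Holm and
Benjamini–Hochberg (via statsmodels); none is hard-wired, and the
pipeline records which one a run used.

## Synthetic data

The transcript generator emulates the input of a transcriptome SSR
survey at desk scale: background sequence i.i.d. from a base
composition (default mildly A/T-rich, A=T=0.30, C=G=0.20), rejection
sampled against the miner itself until repeat-free at the active
thresholds, with implants placed at recorded coordinates and accepted
only if mining returns exactly the implanted locus (junction artifacts
are resampled away). The emitted truth table therefore has zero label
noise. Compositions skewed enough to defeat rejection sampling (e.g.
A ≥ 0.97) raise an explicit error. What this generator does *not*
emulate: real transcriptome redundancy, imperfect/compound repeats,
assembly errors and coverage-dependent fragmentation — so perfect
recall on synthetic data demonstrates detector correctness, not
real-data completeness.

The genotype generator draws, per individual and locus, an autozygous
call (one allele doubled) with probability `F` and otherwise two
independent draws from the allele frequencies; missing calls are masked
at a fixed rate. Expected heterozygosity is `(1 − F)(1 − Σ pᵢ²)` in
closed form, which the suite verifies at n = 10⁴ for F ∈ {0, 0.5, 1}.
Allele codes are assigned 1..k in descending frequency order for
readable fixtures. The default two-population panel (12 individuals ×
9 loci, 2–3 alleles per locus, one panmictic population and one with
F = 0.3) mirrors the design of small marker-validation studies. The
model is a per-locus mixture, not a coalescent: it produces no linkage,
no mutation process and no allele-size structure.

## Problem sizes and determinism

Test and demonstration runs use desk-scale inputs (tens of transcripts
of 250–400 bp, 12-individual populations, 200–10 000 permutations),
which exercise every code path the full-scale analysis uses. All
stochastic components take explicit seeds; pipeline bundles stamp every
output file with a hash of the computational parameters plus the seed,
and rerunning a bundle with the same config and seed reproduces the
files byte for byte.

## Known limitations

* Imperfect, interrupted and compound SSRs are not detected or merged.
* The primer scorer is intentionally simple; it ranks plausibly but is
  no substitute for thermodynamic secondary-structure evaluation when
  ordering oligos.
* Allele codes are abstract labels; binning fragment sizes into alleles
  is upstream of this package, and an optional sidecar table is the
  only link back to base-pair ranges.
* The one-sided HWE tails are ordered by raw heterozygote count; with
  more than two alleles this is a coarser ordering than score-based
  (U-test) variants.
* Monte-Carlo HWE sampling is vectorised per batch but still costs
  minutes at the default 10⁶ draws; enumeration covers every dataset a
  small marker panel produces, so the sampler only matters for much
  larger samples.
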