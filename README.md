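# ssrkit

A toolkit for developing microsatellite (SSR) markers from transcriptome
data and evaluating them as population-genetic markers. It covers the
full desk-work chain used when building SSR panels for non-model
organisms — such as the nipa palm hispid beetle *Octodonta nipae*, an
invasive palm pest whose markers motivated the bundled reference
tables — from unigene FASTA to a scored marker panel:

1. **Mining** — detect every maximal *perfect* microsatellite (an
   uninterrupted tandem run of a primitive 1–6 bp motif) with minimum
   full-copy thresholds of 12, 6, 5, 5, 4 and 4 for mono- through
   hexanucleotide motifs.
2. **Classification** — group motifs into canonical classes closed
   under cyclic rotation and reverse complementation (`CTT` ≡ `TTC` ≡
   `TCT` ≡ `AAG` ≡ … → class `AAG/CTT`) and tabulate frequency matrices
   by repeat type and motif class.
3. **Primer screening** — enumerate and rank primer pairs flanking each
   SSR under hard constraints (product 100–400 bp, primer 18–28 bp with
   optimum 23, GC and nearest-neighbor melting-temperature windows,
   dimer screen) and a transparent additive penalty.
4. **Marker evaluation** — per locus and population: allele count
   N<sub>A</sub>, observed heterozygosity H<sub>o</sub>, Nei's unbiased
   expected heterozygosity
   H<sub>e</sub> = (2n / (2n − 1)) (1 − Σ pᵢ²),
   polymorphic information content
   PIC = 1 − Σ pᵢ² − Σ<sub>i&lt;j</sub> 2 pᵢ² pⱼ²,
   exact Hardy–Weinberg tests on Levene's conditional distribution
   (probability test plus one-sided heterozygote-deficit/-excess
   tails), and genotypic linkage-disequilibrium permutation tests.
5. **Synthetic data** — generators for transcript sets with implanted
   SSRs (exact truth tables) and diploid genotype samples with
   controlled allele frequencies and inbreeding, so every stage can be
   validated end to end without wet-lab data.

Inputs and outputs are plain text: FASTA, GENEPOP and TSV.

## Worked example

```python
from ssrkit import (
    find_perfect_ssrs, canonical_motif_class, summarize_locus,
    hwe_exact_test, GenotypeMatrix,
)

# 1. mine a transcript
loci = find_perfect_ssrs("TTACGACGACGACGACGAA")
print(loci[0].motif, loci[0].repeats, loci[0].start, loci[0].end)
# ACG 5 3 17        <- a perfect (ACG)x5 run at positions 3-17

print(canonical_motif_class("GAC").label)
# ACG/CGT           <- rotation + reverse-complement class

# 2. evaluate a locus: 12 diploids, 11 homozygous (1,1), one (1,2)
mat = GenotypeMatrix(
    population_name="demo",
    individual_ids=[f"i{k}" for k in range(12)],
    locus_names=["L1"],
    calls=[[(1, 1)]] * 11 + [[(1, 2)]],
)
s = summarize_locus(mat, "L1")
print(s.NA, round(s.Ho, 3), round(s.He, 3), round(s.PIC, 3))
# 2 0.083 0.083 0.077   <- one heterozygote among 12: He equals Ho here
#                          and PIC is slightly below He, as it must be

# 3. exact Hardy-Weinberg probability test (Levene conditional dist.)
res = hwe_exact_test({(1, 1): 4, (2, 2): 1})
print(res.method, round(res.p_probability, 3))
# enumeration 0.111     <- only 2 configurations exist; observed has P=1/9
```

The command line mirrors the library:

```bash
ssrkit --seed 7 simulate-fasta --n-seqs 50 --implant ATx6x25 \
       --fasta-out tx.fasta --truth-out truth.tsv
ssrkit mine --fasta tx.fasta --out ssr.tsv
ssrkit classify --ssr-tsv ssr.tsv --out-prefix freq
ssrkit primers --fasta tx.fasta --ssr-tsv ssr.tsv --out primers.tsv
ssrkit --seed 7 simulate-genepop --out pops.gen
ssrkit popgen --genepop pops.gen --out summary.tsv
ssrkit hwe --genepop pops.gen --out hwe.tsv --adjust holm
ssrkit ld  --genepop pops.gen --out ld.tsv --permutations 10000
```

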