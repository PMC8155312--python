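# ambigram

Polymorphism analysis of **ambigrammatic genes** — nucleotide sequences
that carry an open reading frame on the forward strand *and* on the
codon-aligned reverse complement. Ambigrammatic genomes occur in
narnaviruses, whose RdRp segment (and the companion "Robin" segment) can
be read without stop codons in both directions. The package implements a
double-synonym framework to decide, from a set of sampled genomes alone,
whether the reverse open reading frame (rORF) is under protein-level
purifying selection — i.e. whether it actually codes for a functional
protein — together with an ambigrammatic-ORF scanner and a simulator
that generates alignments under known selection regimes.

It is aimed at virologists and molecular evolution researchers with a
codon-aligned set of genomes of an ambigrammatic virus (or candidate
contigs from a metagenomic survey).

## The framework

Every forward codon pairs with a complementary-strand codon read in the
opposite direction. Two facts about the standard genetic code drive the
analysis:

1. **All complementary-strand stops are removable.** Only Leu and Ser
   codons (UUA, CUA, UCA) produce a stop on the aligned reverse
   complement, and each can be replaced by a forward-synonymous
   single-base substitution whose reverse complement is not a stop. An
   ambigrammatic version of any gene is therefore reachable by neutral
   evolution.
2. **Double synonyms exist.** Twelve codons (of Leu, Pro, Gln, Arg, Ser)
   admit a single-base substitution that is synonymous in *both* reading
   directions. If both strands code for protein, these are the only
   assuredly non-deleterious mutations.

Given M codon-aligned sequences of N codons, the package builds a
modal-base consensus and computes, per read direction:

- nucleotide statistics: transition/transversion counts `Nn` and `Nv`,
  the variable-site fraction `r = (n1+n2+n3)/(3NM)`, the Kimura
  transition/transversion rate-ratio estimate `alpha = 2*Nn/Nv` (each
  site offers one transition but two transversions), and the
  codon-position spectrum `(z1:z2:z3)`;
- codon statistics: synonymous / non-synonymous single-base variant
  counts with `R = Nns/Nsy` and its non-coding expectation

  ```text
  R_exp = sum_k [alpha*n_k(n) + n_k(v)] / sum_k [alpha*s_k(n) + s_k(v)]
  ```

  where `s_k`/`n_k` split the 9 single-base neighbours of consensus
  codon k by synonymy and transition/transversion, plus an ORF-wide
  dN/dS;
- two rORF-coding tests:
  - **hotspot test** — ratios `R_n` and `R_f` of the mean variant-set
    size `<n(k)>` and mean non-consensus fraction `<f(k)>` at doubly
    synonymous loci vs. other loci (well above 1 only if the reverse
    strand is coding);
  - **double-synonym frequency test** — `R = Ns/Nd`, single vs. double
    synonyms at variable doubly synonymous loci, against the Kimura
    null `R0 = sum_k [alpha*S_k(n) + S_k(v)] / sum_k [alpha*D_k(n) +
    D_k(v)]` built from each consensus codon's synonym profile. `R`
    near 1 indicates a coding reverse strand; `R` near `R0` indicates
    non-coding.

## Worked example

Simulate 20 genomes of a 300-codon gene whose *forward* protein is under
purifying selection while the reverse strand evolves freely — the
situation the tests are designed to recognise — then analyse them:

```bash
ambigram simulate --M 20 --N 300 --mu 0.01 --regime forward_purifying \
    --seed 11 -o rdrp_like.fasta
ambigram stats rdrp_like.fasta
```

```text
N    M   N_n  N_v  r       alpha    n1  n2  n3  z1        z2  z3
300  20  34   11   0.0025  6.18182  2   0   43  0.133333  0   2.86667
direction   N_sy  N_ns  N_mult  R    R_exp    R_over_R_exp  f_mult  dnds
forward     45    0     0       0    2.27856  0             0       0
complement  6     39    0       6.5  2.3958   2.71308       0       2.29369
```

Nearly all mutations sit at the third codon position (z3 = 2.87) and the
forward direction shows R/R_exp = 0, far below 1: the forward protein is
conserved. The complementary direction instead shows Nns/Nsy = 6.5,
*above* its non-coding expectation 2.40 — most forward-synonymous
changes alter the reverse protein, which no selection is protecting.

```bash
ambigram dsyn rdrp_like.fasta
```

```text
N    N_a  N_s  N_d  R        R0       R_over_R0
300  13   13   6    2.16667  1.83026  1.1838
```

At the 13 variable doubly synonymous loci, single synonyms outnumber
double synonyms by R = 2.17, close to the neutral expectation R0 = 1.83
(R/R0 = 1.18, roughly 1) — exactly what a non-coding reverse strand
looks like. Had the reverse strand been coding, R itself would be near
1 (simulate with `--regime dual_purifying` to see this).

Other subcommands: `ambigram table1` (the synonym/double-synonym table
of the genetic code), `ambigram hotspot` (the R_n/R_f test),
`ambigram dnds`, and `ambigram scan --min-len 200 --min-frac 0.9` to
screen contigs for ambigrammatic regions (BED-like TSV). Everything is
also available as a library (`ambigram.genetic_code`,
`ambigram.alignment_stats`, `ambigram.ambigram_tests`,
`ambigram.orf_scanner`, `ambigram.simulator`).

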