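# Methods

## Setting

An ambigrammatic gene is read in two frames at once: the forward frame
and the reverse complement with codon boundaries aligned (`revcomp_codon`
maps forward codon *i* of *N* to complementary-strand codon *N−i+1*; the
map is an involution). Only this aligned reverse frame matters: stops in
the other two complementary frames cannot in general be removed by
forward-synonymous substitutions, whereas in the aligned frame they
always can. The three forward codons whose aligned reverse complement is
a stop are UUA, CUA (Leu) and UCA (Ser); `stop_fixes` enumerates their
synonymous single-base escapes (UUA→UUG; CUA→CUU/CUG/CUC;
UCA→UCU/UCG/UCC).

The synonym profile of a codon counts its single-base neighbours that
are forward-synonymous, split into transitions S(n) and transversions
S(v), and the doubly synonymous subset D(n), D(v) (neighbours that also
preserve the complementary-strand amino acid). Neighbours whose reverse
complement is a stop are excluded throughout, because such codons cannot
occur inside an ambigrammatic gene. Note that this exclusion empties the
transition slot of UCG (its sole transition synonym is UCA, whose
reverse complement UGA is a stop), so UCG's profile is S = 0+2, D = 0+1;
published tabulations of these counts sometimes print S = 1+2 for UCG,
which is inconsistent with the exclusion rule applied in the sibling
rows (UUG, CUG, UCU). Twelve codons have D(n)+D(v) ≥ 1; they belong to
Leu, Pro, Gln, Arg and Ser, two per (amino acid, complementary amino
acid) pairing. The enumeration is cross-checked in the tests against an
independent Biopython-based neighbour walk.

## Alignment statistics

Input is M ≥ 2 equal-length sequences, trimmed to 3N nucleotides (a
frame offset is either supplied or chosen to minimise stop codons in
the parse; ties take the smallest offset). The consensus takes the
modal base per column, ties broken by the fixed order A<C<G<U for
determinism. Gap/ambiguity symbols never enter counts: a sequence
contributes nothing at a locus where its codon contains one, and f(k)
denominators remain M.

Nucleotide level: (n1, n2, n3) count every per-sequence mismatch from
the consensus by codon position; r = (n1+n2+n3)/(3NM). Nn and Nv count
(sequence, locus) pairs whose codon differs by exactly one base, split
transition/transversion, and alpha = 2·Nn/Nv estimates the Kimura
rate ratio (the factor 2 corrects for each site offering two
transversion targets but one transition target). alpha is reported as
undefined when Nv = 0 rather than raising.

Codon level: the variant set at locus k is the set of distinct
non-consensus codons observed there; n(k) is its size and f(k) the
fraction of sequences off-consensus. Nsy/Nns count single-base variants
by synonymy in the chosen direction, Nmult the 2–3-base variants, and
R = Nns/Nsy. The non-coding expectation R_exp weights each consensus
codon's 9 neighbours by alpha for transitions; mutations to a stop (in
the direction considered) count as non-synonymous, so the four
opportunity counts always sum to 9. R_exp is undefined (None) when the
synonymous opportunity sum is zero (e.g. a single-Met consensus).

Counting convention: n(k) and Nsy/Nns count *distinct* codons once,
matching the conservative "every mutation occurred only once"
treatment used for the ORF-wide dN/dS; a `per_occurrence` flag switches
to per-carrier counting. The two differ subtly away from the
low-divergence limit: synonymous changes concentrate on fewer target
codons (typically one third-position transition), so deduplication
deflates Nsy more than Nns and distinct-counted R runs ~10–20% above
R_exp even under strict neutrality at M = 50. The neutrality identity
E[Nns]/E[Nsy] = R_exp holds exactly for per-occurrence counting, which
is what the corresponding test uses.

ORF-wide dN/dS counts each distinct variant once, includes multi-base
variants (classified purely by amino-acid identity with the consensus),
and normalises the observed non-synonymous and synonymous counts by the
kappa-weighted single-base opportunity sums (default kappa = 2). With no
multi-base variants and kappa equal to alpha it reduces algebraically
to R/R_exp; the multi-base variants enter the numerators only, a
documented convention choice since no principled multi-base opportunity
normalisation exists at this level of model.

## The two reverse-ORF tests

A locus is doubly synonymous when its consensus codon is one of the
twelve double-synonym codons; there are N_ds of them.

Hotspot test: R_n and R_f compare the means of n(k) and f(k) over
doubly synonymous loci against the other loci. If the reverse strand
codes for protein, mutations concentrate where they can be doubly
synonymous and the ratios exceed 1; under the non-coding null they sit
near 1. No closed-form significance procedure is attached; an optional
label-permutation resample (shuffling the doubly-synonymous class
labels over loci) gives a reference interval for chance fluctuation.
This resampling is a convenience of this implementation, not part of
the original test formulation.

Double-synonym frequency test: over the set {k*} of doubly synonymous
loci with at least one variant (membership threshold `min_variants`,
default 1 — the natural reading of "loci where mutations are observed";
a stricter n(k) > 1 variant is available as an option), ns(k) counts
distinct single-base forward-synonymous variants whose reverse
complement is not a stop, and nd(k) the subset also synonymous on the
complementary strand; n(k) ≥ ns(k) ≥ nd(k) always. R = Ns/Nd from the
sums, compared with the null

    R0 = sum_{k in k*} [alpha·S_k(n) + S_k(v)]
       / sum_{k in k*} [alpha·D_k(n) + D_k(v)]

whose denominator is always positive because every double-synonym codon
has D(n)+D(v) ≥ 1. When Nd = 0 the result reports Ns and Nd but flags
R as not computable (exit code 3 on the CLI) — with few doubly
synonymous loci this is a real possibility and silently reporting 0 or
infinity would be misleading. alpha defaults to the same-alignment
estimate 2·Nn/Nv and can be overridden. An optional bootstrap resamples
the loci of {k*} (the natural unit, since R is a ratio of per-locus
sums) to attach a rough interval to R; like the hotspot permutation, it
is a convenience of this implementation.

## Scanner

`ambig_spans` parses a sequence from a frame offset and reports maximal
codon runs with no stop in either aligned frame (ambiguity codons break
runs). `scan` tries all three offsets in both orientations — the
property is strand-symmetric, so the reverse orientation rediscovers
the same spans in mirrored coordinates, reported on the forward strand —
and keeps at most one best (longest) span per record, subject to
span_length ≥ min_len (default 200 nt) and span/record-length fraction
≥ min_frac (default 0.90). The fraction is relative to the whole
record: the screen is designed to flag records that are ambigrammatic
over ~their whole length, not to locate ambigrammatic islands inside
long contigs (lower `--min-frac` for that). In uniform random sequence
each codon hits a stop in one of the two frames with probability
~6/64 per strand pair, so qualifying spans essentially never arise by
chance: the false-positive rate at defaults is 0 across the test
battery's random 2-kb contigs.

## Simulator

The simulator exists to give every statistic ground truth. M
descendants diverge independently from a common ancestor (star
phylogeny — appropriate because the statistics deliberately ignore
phylogenetic correlation; alignments with deep internal structure are
outside its scope). The ancestor is built from uniformly drawn sense
codons, repairing reverse-frame stops with a random synonymous fix, so
it is ambigrammatic by construction and roughly uniform in amino-acid
composition.

Each descendant receives Poisson(mu·3N) proposed single-base mutations:
site uniform, transition with probability kappa/(kappa+2), otherwise
one of the two transversions. Selection acts by proposal rejection —
`neutral` accepts everything; `forward_purifying` requires the forward
amino acid unchanged; `dual_purifying` requires both amino acids
unchanged (every accepted change is then a double synonym, so the
frequency test returns R = 1 identically). By default stop-creating
proposals are rejected in all regimes (`keep_ambigrammatic`), matching
real ambigrammatic samples, which carry no internal stops in either
direction. mu is therefore a *proposed* rate; the accepted rate is
lower under selection. Rejection sampling rather than rate rescaling is
exact for these acceptance rules and transparent at the low divergences
of interest. Every accepted mutation is logged (site, bases, class) and
replaying a log from the ancestor reproduces the descendant exactly.

Default study conditions (M = 50, N = 500, mu = 0.01, kappa = 2) mirror
a realistic sampled-virus scenario: tens of genomes, ~1,000-codon gene
scale, per-site divergence r ≈ 0.005–0.015, transition bias 2. Under
these conditions the validation battery shows: alpha recovery (the
true value lies inside the central 95% of the 200-replicate sampling
distribution — note the stop-rejection constraint imposes a small
upward bias, ~+0.03 at these settings, since transversions hit stop
codons slightly more often than transitions do); hotspot R_n within
[0.8, 1.2] in ≥90% of neutral replicates; dual-purifying R = 1 in every
replicate; forward-purifying forward R/R_exp < 0.5 and complementary
Nns/Nsy above R_exp in ≥95% of replicates.

## What the simulations do and do not show

The generator emulates low-divergence star-shaped polymorphism with
Kimura mutation and hard (accept/reject) selection. It does not model
phylogenetic structure, recombination, indels, codon-usage bias,
rate heterogeneity along the gene, or soft selection coefficients.
Passing tests therefore demonstrate that the statistics recover the
regimes that generated the data under these idealised conditions; on
real data the same statistics carry the usual caveats (shared ancestry
inflates apparent recurrence, and consensus error grows as divergence
rises). Degenerate inputs are handled explicitly: undefined ratios are
reported as None/NA rather than raised, except where a test's
preconditions are structurally unmet (no doubly synonymous locus at
all), which raises an input error.
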