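"""Consensus, variant sets, nucleotide- and codon-level statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambigram.alignment_stats import (
    AlignmentError,
    CodonAlignment,
    build_consensus,
    codon_stats,
    codon_variant_sets,
    dnds_orfwide,
    nucleotide_stats,
    opportunity_counts,
    select_frame,
)
from ambigram.genetic_code import (
    BASES,
    all_codons,
    mutation_class,
    translate,
)


class TestCodonAlignment:
    def test_trimming_to_codon_boundaries(self):
        aln = CodonAlignment(["AAUGGCUC", "AAUGGCUC"], frame_offset=2)
        assert aln.sequences == ["UGGCUC", "UGGCUC"]
        assert aln.N == 2

    def test_dna_normalized(self):
        aln = CodonAlignment(["ATGTTT", "ATGTTT"])
        assert aln.sequences[0] == "AUGUUU"

    def test_rejects_single_sequence(self):
        with pytest.raises(AlignmentError):
            CodonAlignment(["AUG"])

    def test_rejects_ragged(self):
        with pytest.raises(AlignmentError):
            CodonAlignment(["AUGAAA", "AUG"])


class TestConsensus:
    def test_identical_sequences(self):
        cons, counts = build_consensus(CodonAlignment(["AUGGCU"] * 3))
        assert cons == "AUGGCU"
        assert counts.sum() == 18

    def test_majority_per_column(self):
        aln = CodonAlignment(["ACU", "ACG", "GCU"])
        cons, _ = build_consensus(aln)
        assert cons == "ACU"

    def test_tie_breaks_alphabetically(self):
        cons, _ = build_consensus(CodonAlignment(["AAA", "GGG"]))
        assert cons == "AAA"

    def test_gap_only_column_is_an_error(self):
        with pytest.raises(AlignmentError, match="column 2"):
            build_consensus(CodonAlignment(["A-G", "A-G"]))

    def test_gaps_ignored_in_counts(self):
        cons, _ = build_consensus(CodonAlignment(["AUG", "A-G", "C-G"]))
        assert cons == "AUG"


class TestSelectFrame:
    def test_stop_free_frame_zero(self):
        assert select_frame("AUGGCU") == 0

    def test_avoids_stop_frames(self):
        # UAA at offset 0; offset 1 parse GCU,AAC is stop-free
        assert select_frame("UGCUAAC") == 1

    def test_tie_takes_smallest_offset(self):
        assert select_frame("AAAAAA") == 0

    def test_complement_direction_counts_reverse_stops(self):
        # UUA is fine forward (Leu) but its aligned reverse complement UAA
        # is a stop, so the complement criterion moves off frame 0
        assert select_frame("UUAUUA", direction="complement") != 0


class TestNucleotideStats:
    def test_identical_sequences(self):
        aln = CodonAlignment(["AUGGCU"] * 4)
        cons, _ = build_consensus(aln)
        s = nucleotide_stats(aln, cons)
        assert (s.N_n, s.N_v, s.r) == (0, 0, 0.0)
        assert s.alpha is None and s.z_by_pos is None

    def test_single_transition_at_position_three(self):
        # one U->C change at codon position 3 of the first codon
        aln = CodonAlignment(["AUCGGG", "AUUGGG", "AUUGGG"])
        cons, _ = build_consensus(aln)
        s = nucleotide_stats(aln, cons)
        assert (s.N_n, s.N_v) == (1, 0)
        assert s.n_by_pos == (0, 0, 1)
        assert s.z_by_pos == (0.0, 0.0, 3.0)
        assert s.alpha is None  # no transversions observed

    def test_multi_base_codon_counts_positions_not_single(self):
        # one sequence differs at 2 positions of the same codon
        aln = CodonAlignment(["AUG", "AUG", "GUC"])
        cons, _ = build_consensus(aln)
        s = nucleotide_stats(aln, cons)
        assert s.N_n + s.N_v == 0
        assert sum(s.n_by_pos) == 2

    def test_z_normalization(self, rng):
        seqs = ["".join(rng.choice(list(BASES), 30)) for _ in range(5)]
        aln = CodonAlignment(seqs)
        cons, _ = build_consensus(aln)
        s = nucleotide_stats(aln, cons)
        assert s.z_by_pos is not None
        assert sum(s.z_by_pos) == pytest.approx(3.0)


class TestVariantSets:
    def test_identical_sequences(self):
        aln = CodonAlignment(["AUGGCU"] * 3)
        cons, _ = build_consensus(aln)
        for vs in codon_variant_sets(aln, cons):
            assert vs.n == 0 and vs.f(aln.M) == 0.0

    def test_direct_count(self):
        # locus column {AGG x4, CGG x1, AGA x1}
        aln = CodonAlignment(["AGG"] * 4 + ["CGG", "AGA"])
        cons, _ = build_consensus(aln)
        (vs,) = codon_variant_sets(aln, cons)
        assert vs.consensus_codon == "AGG"
        assert {v.codon for v in vs.variants} == {"CGG", "AGA"}
        assert vs.n == 2
        assert vs.f(aln.M) == pytest.approx(2 / 6)

    def test_variant_classification(self, toy_alignment):
        cons, _ = build_consensus(toy_alignment)
        sets = codon_variant_sets(toy_alignment, cons)
        by_codon = {v.codon: v for v in sets[0].variants}
        assert by_codon["CGG"].syn_forward and by_codon["CGG"].syn_complement
        assert by_codon["AGA"].syn_forward and not by_codon["AGA"].syn_complement
        by_codon = {v.codon: v for v in sets[1].variants}
        assert by_codon["CAG"].syn_forward and by_codon["CAG"].syn_complement
        assert not by_codon["GAA"].syn_forward

    def test_ambiguous_codons_skipped_denominator_kept(self):
        aln = CodonAlignment(["AGG", "AGG", "ANG", "CGG"])
        cons, _ = build_consensus(aln)
        (vs,) = codon_variant_sets(aln, cons)
        assert {v.codon for v in vs.variants} == {"CGG"}
        assert vs.f(aln.M) == pytest.approx(1 / 4)


def _oracle_opportunities(codon: str, direction: str) -> tuple:
    """Independent neighbor enumeration using Biopython translation."""
    from Bio.Seq import Seq

    def aa(c):
        if direction == "forward":
            return str(Seq(c).translate())
        return str(Seq(c).reverse_complement_rna().translate())

    ref = aa(codon)
    s_n = s_v = n_n = n_v = 0
    for i in range(3):
        for b in "ACGU":
            if b == codon[i]:
                continue
            nb = codon[:i] + b + codon[i + 1:]
            ts = (codon[i], b) in {
                ("A", "G"), ("G", "A"), ("C", "U"), ("U", "C")
            }
            syn = aa(nb) == ref and ref != "*"
            if syn and ts:
                s_n += 1
            elif syn:
                s_v += 1
            elif ts:
                n_n += 1
            else:
                n_v += 1
    return s_n, s_v, n_n, n_v


class TestCodonStats:
    def test_opportunities_sum_to_nine(self):
        for c in all_codons():
            for d in ("forward", "complement"):
                assert sum(opportunity_counts(c, d)) == 9

    def test_opportunities_against_biopython_oracle(self):
        for c in all_codons()[::3]:
            for d in ("forward", "complement"):
                assert opportunity_counts(c, d) == _oracle_opportunities(c, d)

    def test_all_identical_alignment(self):
        aln = CodonAlignment(["AUGGCU"] * 3)
        cons, _ = build_consensus(aln)
        cs = codon_stats(aln, cons, "forward", alpha=2.0)
        assert (cs.N_sy, cs.N_ns, cs.N_mult) == (0, 0, 0)
        assert cs.R is None

    def test_r_exp_alpha_one_is_plain_neighbor_ratio(self, rng):
        codons = [c for c in all_codons() if translate(c) != "*"]
        cons = "".join(rng.choice(codons, 20))
        aln = CodonAlignment([cons, cons])
        cs = codon_stats(aln, cons, "forward", alpha=1.0)
        nonsyn = syn = 0
        for k in range(0, len(cons), 3):
            s_n, s_v, n_n, n_v = _oracle_opportunities(cons[k:k + 3], "forward")
            syn += s_n + s_v
            nonsyn += n_n + n_v
        assert cs.R_exp == pytest.approx(nonsyn / syn)

    def test_met_only_consensus_has_undefined_r_exp(self):
        aln = CodonAlignment(["AUG", "AUG"])
        cs = codon_stats(aln, "AUG", "forward", alpha=2.0)
        assert cs.R_exp is None

    def test_toy_counts(self, toy_alignment):
        cons, _ = build_consensus(toy_alignment)
        cs = codon_stats(toy_alignment, cons, "forward", alpha=2.0)
        # variants: CGG, AGA (syn), CAG (syn), GAA (non-syn); no multi
        assert (cs.N_sy, cs.N_ns, cs.N_mult) == (3, 1, 0)
        assert cs.R == pytest.approx(1 / 3)
        ccs = codon_stats(toy_alignment, cons, "complement", alpha=2.0)
        # complement-synonymous: CGG, CAG only
        assert (ccs.N_sy, ccs.N_ns) == (2, 2)

    def test_per_occurrence_counting(self, toy_alignment):
        cons, _ = build_consensus(toy_alignment)
        cs = codon_stats(
            toy_alignment, cons, "forward", alpha=2.0, per_occurrence=True
        )
        assert (cs.N_sy, cs.N_ns) == (3, 1)  # each variant carried once here


class TestDnds:
    def test_no_mutations_undefined(self):
        aln = CodonAlignment(["AUGGCU"] * 3)
        cons, _ = build_consensus(aln)
        assert dnds_orfwide(aln, cons, "forward") is None

    def test_pure_synonymous_gives_zero(self):
        aln = CodonAlignment(["GCU", "GCC", "GCA"])  # all Ala
        cons, _ = build_consensus(aln)
        assert dnds_orfwide(aln, cons, "forward") == 0.0

    def test_agrees_with_codon_stats_when_no_multi(self, toy_alignment):
        # with kappa = alpha and no multi-base variants, dN/dS reduces to
        # (Nns/Nsy) / R_exp
        cons, _ = build_consensus(toy_alignment)
        for direction in ("forward", "complement"):
            cs = codon_stats(toy_alignment, cons, direction, alpha=2.0)
            assert cs.N_mult == 0
            val = dnds_orfwide(toy_alignment, cons, direction, kappa=2.0)
            assert val == pytest.approx(cs.R / cs.R_exp)


@st.composite
def small_alignments(draw):
    sense = [c for c in all_codons() if translate(c) != "*"]
    n_loci = draw(st.integers(1, 8))
    m = draw(st.integers(2, 6))
    ancestor = "".join(
        draw(st.sampled_from(sense)) for _ in range(n_loci)
    )
    seqs = []
    for _ in range(m):
        seq = list(ancestor)
        for _ in range(draw(st.integers(0, 4))):
            pos = draw(st.integers(0, 3 * n_loci - 1))
            seq[pos] = draw(st.sampled_from("ACGU"))
        seqs.append("".join(seq))
    return CodonAlignment(seqs)


@settings(max_examples=60, derandomize=True)
@given(small_alignments())
def test_counting_consistency(aln):
    """Nn+Nv equals the single-base (sequence, locus) differences and
    Nsy+Nns the distinct single-base variant codons, on arbitrary inputs."""
    cons, _ = build_consensus(aln)
    s = nucleotide_stats(aln, cons)
    single = 0
    for seq in aln.sequences:
        for k in range(aln.N):
            diffs = sum(
                1 for i in range(3)
                if seq[3 * k + i] != cons[3 * k + i]
            )
            single += diffs == 1
    assert s.N_n + s.N_v == single
    vsets = codon_variant_sets(aln, cons)
    cs = codon_stats(aln, cons, "forward", alpha=2.0, variant_sets=vsets)
    distinct_single = sum(
        1 for vs in vsets for v in vs.variants
        if mutation_class(vs.consensus_codon, v.codon) != "multi"
    )
    assert cs.N_sy + cs.N_ns == distinct_single
    for vs in vsets:
        assert 0 <= vs.f(aln.M) <= 1
        assert vs.n == len({v.codon for v in vs.variants})
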