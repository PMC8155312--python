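"""Consensus construction and polymorphism statistics on codon alignments.

Input is a set of M codon-aligned sequences trimmed to 3N nucleotides.  A
consensus nucleotide is taken at each column (modal base, ties broken
A<C<G<U) and every statistic is a count of differences from the consensus:

* nucleotide level -- transition/transversion totals Nn and Nv, the
  per-site variable fraction ``r = (n1+n2+n3)/(3NM)`` and the
  transition/transversion rate-ratio estimate ``alpha = 2*Nn/Nv`` (a single
  site offers one transition but two transversions, hence the factor 2),
  plus the per-codon-position mutation counts (n1, n2, n3) and their
  normalisation (z1:z2:z3) summing to 3;

* codon level -- per-locus variant sets (distinct non-consensus codons),
  the synonymous/non-synonymous split of single-base variants in a chosen
  read direction, the ratio R = Nns/Nsy, and its expectation R_exp under
  the null hypothesis that the direction is non-coding, obtained by
  weighting each consensus codon's 9 single-base neighbours with the
  Kimura transition/transversion ratio alpha;

* an ORF-wide dN/dS that, unlike R, also includes multi-base variants,
  counting every distinct variant codon once (conservative against
  recombination re-exposing the same mutation in several sequences).

Directions: ``"forward"`` classifies synonymy on the forward amino acids,
``"complement"`` on the amino acids of the codon-aligned reverse
complements.  Loci are 1-based and always reported in forward-strand
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ambigram.genetic_code import (
    BASES,
    STOP,
    CodonError,
    mutation_class,
    neighbors,
    normalize,
    revcomp_codon,
    translate,
)

__all__ = [
    "CodonAlignment",
    "LocusVariantSet",
    "VariantCodon",
    "NucleotideStats",
    "CodonStats",
    "build_consensus",
    "select_frame",
    "nucleotide_stats",
    "codon_variant_sets",
    "codon_stats",
    "dnds_orfwide",
    "opportunity_counts",
]

logger = logging.getLogger(__name__)

_BASE_ORDER = {b: i for i, b in enumerate(BASES)}  # tie-break A<C<G<U

# byte -> base code (A=0, C=1, G=2, U=3; -1 for gap/ambiguity)
_CODES = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_ORDER.items():
    _CODES[ord(_b)] = _i
# transitions are the purine<->purine / pyrimidine<->pyrimidine swaps,
# i.e. |code difference| == 2 under the A,C,G,U encoding
_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignments."""


@dataclass
class CodonAlignment:
    """M codon-aligned nucleotide sequences of identical length 3N."""

    sequences: list[str]
    ids: list[str] | None = None
    direction: str = "forward"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentError("need at least 2 sequences")
        self.sequences = [normalize(s) for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.ids is None:
            self.ids = [f"seq{i + 1}" for i in range(len(self.sequences))]
        if not 0 <= self.frame_offset <= 2:
            raise AlignmentError("frame_offset must be 0, 1 or 2")
        if self.direction not in ("forward", "complement"):
            raise AlignmentError("direction must be 'forward' or 'complement'")
        # trim to codon boundaries: drop frame_offset leading bases + remainder
        if self.frame_offset or len(self.sequences[0]) % 3:
            n3 = 3 * ((len(self.sequences[0]) - self.frame_offset) // 3)
            self.sequences = [
                s[self.frame_offset: self.frame_offset + n3]
                for s in self.sequences
            ]
        if not self.sequences[0]:
            raise AlignmentError("alignment empty after trimming")
        self._codes: np.ndarray | None = None

    @property
    def M(self) -> int:
        return len(self.sequences)

    @property
    def N(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, seq_index: int, locus: int) -> str:
        """Codon of one sequence at a 1-based locus."""
        return self.sequences[seq_index][3 * (locus - 1): 3 * (locus - 1) + 3]

    def base_codes(self) -> np.ndarray:
        """M x 3N int8 matrix of base codes (A=0,C=1,G=2,U=3; -1 invalid)."""
        if self._codes is None:
            raw = np.frombuffer(
                "".join(self.sequences).encode("ascii"), dtype=np.uint8
            )
            self._codes = _CODES[raw].reshape(self.M, 3 * self.N)
        return self._codes


def build_consensus(aln: CodonAlignment) -> tuple[str, np.ndarray]:
    """Per-column modal-base consensus and the per-column base counts.

    Returns the consensus string and a 4 x 3N array of base counts per
    column (rows in A,C,G,U order).  Ties take the alphabetically first
    base.  Non-ACGU symbols (gaps, ambiguity codes) are not counted; a
    column with no valid base at all is an error naming the column.
    """
    codes = aln.base_codes()
    counts = np.stack([(codes == i).sum(axis=0) for i in range(4)])
    empty = np.flatnonzero(counts.sum(axis=0) == 0)
    if empty.size:
        raise AlignmentError(
            f"column {empty[0] + 1} has no unambiguous base"
        )
    consensus = "".join(BASES[i] for i in counts.argmax(axis=0))
    return consensus, counts


def select_frame(seq: str, direction: str = "forward") -> int:
    """Frame offset (0-2) whose codon parse has fewest stop codons.

    The complementary strand is read in the codon-aligned reverse frame of
    the chosen forward frame, so the same offset serves both directions.
    Ties take the smallest offset.
    """
    seq = normalize(seq)
    if len(seq) < 3:
        raise AlignmentError("sequence shorter than one codon")
    best_offset, best_stops = 0, None
    for offset in range(3):
        stops = 0
        for i in range(offset, len(seq) - 2, 3):
            c = seq[i: i + 3]
            try:
                fwd = translate(c)
            except CodonError:
                continue
            if fwd == STOP:
                stops += 1
            if direction == "complement" and translate(revcomp_codon(c)) == STOP:
                stops += 1
        if best_stops is None or stops < best_stops:
            best_offset, best_stops = offset, stops
    return best_offset


@dataclass
class NucleotideStats:
    """Nucleotide-level mutation summary of an alignment vs. its consensus."""

    N: int
    M: int
    N_n: int
    N_v: int
    r: float
    alpha: float | None
    n_by_pos: tuple[int, int, int]
    z_by_pos: tuple[float, float, float] | None


def nucleotide_stats(aln: CodonAlignment, consensus: str) -> NucleotideStats:
    """Transition/transversion totals and codon-position mutation spectrum.

    ``n_by_pos`` counts every nucleotide mismatch from the consensus at
    codon positions 1-3 (per sequence, including mismatches inside
    multi-base codon variants); ``N_n``/``N_v`` count (sequence, codon
    locus) pairs whose codon differs from the consensus codon by exactly
    one base, split by transition/transversion.  Codons containing a
    gap or ambiguity symbol are skipped.  ``alpha = 2*Nn/Nv`` is None
    when no transversions are observed.
    """
    codes = aln.base_codes()
    cons = _CODES[np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)]
    valid = (codes >= 0).reshape(aln.M, aln.N, 3).all(axis=2)
    mm = (codes != cons[None, :]).reshape(aln.M, aln.N, 3) & valid[:, :, None]
    n_pos = tuple(int(x) for x in mm.sum(axis=(0, 1)))
    single = mm.sum(axis=2) == 1                     # M x N
    # the one differing base of each single-base variant codon
    m_idx, k_idx, p_idx = np.nonzero(mm & single[:, :, None])
    site = 3 * k_idx + p_idx
    is_ts = np.abs(
        codes[m_idx, site].astype(np.int16) - cons[site].astype(np.int16)
    ) == 2
    N_n = int(is_ts.sum())
    N_v = int(len(is_ts) - N_n)
    total = sum(n_pos)
    r = total / (3 * aln.N * aln.M)
    alpha = 2 * N_n / N_v if N_v > 0 else None
    z = tuple(3 * n / total for n in n_pos) if total > 0 else None
    return NucleotideStats(
        N=aln.N, M=aln.M, N_n=N_n, N_v=N_v, r=r, alpha=alpha,
        n_by_pos=n_pos, z_by_pos=z,
    )


@dataclass(frozen=True)
class VariantCodon:
    """One distinct non-consensus codon observed at a locus."""

    codon: str
    count: int                 # sequences carrying it
    mclass: str                # transition/transversion/multi
    syn_forward: bool          # same forward amino acid as consensus
    syn_complement: bool       # same reverse-complement amino acid
    comp_stop: bool            # reverse complement is a stop codon


@lru_cache(maxsize=None)
def _classify(cons: str, cod: str) -> tuple[str, bool, bool, bool]:
    comp = revcomp_codon(cod)
    cons_aa = translate(cons)
    cons_comp_aa = translate(revcomp_codon(cons))
    return (
        mutation_class(cons, cod),
        translate(cod) == cons_aa and cons_aa != STOP,
        translate(comp) == cons_comp_aa and cons_comp_aa != STOP,
        translate(comp) == STOP,
    )


@dataclass
class LocusVariantSet:
    """Variant codons at one 1-based codon locus."""

    locus: int
    consensus_codon: str
    variants: list[VariantCodon] = field(default_factory=list)
    non_consensus: int = 0     # sequences not carrying the consensus codon

    @property
    def n(self) -> int:
        """Number of distinct variant codons, n(k)."""
        return len(self.variants)

    def f(self, M: int) -> float:
        """Fraction of the M sequences not carrying the consensus, f(k)."""
        return self.non_consensus / M


def codon_variant_sets(
    aln: CodonAlignment, consensus: str
) -> list[LocusVariantSet]:
    """Enumerate the distinct non-consensus codons at every locus.

    A sequence whose codon contains a gap or ambiguity symbol contributes
    nothing at that locus (logged); the f(k) denominator remains M.
    """
    codes = aln.base_codes()
    cods = codes.reshape(aln.M, aln.N, 3)
    valid = (cods >= 0).all(axis=2)
    # codon ids 0..63 (invalid codons get id -1)
    ids = np.where(
        valid, cods[:, :, 0] * 16 + cods[:, :, 1] * 4 + cods[:, :, 2], -1
    ).astype(np.int16)
    cons_codes = _CODES[np.frombuffer(consensus.encode("ascii"),
                                      dtype=np.uint8)].reshape(aln.N, 3)
    cons_ids = cons_codes[:, 0] * 16 + cons_codes[:, 1] * 4 + cons_codes[:, 2]
    out = []
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("%d codons skipped (gap/ambiguity)", n_skipped)
    for k in range(aln.N):
        col = ids[:, k]
        observed, cnts = np.unique(col[col >= 0], return_counts=True)
        cons = _CODONS[cons_ids[k]]
        variants = []
        non_consensus = 0
        for cid, cnt in zip(observed, cnts):
            if cid == cons_ids[k]:
                continue
            non_consensus += int(cnt)
            cod = _CODONS[cid]
            mclass, syn_f, syn_c, comp_stop = _classify(cons, cod)
            variants.append(VariantCodon(
                codon=cod, count=int(cnt), mclass=mclass,
                syn_forward=syn_f, syn_complement=syn_c, comp_stop=comp_stop,
            ))
        out.append(LocusVariantSet(
            locus=k + 1, consensus_codon=cons, variants=variants,
            non_consensus=non_consensus,
        ))
    return out


def _syn_in_direction(v: VariantCodon, direction: str) -> bool:
    return v.syn_forward if direction == "forward" else v.syn_complement


@lru_cache(maxsize=None)
def opportunity_counts(codon: str, direction: str) -> tuple[int, int, int, int]:
    """Synonymous/non-synonymous single-base opportunities of a codon.

    Returns (s_n, s_v, n_n, n_v): counts of the 9 single-base neighbours
    that are synonymous / non-synonymous in the given direction, split into
    transitions and transversions.  Mutations to a stop codon (in the
    direction considered) count as non-synonymous, so the four numbers
    always sum to 9.
    """
    if direction == "forward":
        ref_aa = translate(codon)
        aa_of = translate
    else:
        ref_aa = translate(revcomp_codon(codon))
        aa_of = lambda c: translate(revcomp_codon(c))  # noqa: E731
    s_n = s_v = n_n = n_v = 0
    for nb in neighbors(codon):
        ts = mutation_class(codon, nb) == "transition"
        syn = aa_of(nb) == ref_aa and ref_aa != STOP
        if syn and ts:
            s_n += 1
        elif syn:
            s_v += 1
        elif ts:
            n_n += 1
        else:
            n_v += 1
    return s_n, s_v, n_n, n_v


@dataclass
class CodonStats:
    """Codon-level mutation summary for one read direction."""

    direction: str
    N_sy: int
    N_ns: int
    N_mult: int
    R: float | None
    R_exp: float | None
    f_mult: float
    dnds: float | None = None


def codon_stats(
    aln: CodonAlignment,
    consensus: str,
    direction: str = "forward",
    alpha: float = 2.0,
    variant_sets: list[LocusVariantSet] | None = None,
    per_occurrence: bool = False,
) -> CodonStats:
    """Synonymous/non-synonymous variant counts and the null ratio R_exp.

    ``N_sy``/``N_ns`` count single-base variant codons by synonymy in
    ``direction``; ``N_mult`` counts variants with 2-3 bases changed.  By
    default each distinct variant codon counts once per locus; with
    ``per_occurrence`` each carrier sequence counts.  ``R = N_ns/N_sy``
    (None when N_sy = 0).  ``R_exp`` is the non-coding expectation
    ``sum_k[alpha*n_k(n)+n_k(v)] / sum_k[alpha*s_k(n)+s_k(v)]`` over the N
    consensus codons (None when the synonymous opportunity sum is 0).
    """
    if variant_sets is None:
        variant_sets = codon_variant_sets(aln, consensus)
    N_sy = N_ns = N_mult = 0
    for vs in variant_sets:
        for v in vs.variants:
            w = v.count if per_occurrence else 1
            if v.mclass == "multi":
                N_mult += w
            elif _syn_in_direction(v, direction):
                N_sy += w
            else:
                N_ns += w
    syn_opp = nonsyn_opp = 0.0
    for vs in variant_sets:
        s_n, s_v, n_n, n_v = opportunity_counts(vs.consensus_codon, direction)
        syn_opp += alpha * s_n + s_v
        nonsyn_opp += alpha * n_n + n_v
    return CodonStats(
        direction=direction,
        N_sy=N_sy,
        N_ns=N_ns,
        N_mult=N_mult,
        R=N_ns / N_sy if N_sy > 0 else None,
        R_exp=nonsyn_opp / syn_opp if syn_opp > 0 else None,
        f_mult=N_mult / aln.N,
    )


def dnds_orfwide(
    aln: CodonAlignment,
    consensus: str,
    direction: str = "forward",
    kappa: float = 2.0,
    variant_sets: list[LocusVariantSet] | None = None,
) -> float | None:
    """ORF-wide dN/dS, counting each distinct variant codon once.

    Conservative convention for data where recombination may re-expose the
    same mutation in several sequences: every mutation in the alignment is
    assumed to have occurred only once.  Multi-base variants are included
    and classified purely by amino-acid identity with the consensus in the
    stated direction.  Observed non-synonymous and synonymous counts are
    normalised by the kappa-weighted single-base opportunity sums; returns
    None when either the synonymous opportunity or the observed synonymous
    count is zero.
    """
    if variant_sets is None:
        variant_sets = codon_variant_sets(aln, consensus)
    n_obs = s_obs = 0
    for vs in variant_sets:
        for v in vs.variants:
            if _syn_in_direction(v, direction):
                s_obs += 1
            else:
                n_obs += 1
    syn_opp = nonsyn_opp = 0.0
    for vs in variant_sets:
        s_n, s_v, n_n, n_v = opportunity_counts(vs.consensus_codon, direction)
        syn_opp += kappa * s_n + s_v
        nonsyn_opp += kappa * n_n + n_v
    if syn_opp == 0 or nonsyn_opp == 0 or s_obs == 0:
        return None
    return (n_obs / nonsyn_opp) / (s_obs / syn_opp)
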