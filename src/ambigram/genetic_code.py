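"""Codon algebra of the standard genetic code in the ambigrammatic setting.

An *ambigrammatic* gene carries an open reading frame on both the forward
strand and the codon-aligned reverse complement.  Every forward codon then
pairs with a complementary-strand codon read in the opposite direction, and
single-nucleotide substitutions can be classified by their effect on *both*
encoded amino acids.  A *double synonym* is a single-base substitution that
is synonymous in the forward frame and whose aligned reverse complement is
also synonymous.

All codons are handled internally as RNA (``T`` is normalized to ``U`` at
ingestion).  Only the standard genetic code is supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data.CodonTable import unambiguous_rna_by_id

__all__ = [
    "STOP",
    "BASES",
    "SynonymProfile",
    "normalize",
    "revcomp_codon",
    "translate",
    "mutation_class",
    "synonym_profile",
    "double_synonym_codons",
    "double_synonym_pairs",
    "stop_fixes",
    "all_codons",
    "neighbors",
]

STOP = "*"
BASES = "ACGU"

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "U", "U": "C"}

_TABLE = unambiguous_rna_by_id[1]  # the standard genetic code

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    STOP: "STOP",
}


class CodonError(ValueError):
    """Raised for malformed codons or domain violations."""


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA ``T`` to RNA ``U``."""
    return seq.upper().replace("T", "U")


def _check(codon: str) -> str:
    codon = normalize(codon)
    if len(codon) != 3 or any(b not in _COMPLEMENT for b in codon):
        raise CodonError(f"invalid codon {codon!r}: need 3 bases from ACGU/T")
    return codon


def all_codons() -> list[str]:
    """The 64 RNA codons in lexicographic (A<C<G<U) order."""
    return ["".join(p) for p in product(BASES, repeat=3)]


def revcomp_codon(codon: str) -> str:
    """Aligned-frame reverse complement of a codon.

    Reversing the read direction and taking the pairing complement maps a
    forward codon onto the complementary-strand codon occupying the same
    aligned position.  The operation is an involution.
    """
    codon = _check(codon)
    return "".join(_COMPLEMENT[b] for b in reversed(codon))


def translate(codon: str) -> str:
    """One-letter amino acid for a codon, ``'*'`` for a stop codon."""
    codon = _check(codon)
    if codon in _TABLE.stop_codons:
        return STOP
    return _TABLE.forward_table[codon]


def aa3(aa: str) -> str:
    """Three-letter name for a one-letter amino acid code (``'*'`` -> STOP)."""
    return _AA3[aa]


def mutation_class(a: str, b: str) -> str:
    """Classify the change between two codons.

    Returns ``"identity"``, ``"transition"`` (one base differs, A<->G or
    C<->U), ``"transversion"`` (one base differs otherwise) or ``"multi"``
    (2-3 bases differ).
    """
    a, b = _check(a), _check(b)
    diffs = [(x, y) for x, y in zip(a, b) if x != y]
    if not diffs:
        return "identity"
    if len(diffs) > 1:
        return "multi"
    x, y = diffs[0]
    return "transition" if _TRANSITION_PARTNER[x] == y else "transversion"


def neighbors(codon: str) -> list[str]:
    """The 9 codons reachable by a single-base substitution."""
    codon = _check(codon)
    out = []
    for i, base in enumerate(codon):
        for alt in BASES:
            if alt != base:
                out.append(codon[:i] + alt + codon[i + 1:])
    return out


@dataclass(frozen=True)
class SynonymProfile:
    """Single/double synonym counts for one codon of an ambigrammatic gene.

    ``s_n``/``s_v`` count the single-base synonymous mutations (transitions /
    transversions) excluding mutations to codons whose aligned reverse
    complement is a stop; ``d_n``/``d_v`` count the subset that also preserve
    the complementary-strand amino acid (double synonyms).  Double synonyms
    are included in the single-synonym counts, so ``d_n <= s_n`` and
    ``d_v <= s_v``.
    """

    codon: str
    aa: str
    comp_aa: str
    s_n: int
    s_v: int
    d_n: int
    d_v: int

    @property
    def is_double(self) -> bool:
        return self.d_n + self.d_v >= 1


@lru_cache(maxsize=None)
def synonym_profile(codon: str) -> SynonymProfile:
    """Enumerate single and double synonyms of a codon.

    The codon must be a sense codon whose aligned reverse complement is also
    a sense codon (codons violating either condition cannot occur inside an
    ambigrammatic gene).
    """
    codon = _check(codon)
    aa = translate(codon)
    if aa == STOP:
        raise CodonError(f"{codon} is a stop codon")
    comp_aa = translate(revcomp_codon(codon))
    if comp_aa == STOP:
        raise CodonError(f"reverse complement of {codon} is a stop codon")
    s_n = s_v = d_n = d_v = 0
    for nb in neighbors(codon):
        if translate(nb) != aa:
            continue
        if translate(revcomp_codon(nb)) == STOP:
            continue  # would break ambigrammaticity; excluded
        is_transition = mutation_class(codon, nb) == "transition"
        if is_transition:
            s_n += 1
        else:
            s_v += 1
        if translate(revcomp_codon(nb)) == comp_aa:
            if is_transition:
                d_n += 1
            else:
                d_v += 1
    return SynonymProfile(codon, aa, comp_aa, s_n, s_v, d_n, d_v)


@lru_cache(maxsize=1)
def double_synonym_codons() -> frozenset[str]:
    """The codons admitting at least one doubly synonymous substitution.

    There are exactly twelve in the standard genetic code, drawn from Leu,
    Pro, Gln, Arg and Ser.
    """
    out = set()
    for codon in all_codons():
        if translate(codon) == STOP or translate(revcomp_codon(codon)) == STOP:
            continue
        if synonym_profile(codon).is_double:
            out.add(codon)
    return frozenset(out)


def double_synonym_pairs() -> set[frozenset[str]]:
    """All unordered codon pairs related by a doubly synonymous substitution."""
    pairs = set()
    for c in double_synonym_codons():
        prof = synonym_profile(c)
        for nb in neighbors(c):
            if (
                translate(nb) == prof.aa
                and translate(revcomp_codon(nb)) == prof.comp_aa
            ):
                pairs.add(frozenset((c, nb)))
    return pairs


def stop_fixes(codon: str) -> set[str]:
    """Synonymous single-base escapes from a complementary-strand stop.

    For a codon whose aligned reverse complement is a stop (UUA, CUA or
    UCA), return every single-base neighbor that codes the same forward
    amino acid and whose reverse complement is not a stop.  Every
    complementary-strand stop is removable this way, which is what makes an
    ambigrammatic version of any gene reachable by synonymous evolution.
    """
    codon = _check(codon)
    if translate(revcomp_codon(codon)) != STOP:
        raise CodonError(f"reverse complement of {codon} is not a stop codon")
    aa = translate(codon)
    fixes = {
        nb
        for nb in neighbors(codon)
        if translate(nb) == aa and translate(revcomp_codon(nb)) != STOP
    }
    assert fixes, "every complementary-strand stop admits a synonymous fix"
    return fixes


def table1_rows() -> list[dict]:
    """Synonym-profile table for all codons that can carry double synonyms.

    One row per sense codon of the amino acids admitting double synonyms
    (Leu, Pro, Gln, Arg, Ser) whose reverse complement is not a stop, in
    the conventional order.
    """
    ds_aas = sorted(
        {synonym_profile(c).aa for c in double_synonym_codons()},
        key="LPQRS".index,
    )
    order = {
        "L": ["UUG", "CUU", "CUC", "CUG"],
        "P": ["CCU", "CCC", "CCA", "CCG"],
        "Q": ["CAA", "CAG"],
        "R": ["CGU", "CGC", "CGA", "CGG", "AGA", "AGG"],
        "S": ["UCU", "UCC", "UCG", "AGU", "AGC"],
    }
    rows = []
    for aa in ds_aas:
        for codon in order[aa]:
            p = synonym_profile(codon)
            rows.append(
                {
                    "aa": aa3(p.aa),
                    "codon": p.codon,
                    "double_synonym": p.is_double,
                    "s_n": p.s_n,
                    "s_v": p.s_v,
                    "d_n": p.d_n,
                    "d_v": p.d_v,
                    "comp_aa": aa3(p.comp_aa),
                }
            )
    return rows
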