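"""Sequence-evolution simulator with known selection regimes.

Generates codon alignments whose ground truth is known, so the
polymorphism statistics and the reverse-ORF tests can be validated:
M descendants diverge independently from a common ambigrammatic ancestor
(a star phylogeny -- the statistics treat every mutation as having
occurred once, so phylogenetic correlation is deliberately absent).
Mutations follow the Kimura two-parameter process: a proposed change picks
a site uniformly, then a transition with probability kappa/(kappa+2) or
one of the two transversions otherwise.  Selection acts by
proposal rejection:

* ``neutral`` -- every proposal accepted;
* ``forward_purifying`` -- accepted only if the forward amino acid is
  unchanged (a strongly conserved forward protein, the RdRp situation);
* ``dual_purifying`` -- accepted only if both the forward and the
  aligned reverse-complement amino acids are unchanged (a protein on each
  strand; every accepted change is then a double synonym).

By default proposals creating a stop codon in either aligned frame are
rejected in all regimes (``keep_ambigrammatic``), matching the empirical
observation that sampled ambigrammatic genomes carry no internal stops.
``mu`` is the expected number of *proposed* substitutions per site per
lineage; the accepted rate is lower under selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ambigram.alignment_stats import CodonAlignment
from ambigram.genetic_code import (
    STOP,
    all_codons,
    revcomp_codon,
    stop_fixes,
    translate,
)

__all__ = ["SimulationConfig", "SimulatedAlignment", "random_ambigram", "evolve"]

REGIMES = ("neutral", "forward_purifying", "dual_purifying")

_TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}
_TRANSVERSIONS = {
    b: tuple(x for x in "ACGU" if x != b and x != _TRANSITION[b])
    for b in "ACGU"
}
_SENSE = [c for c in all_codons() if translate(c) != STOP]


@dataclass
class SimulationConfig:
    M: int = 50
    N: int = 500
    mu: float = 0.01
    kappa: float = 2.0
    regime: str = "neutral"
    keep_ambigrammatic: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.M < 2 or self.N < 1 or self.mu < 0 or self.kappa <= 0:
            raise ValueError("need M >= 2, N >= 1, mu >= 0, kappa > 0")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")


@dataclass
class MutationEvent:
    """One accepted substitution in one lineage."""

    site: int        # 0-based nucleotide position
    from_base: str
    to_base: str
    mclass: str      # transition | transversion

    @property
    def locus(self) -> int:
        """1-based codon locus."""
        return self.site // 3 + 1


@dataclass
class SimulatedAlignment:
    """A star-phylogeny alignment plus its full mutation history."""

    ancestor: str
    sequences: list[str]
    config: SimulationConfig
    logs: list[list[MutationEvent]] = field(default_factory=list)

    def as_alignment(self) -> CodonAlignment:
        ids = [f"sim{i + 1}" for i in range(len(self.sequences))]
        return CodonAlignment(sequences=list(self.sequences), ids=ids)

    def replay(self, index: int) -> str:
        """Rebuild descendant ``index`` from the ancestor and its log."""
        seq = list(self.ancestor)
        for ev in self.logs[index]:
            assert seq[ev.site] == ev.from_base
            seq[ev.site] = ev.to_base
        return "".join(seq)


def random_ambigram(
    N: int, seed: int | np.random.Generator | None = None
) -> str:
    """A random 3N-nt sequence with no stop codon in either aligned frame.

    Sense codons are drawn uniformly; any codon whose aligned reverse
    complement is a stop is repaired by a random synonymous single-base
    fix, which always exists (every complementary-strand stop is removable
    by a forward-synonymous substitution).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    codons = []
    for idx in rng.integers(0, len(_SENSE), size=N):
        codon = _SENSE[idx]
        if translate(revcomp_codon(codon)) == STOP:
            fixes = sorted(stop_fixes(codon))
            codon = fixes[rng.integers(0, len(fixes))]
        codons.append(codon)
    return "".join(codons)


def _acceptable(
    old_codon: str, new_codon: str, regime: str, keep_ambigrammatic: bool
) -> bool:
    new_aa = translate(new_codon)
    new_comp_aa = translate(revcomp_codon(new_codon))
    if keep_ambigrammatic and (new_aa == STOP or new_comp_aa == STOP):
        return False
    if regime == "neutral":
        return True
    if new_aa != translate(old_codon):
        return False
    if regime == "forward_purifying":
        return True
    return new_comp_aa == translate(revcomp_codon(old_codon))


def evolve(config: SimulationConfig) -> SimulatedAlignment:
    """Evolve M descendants from a common random ambigrammatic ancestor.

    Each descendant receives Poisson(mu * 3N) proposed single-base
    mutations; proposals are accepted or rejected according to the regime
    (see module docstring).  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = 3 * config.N
    ancestor = random_ambigram(config.N, rng)
    p_transition = config.kappa / (config.kappa + 2.0)
    sequences: list[str] = []
    logs: list[list[MutationEvent]] = []
    for _ in range(config.M):
        seq = list(ancestor)
        log: list[MutationEvent] = []
        n_proposals = rng.poisson(config.mu * L)
        for _ in range(n_proposals):
            site = int(rng.integers(0, L))
            base = seq[site]
            if rng.random() < p_transition:
                new_base, mclass = _TRANSITION[base], "transition"
            else:
                new_base = _TRANSVERSIONS[base][rng.integers(0, 2)]
                mclass = "transversion"
            k0 = 3 * (site // 3)
            old_codon = "".join(seq[k0: k0 + 3])
            pos = site - k0
            new_codon = old_codon[:pos] + new_base + old_codon[pos + 1:]
            if _acceptable(
                old_codon, new_codon, config.regime, config.keep_ambigrammatic
            ):
                seq[site] = new_base
                log.append(MutationEvent(site, base, new_base, mclass))
        sequences.append("".join(seq))
        logs.append(log)
    return SimulatedAlignment(
        ancestor=ancestor, sequences=sequences, config=config, logs=logs
    )
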