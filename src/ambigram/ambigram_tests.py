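"""Two polymorphism tests for whether a reverse ORF codes for a protein.

If the complementary strand of an ambigrammatic gene codes for a functional
protein, the only assuredly non-deleterious mutations are the doubly
synonymous ones.  Two signatures follow, each testable on a codon alignment:

1. *Mutational hotspots*: loci whose consensus codon admits a double
   synonym should accumulate more variants than other loci.  The test
   compares the mean variant-set size <n(k)> and mean non-consensus
   fraction <f(k)> between the two locus classes; ratios R_n and R_f near
   1 are consistent with a non-coding reverse strand.

2. *Mutation frequencies*: at variable doubly synonymous loci, observed
   forward-synonymous mutations should be overwhelmingly the doubly
   synonymous ones.  The test computes R = Ns/Nd (single synonyms over
   double synonyms) and compares it with the value R0 expected when the
   reverse strand is non-coding and mutations follow a Kimura
   two-parameter process with transition/transversion ratio alpha.  R near
   1 indicates reverse-strand coding; R near R0 indicates non-coding.

Neither test comes with a closed-form significance procedure; an optional
nonparametric resample (bootstrap over the variable doubly synonymous loci
for R, permutation of the locus-class labels for R_n/R_f) is provided for
rough intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ambigram.alignment_stats import LocusVariantSet
from ambigram.genetic_code import double_synonym_codons, synonym_profile

__all__ = [
    "HotspotResult",
    "DsynResult",
    "ds_loci",
    "hotspot_test",
    "null_ratio_r0",
    "dsyn_test",
]


class AmbigramTestError(ValueError):
    """Raised when a test's preconditions are not met."""


def _consensus_codons(consensus: str) -> list[str]:
    if len(consensus) % 3:
        raise AmbigramTestError("consensus length not divisible by 3")
    return [consensus[i: i + 3] for i in range(0, len(consensus), 3)]


def ds_loci(consensus: str) -> set[int]:
    """1-based loci whose consensus codon admits a double synonym."""
    ds = double_synonym_codons()
    return {
        k + 1
        for k, cod in enumerate(_consensus_codons(consensus))
        if cod in ds
    }


@dataclass
class HotspotResult:
    """Outcome of the mutational-hotspot test."""

    N: int
    N_ds: int
    mean_n_ds: float
    mean_n_other: float
    mean_f_ds: float
    mean_f_other: float
    R_n: float | None
    R_f: float | None
    R_n_interval: tuple[float, float] | None = None
    R_f_interval: tuple[float, float] | None = None


def hotspot_test(
    variant_sets: list[LocusVariantSet],
    consensus: str,
    M: int,
    n_resamples: int = 0,
    rng: np.random.Generator | None = None,
) -> HotspotResult:
    """Compare variant abundance at doubly synonymous vs. other loci.

    Computes class means of n(k) (distinct variants) and f(k)
    (non-consensus fraction) and their ratios R_n and R_f.  Large ratios
    are evidence that the complementary strand is coding; the non-coding
    null expects ratios close to 1.  With ``n_resamples`` > 0, central 95%
    intervals of the ratios under random permutation of the locus-class
    labels are attached (a plain label-permutation reference, useful for
    judging whether an observed ratio is within chance fluctuation).
    """
    loci_ds = ds_loci(consensus)
    if not loci_ds or len(loci_ds) == len(variant_sets):
        raise AmbigramTestError(
            "hotspot test needs at least one doubly synonymous locus "
            "and at least one other locus"
        )
    n = np.array([vs.n for vs in variant_sets], dtype=float)
    f = np.array([vs.f(M) for vs in variant_sets], dtype=float)
    is_ds = np.array([vs.locus in loci_ds for vs in variant_sets])

    def ratio(x: np.ndarray, mask: np.ndarray) -> float | None:
        denom = x[~mask].mean()
        return float(x[mask].mean() / denom) if denom > 0 else None

    res = HotspotResult(
        N=len(variant_sets),
        N_ds=int(is_ds.sum()),
        mean_n_ds=float(n[is_ds].mean()),
        mean_n_other=float(n[~is_ds].mean()),
        mean_f_ds=float(f[is_ds].mean()),
        mean_f_other=float(f[~is_ds].mean()),
        R_n=ratio(n, is_ds),
        R_f=ratio(f, is_ds),
    )
    if n_resamples > 0:
        rng = rng or np.random.default_rng()
        rn, rf = [], []
        for _ in range(n_resamples):
            perm = rng.permutation(is_ds)
            r1, r2 = ratio(n, perm), ratio(f, perm)
            if r1 is not None:
                rn.append(r1)
            if r2 is not None:
                rf.append(r2)
        if rn:
            res.R_n_interval = tuple(np.quantile(rn, [0.025, 0.975]))
        if rf:
            res.R_f_interval = tuple(np.quantile(rf, [0.025, 0.975]))
    return res


def null_ratio_r0(
    consensus: str, variable_ds_loci: set[int], alpha: float
) -> float:
    """Non-coding expectation R0 of the single/double synonym ratio.

    For the consensus codons at the variable doubly synonymous loci {k*},
    sums the transition/transversion-split single-synonym counts S(n), S(v)
    and double-synonym counts D(n), D(v) of each codon, weighting
    transitions by the Kimura rate ratio alpha:

        R0 = sum_k [alpha*S_k(n) + S_k(v)] / sum_k [alpha*D_k(n) + D_k(v)]
    """
    if not variable_ds_loci:
        raise AmbigramTestError("no variable doubly synonymous loci")
    codons = _consensus_codons(consensus)
    ds = double_synonym_codons()
    num = den = 0.0
    for k in variable_ds_loci:
        cod = codons[k - 1]
        if cod not in ds:
            raise AmbigramTestError(
                f"locus {k} consensus {cod} is not a double-synonym codon"
            )
        p = synonym_profile(cod)
        num += alpha * p.s_n + p.s_v
        den += alpha * p.d_n + p.d_v
    # every double-synonym codon has d_n + d_v >= 1, so den > 0
    assert den > 0
    return num / den


@dataclass
class DsynResult:
    """Outcome of the doubly-synonymous mutation-frequency test."""

    N: int
    N_a: int                       # variable doubly synonymous loci
    N_s: int                       # single-synonym variants summed over {k*}
    N_d: int                       # doubly synonymous subset
    R: float | None                # Ns/Nd; None when Nd = 0
    R0: float | None
    R_over_R0: float | None
    alpha: float | None = None
    R_interval: tuple[float, float] | None = None


def dsyn_test(
    variant_sets: list[LocusVariantSet],
    consensus: str,
    alpha: float,
    min_variants: int = 1,
    per_occurrence: bool = False,
    n_resamples: int = 0,
    rng: np.random.Generator | None = None,
) -> DsynResult:
    """Single vs. double synonym frequencies at variable double-synonym loci.

    {k*} is the set of doubly synonymous loci with at least ``min_variants``
    distinct variant codons.  At each, ns(k) counts the distinct
    single-base variants that are synonymous in the forward direction
    (and whose reverse complement is not a stop) and nd(k) the subset also
    synonymous on the complementary strand; n(k) >= ns(k) >= nd(k).  The
    sums give R = Ns/Nd, compared against the Kimura null R0.  R close to
    1 indicates reverse-strand coding; R close to R0 is consistent with a
    non-coding reverse strand.  When Nd = 0 the ratio is not computable
    and is reported as None.  With ``n_resamples`` > 0 a bootstrap over
    the loci of {k*} attaches a central 95% interval for R.
    """
    loci_ds = ds_loci(consensus)
    per_locus: dict[int, tuple[int, int]] = {}
    for vs in variant_sets:
        if vs.locus not in loci_ds or vs.n < min_variants or vs.n == 0:
            continue
        ns = nd = 0
        for v in vs.variants:
            if v.mclass == "multi" or not v.syn_forward or v.comp_stop:
                continue
            w = v.count if per_occurrence else 1
            ns += w
            if v.syn_complement:
                nd += w
        per_locus[vs.locus] = (ns, nd)
    if not per_locus:
        raise AmbigramTestError("no variable doubly synonymous loci")
    N_s = sum(ns for ns, _ in per_locus.values())
    N_d = sum(nd for _, nd in per_locus.values())
    r0 = null_ratio_r0(consensus, set(per_locus), alpha)
    res = DsynResult(
        N=len(variant_sets),
        N_a=len(per_locus),
        N_s=N_s,
        N_d=N_d,
        R=N_s / N_d if N_d > 0 else None,
        R0=r0,
        R_over_R0=(N_s / N_d) / r0 if N_d > 0 else None,
        alpha=alpha,
    )
    if n_resamples > 0:
        rng = rng or np.random.default_rng()
        pairs = np.array(list(per_locus.values()), dtype=float)
        ratios = []
        for _ in range(n_resamples):
            idx = rng.integers(0, len(pairs), len(pairs))
            ns, nd = pairs[idx].sum(axis=0)
            if nd > 0:
                ratios.append(ns / nd)
        if ratios:
            res.R_interval = tuple(np.quantile(ratios, [0.025, 0.975]))
    return res
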