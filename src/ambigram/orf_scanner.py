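"""Scan nucleotide sequences for ambigrammatic regions.

A region is ambigrammatic when its codon parse is free of stop codons in
both the forward frame and the codon-aligned reverse-complement frame.
Genuinely ambigrammatic genes (narnavirus RdRp and Robin segments) are
ambigrammatic over essentially their whole length, whereas in random
sequence the per-codon probability of hitting a stop in either frame is
roughly 6/64, so long stop-free runs are exponentially rare.  Screening
therefore uses a minimum span length together with a minimum fraction of
the record covered by the span.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from ambigram.genetic_code import (
    STOP,
    normalize,
    revcomp_codon,
    translate,
)

__all__ = ["AmbigramHit", "ambig_spans", "scan"]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _revcomp_seq(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


@dataclass(frozen=True)
class AmbigramHit:
    """A maximal stop-free run in both aligned frames of one record."""

    seq_id: str
    frame_offset: int
    start: int                 # 1-based inclusive, forward coordinates
    end: int                   # 1-based inclusive
    strand: str = "+"
    stop_positions_outside: tuple[int, ...] = ()   # codon starts, 1-based

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def ambig_fraction(self, seq_length: int) -> float:
        return self.span_length / seq_length


@lru_cache(maxsize=None)
def _codon_ok(codon: str) -> bool:
    if any(b not in _COMPLEMENT for b in codon):
        return False
    return translate(codon) != STOP and translate(revcomp_codon(codon)) != STOP


def ambig_spans(
    seq: str, frame_offset: int = 0, seq_id: str = "seq", strand: str = "+"
) -> list[AmbigramHit]:
    """Maximal runs of codons stop-free in both aligned frames.

    The sequence is parsed into codons from ``frame_offset``; runs are
    maximal stretches where neither the forward codon nor its aligned
    reverse complement is a stop (codons with ambiguity symbols also break
    runs).  Hits are returned longest first; each records the codon-start
    positions of the stop/break codons outside its span.
    """
    seq = normalize(seq)
    if len(seq) < 3:
        return []
    starts = list(range(frame_offset, len(seq) - 2, 3))
    ok = [_codon_ok(seq[i: i + 3]) for i in starts]
    bad_positions = tuple(starts[j] + 1 for j, good in enumerate(ok) if not good)
    hits = []
    run_start = None
    for j, good in enumerate(ok + [False]):
        if good and run_start is None:
            run_start = j
        elif not good and run_start is not None:
            hits.append(AmbigramHit(
                seq_id=seq_id,
                frame_offset=frame_offset,
                start=starts[run_start] + 1,
                end=starts[j - 1] + 3,
                strand=strand,
                stop_positions_outside=bad_positions,
            ))
            run_start = None
    hits.sort(key=lambda h: (-h.span_length, h.start))
    return hits


def _mirror(hit: AmbigramHit, seq_length: int) -> AmbigramHit:
    """Map a hit found on the reverse complement back to forward coordinates."""
    return AmbigramHit(
        seq_id=hit.seq_id,
        frame_offset=hit.frame_offset,
        start=seq_length - hit.end + 1,
        end=seq_length - hit.start + 1,
        strand="-",
        stop_positions_outside=tuple(
            sorted(seq_length - p - 2 + 1 for p in hit.stop_positions_outside)
        ),
    )


def scan(
    records: Iterable[tuple[str, str]],
    min_len: int = 200,
    min_frac: float = 0.90,
) -> list[AmbigramHit]:
    """Screen records for ambigrammatic regions.

    For each record all three frame offsets are tried in both orientations
    and the largest span kept (ambigrammaticity is strand-symmetric, so
    the reverse orientation can only rediscover the same span in mirrored
    coordinates; forward-strand coordinates are reported).  A record
    yields at most one hit, and only if the best span is at least
    ``min_len`` nucleotides long and covers at least ``min_frac`` of the
    record.  Defaults follow the screening convention for Robin-like
    segments: spans over 200 nt covering at least 90% of the record.
    """
    hits = []
    for seq_id, seq in records:
        seq = normalize(seq)
        if len(seq) < 3:
            continue
        candidates = []
        for offset in range(3):
            candidates.extend(ambig_spans(seq, offset, seq_id, "+")[:1])
            candidates.extend(
                _mirror(h, len(seq))
                for h in ambig_spans(_revcomp_seq(seq), offset, seq_id, "-")[:1]
            )
        if not candidates:
            continue
        candidates.sort(
            key=lambda h: (-h.span_length, h.strand, h.frame_offset, h.start)
        )
        best = candidates[0]
        if (
            best.span_length >= min_len
            and best.ambig_fraction(len(seq)) >= min_frac
        ):
            hits.append(best)
    return hits
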