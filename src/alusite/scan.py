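"""Exhaustive strand-aware scanning of a genome for guide target sites.

A *site* is an exact protospacer match immediately followed 3' (on the hit
strand) by a PAM match. Coordinates of the hit are the protospacer interval
on the forward genomic coordinate system, 0-based half-open; minus-strand
hits therefore have their PAM on the forward coordinates immediately 5' of
``start``. Overlapping occurrences are all reported and ``N`` in the genome
matches nothing.

Matching is exact (no mismatch tolerance): the statistic of interest is a
census of consensus binding sites, not an off-target model. The PAM is
required by default for a position to count as a site; pass
``require_pam=False`` to census bare protospacer matches instead.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import IUPAC_CODES, GenomeSequence, GuideSpec

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over ``ACGTN``."""
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (e.g. ``NGG`` -> ``CCN``)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def pattern_matches(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position.

    Only concrete A/C/G/T in ``seq`` can match; ``N`` in the sequence is
    matched by no code.
    """
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq, pattern):
        if base not in IUPAC_CODES[code]:
            return False
    return True


@dataclass(frozen=True, order=True)
class SiteHit:
    """One genomic occurrence of a guide target site.

    ``[start, end)`` is the protospacer interval on forward coordinates;
    for a ``-`` strand hit the genomic sequence of the interval is the
    reverse complement of the protospacer.
    """

    contig: str
    start: int
    end: int
    strand: str
    guide_name: str


def _forward_occurrences(seq: str, sub: str) -> Iterable[int]:
    """All (overlapping) start offsets of ``sub`` in ``seq``."""
    i = seq.find(sub)
    while i != -1:
        yield i
        i = seq.find(sub, i + 1)


def find_guide_sites(
    genome: GenomeSequence, guide: GuideSpec, require_pam: bool = True
) -> list[SiteHit]:
    """Every position on both strands where the protospacer matches exactly
    and (if ``require_pam``) the adjacent 3' PAM matches its IUPAC pattern.

    Returns hits sorted by ``(contig, start, strand)``; deterministic for
    identical inputs. An empty result is valid.
    """
    proto = guide.protospacer
    pam = guide.pam
    L, P = len(proto), len(pam)
    rc_proto = reverse_complement(proto)
    rc_pam = reverse_complement_pattern(pam)
    hits: list[SiteHit] = []
    for contig, seq in genome.contigs.items():
        n = len(seq)
        # + strand: protospacer at [s, s+L), PAM at [s+L, s+L+P)
        for s in _forward_occurrences(seq, proto):
            if require_pam:
                if s + L + P > n or not pattern_matches(seq[s + L : s + L + P], pam):
                    continue
            hits.append(SiteHit(contig, s, s + L, "+", guide.name))
        # - strand: rc(protospacer) at [s, s+L) on forward coords, PAM
        # (reverse-complemented pattern) at [s-P, s)
        for s in _forward_occurrences(seq, rc_proto):
            if require_pam:
                if s - P < 0 or not pattern_matches(seq[s - P : s], rc_pam):
                    continue
            hits.append(SiteHit(contig, s, s + L, "-", guide.name))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def genome_site_count(
    genome: GenomeSequence, guide: GuideSpec, require_pam: bool = True
) -> int:
    """Genome-wide census: number of guide target sites on both strands."""
    return len(find_guide_sites(genome, guide, require_pam=require_pam))


def _check_sorted(hits: list[SiteHit]) -> None:
    for a, b in zip(hits, hits[1:]):
        if (a.contig, a.start, a.strand) > (b.contig, b.start, b.strand):
            raise ValueError(
                "hits must be sorted by (contig, start, strand); "
                "use find_guide_sites output or sort first"
            )


def sites_in_interval(
    hits: list[SiteHit], contig: str, start: int, end: int
) -> int:
    """Count hits whose protospacer START lies in ``[start, end)`` on
    ``contig``. Both strands count; overlapping occurrences each count.

    ``hits`` must be sorted by ``(contig, start, strand)``.
    """
    if start >= end:
        raise ValueError(f"interval must satisfy start < end, got [{start}, {end})")
    _check_sorted(hits)
    key = lambda h: (h.contig, h.start)
    lo = bisect_left(hits, (contig, start), key=key)
    hi = bisect_left(hits, (contig, end), key=key)
    return hi - lo


class SiteIndex:
    """Per-contig sorted arrays of hit intervals for bulk window queries.

    Built once from a sorted hit list; used by the density and peak-overlap
    stages to avoid rescanning per gene or per peak.
    """

    def __init__(self, hits: list[SiteHit]):
        by_contig: dict[str, list[SiteHit]] = {}
        for h in hits:
            by_contig.setdefault(h.contig, []).append(h)
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.prefix_max_end: dict[str, np.ndarray] = {}
        for contig, chunk in by_contig.items():
            chunk.sort(key=lambda h: (h.start, h.end))
            starts = np.array([h.start for h in chunk], dtype=np.int64)
            ends = np.array([h.end for h in chunk], dtype=np.int64)
            self.starts[contig] = starts
            self.ends[contig] = ends
            self.prefix_max_end[contig] = np.maximum.accumulate(ends)

    def count_starts_in(self, contig: str, start: int, end: int) -> int:
        """Hits with protospacer start in ``[start, end)``."""
        starts = self.starts.get(contig)
        if starts is None:
            return 0
        return int(np.searchsorted(starts, end, side="left")
                   - np.searchsorted(starts, start, side="left"))

    def any_overlap(self, contig: str, start: int, end: int) -> bool:
        """True if any hit interval intersects ``[start, end)`` by >= 1 bp."""
        starts = self.starts.get(contig)
        if starts is None or len(starts) == 0:
            return False
        k = int(np.searchsorted(starts, end, side="left"))
        if k == 0:
            return False
        return bool(self.prefix_max_end[contig][k - 1] > start)

    def any_contained(self, contig: str, start: int, end: int) -> bool:
        """True if any hit interval lies fully within ``[start, end)``."""
        starts = self.starts.get(contig)
        if starts is None or len(starts) == 0:
            return False
        lo = int(np.searchsorted(starts, start, side="left"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return False
        return bool(np.any(self.ends[contig][lo:hi] <= end))


def write_bed(hits: Iterable[SiteHit], path: str | Path) -> None:
    """Export hits as BED6 (name = guide name, score 0, strand column used)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{h.guide_name}\t0\t{h.strand}\n")
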