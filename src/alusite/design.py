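"""Protospacer tiling against a motif consensus or promoter window.

Enumerates every candidate protospacer of a requested length whose 3' end
abuts a PAM match, on both strands of a query sequence (e.g. a 36-bp motif
consensus), and reports the PAM-proximal nucleotide composition. Guide
efficacy depends strongly on the bases nearest the PAM; candidates are
scored by counting PAM-proximal positions carrying bases listed in a
user-supplied disfavoured-base table. No default table ships: the rule set
is configuration, and an empty table scores every candidate 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from .scan import pattern_matches, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GuideCandidate:
    """One tiling candidate.

    ``offset`` is the 0-based start of the protospacer interval in the
    query's forward coordinates (same convention as genomic hits);
    ``sequence`` is the protospacer in its own 5'->3' orientation, so for a
    ``-`` candidate it is the reverse complement of the query slice.
    ``pam_proximal`` is the k-mer of the protospacer nearest the PAM
    (position 1 = base adjacent to the PAM = last base of ``sequence``).
    """

    sequence: str
    offset: int
    strand: str
    pam_observed: str
    pam_proximal: str
    disfavored_count: int = 0


def enumerate_protospacers(
    query: str,
    guide_len: int = 14,
    pam: str = "NGG",
    k: int = 4,
    disfavored_table: Mapping[int, Iterable[str]] | None = None,
) -> list[GuideCandidate]:
    """All guide candidates of ``guide_len`` nt with an adjacent 3' PAM on
    either strand of ``query``, sorted by offset then strand.

    Returns an empty list (with a warning) when the query is shorter than
    guide + PAM. If ``disfavored_table`` is given, each candidate's
    ``disfavored_count`` is filled in.
    """
    if guide_len < 10:
        raise ValueError("guide_len must be >= 10")
    query = query.upper()
    P = len(pam)
    if len(query) < guide_len + P:
        logger.warning(
            "query of %d nt is shorter than guide (%d) + PAM (%d); no candidates",
            len(query), guide_len, P,
        )
        return []
    if k > guide_len:
        raise ValueError("k must be <= guide length")
    candidates: list[GuideCandidate] = []
    for o in range(len(query) - guide_len + 1):
        window = query[o : o + guide_len]
        if "N" in window:
            continue
        # + strand: PAM immediately 3' on the query
        pam_fwd = query[o + guide_len : o + guide_len + P]
        if len(pam_fwd) == P and pattern_matches(pam_fwd, pam):
            candidates.append(
                GuideCandidate(
                    sequence=window,
                    offset=o,
                    strand="+",
                    pam_observed=pam_fwd,
                    pam_proximal=window[-k:],
                )
            )
        # - strand: protospacer is rc(window); its 3' PAM sits at
        # [o - P, o) on the forward query coordinates
        if o - P >= 0:
            pam_slice = query[o - P : o]
            if "N" not in pam_slice and pattern_matches(
                reverse_complement(pam_slice), pam
            ):
                seq = reverse_complement(window)
                candidates.append(
                    GuideCandidate(
                        sequence=seq,
                        offset=o,
                        strand="-",
                        pam_observed=reverse_complement(pam_slice),
                        pam_proximal=seq[-k:],
                    )
                )
    candidates.sort(key=lambda c: (c.offset, c.strand))
    if disfavored_table is not None:
        candidates = [
            replace(c, disfavored_count=pam_proximal_report(c, disfavored_table, k))
            for c in candidates
        ]
    return candidates


def pam_proximal_report(
    candidate: GuideCandidate,
    disfavored_table: Mapping[int, Iterable[str]],
    k: int = 4,
) -> int:
    """Number of PAM-proximal positions i <= k whose base is disfavoured.

    ``disfavored_table`` maps position (1 = adjacent to PAM) to a set of
    disfavoured bases; an empty table yields 0.
    """
    if k > len(candidate.sequence):
        raise ValueError("k must be <= guide length")
    bad = {int(pos): frozenset(bases) for pos, bases in disfavored_table.items()}
    for pos in bad:
        if not 1 <= pos <= k:
            raise ValueError(f"disfavored table positions must be in 1..{k}, got {pos}")
    count = 0
    for i in range(1, k + 1):
        base = candidate.sequence[-i]
        if base in bad.get(i, frozenset()):
            count += 1
    return count


def rank_candidates(candidates: Iterable[GuideCandidate]) -> list[GuideCandidate]:
    """Sort by ascending disfavoured count, ties broken by offset."""
    return sorted(candidates, key=lambda c: (c.disfavored_count, c.offset, c.strand))


def write_candidates(candidates: Iterable[GuideCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sequence\toffset\tstrand\tpam_observed\tpam_proximal\tdisfavored_count\n"
        )
        for c in candidates:
            fh.write(
                f"{c.sequence}\t{c.offset}\t{c.strand}\t{c.pam_observed}\t"
                f"{c.pam_proximal}\t{c.disfavored_count}\n"
            )
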