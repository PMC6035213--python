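"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-position scanning, quadratic
interval intersection, exhaustive subset enumeration, closed-form t) and
shares no code with the package's own routines.
"""

from __future__ import annotations

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _pam_ok(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[c] for b, c in zip(seq, pattern)
    )


def brute_force_sites(contigs: dict[str, str], protospacer: str, pam: str,
                      require_pam: bool = True):
    """Every protospacer+PAM occurrence, testing each offset on each strand
    independently. Returns tuples (contig, start, end, strand) sorted."""
    L, P = len(protospacer), len(pam)
    out = []
    for name, seq in contigs.items():
        for s in range(len(seq) - L + 1):
            window = seq[s : s + L]
            if window == protospacer:
                if not require_pam or (
                    s + L + P <= len(seq) and _pam_ok(seq[s + L : s + L + P], pam)
                ):
                    out.append((name, s, s + L, "+"))
            if rc(window) == protospacer:
                if not require_pam or (
                    s - P >= 0 and _pam_ok(rc(seq[s - P : s]), pam)
                ):
                    out.append((name, s, s + L, "-"))
    return sorted(out)


def brute_force_candidates(query: str, guide_len: int, pam: str):
    """Protospacer tiling oracle on a single query string; returns tuples
    (offset, strand, sequence, pam_observed) sorted by (offset, strand)."""
    out = []
    q = query.upper()
    L, P = guide_len, len(pam)
    for o in range(len(q) - L + 1):
        window = q[o : o + L]
        if "N" in window:
            continue
        if o + L + P <= len(q) and _pam_ok(q[o + L : o + L + P], pam):
            out.append((o, "+", window, q[o + L : o + L + P]))
        if o - P >= 0 and "N" not in q[o - P : o] and _pam_ok(rc(q[o - P : o]), pam):
            out.append((o, "-", rc(window), rc(q[o - P : o])))
    return sorted(out, key=lambda c: (c[0], c[1]))


def count_starts_in_window(hits, contig: str, start: int, end: int) -> int:
    """Naive filter over a hit list (objects with .contig/.start)."""
    return sum(1 for h in hits if h.contig == contig and start <= h.start < end)


def exact_subset_p(densities, n: int, observed_mean: float) -> float:
    """Exact upper-tail p by enumerating all size-n subsets of the pool."""
    total = 0
    exceed = 0
    for combo in itertools.combinations(densities, n):
        total += 1
        if sum(combo) / n >= observed_mean:
            exceed += 1
    return exceed / total


def quadratic_overlap_fraction(peaks, hits) -> float:
    """Fraction of peaks intersecting >= 1 hit, checking every pair."""
    n_with = 0
    for p in peaks:
        if any(
            h.contig == p.contig and h.start < p.end and h.end > p.start
            for h in hits
        ):
            n_with += 1
    return n_with / len(peaks)


def pooled_t_by_hand(xs, ys):
    """Classical pooled two-sample t statistic and df, from the textbook
    formula (ys minus xs)."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    t = (my - mx) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, nx + ny - 2
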