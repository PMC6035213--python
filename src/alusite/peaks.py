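"""Fraction of peaks containing a guide site, and a two-group comparison.

For each sample, the statistic is the fraction of its peaks whose interval
intersects at least one guide-site protospacer interval by >= 1 bp on the
same contig (``mode="any"``; ``mode="full"`` instead requires an entire
protospacer inside the peak). Each peak counts at most once no matter how
many sites it contains.

Control and treated groups of per-sample fractions are compared with a
classical pooled-variance two-sample two-tailed Student's t-test
(``method="welch"`` switches to Welch). Fractions are compared
untransformed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import PeakRecord
from .scan import SiteHit, SiteIndex, _check_sorted

logger = logging.getLogger(__name__)


def sample_overlap_fraction(
    peaks: Sequence[PeakRecord],
    hits: list[SiteHit],
    mode: str = "any",
) -> float:
    """Fraction of ``peaks`` overlapping >= 1 guide site.

    ``hits`` must be sorted (scanner output). Invariant to peak and hit
    order; duplicated peak records do not change the value.
    """
    if not peaks:
        raise ValueError("peak list must be non-empty")
    if mode not in ("any", "full"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    _check_sorted(hits)
    index = SiteIndex(hits)
    if mode == "any":
        n_with = sum(index.any_overlap(p.contig, p.start, p.end) for p in peaks)
    else:
        n_with = sum(index.any_contained(p.contig, p.start, p.end) for p in peaks)
    return n_with / len(peaks)


@dataclass(frozen=True)
class OverlapComparison:
    """Two-group comparison of per-sample overlap fractions."""

    per_sample_fraction: dict[str, float]
    group_assignment: dict[str, str]
    mean_control: float
    mean_treated: float
    t_statistic: float
    p_value: float
    method: str = "student"
    p_flag: str | None = None

    @property
    def n_control(self) -> int:
        return sum(1 for g in self.group_assignment.values() if g == "control")

    @property
    def n_treated(self) -> int:
        return sum(1 for g in self.group_assignment.values() if g == "treated")

    def to_dict(self) -> dict:
        d = {
            "per_sample_fraction": dict(self.per_sample_fraction),
            "per_sample_percent": {
                k: 100.0 * v for k, v in self.per_sample_fraction.items()
            },
            "group_assignment": dict(self.group_assignment),
            "mean_control": self.mean_control,
            "mean_treated": self.mean_treated,
            "mean_control_percent": 100.0 * self.mean_control,
            "mean_treated_percent": 100.0 * self.mean_treated,
            "n_control": self.n_control,
            "n_treated": self.n_treated,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "method": self.method,
        }
        if self.p_flag:
            d["p_flag"] = self.p_flag
        return d

    def summary(self) -> str:
        lines = [
            "Peak / guide-site overlap comparison",
            "=" * 38,
            f"Control:  n = {self.n_control}, mean = {100 * self.mean_control:.2f}% "
            "of peaks with >= 1 site",
            f"Treated:  n = {self.n_treated}, mean = {100 * self.mean_treated:.2f}% "
            "of peaks with >= 1 site",
            f"t ({self.method}, two-tailed) = {self.t_statistic:.3f}",
            f"p = {self.p_value:.4g}" + (f"  [{self.p_flag}]" if self.p_flag else ""),
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def compare_groups(
    fractions_control: Sequence[float],
    fractions_treated: Sequence[float],
    control_ids: Sequence[str] | None = None,
    treated_ids: Sequence[str] | None = None,
    method: str = "student",
) -> OverlapComparison:
    """Pooled-variance two-sample two-tailed Student's t-test on per-sample
    overlap fractions (``method="welch"`` for unequal variances).

    t is signed as treated minus control. Degenerate cases: zero pooled
    variance with equal means gives t = 0, p = 1; zero pooled variance with
    unequal means is reported as p below machine precision with a flag.
    """
    c = np.asarray(fractions_control, dtype=float)
    t = np.asarray(fractions_treated, dtype=float)
    if len(c) < 2 or len(t) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    if method not in ("student", "welch"):
        raise ValueError(f"unknown method {method!r}")
    if control_ids is None:
        control_ids = [f"control_{i + 1}" for i in range(len(c))]
    if treated_ids is None:
        treated_ids = [f"treated_{i + 1}" for i in range(len(t))]
    fractions = {**dict(zip(control_ids, c)), **dict(zip(treated_ids, t))}
    groups = {**{k: "control" for k in control_ids},
              **{k: "treated" for k in treated_ids}}
    mean_c, mean_t = float(c.mean()), float(t.mean())
    flag = None
    if c.var(ddof=1) == 0.0 and t.var(ddof=1) == 0.0:
        if mean_c == mean_t:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = float("inf") if mean_t > mean_c else float("-inf")
            p = 0.0
            flag = "p below machine precision (zero within-group variance)"
    else:
        res = stats.ttest_ind(t, c, equal_var=(method == "student"))
        t_stat, p = float(res.statistic), float(res.pvalue)
    return OverlapComparison(
        per_sample_fraction={k: float(v) for k, v in fractions.items()},
        group_assignment=groups,
        mean_control=mean_c,
        mean_treated=mean_t,
        t_statistic=t_stat,
        p_value=p,
        method=method,
        p_flag=flag,
    )


class PeakOverlap:
    """Model object: per-sample peak sets scored against a guide-site list.

    Parameters
    ----------
    peaks_by_sample
        Mapping sample_id -> list of :class:`~alusite.io.PeakRecord`.
    hits
        Sorted guide-site list for the same genome.
    groups
        Mapping sample_id -> ``"control"`` or ``"treated"``.
    mode
        Overlap rule, ``"any"`` (>= 1 bp intersection, default) or
        ``"full"`` (whole protospacer inside the peak).

    ``fit()`` returns an :class:`OverlapComparison`.
    """

    def __init__(
        self,
        peaks_by_sample: Mapping[str, Sequence[PeakRecord]],
        hits: list[SiteHit],
        groups: Mapping[str, str],
        mode: str = "any",
    ):
        missing = set(peaks_by_sample) - set(groups)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        bad = {g for g in groups.values()} - {"control", "treated"}
        if bad:
            raise ValueError(f"groups must be control/treated, got {sorted(bad)}")
        self.peaks_by_sample = {k: list(v) for k, v in peaks_by_sample.items()}
        self.groups = dict(groups)
        self.hits = hits
        self.mode = mode

    def fractions(self) -> dict[str, float]:
        return {
            sid: sample_overlap_fraction(peaks, self.hits, mode=self.mode)
            for sid, peaks in self.peaks_by_sample.items()
        }

    def fit(self, method: str = "student") -> OverlapComparison:
        fr = self.fractions()
        ctrl = [(sid, f) for sid, f in fr.items() if self.groups[sid] == "control"]
        trt = [(sid, f) for sid, f in fr.items() if self.groups[sid] == "treated"]
        logger.info(
            "peak overlap: %d control and %d treated samples", len(ctrl), len(trt)
        )
        return compare_groups(
            [f for _, f in ctrl],
            [f for _, f in trt],
            control_ids=[sid for sid, _ in ctrl],
            treated_ids=[sid for sid, _ in trt],
            method=method,
        )
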