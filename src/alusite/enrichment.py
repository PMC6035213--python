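"""TSS-anchored upstream-window site density and its Monte Carlo null.

The statistic: for each gene, count guide target sites whose protospacer
start falls in a window anchored on the transcription start site — by
default 10 kb upstream to 1 kb downstream, strand-aware — and divide by the
window's effective width in kb (windows are clipped at contig boundaries).
A gene set's statistic is the unweighted arithmetic mean of its per-gene
densities (an aggregate total-sites/total-kb variant is available via
``statistic="aggregate"``).

Significance is assessed against a Monte Carlo resampling null: per-gene
densities are precomputed once for the whole gene pool; each permutation
draws ``n_genes`` genes uniformly without replacement from the pool and
records the mean of their precomputed densities. The one-sided upper-tail
empirical p-value is ``exceed_count / n_perm`` where ``exceed_count`` is
the number of permutation means >= the observed mean. With zero
exceedances the result is flagged ``p < 1/n_perm``; a +1-corrected
estimator ``(exceed_count+1)/(n_perm+1)`` is available via
``estimator="plus_one"``.

Genes whose clipped window is shorter than ``min_effective_kb`` (default
1 kb) are excluded from both observed sets and the pool, with a logged
count, to avoid extreme density inflation at contig edges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GeneRecord, GenomeSequence
from .scan import SiteHit, SiteIndex, _check_sorted

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """TSS-anchored analysis window, in kb upstream/downstream of the TSS
    along the gene's own orientation."""

    upstream_kb: float = 10.0
    downstream_kb: float = 1.0

    def __post_init__(self) -> None:
        if self.upstream_kb < 0 or self.downstream_kb < 0:
            raise ValueError("window extents must be >= 0")
        if self.upstream_kb + self.downstream_kb <= 0:
            raise ValueError("window must have positive total width")

    @property
    def span_bp(self) -> int:
        return int(round((self.upstream_kb + self.downstream_kb) * 1000))

    def to_dict(self) -> dict:
        return {"upstream_kb": self.upstream_kb, "downstream_kb": self.downstream_kb}


def upstream_window(
    gene: GeneRecord, spec: WindowSpec, contig_length: int
) -> tuple[int, int, float]:
    """Forward-coordinate window ``[start, end)`` for a gene and its
    effective width in kb after clipping to ``[0, contig_length)``.

    For a ``+`` gene the window is ``[tss - up, tss + down)``; for a ``-``
    gene it mirrors to ``[tss - down, tss + up)``.
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be > 0")
    up = int(round(spec.upstream_kb * 1000))
    down = int(round(spec.downstream_kb * 1000))
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    start = max(start, 0)
    end = min(end, contig_length)
    effective_kb = max(end - start, 0) / 1000.0
    return start, end, effective_kb


def gene_density(
    hits: list[SiteHit],
    gene: GeneRecord,
    spec: WindowSpec,
    genome: GenomeSequence,
) -> float:
    """Site density (sites per kb) in the gene's TSS window.

    Raises
    ------
    ValueError
        If the clipped window is degenerate (width 0); such genes are
        excluded upstream with a warning rather than scored.
    """
    _check_sorted(hits)
    index = SiteIndex(hits)
    return _gene_density_indexed(index, gene, spec, genome)


def _gene_density_indexed(
    index: SiteIndex, gene: GeneRecord, spec: WindowSpec, genome: GenomeSequence
) -> float:
    start, end, eff_kb = upstream_window(gene, spec, genome.length_of(gene.contig))
    if eff_kb == 0:
        raise ValueError(
            f"gene {gene.gene_id}: window degenerate after clipping; exclude it"
        )
    return index.count_starts_in(gene.contig, start, end) / eff_kb


@dataclass(frozen=True)
class DensityResult:
    """Observed per-gene densities (sites/kb) for a gene set and their
    unweighted mean."""

    set_id: str
    n_genes: int
    per_gene_density: tuple[float, ...]
    mean_density: float

    def __post_init__(self) -> None:
        if self.n_genes != len(self.per_gene_density):
            raise ValueError("n_genes must equal len(per_gene_density)")
        if any(d < 0 for d in self.per_gene_density):
            raise ValueError("densities must be >= 0")

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "n_genes": self.n_genes,
            "mean_density": self.mean_density,
            "per_gene_density": list(self.per_gene_density),
        }


def set_mean_density(
    genes: Sequence[GeneRecord],
    hits: list[SiteHit],
    spec: WindowSpec,
    genome: GenomeSequence,
    set_id: str = "set",
    min_effective_kb: float = 1.0,
) -> DensityResult:
    """Per-gene densities (in input order) and their unweighted mean.

    Genes whose clipped window is shorter than ``min_effective_kb`` are
    excluded with a logged count.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    _check_sorted(hits)
    index = SiteIndex(hits)
    kept, densities = _pool_densities(index, genes, spec, genome, min_effective_kb)
    if len(kept) < len(genes):
        logger.warning(
            "set %s: excluded %d/%d genes with window < %.2f kb",
            set_id, len(genes) - len(kept), len(genes), min_effective_kb,
        )
    if not kept:
        raise ValueError(f"set {set_id}: no genes left after window clipping")
    return DensityResult(
        set_id=set_id,
        n_genes=len(kept),
        per_gene_density=tuple(float(d) for d in densities),
        mean_density=float(np.mean(densities)),
    )


def _pool_densities(
    index: SiteIndex,
    genes: Sequence[GeneRecord],
    spec: WindowSpec,
    genome: GenomeSequence,
    min_effective_kb: float,
) -> tuple[list[GeneRecord], np.ndarray]:
    """Counts/widths for each usable gene; returns (kept genes, densities)."""
    kept: list[GeneRecord] = []
    dens: list[float] = []
    for gene in genes:
        start, end, eff_kb = upstream_window(
            gene, spec, genome.length_of(gene.contig)
        )
        if eff_kb < min_effective_kb:
            continue
        kept.append(gene)
        dens.append(index.count_starts_in(gene.contig, start, end) / eff_kb)
    return kept, np.asarray(dens, dtype=float)


@dataclass(frozen=True)
class MCEnrichmentResult:
    """Monte Carlo enrichment test summary.

    ``p_value = exceed_count / n_perm`` (one-sided upper tail); when
    ``exceed_count == 0`` the estimate is a bound and ``p_flag`` says so.
    """

    set_id: str
    observed_mean: float
    n_genes: int
    pool_size: int
    n_perm: int
    exceed_count: int
    p_value: float
    seed: int
    window: WindowSpec
    statistic: str = "per_gene_mean"
    estimator: str = "plain"
    p_flag: str | None = None
    null_mean: float = float("nan")
    null_sd: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "set_id": self.set_id,
            "observed_mean": self.observed_mean,
            "n_genes": self.n_genes,
            "pool_size": self.pool_size,
            "n_perm": self.n_perm,
            "exceed_count": self.exceed_count,
            "p_value": self.p_value,
            "seed": self.seed,
            "window": self.window.to_dict(),
            "statistic": self.statistic,
            "estimator": self.estimator,
        }
        if self.p_flag:
            d["p_flag"] = self.p_flag
        return d

    def summary(self) -> str:
        lines = [
            "Guide-site upstream-window enrichment (Monte Carlo)",
            "=" * 51,
            f"Gene set:            {self.set_id} (n = {self.n_genes})",
            f"Pool size:           {self.pool_size}",
            f"Window:              -{self.window.upstream_kb:g} kb / "
            f"+{self.window.downstream_kb:g} kb around TSS",
            f"Statistic:           {self.statistic}",
            f"Observed mean:       {self.observed_mean:.4f} sites/kb",
            f"Null mean (MC):      {self.null_mean:.4f} sites/kb",
            f"Permutations:        {self.n_perm}",
            f"Exceedances:         {self.exceed_count}",
            f"p-value (upper):     {self.p_value:.3g}"
            + (f"  [{self.p_flag}]" if self.p_flag else ""),
            f"Seed:                {self.seed}",
        ]
        return "\n".join(lines)


def _permutation_means(
    densities: np.ndarray,
    widths_kb: np.ndarray | None,
    n_genes: int,
    n_perm: int,
    rng: np.random.Generator,
    statistic: str,
) -> np.ndarray:
    pool_size = len(densities)
    means = np.empty(n_perm, dtype=float)
    if statistic == "per_gene_mean":
        for i in range(n_perm):
            idx = rng.choice(pool_size, size=n_genes, replace=False)
            means[i] = densities[idx].mean()
    elif statistic == "aggregate":
        counts = densities * widths_kb
        for i in range(n_perm):
            idx = rng.choice(pool_size, size=n_genes, replace=False)
            means[i] = counts[idx].sum() / widths_kb[idx].sum()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return means


def mc_enrichment(
    observed: DensityResult,
    pool: Sequence[GeneRecord],
    hits: list[SiteHit],
    spec: WindowSpec,
    genome: GenomeSequence,
    n_perm: int = 100_000,
    seed: int = 0,
    estimator: str = "plain",
    statistic: str = "per_gene_mean",
    min_effective_kb: float = 1.0,
) -> MCEnrichmentResult:
    """Monte Carlo enrichment test of an observed gene-set mean density
    against resampled sets of the same size from ``pool``.

    The full pool's per-gene densities are computed once; the observed
    genes are NOT removed from the pool before resampling (plain
    subsampling null).
    """
    model = GuideSiteEnrichment(
        set_genes=None,
        pool_genes=pool,
        hits=hits,
        genome=genome,
        window=spec,
        set_id=observed.set_id,
        statistic=statistic,
        min_effective_kb=min_effective_kb,
    )
    return model._fit_observed(observed, n_perm=n_perm, seed=seed, estimator=estimator)


class GuideSiteEnrichment:
    """Model object: a designated gene set scored against a gene pool.

    Parameters
    ----------
    set_genes
        The designated gene set (or ``None`` when an already-computed
        :class:`DensityResult` will be supplied to the internal fit).
    pool_genes
        The resampling pool (e.g. all protein-coding genes).
    hits
        Sorted guide-site hits from :func:`alusite.scan.find_guide_sites`.
    genome
        Genome the hits refer to (contig lengths for window clipping).
    window
        TSS window spec; default -10 kb / +1 kb.
    statistic
        ``"per_gene_mean"`` (default) or ``"aggregate"``.

    ``fit(n_perm, seed)`` returns an :class:`EnrichmentResults`.
    """

    def __init__(
        self,
        set_genes: Sequence[GeneRecord] | None,
        pool_genes: Sequence[GeneRecord],
        hits: list[SiteHit],
        genome: GenomeSequence,
        window: WindowSpec = WindowSpec(),
        set_id: str = "set",
        statistic: str = "per_gene_mean",
        min_effective_kb: float = 1.0,
    ):
        if statistic not in ("per_gene_mean", "aggregate"):
            raise ValueError(f"unknown statistic {statistic!r}")
        if not pool_genes:
            raise ValueError("pool must be non-empty")
        _check_sorted(hits)
        self.set_genes = list(set_genes) if set_genes is not None else None
        self.window = window
        self.genome = genome
        self.set_id = set_id
        self.statistic = statistic
        self.min_effective_kb = min_effective_kb
        self._index = SiteIndex(hits)
        kept, dens = _pool_densities(
            self._index, pool_genes, window, genome, min_effective_kb
        )
        n_excluded = len(pool_genes) - len(kept)
        if n_excluded:
            logger.warning(
                "pool: excluded %d/%d genes with window < %.2f kb",
                n_excluded, len(pool_genes), min_effective_kb,
            )
        self.pool_genes = kept
        self.pool_densities = dens
        self.pool_widths_kb = np.array(
            [
                upstream_window(g, window, genome.length_of(g.contig))[2]
                for g in kept
            ],
            dtype=float,
        )

    @property
    def pool_size(self) -> int:
        return len(self.pool_genes)

    def observed_density(self) -> DensityResult:
        if self.set_genes is None:
            raise ValueError("model was built without a designated gene set")
        kept, dens = _pool_densities(
            self._index, self.set_genes, self.window, self.genome,
            self.min_effective_kb,
        )
        if not kept:
            raise ValueError("gene set empty after window clipping")
        if self.statistic == "aggregate":
            widths = np.array(
                [
                    upstream_window(g, self.window, self.genome.length_of(g.contig))[2]
                    for g in kept
                ]
            )
            mean = float((dens * widths).sum() / widths.sum())
        else:
            mean = float(dens.mean())
        return DensityResult(
            set_id=self.set_id,
            n_genes=len(kept),
            per_gene_density=tuple(float(d) for d in dens),
            mean_density=mean,
        )

    def fit(
        self, n_perm: int = 100_000, seed: int = 0, estimator: str = "plain"
    ) -> "EnrichmentResults":
        observed = self.observed_density()
        mc = self._fit_observed(observed, n_perm=n_perm, seed=seed, estimator=estimator)
        return EnrichmentResults(model=self, density=observed, mc=mc)

    def _fit_observed(
        self, observed: DensityResult, n_perm: int, seed: int, estimator: str
    ) -> MCEnrichmentResult:
        if estimator not in ("plain", "plus_one"):
            raise ValueError(f"unknown estimator {estimator!r}")
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        n_genes = observed.n_genes
        if n_genes >= self.pool_size:
            raise ValueError(
                f"set size ({n_genes}) must be smaller than pool size "
                f"({self.pool_size})"
            )
        rng = np.random.default_rng(seed)
        means = _permutation_means(
            self.pool_densities,
            self.pool_widths_kb,
            n_genes,
            n_perm,
            rng,
            self.statistic,
        )
        exceed = int(np.count_nonzero(means >= observed.mean_density))
        if estimator == "plus_one":
            p = (exceed + 1) / (n_perm + 1)
        else:
            p = exceed / n_perm
        flag = None
        if exceed == 0 and estimator == "plain":
            flag = f"p < {1.0 / n_perm:g}"
        return MCEnrichmentResult(
            set_id=observed.set_id,
            observed_mean=observed.mean_density,
            n_genes=n_genes,
            pool_size=self.pool_size,
            n_perm=n_perm,
            exceed_count=exceed,
            p_value=p,
            seed=seed,
            window=self.window,
            statistic=self.statistic,
            estimator=estimator,
            p_flag=flag,
            null_mean=float(means.mean()),
            null_sd=float(means.std(ddof=1)) if n_perm > 1 else float("nan"),
        )


@dataclass(frozen=True)
class EnrichmentResults:
    """Fitted enrichment results: observed densities plus the MC null."""

    model: GuideSiteEnrichment
    density: DensityResult
    mc: MCEnrichmentResult

    @property
    def p_value(self) -> float:
        return self.mc.p_value

    @property
    def observed_mean(self) -> float:
        return self.mc.observed_mean

    def summary(self) -> str:
        return self.mc.summary()

    def to_dict(self) -> dict:
        return self.mc.to_dict()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
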