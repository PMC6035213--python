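"""Synthetic genomes with planted guide sites and known ground truth.

The generator emulates the study conditions end to end: an i.i.d. random
genome at a chosen GC content, *sanitized* so that no guide site exists
before planting; a pool of protein-coding genes laid out in non-overlapping
TSS windows; guide sites planted per gene at Poisson counts matching a
target per-kb density (one rate for a designated enriched subset, another
for the background pool); and per-sample peak sets in which each peak is
independently site-bearing with a group-specific probability.

Because sanitization removes every accidental site, the scanner's output on
the emitted genome equals the planted truth exactly, which makes every
downstream statistic deterministic given the seed.

Default rates mirror the quantities the pipeline is meant to recover:
background 0.215 and enriched 0.409 sites/kb in a -10 kb/+1 kb TSS window,
and peak site-bearing probabilities 0.008 (control) vs 0.019 (treated).

Each stage accepts an explicit ``numpy`` Generator so a composite run
(:func:`simulate_dataset`) consumes one stream; called standalone, a stage
derives its own stream from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .enrichment import WindowSpec, upstream_window
from .io import (
    GeneRecord,
    GenomeSequence,
    GuideSpec,
    PeakRecord,
    SampleSheetRow,
    write_fasta,
    write_gene_set,
    write_genes,
    write_guides,
    write_peaks,
    write_sample_sheet,
)
from .scan import SiteHit, SiteIndex, find_guide_sites, reverse_complement

logger = logging.getLogger(__name__)

_SANITIZE_MAX_ITER = 100
_PLACEMENT_MAX_TRIES = 1000
_EDGE_MARGIN = 1000  # bp kept free at each contig end
_WINDOW_GAP = 100  # bp between adjacent gene windows


class GenerationError(RuntimeError):
    """The requested synthetic dataset cannot be realized."""


#: Default synthetic guide: a 14-nt protospacer with NGG PAM. The sequence
#: is synthetic (arbitrary, fixed for reproducibility), standing in for a
#: real 14-nt motif-targeting guide whose sequence is experiment input.
DEFAULT_GUIDE = GuideSpec(name="g1", protospacer="GATTCGCAAGCTGT", pam="NGG")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic dataset; defaults are the study conditions
    the recovery tests target."""

    seed: int
    n_contigs: int = 4
    contig_length: int = 6_500_000
    gc_content: float = 0.41
    pool_size: int = 2000
    enriched_set_size: int = 18
    background_density: float = 0.215
    enriched_density: float = 0.409
    guide: GuideSpec = DEFAULT_GUIDE
    window: WindowSpec = WindowSpec()
    peaks_per_sample: int = 1000
    n_control_samples: int = 3
    n_treated_samples: int = 5
    control_overlap_fraction: float = 0.008
    treated_overlap_fraction: float = 0.019
    peak_width: int = 500
    pam_realization: str = "AGG"
    sanitize: bool = True

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("need at least one contig of positive length")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.background_density < 0 or self.enriched_density < 0:
            raise ValueError("densities must be >= 0")
        if self.enriched_set_size >= self.pool_size:
            raise ValueError("enriched_set_size must be < pool_size")
        for f in (self.control_overlap_fraction, self.treated_overlap_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("overlap fractions must be in [0, 1]")
        if self.peak_width < len(self.guide.protospacer):
            raise ValueError("peak_width must be >= protospacer length")
        if len(self.pam_realization) != len(self.guide.pam):
            raise ValueError("pam_realization must match PAM pattern length")
        if self.total_window_capacity() < self.pool_size:
            raise ValueError(
                f"contigs host at most {self.total_window_capacity()} "
                f"non-overlapping windows, need {self.pool_size}; "
                "increase contig_length or n_contigs"
            )

    def slot_length(self) -> int:
        return self.window.span_bp + _WINDOW_GAP

    def per_contig_capacity(self) -> int:
        usable = self.contig_length - 2 * _EDGE_MARGIN
        return max(usable // self.slot_length(), 0)

    def total_window_capacity(self) -> int:
        return self.n_contigs * self.per_contig_capacity()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["guide"] = {
            "name": self.guide.name,
            "protospacer": self.guide.protospacer,
            "pam": self.guide.pam,
        }
        d["window"] = self.window.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "guide" in d and isinstance(d["guide"], dict):
            d["guide"] = GuideSpec(**d["guide"])
        if "window" in d and isinstance(d["window"], dict):
            d["window"] = WindowSpec(**d["window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class TruthRecord:
    """Planted ground truth emitted alongside a synthetic dataset."""

    planted_sites: list[SiteHit] = field(default_factory=list)
    enriched_gene_ids: list[str] = field(default_factory=list)
    per_gene_planted_count: dict[str, int] = field(default_factory=dict)
    per_sample_site_bearing_peaks: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_sites": [
                {
                    "contig": h.contig,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "guide_name": h.guide_name,
                }
                for h in self.planted_sites
            ],
            "enriched_gene_ids": list(self.enriched_gene_ids),
            "per_gene_planted_count": dict(self.per_gene_planted_count),
            "per_sample_site_bearing_peaks": dict(self.per_sample_site_bearing_peaks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            planted_sites=[SiteHit(**h) for h in d.get("planted_sites", [])],
            enriched_gene_ids=list(d.get("enriched_gene_ids", [])),
            per_gene_planted_count=dict(d.get("per_gene_planted_count", {})),
            per_sample_site_bearing_peaks=dict(
                d.get("per_sample_site_bearing_peaks", {})
            ),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# stage 1: background genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_contig(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    # inverse-CDF draw; noticeably faster than Generator.choice at Mb scale
    cum = np.cumsum(_base_probs(gc))
    return _BASES[np.searchsorted(cum, rng.random(n), side="right")]


def _arrays_to_genome(arrays: dict[str, np.ndarray]) -> GenomeSequence:
    return GenomeSequence(
        contigs={name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    )


def generate_background(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> GenomeSequence:
    """i.i.d. random genome at ``gc_content``; if ``config.sanitize``,
    accidental guide sites are destroyed by resampling single bases until
    the scanner finds zero hits.

    Raises
    ------
    GenerationError
        If sanitization fails to converge (pathological guide, e.g. one
        matched by almost every window).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arrays = {
        f"chr{i + 1}": _random_contig(config.contig_length, config.gc_content, rng)
        for i in range(config.n_contigs)
    }
    if config.sanitize:
        _sanitize(arrays, config, rng)
    return _arrays_to_genome(arrays)


def _sanitize(
    arrays: dict[str, np.ndarray], config: SynthConfig, rng: np.random.Generator
) -> None:
    p = _base_probs(config.gc_content)
    for _ in range(_SANITIZE_MAX_ITER):
        genome = _arrays_to_genome(arrays)
        hits = find_guide_sites(genome, config.guide)
        if not hits:
            return
        for h in hits:
            pos = int(rng.integers(h.start, h.end))
            arrays[h.contig][pos] = _BASES[rng.choice(4, p=p)]
    raise GenerationError(
        f"sanitization did not converge in {_SANITIZE_MAX_ITER} iterations"
    )


# ---------------------------------------------------------------------------
# stage 2: genes and planted sites


def _site_construct(config: SynthConfig, strand: str) -> bytes:
    """Forward-strand bytes of one planted site (protospacer + PAM)."""
    proto = config.guide.protospacer
    if strand == "+":
        return (proto + config.pam_realization).encode("ascii")
    return reverse_complement(proto + config.pam_realization).encode("ascii")


def plant_gene_sites(
    genome: GenomeSequence,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequence, list[GeneRecord], TruthRecord]:
    """Lay out the gene pool in non-overlapping TSS windows and plant guide
    sites per gene at Poisson counts.

    Each gene's site count is drawn from Poisson(density x window kb),
    using ``enriched_density`` for the designated enriched subset and
    ``background_density`` otherwise; sites are written at uniform
    non-overlapping positions inside the gene's window on random strands.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    arrays = {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for name, seq in genome.contigs.items()
    }
    contig_names = list(arrays)
    slot = config.slot_length()
    cap = config.per_contig_capacity()
    if config.n_contigs * cap < config.pool_size:
        raise GenerationError(
            "cannot place all gene windows; increase contig_length"
        )
    up = int(round(config.window.upstream_kb * 1000))
    down = int(round(config.window.downstream_kb * 1000))
    span = config.window.span_bp
    site_len = len(config.guide.protospacer) + len(config.pam_realization)
    proto_len = len(config.guide.protospacer)

    enriched_idx = set(
        int(i)
        for i in rng.choice(config.pool_size, size=config.enriched_set_size,
                            replace=False)
    )
    n_digits = len(str(config.pool_size))
    genes: list[GeneRecord] = []
    truth = TruthRecord()
    for i in range(config.pool_size):
        contig = contig_names[i // cap]
        slot_start = _EDGE_MARGIN + (i % cap) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        tss = slot_start + (up if strand == "+" else down)
        gene_id = f"gene_{i + 1:0{n_digits}d}"
        gene = GeneRecord(gene_id, contig, tss, strand, "protein_coding")
        genes.append(gene)
        win_start, win_end = slot_start, slot_start + span
        density = (
            config.enriched_density if i in enriched_idx
            else config.background_density
        )
        count = int(rng.poisson(density * span / 1000.0))
        positions = _nonoverlapping_positions(
            rng, win_start, win_end - site_len, count, site_len
        )
        truth.per_gene_planted_count[gene_id] = count
        for p in positions:
            site_strand = "+" if rng.random() < 0.5 else "-"
            arrays[contig][p : p + site_len] = np.frombuffer(
                _site_construct(config, site_strand), dtype=np.uint8
            )
            proto_start = p if site_strand == "+" else p + len(config.pam_realization)
            truth.planted_sites.append(
                SiteHit(contig, proto_start, proto_start + proto_len,
                        site_strand, config.guide.name)
            )
        if i in enriched_idx:
            truth.enriched_gene_ids.append(gene_id)
    truth.planted_sites.sort(key=lambda h: (h.contig, h.start, h.strand))
    logger.info(
        "planted %d sites over %d genes (%d enriched)",
        len(truth.planted_sites), len(genes), len(truth.enriched_gene_ids),
    )
    return _arrays_to_genome(arrays), genes, truth


def _nonoverlapping_positions(
    rng: np.random.Generator, lo: int, hi: int, count: int, min_gap: int
) -> list[int]:
    """``count`` uniform starts in [lo, hi] with pairwise gaps >= min_gap."""
    if count == 0:
        return []
    if hi < lo:
        raise GenerationError("window too small for a planted site")
    for _ in range(_PLACEMENT_MAX_TRIES):
        starts = np.sort(rng.integers(lo, hi + 1, size=count))
        if count == 1 or np.all(np.diff(starts) >= min_gap):
            return [int(s) for s in starts]
    raise GenerationError(
        f"could not place {count} non-overlapping sites in [{lo}, {hi}]"
    )


# ---------------------------------------------------------------------------
# stage 3: peaks


def generate_peaks(
    genome: GenomeSequence,
    truth: TruthRecord,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[PeakRecord]], dict[str, str], TruthRecord]:
    """Per-sample peak sets with a controlled site-bearing fraction.

    Each of ``peaks_per_sample`` peaks is independently site-bearing with
    its group's overlap fraction. Site-bearing peaks are centred on a
    uniformly chosen planted site (guaranteeing >= 1 bp overlap for any
    ``peak_width`` >= protospacer length); the rest are placed uniformly in
    regions verified free of planted sites. Realized site-bearing counts
    are recorded in the truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    index = SiteIndex(truth.planted_sites)
    contig_names = list(genome.contigs)
    lengths = np.array([genome.length_of(c) for c in contig_names], dtype=float)
    contig_probs = lengths / lengths.sum()
    width = config.peak_width
    samples = [
        (f"control_{i + 1}", "control", config.control_overlap_fraction)
        for i in range(config.n_control_samples)
    ] + [
        (f"treated_{i + 1}", "treated", config.treated_overlap_fraction)
        for i in range(config.n_treated_samples)
    ]
    peaks_by_sample: dict[str, list[PeakRecord]] = {}
    groups: dict[str, str] = {}
    for sample_id, group, frac in samples:
        groups[sample_id] = group
        bearing = rng.random(config.peaks_per_sample) < frac
        if bearing.any() and not truth.planted_sites:
            raise GenerationError(
                "site-bearing peaks requested but no sites were planted"
            )
        records: list[PeakRecord] = []
        for is_bearing in bearing:
            if is_bearing:
                site = truth.planted_sites[
                    int(rng.integers(0, len(truth.planted_sites)))
                ]
                clen = genome.length_of(site.contig)
                mid = (site.start + site.end) // 2
                a = min(max(mid - width // 2, 0), clen - width)
                records.append(PeakRecord(sample_id, site.contig, a, a + width))
            else:
                records.append(
                    _site_free_peak(
                        rng, sample_id, contig_names, contig_probs, genome,
                        index, width,
                    )
                )
        peaks_by_sample[sample_id] = records
        truth.per_sample_site_bearing_peaks[sample_id] = int(bearing.sum())
    return peaks_by_sample, groups, truth


def _site_free_peak(
    rng: np.random.Generator,
    sample_id: str,
    contig_names: list[str],
    contig_probs: np.ndarray,
    genome: GenomeSequence,
    index: SiteIndex,
    width: int,
) -> PeakRecord:
    for _ in range(_PLACEMENT_MAX_TRIES):
        contig = contig_names[int(rng.choice(len(contig_names), p=contig_probs))]
        clen = genome.length_of(contig)
        if clen < width:
            continue
        a = int(rng.integers(0, clen - width + 1))
        if not index.any_overlap(contig, a, a + width):
            return PeakRecord(sample_id, contig, a, a + width)
    raise GenerationError("could not place a site-free peak; genome too dense")


# ---------------------------------------------------------------------------
# composite dataset


@dataclass
class SynthDataset:
    """A complete synthetic dataset plus its planted truth."""

    config: SynthConfig
    genome: GenomeSequence
    genes: list[GeneRecord]
    truth: TruthRecord
    peaks_by_sample: dict[str, list[PeakRecord]]
    groups: dict[str, str]

    @property
    def enriched_genes(self) -> list[GeneRecord]:
        wanted = set(self.truth.enriched_gene_ids)
        return [g for g in self.genes if g.gene_id in wanted]


def simulate_dataset(config: SynthConfig, with_peaks: bool = True) -> SynthDataset:
    """Run all generator stages on a single RNG stream seeded from
    ``config.seed``. Same seed, same dataset, byte for byte."""
    rng = np.random.default_rng(config.seed)
    background = generate_background(config, rng)
    genome, genes, truth = plant_gene_sites(background, config, rng)
    if with_peaks:
        peaks, groups, truth = generate_peaks(genome, truth, config, rng)
    else:
        peaks, groups = {}, {}
    return SynthDataset(
        config=config,
        genome=genome,
        genes=genes,
        truth=truth,
        peaks_by_sample=peaks,
        groups=groups,
    )


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset as files (FASTA/TSV/BED/JSON/YAML); returns the
    paths written, keyed by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(dataset.genome, paths["genome"])
    paths["genes"] = outdir / "genes.tsv"
    write_genes(dataset.genes, paths["genes"])
    paths["enriched_set"] = outdir / "enriched_set.txt"
    write_gene_set(dataset.truth.enriched_gene_ids, paths["enriched_set"])
    paths["guides"] = outdir / "guides.tsv"
    write_guides([dataset.config.guide], paths["guides"])
    sheet: list[SampleSheetRow] = []
    for sample_id, records in dataset.peaks_by_sample.items():
        bed = outdir / f"peaks_{sample_id}.bed"
        write_peaks(records, bed)
        paths[f"peaks_{sample_id}"] = bed
        sheet.append(SampleSheetRow(sample_id, str(bed), dataset.groups[sample_id]))
    if sheet:
        paths["sample_sheet"] = outdir / "sample_sheet.tsv"
        write_sample_sheet(sheet, paths["sample_sheet"])
    paths["truth"] = outdir / "truth.json"
    dataset.truth.to_json(paths["truth"])
    paths["config"] = outdir / "config.yaml"
    dataset.config.to_yaml(paths["config"])
    logger.info("wrote synthetic dataset to %s (seed %d)", outdir, dataset.config.seed)
    return paths
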