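"""Readers and writers for the pipeline's external file formats.

All genomic intervals in this package are 0-based half-open ``[start, end)``,
BED-compatible. Sequences are uppercased on read; the alphabet is
``{A, C, G, T, N}`` and ``N`` never matches any guide base downstream.

Formats:

* genome — FASTA (via Biopython); the header token before the first
  whitespace becomes the contig name.
* gene annotation — 5-column TSV ``gene_id  contig  tss  strand  biotype``
  with an optional header line (auto-detected by a non-integer ``tss``).
* guides — TSV ``name  protospacer  [pam]``; PAM defaults to ``NGG``.
* peaks — BED3+; columns beyond the third are ignored.
* gene sets — plain text, one gene id per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: IUPAC nucleotide codes mapped to the set of concrete bases they match.
#: ``N`` in a *genome* is matched by no code (the sets contain only ACGT).
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class FormatError(ValueError):
    """An input file violates its documented dialect."""


@dataclass(frozen=True)
class GenomeSequence:
    """Named contigs of uppercase A/C/G/T/N sequence.

    Parameters
    ----------
    contigs
        Mapping of contig name to sequence string. Names must be unique and
        non-empty; sequences must be non-empty and drawn from ``ACGTN``.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig name must be non-empty")
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length_of(self, contig: str) -> int:
        return len(self.contigs[contig])


@dataclass(frozen=True)
class GeneRecord:
    """One gene: TSS anchor, strand and biotype on a named contig.

    ``tss`` is the 0-based position of the transcription start site.
    """

    gene_id: str
    contig: str
    tss: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA target-site class: protospacer plus 3' PAM pattern.

    The protospacer is the exact genomic match sequence (no ambiguity
    codes); the PAM is an IUPAC pattern, ``NGG`` for SpCas9/SpdCas9.
    """

    name: str
    protospacer: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("guide name must be non-empty")
        proto = self.protospacer
        if len(proto) < 10:
            raise ValueError(
                f"guide {self.name}: protospacer must be >= 10 nt, got {len(proto)}"
            )
        bad = set(proto) - set("ACGT")
        if bad:
            raise ValueError(
                f"guide {self.name}: protospacer restricted to ACGT, found {sorted(bad)}"
            )
        if not self.pam:
            raise ValueError(f"guide {self.name}: pam must be non-empty")
        bad_pam = set(self.pam) - set(IUPAC_CODES)
        if bad_pam:
            raise ValueError(
                f"guide {self.name}: pam has non-IUPAC characters {sorted(bad_pam)}"
            )


@dataclass(frozen=True)
class PeakRecord:
    """One ATAC-seq (or other) peak interval, 0-based half-open."""

    sample_id: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"peak interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a genome from FASTA. Sequences are uppercased; the header token
    before the first whitespace becomes the contig name.

    Raises
    ------
    FormatError
        On duplicate contig names or characters outside ``ACGTNacgtn``.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in contigs:
            raise FormatError(f"{path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: contig {name!r} contains invalid characters {sorted(bad)}"
            )
        contigs[name] = seq
    if not contigs:
        logger.warning("%s: no FASTA records found", path)
    return GenomeSequence(contigs=contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# gene annotation TSV


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read the 5-column gene annotation TSV.

    A header line is auto-detected: if the third field of the first
    non-empty line is not an integer, the line is skipped as a header.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    first_data = True
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise FormatError(
                f"{path}:{lineno}: expected 5 tab-separated columns, got {len(fields)}"
            )
        if first_data and not _is_int(fields[2]):
            first_data = False  # header line
            continue
        first_data = False
        gene_id, contig, tss_s, strand, biotype = fields[:5]
        if not _is_int(tss_s):
            raise FormatError(f"{path}:{lineno}: tss is not an integer: {tss_s!r}")
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        try:
            rec = GeneRecord(gene_id, contig, int(tss_s), strand, biotype)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        seen.add(gene_id)
        genes.append(rec)
    if not genes:
        logger.warning("%s: no gene records parsed", path)
    return genes


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig\ttss\tstrand\tbiotype\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.contig}\t{g.tss}\t{g.strand}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# guides TSV


_GUIDE_HEADER_TOKENS = {"name", "guide", "guide_name"}


def read_guides(path: str | Path) -> list[GuideSpec]:
    """Read guides from TSV (``name  protospacer  [pam]``)."""
    guides: list[GuideSpec] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0].strip().lower() in _GUIDE_HEADER_TOKENS and lineno == 1:
            continue
        if len(fields) < 2:
            raise FormatError(
                f"{path}:{lineno}: expected at least 2 columns (name, protospacer)"
            )
        name = fields[0].strip()
        proto = fields[1].strip().upper()
        pam = fields[2].strip().upper() if len(fields) > 2 and fields[2].strip() else "NGG"
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate guide name {name!r}")
        try:
            spec = GuideSpec(name=name, protospacer=proto, pam=pam)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        seen.add(name)
        guides.append(spec)
    if not guides:
        logger.warning("%s: no guides parsed", path)
    return guides


def write_guides(guides: Iterable[GuideSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tprotospacer\tpam\n")
        for g in guides:
            fh.write(f"{g.name}\t{g.protospacer}\t{g.pam}\n")


# ---------------------------------------------------------------------------
# peaks BED


def read_peaks(path: str | Path, sample_id: str) -> list[PeakRecord]:
    """Read BED3+ peak calls, tagging every record with ``sample_id``.

    BED's 0-based half-open convention is preserved unchanged; columns
    beyond the third are ignored. ``track``/``browser``/comment lines are
    skipped.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        contig = fields[0]
        if not (_is_int(fields[1]) and _is_int(fields[2])):
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        start, end = int(fields[1]), int(fields[2])
        if start >= end:
            raise FormatError(
                f"{path}:{lineno}: start must be < end, got {start} >= {end}"
            )
        peaks.append(PeakRecord(sample_id=sample_id, contig=contig, start=start, end=end))
    logger.info("%s: parsed %d peaks for sample %s", path, len(peaks), sample_id)
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# gene sets and sample sheets


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    return ids


def write_gene_set(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


@dataclass(frozen=True)
class SampleSheetRow:
    sample_id: str
    path: str
    group: str


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """TSV ``sample_id  path  group`` with group in {control, treated};
    optional header detected on the literal token ``sample_id``."""
    rows: list[SampleSheetRow] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0].strip() == "sample_id":
            continue
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected sample_id, path, group")
        sample_id, p, group = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if group not in ("control", "treated"):
            raise FormatError(
                f"{path}:{lineno}: group must be 'control' or 'treated', got {group!r}"
            )
        rows.append(SampleSheetRow(sample_id, p, group))
    if not rows:
        raise FormatError(f"{path}: empty sample sheet")
    return rows


def write_sample_sheet(rows: Iterable[SampleSheetRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpath\tgroup\n")
        for r in rows:
            fh.write(f"{r.sample_id}\t{r.path}\t{r.group}\n")
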