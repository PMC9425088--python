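"""Genomic coordinate primitives and flat-file readers/writers.

Coordinates are 0-based half-open throughout (BED convention): ``start`` is
inclusive, ``end`` exclusive.  Strand is ``'+'``, ``'-'`` or ``'.'``
(unstranded).  ChIP-seq peaks default to unstranded; eCLIP peaks are stranded
because the protocol preserves transcript orientation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Interval",
    "Peak",
    "GeneModel",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "standardize_peak",
    "peaks_near_tss",
    "peaks_in_gene_body",
    "extract_sequence",
]

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BedParseError(ValueError):
    """Raised for malformed BED-like lines; message names the line number."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor of (start+end)/2."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """One binding peak: the atomic evidence unit for either layer."""

    interval: Interval
    score: float | None = None
    assay: str = "chip"  # 'chip' (unstranded DNA binding) or 'eclip' (stranded RNA binding)
    source_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "eclip"):
            raise ValueError(f"assay must be 'chip' or 'eclip', got {self.assay!r}")
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be non-negative")

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass(frozen=True)
class GeneModel:
    """A gene body with TSS and regulatory role flags.

    The TSS defaults to the strand-appropriate body end: ``start`` on '+',
    ``end - 1`` on '-'.  An explicit TSS from an annotation column overrides
    this but must lie inside the body.
    """

    gene_id: str
    symbol: str
    interval: Interval
    tss: int = -1
    is_tf: bool = False
    is_sf: bool = False
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss == -1:
            object.__setattr__(self, "tss", self._default_tss())
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} outside gene body "
                f"[{self.interval.start}, {self.interval.end})"
            )

    def _default_tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# BED-like I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, assay: str = "chip") -> list[Peak]:
    """Read BED3/BED6 (narrowPeak tolerated: extra columns ignored).

    Lines starting with '#', 'track' or 'browser' are skipped.  ChIP peaks
    with no strand column come back unstranded; eCLIP peaks keep the strand
    column (column 6) when present.
    """
    peaks: list[Peak] = []
    source = str(Path(path).name)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = "."
            if len(fields) > 5:
                strand = fields[5]
                if strand not in STRANDS:
                    raise BedParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                interval = Interval(fields[0], start, end, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(Peak(interval, score=score, assay=assay, source_id=source, name=name))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (name '.', score '.' when absent)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            score = "." if p.score is None else format(p.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation table
# ---------------------------------------------------------------------------

_GENE_COLUMNS = [
    "gene_id", "symbol", "chrom", "start", "end", "strand", "tss",
    "is_tf", "is_sf", "biotype",
]


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in ("1", "true", "yes")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the tab-separated gene annotation (header required).

    Required columns: gene_id, symbol, chrom, start, end, strand.
    Optional: tss (blank -> strand default), is_tf, is_sf, biotype.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene_id", "symbol", "chrom", "start", "end", "strand"):
            if col not in idx:
                raise ValueError(f"{path}: missing required column {col!r}")
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            interval = Interval(
                f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]), f[idx["strand"]]
            )
            tss = -1
            if "tss" in idx and f[idx["tss"]] not in ("", "."):
                tss = int(f[idx["tss"]])
            genes.append(
                GeneModel(
                    gene_id=f[idx["gene_id"]],
                    symbol=f[idx["symbol"]],
                    interval=interval,
                    tss=tss,
                    is_tf="is_tf" in idx and _parse_bool(f[idx["is_tf"]]),
                    is_sf="is_sf" in idx and _parse_bool(f[idx["is_sf"]]),
                    biotype=f[idx["biotype"]] if "biotype" in idx else "protein_coding",
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id, g.symbol, g.chrom,
                        str(g.interval.start), str(g.interval.end), g.strand,
                        str(g.tss), str(int(g.is_tf)), str(int(g.is_sf)), g.biotype,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped) multi-record FASTA into a chrom->sequence map."""
    genome: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def standardize_peak(peak: Peak, width: int) -> Peak:
    """Resize a peak to exactly ``width`` bp around its center.

    Center is floor((start+end)/2) of the input; the new start is clipped at
    zero, preserving width rather than symmetry at the chromosome edge.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    center = peak.interval.center
    new_start = max(0, center - width // 2)
    new_end = new_start + width
    return replace(peak, interval=replace(peak.interval, start=new_start, end=new_end))


def peaks_near_tss(gene: GeneModel, peaks: Iterable[Peak], window: int = 100_000) -> list[Peak]:
    """Peaks whose center lies within ``window`` bp of the gene's TSS.

    The window is closed on both sides: a center exactly ``window`` away is in.
    Input order is preserved.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    lo, hi = gene.tss - window, gene.tss + window
    return [
        p for p in peaks
        if p.interval.chrom == gene.chrom and lo <= p.center <= hi
    ]


def peaks_in_gene_body(gene: GeneModel, peaks: Iterable[Peak], stranded: bool = False) -> list[Peak]:
    """Peaks overlapping the gene body by >=1 bp.

    With ``stranded=True`` the peak strand must match the gene strand;
    unstranded peaks always pass.
    """
    out = []
    for p in peaks:
        if not p.interval.overlaps(gene.interval):
            continue
        if stranded and p.interval.strand != "." and p.interval.strand != gene.strand:
            continue
        out.append(p)
    return out


def extract_sequence(genome: Mapping[str, str], interval: Interval, as_rna: bool = False) -> str:
    """Strand-aware sequence slice: '-' intervals come back reverse-complemented.

    ``as_rna=True`` additionally maps T to U after strand resolution.
    """
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise IndexError(
            f"interval end {interval.end} exceeds {interval.chrom} length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    if as_rna:
        seq = seq.replace("T", "U").replace("t", "u")
    return seq
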