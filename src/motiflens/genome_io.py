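"""Genome, interval and annotation I/O.

All coordinates are 0-based half-open throughout the package; conversion to
1-based browser display happens only at rendering boundaries.  Regions come
and go as minimal BED (chromosome, start, end; further columns optional up
to BED6, anything beyond ignored).  G+C content is expressed per 100 bp,
the unit used for the 11-bin matching scheme of the control sampler.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GC_BIN_LABELS",
    "Genome",
    "GenomicInterval",
    "gc_bin",
    "gc_count_per_100bp",
    "genome_windows",
    "intersect",
    "parse_tss",
    "read_bed",
    "read_fasta",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span with optional BED6 annotations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Genome:
    """In-memory genome: upper-cased sequences plus a soft-mask flag track."""

    sequences: dict[str, str]
    softmask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if chrom not in self.softmask:
                self.softmask[chrom] = np.zeros(len(seq), dtype=bool)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.sequences.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


def read_fasta(path) -> Genome:
    """Read a (possibly soft-masked) FASTA file into a :class:`Genome`.

    Lowercase bases are upper-cased but remembered in a parallel boolean
    mask; N bases are allowed.  Duplicate record names are an error.
    """
    sequences: dict[str, str] = {}
    softmask: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
            raw = str(rec.seq)
            mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
            softmask[rec.id] = (mask >= ord("a")) & (mask <= ord("z"))
            sequences[rec.id] = raw.upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences=sequences, softmask=softmask)


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[GenomicInterval]:
    """Parse minimal BED (>=3 tab-separated columns; extras beyond 6 ignored)."""
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        src = "<stream>"
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        src = str(path)
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{src} line {lineno}: fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(
                f"{src} line {lineno}: non-integer coordinates "
                f"{fields[1]!r}/{fields[2]!r}"
            ) from None
        name = fields[3] if len(fields) > 3 and fields[3] != "" else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                raise ValueError(
                    f"{src} line {lineno}: non-numeric score {fields[4]!r}"
                ) from None
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
        except ValueError as exc:
            raise ValueError(f"{src} line {lineno}: {exc}") from None
    return intervals


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def bed_line(iv: GenomicInterval) -> str:
    """Render an interval with exactly as many columns as it carries."""
    fields = [iv.chrom, str(iv.start), str(iv.end)]
    ncols = 3
    if iv.strand != ".":
        ncols = 6
    elif iv.score is not None:
        ncols = 5
    elif iv.name is not None:
        ncols = 4
    if ncols >= 4:
        fields.append(iv.name if iv.name is not None else ".")
    if ncols >= 5:
        fields.append(_format_score(iv.score))
    if ncols >= 6:
        fields.append(iv.strand)
    return "\t".join(fields)


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(bed_line(iv) + "\n")


def gc_count_per_100bp(genome: Genome, interval: GenomicInterval) -> float:
    """G+C content of an interval, per 100 bp.

    N bases count in the denominator but never the numerator, so gap-rich
    windows read as AT-rich rather than being dropped here.
    """
    seq = genome.fetch(interval)
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


# The 11-bin G+C matching scheme (per 100 bp), half-open on the continuous
# scale: [0,20) [20,30) [30,35) [35,40) [40,45) [45,50) [50,55) [55,60)
# [60,70) [70,80) [80,100].
_GC_BIN_EDGES = np.array([20.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 70.0, 80.0])
GC_BIN_LABELS = (
    "0-19", "20-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-69", "70-79", "80-100",
)


def gc_bin(gc_per_100bp: float) -> str:
    """Map a per-100bp G+C value to its bin label."""
    if not 0.0 <= gc_per_100bp <= 100.0:
        raise ValueError(f"G+C per 100bp out of range: {gc_per_100bp}")
    return GC_BIN_LABELS[int(np.searchsorted(_GC_BIN_EDGES, gc_per_100bp, side="right"))]


def genome_windows(
    genome: Genome, size: int = 500, step: int = 100
) -> list[GenomicInterval]:
    """Tile each chromosome with sliding windows labeled by G+C bin.

    Windows are ``[k*step, k*step + size)``; a trailing partial window is
    dropped, as are chromosomes shorter than ``size``.  The bin label is
    stored in the interval's ``name``.
    """
    windows: list[GenomicInterval] = []
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        if n < size:
            continue
        for start in range(0, n - size + 1, step):
            iv = GenomicInterval(chrom, start, start + size)
            label = gc_bin(gc_count_per_100bp(genome, iv))
            windows.append(GenomicInterval(chrom, start, start + size, name=label))
    return windows


def intersect(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (i in a, j in b) overlapping by >= 1 bp (half-open).

    Output order is deterministic: a's input order, then b by coordinate.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for j in b:
        by_chrom.setdefault(j.chrom, []).append(j)
    starts: dict[str, np.ndarray] = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda iv: (iv.start, iv.end))
        starts[chrom] = np.array([iv.start for iv in items])
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for i in a:
        items = by_chrom.get(i.chrom)
        if not items:
            continue
        # candidates have start < i.end; filter by end > i.start
        hi = int(np.searchsorted(starts[i.chrom], i.end, side="left"))
        for j in items[:hi]:
            if j.end > i.start:
                pairs.append((i, j))
    return pairs


def _attr_value(attrs: str, keys: tuple[str, ...], src: str, lineno: int) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        pieces = part.split(None, 1)
        if len(pieces) != 2:
            raise ValueError(f"{src} line {lineno}: unparseable attribute {part!r}")
        key, value = pieces
        if key in keys:
            return value.strip().strip('"')
    return None


def parse_tss(path) -> list[GenomicInterval]:
    """Extract protein-coding transcription start sites as 1 bp intervals.

    Accepts an ENSEMBL-style GTF (one TSS per protein-coding transcript:
    the 5' end — start for +, end for -) or a BED file of precomputed TSS
    (reduced to the 5' base when longer than 1 bp).  Duplicate
    (chrom, position, strand) sites are collapsed.
    """
    path = str(path)
    if path.endswith((".bed", ".bed3", ".bed6")):
        out = []
        for iv in read_bed(path):
            if len(iv) == 1:
                out.append(iv)
            elif iv.strand == "-":
                out.append(
                    GenomicInterval(iv.chrom, iv.end - 1, iv.end, name=iv.name, strand="-")
                )
            else:
                out.append(
                    GenomicInterval(
                        iv.chrom, iv.start, iv.start + 1, name=iv.name, strand=iv.strand
                    )
                )
        return _dedupe_tss(out)

    tss: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path} line {lineno}: fewer than 9 GTF columns")
            if fields[2] != "transcript":
                continue
            biotype = _attr_value(
                fields[8], ("transcript_biotype", "gene_biotype"), path, lineno
            )
            if biotype != "protein_coding":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: non-integer GTF coordinates"
                ) from None
            strand = fields[6]
            name = _attr_value(fields[8], ("gene_name", "transcript_id"), path, lineno)
            if strand == "-":
                iv = GenomicInterval(fields[0], end1 - 1, end1, name=name, strand="-")
            else:
                iv = GenomicInterval(fields[0], start1 - 1, start1, name=name, strand="+")
            tss.append(iv)
    return _dedupe_tss(tss)


def _dedupe_tss(tss: list[GenomicInterval]) -> list[GenomicInterval]:
    seen: set[tuple[str, int, str]] = set()
    out = []
    for iv in tss:
        key = (iv.chrom, iv.start, iv.strand)
        if key not in seen:
            seen.add(key)
            out.append(iv)
    return out
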