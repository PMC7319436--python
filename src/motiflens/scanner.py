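"""Genome-wide motif occurrence calling.

Every window of motif length L, on both strands, whose log-odds score
reaches the score threshold corresponding to the motif's P-value cutoff is
reported as an occurrence.  Minus-strand windows are scored on the reverse
complement but reported with the forward-strand footprint coordinates and
strand "-"; windows containing N are skipped.  Palindromic windows that
pass on both strands yield two records.

Scanning is vectorised per chromosome: the sequence is integer-encoded
once, each motif column contributes a numpy gather, and the minus strand
reuses the forward encoding by scoring with the reverse-complemented score
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, GenomicInterval, intersect
from .motif_model import (
    Background,
    DEFAULT_FREQ_FLOOR,
    DEFAULT_GRANULARITY,
    Motif,
    ScoreDistribution,
    UNIFORM_BG,
    log_odds,
    pvalue_of_score,
    reverse_complement,
    score_distribution,
    score_of_pvalue,
)

__all__ = [
    "MotifOccurrence",
    "occurrences_to_track",
    "scan",
    "scan_regions",
]


@dataclass(frozen=True)
class MotifOccurrence:
    """A window where a motif scores at or above its threshold."""

    interval: GenomicInterval
    motif_id: str
    strand: str
    score: float
    pvalue: float
    matched_seq: str


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(code: np.ndarray, lom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all length-L windows plus a validity mask (no N)."""
    L = lom.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    safe = np.where(code < 0, 0, code)
    scores = np.zeros(n)
    for i in range(L):
        scores += lom[i][safe[i : i + n]]
    bad = (code < 0).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[L:] - cbad[:-L]) == 0
    return scores, valid


def _motif_machinery(
    motif: Motif,
    background: Background,
    granularity: float,
) -> tuple[np.ndarray, ScoreDistribution]:
    lom = log_odds(motif.frequencies, background, freq_floor=DEFAULT_FREQ_FLOOR)
    dist = score_distribution(lom, background, granularity)
    return lom, dist


def scan(
    genome: Genome,
    motif: Motif,
    threshold_p: float | None = None,
    background: Background = UNIFORM_BG,
    granularity: float = DEFAULT_GRANULARITY,
    exclude_softmasked: bool = False,
) -> list[MotifOccurrence]:
    """Call occurrences of one motif over the whole genome, both strands.

    ``threshold_p`` defaults to the motif's own (dynamic) threshold.
    Output is sorted by (chrom, start, strand).
    """
    if threshold_p is None:
        threshold_p = motif.threshold_p
    if not 0.0 < threshold_p <= 1.0:
        raise ValueError("threshold_p must be in (0, 1]")
    lom, dist = _motif_machinery(motif, background, granularity)
    s_min = score_of_pvalue(dist, threshold_p)
    lom_rc = lom[::-1, ::-1]  # scores the reverse complement of each window
    L = motif.length

    occurrences: list[MotifOccurrence] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        code = _encode(seq)
        fwd, valid = _window_scores(code, lom)
        rev, _ = _window_scores(code, lom_rc)
        if exclude_softmasked:
            sm = genome.softmask[chrom].astype(np.int32)
            csm = np.concatenate([[0], np.cumsum(sm)])
            valid &= (csm[L:] - csm[:-L]) == 0
        for strand, scores in (("+", fwd), ("-", rev)):
            hits = np.flatnonzero(valid & (scores >= s_min))
            for pos in hits:
                start = int(pos)
                window = seq[start : start + L]
                occurrences.append(
                    MotifOccurrence(
                        interval=GenomicInterval(chrom, start, start + L),
                        motif_id=motif.id,
                        strand=strand,
                        score=float(scores[pos]),
                        pvalue=pvalue_of_score(dist, float(scores[pos])),
                        matched_seq=window if strand == "+" else reverse_complement(window),
                    )
                )
    occurrences.sort(key=lambda o: (o.interval.chrom, o.interval.start, o.strand))
    return occurrences


def scan_regions(
    genome: Genome,
    regions: list[GenomicInterval],
    motifs: list[Motif],
    thresholds: dict[str, float] | None = None,
    background: Background = UNIFORM_BG,
    granularity: float = DEFAULT_GRANULARITY,
    occurrences: list[MotifOccurrence] | None = None,
) -> dict[int, list[MotifOccurrence]]:
    """Assign motif occurrences to regions by >= 1 bp overlap.

    Returns a map from region index (position in ``regions``) to the
    occurrences overlapping it; an occurrence overlapping several regions
    is assigned to each.  Precomputed ``occurrences`` may be supplied to
    avoid rescanning the genome for every region set.
    """
    lengths = genome.lengths
    for r in regions:
        if r.chrom not in lengths or r.end > lengths[r.chrom]:
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} is out of genome bounds"
            )
    if occurrences is None:
        occurrences = []
        for motif in motifs:
            tp = (thresholds or {}).get(motif.id)
            occurrences.extend(
                scan(genome, motif, threshold_p=tp, background=background,
                     granularity=granularity)
            )
    assigned: dict[int, list[MotifOccurrence]] = {i: [] for i in range(len(regions))}
    occ_by_iv: dict[tuple[str, int, int], list[MotifOccurrence]] = {}
    for occ in occurrences:
        key = (occ.interval.chrom, occ.interval.start, occ.interval.end)
        occ_by_iv.setdefault(key, []).append(occ)
    occ_ivs = [GenomicInterval(c, s, e) for (c, s, e) in occ_by_iv]
    region_index = {id(r): i for i, r in enumerate(regions)}
    for r, occ_iv in intersect(regions, occ_ivs):
        i = region_index[id(r)]
        assigned[i].extend(occ_by_iv[(occ_iv.chrom, occ_iv.start, occ_iv.end)])
    return assigned


def _hex_to_rgb(color: str) -> str:
    color = color.lstrip("#")
    if len(color) != 6:
        return "0,0,0"
    return ",".join(str(int(color[i : i + 2], 16)) for i in (0, 2, 4))


def bed_score(pvalue: float) -> int:
    """UCSC-style track score: round(-10*log10(p)), capped at 1000."""
    if pvalue <= 0:
        return 1000
    return int(round(min(1000.0, -10.0 * np.log10(pvalue))))


def occurrences_to_track(
    occurrences: list[MotifOccurrence], motifs: list[Motif]
) -> str:
    """Render occurrences as BED9 text with per-motif itemRgb colors."""
    by_id = {m.id: m for m in motifs}
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand\tthickStart\tthickEnd\titemRgb"]
    for occ in sorted(
        occurrences, key=lambda o: (o.interval.chrom, o.interval.start, o.strand)
    ):
        m = by_id.get(occ.motif_id)
        name = m.name if m is not None else occ.motif_id
        rgb = _hex_to_rgb(m.color) if m is not None else "0,0,0"
        iv = occ.interval
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    name,
                    str(bed_score(occ.pvalue)),
                    occ.strand,
                    str(iv.start),
                    str(iv.end),
                    rgb,
                ]
            )
        )
    return "\n".join(lines) + "\n"
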