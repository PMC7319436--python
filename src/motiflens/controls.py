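"""Control region construction and G+C quality control.

Two kinds of controls contrast motif frequency in the input regions:

* **local controls** — the sequence immediately flanking each region, half
  the region size on each side, so the total flanking length equals the
  region length;
* **global controls** — random genomic windows drawn, per input region,
  from a pool of 500 bp windows (sliding by 100 bp) stratified into 11
  G+C bins, restricted to windows that are uniquely mappable (when a
  mappability mask is given), non-blacklisted and low-N.  Each sampled
  window is recentred and trimmed to the paired region's exact length, so
  the bin histogram of the controls matches the input by construction.

A mismatch warning fires when user-provided controls differ from the input
by more than five G+Cs per 100 bp in median, the regime where enrichment
fold changes become composition artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import (
    GC_BIN_LABELS,
    Genome,
    GenomicInterval,
    gc_bin,
    gc_count_per_100bp,
    genome_windows,
    intersect,
)

__all__ = [
    "GCProfile",
    "SamplablePool",
    "build_pool",
    "gc_mismatch_warning",
    "gc_profile",
    "global_controls",
    "local_controls",
]


@dataclass
class GCProfile:
    """Per-region G+C (per 100 bp) with its median and 11-bin histogram."""

    per_region_gc: list[float]
    median: float
    histogram: dict[str, int]


def gc_profile(genome: Genome, regions: list[GenomicInterval]) -> GCProfile:
    if not regions:
        raise ValueError("cannot profile an empty region set")
    gcs = [gc_count_per_100bp(genome, r) for r in regions]
    hist = {label: 0 for label in GC_BIN_LABELS}
    for gc in gcs:
        hist[gc_bin(gc)] += 1
    return GCProfile(per_region_gc=gcs, median=float(np.median(gcs)), histogram=hist)


def local_controls(
    regions: list[GenomicInterval], genome: Genome | None = None
) -> list[GenomicInterval]:
    """Flanks of half the region size on each side (left gets the odd base).

    Flanks are clipped at chromosome bounds; a fully clipped flank is
    dropped.  Total local-control length per unclipped region equals the
    region length.
    """
    lengths = genome.lengths if genome is not None else None
    flanks: list[GenomicInterval] = []
    for r in regions:
        size = len(r)
        left = (size + 1) // 2
        right = size // 2
        lstart = max(0, r.start - left)
        if lstart < r.start:
            flanks.append(GenomicInterval(r.chrom, lstart, r.start, name=r.name))
        rend = r.end + right
        if lengths is not None:
            rend = min(rend, lengths.get(r.chrom, rend))
        if rend > r.end:
            flanks.append(GenomicInterval(r.chrom, r.end, rend, name=r.name))
    return flanks


@dataclass
class SamplablePool:
    """Genome windows eligible as global controls, indexed by G+C bin."""

    by_bin: dict[str, list[GenomicInterval]]

    def size(self) -> int:
        return sum(len(v) for v in self.by_bin.values())


def _coverage_ok(
    window: GenomicInterval, merged: dict[str, list[tuple[int, int]]]
) -> bool:
    """True iff the window lies entirely inside the merged mask intervals."""
    spans = merged.get(window.chrom, [])
    for s, e in spans:
        if s <= window.start and window.end <= e:
            return True
        if s > window.start:
            break
    return False


def _merge(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        spans = by_chrom.setdefault(iv.chrom, [])
        if spans and iv.start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], iv.end))
        else:
            spans.append((iv.start, iv.end))
    return by_chrom


def build_pool(
    genome: Genome,
    mappability: list[GenomicInterval] | None = None,
    blacklist: list[GenomicInterval] | None = None,
    size: int = 500,
    step: int = 100,
    max_n_fraction: float = 0.10,
) -> SamplablePool:
    """Index eligible 500/100 sliding windows by G+C bin.

    A window is eligible when it lies entirely inside the mappability mask
    (if one is given), overlaps no blacklist interval, and has at most
    ``max_n_fraction`` N bases (assembly gaps).
    """
    windows = genome_windows(genome, size=size, step=step)
    if blacklist:
        excluded = {
            (w.chrom, w.start, w.end) for w, _ in intersect(windows, blacklist)
        }
        windows = [w for w in windows if (w.chrom, w.start, w.end) not in excluded]
    if mappability is not None:
        merged = _merge(mappability)
        windows = [w for w in windows if _coverage_ok(w, merged)]
    by_bin: dict[str, list[GenomicInterval]] = {label: [] for label in GC_BIN_LABELS}
    for w in windows:
        seq = genome.fetch(w)
        if seq.count("N") > max_n_fraction * len(seq):
            continue
        by_bin[w.name].append(w)
    return SamplablePool(by_bin=by_bin)


class PoolExhaustedError(RuntimeError):
    """A required G+C bin ran out of samplable windows."""


def global_controls(
    genome: Genome,
    regions: list[GenomicInterval],
    pool: SamplablePool,
    n_per_region: int = 1,
    seed: int = 0,
    on_exhausted: str = "error",
) -> list[GenomicInterval]:
    """Sample G+C-matched control regions, one bin-matched draw per region.

    For each input region the sampler draws windows uniformly without
    replacement from the pool bin matching the region's G+C bin, rejecting
    windows that overlap any input region, then recentres and trims the
    window to the region's exact length.  Fully deterministic given the
    seed.

    When a region's bin has no remaining windows, ``on_exhausted`` decides:
    ``"error"`` (default) raises :class:`PoolExhaustedError` naming the bin;
    ``"nearest"`` substitutes the closest non-empty bin (regions shorter
    than the 500 bp pool windows have a wider G+C spread than the windows
    themselves, so extreme-composition regions can lack an exact-bin
    window even on a perfectly matched genome).
    """
    if on_exhausted not in ("error", "nearest"):
        raise ValueError("on_exhausted must be 'error' or 'nearest'")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    # pre-shuffle each bin once; consuming from the front = sampling
    # uniformly without replacement
    order: dict[str, list[GenomicInterval]] = {}
    for label, windows in pool.by_bin.items():
        idx = rng.permutation(len(windows))
        order[label] = [windows[i] for i in idx]
    region_spans = _merge(regions)

    def overlaps_input(iv: GenomicInterval) -> bool:
        spans = region_spans.get(iv.chrom, [])
        starts = [s for s, _ in spans]
        k = int(np.searchsorted(starts, iv.end, side="left"))
        return any(e > iv.start for _, e in spans[:k])

    controls: list[GenomicInterval] = []
    for r in regions:
        label = gc_bin(gc_count_per_100bp(genome, r))
        bin_idx = GC_BIN_LABELS.index(label)
        for _ in range(n_per_region):
            if on_exhausted == "nearest":
                labels = sorted(
                    GC_BIN_LABELS,
                    key=lambda lab: abs(GC_BIN_LABELS.index(lab) - bin_idx),
                )
            else:
                labels = [label]
            placed = False
            for use_label in labels:
                while order[use_label]:
                    w = order[use_label].pop()
                    center = (w.start + w.end) // 2
                    half = len(r) // 2
                    start = max(0, center - half)
                    end = min(lengths[w.chrom], start + len(r))
                    start = max(0, end - len(r))
                    ctrl = GenomicInterval(w.chrom, start, end, name=f"ctrl_{use_label}")
                    if overlaps_input(ctrl):
                        continue
                    controls.append(ctrl)
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise PoolExhaustedError(
                    f"G+C bin {label!r} exhausted while sampling a control for "
                    f"{r.chrom}:{r.start}-{r.end} (pool had "
                    f"{len(pool.by_bin[label])} windows)"
                )
    return controls


def gc_mismatch_warning(input_profile: GCProfile, control_profile: GCProfile) -> bool:
    """True iff the median G+C differs by more than 5 per 100 bp."""
    if not input_profile.per_region_gc or not control_profile.per_region_gc:
        raise ValueError("empty region set in G+C profile")
    return abs(input_profile.median - control_profile.median) > 5.0
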