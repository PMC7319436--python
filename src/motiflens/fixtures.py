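"""Seeded synthetic genomes with planted motif instances.

The generator emulates the minimal structure the pipeline consumes: an
i.i.d. genome with a single G+C parameter, a set of non-overlapping
equal-length regions (ChIP-seq-peak-like, centered on a notional summit),
and motif instances written into a fraction of the regions near their
centers with Gaussian positional jitter and random strand — the signature
of a factor binding at peak summits.  It makes no attempt to mimic
repeats, CpG islands or chromatin structure; a truth table records every
planted instance so recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval
from .motif_model import Motif, motif_from_sequence, reverse_complement

__all__ = ["FixtureSpec", "make_fixture", "plant", "synthetic_genome"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the canonical planted-motif benchmark: 200 regions
    of 200 bp on a 500 kb chromosome at mammalian-like 41% G+C, a 10 bp
    consensus planted in 80% of regions with 5 bp positional jitter.
    """

    genome_length: int = 500_000
    n_chroms: int = 1
    gc_fraction: float = 0.41
    n_regions: int = 200
    region_length: int = 200
    planted_motif: str = "ACGGAAGTGC"  # 10 bp consensus
    plant_rate: float = 0.8
    offset_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.region_length < len(self.planted_motif):
            raise ValueError("region_length must be >= motif length")

    @property
    def motif(self) -> Motif:
        return motif_from_sequence(self.planted_motif)


def synthetic_genome(spec: FixtureSpec) -> Genome:
    """i.i.d. genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2, per-seed determinism."""
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_fraction / 2.0
    p_at = (1.0 - spec.gc_fraction) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for c in range(spec.n_chroms):
        draws = rng.choice(4, size=spec.genome_length, p=probs)
        sequences[f"chr{c + 1}"] = alphabet[draws].tobytes().decode("ascii")
    return Genome(sequences=sequences)


def plant(
    genome: Genome, spec: FixtureSpec
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Place non-overlapping regions and write motif instances into them.

    Instances overwrite genome bases in place (coordinates stay stable),
    at region center plus truncated Gaussian jitter, on a random strand.
    Returns the regions and a truth table (chrom, start, end, strand,
    region_index) of every planted instance.
    """
    rng = np.random.default_rng(spec.seed + 1)
    consensus = spec.planted_motif.upper()
    L = len(consensus)
    regions: list[GenomicInterval] = []
    chroms = sorted(genome.sequences)
    per_chrom = int(np.ceil(spec.n_regions / len(chroms)))
    placed = 0
    mutable = {c: bytearray(genome.sequences[c].encode("ascii")) for c in chroms}
    truth_rows = []
    for chrom in chroms:
        n_here = min(per_chrom, spec.n_regions - placed)
        if n_here <= 0:
            break
        clen = len(genome.sequences[chrom])
        free = clen - n_here * spec.region_length
        if free < 0:
            raise ValueError(
                f"genome too small: cannot place {n_here} regions of "
                f"{spec.region_length} bp on {chrom} ({clen} bp)"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=n_here))
        for k in range(n_here):
            start = int(gaps[k]) + k * spec.region_length
            regions.append(
                GenomicInterval(
                    chrom, start, start + spec.region_length, name=f"region_{placed}"
                )
            )
            placed += 1
    n_plant = int(round(spec.plant_rate * len(regions)))
    which = sorted(rng.choice(len(regions), size=n_plant, replace=False).tolist())
    for i in which:
        r = regions[i]
        center = (r.start + r.end) // 2
        lo, hi = r.start, r.end - L  # instance must stay inside the region
        for _ in range(100):
            jitter = int(round(rng.normal(0.0, spec.offset_sigma)))
            pos = center - L // 2 + jitter
            if lo <= pos <= hi:
                break
        else:
            pos = min(hi, max(lo, center - L // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        inst = consensus if strand == "+" else reverse_complement(consensus)
        mutable[r.chrom][pos : pos + L] = inst.encode("ascii")
        truth_rows.append(
            {
                "chrom": r.chrom,
                "start": pos,
                "end": pos + L,
                "strand": strand,
                "region_index": i,
            }
        )
    for chrom in chroms:
        genome.sequences[chrom] = mutable[chrom].decode("ascii")
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "strand", "region_index"]
    )
    return regions, truth


def make_fixture(spec: FixtureSpec) -> tuple[Genome, list[GenomicInterval], pd.DataFrame]:
    """Generate genome + regions + truth table in one call."""
    genome = synthetic_genome(spec)
    regions, truth = plant(genome, spec)
    return genome, regions, truth
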