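"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, O(n*m)
loops) and shares no code path with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def enumerate_kmer_scores(lom: np.ndarray, background) -> list[tuple[float, float]]:
    """(score, probability) of every k-mer under the i.i.d. background."""
    L = lom.shape[0]
    p = list(background.p)
    out = []
    for kmer in itertools.product(range(4), repeat=L):
        score = sum(lom[i, b] for i, b in enumerate(kmer))
        prob = math.prod(p[b] for b in kmer)
        out.append((score, prob))
    return out


def enum_pvalue(kmer_scores, s: float) -> float:
    """P(score >= s) from exhaustive enumeration."""
    return sum(prob for score, prob in kmer_scores if score >= s)


def enum_mass_near(kmer_scores, s: float, width: float) -> float:
    """Probability mass of k-mers whose score is within `width` of s."""
    return sum(prob for score, prob in kmer_scores if abs(score - s) <= width)


def brute_force_scan(sequences: dict[str, str], lom: np.ndarray, s_min: float):
    """Naive both-strand window scorer; returns (chrom, start, strand, score)."""
    L = lom.shape[0]
    idx = {b: i for i, b in enumerate(BASES)}
    hits = []
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            if any(c not in idx for c in window):
                continue
            fwd = sum(lom[i, idx[c]] for i, c in enumerate(window))
            rev = sum(lom[i, idx[c]] for i, c in enumerate(revcomp(window)))
            if fwd >= s_min:
                hits.append((chrom, start, "+", fwd))
            if rev >= s_min:
                hits.append((chrom, start, "-", rev))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def brute_force_pairs(a, b):
    """All-pairs >=1bp overlap check under half-open semantics."""
    pairs = []
    for i in a:
        for j in sorted(b, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            if i.chrom == j.chrom and i.start < j.end and j.start < i.end:
                pairs.append((i, j))
    return pairs


def hypergeom_sum_pvalue(k_in: int, n_in: int, k_ctrl: int, n_ctrl: int) -> float:
    """Upper-tail hypergeometric by explicit summation of pmf terms."""
    N = n_in + n_ctrl
    K = k_in + k_ctrl
    total = 0.0
    for x in range(k_in, min(K, n_in) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n_in - x) / math.comb(N, n_in)
        )
    return min(1.0, total)


def random_count_matrix(rng: np.random.Generator, length: int) -> np.ndarray:
    """A random JASPAR-like count matrix with no all-zero columns."""
    counts = rng.integers(0, 50, size=(length, 4)).astype(float)
    for i in range(length):
        if counts[i].sum() == 0:
            counts[i, rng.integers(0, 4)] = 1.0
    return counts


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=probs))
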