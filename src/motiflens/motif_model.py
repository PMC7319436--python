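"""Position-weight-matrix models of transcription-factor binding motifs.

A motif is a count matrix over the four DNA bases (one row per position,
columns A, C, G, T).  From the counts we derive, with a configurable
pseudocount, a frequency matrix ``f[i, b]``; from the frequencies an
information content (IC, in bits) measuring the motif's specificity against
a background base composition ``p[b]``; and from the IC a *dynamic* P-value
threshold for occurrence calling::

    IC = sum_i sum_b f[i, b] * log2(f[i, b] / p[b])
    threshold = 2 ** (-IC)

so that highly informative motifs are called at stringent thresholds and
degenerate motifs at lenient ones.

Occurrence calling needs the exact null distribution of the window log-odds
score.  ``score_distribution`` computes it by dynamic programming: each
column's four scores are rounded to a grid of width ``granularity`` and the
per-column score distributions are convolved position by position, giving
the probability mass function of the total score of a random i.i.d.
background k-mer.  P-value <-> score-threshold queries are then table
lookups on the survival function.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BASES",
    "Background",
    "Motif",
    "ScoreDistribution",
    "counts_to_frequencies",
    "dynamic_threshold",
    "information_content",
    "log_odds",
    "motif_from_sequence",
    "parse_jaspar",
    "pvalue_of_score",
    "score_distribution",
    "score_of_pvalue",
    "write_jaspar",
]

BASES = "ACGT"

#: frequency floor applied before taking logs when a matrix contains zeros
DEFAULT_FREQ_FLOOR = 1e-4

#: score-grid width (bits) for the exact score distribution
DEFAULT_GRANULARITY = 1e-3

#: total pseudocount added per matrix column, split by background frequency
DEFAULT_PSEUDOCOUNT = 1.0

# qualitative palette cycled over motifs that have no configured color
DEFAULT_COLORS = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#17becf", "#666666", "#bcbd22",
)


@dataclass(frozen=True)
class Background:
    """i.i.d. background base composition (A, C, G, T)."""

    p: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if abs(sum(self.p) - 1.0) > 1e-12:
            raise ValueError(f"background frequencies sum to {sum(self.p)}, not 1")
        if any(x <= 0 for x in self.p):
            raise ValueError("background frequencies must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


UNIFORM_BG = Background()


@dataclass
class Motif:
    """A named count/frequency matrix with its occurrence-calling threshold.

    ``counts`` and ``frequencies`` are ``L x 4`` arrays (columns A, C, G, T);
    each frequency row sums to 1.  ``threshold_p`` defaults to the dynamic
    threshold ``2**-IC`` and may be overridden per motif.
    """

    id: str
    name: str
    counts: np.ndarray
    frequencies: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    color: str = DEFAULT_COLORS[0]
    threshold_p: float = 1.0
    is_exact_sequence: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"motif {self.id}: counts must be L x 4")
        if self.frequencies.shape != self.counts.shape:
            raise ValueError(f"motif {self.id}: frequency/count shape mismatch")
        rowsums = self.frequencies.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.id}: frequency rows do not sum to 1")
        if not 0.0 < self.threshold_p <= 1.0:
            raise ValueError(f"motif {self.id}: threshold_p must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def information_content(self, background: Background = UNIFORM_BG) -> float:
        return information_content(self.frequencies, background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.frequencies, axis=1))

    def with_threshold(self, p: float) -> "Motif":
        return replace(self, threshold_p=p)


class JasparParseError(ValueError):
    """Raised on malformed JASPAR matrix text, naming record and line."""


_ROW_RE = re.compile(r"^\s*([ACGTacgt])\s*\[?\s*([^\[\]]*?)\s*\]?\s*$")


def parse_jaspar(
    text: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Background = UNIFORM_BG,
) -> list[Motif]:
    """Parse one or more JASPAR-format matrix records into :class:`Motif`.

    A record is a ``>ID NAME`` header followed by four count rows, one per
    base, in the bracketed dialect (``A [ 10 0 3 ]``).  Frequencies are
    derived with :func:`counts_to_frequencies`; the dynamic threshold is set
    from the information content of the pseudocounted matrix.
    """
    motifs: list[Motif] = []
    header: str | None = None
    header_line = 0
    rows: dict[str, np.ndarray] = {}

    def flush(last_line: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(BASES):
            missing = sorted(set(BASES) - set(rows))
            raise JasparParseError(
                f"record '{header}' (line {header_line}): missing rows {missing}"
            )
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise JasparParseError(
                f"record '{header}' (line {header_line}): count rows of unequal length"
            )
        counts = np.stack([rows[b] for b in BASES], axis=1)
        parts = header.split(None, 1)
        motif_id = parts[0]
        name = parts[1].strip() if len(parts) > 1 else motif_id
        freqs = counts_to_frequencies(counts, pseudocount, background)
        ic = information_content(freqs, background)
        motifs.append(
            Motif(
                id=motif_id,
                name=name,
                counts=counts,
                frequencies=freqs,
                pseudocount=pseudocount,
                color=DEFAULT_COLORS[len(motifs) % len(DEFAULT_COLORS)],
                threshold_p=dynamic_threshold(ic),
            )
        )
        header, rows = None, {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno - 1)
            header = line[1:].strip()
            header_line = lineno
            if not header:
                raise JasparParseError(f"line {lineno}: empty record header")
            continue
        if header is None:
            raise JasparParseError(f"line {lineno}: count row before any '>' header")
        m = _ROW_RE.match(line)
        if not m:
            raise JasparParseError(
                f"record '{header}' line {lineno}: unparseable count row {line!r}"
            )
        base = m.group(1).upper()
        if base in rows:
            raise JasparParseError(
                f"record '{header}' line {lineno}: duplicate {base} row"
            )
        try:
            values = np.asarray([float(x) for x in m.group(2).split()], dtype=float)
        except ValueError as exc:
            raise JasparParseError(
                f"record '{header}' line {lineno}: non-numeric count ({exc})"
            ) from None
        if values.size == 0:
            raise JasparParseError(f"record '{header}' line {lineno}: empty count row")
        if np.any(values < 0):
            raise JasparParseError(f"record '{header}' line {lineno}: negative count")
        rows[base] = values
    flush(lineno if text.strip() else 0)
    return motifs


def write_jaspar(motifs: list[Motif]) -> str:
    """Serialize motifs back to bracketed JASPAR text (counts preserved)."""
    chunks = []
    for m in motifs:
        lines = [f">{m.id} {m.name}"]
        for b, base in enumerate(BASES):
            vals = []
            for v in m.counts[:, b]:
                vals.append(str(int(v)) if float(v).is_integer() else repr(float(v)))
            lines.append(f"{base} [ {' '.join(vals)} ]")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")


def counts_to_frequencies(
    counts: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Background = UNIFORM_BG,
) -> np.ndarray:
    """f[i,b] = (c[i,b] + pseudocount * p[b]) / (sum_b c[i,b] + pseudocount)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"all-zero counts at position {bad} (uninformative column)")
    p = background.array
    return (counts + pseudocount * p[None, :]) / (totals + pseudocount)[:, None]


def information_content(
    frequencies: np.ndarray, background: Background = UNIFORM_BG
) -> float:
    """Total information content in bits; 0*log2(0/p) is taken as 0."""
    f = np.asarray(frequencies, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    p = background.array
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log2(f / p[None, :])
    terms[f == 0] = 0.0
    return float(terms.sum())


def dynamic_threshold(ic: float) -> float:
    """Per-motif occurrence-calling P-value threshold: p = 2**-IC."""
    if ic < 0:
        raise ValueError("information content must be non-negative")
    return 2.0 ** (-ic)


def log_odds(
    frequencies: np.ndarray,
    background: Background = UNIFORM_BG,
    freq_floor: float | None = DEFAULT_FREQ_FLOOR,
) -> np.ndarray:
    """Per-cell log2(f/p) score matrix; zeros floored at ``freq_floor``.

    A window of length L scores ``sum_i s[i, base_i]``.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    if freq_floor is not None:
        f = np.maximum(f, freq_floor)
    elif np.any(f <= 0):
        raise ValueError("zero frequency with no floor; use a pseudocount or floor")
    return np.log2(f / background.array[None, :])


@dataclass
class ScoreDistribution:
    """Discretized null distribution of the total window log-odds score.

    ``support`` holds the score grid (multiples of ``granularity``) and
    ``pmf`` the probability of each grid point under the i.i.d. background.
    ``sf[i] = P(score >= support[i])`` is precomputed for threshold queries.
    """

    granularity: float
    support: np.ndarray
    pmf: np.ndarray
    sf: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _grid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sf is None:
            self.sf = np.cumsum(self.pmf[::-1])[::-1]
        if self._grid is None:
            self._grid = np.rint(
                np.asarray(self.support) / self.granularity
            ).astype(np.int64)

    @property
    def min_score(self) -> float:
        return float(self.support[0])

    @property
    def max_score(self) -> float:
        return float(self.support[-1])


def score_distribution(
    score_matrix: np.ndarray,
    background: Background = UNIFORM_BG,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreDistribution:
    """Exact pmf of the window score by position-wise convolution.

    Each cell score is rounded to the nearest multiple of ``granularity``;
    the resulting integer-grid distributions of the L columns are convolved.
    The P-value error of downstream queries is bounded by the probability
    mass within one grid bin.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    s = np.asarray(score_matrix, dtype=float)
    if s.ndim == 1:
        s = s[None, :]
    idx = np.rint(s / granularity).astype(np.int64)  # L x 4 grid indices
    p = background.array

    lo = int(idx.min(axis=1).sum())
    hi = int(idx.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # running distribution over [cur_lo, cur_hi]
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(idx.shape[0]):
        col = idx[i]
        new_lo = cur_lo + int(col.min())
        new = np.zeros(len(cur) + int(col.max() - col.min()))
        for b in range(4):
            off = cur_lo + int(col[b]) - new_lo
            new[off : off + len(cur)] += p[b] * cur
        cur, cur_lo = new, new_lo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    # keep only attained grid points: support bounds are reachable scores
    # and score_of_pvalue answers with a score some k-mer actually has
    nz = np.flatnonzero(pmf > 0)
    support = (lo + nz) * granularity
    return ScoreDistribution(granularity=granularity, support=support, pmf=pmf[nz])


def pvalue_of_score(dist: ScoreDistribution, s: float) -> float:
    """P(score >= s) under the background; monotone non-increasing in s."""
    k = int(np.rint(s / dist.granularity))
    i = int(np.searchsorted(dist._grid, k, side="left"))
    if i <= 0:
        return 1.0
    if i >= len(dist.support):
        return 0.0
    return float(dist.sf[i])


def score_of_pvalue(dist: ScoreDistribution, p: float) -> float:
    """Smallest support score s with P(score >= s) <= p.

    Occurrence calling then uses ``window score >= s`` (inclusive), so a
    deterministic motif's consensus passes its own dynamic threshold.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    # sf is non-increasing; find the first index where it drops to <= p
    i = int(np.searchsorted(-dist.sf, -p, side="left"))
    if i >= len(dist.support):
        return float(dist.support[-1])
    return float(dist.support[i])


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_from_sequence(seq: str, color: str = DEFAULT_COLORS[0]) -> Motif:
    """Build an exact-matching motif from a 6-12 bp DNA sequence.

    The matrix is deterministic (frequency 1 at each consensus base, zero
    pseudocount) and the threshold is ``4**-L`` — the probability of the
    unique maximal score under the uniform background — so scanning finds
    exactly the literal matches of the sequence and its reverse complement.
    """
    seq = seq.strip().upper()
    if not 6 <= len(seq) <= 12:
        raise ValueError(
            f"exact motif sequences must be 6-12 bp, got {len(seq)} ({seq!r})"
        )
    if any(c not in BASES for c in seq):
        bad = next(c for c in seq if c not in BASES)
        raise ValueError(f"exact motif sequence contains non-ACGT base {bad!r}")
    L = len(seq)
    counts = np.zeros((L, 4))
    for i, c in enumerate(seq):
        counts[i, BASES.index(c)] = 1.0
    return Motif(
        id=seq,
        name=seq,
        counts=counts,
        frequencies=counts.copy(),
        pseudocount=0.0,
        color=color,
        threshold_p=4.0 ** (-L),
        is_exact_sequence=True,
    )
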