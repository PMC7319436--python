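"""Motif enrichment statistics: input regions vs. control regions.

The unit of counting is the *region*: a region either contains at least
one occurrence of a motif or it does not, regardless of how many
occurrences it holds.  For each motif the table reports the count and
percentage of motif-containing regions in the input set and in the global
and local control sets, the fold change of percentages, and an upper-tail
hypergeometric P-value (the ``phyper`` convention: draw the input regions
from the pooled input+control population whose successes are the pooled
motif-containing regions, and ask for P(X >= k_input) including the
observed count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genome_io import GenomicInterval
from .motif_model import Motif
from .scanner import MotifOccurrence

__all__ = [
    "EnrichmentRow",
    "count_regions_with_motif",
    "enrichment_table",
    "enrichment_to_frame",
    "fold_change",
    "hypergeom_pvalue",
    "scatter_data",
]

#: P-values below this display cap are printed as "0"
PVALUE_DISPLAY_FLOOR = 1e-300


@dataclass
class EnrichmentRow:
    """Per-motif counts, percentages, fold changes and P-values."""

    motif_id: str
    motif_name: str
    n_input: int
    k_input: int
    pct_input: float
    n_global: int
    k_global: int
    pct_global: float
    fc_global: float
    p_global: float
    n_local: int
    k_local: int
    pct_local: float
    fc_local: float
    p_local: float


def count_regions_with_motif(
    assigned: dict[int, list[MotifOccurrence]], motif_id: str
) -> int:
    """Number of distinct regions with >= 1 occurrence of the motif."""
    return sum(
        1
        for occs in assigned.values()
        if any(o.motif_id == motif_id for o in occs)
    )


def hypergeom_pvalue(k_in: int, n_in: int, k_ctrl: int, n_ctrl: int) -> float:
    """Upper-tail hypergeometric P-value including the observed count.

    P(X >= k_in) with X ~ Hypergeom(N = n_in + n_ctrl, K = k_in + k_ctrl,
    draws = n_in); equivalent to R's
    ``phyper(k_in - 1, K, N - K, n_in, lower.tail = FALSE)``.
    """
    for k, n, what in ((k_in, n_in, "input"), (k_ctrl, n_ctrl, "control")):
        if not 0 <= k <= n:
            raise ValueError(f"invalid {what} counts: k={k}, n={n}")
    if k_in == 0:
        return 1.0
    N = n_in + n_ctrl
    K = k_in + k_ctrl
    return float(hypergeom.sf(k_in - 1, N, K, n_in))


def fold_change(pct_in: float, pct_ctrl: float) -> float:
    """Ratio of percentages; Inf when only the control is empty, NaN for 0/0."""
    if pct_ctrl == 0.0:
        return math.inf if pct_in > 0 else math.nan
    return pct_in / pct_ctrl


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else 0.0


def enrichment_table(
    regions: list[GenomicInterval],
    global_ctrl: list[GenomicInterval],
    local_ctrl: list[GenomicInterval],
    motifs: list[Motif],
    occ_input: dict[int, list[MotifOccurrence]],
    occ_global: dict[int, list[MotifOccurrence]],
    occ_local: dict[int, list[MotifOccurrence]],
) -> list[EnrichmentRow]:
    """One row per motif, ranked by ascending global P-value.

    Ties are broken by descending global fold change, then motif id.  All
    three region sets must have been scanned with the same motifs and
    thresholds for the comparison to be meaningful.
    """
    rows: list[EnrichmentRow] = []
    n_in, n_gl, n_lo = len(regions), len(global_ctrl), len(local_ctrl)
    for m in motifs:
        k_in = count_regions_with_motif(occ_input, m.id)
        k_gl = count_regions_with_motif(occ_global, m.id)
        k_lo = count_regions_with_motif(occ_local, m.id)
        pct_in, pct_gl, pct_lo = _pct(k_in, n_in), _pct(k_gl, n_gl), _pct(k_lo, n_lo)
        rows.append(
            EnrichmentRow(
                motif_id=m.id,
                motif_name=m.name,
                n_input=n_in,
                k_input=k_in,
                pct_input=pct_in,
                n_global=n_gl,
                k_global=k_gl,
                pct_global=pct_gl,
                fc_global=fold_change(pct_in, pct_gl),
                p_global=hypergeom_pvalue(k_in, n_in, k_gl, n_gl),
                n_local=n_lo,
                k_local=k_lo,
                pct_local=pct_lo,
                fc_local=fold_change(pct_in, pct_lo),
                p_local=hypergeom_pvalue(k_in, n_in, k_lo, n_lo),
            )
        )

    def sort_key(r: EnrichmentRow):
        fc = r.fc_global
        if math.isnan(fc):
            fc = -1.0  # absent everywhere sorts last among ties
        return (r.p_global, -fc if not math.isinf(fc) else -math.inf, r.motif_id)

    rows.sort(key=sort_key)
    return rows


def _format_p(p: float) -> str:
    if p < PVALUE_DISPLAY_FLOOR:
        return "0"
    return f"{p:.6g}"


def _format_fc(fc: float) -> str:
    if math.isnan(fc):
        return "NA"
    if math.isinf(fc):
        return "Inf"
    return f"{fc:.6g}"


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular form with display formatting for fold changes and P-values."""
    records = []
    for r in rows:
        d = asdict(r)
        d["pct_input"] = round(r.pct_input, 4)
        d["pct_global"] = round(r.pct_global, 4)
        d["pct_local"] = round(r.pct_local, 4)
        d["fc_global"] = _format_fc(r.fc_global)
        d["fc_local"] = _format_fc(r.fc_local)
        d["p_global"] = _format_p(r.p_global)
        d["p_local"] = _format_p(r.p_local)
        records.append(d)
    return pd.DataFrame.from_records(records)


def scatter_data(
    rows: list[EnrichmentRow], color_cap: float = 300.0
) -> tuple[list[dict], list[str]]:
    """Scatterplot coordinates: x = pct_input, y = log2(global fold change).

    Color encodes -log10(global P), capped.  Motifs with infinite or
    undefined fold changes cannot be placed on a log2 axis and are returned
    separately by id.
    """
    points: list[dict] = []
    excluded: list[str] = []
    for r in rows:
        if math.isinf(r.fc_global) or math.isnan(r.fc_global) or r.fc_global == 0:
            excluded.append(r.motif_id)
            continue
        neglog = color_cap if r.p_global <= 0 else min(color_cap, -math.log10(r.p_global))
        points.append(
            {
                "motif_id": r.motif_id,
                "motif_name": r.motif_name,
                "x": r.pct_input,
                "y": math.log2(r.fc_global),
                "color_value": neglog,
            }
        )
    return points, excluded
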