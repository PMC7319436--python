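"""Positional summaries: metaplots, per-region genomic views, SVG output.

The metaplot answers "where inside the regions do the motifs sit?": for
each base-pair offset from the region center, it reports the percent of
regions in which some occurrence of the motif covers that base.  For
ChIP-seq peaks centered on their summits, a motif bound directly by the
immunoprecipitated factor shows a sharp peak at offset 0.

The genomic view lays regions out one per row — gray bars scaled to the
longest region — with motif occurrences as colored boxes and
protein-coding TSS as directional arrows, paginated with a hard cap.

All figures are emitted as SVG by a small deterministic string writer:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, intersect
from .motif_model import Motif, information_content
from .scanner import MotifOccurrence

__all__ = [
    "MetaplotMatrix",
    "MotifBox",
    "ViewLayout",
    "ViewRow",
    "genomic_view_layout",
    "metaplot",
    "metaplot_to_frame",
    "metaplot_with_control",
    "moving_average",
    "render_svg",
]

MAX_PAGES = 10


# ---------------------------------------------------------------------------
# metaplot

@dataclass
class MetaplotMatrix:
    """Percent of regions with motif coverage at each offset from center."""

    offsets: np.ndarray  # -W .. +W inclusive
    values: dict[str, np.ndarray]  # motif_id -> percent per offset
    n_regions: int


def metaplot(
    regions: list[GenomicInterval],
    assigned: dict[int, list[MotifOccurrence]],
    motifs: list[Motif],
    half_width: int | None = None,
) -> MetaplotMatrix:
    """Coverage metaplot around region centers.

    At offset d, a region counts for motif m iff some occurrence of m
    covers the single base ``center + d`` (center = floor((start+end)/2)),
    the base also lying inside the region.  Offsets outside a short region
    keep that region in the denominator.  ``half_width`` defaults to half
    the maximum region length.
    """
    if not regions:
        raise ValueError("metaplot needs at least one region")
    if half_width is None:
        half_width = max(len(r) for r in regions) // 2
    W = int(half_width)
    offsets = np.arange(-W, W + 1)
    n_off = len(offsets)
    values = {m.id: np.zeros(n_off) for m in motifs}
    covered = {m.id: np.zeros(n_off, dtype=bool) for m in motifs}
    for i, r in enumerate(regions):
        center = (r.start + r.end) // 2
        for arr in covered.values():
            arr[:] = False
        for occ in assigned.get(i, []):
            if occ.motif_id not in covered:
                continue
            lo = max(occ.interval.start, r.start) - center
            hi = min(occ.interval.end, r.end) - center
            lo, hi = max(lo, -W), min(hi, W + 1)
            if lo < hi:
                covered[occ.motif_id][lo + W : hi + W] = True
        for mid, arr in covered.items():
            values[mid] += arr
    for mid in values:
        values[mid] = 100.0 * values[mid] / len(regions)
    return MetaplotMatrix(offsets=offsets, values=values, n_regions=len(regions))


def metaplot_with_control(
    regions: list[GenomicInterval],
    controls: list[GenomicInterval],
    occ_input: dict[int, list[MotifOccurrence]],
    occ_ctrl: dict[int, list[MotifOccurrence]],
    motifs: list[Motif],
    half_width: int | None = None,
) -> tuple[MetaplotMatrix, MetaplotMatrix]:
    """Input and control metaplots over one shared offset axis."""
    if half_width is None:
        half_width = max(len(r) for r in regions) // 2
    return (
        metaplot(regions, occ_input, motifs, half_width),
        metaplot(controls, occ_ctrl, motifs, half_width),
    )


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average for display smoothing (raw values are kept)."""
    if width <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(width) / width
    padded = np.pad(np.asarray(values, dtype=float), width, mode="edge")
    return np.convolve(padded, kernel, mode="same")[width:-width]


def metaplot_to_frame(mp: MetaplotMatrix) -> pd.DataFrame:
    data = {"offset": mp.offsets}
    for mid in sorted(mp.values):
        data[mid] = np.round(mp.values[mid], 6)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# genomic view

@dataclass
class MotifBox:
    """One occurrence drawn inside a region row."""

    offset: int  # bp from region start
    length: int
    strand: str
    motif_id: str
    score: float
    pvalue: float
    matched_seq: str


@dataclass
class ViewRow:
    region: GenomicInterval
    rel_length: float  # region length / max region length, in (0, 1]
    boxes: list[MotifBox] = field(default_factory=list)
    tss: list[tuple[int, str]] = field(default_factory=list)  # (offset, strand)


@dataclass
class ViewLayout:
    pages: list[list[ViewRow]]
    truncated: int  # regions with occurrences that did not fit the page cap


def genomic_view_layout(
    regions: list[GenomicInterval],
    assigned: dict[int, list[MotifOccurrence]],
    tss: list[GenomicInterval] | None = None,
    rows_per_page: int = 25,
    max_pages: int = MAX_PAGES,
) -> ViewLayout:
    """Rows for every region holding >= 1 occurrence, paginated.

    Bar lengths are scaled to the longest displayed region; rendering is
    capped at ``max_pages`` pages and the number of regions beyond the cap
    is reported instead of drawn.
    """
    kept = [(i, r) for i, r in enumerate(regions) if assigned.get(i)]
    if not kept:
        return ViewLayout(pages=[], truncated=0)
    max_len = max(len(r) for _, r in kept)
    tss_pairs = intersect([r for _, r in kept], tss) if tss else []
    tss_by_region: dict[int, list[tuple[int, str]]] = {}
    if tss_pairs:
        id_to_idx = {id(r): i for i, r in kept}
        for r, t in tss_pairs:
            tss_by_region.setdefault(id_to_idx[id(r)], []).append(
                (t.start - r.start, t.strand)
            )
    rows: list[ViewRow] = []
    for i, r in kept:
        boxes = [
            MotifBox(
                offset=o.interval.start - r.start,
                length=len(o.interval),
                strand=o.strand,
                motif_id=o.motif_id,
                score=o.score,
                pvalue=o.pvalue,
                matched_seq=o.matched_seq,
            )
            for o in sorted(
                assigned[i], key=lambda o: (o.interval.start, o.strand, o.motif_id)
            )
        ]
        rows.append(
            ViewRow(
                region=r,
                rel_length=len(r) / max_len,
                boxes=boxes,
                tss=sorted(tss_by_region.get(i, [])),
            )
        )
    capacity = rows_per_page * max_pages
    truncated = max(0, len(rows) - capacity)
    rows = rows[:capacity]
    pages = [rows[k : k + rows_per_page] for k in range(0, len(rows), rows_per_page)]
    return ViewLayout(pages=pages, truncated=truncated)


def view_layout_to_jsonl(layout: ViewLayout) -> str:
    """Line-delimited JSON export of the layout for downstream tooling."""
    import json

    lines = []
    for p, page in enumerate(layout.pages):
        for row in page:
            lines.append(
                json.dumps(
                    {
                        "page": p,
                        "region": f"{row.region.chrom}:{row.region.start}-{row.region.end}",
                        "rel_length": round(row.rel_length, 6),
                        "boxes": [
                            {
                                "offset": b.offset,
                                "length": b.length,
                                "strand": b.strand,
                                "motif_id": b.motif_id,
                                "score": round(b.score, 4),
                                "pvalue": float(f"{b.pvalue:.4g}"),
                                "seq": b.matched_seq,
                            }
                            for b in row.boxes
                        ],
                        "tss": [{"offset": o, "strand": s} for o, s in row.tss],
                    },
                    sort_keys=True,
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# SVG rendering (deterministic string writer)

def _f(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


class _SVG:
    def __init__(self, width: float, height: float) -> None:
        self.width, self.height = width, height
        self.parts: list[str] = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
            f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">'
        ]

    def rect(self, x, y, w, h, fill, opacity=None, title=None):
        extra = f' fill-opacity="{_f(opacity)}"' if opacity is not None else ""
        body = (
            f'<rect x="{_f(x)}" y="{_f(y)}" width="{_f(w)}" height="{_f(h)}" '
            f'fill="{fill}"{extra}'
        )
        if title:
            self.parts.append(body + f"><title>{title}</title></rect>")
        else:
            self.parts.append(body + "/>")

    def line(self, x1, y1, x2, y2, stroke="#000000", width=1.0):
        self.parts.append(
            f'<line x1="{_f(x1)}" y1="{_f(y1)}" x2="{_f(x2)}" y2="{_f(y2)}" '
            f'stroke="{stroke}" stroke-width="{_f(width)}"/>'
        )

    def polyline(self, points, stroke, width=1.5):
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in points)
        self.parts.append(
            f'<polyline points="{pts}" fill="none" stroke="{stroke}" '
            f'stroke-width="{_f(width)}"/>'
        )

    def polygon(self, points, fill):
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in points)
        self.parts.append(f'<polygon points="{pts}" fill="{fill}"/>')

    def circle(self, cx, cy, r, fill, title=None):
        body = f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r)}" fill="{fill}"'
        if title:
            self.parts.append(body + f"><title>{title}</title></circle>")
        else:
            self.parts.append(body + "/>")

    def text(self, x, y, s, size=10.0, anchor="start", fill="#000000", transform=None):
        tr = f' transform="{transform}"' if transform else ""
        self.parts.append(
            f'<text x="{_f(x)}" y="{_f(y)}" font-size="{_f(size)}" '
            f'font-family="sans-serif" text-anchor="{anchor}" fill="{fill}"{tr}>'
            f"{s}</text>"
        )

    def tostring(self) -> str:
        return "\n".join(self.parts + ["</svg>"]) + "\n"


_LOGO_COLORS = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}


def _draw_logo(svg: _SVG, motif: Motif, x: float, y: float, width: float, height: float):
    """Sequence logo: letter heights proportional to column IC (bits, max 2)."""
    L = motif.length
    col_w = width / L
    for i in range(L):
        col = motif.frequencies[i]
        ic = information_content(col[None, :])
        ybase = y + height
        for b in np.argsort(col):  # draw small letters first, stack upward
            fheight = float(col[b]) * ic / 2.0 * height
            if fheight < 0.5:
                continue
            base = "ACGT"[int(b)]
            # scale a 10px glyph to the stack slice
            sy = fheight / 10.0
            sx = col_w / 8.0
            svg.text(
                0,
                0,
                base,
                size=10.0,
                anchor="middle",
                fill=_LOGO_COLORS[base],
                transform=(
                    f"translate({_f(x + i * col_w + col_w / 2)},{_f(ybase)}) "
                    f"scale({_f(sx)},{_f(sy)})"
                ),
            )
            ybase -= fheight


def _render_metaplot(
    mp: MetaplotMatrix,
    motifs: list[Motif] | None,
    control: MetaplotMatrix | None = None,
) -> str:
    W, H = 640.0, 400.0
    ml, mr, mt, mb = 60.0, 170.0, 30.0, 50.0
    pw, ph = W - ml - mr, H - mt - mb
    svg = _SVG(W, H)
    ymax = max(
        [float(v.max()) for v in mp.values.values()]
        + ([float(v.max()) for v in control.values.values()] if control else [])
        + [1e-9]
    )
    ymax = max(ymax, 1.0)
    xs = mp.offsets
    colors = {m.id: m.color for m in motifs} if motifs else {}

    def xpix(off):
        return ml + (off - xs[0]) / max(1, (xs[-1] - xs[0])) * pw

    def ypix(v):
        return mt + ph - v / ymax * ph

    svg.rect(ml, mt, pw, ph, "#ffffff")
    svg.line(ml, mt + ph, ml + pw, mt + ph)
    svg.line(ml, mt, ml, mt + ph)
    svg.line(xpix(0), mt, xpix(0), mt + ph, stroke="#dddddd")
    for frac in (0.0, 0.5, 1.0):
        svg.text(ml - 6, ypix(ymax * frac) + 3, _f(ymax * frac), anchor="end", size=9)
    for off in (int(xs[0]), 0, int(xs[-1])):
        svg.text(xpix(off), mt + ph + 14, str(off), anchor="middle", size=9)
    svg.text(ml + pw / 2, H - 12, "offset from region center (bp)", anchor="middle")
    svg.text(
        16, mt + ph / 2, "% regions with motif", anchor="middle",
        transform=f"rotate(-90 16 {_f(mt + ph / 2)})",
    )
    if control is not None:
        for mid in sorted(control.values):
            pts = [(xpix(o), ypix(v)) for o, v in zip(xs, control.values[mid])]
            svg.polyline(pts, "#999999", width=1.2)
    for mid in sorted(mp.values):
        pts = [(xpix(o), ypix(v)) for o, v in zip(xs, mp.values[mid])]
        svg.polyline(pts, colors.get(mid, "#000000"))
    # legend with sequence logos
    if motifs:
        ly = mt
        for m in motifs:
            svg.line(W - mr + 8, ly + 8, W - mr + 28, ly + 8, stroke=m.color, width=2)
            svg.text(W - mr + 34, ly + 11, m.name, size=9)
            _draw_logo(svg, m, W - mr + 34, ly + 14, min(120.0, 10.0 * m.length), 22.0)
            ly += 46
    return svg.tostring()


def _render_scatter(points: list[dict]) -> str:
    W, H = 520.0, 420.0
    ml, mr, mt, mb = 60.0, 30.0, 30.0, 50.0
    pw, ph = W - ml - mr, H - mt - mb
    svg = _SVG(W, H)
    svg.rect(ml, mt, pw, ph, "#ffffff")
    svg.line(ml, mt + ph, ml + pw, mt + ph)
    svg.line(ml, mt, ml, mt + ph)
    if points:
        ymin = min(0.0, min(p["y"] for p in points))
        ymax = max(0.5, max(p["y"] for p in points))
        cmax = max(1.0, max(p["color_value"] for p in points))
    else:
        ymin, ymax, cmax = 0.0, 1.0, 1.0
        svg.text(ml + pw / 2, mt + ph / 2, "no plottable motifs", anchor="middle")

    def xpix(v):
        return ml + v / 100.0 * pw

    def ypix(v):
        return mt + ph - (v - ymin) / (ymax - ymin or 1.0) * ph

    if ymin < 0 < ymax:
        svg.line(ml, ypix(0), ml + pw, ypix(0), stroke="#dddddd")
    for p in sorted(points, key=lambda q: q["motif_id"]):
        shade = int(40 + 200 * (1 - p["color_value"] / cmax))
        color = f"#{255 - shade:02x}2a{shade:02x}"
        svg.circle(
            xpix(p["x"]), ypix(p["y"]), 4, color,
            title=f'{p["motif_name"]} ({p["motif_id"]})',
        )
        svg.text(xpix(p["x"]) + 6, ypix(p["y"]) + 3, p["motif_name"], size=8)
    svg.text(ml + pw / 2, H - 12, "% input regions with motif", anchor="middle")
    svg.text(
        16, mt + ph / 2, "log2 fold change vs global controls", anchor="middle",
        transform=f"rotate(-90 16 {_f(mt + ph / 2)})",
    )
    return svg.tostring()


def _render_view(layout: ViewLayout, motifs: list[Motif] | None) -> str:
    row_h, bar_h = 26.0, 10.0
    W = 760.0
    ml = 180.0
    bar_w = W - ml - 40.0
    colors = {m.id: m.color for m in motifs} if motifs else {}
    names = {m.id: m.name for m in motifs} if motifs else {}
    legend_h = 50.0 + 30.0 * (len(motifs) if motifs else 0)
    if not layout.pages:
        svg = _SVG(W, 60)
        svg.text(W / 2, 32, "no regions contain a motif occurrence", anchor="middle")
        return svg.tostring()
    page_h = max(len(p) for p in layout.pages) * row_h + 40.0
    H = len(layout.pages) * page_h + legend_h + (20.0 if layout.truncated else 0.0)
    svg = _SVG(W, H)
    y = 0.0
    for pnum, page in enumerate(layout.pages, start=1):
        svg.text(8, y + 16, f"page {pnum}", size=11)
        ry = y + 28.0
        for row in page:
            r = row.region
            label = f"{r.chrom}:{r.start + 1:,}-{r.end:,}"  # 1-based for display
            svg.text(8, ry + bar_h, label, size=9)
            blen = bar_w * row.rel_length
            svg.rect(ml, ry + 3, blen, bar_h, "#bbbbbb", title=label)
            scale = blen / len(r)
            for box in row.boxes:
                bx = ml + box.offset * scale
                bw = max(1.5, box.length * scale)
                svg.rect(
                    max(ml, bx), ry + 1, bw, bar_h + 4,
                    colors.get(box.motif_id, "#333333"),
                    title=(
                        f"{names.get(box.motif_id, box.motif_id)} {box.strand} "
                        f"{box.matched_seq} score={box.score:.2f} "
                        f"P={box.pvalue:.3g}"
                    ),
                )
            for off, strand in row.tss:
                tx = ml + off * scale
                dx = 6.0 if strand != "-" else -6.0
                svg.polygon(
                    [(tx, ry - 2), (tx, ry + 4), (tx + dx, ry + 1)], "#000000"
                )
            ry += row_h
        y += page_h
    if layout.truncated:
        svg.text(8, y + 12, f"... {layout.truncated} more regions not shown", size=10)
        y += 20.0
    svg.text(8, y + 18, "legend", size=11)
    ly = y + 26.0
    for m in motifs or []:
        svg.rect(8, ly + 2, 14, 10, m.color)
        svg.text(28, ly + 11, f"{m.name} ({m.id})", size=9)
        _draw_logo(svg, m, 170, ly, min(140.0, 12.0 * m.length), 24.0)
        ly += 30.0
    return svg.tostring()


def render_svg(
    obj,
    path,
    motifs: list[Motif] | None = None,
    control: MetaplotMatrix | None = None,
) -> None:
    """Render a ViewLayout, MetaplotMatrix or scatter point list to SVG.

    Output bytes are a pure function of the inputs (determinism contract);
    text labels only, no embedded fonts.
    """
    if isinstance(obj, ViewLayout):
        text = _render_view(obj, motifs)
    elif isinstance(obj, MetaplotMatrix):
        text = _render_metaplot(obj, motifs, control)
    elif isinstance(obj, list):
        text = _render_scatter(obj)
    else:
        raise TypeError(f"cannot render object of type {type(obj).__name__}")
    with open(path, "w") as fh:
        fh.write(text)
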