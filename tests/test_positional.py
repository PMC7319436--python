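"""Metaplot coverage arithmetic, genomic-view layout and SVG rendering."""

import numpy as np
import pytest

from motiflens import (
    Genome,
    GenomicInterval,
    genomic_view_layout,
    metaplot,
    metaplot_to_frame,
    metaplot_with_control,
    motif_from_sequence,
    render_svg,
    scan_regions,
)
from motiflens.positional import ViewLayout, moving_average, view_layout_to_jsonl
from motiflens.scanner import MotifOccurrence

from helpers import random_sequence


def occ(chrom, start, end, motif_id="M1"):
    return MotifOccurrence(
        GenomicInterval(chrom, start, end), motif_id, "+", 10.0, 1e-4, "A" * (end - start)
    )


MOTIF = motif_from_sequence("ACGTAC")


class TestMetaplot:
    def test_center_coverage_is_100(self):
        regions = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        assigned = {0: [occ("c", 45, 55, MOTIF.id)], 1: [occ("c", 245, 255, MOTIF.id)]}
        mp = metaplot(regions, assigned, [MOTIF], half_width=20)
        assert mp.values[MOTIF.id][np.where(mp.offsets == 0)[0][0]] == 100.0

    def test_no_occurrences_all_zero(self):
        regions = [GenomicInterval("c", 0, 100)]
        mp = metaplot(regions, {0: []}, [MOTIF], half_width=10)
        assert np.all(mp.values[MOTIF.id] == 0.0)

    def test_halfopen_footprint_coverage(self):
        # region [0,100): center 50; occurrence [47,53) covers offsets -3..+2
        regions = [GenomicInterval("c", 0, 100)]
        mp = metaplot(regions, {0: [occ("c", 47, 53, MOTIF.id)]}, [MOTIF], half_width=5)
        expected = {-3, -2, -1, 0, 1, 2}
        for off, val in zip(mp.offsets, mp.values[MOTIF.id]):
            assert val == (100.0 if off in expected else 0.0)

    def test_short_region_stays_in_denominator(self):
        regions = [GenomicInterval("c", 0, 10), GenomicInterval("c", 100, 200)]
        assigned = {0: [], 1: [occ("c", 120, 126, MOTIF.id)]}
        mp = metaplot(regions, assigned, [MOTIF], half_width=40)
        # offset -30 lies outside the 10bp region but inside the 100bp one
        i = np.where(mp.offsets == -30)[0][0]
        assert mp.values[MOTIF.id][i] == 50.0

    def test_default_half_width_is_half_max_region(self):
        regions = [GenomicInterval("c", 0, 100), GenomicInterval("c", 0, 50)]
        mp = metaplot(regions, {0: [], 1: []}, [MOTIF])
        assert mp.offsets[0] == -50 and mp.offsets[-1] == 50

    def test_invariant_to_region_order_and_translation(self):
        regions = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        assigned = {0: [occ("c", 45, 51, MOTIF.id)], 1: []}
        mp1 = metaplot(regions, assigned, [MOTIF], half_width=10)
        # swap order
        mp2 = metaplot(
            regions[::-1], {0: [], 1: [occ("c", 45, 51, MOTIF.id)]}, [MOTIF], 10
        )
        np.testing.assert_array_equal(mp1.values[MOTIF.id], mp2.values[MOTIF.id])
        # translate everything by 1000
        shifted = [GenomicInterval("c", r.start + 1000, r.end + 1000) for r in regions]
        mp3 = metaplot(
            shifted, {0: [occ("c", 1045, 1051, MOTIF.id)], 1: []}, [MOTIF], 10
        )
        np.testing.assert_array_equal(mp1.values[MOTIF.id], mp3.values[MOTIF.id])

    def test_numerators_add_over_disjoint_subsets(self):
        regions = [GenomicInterval("c", i * 100, i * 100 + 60) for i in range(4)]
        assigned = {
            i: [occ("c", r.start + 28, r.start + 34, MOTIF.id)] if i % 2 else []
            for i, r in enumerate(regions)
        }
        full = metaplot(regions, assigned, [MOTIF], half_width=5)
        part1 = metaplot(regions[:2], {i: assigned[i] for i in range(2)}, [MOTIF], 5)
        part2 = metaplot(
            regions[2:], {i - 2: assigned[i] for i in range(2, 4)}, [MOTIF], 5
        )
        np.testing.assert_allclose(
            full.values[MOTIF.id] * 4, part1.values[MOTIF.id] * 2 + part2.values[MOTIF.id] * 2
        )

    def test_paired_with_control_shares_offsets(self, rng):
        genome = Genome(sequences={"c": random_sequence(rng, 2000)})
        regions = [GenomicInterval("c", 0, 100), GenomicInterval("c", 300, 400)]
        controls = [GenomicInterval("c", 600, 700), GenomicInterval("c", 900, 1000)]
        occ_in = scan_regions(genome, regions, [MOTIF])
        occ_ct = scan_regions(genome, controls, [MOTIF])
        mp_in, mp_ct = metaplot_with_control(
            regions, controls, occ_in, occ_ct, [MOTIF]
        )
        np.testing.assert_array_equal(mp_in.offsets, mp_ct.offsets)

    def test_identical_sets_give_identical_curves(self):
        regions = [GenomicInterval("c", 0, 100)]
        assigned = {0: [occ("c", 45, 51, MOTIF.id)]}
        mp_in, mp_ct = metaplot_with_control(
            regions, regions, assigned, assigned, [MOTIF], half_width=10
        )
        np.testing.assert_array_equal(mp_in.values[MOTIF.id], mp_ct.values[MOTIF.id])

    def test_moving_average_preserves_length_and_mean(self):
        v = np.array([0.0, 0, 100, 0, 0])
        sm = moving_average(v, 3)
        assert len(sm) == len(v)
        assert sm[2] == pytest.approx(100 / 3)


class TestViewLayout:
    def test_regions_without_occurrences_hidden(self):
        regions = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        layout = genomic_view_layout(regions, {0: [occ("c", 10, 16)], 1: []})
        shown = [row.region.start for page in layout.pages for row in page]
        assert shown == [0]

    def test_pagination_cap_arithmetic(self):
        regions = [GenomicInterval("c", i * 10, i * 10 + 8) for i in range(25)]
        assigned = {i: [occ("c", i * 10, i * 10 + 6)] for i in range(25)}
        layout = genomic_view_layout(regions, assigned, rows_per_page=2, max_pages=10)
        assert len(layout.pages) == 10
        assert sum(len(p) for p in layout.pages) == 20
        assert layout.truncated == 5

    def test_longest_region_has_unit_bar(self):
        regions = [GenomicInterval("c", 0, 50), GenomicInterval("c", 100, 300)]
        assigned = {0: [occ("c", 10, 16)], 1: [occ("c", 150, 156)]}
        layout = genomic_view_layout(regions, assigned)
        rels = [row.rel_length for page in layout.pages for row in page]
        assert max(rels) == 1.0 and min(rels) == pytest.approx(0.25)

    def test_tss_arrows_attached_with_offsets(self):
        regions = [GenomicInterval("c", 100, 200)]
        assigned = {0: [occ("c", 120, 126)]}
        tss = [GenomicInterval("c", 150, 151, strand="-")]
        layout = genomic_view_layout(regions, assigned, tss=tss)
        assert layout.pages[0][0].tss == [(50, "-")]

    def test_jsonl_roundtrip_is_parseable(self):
        import json

        regions = [GenomicInterval("c", 0, 100)]
        layout = genomic_view_layout(regions, {0: [occ("c", 10, 16)]})
        for line in view_layout_to_jsonl(layout).strip().split("\n"):
            rec = json.loads(line)
            assert rec["region"] == "c:0-100"


class TestRenderSvg:
    def test_empty_layout_message(self, tmp_path):
        out = tmp_path / "v.svg"
        render_svg(ViewLayout(pages=[], truncated=0), out)
        text = out.read_text()
        assert text.startswith("<svg") and "no regions" in text

    def test_byte_identical_across_runs(self, tmp_path):
        regions = [GenomicInterval("c", 0, 100)]
        assigned = {0: [occ("c", 10, 16, MOTIF.id)]}
        layout = genomic_view_layout(regions, assigned)
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_svg(layout, a, motifs=[MOTIF])
        render_svg(layout, b, motifs=[MOTIF])
        assert a.read_bytes() == b.read_bytes()

    def test_legend_contains_logo_letters(self, tmp_path):
        regions = [GenomicInterval("c", 0, 100)]
        layout = genomic_view_layout(regions, {0: [occ("c", 10, 16, MOTIF.id)]})
        out = tmp_path / "v.svg"
        render_svg(layout, out, motifs=[MOTIF])
        text = out.read_text()
        # the ACGTAC logo draws one scaled letter per consensus base
        assert text.count("scale(") >= 6 and "legend" in text

    def test_metaplot_and_scatter_render_valid_xml(self, tmp_path):
        import xml.etree.ElementTree as ET

        regions = [GenomicInterval("c", 0, 100)]
        mp = metaplot(regions, {0: [occ("c", 45, 51, MOTIF.id)]}, [MOTIF], 20)
        p1 = tmp_path / "m.svg"
        render_svg(mp, p1, motifs=[MOTIF])
        ET.fromstring(p1.read_text())
        p2 = tmp_path / "s.svg"
        render_svg(
            [{"motif_id": "M", "motif_name": "M", "x": 40.0, "y": 1.5, "color_value": 8.0}],
            p2,
        )
        ET.fromstring(p2.read_text())

    def test_unknown_object_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            render_svg(42, tmp_path / "x.svg")
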