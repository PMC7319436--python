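"""Motif parsing, information content and exact score-distribution P-values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motiflens import (
    Background,
    counts_to_frequencies,
    dynamic_threshold,
    information_content,
    log_odds,
    motif_from_sequence,
    parse_jaspar,
    pvalue_of_score,
    score_distribution,
    score_of_pvalue,
    write_jaspar,
)
from motiflens.motif_model import JasparParseError

from helpers import (
    enum_mass_near,
    enum_pvalue,
    enumerate_kmer_scores,
    random_count_matrix,
)

JASPAR_TEXT = """\
>MA0001.1 AGL3
A [ 10 0 ]
C [ 0 10 ]
G [ 0 0 ]
T [ 0 0 ]
>MA0002.1 RUNX1
A [ 3 1 ]
C [ 1 0 ]
G [ 0 3 ]
T [ 0 0 ]
"""


class TestParseJaspar:
    def test_counts_transcribed(self):
        motifs = parse_jaspar(JASPAR_TEXT)
        assert [m.id for m in motifs] == ["MA0001.1", "MA0002.1"]
        assert motifs[0].name == "AGL3"
        assert motifs[0].length == 2
        np.testing.assert_array_equal(
            motifs[0].counts, [[10, 0, 0, 0], [0, 10, 0, 0]]
        )

    def test_empty_input_gives_empty_list(self):
        assert parse_jaspar("") == []

    def test_unequal_row_lengths_rejected_with_record_name(self):
        bad = ">MA0003.1 X\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n"
        with pytest.raises(JasparParseError, match="MA0003.1"):
            parse_jaspar(bad)

    def test_malformed_row_names_line(self):
        bad = ">MA0003.1 X\nA [ 1 2 ]\nQ [ 1 2 ]\n"
        with pytest.raises(JasparParseError, match="line 3"):
            parse_jaspar(bad)

    def test_roundtrip_preserves_counts_exactly(self, rng):
        counts = random_count_matrix(rng, 7)
        text = f">MA0007.2 DEMO\n" + "\n".join(
            f"{b} [ {' '.join(str(int(v)) for v in counts[:, i])} ]"
            for i, b in enumerate("ACGT")
        )
        first = parse_jaspar(text)
        second = parse_jaspar(write_jaspar(first))
        np.testing.assert_array_equal(first[0].counts, second[0].counts)
        assert first[0].id == second[0].id and first[0].name == second[0].name


class TestCountsToFrequencies:
    def test_zero_pseudocount_is_plain_normalisation(self):
        f = counts_to_frequencies(np.array([[4, 0, 0, 0.0]]), pseudocount=0)
        np.testing.assert_allclose(f, [[1, 0, 0, 0]])

    def test_pseudocount_split_by_background(self):
        f = counts_to_frequencies(np.array([[3, 1, 0, 0.0]]), pseudocount=1)
        np.testing.assert_allclose(f, [[3.25 / 5, 1.25 / 5, 0.25 / 5, 0.25 / 5]])

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            counts_to_frequencies(np.array([[1, 1, 1, 1], [0, 0, 0, 0.0]]))

    @given(st.integers(1, 8), st.floats(0.0, 5.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_rows_always_sum_to_one(self, length, pseudocount, seed):
        counts = random_count_matrix(np.random.default_rng(seed), length)
        f = counts_to_frequencies(counts, pseudocount)
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-9)


class TestInformationContent:
    def test_uniform_column_is_zero(self):
        assert information_content(np.full((1, 4), 0.25)) == pytest.approx(0, abs=1e-12)

    def test_deterministic_lmer_is_two_bits_per_column(self):
        f = np.zeros((4, 4))
        f[np.arange(4), [0, 1, 2, 3]] = 1.0
        assert information_content(f) == pytest.approx(8.0, abs=1e-12)

    def test_half_half_column_is_one_bit(self):
        assert information_content(np.array([[0.5, 0.5, 0, 0]])) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_zero_iff_background(self, rng):
        # any non-background matrix has strictly positive IC (KL >= 0)
        counts = random_count_matrix(rng, 5)
        f = counts_to_frequencies(counts, 1.0)
        assert information_content(f) > 0
        assert information_content(f) <= 2 * 5


class TestDynamicThreshold:
    @pytest.mark.parametrize("ic,expected", [(0, 1.0), (2, 0.25), (20, 2.0**-20)])
    def test_closed_form(self, ic, expected):
        assert dynamic_threshold(ic) == pytest.approx(expected, rel=1e-12)

    def test_additivity(self):
        assert dynamic_threshold(3.7) * dynamic_threshold(1.3) == pytest.approx(
            dynamic_threshold(5.0), rel=1e-12
        )

    def test_negative_ic_rejected(self):
        with pytest.raises(ValueError):
            dynamic_threshold(-0.1)


class TestLogOdds:
    def test_uniform_scores_zero(self):
        lom = log_odds(np.full((3, 4), 0.25))
        np.testing.assert_allclose(lom, 0.0, atol=1e-12)

    def test_cell_formula(self):
        lom = log_odds(np.array([[0.5, 0.25, 0.125, 0.125]]))
        np.testing.assert_allclose(lom, [[1.0, 0.0, -1.0, -1.0]], atol=1e-12)

    def test_zero_frequency_without_floor_rejected(self):
        with pytest.raises(ValueError):
            log_odds(np.array([[1.0, 0, 0, 0]]), freq_floor=None)


class TestScoreDistribution:
    def test_single_uniform_column_is_point_mass(self, uniform_bg):
        dist = score_distribution(log_odds(np.full((1, 4), 0.25)), uniform_bg)
        assert len(dist.support) == 1
        assert dist.pmf[0] == pytest.approx(1.0)
        assert dist.support[0] == pytest.approx(0.0, abs=1e-3)

    def test_dinucleotide_pmf_matches_enumeration_exactly(self, uniform_bg):
        # all 16 dinucleotides have probability 1/16; the pmf must place
        # exactly that mass on each attained (grid-rounded) score sum
        f = np.tile([0.7, 0.1, 0.1, 0.1], (2, 1))
        lom = log_odds(f, uniform_bg)
        g = 1e-3
        dist = score_distribution(lom, uniform_bg, granularity=g)
        import itertools

        expected: dict[int, float] = {}
        cell = np.rint(lom / g).astype(int)
        for kmer in itertools.product(range(4), repeat=2):
            key = int(sum(cell[i, b] for i, b in enumerate(kmer)))
            expected[key] = expected.get(key, 0.0) + 1.0 / 16.0
        got = {
            int(round(s / g)): p for s, p in zip(dist.support, dist.pmf)
        }
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_matrices_match_enumeration(self, seed, uniform_bg):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 7))
        lom = log_odds(counts_to_frequencies(random_count_matrix(rng, L), 1.0))
        dist = score_distribution(lom, uniform_bg)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        kmers = enumerate_kmer_scores(lom, uniform_bg)
        # per-cell rounding can shift a k-mer's summed score by up to
        # L*granularity/2, so the comparison tolerance is the enumeration
        # mass within that window of s
        drift = (L / 2 + 1) * dist.granularity
        for s in rng.uniform(dist.min_score, dist.max_score, size=12):
            tol = enum_mass_near(kmers, s, drift) + 1e-9
            assert abs(pvalue_of_score(dist, s) - enum_pvalue(kmers, s)) <= tol

    def test_survival_is_monotone(self, uniform_bg, rng):
        lom = log_odds(counts_to_frequencies(random_count_matrix(rng, 5), 1.0))
        dist = score_distribution(lom, uniform_bg)
        assert np.all(np.diff(dist.sf) <= 1e-15)


class TestPvalueScoreQueries:
    def test_extremes(self, uniform_bg, rng):
        lom = log_odds(counts_to_frequencies(random_count_matrix(rng, 4), 1.0))
        dist = score_distribution(lom, uniform_bg)
        assert pvalue_of_score(dist, dist.min_score - 1) == 1.0
        assert pvalue_of_score(dist, dist.max_score + 1) == 0.0

    def test_p_of_one_gives_min_score(self, uniform_bg, rng):
        lom = log_odds(counts_to_frequencies(random_count_matrix(rng, 4), 1.0))
        dist = score_distribution(lom, uniform_bg)
        assert score_of_pvalue(dist, 1.0) == pytest.approx(dist.min_score)

    def test_roundtrip_bound(self, uniform_bg, rng):
        lom = log_odds(counts_to_frequencies(random_count_matrix(rng, 5), 1.0))
        dist = score_distribution(lom, uniform_bg)
        for p in (1.0, 0.5, 0.1, 1e-2, 1e-3):
            s = score_of_pvalue(dist, p)
            assert pvalue_of_score(dist, s) <= p + 1e-15

    def test_deterministic_motif_consensus_is_unique_passer(self):
        m = motif_from_sequence("ACGTAC")
        lom = log_odds(m.frequencies)
        dist = score_distribution(lom)
        s_min = score_of_pvalue(dist, m.threshold_p)
        assert s_min == pytest.approx(2 * 6, abs=1e-2)  # the maximal score
        assert pvalue_of_score(dist, s_min) == pytest.approx(4.0**-6, rel=1e-9)

    def test_invalid_p_rejected(self, uniform_bg, rng):
        lom = log_odds(counts_to_frequencies(random_count_matrix(rng, 3), 1.0))
        dist = score_distribution(lom, uniform_bg)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                score_of_pvalue(dist, bad)


class TestMotifFromSequence:
    def test_forced_attributes(self):
        m = motif_from_sequence("ACGTAC")
        assert m.length == 6
        assert m.information_content() == pytest.approx(12.0, abs=1e-9)
        assert m.threshold_p == pytest.approx(4.0**-6)
        assert m.consensus == "ACGTAC"

    @pytest.mark.parametrize("bad", ["ACGT", "ACGTACGTACGTA", "ACGTNN", "acg tac"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            motif_from_sequence(bad)
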