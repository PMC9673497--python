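import re
from itertools import islice

import numpy as np
import pytest
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from stimgene.pattern_mining import (
    PatternStats,
    SlaapPattern,
    SlnPattern,
    _slnp_from_index,
    _slnp_presence_counts,
    _slnp_space_size,
    bh_adjust,
    chi2_presence,
    co_occurrence_count,
    enumerate_slaaps,
    enumerate_slnps,
    flag_slaaps,
    flag_slnps,
    idr_conditional_frequency,
    pattern_present,
    top_k,
)
from stimgene.protein_features import AMINO_ACIDS


class TestEnumeration:
    def test_length3_count_and_uniqueness(self):
        texts = {p.text for p in enumerate_slnps(3)}
        assert len(texts) == 2940

    def test_length4_count(self):
        assert sum(1 for _ in enumerate_slnps(4)) == 44100

    def test_length5_closed_form_and_sampled_uniqueness(self, rng):
        assert _slnp_space_size(5) == 661500
        sample_idx = rng.choice(661500, size=2000, replace=False)
        sampled = {_slnp_from_index(5, int(i)).text for i in sample_idx}
        assert len(sampled) == 2000

    def test_ends_never_full_set(self):
        for p in islice(enumerate_slnps(3), 0, 2940, 97):
            assert len(p.positions[0]) <= 3 and len(p.positions[-1]) <= 3

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            list(enumerate_slnps(6))

    def test_slaap_3fixed_subtotal(self):
        count = sum(1 for p in enumerate_slaaps() if len(p.fixed) == 3)
        assert count == 32_000

    def test_slaap_membership(self):
        kens = [p for p in islice(enumerate_slaaps(), 32_000) if p.text == "KEN"]
        assert len(kens) == 1

    def test_index_decode_matches_enumeration_order(self):
        patterns = list(enumerate_slnps(3))
        for i in (0, 1, 17, 2939):
            assert _slnp_from_index(3, i).text == patterns[i].text


class TestPatternText:
    @pytest.mark.parametrize("text", ["T[AT]AAA", "ATA[AG][GT]", "AxT", "[ACG]x[AT]C"])
    def test_slnp_parse_round_trip(self, text):
        assert SlnPattern.parse(text).text == text

    def test_bracket_classes_canonicalised_to_base_order(self):
        assert SlnPattern.parse("ATA[AG][TG]").text == "ATA[AG][GT]"

    @pytest.mark.parametrize("text", ["SxNxE", "KEN", "LxNL", "KxExL"])
    def test_slaap_parse_round_trip(self, text):
        assert SlaapPattern.parse(text).text == text

    def test_slnp_end_constraint(self):
        with pytest.raises(ValueError):
            SlnPattern.parse("xAT")


class TestPatternPresent:
    def test_slnp_span(self):
        p = SlnPattern.parse("T[AT]AAA")
        assert pattern_present(p, "GGTTAAAG", return_spans=True) == [(2, 7)]

    def test_slaap_span(self):
        p = SlaapPattern.parse("SxNxE")
        assert pattern_present(p, "MSKNAEG", return_spans=True) == [(1, 6)]

    def test_slaap_no_match(self):
        assert pattern_present(SlaapPattern.parse("KEN"), "KEQ") is False

    def test_wildcard_rejects_nonstandard(self):
        assert pattern_present(SlaapPattern.parse("KxNA"), "KXNA") is False
        assert pattern_present(SlaapPattern.parse("KxNA"), "KMNA") is True

    def test_alphabet_mismatch(self):
        with pytest.raises(ValueError):
            pattern_present(SlnPattern.parse("AAA"), "KEN")


def _slnp_regex(pattern):
    parts = []
    for subset in pattern.positions:
        bases = "".join(sorted(subset))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def _slaap_regex(pattern):
    parts = [pattern.fixed[0]]
    for aa, gap in zip(pattern.fixed[1:], pattern.gaps):
        if gap:
            parts.append(f"[{AMINO_ACIDS}]")
        parts.append(aa)
    return re.compile("".join(parts))


class TestRegexOracle:
    def test_slnp_agrees_with_regex(self, rng):
        space3 = list(enumerate_slnps(3))
        for _ in range(1500):
            length = int(rng.integers(3, 5 + 1))
            if length == 3:
                pattern = space3[int(rng.integers(len(space3)))]
            else:
                pattern = _slnp_from_index(length, int(rng.integers(_slnp_space_size(length))))
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(3, 40)),
                                     p=[0.235] * 4 + [0.06]))
            assert pattern_present(pattern, seq) == bool(_slnp_regex(pattern).search(seq))

    def test_slaap_agrees_with_regex(self, rng):
        slaaps = list(islice(enumerate_slaaps(), 0, 1_312_000, 1777))
        for _ in range(1500):
            pattern = slaaps[int(rng.integers(len(slaaps)))]
            seq = "".join(rng.choice(list(AMINO_ACIDS + "X"), size=int(rng.integers(3, 60))))
            assert pattern_present(pattern, seq) == bool(_slaap_regex(pattern).search(seq))


class TestChi2:
    def test_derived_example(self):
        stat, p = chi2_presence(8, 2, 2, 8)
        assert stat == pytest.approx(7.2)
        assert p == pytest.approx(0.0072903580915, rel=1e-9)

    def test_no_association(self):
        assert chi2_presence(5, 5, 5, 5) == (0.0, 1.0)

    def test_perfect_association(self):
        stat, _ = chi2_presence(10, 0, 0, 10)
        assert stat == pytest.approx(20.0)

    def test_zero_margin_flagged(self):
        stat, p = chi2_presence(0, 10, 0, 10)
        assert np.isnan(stat) and np.isnan(p)

    def test_against_scipy(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, size=4)
            stat, p = chi2_presence(a, b, c, d)
            res = chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(res[0], rel=1e-12)
            assert p == pytest.approx(res[1], rel=1e-9)


class TestBhAdjust:
    def test_derived_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])

    def test_single(self):
        assert list(bh_adjust([0.05])) == [0.05]

    def test_all_equal(self):
        assert list(bh_adjust([0.2, 0.2, 0.2])) == pytest.approx([0.2, 0.2, 0.2])

    def test_against_statsmodels(self, rng):
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(list(expected), rel=1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(list(bh_adjust(p[perm])), rel=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestPresenceCounts:
    def test_fast_counts_match_direct_scan(self, rng):
        seqs = ["".join(rng.choice(list("ACGTN"), size=60, p=[0.24] * 4 + [0.04]))
                for _ in range(15)]
        counts = _slnp_presence_counts(seqs, 3)
        patterns = list(enumerate_slnps(3))
        for i in rng.choice(2940, size=120, replace=False):
            expected = sum(pattern_present(patterns[i], s) for s in seqs)
            assert counts[i] == expected


def _seqs_with(motif, n_with, n_without, rng, length=30):
    out = []
    for i in range(n_with + n_without):
        seq = "".join(rng.choice(list("CG"), size=length))  # motif-free background
        if i < n_with:
            pos = int(rng.integers(0, length - len(motif)))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        out.append(seq)
    return out


class TestFlagSlnps:
    def test_single_strong_pattern_flagged(self, rng):
        pos = _seqs_with("AATTA", 8, 2, rng)
        neg = _seqs_with("AATTA", 2, 8, rng)
        flagged = flag_slnps(pos, neg, min_freq_diff=0.05, alpha_adj=0.05, lengths=(5,))
        texts = {s.pattern.text for s in flagged}
        assert "AATTA" in texts
        stats = next(s for s in flagged if s.pattern.text == "AATTA")
        assert (stats.a, stats.b, stats.c, stats.d) == (8, 2, 2, 8)
        assert stats.chi2 == pytest.approx(7.2)

    def test_small_freq_diff_never_flagged(self, rng):
        # same presence frequencies in both classes -> diff 0 < cutoff
        seqs = _seqs_with("AATTA", 5, 5, rng)
        flagged = flag_slnps(seqs, list(seqs), lengths=(3,))
        assert flagged == []

    def test_identical_classes_no_flags(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(10)]
        assert flag_slnps(seqs, list(seqs), lengths=(3,)) == []

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            flag_slnps([], ["ACGT"])

    def test_alpha_anti_monotone(self, rng):
        pos = ["".join(rng.choice(list("ACGT"), size=60, p=[0.4, 0.1, 0.1, 0.4]))
               for _ in range(30)]
        neg = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(30)]
        strict = {s.pattern.text for s in
                  flag_slnps(pos, neg, alpha_adj=0.01, lengths=(3,))}
        loose = {s.pattern.text for s in
                 flag_slnps(pos, neg, alpha_adj=0.10, lengths=(3,))}
        assert strict <= loose

    def test_ranked_by_adjusted_p(self, rng):
        pos = ["".join(rng.choice(list("ACGT"), size=60, p=[0.4, 0.1, 0.1, 0.4]))
               for _ in range(30)]
        neg = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(30)]
        flagged = flag_slnps(pos, neg, alpha_adj=0.5, lengths=(3,))
        p_adj = [s.p_adj for s in flagged]
        assert p_adj == sorted(p_adj)


class TestFlagSlaaps:
    def test_planted_motif_flagged(self, rng):
        # planted prevalences mirror the generator defaults (15.2% / 8.8%)
        n = 500
        pattern = SlaapPattern.parse("SxNxE")
        pos, neg = [], []
        for i in range(n):
            base = "".join(rng.choice(list("GAVLIP"), size=40))  # motif-free
            pos.append("SANTE" + base if i < round(0.152 * n) else base)
            neg.append("SANTE" + base if i < round(0.088 * n) else base)
        flagged = flag_slaaps(pos, neg, alpha=0.05)
        assert "SxNxE" in {s.pattern.text for s in flagged}

    def test_absent_motif_not_flagged(self, rng):
        seqs = ["".join(rng.choice(list("GAVLIP"), size=30)) for _ in range(20)]
        flagged = flag_slaaps(seqs, list(seqs))
        assert flagged == []

    def test_direction_requirement(self, rng):
        n = 200
        pos, neg = [], []
        for i in range(n):
            base = "".join(rng.choice(list("GAVLIP"), size=40))
            pos.append("KEN" + base if i < 30 else base)
            neg.append("KEN" + base if i < 120 else base)
        flagged = flag_slaaps(neg, pos)  # enriched class first -> flagged
        assert "KEN" in {s.pattern.text for s in flagged}
        swapped = flag_slaaps(pos, neg)  # depleted in "positives" -> not flagged
        assert "KEN" not in {s.pattern.text for s in swapped}


class TestTopK:
    def _fake(self, n):
        return [PatternStats(SlaapPattern.parse("KEN"), 0.5, 0.1, 5, 5, 1, 9,
                             4.0, 0.01 * (i + 1), 0.02 * (i + 1)) for i in range(n)]

    def test_truncates(self):
        assert len(top_k(self._fake(200), 100)) == 100

    def test_fewer_than_k(self):
        assert len(top_k(self._fake(3), 100)) == 3

    def test_zero(self):
        assert top_k(self._fake(3), 0) == []


class TestCoOccurrence:
    def test_counts(self):
        patterns = [SlaapPattern.parse("KEN"), SlaapPattern.parse("ENS")]
        assert co_occurrence_count(patterns, "MKENSAE") == 2
        assert co_occurrence_count(patterns, "MGGG") == 0

    def test_bounded(self, rng):
        patterns = [SlaapPattern.parse(t) for t in ("KEN", "SxEA", "LxNL")]
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
            assert 0 <= co_occurrence_count(patterns, seq) <= 3


class TestIdrConditionalFrequency:
    def test_fully_disordered(self):
        p = SlaapPattern.parse("KEN")
        assert idr_conditional_frequency(p, ["MKENG"], [[1.0] * 5]) == 1.0

    def test_fully_ordered(self):
        p = SlaapPattern.parse("KEN")
        assert idr_conditional_frequency(p, ["MKENG"], [[0.0] * 5]) == 0.0

    def test_span_must_stay_inside(self):
        p = SlaapPattern.parse("SxNxE")
        scores = [0.9, 0.9, 0.9, 0.9, 0.4]
        assert idr_conditional_frequency(p, ["SKNTE"], [scores]) == 0.0

    def test_pooled_over_proteins(self):
        p = SlaapPattern.parse("KEN")
        proteins = ["MKENG", "AKENA"]
        scores = [[1.0] * 5, [0.0] * 5]
        assert idr_conditional_frequency(p, proteins, scores) == 0.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            idr_conditional_frequency(SlaapPattern.parse("KEN"), ["MKENG"], [[1.0]])
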