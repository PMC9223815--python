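"""Similarity criteria, TP/FP/FN classification and the metric formulas.

The match-count alignment is checked against a brute-force enumeration
of all global alignments on tiny strings; classification is checked
against an exhaustive set-logic oracle on randomized inputs.
"""

import itertools

import numpy as np
import pytest

from circrecon import EvalCounts, classify, is_similar, match_count, metrics

BASES = "ACGT"


def brute_force_best_alignment(a, b):
    """Enumerate every global alignment; return (max score, matches at that score).

    Scoring: match +1, mismatch -1, gap -1; ties resolved toward more
    matched columns.  Exponential — only for very short strings.
    """

    def rec(i, j):
        if i == len(a) and j == len(b):
            return (0, 0)
        options = []
        if i < len(a) and j < len(b):
            s, m = rec(i + 1, j + 1)
            if a[i] == b[j]:
                options.append((s + 1, m + 1))
            else:
                options.append((s - 1, m))
        if i < len(a):
            s, m = rec(i + 1, j)
            options.append((s - 1, m))
        if j < len(b):
            s, m = rec(i, j + 1)
            options.append((s - 1, m))
        return max(options)

    return rec(0, 0)


class TestMatchCount:
    def test_identical_sequences_match_everywhere(self):
        seq = "ACGT" * 75
        assert match_count(seq, seq) == 300

    def test_disjoint_alphabets_share_nothing(self):
        assert match_count("AAAA", "CCCC") == 0

    def test_substitution_only_divergence(self):
        # 30 mismatching positions that no gapped alignment can rescue
        a = "A" * 300
        b = "A" * 270 + "C" * 30
        assert match_count(a, b) == 270

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            match_count("", "ACGT")

    def test_matches_exhaustive_enumeration_on_short_strings(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            a = "".join(rng.choice(list(BASES), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list(BASES), size=rng.integers(1, 7)))
            _, expected_m = brute_force_best_alignment(a, b)
            assert match_count(a, b) == expected_m, (a, b)


class TestSimilarity:
    def test_identical_long_sequences_are_similar(self):
        seq = "ACGT" * 75
        res = is_similar(seq, seq)
        assert res.identity_pct == 100.0
        assert res.criteria1 and res.criteria2 and res.similar
        assert abs((res.len_a + res.len_b) / 2 - res.match_count) == 0

    def test_ten_percent_divergence_fails_criterion_one(self):
        a = "A" * 300
        b = "A" * 270 + "C" * 30
        res = is_similar(a, b)
        assert res.match_count == 270
        assert res.identity_pct == pytest.approx(90.0)
        assert not res.criteria1
        assert not res.similar

    def test_single_base_pair_is_degenerate_similar(self):
        res = is_similar("G", "G")
        assert res.similar and res.identity_pct == 100.0

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = "".join(rng.choice(list(BASES), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list(BASES), size=rng.integers(5, 40)))
            assert is_similar(a, b).similar == is_similar(b, a).similar

    def test_literal_criterion_two_is_vacuous_below_full_identity(self):
        a = "A" * 300
        b = "A" * 150 + "C" * 150  # wildly dissimilar
        res = is_similar(a, b, literal_criteria2=True)
        assert res.criteria2  # M - average < 10 always holds since M <= min <= average
        assert not res.similar  # criterion 1 still gates it

    def test_or_combination(self):
        a = "A" * 300
        b = "A" * 270 + "C" * 30  # fails crit1 (90%) and crit2 (|300-270|=30)
        assert not is_similar(a, b, combine="or").similar
        c = "A" * 280 + "C" * 20  # 93.3% identity fails crit1; |300-... avg=300, M=280 -> fails
        long_ref = "A" * 300
        near = "A" * 298 + "C" * 2  # 99.3% identity, window 2 -> both pass
        assert is_similar(long_ref, near, combine="or").similar


class TestClassification:
    REF = {
        "c1": "ACGTACGTAC" * 30,
        "c3": "TTGGCCAATT" * 25,
    }

    def test_direct_tp_fp_fn_example(self):
        current = {"c1": self.REF["c1"], "c2": "G" * 200}
        other = {"c1": self.REF["c1"], "c3": self.REF["c3"]}
        counts = classify(current, self.REF, other)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)
        assert counts.tp + counts.fp == counts.n_reconstructed

    def test_identical_method_sets_have_no_false_negatives(self):
        current = dict(self.REF)
        counts = classify(current, self.REF, other=dict(self.REF))
        assert counts.fn == 0
        assert counts.tp == 2

    def test_without_competitor_fn_is_undefined(self):
        counts = classify({"c1": self.REF["c1"]}, self.REF)
        assert counts.fn is None
        assert metrics(counts).sensitivity_pct is None
        assert metrics(counts).f1 is None

    def test_randomized_sets_match_set_logic_oracle(self):
        rng = np.random.default_rng(31)
        pool = {f"c{i}": "".join(rng.choice(list(BASES), size=120)) for i in range(12)}
        for _ in range(25):
            ref_ids = set(rng.choice(list(pool), size=6, replace=False))
            cur_ids = set(rng.choice(list(pool), size=5, replace=False))
            oth_ids = set(rng.choice(list(pool), size=5, replace=False))
            reference = {k: pool[k] for k in ref_ids}
            current = {k: pool[k] for k in cur_ids}
            other = {k: pool[k] for k in oth_ids}
            counts = classify(current, reference, other)
            # oracle: identical sequences are similar; distinct random
            # 120-mers fall far below the 95% identity bar
            tp = len(cur_ids & ref_ids)
            fn = len((oth_ids & ref_ids) - cur_ids)
            assert (counts.tp, counts.fp, counts.fn) == (tp, len(cur_ids) - tp, fn)
            assert counts.tp + counts.fp == len(current)

    def test_all_vs_all_mode_finds_renamed_references(self):
        current = {"renamed": self.REF["c1"]}
        assert classify(current, self.REF, match_mode="id").tp == 1  # falls back to scan
        assert classify(current, self.REF, match_mode="all").tp == 1


class TestMetrics:
    @pytest.mark.parametrize(
        "nrs, tp, fn, precision, sensitivity, f1",
        [
            (3048, 1245, 324, 40.85, 79.35, 0.5393),
            (3411, 1942, 99, 56.93, 95.15, 0.7124),
            (2552, 1034, 351, 40.52, 74.66, 0.5253),
            (2959, 1707, 92, 57.69, 94.89, 0.7175),
            (2616, 1080, 330, 41.28, 76.60, 0.5365),
            (3002, 1769, 94, 58.93, 94.95, 0.7272),
            (9209, 1965, 51, 21.34, 97.47, 0.3501),
            (9658, 2138, 7, 22.14, 99.67, 0.3623),
            (8649, 1798, 420, 20.79, 81.06, 0.3309),
            (10864, 2315, 5, 21.31, 99.78, 0.3512),
        ],
    )
    def test_published_benchmark_rows_reproduce(self, nrs, tp, fn, precision, sensitivity, f1):
        report = metrics(EvalCounts(nrs, tp, nrs - tp, fn)).rounded()
        assert report["precision_pct"] == precision
        assert report["sensitivity_pct"] == sensitivity
        assert report["f1"] == f1

    @pytest.mark.parametrize(
        "nsc, nrs, rate",
        [(3756, 3411, 90.81), (3254, 2959, 90.93), (3290, 3002, 91.25),
         (9699, 9658, 99.58), (10911, 10864, 99.57),
         (3756, 3048, 81.15), (3254, 2552, 78.43), (3290, 2616, 79.51),
         (9699, 9209, 94.95), (10911, 8649, 79.27)],
    )
    def test_reconstruction_rate(self, nsc, nrs, rate):
        report = metrics(EvalCounts(nrs, 0, nrs), n_candidates=nsc)
        assert report.rounded()["reconstruction_rate_pct"] == rate

    def test_scale_invariance(self):
        base = metrics(EvalCounts(200, 100, 100, 100))
        scaled = metrics(EvalCounts(600, 300, 300, 300))
        assert base.precision_pct == scaled.precision_pct
        assert base.f1 == scaled.f1

    def test_f1_is_a_harmonic_mean(self):
        """F1 (as a percentage) sits between min and the arithmetic mean of
        precision and sensitivity — the defining bounds of a harmonic mean."""
        rng = np.random.default_rng(41)
        for _ in range(200):
            tp = int(rng.integers(0, 100))
            fp = int(rng.integers(0, 100))
            fn = int(rng.integers(0, 100))
            if tp + fp == 0 or tp + fn == 0:
                continue
            rep = metrics(EvalCounts(tp + fp, tp, fp, fn))
            lo = min(rep.precision_pct, rep.sensitivity_pct)
            hi = (rep.precision_pct + rep.sensitivity_pct) / 2
            assert lo - 1e-9 <= rep.f1 * 100 <= hi + 1e-9

    def test_zero_denominators_reported_absent_not_zero(self):
        rep = metrics(EvalCounts(0, 0, 0, 5))
        assert rep.precision_pct is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            EvalCounts(10, 5, 4, 0)
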