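"""Root decomposition and Boolean scoring against brute-force oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from boolerank import (
    ATTRIBUTES,
    boolean_score,
    closed_form_score,
    enumerate_roots,
    reference_score_report,
    root_probability,
    score_genes,
    shortlist,
)

from conftest import REFERENCE_WEIGHTS, make_weight_table

ALL_PATTERNS = [format(i, "07b") for i in range(1, 128)]


class TestEnumerateRoots:
    @pytest.mark.parametrize("k", range(1, 8))
    def test_root_count_is_two_to_k_minus_one(self, k):
        pattern = "1" * k + "0" * (7 - k)
        roots = enumerate_roots(pattern)
        assert len(roots) == 2**k - 1
        assert len(set(roots)) == len(roots)  # no duplicates
        assert all(roots)  # no empty root

    def test_single_attribute_root_is_the_pattern_itself(self):
        assert enumerate_roots("0000001") == [("Hub",)]

    def test_all_zero_pattern_raises(self):
        with pytest.raises(ValueError, match="no set attributes|all-zero"):
            enumerate_roots("0000000")

    def test_roots_are_subsets_of_set_bits(self):
        roots = enumerate_roots("0011011")
        present = {"PK", "TS", "TF", "Hub"}
        assert all(set(r) <= present for r in roots)


class TestRootProbability:
    def test_singleton_root_is_its_weight(self, reference_weights):
        assert root_probability(("Hub",), reference_weights) == pytest.approx(
            0.072986, abs=1e-9
        )

    def test_pair_root_is_the_mean(self, reference_weights):
        got = root_probability(("PK", "TS"), reference_weights)
        assert got == pytest.approx((0.037870 + 0.038675) / 2, abs=1e-9)

    def test_equal_weights_give_back_the_weight(self):
        wt = make_weight_table({a: 0.3 for a in ATTRIBUTES})
        for root in (("Meth",), ("SP", "TF"), tuple(ATTRIBUTES)):
            assert root_probability(root, wt) == pytest.approx(0.3, abs=1e-14)


class TestBooleanScore:
    def test_brute_force_equals_closed_form_everywhere(self, reference_weights, rng):
        random_wt = make_weight_table(
            {a: float(w) for a, w in zip(ATTRIBUTES, rng.random(7))}
        )
        for wt in (reference_weights, random_wt):
            for pattern in ALL_PATTERNS:
                brute = boolean_score(pattern, wt).score
                assert abs(brute - closed_form_score(pattern, wt)) < 1e-12

    def test_score_strictly_increasing_in_each_weight(self):
        pattern = "0011011"
        base = {a: 0.05 for a in ATTRIBUTES}
        s0 = boolean_score(pattern, make_weight_table(base)).score
        for attr in ("PK", "TS", "TF", "Hub"):  # the set attributes
            bumped = dict(base, **{attr: 0.06})
            assert boolean_score(pattern, make_weight_table(bumped)).score > s0

    def test_all_ones_pattern_brute_force_value(self, reference_weights):
        # 127-root summation collapses to (127/7) * total weight
        total = sum(REFERENCE_WEIGHTS.values())
        got = boolean_score("1111111", reference_weights)
        assert got.n_roots == 127
        assert got.score == pytest.approx(127 / 7 * total, abs=1e-10)

    def test_bit_order_pinned_by_published_scores(self, reference_weights):
        """Exhaustive search over all 7! attribute-to-position assignments:
        only assignments agreeing with the adopted order on positions
        2 (SP), 5 (PTM), 6 (TF), 7 (Hub) — with PK/TS interchangeable at
        positions 3-4 — reproduce the four published non-Meth pattern
        scores within 1e-4."""
        targets = {
            "0011011": 0.743532,
            "0011101": 0.735481,
            "0011110": 0.644578,
            "0111010": 0.607561,
        }
        matches = []
        weights = REFERENCE_WEIGHTS
        for assignment in permutations(ATTRIBUTES):
            ok = True
            for pattern, printed in targets.items():
                present = [assignment[i] for i, b in enumerate(pattern) if b == "1"]
                k = len(present)
                score = (2**k - 1) / k * sum(weights[a] for a in present)
                if abs(score - printed) > 1e-4:
                    ok = False
                    break
            if ok:
                matches.append(assignment)
        assert len(matches) == 2  # PK/TS swap is the only freedom
        for m in matches:
            assert m[1] == "SP" and m[4] == "PTM" and m[5] == "TF" and m[6] == "Hub"
            assert m[0] == "Meth" and {m[2], m[3]} == {"PK", "TS"}
        assert ATTRIBUTES in matches  # the adopted order is one of them

    def test_identical_patterns_identical_scores(self, reference_weights):
        attrs = pd.DataFrame(
            [[0, 1, 1, 1, 0, 1, 0]] * 3,
            columns=list(ATTRIBUTES),
            index=["g1", "g2", "g3"],
        )
        scored = score_genes(attrs, reference_weights)
        assert scored["score"].nunique() == 1

    def test_all_zero_gene_scores_zero(self, reference_weights):
        attrs = pd.DataFrame(
            [[0] * 7, [1] * 7], columns=list(ATTRIBUTES), index=["null", "full"]
        )
        scored = score_genes(attrs, reference_weights)
        assert scored.loc["null", "score"] == 0.0
        assert not scored.loc["null", "shortlisted"]
        assert scored.loc["full", "shortlisted"]


class TestShortlist:
    def test_strict_inequality_at_cutoff(self, reference_weights):
        scores = pd.DataFrame(
            {"score": [0.49, 0.50, 0.51]}, index=["a", "b", "c"]
        )
        lists = shortlist(scores, cutoff=0.5)
        assert lists["non_de"] == ["c"]
        assert lists["de"] == []

    def test_empty_input_empty_output(self):
        lists = shortlist(pd.DataFrame({"score": []}))
        assert lists == {"de": [], "non_de": []}

    def test_partition_by_de_call(self):
        scores = pd.DataFrame({"score": [0.9, 0.8, 0.7]}, index=["a", "b", "c"])
        calls = pd.Series({"a": "up", "b": "none", "c": "down"})
        lists = shortlist(scores, calls, cutoff=0.5)
        assert lists["de"] == ["a", "c"]
        assert lists["non_de"] == ["b"]

    def test_negative_cutoff_raises(self):
        with pytest.raises(ValueError):
            shortlist(pd.DataFrame({"score": [1.0]}), cutoff=-0.1)


def test_reference_report_flags_meth_patterns(reference_weights):
    """Four distinct non-Meth patterns reproduce the published scores; the
    two Meth-containing patterns are reported with both values and flagged."""
    report = reference_score_report(reference_weights)
    by_pattern = report.drop_duplicates("pattern").set_index("pattern")
    for pattern in ("0011011", "0011101", "0011110", "0111010"):
        assert by_pattern.loc[pattern, "reproduced"]
    for pattern in ("1011001", "1011010"):
        row = by_pattern.loc[pattern]
        assert not row["reproduced"]
        assert {"printed_rank", "computed_score"} <= set(report.columns)
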