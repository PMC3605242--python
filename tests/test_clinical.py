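"""Signature scoring, Welch test, median split, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boolerank import (
    SignatureDefinition,
    combined_score,
    default_signature,
    gen_clinical,
    km_curve,
    logrank,
    median_split,
    signature_score,
    survival_by_median_split,
    welch_t,
)

SAMPLES = ["s1", "s2", "s3", "s4"]


class TestSignatureScore:
    def test_all_zero_expression_scores_zero(self):
        expr = pd.DataFrame(0.0, index=["u", "d"], columns=SAMPLES)
        sig = SignatureDefinition(up_genes={"u"}, down_genes={"d"})
        assert (signature_score(expr, sig) == 0).all()

    def test_hand_sum(self):
        expr = pd.DataFrame(
            {"s1": [2.0, 3.0, 1.0, 4.0]}, index=["g2", "g3", "g1", "g4"]
        )
        sig = SignatureDefinition(up_genes={"g2", "g3"}, down_genes={"g1", "g4"})
        assert signature_score(expr, sig)["s1"] == pytest.approx(0.0)

    def test_linearity(self, rng):
        genes = [f"g{i}" for i in range(6)]
        sig = SignatureDefinition(up_genes=set(genes[:3]), down_genes=set(genes[3:]))
        x = pd.DataFrame(rng.normal(size=(6, 4)), index=genes, columns=SAMPLES)
        y = pd.DataFrame(rng.normal(size=(6, 4)), index=genes, columns=SAMPLES)
        pd.testing.assert_series_equal(
            signature_score(x + y, sig),
            signature_score(x, sig) + signature_score(y, sig),
        )

    def test_shifted_construction_separates_classes(self, rng):
        up = {f"u{i}" for i in range(5)}
        down = {f"d{i}" for i in range(5)}
        genes = sorted(up) + sorted(down)
        tumor = pd.DataFrame(
            rng.normal(8, 1, size=(10, 6)), index=genes
        )
        tumor.loc[sorted(up)] += 2
        tumor.loc[sorted(down)] -= 2
        normal = pd.DataFrame(rng.normal(8, 1, size=(10, 6)), index=genes)
        sig = SignatureDefinition(up_genes=up, down_genes=down)
        assert signature_score(tumor, sig).mean() > signature_score(normal, sig).mean()

    def test_missing_genes_skipped_with_warning(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["present"])
        sig = SignatureDefinition(up_genes={"present", "absent"}, down_genes=set())
        with pytest.warns(UserWarning, match="absent"):
            score = signature_score(expr, sig)
        assert score["s1"] == 1.0

    def test_no_signature_gene_present_raises(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["x"])
        sig = SignatureDefinition(up_genes={"a"}, down_genes={"b"})
        with pytest.raises(ValueError):
            signature_score(expr, sig)

    def test_overlapping_definition_rejected(self):
        with pytest.raises(ValueError):
            SignatureDefinition(up_genes={"a"}, down_genes={"a"})

    def test_default_signature_is_seven_up_ten_down(self):
        sig = default_signature()
        assert len(sig.up_genes) == 7
        assert len(sig.down_genes) == 10
        assert {"IRAK1", "CHEK1", "BUB1"} <= sig.up_genes
        assert {"AR", "LYN", "VIM"} <= sig.down_genes


class TestWelchT:
    def test_identical_groups_give_t_zero_p_one(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # s^2 = 0.5 in each group of 2: t = -10/sqrt(0.5), Welch df = 2
        t, df, p = welch_t([0, 1], [10, 11])
        assert t == pytest.approx(-10 / np.sqrt(0.5), abs=1e-10)
        assert df == pytest.approx(2.0, abs=1e-10)

    def test_sign_flips_on_group_swap(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=6)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([3.0, 3.0], [5.0, 5.0])


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split(pd.Series([1, 2, 3, 4], index=SAMPLES))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_broken_by_sample_id(self):
        labels = median_split(pd.Series([5, 5, 5, 5], index=["b", "a", "d", "c"]))
        assert labels["a"] == "low" and labels["b"] == "low"
        assert labels["c"] == "high" and labels["d"] == "high"

    def test_odd_n_puts_median_in_low(self):
        labels = median_split(pd.Series([10, 20, 30, 40, 50]))
        assert (labels == "low").sum() == 3

    def test_even_38_sample_split_is_balanced(self, rng):
        values = pd.Series(rng.normal(size=38))
        labels = median_split(values)
        assert (labels == "low").sum() == (labels == "high").sum() == 19

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([1, 2, 3]))


class TestKMCurve:
    def test_all_events_product_limit_by_hand(self):
        table = km_curve([1, 2, 3], [1, 1, 1])
        assert table.loc[1, "survival"] == pytest.approx(2 / 3)
        assert table.loc[2, "survival"] == pytest.approx(1 / 3)
        assert table.loc[3, "survival"] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        table = km_curve([1, 2, 3], [0, 0, 0])
        assert (table["survival"] == 1.0).all()

    def test_mixed_six_sample_fixture(self):
        # times (1,2,2,3,4,5), events (1,0,1,1,0,1): hand product-limit
        table = km_curve([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1])
        assert table.loc[1, "survival"] == pytest.approx(5 / 6)
        assert table.loc[2, "survival"] == pytest.approx(5 / 6 * 4 / 5)
        assert table.loc[3, "survival"] == pytest.approx(5 / 6 * 4 / 5 * 2 / 3)
        assert table.loc[5, "survival"] == pytest.approx(0.0)
        assert table.loc[1, "at_risk"] == 6

    def test_curve_is_monotone_non_increasing(self, rng):
        times = rng.exponential(100, size=30)
        events = rng.integers(0, 2, size=30)
        surv = km_curve(times, events)["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all()
        assert surv[0] <= 1.0

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            km_curve([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [3, 5, 8, 11]
        events = [1, 1, 0, 1]
        chi2, p = logrank(times + times, events + events, ["a"] * 4 + ["b"] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_label_swap(self):
        clin = gen_clinical(40, hazard_ratio=3.0, censor_rate=0.2, seed=5)
        chi2a, pa = logrank(clin["time"], clin["event"], clin["group"])
        swapped = clin["group"].map({"good": "poor", "poor": "good"})
        chi2b, pb = logrank(clin["time"], clin["event"], swapped)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_single_group_and_no_events_raise(self):
        with pytest.raises(ValueError):
            logrank([1, 2, 3], [1, 1, 1], ["a", "a", "a"])
        with pytest.raises(ValueError):
            logrank([1, 2], [0, 0], ["a", "b"])


class TestCombinedScore:
    def test_constant_genes_constant_score(self):
        expr = pd.DataFrame(
            3.0, index=["CHEK1", "AR", "LYN"], columns=["s1", "s2"]
        )
        assert (combined_score(expr) == 3.0).all()

    def test_hand_sum(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 1.0, 0.0], "s2": [2.0, 2.0, 0.0]},
            index=["CHEK1", "AR", "LYN"],
        )
        assert list(combined_score(expr)) == [2.0, 4.0]

    def test_missing_gene_raises(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["CHEK1"])
        with pytest.raises(ValueError, match="absent"):
            combined_score(expr)

    def test_combined_score_beats_single_genes_when_it_drives_hazard(self):
        """If survival hazard follows g1 + g2 - g3, the median split on the
        combined score separates prognosis groups better (smaller log-rank
        p on average) than any single constituent gene."""
        rng = np.random.default_rng(77)
        logp = {"combined": [], "g1": [], "g2": [], "g3": []}
        for _ in range(100):
            n = 80
            x = pd.DataFrame(
                rng.normal(size=(3, n)),
                index=["g1", "g2", "g3"],
                columns=[f"s{i}" for i in range(n)],
            )
            risk = (x.loc["g1"] + x.loc["g2"] - x.loc["g3"]).to_numpy()
            times = rng.exponential(1.0 / np.exp(0.9 * risk))
            events = np.ones(n, dtype=int)
            clin = pd.DataFrame(
                {"sample": x.columns, "time": times, "event": events}
            )
            for name, values in (
                ("combined", combined_score(x, ("g1", "g2", "g3"))),
                ("g1", x.loc["g1"]),
                ("g2", x.loc["g2"]),
                ("g3", x.loc["g3"]),
            ):
                _, _, p = survival_by_median_split(pd.Series(values), clin)
                logp[name].append(np.log(max(p, 1e-300)))
        mean_combined = np.mean(logp["combined"])
        for gene in ("g1", "g2", "g3"):
            assert mean_combined < np.mean(logp[gene])


def test_survival_by_median_split_joins_scores_and_clinical():
    clin = gen_clinical(30, hazard_ratio=4.0, censor_rate=0.1, seed=3)
    risk = pd.Series(
        (clin["group"] == "poor").astype(float).to_numpy()
        + np.linspace(0, 0.01, 30),
        index=clin["sample"],
    )
    table, chi2, p = survival_by_median_split(risk, clin)
    assert set(table["group"]) == {"low", "high"}
    assert chi2 > 0
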