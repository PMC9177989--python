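"""ROC/AUC, enrichment significance and tissue-domain ranking."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from spotdecon.containers import FractionMap
from spotdecon.evaluation import (
    auc_significance,
    bonferroni,
    domain_fraction_ranking,
    region_auc_report,
    roc_auc,
)


def brute_force_auc(scores, positives):
    """Exhaustive pairwise concordance with half credit for ties."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    credit = 0.0
    for a in pos:
        for b in neg:
            credit += 1.0 if a > b else (0.5 if a == b else 0.0)
    return credit / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_inverted_labels_complement(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = np.array([True, True, False, False])
        assert roc_auc(scores, ~labels) == 0.0

    def test_tie_credit_example(self):
        scores = [0.5, 0.5, 0.4]
        positives = [True, False, True]
        assert roc_auc(scores, positives) == pytest.approx(
            brute_force_auc(scores, positives)
        )

    def test_matches_brute_force_exhaustively(self, rng):
        """All labelings of small spot sets, with ties in the scores."""
        for n in (3, 5, 8):
            scores = rng.integers(0, 4, size=n) / 4.0
            for bits in range(1, 2**n - 1):
                positives = [(bits >> i) & 1 == 1 for i in range(n)]
                assert roc_auc(scores, positives) == pytest.approx(
                    brute_force_auc(scores, positives)
                )
        for _ in range(25):
            scores = rng.random(12).round(1)
            positives = rng.random(12) < 0.5
            if positives.all() or not positives.any():
                continue
            assert roc_auc(scores, positives) == pytest.approx(
                brute_force_auc(scores, positives)
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


class TestAucSignificance:
    def test_complete_separation_exact_p(self):
        scores = [10, 9, 8, 7, 6, 5, 4, 3, 2, 1]
        positives = [True] * 5 + [False] * 5
        assert auc_significance(scores, positives) == pytest.approx(
            1 / comb(10, 5), rel=1e-9
        )

    def test_identical_distributions_not_significant(self, rng):
        scores = np.concatenate([np.arange(10), np.arange(10) + 0.5])
        positives = np.array([True] * 10 + [False] * 10)
        assert auc_significance(scores, positives) > 0.3

    def test_monotone_in_added_positive(self, rng):
        scores = list(rng.random(10))
        positives = [True] * 5 + [False] * 5
        p_before = auc_significance(scores, positives)
        p_after = auc_significance(scores + [2.0], positives + [True])
        assert p_after <= p_before + 1e-12

    def test_bonferroni_definition(self):
        assert bonferroni(0.01, 5) == pytest.approx(0.05)
        assert bonferroni(0.5, 10) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


def _toy_fraction_map():
    """3 regions x hand-set fractions for 3 types over 9 spots."""
    fractions = np.array([
        # region A spots: t0-dominant
        [0.8, 0.1, 0.1], [0.7, 0.2, 0.1], [0.9, 0.05, 0.05],
        # region B spots: t1-dominant
        [0.1, 0.8, 0.1], [0.2, 0.7, 0.1], [0.1, 0.85, 0.05],
        # region C spots: mixed
        [0.4, 0.3, 0.3], [0.3, 0.4, 0.3], [0.35, 0.35, 0.3],
    ])
    return FractionMap(
        spot_ids=[f"s{i}" for i in range(9)],
        cell_types=["t0", "t1", "t2"],
        fractions=fractions,
        region_label=np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3, dtype=object),
    )


class TestDomainRanking:
    def test_matches_hand_computation(self):
        fm = _toy_fraction_map()
        tables = domain_fraction_ranking(fm, min_scaled_mean=0.0, top_n=3)
        # hand-computed: t0 scaled by (x-0.1)/(0.9-0.1); region A mean
        # ((0.875+0.75+1)/3)=0.875; elsewhere mean over B and C spots
        a = tables["A"]
        row_t0 = a[a.cell_type == "t0"].iloc[0]
        assert row_t0["mean_in"] == pytest.approx(0.875)
        out_vals = [(0.1 - 0.1) / 0.8, (0.2 - 0.1) / 0.8, (0.1 - 0.1) / 0.8,
                    (0.4 - 0.1) / 0.8, (0.3 - 0.1) / 0.8, (0.35 - 0.1) / 0.8]
        assert row_t0["mean_out"] == pytest.approx(np.mean(out_vals))
        assert a.iloc[0]["cell_type"] == "t0"  # top-ranked in its region
        assert tables["B"].iloc[0]["cell_type"] == "t1"

    def test_region_exclusive_type_ranks_top_with_infinite_ratio(self):
        fractions = np.array([
            [1.0, 0.0], [1.0, 0.0],
            [0.0, 1.0], [0.0, 1.0], [0.0, 1.0],
        ])
        fm = FractionMap(
            [f"s{i}" for i in range(5)], ["tR", "tOther"], fractions,
            region_label=np.array(["R", "R", "Q", "Q", "Q"], dtype=object),
        )
        tables = domain_fraction_ranking(fm, min_scaled_mean=0.2)
        top = tables["R"].iloc[0]
        assert top["cell_type"] == "tR"
        assert np.isinf(top["ratio"])

    def test_uniform_type_excluded_by_threshold(self):
        fm = _toy_fraction_map()
        tables = domain_fraction_ranking(fm, min_scaled_mean=0.6, top_n=3)
        assert list(tables["A"].cell_type) == ["t0"]

    def test_invariant_to_spot_order(self, rng):
        fm = _toy_fraction_map()
        perm = rng.permutation(9)
        fm2 = FractionMap(
            [fm.spot_ids[i] for i in perm], fm.cell_types,
            fm.fractions[perm], region_label=fm.region_label[perm],
        )
        t1 = domain_fraction_ranking(fm, min_scaled_mean=0.0, top_n=3)
        t2 = domain_fraction_ranking(fm2, min_scaled_mean=0.0, top_n=3)
        for region in t1:
            pd.testing.assert_frame_equal(t1[region], t2[region])


def test_region_auc_report_flags_significance():
    rng = np.random.default_rng(4)
    n = 60
    region = np.array(["L1"] * 30 + ["L2"] * 30, dtype=object)
    f0 = np.where(region == "L1", 0.7, 0.2) + rng.normal(0, 0.02, n)
    f0 = np.clip(f0, 0.01, 0.95)
    fractions = np.column_stack([f0, 1 - f0])
    fm = FractionMap(
        [f"s{i}" for i in range(n)], ["enriched", "rest"], fractions,
        region_label=region,
    )
    report = region_auc_report(fm, {"enriched": "L1", "rest": "L2"})
    row = report[report.cell_type == "enriched"].iloc[0]
    assert row["AUC"] > 0.95
    assert row["significant"]
    assert report["corrected_p"].between(0, 1).all()


def test_unknown_spots_excluded():
    fm = FractionMap(
        ["a", "b", "c", "d"], ["t", "u"],
        [[0.9, 0.1], [0.1, 0.9], [0.8, 0.2], [0.5, 0.5]],
        region_label=np.array(["R", "Q", "unknown", "Q"], dtype=object),
    )
    report = region_auc_report(fm, {"t": "R"})
    # with the unknown spot excluded: positives {0.9}, negatives {0.1, 0.5}
    assert report.iloc[0]["AUC"] == 1.0
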