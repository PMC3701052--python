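"""ROC/AUC scoring, candidate selection, and replication.

The authoritative AUC oracle is the all-pairs count: over every (a, b)
cross-group pair, a favourable pair scores 1, a tie scores 1/2.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cytoscreen as cs


def all_pairs_auc(a, b):
    """Brute-force Mann-Whitney AUC: P(b > a) + 0.5 P(b = a)."""
    total = 0.0
    for x in a:
        for y in b:
            if y > x:
                total += 1.0
            elif y == x:
                total += 0.5
    return total / (len(a) * len(b))


class TestRocAuc:
    def test_perfect_separation(self):
        sp = cs.roc_auc([0.1, 0.2, 0.5, 0.9], ["A", "A", "B", "B"])
        assert sp.auc == 1.0
        assert sp.orientation == "higher-in-B"
        assert sp.sensitivity == 1.0 and sp.specificity == 1.0
        assert sp.accuracy == 1.0

    def test_pure_ties_give_half(self):
        sp = cs.roc_auc([0.3, 0.3, 0.3, 0.3], ["A", "A", "B", "B"])
        assert sp.auc == 0.5
        assert sp.degenerate

    def test_overlapping_groups_match_all_pairs_oracle(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        raw = all_pairs_auc(a, b)
        # 6 favourable pairs + 2 ties of 9 -> raw (6 + 0.5*2)/9 = 7/9
        assert raw == pytest.approx(7 / 9)
        sp = cs.roc_auc(a + b, ["A"] * 3 + ["B"] * 3)
        assert sp.auc == pytest.approx(raw)

    def test_orientation_folding(self):
        sp = cs.roc_auc([0.9, 0.8, 0.1, 0.2], ["A", "A", "B", "B"])
        assert sp.orientation == "lower-in-B"
        assert sp.auc == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two group levels"):
            cs.roc_auc([1, 2], ["A", "A"])

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_equals_all_pairs_oracle_with_ties(self, data):
        # discrete values force plenty of ties; n <= 50 per group
        n_a = data.draw(st.integers(1, 50))
        n_b = data.draw(st.integers(1, 50))
        vals = st.integers(0, 5).map(float)
        a = data.draw(st.lists(vals, min_size=n_a, max_size=n_a))
        b = data.draw(st.lists(vals, min_size=n_b, max_size=n_b))
        raw = all_pairs_auc(a, b)
        sp = cs.roc_auc(a + b, ["A"] * n_a + ["B"] * n_b)
        assert sp.auc == pytest.approx(max(raw, 1 - raw))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        freq = rng.random(16)
        labels = ["A"] * 8 + ["B"] * 8
        base = cs.roc_auc(freq, labels)
        warped = cs.roc_auc(np.exp(3 * freq), labels)
        assert warped.auc == pytest.approx(base.auc)
        assert warped.orientation == base.orientation

    def test_label_swap_keeps_auc_flips_orientation(self):
        rng = np.random.default_rng(1)
        freq = np.concatenate([rng.normal(0.2, 0.02, 8),
                               rng.normal(0.4, 0.02, 8)])
        labels = np.array(["A"] * 8 + ["B"] * 8)
        fwd = cs.roc_auc(freq, labels)
        swapped = cs.roc_auc(freq, np.where(labels == "A", "B", "A"))
        assert swapped.auc == fwd.auc
        assert swapped.orientation != fwd.orientation

    def test_confusion_formulas_on_known_split(self):
        # unique Youden optimum: all of A below the cut, 3 of 4 B above
        freq = [0.1, 0.2, 0.3, 0.35, 0.25, 0.5, 0.7, 0.8]
        labels = ["A", "A", "A", "A", "B", "B", "B", "B"]
        sp = cs.roc_auc(freq, labels)
        cc = cs.ConfusionCounts(tp=3, fn=1, fp=0, tn=4)
        assert sp.sensitivity == pytest.approx(cc.sensitivity)
        assert sp.specificity == pytest.approx(cc.specificity)
        assert sp.accuracy == pytest.approx(7 / 8)


class TestScoreAll:
    def _table(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(12)]
        labels = {c: ("A" if i < 6 else "B") for i, c in enumerate(cols)}
        freq = pd.DataFrame(rng.random((20, 12)),
                            index=[f"P{j}+" for j in range(20)], columns=cols)
        freq.loc["P0+"] = [0.0] * 6 + [1.0] * 6  # copies the label
        return freq, labels

    def test_label_copy_tops_ranking(self):
        freq, labels = self._table()
        scores = cs.score_all(freq, labels)
        assert scores.index[0] == "P0+"
        assert scores.loc["P0+", "auc"] == 1.0

    def test_cdf_non_decreasing_ends_at_one(self):
        freq, labels = self._table()
        cdf = cs.auc_cdf(cs.score_all(freq, labels))
        assert (np.diff(cdf["cdf"]) >= 0).all()
        assert cdf["cdf"].iloc[-1] == 1.0
        assert (np.diff(cdf["auc"]) >= 0).all()

    def test_permutation_collapses_high_scores(self, screened):
        # with true labels many phenotypes separate the platforms; under
        # permuted labels almost none should
        frac_true = (screened.scores["auc"] > 0.9).mean()
        null = cs.permutation_null(
            screened.averaged, screened.averaged_labels,
            n_permutations=5, cutoff=0.9, seed=0,
        )
        assert null["fraction_above_cutoff"].mean() < frac_true / 2


class TestSelection:
    def _scores(self, aucs):
        return pd.DataFrame(
            {"auc": list(aucs.values())}, index=list(aucs.keys())
        )

    def test_cutoff_is_strict(self):
        scores = self._scores({"X+": 0.9, "Y+": 0.901})
        assert cs.select_candidates(scores, cutoff=0.9) == ["Y+"]

    def test_force_include_kept_despite_low_score(self):
        scores = self._scores(
            {"CD4+": 0.55, "Foxp3+": 0.6, "IL17A+": 0.5, "CD8+": 0.52,
             "IL10+": 0.99}
        )
        sel = cs.select_candidates(
            scores, cutoff=0.9, force_include=cs.DEFAULT_FORCE_INCLUDE
        )
        assert set(sel) == {"CD4+", "Foxp3+", "IL17A+", "CD8+", "IL10+"}

    def test_low_cutoff_selects_everything_non_degenerate(self):
        scores = self._scores({"X+": 0.51, "Y+": 0.7, "Z+": 0.8})
        assert set(cs.select_candidates(scores, cutoff=0.5)) == {"X+", "Y+", "Z+"}

    def test_unknown_force_include_raises(self):
        with pytest.raises(KeyError, match="force_include"):
            cs.select_candidates(self._scores({"X+": 0.6}),
                                 force_include=["NOPE+"])


class TestReplicate:
    def _freq(self, effect):
        rng = np.random.default_rng(3)
        cols = [f"v{i}" for i in range(12)]
        labels = {c: ("A" if i < 6 else "B") for i, c in enumerate(cols)}
        base = rng.normal(0.2, 0.005, 12)
        shifted = base.copy()
        if effect:
            shifted[6:] += 0.1
        freq = pd.DataFrame(
            {c: [v] for c, v in zip(cols, shifted)}, index=["M+"]
        )
        return freq, labels

    def test_effect_in_both_cohorts_confirmed(self):
        freq, labels = self._freq(effect=True)
        verdict = cs.replicate(["M+"], freq, labels, cutoff=0.9)
        assert verdict.loc["M+", "confirmed"]

    def test_effect_absent_in_cohort2_not_confirmed(self):
        freq, labels = self._freq(effect=False)
        verdict = cs.replicate(["M+"], freq, labels, cutoff=0.9)
        assert not verdict.loc["M+", "confirmed"]

    def test_empty_selection_empty_verdict(self):
        freq, labels = self._freq(effect=True)
        assert len(cs.replicate([], freq, labels)) == 0

    def test_missing_phenotype_raises(self):
        freq, labels = self._freq(effect=True)
        with pytest.raises(KeyError, match="absent"):
            cs.replicate(["GONE+"], freq, labels)
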