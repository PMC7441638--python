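import numpy as np
import pandas as pd
import pytest

from queendx import (
    LfqMatrix,
    MarkerPanel,
    SimulationConfig,
    blind_trial,
    classify_by_threshold,
    evaluate_confusion,
    generate_blind_trial,
    log2_transform,
    normalize_to_reference,
    select_candidate_markers,
    select_reference_protein,
)


def de_frame(rows):
    """rows: (accession, log2_fc, t, adj_p, significant)"""
    return pd.DataFrame(
        {
            "accession": [r[0] for r in rows],
            "log2_fc": [r[1] for r in rows],
            "t_stat": [r[2] for r in rows],
            "adj_p": [r[3] for r in rows],
            "significant": [r[4] for r in rows],
            "direction": ["up" if r[1] >= 0 else "down" for r in rows],
        }
    )


def matrix_from(values, accs, samples, log2=False):
    return LfqMatrix(
        intensities=pd.DataFrame(np.asarray(values, dtype=float), index=accs, columns=samples),
        log2=log2,
    )


class TestMarkerSelection:
    def test_unique_minimum_adjusted_p_wins_at_k_one(self):
        de = de_frame([("A", 1.0, 3.0, 0.01, True), ("B", 1.0, 2.0, 0.20, False)])
        panel = select_candidate_markers(de, k=1, stressor="heat")
        assert panel.markers == [("A", "heat")]
        assert not panel.warning

    def test_all_downregulated_gives_empty_panel_with_warning(self):
        de = de_frame([("A", -1.0, -3.0, 0.01, True), ("B", -2.0, -4.0, 0.001, True)])
        panel = select_candidate_markers(de, k=2)
        assert panel.markers == []
        assert panel.warning

    def test_padding_when_too_few_significant_upregulated(self):
        de = de_frame(
            [("A", 1.0, 5.0, 0.01, True), ("B", 0.5, 1.5, 0.40, False),
             ("C", 0.2, 1.0, 0.80, False)]
        )
        panel = select_candidate_markers(de, k=2)
        assert panel.accessions == ["A", "B"]
        assert panel.warning

    def test_ties_break_by_larger_absolute_t(self):
        de = de_frame([("B", 1.0, 2.0, 0.01, True), ("A", 1.0, 6.0, 0.01, True)])
        panel = select_candidate_markers(de, k=1)
        assert panel.accessions == ["A"]


class TestReferenceSelection:
    def test_exactly_constant_row_is_chosen(self):
        vals = [[8.0, 8.0, 8.0], [4.0, 9.0, 5.0], [7.0, 6.0, 9.0]]
        m = matrix_from(vals, ["X", "CONST", "Y"], ["s1", "s2", "s3"])
        m.intensities.loc["CONST"] = 8.0
        assert select_reference_protein(m) == "CONST"

    def test_machine_precision_tie_resolves_lexicographically(self):
        vals = [[2.0, 4.0], [4.0, 8.0], [3.0, 11.0]]
        m = matrix_from(vals, ["B", "A", "C"], ["s1", "s2"])
        # rows A and B have identical log2 variance (both are one doubling)
        assert select_reference_protein(m) == "A"

    def test_no_fully_observed_protein_raises(self):
        vals = [[np.nan, 2.0], [3.0, np.nan]]
        m = matrix_from(vals, ["A", "B"], ["s1", "s2"])
        with pytest.raises(ValueError, match="every sample"):
            select_reference_protein(m)


class TestNormalization:
    def test_marker_equal_to_reference_gives_ones(self):
        m = matrix_from([[3.0, 5.0], [3.0, 5.0]], ["M", "R"], ["s1", "s2"])
        v = normalize_to_reference(m, "M", "R")
        np.testing.assert_allclose(v.to_numpy(), 1.0)

    def test_missing_marker_value_maps_to_zero(self):
        m = matrix_from([[np.nan, 6.0], [3.0, 3.0]], ["M", "R"], ["s1", "s2"])
        v = normalize_to_reference(m, "M", "R")
        assert v["s1"] == 0.0
        assert v["s2"] == pytest.approx(2.0)

    def test_constant_double_ratio(self):
        m = matrix_from([[6.0, 10.0], [3.0, 5.0]], ["M", "R"], ["s1", "s2"])
        np.testing.assert_allclose(normalize_to_reference(m, "M", "R").to_numpy(), 2.0)

    def test_missing_reference_raises_with_sample_names(self):
        m = matrix_from([[1.0, 2.0], [3.0, np.nan]], ["M", "R"], ["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            normalize_to_reference(m, "M", "R")

    def test_log2_matrix_ratio_on_linear_scale(self):
        m = matrix_from([[11.0], [10.0]], ["M", "R"], ["s1"], log2=True)
        assert normalize_to_reference(m, "M", "R")["s1"] == pytest.approx(2.0)


class TestThresholdClassifier:
    def test_strictly_above_threshold_is_flagged(self):
        v = pd.Series([0.06, 0.01, 0.05, 0.0], index=list("abcd"))
        flags = classify_by_threshold(v, 0.05)
        assert list(flags) == [True, False, False, False]  # 0.05 itself not flagged

    def test_raising_threshold_never_adds_flags(self):
        rng = np.random.default_rng(8)
        v = pd.Series(rng.uniform(0, 0.2, size=50))
        prev = classify_by_threshold(v, 0.01)
        for thr in [0.02, 0.05, 0.1, 0.5]:
            cur = classify_by_threshold(v, thr)
            assert set(v.index[cur]) <= set(v.index[prev])
            prev = cur

    def test_flags_invariant_to_per_sample_rescaling(self):
        vals = 2.0 ** np.random.default_rng(9).uniform(18, 25, size=(3, 6))
        m = matrix_from(vals, ["M", "R", "X"], [f"s{i}" for i in range(6)])
        base = classify_by_threshold(normalize_to_reference(m, "M", "R"))
        scaled = m.copy()
        scaled.intensities.iloc[:, 2] *= 17.3  # common per-sample factor cancels
        after = classify_by_threshold(normalize_to_reference(scaled, "M", "R"))
        assert list(base) == list(after)


class TestConfusion:
    def test_published_blind_trial_rates(self):
        # 16 queens, 8 truly heat-shocked; marker 1: 8 flagged of which 6
        # correct -> TPR 6/8; marker 2: 5 flagged of which 2 correct -> 2/8
        truth = [True] * 8 + [False] * 8
        flags1 = [True] * 6 + [False] * 2 + [True] * 2 + [False] * 6
        oc1 = evaluate_confusion(flags1, truth)
        assert oc1.tpr == pytest.approx(0.75)
        flags2 = [True] * 2 + [False] * 6 + [True] * 3 + [False] * 5
        oc2 = evaluate_confusion(flags2, truth)
        assert oc2.tpr == pytest.approx(0.25)

    def test_perfect_flags(self):
        oc = evaluate_confusion([True, True, False], [True, True, False])
        assert oc.tpr == 1.0 and oc.fpr == 0.0 and oc.ppv == 1.0

    def test_sensitivity_and_miss_rate_sum_to_one(self):
        rng = np.random.default_rng(2)
        truth = rng.random(30) < 0.5
        flags = rng.random(30) < 0.5
        oc = evaluate_confusion(flags, truth)
        if oc.tp + oc.fn:
            assert oc.tpr + oc.fn / (oc.tp + oc.fn) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_confusion([True], [True, False])


class TestBlindTrial:
    @pytest.fixture
    def trial(self):
        cfg = SimulationConfig(
            n_proteins=80,
            marker_effects={"XP_001120006.2": ("heatshock", 3.0),
                            "XP_395659.1": ("heatshock", 2.5)},
            seed=21,
        )
        return generate_blind_trial(cfg, n_total=16, n_stressed=8)

    def test_sixteen_samples_eight_sealed_stressed(self, trial):
        matrix, truth = trial
        assert matrix.n_samples == 16
        assert not truth.sealed_labels.opened
        labels = truth.sealed_labels.unseal()
        assert sum(labels.values()) == 8

    def test_unsealing_before_prediction_is_rejected(self, trial):
        matrix, truth = trial
        truth.sealed_labels.unseal()
        panel = MarkerPanel(markers=[("XP_001120006.2", "heat")], selection_rule="", k=1)
        with pytest.raises(RuntimeError, match="blind"):
            blind_trial(log2_transform(matrix), panel, truth.sealed_labels)

    def test_infinite_threshold_flags_nothing(self, trial):
        matrix, truth = trial
        panel = MarkerPanel(markers=[("XP_001120006.2", "heat")], selection_rule="", k=1)
        res = blind_trial(log2_transform(matrix), panel, truth.sealed_labels,
                          threshold=np.inf)
        assert res.per_marker["XP_001120006.2"].tpr == 0.0

    def test_joint_and_rule_never_beats_its_best_member(self, trial):
        matrix, truth = trial
        # second "marker" is pure noise: joint AND rule can only lose flags
        noise_acc = next(a for a in matrix.accessions if a.startswith("PROT_"))
        panel = MarkerPanel(
            markers=[("XP_001120006.2", "heat"), (noise_acc, "heat")],
            selection_rule="", k=2,
        )
        res = blind_trial(log2_transform(matrix), panel, truth.sealed_labels)
        single = res.per_marker["XP_001120006.2"]
        assert res.joint.tp <= single.tp
        assert res.joint.tpr <= single.tpr or np.isnan(res.joint.tpr)
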