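"""Match indicators, DOR/PPV/NPV arithmetic and the statistical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import morphonorm as mn
from morphonorm import accuracy as acc
from morphonorm.fingerprint import RegionScore
from morphonorm.schema import GroundTruth


def _det(region, hemi, value=3.0):
    return RegionScore(region=region, hemisphere=hemi, L_r=value)


MESIO_GT = GroundTruth(
    dataset_id="d1",
    expert_regions={("left", "hippocampus")},
    eeg_lateralization="left",
    resection=("left", "temporal", ("hippocampus", "amygdala", "entorhinal")),
    engel_class="I",
    followup_months=24.0,
)


class TestDatasetIndicators:
    def test_sublobar_containment(self):
        det = [_det("hippocampus", "left")]
        assert acc.dataset_sensitivity(det, MESIO_GT, "surgery") == 1.0

    def test_wrong_hemisphere_misses(self):
        det = [_det("hippocampus", "right"), _det("superiortemporal", "right")]
        assert acc.dataset_sensitivity(det, MESIO_GT, "expert") == 0.0
        assert acc.dataset_sensitivity(det, MESIO_GT, "eeg") == 0.0

    def test_lobar_level_match(self):
        det = [_det("middletemporal", "left")]  # temporal lobe, not the GT label
        assert acc.dataset_sensitivity(det, MESIO_GT, "expert", level="sublobar") == 0.0
        assert acc.dataset_sensitivity(det, MESIO_GT, "expert", level="lobar") == 1.0

    def test_rank_four_hit_is_sensitive_but_not_specific(self):
        det = [
            _det("cuneus", "right", 6.0),
            _det("precuneus", "right", 5.0),
            _det("lingual", "right", 4.0),
            _det("hippocampus", "left", 3.0),
        ]
        assert acc.dataset_sensitivity(det, MESIO_GT, "expert") == 1.0
        assert acc.dataset_specificity(det, MESIO_GT, "expert") == 0.0

    def test_no_detections_scores_zero_for_lesional_gt(self):
        assert acc.dataset_sensitivity([], MESIO_GT, "expert") == 0.0

    def test_unavailable_source_is_not_applicable(self):
        gt = GroundTruth(dataset_id="d2", eeg_lateralization="diffuse")
        det = [_det("hippocampus", "left")]
        assert np.isnan(acc.dataset_sensitivity(det, gt, "expert"))
        assert np.isnan(acc.dataset_sensitivity(det, gt, "eeg"))

    def test_unfavorable_surgery_excluded(self):
        gt = GroundTruth(
            dataset_id="d3",
            resection=("left", "temporal", ("hippocampus",)),
            engel_class="III",
            followup_months=24.0,
        )
        assert np.isnan(acc.dataset_sensitivity([_det("hippocampus", "left")], gt, "surgery"))

    def test_expert_eeg_agreement(self):
        assert acc.expert_eeg_agreement(MESIO_GT) == 1.0
        flipped = GroundTruth(
            dataset_id="d4", expert_regions={("right", "hippocampus")}, eeg_lateralization="left"
        )
        assert acc.expert_eeg_agreement(flipped) == 0.0


class TestAggregate:
    def test_matches_hand_count_on_random_indicators(self):
        rng = np.random.default_rng(0)
        values = rng.choice([1.0, 0.0, np.nan], size=60, p=[0.5, 0.3, 0.2])
        table = pd.DataFrame({"sens_expert": values})
        finite = values[~np.isnan(values)]
        assert acc.aggregate(table, "sens_expert") == pytest.approx(finite.mean())
        k, n = acc.aggregate_counts(table, "sens_expert")
        assert (k, n) == (int(finite.sum()), len(finite))

    def test_all_consistent(self):
        table = pd.DataFrame({"sens_eeg": [1.0, 1.0, 1.0]})
        assert acc.aggregate(table, "sens_eeg") == 1.0

    def test_no_evaluable_dataset_rejected(self):
        with pytest.raises(ValueError):
            acc.aggregate(pd.DataFrame({"sens_eeg": [np.nan]}), "sens_eeg")


class TestDiagnosticOddsRatio:
    def test_no_association(self):
        assert acc.diagnostic_odds_ratio(1, 1, 1, 1)[2] == pytest.approx(1.0)

    def test_closed_form(self):
        lr_pos, lr_neg, dor = acc.diagnostic_odds_ratio(9, 1, 1, 9)
        assert dor == pytest.approx(81.0)
        assert lr_pos / lr_neg == pytest.approx(81.0)

    def test_prevalence_invariance(self):
        """Doubling the abnormal column (tp, fn) leaves the DOR unchanged."""
        base = acc.diagnostic_odds_ratio(12, 5, 4, 30)[2]
        doubled = acc.diagnostic_odds_ratio(24, 5, 8, 30)[2]
        assert doubled == pytest.approx(base, rel=1e-12)

    def test_continuity_correction_keeps_log_finite(self):
        _, _, dor = acc.diagnostic_odds_ratio(5, 0, 2, 10)
        assert np.isfinite(np.log(dor)) and dor > 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            acc.diagnostic_odds_ratio(-1, 0, 0, 0)


class TestPredictiveValues:
    def test_perfect_classifier(self):
        assert acc.predictive_values(10, 0, 0, 10) == (1.0, 1.0)

    def test_zero_tp_with_false_positives(self):
        ppv, npv = acc.predictive_values(0, 5, 0, 10)
        assert ppv == 0.0 and npv == 1.0

    def test_undefined_columns_missing(self):
        ppv, npv = acc.predictive_values(0, 0, 0, 0)
        assert np.isnan(ppv) and np.isnan(npv)
        _, npv_zero = acc.predictive_values(0, 0, 3, 0)
        assert npv_zero == 0.0


class TestRandomizationTest:
    def test_identical_groups_not_significant(self):
        p = acc.randomization_test([[1.0, 2.0, 3.0]] * 2, n_resamples=500, seed=0)
        assert p > 0.3

    def test_degenerate_data_gives_one(self):
        assert acc.randomization_test([[2.0, 2.0], [2.0, 2.0]], seed=0, n_resamples=100) == 1.0

    def test_fully_separated_binary_groups(self):
        p = acc.randomization_test(
            [np.ones(20), np.zeros(20)], n_resamples=4000, seed=1
        )
        assert p <= 0.001

    def test_reproducible_under_fixed_seed(self):
        groups = [np.arange(8.0), np.arange(8.0) + 0.8]
        a = acc.randomization_test(groups, n_resamples=300, seed=7)
        b = acc.randomization_test(groups, n_resamples=300, seed=7)
        assert a == b

    def test_never_zero(self):
        p = acc.randomization_test([np.ones(6), np.zeros(6)], n_resamples=200, seed=2)
        assert p >= 1.0 / 201


class TestExactAndBinomialTests:
    def test_balanced_fisher_table(self):
        assert acc.exact_test_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_binomial_at_expectation(self):
        p = acc.binomial_rate_test(10, 1000, 0.01)
        assert 0.4 < p < 0.65

    def test_binomial_matches_brute_force_summation(self):
        count, n, p0 = 4, 12, 0.2
        expected = sum(
            sps.binom.pmf(k, n, p0) for k in range(count, n + 1)
        )
        assert acc.binomial_rate_test(count, n, p0) == pytest.approx(expected, rel=1e-10)

    def test_all_successes_magnitude(self):
        p = acc.binomial_rate_test(100, 100, 0.01)
        assert p == pytest.approx(0.01**100, rel=1e-6)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            acc.binomial_rate_test(5, 4, 0.1)


class TestSequentialGroupTest:
    def test_indistinguishable_groups_skip_second_level(self):
        rng = np.random.default_rng(3)
        pooled = rng.standard_normal(200)
        result = acc.sequential_group_test({"a": pooled[:100], "b": pooled[100:]})
        if result.kruskal_p >= 0.05:
            assert result.pairwise == {}

    def test_one_shifted_group_found_pairwise(self):
        rng = np.random.default_rng(4)
        data = {
            "a": rng.standard_normal(30),
            "b": rng.standard_normal(30),
            "c": rng.standard_normal(30) + 2.0,
        }
        result = acc.sequential_group_test(data)
        assert result.kruskal_band == "significant"
        assert result.pairwise[("a", "c")][1] == "significant"
        assert result.pairwise[("b", "c")][1] == "significant"

    def test_band_labels(self):
        assert acc._band(0.005) == "significant"
        assert acc._band(0.03) == "trend"
        assert acc._band(0.2) == "not significant"

    def test_tiny_group_excluded(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            acc.sequential_group_test({"a": [1.0, 2.0, 1.5], "b": [2.0, 2.5, 1.7], "c": [1.0]})
        assert "excluded" in caplog.text


class TestRegionalAccuracy:
    def test_counts_and_summaries(self):
        scores = {
            "d1": [_det("hippocampus", "left", 3.0), _det("cuneus", "left", 1.0)],
            "d2": [_det("hippocampus", "left", 1.0), _det("cuneus", "left", 3.0)],
        }
        gts = [
            GroundTruth(dataset_id="d1", expert_regions={("left", "hippocampus")}),
            GroundTruth(dataset_id="d2", expert_regions={("left", "hippocampus")}),
        ]
        regional = {(r.region, r.hemisphere): r for r in acc.regional_accuracy(scores, gts)}
        hip = regional[("hippocampus", "left")]
        assert (hip.tp, hip.fp, hip.fn, hip.tn) == (1, 0, 1, 0)
        cun = regional[("cuneus", "left")]
        assert (cun.tp, cun.fp, cun.fn, cun.tn) == (0, 1, 0, 1)
        assert cun.ppv == 0.0 and cun.npv == 1.0

    def test_lobe_lookup_covers_all_cortical_labels(self):
        for region in mn.schema.DK_REGIONS + mn.schema.DESTRIEUX_REGIONS:
            assert acc.lobe_of(region) in acc.LOBES


class TestReferenceMatchTable:
    def test_shape_and_subtype_fractions(self):
        table = acc.load_reference_match_table()
        assert len(table) == 47
        mtle_left = table[table["subtype"] == "MTLE-HS-left"]
        assert acc.aggregate(mtle_left, "sens_expert") == pytest.approx(16 / 18)
        assert acc.aggregate(mtle_left, "spec_surgery") == pytest.approx(1.0)
        ltle_left = table[table["subtype"] == "LTLE-left"]
        assert acc.aggregate(ltle_left, "sens_expert") == pytest.approx(3 / 5)
        assert acc.aggregate(ltle_left, "spec_expert") == pytest.approx(1 / 5)

    def test_surgery_consistency_buckets_partition(self):
        table = acc.load_reference_match_table()
        buckets = acc.surgery_overlap_by_consistency(table)
        total = sum(n for _, n in buckets.values())
        _, n_surgery = acc.aggregate_counts(table, "spec_surgery")
        assert total == n_surgery
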