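"""Sliding-window scan, interval algebra and AUC scaling contracts."""

import numpy as np
import pytest
from scipy.stats import chi2

from chipquant.model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    GenomicInterval,
    Mark,
    PeakSet,
)
from chipquant.sustained import (
    WindowTest,
    apply_scaling,
    cumulative_auc,
    dichotomize,
    intersect_across_conditions,
    merge_significant,
    normalize_by_sustained_regions,
    scaling_factors,
    scan_windows,
    window_chisq,
)
from conftest import make_peak, peakset_from_heights


class TestDichotomize:
    def test_linear_interpolation_quantile(self):
        """Heights 1..10 at q=0.90: cutoff 9.1, exactly one positive."""
        labels = dichotomize(peakset_from_heights(range(1, 11)), 0.90)
        assert labels.sum() == 1
        heights = np.arange(1, 11)
        assert np.quantile(heights, 0.9) == pytest.approx(9.1)
        assert labels[-1]

    def test_equal_heights_give_no_positives(self):
        labels = dichotomize(peakset_from_heights([5.0] * 20), 0.90)
        assert labels.sum() == 0  # strict '>' at the cutoff

    def test_one_in_ten_positive_for_1_to_100(self):
        labels = dichotomize(peakset_from_heights(range(1, 101)), 0.90)
        assert labels.sum() == 10

    def test_too_few_peaks_error(self):
        with pytest.raises(ChipquantError, match="10 peaks"):
            dichotomize(peakset_from_heights([1, 2, 3]), 0.90)


class TestWindowChisq:
    def test_enriched_window_statistic_and_tail(self):
        """n=20, k=12, pi=0.10: X2 = 55.5556; tail equals chi2(1df) sf."""
        stat, p = window_chisq(20, 12, 0.10)
        expected = (12 - 2) ** 2 / 2 + (8 - 18) ** 2 / 18
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(55.5556, abs=5e-5)
        assert p == pytest.approx(chi2.sf(stat, 1), rel=1e-10)

    def test_observed_equals_expected_is_null(self):
        stat, p = window_chisq(20, 2, 0.10)
        assert stat == 0.0 and p == 1.0

    def test_depletion_is_not_enrichment(self):
        stat, p = window_chisq(20, 0, 0.10)
        assert p == 1.0 and stat > 0

    def test_empty_window_undefined(self):
        with pytest.raises(ChipquantError):
            window_chisq(0, 0, 0.1)


class TestScanWindows:
    def test_isolated_positive_peak(self):
        """A lone positive with global pi=0.1 scores X2 = 9.0."""
        ps = peakset_from_heights([1] * 9 + [10], spacing=100_000)
        labels = dichotomize(ps)
        tests = scan_windows(ps, labels, 20_000)
        lone = [t for t in tests if t.n_positive == 1][0]
        assert lone.n_peaks == 1
        expected = (1 - 0.1) ** 2 / 0.1 + (0 - 0.9) ** 2 / 0.9
        assert lone.chisq_stat == pytest.approx(expected) == pytest.approx(9.0)

    def test_peaks_30kb_apart_do_not_share_windows(self):
        ps = peakset_from_heights([5, 5], spacing=30_000)
        tests = scan_windows(ps, np.array([True, False]), 20_000)
        assert all(t.n_peaks == 1 for t in tests)

    def test_dense_positive_cluster_all_significant(self):
        peaks = [make_peak("chr1", 10_000_000 + i * 100, 50, 10.0) for i in range(50)]
        peaks += [make_peak("chr1", 20_000_000 + 100_000 * i, 50, 1.0) for i in range(450)]
        ps = PeakSet(mark=Mark.H3K27ME3, condition=Condition.T0, peaks=peaks)
        labels = ps.heights() > 5
        assert labels.mean() == pytest.approx(0.1)
        tests = scan_windows(ps, labels, 20_000)
        cluster = [t for t in tests if t.n_positive == 50]
        assert len(cluster) == 50
        assert all(t.p_value < 1e-5 for t in cluster)


class TestMergeAndIntersect:
    def _wt(self, chrom, start, end, p):
        return WindowTest(GenomicInterval(chrom, start, end), 1, 1, 10.0, p)

    def test_overlapping_windows_merge(self):
        tests = [
            self._wt("chr1", 0, 20_000, 1e-9),
            self._wt("chr1", 10_000, 30_000, 1e-9),
            self._wt("chr1", 50_000, 70_000, 0.5),
        ]
        regions = merge_significant(tests, 1e-5)
        assert regions == [GenomicInterval("chr1", 0, 30_000)]

    def test_no_significant_windows_empty(self):
        assert merge_significant([self._wt("chr1", 0, 20_000, 0.1)], 1e-5) == []

    def test_disjoint_windows_stay_separate(self):
        tests = [
            self._wt("chr1", i * 100_000, i * 100_000 + 20_000, 1e-9)
            for i in range(3)
        ]
        assert len(merge_significant(tests, 1e-5)) == 3

    def test_intersection_interval_algebra(self):
        per_cond = {
            Condition.T0: [GenomicInterval("chr1", 0, 30_000)],
            Condition.T8: [GenomicInterval("chr1", 10_000, 40_000)],
            Condition.T24: [GenomicInterval("chr1", 10_000, 30_000)],
            Condition.T_PLUS8: [GenomicInterval("chr1", 5_000, 35_000)],
        }
        result = intersect_across_conditions(per_cond, min_fragment=20_000)
        assert result == [GenomicInterval("chr1", 10_000, 30_000)]

    def test_identical_sets_are_identity(self):
        regions = [GenomicInterval("chr1", 0, 50_000)]
        per_cond = {c: list(regions) for c in CONDITIONS}
        assert intersect_across_conditions(per_cond) == regions

    def test_region_absent_in_one_condition_excluded(self):
        per_cond = {c: [GenomicInterval("chr1", 0, 50_000)] for c in CONDITIONS}
        per_cond[Condition.T24] = [GenomicInterval("chr2", 0, 50_000)]
        with pytest.raises(ChipquantError, match="no sustained regions"):
            intersect_across_conditions(per_cond)


class TestCumulativeAuc:
    def test_membership_by_mean_location(self):
        peaks = [
            make_peak("chr1", 1000, 100, 1.0),   # auc 100, inside
            make_peak("chr1", 2000, 200, 1.0),   # auc 200, inside
            make_peak("chr1", 99_000, 100, 1.0),  # outside
            make_peak("chr1", 4950, 200, 1.0),   # straddles boundary, mean inside
        ]
        ps = PeakSet(mark=Mark.H3K27ME3, condition=Condition.T0, peaks=peaks)
        regions = [GenomicInterval("chr1", 500, 5100)]
        assert cumulative_auc(ps, regions) == pytest.approx(100 + 200 + 200)
        assert cumulative_auc(ps, []) == 0.0


class TestScaling:
    def test_divide_by_smallest(self):
        aucs = dict(zip(CONDITIONS, [100.0, 160.0, 240.0, 130.0]))
        factors = scaling_factors(aucs)
        assert [factors[c] for c in CONDITIONS] == pytest.approx([1.0, 1.6, 2.4, 1.3])

    def test_equal_aucs_identity(self):
        factors = scaling_factors({c: 7.0 for c in CONDITIONS})
        assert all(v == 1.0 for v in factors.values())

    def test_label_permutation_equivariance(self):
        vals = [100.0, 160.0, 240.0, 130.0]
        f1 = scaling_factors(dict(zip(CONDITIONS, vals)))
        perm = [CONDITIONS[i] for i in (2, 0, 3, 1)]
        f2 = scaling_factors(dict(zip(perm, vals)))
        assert all(f2[c] == f1[p] for c, p in zip(perm, CONDITIONS))

    def test_nonpositive_auc_rejected(self):
        with pytest.raises(ChipquantError):
            scaling_factors(dict(zip(CONDITIONS, [0.0, 1.0, 1.0, 1.0])))

    def test_apply_scaling_divides_and_records(self):
        ps = peakset_from_heights([8.0], width=30)
        scaled = apply_scaling(ps, 2.4)
        assert scaled.peaks[0].max_height == pytest.approx(8.0 / 2.4)
        assert scaled.peaks[0].auc == pytest.approx(240.0 / 2.4)
        assert scaled.scaling_factor_applied == 2.4

    def test_factor_one_is_identity(self):
        ps = peakset_from_heights([8.0])
        scaled = apply_scaling(ps, 1.0)
        assert scaled.peaks[0].max_height == 8.0

    def test_double_normalization_detected(self):
        ps = apply_scaling(peakset_from_heights([8.0]), 1.5)
        with pytest.raises(ChipquantError, match="already normalized"):
            apply_scaling(ps, 1.5)


class TestFullNormalization:
    def test_conservation_after_scaling(self, pipeline):
        """Post-scaling cumulative AUC over sustained regions is equal."""
        res = pipeline.k27
        aucs = [
            cumulative_auc(res.normalized[c], res.sustained_regions)
            for c in CONDITIONS
        ]
        assert max(aucs) - min(aucs) <= 1e-6 * max(aucs)

    def test_equivariance_to_global_rescale(self, pipeline):
        """Multiplying one condition's signal by c multiplies its factor by c."""
        base = pipeline.k27.scaling_factors
        scaled_inputs = {}
        for cond, ps in pipeline.k27_raw.items():
            peaks = ps.peaks
            if cond == Condition.T8:
                peaks = [
                    type(p)(p.interval, p.mean_location, p.max_height * 3, p.auc * 3)
                    for p in peaks
                ]
            scaled_inputs[cond] = PeakSet(
                mark=ps.mark, condition=cond, peaks=peaks
            )
        res = normalize_by_sustained_regions(scaled_inputs)
        assert res.scaling_factors[Condition.T8] == pytest.approx(
            3 * base[Condition.T8], abs=1e-6 * 3 * base[Condition.T8]
        )

    def test_idempotence_on_normalized_data(self, pipeline):
        """Re-normalizing normalized data yields factors of 1."""
        fresh = {
            c: PeakSet(mark=ps.mark, condition=c, peaks=ps.peaks)
            for c, ps in pipeline.k27.normalized.items()
        }
        res = normalize_by_sustained_regions(fresh)
        for c in CONDITIONS:
            assert res.scaling_factors[c] == pytest.approx(1.0, abs=1e-3)
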