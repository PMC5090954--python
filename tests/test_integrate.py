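"""Gene-level integration: regions, marking, bivalency, CpG classes, overlaps."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from chipquant.integrate import (
    call_bivalent,
    call_marked,
    classify_promoter_cpg,
    cpg_state_table,
    enrichment_dynamics,
    gene_region,
    reference_set_overlap,
    sample_correlation,
)
from chipquant.model import (
    CONDITIONS,
    ChipquantError,
    Condition,
    GeneModel,
    GenomicInterval,
    Mark,
    PeakSet,
)
from conftest import make_peak


def normalized_peakset(peaks, mark=Mark.H3K27ME3, condition=Condition.T0):
    return PeakSet(
        mark=mark, condition=condition, peaks=peaks, scaling_factor_applied=1.0
    )


class TestGeneRegion:
    def test_plus_strand_flanks(self):
        g = GeneModel("G1", "chr1", "+", 10_000, 20_000)
        assert gene_region(g, 5000) == GenomicInterval("chr1", 5_000, 25_000)

    def test_minus_strand_same_span(self):
        g = GeneModel("G1", "chr1", "-", 20_000, 10_000)
        assert gene_region(g, 5000) == GenomicInterval("chr1", 5_000, 25_000)

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("G1", "chr1", "+", 2_000, 9_000)
        assert gene_region(g, 5000).start == 0


class TestCallMarked:
    def test_supra_threshold_peak_marks_gene(self):
        g = GeneModel("G1", "chr1", "+", 10_000, 20_000)
        ps = normalized_peakset([make_peak("chr1", 12_000, 500, 2.0**6.1)])
        enr = call_marked(ps, [g], background_log2=5.0)
        assert enr["G1"].marked
        assert enr["G1"].total_auc == pytest.approx(2.0**6.1 * 500)

    def test_subthreshold_peaks_contribute_auc_but_not_marking(self):
        g = GeneModel("G1", "chr1", "+", 10_000, 20_000)
        ps = normalized_peakset(
            [make_peak("chr1", 12_000, 500, 4.0), make_peak("chr1", 14_000, 500, 8.0)]
        )
        enr = call_marked(ps, [g], background_log2=5.0)
        assert not enr["G1"].marked
        assert enr["G1"].total_auc == pytest.approx((4.0 + 8.0) * 500)
        assert enr["G1"].log2_auc == pytest.approx(math.log2(6000.0))

    def test_gene_without_peaks_has_missing_log2(self):
        g = GeneModel("G1", "chr1", "+", 10_000, 20_000)
        enr = call_marked(normalized_peakset([]), [g], background_log2=5.0)
        assert enr["G1"].total_auc == 0.0 and enr["G1"].log2_auc is None

    def test_peak_in_overlapping_regions_counts_for_both(self):
        g1 = GeneModel("G1", "chr1", "+", 10_000, 20_000)
        g2 = GeneModel("G2", "chr1", "+", 18_000, 30_000)
        ps = normalized_peakset([make_peak("chr1", 19_000, 500, 2.0**6.0)])
        enr = call_marked(ps, [g1, g2], background_log2=5.0)
        assert enr["G1"].marked and enr["G2"].marked

    def test_unnormalized_peaks_refused(self):
        g = GeneModel("G1", "chr1", "+", 10_000, 20_000)
        ps = PeakSet(Mark.H3K27ME3, Condition.T0, [make_peak("chr1", 12_000, 500, 64.0)])
        with pytest.raises(ChipquantError, match="normalized"):
            call_marked(ps, [g], background_log2=5.0)

    def test_input_order_invariance(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 50_000 * (i + 1), 50_000 * (i + 1) + 9000)
            for i in range(10)
        ]
        peaks = [
            make_peak("chr1", int(rng.integers(40_000, 520_000)), 300, float(h))
            for h in rng.uniform(1, 100, 60)
        ]
        a = call_marked(normalized_peakset(peaks), genes, 5.0)
        shuffled = [peaks[i] for i in rng.permutation(len(peaks))]
        b = call_marked(normalized_peakset(shuffled), genes, 5.0)
        assert {g: e.total_auc for g, e in a.items()} == pytest.approx(
            {g: e.total_auc for g, e in b.items()}
        )

    def test_marked_count_monotone_in_threshold(self, pipeline):
        """Raising the background never increases the number of marked genes."""
        ds = pipeline.dataset
        ps = pipeline.k27.normalized[Condition.T0]
        counts = []
        for bg in np.arange(2.0, 7.0, 0.5):
            enr = call_marked(ps, ds.genes, bg)
            counts.append(sum(e.marked for e in enr.values()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBivalency:
    def _enr(self, marked_k4, marked_k27):
        from chipquant.integrate import GeneEnrichment

        k4 = {
            g: GeneEnrichment(g, Condition.T0, Mark.H3K4ME3, 1.0, 0.0, m)
            for g, m in marked_k4.items()
        }
        k27 = {
            g: GeneEnrichment(g, Condition.T0, Mark.H3K27ME3, 1.0, 0.0, m)
            for g, m in marked_k27.items()
        }
        return k4, k27

    def test_truth_table(self):
        k4, k27 = self._enr(
            {"a": True, "b": True, "c": False, "d": False},
            {"a": True, "b": False, "c": True, "d": False},
        )
        calls = call_bivalent(k4, k27)
        assert calls["a"].state == "bivalent"
        assert calls["b"].state == "K4_only"
        assert calls["c"].state == "K27_only"
        assert calls["d"].state == "none"

    def test_mismatched_universe_error(self):
        k4, k27 = self._enr({"a": True}, {"b": True})
        with pytest.raises(ChipquantError, match="universe"):
            call_bivalent(k4, k27)

    def test_planted_bivalent_recovered_exactly(self, pipeline):
        """With the noise floor below background, recovery is exact."""
        ds = pipeline.dataset
        bg = pipeline.report.background_log2
        e4 = call_marked(pipeline.k4.normalized[Condition.T0], ds.genes, bg)
        e27 = call_marked(pipeline.k27.normalized[Condition.T0], ds.genes, bg)
        calls = call_bivalent(e4, e27)
        bivalent = {g for g, c in calls.items() if c.state == "bivalent"}
        assert bivalent == ds.truth.bivalent_gene_ids


class TestDynamics:
    def _enrichment(self, aucs_by_cond):
        from chipquant.integrate import GeneEnrichment

        out = {}
        for cond, aucs in aucs_by_cond.items():
            out[cond] = {
                f"g{i}": GeneEnrichment(
                    f"g{i}", cond, Mark.H3K4ME3, a, math.log2(a) if a else None, True
                )
                for i, a in enumerate(aucs)
            }
        return out

    def test_identical_conditions_fc_one_p_one(self):
        aucs = [10.0, 20.0, 40.0, 80.0]
        dyn = enrichment_dynamics(
            self._enrichment({Condition.T0: aucs, Condition.T8: aucs})
        )
        assert dyn[Condition.T8].fold_change_vs_t0 == pytest.approx(1.0)
        assert dyn[Condition.T8].wilcoxon_p_vs_t0 == 1.0

    def test_mean_log2_shift_maps_to_fold_change(self):
        """Mean log2 AUC 5.0 -> 5.911 corresponds to FC 1.88."""
        base = 2.0 ** np.linspace(4.0, 6.0, 9)
        assert np.mean(np.log2(base)) == pytest.approx(5.0)
        shifted = base * 2.0**0.911
        dyn = enrichment_dynamics(
            self._enrichment({Condition.T0: base, Condition.T8: shifted})
        )
        assert dyn[Condition.T8].fold_change_vs_t0 == pytest.approx(
            2.0**0.911, rel=1e-12
        )
        assert dyn[Condition.T8].fold_change_vs_t0 == pytest.approx(1.88, abs=0.005)

    def test_common_linear_scale_cancels(self):
        a = [10.0, 20.0, 40.0, 30.0, 50.0]
        b = [15.0, 18.0, 80.0, 20.0, 60.0]
        d1 = enrichment_dynamics(self._enrichment({Condition.T0: a, Condition.T8: b}))
        d2 = enrichment_dynamics(
            self._enrichment(
                {Condition.T0: [x * 7 for x in a], Condition.T8: [x * 7 for x in b]}
            )
        )
        assert d1[Condition.T8].fold_change_vs_t0 == pytest.approx(
            d2[Condition.T8].fold_change_vs_t0
        )

    def test_too_few_paired_genes_error(self):
        with pytest.raises(ChipquantError, match="fewer than 2"):
            enrichment_dynamics(
                self._enrichment({Condition.T0: [10.0, 0.0], Condition.T8: [0.0, 5.0]})
            )

    def test_planted_global_shift_recovered(self, pipeline):
        """Pipeline fold change tracks the planted mean log2 shift.

        The paired universe includes genes whose AUC is background noise
        only (planted shift 0), so the oracle expectation is the mean of
        the planted per-gene shifts over the universe actually used; a
        0.15-log2 tolerance covers the dilution by sub-threshold noise
        AUC inside gene regions.
        """
        ds = pipeline.dataset
        bg = pipeline.report.background_log2
        per_cond = {
            c: call_marked(pipeline.k4.normalized[c], ds.genes, bg)
            for c in CONDITIONS
        }
        dyn = enrichment_dynamics(per_cond)
        base = per_cond[Condition.T0]
        for cond in (Condition.T8, Condition.T24, Condition.T_PLUS8):
            universe = [
                g
                for g, e in per_cond[cond].items()
                if e.total_auc > 0 and base[g].total_auc > 0
            ]
            expected = float(
                np.mean(
                    [ds.truth.gene_k4_log2fc[cond].get(g, 0.0) for g in universe]
                )
            )
            measured = math.log2(dyn[cond].fold_change_vs_t0)
            assert measured == pytest.approx(expected, abs=0.15)
            assert dyn[cond].wilcoxon_p_vs_t0 < 0.05


class TestCpGClassification:
    def test_saturated_cpg_sequence_is_hcp(self):
        assert classify_promoter_cpg("CG" * 250) == "HCP"

    def test_cpg_free_sequence_is_lcp(self):
        assert classify_promoter_cpg("AT" * 250) == "LCP"

    def test_constructed_intermediate_window(self):
        """ratio ~0.6 at GC 0.5 falls between the 0.48 and 0.75 cutoffs."""
        block = "CATG" * 120  # no CpG: C always followed by A
        seq = (("CG" * 19) + block)[:500]
        c, g = seq.count("C"), seq.count("G")
        ratio = seq.count("CG") * 500 / (c * g)
        assert 0.48 <= ratio < 0.75
        assert (c + g) / 500 <= 0.55
        assert classify_promoter_cpg(seq) == "ICP"

    def test_short_sequence_error(self):
        with pytest.raises(ChipquantError, match="short"):
            classify_promoter_cpg("ACGT" * 100)

    def test_excess_n_is_unknown(self):
        seq = "N" * 60 + "CG" * 220
        assert classify_promoter_cpg(seq) == "unknown"

    def test_tss_offset_trims_long_sequences(self):
        seq = "AT" * 200 + "CG" * 450 + "AT" * 200
        assert classify_promoter_cpg(seq, tss_offset=1100) == "HCP"
        with pytest.raises(ChipquantError, match="cover"):
            classify_promoter_cpg(seq, tss_offset=100)

    def test_agrees_with_bruteforce_window_counter(self, rng):
        """Cumulative-sum scan equals a per-window string counter."""

        def brute(seq, window=500):
            hcp = lcp_hit = False
            for s in range(len(seq) - window + 1):
                w = seq[s : s + window]
                c, g = w.count("C"), w.count("G")
                ratio = w.count("CG") * window / (c * g) if c and g else 0.0
                if ratio > 0.75 and (c + g) / window > 0.55:
                    hcp = True
                if ratio >= 0.48:
                    lcp_hit = True
            return "HCP" if hcp else ("ICP" if lcp_hit else "LCP")

        bases = np.array(list("ACGT"))
        for _ in range(20):
            probs = rng.dirichlet([1, 2, 2, 1])
            seq = "".join(rng.choice(bases, size=900, p=probs))
            assert classify_promoter_cpg(seq) == brute(seq)


class TestCpGStateTable:
    def _calls(self, states):
        from chipquant.integrate import BivalencyCall

        return {
            g: BivalencyCall(g, Condition.T0, s) for g, s in states.items()
        }

    def test_counts_and_percentages(self):
        states = {f"h{i}": ("K4_only" if i < 7 else "none") for i in range(10)}
        classes = {g: "HCP" for g in states}
        counts = cpg_state_table(self._calls(states), classes)
        assert counts.k4_marked["HCP"] == 7
        assert counts.percentages("k4_marked")["HCP"] == pytest.approx(70.0)

    def test_empty_class_percentage_is_missing(self):
        states = {"a": "bivalent"}
        counts = cpg_state_table(self._calls(states), {"a": "HCP"})
        assert counts.percentages("bivalent")["LCP"] is None
        assert counts.percentages("bivalent")["HCP"] == pytest.approx(100.0)

    def test_bivalent_fraction_highest_in_hcp_on_synthetic(self, pipeline):
        ds = pipeline.dataset
        bg = pipeline.report.background_log2
        e4 = call_marked(pipeline.k4.normalized[Condition.T0], ds.genes, bg)
        e27 = call_marked(pipeline.k27.normalized[Condition.T0], ds.genes, bg)
        calls = call_bivalent(e4, e27)
        counts = cpg_state_table(calls, ds.truth.cpg_class_by_gene)
        pct = counts.percentages("bivalent")
        assert pct["HCP"] > pct["ICP"] > pct["LCP"]


class TestReferenceOverlap:
    def test_self_overlap_is_perfect(self):
        universe = {f"g{i}" for i in range(200)}
        s = {f"g{i}" for i in range(40)}
        res = reference_set_overlap(s, {"self": s}, universe)["self"]
        assert res.jaccard == 1.0 and res.overlap == 40
        assert res.hypergeom_p < 1e-20

    def test_disjoint_sets(self):
        universe = {f"g{i}" for i in range(100)}
        res = reference_set_overlap(
            {"g0"}, {"other": {"g99"}}, universe
        )["other"]
        assert res.overlap == 0 and res.jaccard == 0.0

    def test_hypergeometric_tail_against_exact_sum(self):
        """universe 1000, set 100, reference 100, overlap 30."""
        universe = {f"g{i}" for i in range(1000)}
        s = {f"g{i}" for i in range(100)}
        ref = {f"g{i}" for i in range(70, 170)}
        res = reference_set_overlap(s, {"ref": ref}, universe)["ref"]
        assert res.overlap == 30
        exact = sum(
            comb(100, k, exact=True) * comb(900, 100 - k, exact=True)
            for k in range(30, 101)
        ) / comb(1000, 100, exact=True)
        assert res.hypergeom_p == pytest.approx(float(exact), rel=1e-9)


class TestSampleCorrelation:
    def _track(self, rng, n=2000):
        # dense enough that most genome bins carry signal in both samples
        positions = rng.integers(0, 5_000_000, n)
        return normalized_peakset(
            [
                make_peak("chr1", int(p), 200, float(h))
                for p, h in zip(positions, rng.uniform(1, 50, n))
            ]
        )

    def test_identical_tracks_perfectly_correlated(self, rng):
        a = self._track(rng)
        assert sample_correlation(a, a).statistic == pytest.approx(1.0)

    def test_rank_invariance_under_doubling(self, rng):
        a = self._track(rng)
        b = normalized_peakset(
            [
                type(p)(p.interval, p.mean_location, p.max_height, p.auc * 2)
                for p in a.peaks
            ]
        )
        assert sample_correlation(a, b).statistic == pytest.approx(1.0)

    def test_independent_tracks_uncorrelated(self, rng):
        a = self._track(rng)
        b = self._track(rng)
        res = sample_correlation(a, b)
        assert abs(res.statistic) < 0.2
        assert res.p_value > 0.05

    def test_too_few_bins_error(self):
        a = normalized_peakset([make_peak("chr1", 100, 50, 1.0)])
        with pytest.raises(ChipquantError, match="bins"):
            sample_correlation(a, a)
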