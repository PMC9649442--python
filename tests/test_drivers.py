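import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cllstrat.drivers import (
    GeneTestResult,
    Lesion,
    bh_fdr,
    binomial_recurrence_test,
    combine_hmp_weighted,
    combine_stouffer_weighted,
    focality_recurrence,
    minimally_affected_regions,
    select_drivers_method1,
    select_drivers_method2,
)
from cllstrat.variants import CNASegment


class TestStouffer:
    def test_all_half_is_half(self):
        assert combine_stouffer_weighted([0.5] * 4, [1] * 4) == pytest.approx(0.5)

    def test_single_test_identity(self):
        assert combine_stouffer_weighted([0.05], [1]) == pytest.approx(0.05)

    def test_four_equal_pvalues_normal_tail_oracle(self):
        # Z = 4 z_{0.05} / sqrt(4); tail computed from the normal CDF directly
        expected = norm.sf(4 * norm.isf(0.05) / 2)
        assert combine_stouffer_weighted([0.05] * 4, [1] * 4) == pytest.approx(expected)
        assert expected == pytest.approx(5.0146e-4, rel=1e-3)

    def test_equal_weights_match_unweighted_and_rescaling_invariance(self):
        p = [0.01, 0.2, 0.5, 0.9]
        unweighted = combine_stouffer_weighted(p)
        assert combine_stouffer_weighted(p, [1, 1, 1, 1]) == pytest.approx(unweighted)
        assert combine_stouffer_weighted(p, [7, 7, 7, 7]) == pytest.approx(unweighted)

    def test_boundary_pvalues_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = combine_stouffer_weighted([0.0, 1.0], [1, 1])
        assert 0 < out < 1


class TestHarmonicMean:
    def test_equal_values_identity(self):
        assert combine_hmp_weighted([0.3] * 4, [1] * 4) == pytest.approx(0.3)

    def test_two_value_formula(self):
        assert combine_hmp_weighted([0.01, 1.0], [1, 1]) == pytest.approx(2 / 101)

    @given(
        st.lists(st.floats(1e-6, 1.0 - 1e-6), min_size=1, max_size=8),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_min_and_max(self, p, wseed):
        w = np.random.default_rng(wseed).uniform(0.1, 5.0, size=len(p))
        out = combine_hmp_weighted(p, w)
        assert min(p) - 1e-12 <= out <= max(p) + 1e-12


def _brute_force_bh(p):
    """Independent step-up oracle: q_(i) = min over j >= i of p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = running
    return q


class TestBHFDR:
    def test_single_value(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_permutation_equivariance(self):
        p = [0.2, 0.001, 0.8, 0.04, 0.04]
        base = bh_fdr(p)
        perm = [3, 0, 4, 1, 2]
        np.testing.assert_allclose(bh_fdr([p[i] for i in perm]), [base[i] for i in perm])

    def test_matches_bruteforce_on_all_permutations_of_five(self):
        p5 = [0.003, 0.04, 0.04, 0.2, 0.9]
        for perm in itertools.permutations(p5):
            np.testing.assert_allclose(bh_fdr(list(perm)), _brute_force_bh(list(perm)))


class TestMethod1Selection:
    def _results(self, fdr_rows):
        """Build gene results whose per-algorithm BH-FDR equals the given rows
        by using a large all-null background (p=1 for padding genes)."""
        genes = [
            GeneTestResult(f"G{i}", list(row)) for i, row in enumerate(fdr_rows)
        ]
        return genes

    def test_two_of_four_vote(self):
        # one clearly significant gene among nulls: 2 of 4 algorithms fire
        rows = [[1e-8, 1e-8, 0.9, 0.9]] + [[0.9, 0.9, 0.9, 0.9]] * 20
        selected = select_drivers_method1(self._results(rows), alpha=0.05)
        assert "G0" in selected
        assert all(g == "G0" for g in selected) or selected == {"G0"}

    def test_single_algorithm_insufficient_when_combined_not_significant(self):
        rows = [[0.04, 0.9, 0.9, 0.9]] + [[0.5, 0.5, 0.5, 0.5]] * 10
        results = self._results(rows)
        selected = select_drivers_method1(results, alpha=0.05)
        g0 = results[0]
        if "G0" in selected:  # only via a combined route, never the vote
            assert "vote_2of4" not in g0.selected_by
        assert sum(f < 0.05 for f in g0.fdr_per_algorithm) < 2

    def test_all_null_never_selected(self):
        rows = [[1.0, 1.0, 1.0, 1.0]] * 5
        assert select_drivers_method1(self._results(rows), alpha=0.05) == set()

    def test_mismatched_algorithm_counts_rejected(self):
        results = [GeneTestResult("A", [0.5] * 4), GeneTestResult("B", [0.5] * 3)]
        with pytest.raises(ValueError):
            select_drivers_method1(results)

    def test_power_and_false_selection_on_planted_driver(self):
        """One gene with a 20x mutation-rate excess in 200-sample cohorts:
        the vote/combination selection finds it in >= 90% of cohorts and
        selects a null gene in at most ~alpha of cohorts."""
        rng = np.random.default_rng(77)
        n_cohorts, n_genes, n_samples = 120, 50, 200
        rate, L = 1e-6, 1500
        p_null = 1 - np.exp(-rate * L)
        p_driver = 1 - np.exp(-20 * rate * L)
        hits = fa = 0
        for _ in range(n_cohorts):
            results = []
            for g in range(n_genes):
                p_hit = p_driver if g == 0 else p_null
                pvals = [
                    binomial_recurrence_test(
                        int(rng.binomial(n_samples, p_hit)), n_samples, L, rate
                    )
                    for _ in range(4)
                ]
                results.append(GeneTestResult(f"G{g}", pvals))
            sel = select_drivers_method1(results, alpha=0.05)
            hits += "G0" in sel
            fa += bool(sel - {"G0"})
        assert hits / n_cohorts >= 0.9
        se = np.sqrt(0.05 * 0.95 / n_cohorts)
        assert fa / n_cohorts <= 0.05 + 3 * se


def _seg(chrom, start, end, type="loss"):
    return CNASegment(chrom, start, end, type, total_copy_number=1 if type == "loss" else 3)


def _bruteforce_regions(segments_by_sample, min_samples, length=10_000):
    """Per-base coverage oracle on a toy chromosome."""
    out = {}
    for t in ("gain", "loss"):
        cov = np.zeros(length + 2, dtype=int)
        persample = {}
        for sample, segs in segments_by_sample.items():
            mask = np.zeros(length + 2, dtype=bool)
            for s in segs:
                if s.type == t:
                    mask[s.start : s.end + 1] = True
            persample[sample] = mask
        cov = np.sum(list(persample.values()), axis=0)
        out[t] = cov
    return out


class TestMinimallyAffectedRegions:
    def test_identical_segment_in_four_samples(self):
        segs = {f"s{i}": [_seg("chr1", 100, 500)] for i in range(4)}
        regions = minimally_affected_regions(segs)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_samples, r.type) == (100, 500, 4, "loss")

    def test_three_samples_insufficient(self):
        segs = {f"s{i}": [_seg("chr1", 100, 500)] for i in range(3)}
        assert minimally_affected_regions(segs) == []

    def test_staggered_core_is_intersection(self):
        segs = {
            f"s{i}": [_seg("chr1", 100 + 10 * i, 500 + 10 * i)] for i in range(5)
        }
        regions = minimally_affected_regions(segs, min_samples=4)
        # max-coverage core = intersection of all five: [140, 500]
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (140, 500)
        assert regions[0].n_samples == 5

    def test_agrees_with_per_base_coverage_oracle(self, rng):
        segs = {
            f"s{i}": [
                _seg("chrT", int(a), int(a + rng.integers(50, 2000)),
                     type=rng.choice(["gain", "loss"]))
                for a in rng.integers(1, 8000, size=3)
            ]
            for i in range(8)
        }
        cov = _bruteforce_regions(segs, 4)
        regions = minimally_affected_regions(segs, min_samples=4)
        for r in regions:
            c = cov[r.type]
            # the reported core has the claimed coverage everywhere
            assert (c[r.start : r.end + 1] >= r.n_samples).all()
            assert c[r.start : r.end + 1].max() == r.n_samples
        # every base with coverage >= 4 is inside some reported run's type
        for t in ("gain", "loss"):
            covered = set()
            for r in regions:
                if r.type == t:
                    covered.update(range(r.start, r.end + 1))
            peak_bases = np.where(cov[t] >= 4)[0]
            if peak_bases.size:
                # cores are max-coverage subsets of >= 4 runs
                assert any(b in covered for b in peak_bases)


class TestFocalityRecurrence:
    def test_degenerate_maximum(self):
        lesions = [Lesion("s1", {"TP53"}, "loss")]
        fr = focality_recurrence("TP53", lesions, n_cohort=1)
        assert fr.recurrence_score == pytest.approx(1.0)
        assert fr.focality_score == pytest.approx(1.0)

    def test_broad_lesion_focality(self):
        lesions = [Lesion("s1", {f"G{i}" for i in range(10)} | {"TP53"}, "loss")]
        fr = focality_recurrence("TP53", lesions, n_cohort=1)
        assert fr.focality_score == pytest.approx(1 / 11)

    def test_unaltered_gene_scores_zero(self):
        lesions = [Lesion("s1", {"ATM"}, "loss")]
        fr = focality_recurrence("TP53", lesions, n_cohort=10)
        assert fr.recurrence_score == fr.focality_score == fr.combined_score == 0.0

    def test_zero_gene_lesion_rejected(self):
        with pytest.raises(ValueError):
            Lesion("s1", set(), "loss")


class TestMethod2Selection:
    def _fr(self, snv, mech="TSG", direction="loss", score=0.9):
        from cllstrat.drivers import FocalityRecurrence

        return FocalityRecurrence("G", score, score, score * score, snv, mech, direction)

    def test_candidate_with_five_snvs(self):
        cand, perm = select_drivers_method2([self._fr(5)], score_threshold=0.5)
        assert cand == {"G"} and perm == set()

    def test_four_snvs_goes_permissive(self):
        cand, perm = select_drivers_method2([self._fr(4)], score_threshold=0.5)
        assert cand == set() and perm == {"G"}

    def test_discordant_mechanism_excluded(self):
        cand, perm = select_drivers_method2(
            [self._fr(10, mech="oncogene", direction="loss")], score_threshold=0.5
        )
        assert cand == set() and perm == set()
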