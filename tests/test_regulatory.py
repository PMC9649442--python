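import math

import numpy as np
import pytest
from scipy.stats import kstest

from cllstrat.regulatory import (
    GenomicInterval,
    RECatalogEntry,
    build_re_catalog,
    call_allelic_skew,
    expression_contrast,
    link_enhancer_targets,
    fdr_across_catalog,
)
from cllstrat.regulatory import test_re_recurrence as re_recurrence_test
from cllstrat.synthetic import generate_re_signal


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestCatalog:
    def test_intersection_by_hand(self):
        catalog = build_re_catalog([iv(100, 200)], [iv(150, 250)])
        assert len(catalog) == 1
        assert (catalog[0].interval.start, catalog[0].interval.end) == (150, 200)

    def test_disjoint_tracks_empty(self):
        assert build_re_catalog([iv(100, 200)], [iv(300, 400)]) == []

    def test_commutative_in_track_order(self):
        atac = [iv(0, 500), iv(900, 1200)]
        k27 = [iv(100, 1000)]
        a = build_re_catalog(atac, k27)
        b = build_re_catalog(list(reversed(atac)), k27)
        assert [(e.interval.start, e.interval.end) for e in a] == [
            (e.interval.start, e.interval.end) for e in b
        ]

    def test_state_requires_two_samples(self):
        tracks_one = {"s1": [(iv(0, 1000), "enhancer")]}
        entry = build_re_catalog([iv(100, 200)], [iv(100, 200)], tracks_one)[0]
        assert entry.re_type is None and entry.state_support == 0

        tracks_two = {
            "s1": [(iv(0, 1000), "enhancer")],
            "s2": [(iv(0, 1000), "enhancer")],
        }
        entry = build_re_catalog([iv(100, 200)], [iv(100, 200)], tracks_two)[0]
        assert entry.re_type == "enhancer" and entry.state_support == 2

    def test_ighv_specific_flagging(self):
        entries = build_re_catalog(
            [iv(100, 200), iv(500, 600)],
            [iv(100, 200), iv(500, 600)],
            u_track=[iv(100, 200)],
            m_track=[iv(500, 600)],
        )
        assert entries[0].ighv_specificity == "u-only"
        assert entries[1].ighv_specificity == "m-only"

    def test_outputs_non_overlapping(self):
        entries = build_re_catalog(
            [iv(0, 300), iv(250, 600)], [iv(100, 500)]
        )
        spans = sorted((e.interval.start, e.interval.end) for e in entries)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            iv(200, 100)


class TestLinking:
    def test_identical_vectors_linked(self):
        data = generate_re_signal(30, 2, 2, [(0, 0)], rho=1.0, seed=0)
        links = link_enhancer_targets(
            data.re_entries, data.signal, data.expr, data.tads, data.gene_locations
        )
        linked = {(l.re_id, l.gene) for l in links}
        assert data.linked_pairs[0] in linked
        assert all(abs(l.pearson_r) <= 1 for l in links)

    def test_gene_outside_tad_never_tested(self):
        # one RE in TAD 0, one gene placed in TAD 1: no pair is testable
        data = generate_re_signal(30, 1, 6, [], rho=0.0, seed=1)
        gene_far = {"GENE005": data.gene_locations["GENE005"]}
        links = link_enhancer_targets(
            data.re_entries, data.signal, data.expr.loc[["GENE005"]],
            data.tads, gene_far,
        )
        assert links == []

    def test_planted_rho08_recovery(self):
        """At rho=0.8 and n=100 samples, >= 95% of planted links are found
        at the r >= 0.3, FDR <= 0.05 criteria."""
        pairs = [(i, i) for i in range(40)]
        data = generate_re_signal(100, 40, 40, pairs, rho=0.8, seed=2)
        links = link_enhancer_targets(
            data.re_entries, data.signal, data.expr, data.tads, data.gene_locations
        )
        found = {(l.re_id, l.gene) for l in links}
        recovered = sum(p in found for p in data.linked_pairs)
        assert recovered / len(pairs) >= 0.95

    def test_links_stay_within_tad(self):
        pairs = [(i, i) for i in range(10)]
        data = generate_re_signal(60, 10, 10, pairs, rho=0.9, seed=3)
        tad_of = {e.id: t for e in data.re_entries for t in data.tads
                  if e.interval.overlaps(t)}
        links = link_enhancer_targets(
            data.re_entries, data.signal, data.expr, data.tads, data.gene_locations
        )
        for l in links:
            assert data.gene_locations[l.gene].overlaps(tad_of[l.re_id])

    def test_too_few_shared_samples_rejected(self):
        data = generate_re_signal(2, 2, 2, [], rho=0.0, seed=4)
        with pytest.raises(ValueError):
            link_enhancer_targets(
                data.re_entries, data.signal, data.expr, data.tads,
                data.gene_locations,
            )


def _re(start=0, end=1000):
    interval = GenomicInterval("chr1", start, end)
    return RECatalogEntry(interval, "enhancer", 2, id="RE_test")


class TestRecurrence:
    def test_no_mutations_p_one(self):
        t = re_recurrence_test(_re(), {}, n_samples=485, background_rate=1e-6)
        assert t.p_recurrence == 1.0
        assert t.hotspot_positions == [] and not t.kataegis_flag

    def test_binomial_tail_exhaustive_oracle(self):
        """1 kb element, rate 1e-6/bp, 485 samples, 6 mutated: tail equals
        the exhaustively summed binomial upper tail."""
        muts = {f"s{i}": [("chr1", 100 + i)] for i in range(6)}
        t = re_recurrence_test(_re(), muts, n_samples=485, background_rate=1e-6)
        p_hit = 1 - math.exp(-1e-6 * 1000)
        oracle = sum(
            math.comb(485, k) * p_hit**k * (1 - p_hit) ** (485 - k)
            for k in range(6, 486)
        )
        assert t.p_recurrence == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(1.1610e-5, rel=1e-3)

    def test_hotspot_three_samples_same_site(self):
        muts = {f"s{i}": [("chr1", 500)] for i in range(3)}
        t = re_recurrence_test(_re(), muts, n_samples=485, background_rate=1e-6)
        assert t.hotspot_positions == [500]

    def test_kataegis_six_in_window_one_sample(self):
        muts = {"s1": [("chr1", 100 + 50 * i) for i in range(6)]}
        t = re_recurrence_test(_re(), muts, n_samples=485, background_rate=1e-6)
        assert t.kataegis_flag

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)

    def test_null_pvalues_uniform(self, rng):
        """Recurrence p-values are ~Uniform(0,1) when data match the
        background model (KS test over 1000 simulated elements)."""
        n_samples, rate, length = 200, 1e-5, 1000
        p_hit = 1 - math.exp(-rate * length)
        from scipy.stats import binom

        # discrete statistic: randomized (uniform-smoothed) p-values are
        # exactly Uniform(0,1) under the null
        smoothed = []
        for i in range(1000):
            n_mut = rng.binomial(n_samples, p_hit)
            muts = {f"s{j}": [("chr1", int(rng.integers(1, length)))] for j in range(n_mut)}
            t = re_recurrence_test(
                _re(), muts, n_samples=n_samples, background_rate=rate
            )
            lo = binom.sf(n_mut, n_samples, p_hit)
            smoothed.append(lo + rng.random() * (t.p_recurrence - lo))
        assert kstest(smoothed, "uniform").pvalue > 0.01

    def test_fdr_across_catalog_sets_and_selects(self):
        tests = [
            re_recurrence_test(
                _re(), {f"s{i}": [("chr1", 10 + i)] for i in range(k)},
                n_samples=485, background_rate=1e-6,
            )
            for k in (0, 1, 8)
        ]
        sig = fdr_across_catalog(tests, fdr_threshold=0.1)
        assert all(not math.isnan(t.fdr) for t in tests)
        assert {t.n_mutated_samples for t in sig} == {8}


class TestAllelicSkew:
    @pytest.mark.parametrize(
        "wgs, assay, depth, expected",
        [
            (0.40, 0.55, 12, "alt-skewed"),
            (0.40, 0.45, 50, "none"),
            (0.40, 0.70, 8, "insufficient"),
            (0.55, 0.40, 12, "ref-skewed"),
            (0.40, 0.50, 10, "none"),  # |diff| exactly 0.1: inside band
        ],
    )
    def test_threshold_logic(self, wgs, assay, depth, expected):
        call = call_allelic_skew(("chr1", 1, "A", "T"), wgs, assay, depth)
        assert call.skew == expected

    def test_symmetry_under_negated_difference(self, rng):
        for _ in range(50):
            wgs, d = rng.uniform(0.2, 0.8), rng.uniform(-0.3, 0.3)
            up = call_allelic_skew(("chr1", 1, "A", "T"), wgs, wgs + d, 30).skew
            dn = call_allelic_skew(("chr1", 1, "A", "T"), wgs, wgs - d, 30).skew
            flip = {"alt-skewed": "ref-skewed", "ref-skewed": "alt-skewed", "none": "none"}
            assert dn == flip[up]


class TestExpressionContrast:
    def test_identical_groups(self):
        ratio, p = expression_contrast([10, 12, 11], [10, 12, 11])
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_textbook_welch_numbers(self):
        ratio, p = expression_contrast([10, 12, 11], [5, 6, 5, 6])
        assert ratio == pytest.approx(2.0)
        assert p == pytest.approx(0.0033958, rel=1e-4)

    def test_single_mut_sample_flagged(self):
        ratio, p = expression_contrast([10], [5, 6, 5])
        assert ratio == pytest.approx(10 / (16 / 3))
        assert math.isnan(p)

    def test_zero_wt_mean_flagged(self):
        ratio, _ = expression_contrast([1, 2], [0, 0])
        assert math.isnan(ratio)
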