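import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_site, nb_draw
from nbcall import (
    AlterationKey,
    CallerConfig,
    ErrorModelFit,
    SampleCounts,
    SitePileup,
    apply_post_filters,
    assign_tn_status,
    bh_adjust,
    call_site,
    compute_pvalues,
    compute_rvsb,
    intersect_replicates,
    phred_qval,
    predict_detectability,
)
from nbcall.calling import SampleCall, SiteCalls
from nbcall.model import _nb_logpmf


def _fit(e, sigma, n):
    return ErrorModelFit(e_hat=e, sigma_hat=sigma, weights=np.ones(n), n_iter=1, converged=True)


def _pileup(counts):
    return SitePileup(AlterationKey("chr1", 100, "G", "T"), counts)


class TestComputePvalues:
    def test_ao_zero_is_one(self):
        site = _pileup([SampleCounts(f"s{i}", 500, 500) for i in range(5)])
        p = compute_pvalues(site, _fit(1e-3, 0.1, 5))
        assert np.all(p == 1.0)

    def test_poisson_limit_hand_sum(self):
        # e=1e-4, DP=10000 -> mu=1; AO=6 -> 1 - e^-1 * sum_0^5 1/k!
        site = _pileup(
            [SampleCounts("a", 5000, 5000, 3, 3)] + [SampleCounts(f"s{i}", 5000, 5000) for i in range(4)]
        )
        p = compute_pvalues(site, _fit(1e-4, 0.0, 5))
        expected = 1.0 - math.exp(-1) * sum(1 / math.factorial(k) for k in range(6))
        assert p[0] == pytest.approx(expected, rel=1e-10)
        assert p[0] == pytest.approx(5.9418e-4, abs=1e-8)

    def test_nb_brute_force(self):
        site = _pileup(
            [SampleCounts("a", 10000, 10000, 30, 30)] + [SampleCounts(f"s{i}", 10000, 10000) for i in range(3)]
        )
        p = compute_pvalues(site, _fit(1e-3, 0.3, 4))
        k = np.arange(60)
        brute = 1.0 - float(np.exp(_nb_logpmf(k, np.full(60, 20.0), 0.3)).sum())
        assert p[0] == pytest.approx(brute, rel=1e-10)

    def test_dp_zero_gets_one(self):
        site = _pileup([SampleCounts("a"), SampleCounts("b", 100, 100, 5, 5)])
        p = compute_pvalues(site, _fit(1e-3, 0.1, 2))
        assert p[0] == 1.0

    def test_degenerate_zero_rate(self):
        site = _pileup([SampleCounts("a", 50, 50, 1, 0), SampleCounts("b", 50, 50)])
        p = compute_pvalues(site, _fit(0.0, 0.0, 2))
        assert p[1] == 1.0
        assert 0 < p[0] < 1e-300

    def test_length_mismatch(self):
        site = _pileup([SampleCounts("a", 10, 10)])
        with pytest.raises(ValueError):
            compute_pvalues(site, _fit(1e-3, 0.1, 3))


class TestBhAdjust:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0] * 7) == 1.0)

    def test_single_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_q_ge_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariant(self, p):
        p = np.asarray(p)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(p))
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestPhredQval:
    def test_paper_threshold(self):
        assert phred_qval(1e-5) == pytest.approx(50.0)

    def test_one_is_zero(self):
        assert phred_qval(1.0) == 0.0

    def test_closed_form(self):
        assert phred_qval(0.001) == pytest.approx(30.0)

    def test_zero_maps_to_cap(self):
        assert phred_qval(0.0, cap=255) == 255


class TestRvsb:
    def test_balanced(self):
        assert compute_rvsb(SampleCounts("s", 105, 105, 5, 5)) == pytest.approx(0.5)

    def test_one_sided(self):
        assert compute_rvsb(SampleCounts("s", 110, 100, 10, 0)) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # AO_f=8, AO_r=2, RO_f=RO_r=100 -> max(800, 200)/1000
        assert compute_rvsb(SampleCounts("s", 108, 102, 8, 2)) == pytest.approx(0.8)

    def test_undefined_at_ao_zero(self):
        assert compute_rvsb(SampleCounts("s", 100, 100)) is None

    def test_undefined_denominator(self):
        # all reads are variant on both strands: RO == 0 on both
        assert compute_rvsb(SampleCounts("s", 5, 5, 5, 5)) is None


class TestCallSite:
    def test_no_alternate_reads_no_variants(self):
        site = _pileup([SampleCounts(f"s{i}", 250, 250) for i in range(30)])
        sc = call_site(site)
        assert not any(c.is_variant for c in sc.calls)

    def test_single_spike_called(self, rng):
        site = make_site(rng, n=100, dp=10000, e=1e-4, sigma=0.1, spike_idx=(4,), spike_vaf=0.005)
        sc = call_site(site)
        called = [c.sample_id for c in sc.variant_calls]
        assert called == ["s004"]
        assert sc.calls[4].qval >= 50

    def test_widespread_variant_absorbed(self, rng):
        # >20% of samples carry the variant: the error model absorbs it
        site = make_site(rng, n=100, dp=5000, e=1e-3, sigma=0.1,
                         spike_idx=tuple(range(25)), spike_vaf=0.25)
        sc = call_site(site)
        spiked_called = [c for c in sc.calls[:25] if c.is_variant]
        assert len(spiked_called) < 13

    def test_qval_monotone_in_ao(self):
        fit = _fit(1e-3, 0.2, 4)
        qvals = []
        for ao in [2, 5, 10, 40]:
            site = _pileup(
                [SampleCounts("a", 2500, 2500, ao, 0)]
                + [SampleCounts(f"s{i}", 2500, 2500) for i in range(3)]
            )
            qvals.append(call_site(site, fit=fit).calls[0].qval)
        assert qvals == sorted(qvals)


class TestPostFilters:
    def _calls(self, key, entries):
        calls = [
            SampleCall(sid, 1e-9, 1e-9, 90.0, counts=c, is_variant=True, rvsb=r)
            for sid, c, r in entries
        ]
        return SiteCalls(key=key, fit=_fit(1e-4, 0.1, len(calls)), calls=calls)

    def test_isolated_clean_variant(self):
        key = AlterationKey("chr1", 100, "G", "T")
        s = self._calls(key, [("a", SampleCounts("a", 505, 505, 5, 5), 0.5)])
        apply_post_filters([s])
        assert s.calls[0].filter_flags == set()

    def test_rvsb_fail(self):
        key = AlterationKey("chr1", 100, "G", "T")
        s = self._calls(key, [("a", SampleCounts("a", 510, 500, 10, 0), 0.99)])
        apply_post_filters([s])
        assert "RVSB_FAIL" in s.calls[0].filter_flags

    def test_proximity_fail(self):
        k1 = AlterationKey("chr1", 100, "G", "T")
        k2 = AlterationKey("chr1", 103, "C", "A")
        low = self._calls(k1, [("a", SampleCounts("a", 2501, 2501, 5, 5), 0.5)])  # VAF 0.002
        high = self._calls(k2, [("a", SampleCounts("a", 2500, 2500, 1250, 1250), 0.5)])  # VAF 0.5
        apply_post_filters([low, high])
        assert "PROXIMITY_FAIL" in low.calls[0].filter_flags
        assert "PROXIMITY_FAIL" not in high.calls[0].filter_flags

    def test_proximity_respects_window(self):
        k1 = AlterationKey("chr1", 100, "G", "T")
        k2 = AlterationKey("chr1", 110, "C", "A")
        low = self._calls(k1, [("a", SampleCounts("a", 2501, 2501, 5, 5), 0.5)])
        high = self._calls(k2, [("a", SampleCounts("a", 2500, 2500, 1250, 1250), 0.5)])
        apply_post_filters([low, high])
        assert low.calls[0].filter_flags == set()

    def test_lowconf_change(self):
        key = AlterationKey("chr1", 100, "G", "T")
        cfg = CallerConfig(lowconf_changes=frozenset({"G>T"}))
        s = self._calls(key, [("a", SampleCounts("a", 505, 505, 5, 5), 0.5)])  # VAF ~1%
        apply_post_filters([s], cfg)
        assert "LOWCONF_CHANGE_FAIL" in s.calls[0].filter_flags

    def test_sample_qc(self):
        sites = []
        for i in range(150):
            key = AlterationKey("chr1", 100 + 10 * i, "G", "T")
            sites.append(self._calls(key, [("a", SampleCounts("a", 505, 505, 5, 5), 0.5)]))
        apply_post_filters(sites)
        assert all("SAMPLE_QC_FAIL" in s.calls[0].filter_flags for s in sites)

    def test_annotation_only(self, rng):
        site = make_site(rng, n=50, dp=5000, e=1e-3, sigma=0.1, spike_idx=(0,), spike_vaf=0.1)
        sc = call_site(site)
        before = [(c.p_value, c.q_value, c.qval) for c in sc.calls]
        apply_post_filters([sc])
        assert [(c.p_value, c.q_value, c.qval) for c in sc.calls] == before

    def test_unsorted_rejected(self):
        k1 = AlterationKey("chr1", 200, "G", "T")
        k2 = AlterationKey("chr1", 100, "C", "A")
        s1 = self._calls(k1, [("a", SampleCounts("a", 505, 505, 5, 5), 0.5)])
        s2 = self._calls(k2, [("a", SampleCounts("a", 505, 505, 5, 5), 0.5)])
        with pytest.raises(ValueError):
            apply_post_filters([s1, s2])


class TestIntersectReplicates:
    def _site(self, key, variants, all_samples=("s1", "s2")):
        calls = [
            SampleCall(s, 1e-9, 1e-9, 90.0, counts=SampleCounts(s, 100, 100, 5, 5),
                       is_variant=s in variants)
            for s in all_samples
        ]
        return SiteCalls(key=key, fit=_fit(1e-4, 0.1, len(calls)), calls=calls)

    def test_identity(self):
        k = AlterationKey("c", 1, "G", "T")
        a = [self._site(k, {"s1", "s2"})]
        b = [self._site(k, {"s1", "s2"})]
        assert intersect_replicates(a, b) == {(k, "s1"), (k, "s2")}

    def test_disjoint(self):
        k1 = AlterationKey("c", 1, "G", "T")
        k2 = AlterationKey("c", 2, "C", "A")
        assert intersect_replicates([self._site(k1, {"s1"})], [self._site(k2, {"s1"})]) == set()

    def test_partial_overlap(self):
        kgt = AlterationKey("c", 1, "G", "T")
        kca = AlterationKey("c", 2, "C", "A")
        a = [self._site(kgt, {"s1"}), self._site(kca, {"s2"})]
        b = [self._site(kgt, {"s1"}), self._site(kca, set())]
        assert intersect_replicates(a, b) == {(kgt, "s1")}

    def test_pairing_map(self):
        k = AlterationKey("c", 1, "G", "T")
        a = [self._site(k, {"s1"}, all_samples=("s1",))]
        b = [self._site(k, {"r1"}, all_samples=("r1",))]
        assert intersect_replicates(a, b, {"s1": "r1"}) == {(k, "s1")}

    def test_missing_pair_sample(self):
        k = AlterationKey("c", 1, "G", "T")
        a = [self._site(k, {"s1"})]
        b = [self._site(k, {"s1"})]
        with pytest.raises(KeyError):
            intersect_replicates(a, b, {"sX": "s1"})


class TestTnStatus:
    def _call(self, sid, dp, ao, qval):
        half = dp // 2
        return SampleCall(sid, 1e-9, 1e-9, qval,
                          counts=SampleCounts(sid, half, dp - half, ao, 0))

    def test_germline(self):
        t = self._call("t", 1000, 400, 200.0)
        n = self._call("n", 1000, 450, 200.0)
        assert assign_tn_status(t, n, _fit(1e-4, 0.1, 2)) == "GERMLINE"

    def test_low_coverage_unknown(self):
        # Binomial(2, 0.5): P(X >= 1) = 0.75 < 0.9 for any a* >= 1
        t = self._call("t", 1000, 100, 90.0)
        n = self._call("n", 2, 0, 0.0)
        assert assign_tn_status(t, n, _fit(1e-4, 0.1, 2)) == "UNKNOWN"

    def test_well_covered_somatic(self):
        t = self._call("t", 1000, 100, 90.0)
        n = self._call("n", 200, 0, 0.0)
        assert assign_tn_status(t, n, _fit(1e-4, 0.1, 2)) == "SOMATIC"

    def test_missing_normal(self):
        t = self._call("t", 1000, 100, 90.0)
        assert assign_tn_status(t, None, None) == "UNKNOWN"


class TestDetectability:
    def test_clearly_detectable(self):
        ok, m_reads, m_err = predict_detectability(1e-3, 10000, 1e-5)
        assert ok
        assert m_reads == pytest.approx(1.0)
        assert m_err == pytest.approx(2.0)

    def test_too_few_reads(self):
        ok, m_reads, _ = predict_detectability(1e-3, 1000, 1e-5)
        assert not ok
        assert m_reads == pytest.approx(0.0)

    def test_error_rate_too_close(self):
        ok, _, m_err = predict_detectability(2e-3, 100000, 1e-3)
        assert not ok
        assert m_err == pytest.approx(np.log10(2.0))

    def test_zero_error_rate(self):
        ok, _, m_err = predict_detectability(0.01, 10000, 0.0)
        assert ok
        assert m_err == math.inf

    def test_domain(self):
        with pytest.raises(ValueError):
            predict_detectability(0.0, 100, 1e-4)
        with pytest.raises(ValueError):
            predict_detectability(0.1, 0, 1e-4)


class TestNullFdr:
    def test_fdr_control_under_null(self, rng):
        # per-alteration fraction of q < alpha stays near/below alpha
        n_sites, n = 60, 100
        hits = {0.05: 0, 0.01: 0}
        total = 0
        for _ in range(n_sites):
            site = make_site(rng, n=n, dp=1000, e=1e-3, sigma=0.1)
            sc = call_site(site)
            q = np.array([c.q_value for c in sc.calls])
            total += n
            for alpha in hits:
                hits[alpha] += int(np.sum(q < alpha))
        for alpha, h in hits.items():
            frac = h / total
            se = math.sqrt(alpha * (1 - alpha) / total)
            assert frac <= alpha + 3 * se
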