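"""Fisher responder calling, Holm adjustment and per-donor summaries."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from epitopemap import (
    StimulationRecord,
    call_responders,
    donor_positive,
    fisher_one_sided,
    holm_adjust,
    log_fold_change,
    percent_responders,
    pools_per_donor,
)
from epitopemap.responders import (
    SEB,
    UNSTIMULATED,
    CountError,
    MissingControlError,
    is_pool,
    pool_stimulus,
    positive_stimuli,
)

MARKERS = ("IFNg", "TNFa", "IL2")


def hypergeometric_tail(a, b, c, d):
    """Independent oracle: direct summation of the conditional tail P(X >= a).

    X is the top-left cell of a 2x2 table with both margins fixed; the sum
    runs over all admissible tables at least as extreme as the observed one.
    """
    row1, col1, total = a + b, a + c, a + b + c + d
    num = 0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k <= total - col1:
            num += comb(col1, k) * comb(total - col1, row1 - k)
    return num / comb(total, row1)


class TestFisher:
    def test_no_enrichment_possible(self):
        assert fisher_one_sided(0, 10_000, 10, 10_000) == pytest.approx(1.0)

    def test_identical_proportions(self):
        assert fisher_one_sided(10, 10_000, 10, 10_000) >= 0.5

    def test_against_tail_oracle_example(self):
        got = fisher_one_sided(30, 10_000, 10, 10_000)
        want = hypergeometric_tail(30, 9970, 10, 9990)
        assert got == pytest.approx(want, abs=1e-10)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_against_tail_oracle_random_tables(self, seed):
        """Agreement with the brute-force tail sum on tables with margins <= 200."""
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(rng.integers(0, 101)) for _ in range(4))
        if a + b == 0 or c + d == 0:
            return
        got = fisher_one_sided(a, a + b, c, c + d)
        assert got == pytest.approx(hypergeometric_tail(a, b, c, d), abs=1e-10)

    def test_against_scipy_fisher_exact(self):
        for table in [(3, 97, 1, 99), (15, 85, 5, 95), (0, 50, 2, 48)]:
            a, b, c, d = table
            got = fisher_one_sided(a, a + b, c, c + d)
            want = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert got == pytest.approx(want, abs=1e-12)

    def test_zero_total_errors(self):
        with pytest.raises(CountError):
            fisher_one_sided(0, 0, 1, 100)


class TestHolm:
    def test_hand_computed_stepdown(self):
        assert holm_adjust([0.01, 0.02, 0.5]) == pytest.approx([0.03, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.037]) == pytest.approx([0.037])

    def test_ties_multiply_and_cap(self):
        assert holm_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.9, 0.9, 0.9])
        assert holm_adjust([0.6, 0.6]) == pytest.approx([1.0, 1.0])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_permutation_invariant_and_dominates_raw(self, ps):
        adj = holm_adjust(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        order = np.argsort(ps, kind="stable")
        shuffled = [ps[i] for i in order]
        adj_shuffled = holm_adjust(shuffled)
        assert sorted(adj) == pytest.approx(sorted(adj_shuffled))


def _records_for_donor(donor, n_pools=3, base=10, total=100_000, boost=None):
    """Flat count records; ``boost`` maps (stimulus, marker) -> positive count."""
    recs = []
    for m in MARKERS:
        recs.append(StimulationRecord(donor, UNSTIMULATED, m, base, total))
        for i in range(1, n_pools + 1):
            stim = pool_stimulus(i)
            pos = (boost or {}).get((stim, m), base)
            recs.append(StimulationRecord(donor, stim, m, pos, total))
    return recs


class TestCallResponders:
    def test_null_donor_has_no_positives(self):
        calls = call_responders(_records_for_donor("d1"))
        assert not any(c.positive for c in calls)

    def test_single_planted_enrichment_called(self):
        """A 20-fold enriched (pool, marker) is the only positive call."""
        boost = {(pool_stimulus(2), "TNFa"): 200}
        calls = call_responders(_records_for_donor("d1", boost=boost))
        positives = [(c.stimulus, c.marker) for c in calls if c.positive]
        assert positives == [(pool_stimulus(2), "TNFa")]
        # Holm adjustment within this donor's family of 9 tests, checked by hand
        raw = {(c.stimulus, c.marker): c.raw_p for c in calls}
        adj = {(c.stimulus, c.marker): c.adjusted_p for c in calls}
        key = (pool_stimulus(2), "TNFa")
        assert adj[key] == pytest.approx(min(1.0, raw[key] * 9), rel=1e-9)

    def test_missing_control_names_donor_and_marker(self):
        recs = [StimulationRecord("d9", pool_stimulus(1), "IFNg", 5, 1000)]
        with pytest.raises(MissingControlError, match="d9.*IFNg"):
            call_responders(recs)

    def test_adjusted_dominates_raw(self):
        boost = {(pool_stimulus(1), "IFNg"): 40}
        calls = call_responders(_records_for_donor("d1", boost=boost))
        assert all(c.adjusted_p >= c.raw_p - 1e-12 for c in calls)


class TestSummaries:
    def _calls(self):
        boost = {
            (pool_stimulus(1), "IFNg"): 300,
            (pool_stimulus(3), "IL2"): 300,
        }
        recs = _records_for_donor("d1", boost=boost)
        recs += _records_for_donor("d2")
        recs += _records_for_donor("d3", boost={(pool_stimulus(1), "TNFa"): 300})
        return call_responders(recs)

    def test_donor_positive_is_or_over_markers(self):
        calls = self._calls()
        d1p1 = [c for c in calls if c.donor_id == "d1" and c.stimulus == pool_stimulus(1)]
        assert donor_positive(d1p1)
        d2p1 = [c for c in calls if c.donor_id == "d2" and c.stimulus == pool_stimulus(1)]
        assert not donor_positive(d2p1)

    def test_percent_responders(self):
        calls = self._calls()
        assert percent_responders(calls, pool_stimulus(1)) == pytest.approx(200 / 3)
        assert percent_responders(calls, pool_stimulus(2)) == 0.0
        assert percent_responders(calls, pool_stimulus(3)) == pytest.approx(100 / 3)

    def test_pools_per_donor(self):
        counts = pools_per_donor(self._calls())
        assert counts == {"d1": 2, "d2": 0, "d3": 1}

    def test_controls_and_proteins_excluded_from_pool_counts(self):
        recs = _records_for_donor("d1")
        total = 100_000
        for m in MARKERS:
            recs.append(StimulationRecord("d1", SEB, m, 600, total))
            recs.append(StimulationRecord("d1", "protein", m, 600, total))
        calls = call_responders(recs)
        assert donor_positive([c for c in calls if c.stimulus == SEB])
        assert pools_per_donor(calls) == {"d1": 0}
        assert positive_stimuli(calls, pools_only=True)["d1"] == set()

    def test_is_pool(self):
        assert is_pool("pool_7") and is_pool("Pool 7")
        assert not is_pool(SEB) and not is_pool("protein")


class TestLogFoldChange:
    def test_doubling_rate_is_one_bit(self):
        assert log_fold_change(20, 10**5, 10, 10**5, pseudocount=0) == pytest.approx(1.0)

    def test_equal_rates_zero(self):
        assert log_fold_change(10, 10**5, 10, 10**5, pseudocount=0) == 0.0

    def test_zero_count_with_pseudocount(self):
        got = log_fold_change(0, 10**5, 10, 10**5, pseudocount=0.5)
        assert got == pytest.approx(math.log2(0.5 / 10.5))
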