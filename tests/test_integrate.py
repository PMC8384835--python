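"""Cross-assay integration: donor matching, residue merge and the final list."""

import math

import numpy as np
import pytest
from _oracles import brute_force_epitopes

from epitopemap import (
    DonorGenotype,
    MappsPeptide,
    PeptidePool,
    ResponderCall,
    combine_and_filter,
    epitope_population_coverage,
    integrate_epitopes,
    match_donors,
    matched_residues,
)
from epitopemap.simulate import simulate_protein


def _genotype(donor, a, b):
    return DonorGenotype(donor, (f"DRB1*{a:02d}:01", f"DRB1*{b:02d}:01"))


def _call(donor, stimulus, positive):
    p = 0.001 if positive else 0.9
    return ResponderCall(donor, stimulus, "IFNg", p, p, positive)


def _pep(donor, start, end, protein):
    return MappsPeptide(
        donor, protein.subsequence(start, end), 0.01, start=start, end=end
    )


class TestMatchDonors:
    def test_shared_allele(self):
        got = match_donors([_genotype("m1", 7, 15)], [_genotype("t1", 7, 4)])
        assert len(got) == 1
        assert got[0].shared_alleles == {"DRB1*07:01"}

    def test_disjoint_no_match(self):
        assert match_donors([_genotype("m1", 1, 2)], [_genotype("t1", 3, 4)]) == []

    def test_identical_homozygotes(self):
        got = match_donors([_genotype("m1", 9, 9)], [_genotype("t1", 9, 9)])
        assert len(got) == 1 and got[0].shared_alleles == {"DRB1*09:01"}


class TestMatchedResidues:
    pool = PeptidePool(1, (1,), 1, 60)
    protein = simulate_protein(120, np.random.default_rng(0))

    def _pep(self, start, end):
        return _pep("m1", start, end, self.protein)

    def test_containment(self):
        assert matched_residues([self._pep(12, 25)], [self.pool]) == set(range(12, 26))

    def test_partial_overlap_kept(self):
        assert matched_residues([self._pep(55, 70)], [self.pool]) == set(range(55, 61))

    def test_no_positive_pools_empty(self):
        assert matched_residues([self._pep(12, 25)], []) == set()


class TestCombineAndFilter:
    def test_union_of_runs(self):
        got = combine_and_filter([set(range(12, 26)), set(range(20, 31))])
        assert got == [(12, 30)]

    def test_short_run_discarded(self):
        assert combine_and_filter([set(range(10, 18))]) == []  # length 8 < 9

    def test_boundary_length_kept(self):
        assert combine_and_filter([set(range(10, 19))]) == [(10, 18)]  # length 9


class TestEndToEnd:
    def _toy(self):
        """One planted epitope, one matched donor pair, one covering peptide."""
        protein = simulate_protein(120, np.random.default_rng(5))
        pools = [PeptidePool(1, (1,), 1, 60), PeptidePool(2, (2,), 51, 110)]
        tcell = [_genotype("t1", 1, 2)]
        mappsg = [_genotype("m1", 2, 3)]
        calls = [_call("t1", "pool_1", True), _call("t1", "pool_2", False)]
        peps = [_pep("m1", 30, 46, protein)]
        return protein, pools, tcell, mappsg, calls, peps

    def test_toy_single_candidate(self):
        protein, pools, tcell, mappsg, calls, peps = self._toy()
        cands = integrate_epitopes(calls, peps, tcell, mappsg, pools, protein)
        assert len(cands) == 1
        c = cands[0]
        assert (c.start, c.end) == (30, 46)  # peptide span within pool span
        assert c.sequence == protein.subsequence(30, 46)
        assert c.associated_alleles == {"DRB1*02:01"}
        assert {m.tcell_donor_id for m in c.supporting_matches} == {"t1"}

    def test_no_matches_no_candidates(self):
        protein, pools, _, _, calls, peps = self._toy()
        cands = integrate_epitopes(
            calls, peps, [_genotype("t1", 1, 4)], [_genotype("m1", 2, 3)],
            pools, protein,
        )
        assert cands == []

    def test_candidate_provenance_invariant(self):
        """Every candidate overlaps a matched MAPPs identification and a
        positive pool span of the matched T-cell donor."""
        protein, pools, tcell, mappsg, calls, peps = self._toy()
        cands = integrate_epitopes(calls, peps, tcell, mappsg, pools, protein)
        for c in cands:
            assert c.supporting_matches
            assert any(
                min(c.end, p.end) >= max(c.start, p.start) for p in peps
            )
            assert any(
                min(c.end, q.span_end) >= max(c.start, q.span_start)
                for q in pools
            )

    def test_adding_peptide_never_removes_candidates(self):
        protein, pools, tcell, mappsg, calls, peps = self._toy()
        before = {(c.start, c.end) for c in
                  integrate_epitopes(calls, peps, tcell, mappsg, pools, protein)}
        more = peps + [_pep("m1", 70, 85, protein)]
        calls2 = [_call("t1", "pool_1", True), _call("t1", "pool_2", True)]
        after = {(c.start, c.end) for c in
                 integrate_epitopes(calls2, more, tcell, mappsg, pools, protein)}
        for a, b in before:
            assert any(lo <= a and b <= hi for lo, hi in after)


def _random_instance(rng):
    """A small random instance: <= 5 donors/cohort, <= 3 pools, <= 8 peptides."""
    length = int(rng.integers(60, 120))
    protein = simulate_protein(length, rng)
    n_pools = int(rng.integers(1, 4))
    bounds = np.linspace(1, length, n_pools + 1).astype(int)
    pools = []
    for i in range(n_pools):
        lo = max(1, bounds[i] - 5)
        hi = min(length, bounds[i + 1] + 5)
        pools.append(PeptidePool(i + 1, (i + 1,), int(lo), int(hi)))
    tcell = [
        _genotype(f"t{i}", rng.integers(1, 5), rng.integers(1, 5))
        for i in range(int(rng.integers(1, 6)))
    ]
    mappsg = [
        _genotype(f"m{i}", rng.integers(1, 5), rng.integers(1, 5))
        for i in range(int(rng.integers(1, 6)))
    ]
    calls = [
        _call(t.donor_id, f"pool_{q.pool_id}", bool(rng.random() < 0.5))
        for t in tcell
        for q in pools
    ]
    peps = []
    for _ in range(int(rng.integers(1, 9))):
        plen = int(rng.integers(7, 25))
        start = int(rng.integers(1, length - plen + 2))
        donor = f"m{rng.integers(len(mappsg))}"
        peps.append(_pep(donor, start, start + plen - 1, protein))
    return protein, pools, tcell, mappsg, calls, peps


def test_pipeline_equals_brute_force_oracle():
    """On randomized small instances the candidate spans equal an exhaustive
    enumeration of the four-step procedure."""
    rng = np.random.default_rng(20210824)
    for _ in range(40):
        protein, pools, tcell, mappsg, calls, peps = _random_instance(rng)
        got = [
            (c.start, c.end)
            for c in integrate_epitopes(calls, peps, tcell, mappsg, pools, protein)
        ]
        want = brute_force_epitopes(calls, peps, tcell, mappsg, pools)
        assert sorted(got) == want


class TestCoverage:
    def test_no_candidates_zero(self):
        assert epitope_population_coverage([], {"DRB1*01:01": 0.5}) == 0.0

    def test_shared_allele_counted_once(self):
        protein = simulate_protein(60, np.random.default_rng(1))
        from epitopemap import DonorMatch, EpitopeCandidate

        m = DonorMatch("m1", "t1", frozenset({"DRB1*01:01"}))
        c1 = EpitopeCandidate(protein.subsequence(1, 12), 1, 12, (m,),
                              frozenset({"DRB1*01:01"}))
        c2 = EpitopeCandidate(protein.subsequence(20, 31), 20, 31, (m,),
                              frozenset({"DRB1*01:01"}))
        got = epitope_population_coverage([c1, c2], {"DRB1*01:01": 0.13})
        assert got == pytest.approx(13.0)
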