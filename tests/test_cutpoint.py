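"""Minimum-p-value cutpoint optimization: candidate enumeration, log-rank
scanning against a brute-force oracle, and both selection corrections."""

import numpy as np
import pytest

from tilscore import (SimulationConfig, candidate_cutoffs, generate_cohort,
                      generate_null_cohort, miller_siegmund_correct,
                      optimize_cutpoint, permutation_correct, scan_cutpoints)
from tilscore.errors import DataError
from oracles import brute_logrank_2group


def toy_cohort(seed=0, n=12):
    rng = np.random.default_rng(seed)
    dens = rng.uniform(10, 200, n)
    times = np.ceil(rng.exponential(12, n))  # ties likely
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[0] = 1
    return dens, times, events


class TestCandidateCutoffs:
    def test_enumeration_with_min_group_constraint(self):
        # n=10, frac 0.2 -> k=2: candidates 2..8
        cands = candidate_cutoffs(np.arange(1, 11, dtype=float), 0.2)
        assert list(cands) == [2, 3, 4, 5, 6, 7, 8]

    def test_single_feasible_split(self):
        cands = candidate_cutoffs([1.0, 2.0, 3.0, 4.0], 0.5)
        assert list(cands) == [2.0]

    def test_all_equal_is_an_error(self):
        with pytest.raises(DataError):
            candidate_cutoffs([5.0] * 8, 0.2)

    def test_candidates_respect_strict_greater_convention(self):
        dens = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 3.0])
        for v in candidate_cutoffs(dens, 1 / 3):
            assert (dens <= v).sum() >= 2 and (dens > v).sum() >= 2


class TestScan:
    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            dens, times, events = toy_cohort(seed)
            scan = scan_cutpoints(dens, times, events, min_group_frac=0.1)
            for cutoff, chi, _ in scan:
                expected = brute_logrank_2group(times, events, dens > cutoff)
                assert chi == pytest.approx(expected, abs=1e-10)

    def test_identical_survival_both_sides(self):
        # duplicated cohort halves: same survival pattern in each group
        dens = np.r_[np.full(6, 10.0), np.full(6, 100.0)]
        times = np.r_[1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6.0]
        events = np.ones(12, dtype=int)
        scan = scan_cutpoints(dens, times, events, min_group_frac=0.5)
        assert all(chi == pytest.approx(0.0, abs=1e-12) for _, chi, _ in scan)

    def test_strong_effect_peaks_at_interior_candidate(self):
        n = 40
        dens = np.arange(1.0, n + 1)
        times = dens.copy()  # perfectly rank-concordant
        events = np.ones(n, dtype=int)
        scan = scan_cutpoints(dens, times, events, 0.1)
        chis = [c for _, c, _ in scan]
        assert 0 < int(np.argmax(chis)) < len(chis) - 1

    def test_zero_events_rejected(self):
        dens, times, _ = toy_cohort()
        with pytest.raises(DataError):
            scan_cutpoints(dens, times, np.zeros_like(times, dtype=int))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            scan_cutpoints([1, 2, 3], [1, 2], [1, 0])


class TestOptimize:
    def test_argmax_matches_exhaustive_oracle(self):
        for seed in range(8):
            dens, times, events = toy_cohort(seed, n=25)
            res = optimize_cutpoint(dens, times, events, 0.1,
                                    correction="none")
            cands = candidate_cutoffs(dens, 0.1)
            brute = [brute_logrank_2group(times, events, dens > v)
                     for v in cands]
            best = int(np.argmax(brute))  # first max = smallest cutoff
            assert res.cutoff == pytest.approx(float(cands[best]))
            assert res.chi_square == pytest.approx(brute[best], abs=1e-10)

    def test_single_candidate_none_correction(self):
        dens = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([5.0, 6.0, 2.0, 1.0])
        events = np.array([1, 0, 1, 1])
        res = optimize_cutpoint(dens, times, events, 0.5, correction="none")
        assert res.cutoff == 2.0
        assert res.n_candidates == 1
        assert res.corrected_p == pytest.approx(res.raw_p)
        assert res.n_low == 2 and res.n_high == 2

    def test_corrected_exceeds_raw_with_many_candidates(self):
        c = generate_null_cohort(SimulationConfig(seed=11, n_patients=200))
        res = optimize_cutpoint(c.cd8_im, c.os_months, c.os_event)
        assert res.n_candidates > 1
        assert res.corrected_p > res.raw_p
        assert 0 < res.raw_p <= 1 and 0 < res.corrected_p <= 1
        again = optimize_cutpoint(c.cd8_im, c.os_months, c.os_event)
        assert again == res  # deterministic for fixed input

    def test_missing_densities_excluded(self):
        dens, times, events = toy_cohort(3, n=30)
        dens = dens.copy()
        dens[:5] = np.nan
        res = optimize_cutpoint(dens, times, events, 0.1, correction="none")
        assert res.n_low + res.n_high == 25


class TestMillerSiegmund:
    def test_frozen_numeric_oracle_value(self):
        # computed once with an independent scipy implementation of the bound
        assert miller_siegmund_correct(0.001, 0.1, 0.9) == pytest.approx(
            0.025485226351106238, rel=1e-12)

    def test_monotone_in_p_min(self):
        assert (miller_siegmund_correct(0.001, 0.1, 0.9)
                < miller_siegmund_correct(0.01, 0.1, 0.9))

    def test_clamps_to_one_near_p_one(self):
        assert miller_siegmund_correct(1 - 1e-12, 0.1, 0.9) == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            miller_siegmund_correct(0.0, 0.1, 0.9)
        assert miller_siegmund_correct(1.0, 0.1, 0.9) == 1.0

    def test_never_below_raw_p(self):
        for p in (1e-6, 1e-3, 0.05, 0.3, 0.9):
            assert miller_siegmund_correct(p, 0.1, 0.9) >= p


class TestPermutation:
    def test_floor_when_observed_beats_all(self):
        # strong true effect: observed min-p below every permuted one
        c = generate_cohort(SimulationConfig(seed=2, n_patients=120))
        p = permutation_correct(c.cd8_im, c.os_months, c.os_event,
                                n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_seeded_reproducibility(self):
        c = generate_null_cohort(SimulationConfig(seed=8, n_patients=80))
        args = (c.cd8_im, c.os_months, c.os_event)
        p1 = permutation_correct(*args, n_perm=199, seed=5)
        p2 = permutation_correct(*args, n_perm=199, seed=5)
        assert p1 == p2

    def test_minimum_permutation_count_enforced(self):
        c = generate_null_cohort(SimulationConfig(seed=8, n_patients=80))
        with pytest.raises(DataError):
            permutation_correct(c.cd8_im, c.os_months, c.os_event, n_perm=50)
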