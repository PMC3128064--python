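import itertools
import math

import numpy as np
import pytest

from sbse.engine import (
    bin_matches,
    composite_scan,
    enrichment_score,
    sbse_scan,
    sbse_scan_binned,
)
from sbse.fixtures import FixtureSpec, generate_fixture
from sbse.profile import absolute_order, shuffle_profile
from sbse.seedcore import build_match_vector

from conftest import TOY_A, TOY_D, direct_scan, random_profile


class TestOracleEquivalence:
    """The log-space recursion must agree with direct-probability products."""

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_exhaustive_small_n(self, n):
        rng = np.random.default_rng(n)
        A = rng.permutation(np.arange(1, n + 1))
        for bits in itertools.product([0, 1], repeat=n):
            D = np.array(bits)
            res = sbse_scan(D, A, keep_matrix=True)
            _, scores = direct_scan(D, A)
            engine_scores = -res.trace.matrix  # log base e
            np.testing.assert_allclose(engine_scores, np.array(scores), atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_n12(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(9, 13))
        D = rng.integers(0, 2, n)
        prof = random_profile(rng, n)
        A = absolute_order(prof)
        res = sbse_scan(D, A, keep_matrix=True)
        posts, scores = direct_scan(D, A.order)
        np.testing.assert_allclose(-res.trace.matrix, np.array(scores), atol=1e-9)
        # posteriors normalize at every (i, j) by construction of the oracle;
        # the engine's pair must match it within the same tolerance
        final_ph = 1.0 - np.exp(-res.final_trace)
        np.testing.assert_allclose(final_ph, np.array(posts[-1]), atol=1e-9)

    def test_posterior_normalization_every_update(self):
        rng = np.random.default_rng(17)
        D = rng.integers(0, 2, 10)
        prof = random_profile(rng, 10)
        res = sbse_scan(D, absolute_order(prof), keep_matrix=True)
        log_ph0 = res.trace.matrix
        ph0 = np.exp(log_ph0)
        posts, _ = direct_scan(D, absolute_order(prof).order)
        np.testing.assert_allclose(ph0 + np.array(posts), 1.0, atol=1e-12)


class TestWorkedExample:
    def test_running_optimum_at_step_four_isolates_most_downregulated(self):
        res = sbse_scan(TOY_D, TOY_A, keep_matrix=True)
        # after four observations the best division separates ranks 1..5
        # from the most down-regulated gene (rank 6)
        assert res.division_ranks[res.division_path[3]] == 5
        assert res.step_trace[3] == pytest.approx(math.log(5))

    def test_global_optimum_places_enrichment_downward(self):
        res = sbse_scan(TOY_D, TOY_A)
        assert res.side == "down"
        # frozen from the direct-probability oracle under the documented
        # running-count convention: P{H_2 | D} = 5/6 after all six steps
        assert res.max_score == pytest.approx(math.log(6))
        assert (res.i_star, res.j_star) == (2, 6)

    def test_first_observation_leaves_prior(self):
        res = sbse_scan(TOY_D, TOY_A)
        assert res.step_trace[0] == pytest.approx(-math.log(0.5))


class TestDegenerateInputs:
    def test_all_zero_vector_stays_at_prior(self):
        res = sbse_scan(np.zeros(8, dtype=int), np.arange(1, 9))
        np.testing.assert_allclose(res.final_trace, -math.log(0.5))
        np.testing.assert_allclose(res.step_trace, -math.log(0.5))

    def test_all_ones_vector_stays_at_prior(self):
        res = sbse_scan(np.ones(8, dtype=int), np.arange(1, 9))
        np.testing.assert_allclose(res.final_trace, -math.log(0.5))

    def test_too_short(self):
        with pytest.raises(ValueError):
            sbse_scan(np.array([1]), np.array([1]))

    def test_bad_prior(self):
        with pytest.raises(ValueError):
            sbse_scan(TOY_D, TOY_A, prior=1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sbse_scan(TOY_D, np.arange(1, 6))


class TestBinning:
    def test_toy_bin_counts(self):
        B = bin_matches(TOY_D, 3)
        assert B.x.tolist() == [0, 2, 1]
        assert B.y.tolist() == [2, 0, 1]

    def test_m_equals_n_singleton_bins(self):
        B = bin_matches(TOY_D, 6)
        assert B.sizes.tolist() == [1] * 6

    def test_m2_split_recount(self):
        rng = np.random.default_rng(4)
        D = rng.integers(0, 2, 31)
        B = bin_matches(D, 2)
        mid = 16  # larger bin first: 16 + 15
        assert B.x.tolist() == [int(D[:mid].sum()), int(D[mid:].sum())]
        assert B.N == 31

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            bin_matches(TOY_D, 1)
        with pytest.raises(ValueError):
            bin_matches(TOY_D, 7)

    def test_bins_contiguous_and_cover(self):
        B = bin_matches(np.zeros(100, dtype=int), 7)
        spans = B.spans
        assert spans[0, 0] == 1 and spans[-1, 1] == 100
        assert all(spans[i + 1, 0] == spans[i, 1] + 1 for i in range(6))
        assert max(B.sizes) - min(B.sizes) <= 1
        assert np.all(np.diff(B.sizes) <= 0)  # larger bins first

    @pytest.mark.parametrize("seed", range(50))
    def test_m_equals_n_matches_unbinned(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 201))
        prof = random_profile(rng, n)
        D = build_vector(rng, n)
        unbinned = sbse_scan(D, absolute_order(prof), keep_matrix=False)
        binned = sbse_scan_binned(bin_matches(D, n, profile=prof))
        np.testing.assert_allclose(binned.final_trace, unbinned.final_trace,
                                   rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(binned.step_trace, unbinned.step_trace,
                                   rtol=1e-12, atol=1e-12)
        assert binned.i_star == unbinned.i_star
        assert binned.j_star == unbinned.j_star
        assert binned.max_score == pytest.approx(unbinned.max_score)

    def test_m2_all_ones_lower_half(self):
        D = np.concatenate([np.zeros(10, dtype=int), np.ones(10, dtype=int)])
        res = sbse_scan_binned(bin_matches(D, 2))
        assert res.i_star == 10
        assert res.side == "down"


def build_vector(rng, n):
    return rng.integers(0, 2, n)


class TestEnrichmentScore:
    def test_prior_state(self):
        assert enrichment_score(0.5) == pytest.approx(-math.log(0.5))

    def test_floor_cap(self):
        assert enrichment_score(1.0) == pytest.approx(300 * math.log(10))
        assert enrichment_score(1.0, log_base=10) == pytest.approx(300.0)

    def test_strictly_monotone_in_posterior(self):
        grid = np.linspace(0.01, 0.999, 50)
        scores = [enrichment_score(p) for p in grid]
        assert np.all(np.diff(scores) > 0)


class TestReversalSymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_negating_fold_changes_mirrors_optimum(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 60
        prof = random_profile(rng, n)
        D = rng.integers(0, 2, n)
        fwd = sbse_scan(D, absolute_order(prof))
        from sbse.profile import ExpressionRecord, rank_by_fold_change

        neg = rank_by_fold_change(
            [ExpressionRecord(i, -fc) for i, fc in
             zip(prof.identifiers, prof.fold_changes)]
        )
        rev = sbse_scan(D[::-1].copy(), absolute_order(neg))
        assert rev.max_score == pytest.approx(fwd.max_score)
        assert rev.i_star == n - fwd.i_star
        assert {rev.side, fwd.side} == {"up", "down"} or (
            fwd.side == rev.side and fwd.max_score == pytest.approx(-math.log(0.5))
        )


class TestPlantedSignal:
    """Behaviour on synthetic fixtures with known ground truth."""

    N = 1000
    BINS = 200

    def _score(self, profile, repo, motif="GCCTTA"):
        D = build_match_vector(profile, repo, motif)
        return sbse_scan_binned(bin_matches(D, self.BINS)).max_score

    def test_shuffle_abrogates_planted_signal(self):
        spec = FixtureSpec(n_genes=self.N, seed=5)
        profile, repo, _ = generate_fixture(spec)
        planted = self._score(profile, repo)
        null = [self._score(shuffle_profile(profile, s), repo) for s in range(20)]
        assert planted > max(null)
        # the shuffled scores should look like noise, far below the signal
        assert np.median(null) < planted / 4

    def test_score_monotone_in_planting_strength(self):
        probs = [0.1, 0.3, 0.6, 1.0]
        means = []
        for p in probs:
            scores = [
                self._score(*generate_fixture(
                    FixtureSpec(n_genes=self.N, plant_prob=p, seed=s))[:2])
                for s in range(5)
            ]
            means.append(np.mean(scores))
        assert np.all(np.diff(means) >= 0)

    def test_boundary_recovery_within_two_percent(self):
        hits = 0
        n = 5000
        for s in range(20):
            spec = FixtureSpec(n_genes=n, plant_prob=1.0, background_rate=0.05,
                               target_fraction=0.1, seed=s)
            profile, repo, truth = generate_fixture(spec)
            D = build_match_vector(profile, repo, spec.planted_motif)
            res = sbse_scan(D, absolute_order(profile), keep_matrix=False)
            if abs(res.i_star - truth.boundary_rank) <= 0.02 * n:
                hits += 1
        assert hits >= 18  # at least 90% of seeded runs


class TestComposite:
    def test_result_row_per_motif(self):
        spec = FixtureSpec(n_genes=400, seed=2)
        profile, repo, _ = generate_fixture(spec)
        comp = composite_scan(profile, repo, k=6, M=50)
        assert len(comp.table) == 4096
        assert comp.step_traces.shape == (4096, 50)

    def test_planted_motif_ranks_first(self):
        spec = FixtureSpec(n_genes=1000, seed=8, background_rate=0.0)
        profile, repo, _ = generate_fixture(spec)
        comp = composite_scan(profile, repo, k=6, M=100)
        assert comp.rank_of("GCCTTA") == 1
        row = comp.table.iloc[comp.table["max_score"].idxmax()]
        assert row.side == "down"
        assert comp.robust_z_of("GCCTTA") > 5

    def test_shuffled_profile_drops_below_prominence(self):
        spec = FixtureSpec(n_genes=1000, seed=8, background_rate=0.0)
        profile, repo, _ = generate_fixture(spec)
        comp = composite_scan(shuffle_profile(profile, 1), repo, k=6, M=100)
        assert comp.robust_z_of("GCCTTA") < 5
        assert not comp.table.loc[comp.table.motif == "GCCTTA", "prominent"].item()

    def test_agrees_with_single_motif_binned_scan(self):
        spec = FixtureSpec(n_genes=400, seed=2)
        profile, repo, _ = generate_fixture(spec)
        comp = composite_scan(profile, repo, k=6, M=50)
        D = build_match_vector(profile, repo, "GCCTTA")
        single = sbse_scan_binned(bin_matches(D, 50))
        target = comp.table.loc[comp.table.motif == "GCCTTA"].iloc[0]
        assert target.max_score == pytest.approx(single.max_score)
        assert target.i_star == single.i_star
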