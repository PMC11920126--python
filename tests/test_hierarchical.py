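import numpy as np
import pytest

from metasdt import (
    CellAssignment,
    PosteriorSamples,
    RatingCounts,
    compute_hdi,
    compute_pd,
    fit_hierarchical_mratio,
    summarize_effects,
)
from metasdt.pipeline import cells_from_trials


class TestHdi:
    def test_degenerate_sample(self):
        lo, hi = compute_hdi(np.full(500, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_standard_normal_interval(self):
        draws = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = compute_hdi(draws)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_uniform_width_equals_mass(self):
        draws = np.random.default_rng(1).random(1_000_000)
        lo, hi = compute_hdi(draws)
        assert hi - lo == pytest.approx(0.95, abs=0.005)

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_mass_rejected(self, mass):
        with pytest.raises(ValueError):
            compute_hdi(np.zeros(200), mass)


class TestPd:
    def test_symmetric_sample_is_half(self):
        draws = np.random.default_rng(2).standard_normal(200_000)
        assert compute_pd(draws) == pytest.approx(0.5, abs=0.005)

    def test_one_sided_sample_is_one(self):
        assert compute_pd(np.abs(np.random.default_rng(3).standard_normal(500)) + 0.1) == 1.0

    def test_shifted_normal_matches_cdf(self):
        draws = 1.0 + np.random.default_rng(4).standard_normal(1_000_000)
        assert compute_pd(draws) == pytest.approx(0.8413, abs=0.002)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_pd(np.array([]))


def synthetic_samples(rng, shift=0.0, scale=1.0, split=False) -> PosteriorSamples:
    draws = {}
    for name in ("mu", "beta_instruction", "beta_difficulty", "beta_interaction",
                 "sigma_participant", "sigma_cell"):
        arr = shift + scale * rng.standard_normal((3, 800))
        if split and name == "beta_instruction":
            arr = np.stack([rng.normal(-5, 1, 800), rng.normal(5, 1, 800),
                            rng.normal(-5, 1, 800)])
        draws[name] = arr
    return PosteriorSamples(draws=draws, phase="pre", participant_ids=("a", "b"))


class TestSummaries:
    def test_null_chains_converged_and_no_effect(self):
        summaries = summarize_effects(synthetic_samples(np.random.default_rng(5)))
        for s in summaries:
            assert s.rhat == pytest.approx(1.0, abs=0.01)
            assert s.decision == "no-effect"
            assert s.converged

    def test_disjoint_chains_flagged(self):
        summaries = summarize_effects(
            synthetic_samples(np.random.default_rng(6), split=True))
        instr = {s.effect: s for s in summaries}["instruction"]
        assert instr.rhat > 1.5
        assert not instr.converged

    def test_clear_effect_detected(self):
        summaries = summarize_effects(
            synthetic_samples(np.random.default_rng(7), shift=2.0, scale=0.5))
        for s in summaries:
            assert s.decision == "effect"
            assert s.hdi_low > 0
            assert s.pd == pytest.approx(1.0, abs=0.01)
            assert s.hdi_low <= s.median <= s.hdi_high


def toy_cells(rng, n_per_group=4, n_trials=40, duplicate=None):
    cells = []
    for g, instr in ((0, "bet"), (1, "confidence")):
        for i in range(n_per_group):
            pid = f"{instr}_{i}"
            for diff in ("easy", "hard"):
                if duplicate is not None:
                    counts = duplicate
                else:
                    counts = RatingCounts(rng.integers(2, 12, size=(2, 2, 2)))
                cells.append(CellAssignment(
                    participant_id=pid, instruction=instr, difficulty=diff,
                    counts=counts, d_prime=1.0, criterion=0.0))
    return cells


class TestFitContracts:
    def test_seed_is_mandatory(self, small_cohort):
        _, trials, _ = small_cohort
        cells = cells_from_trials(trials, "pre")
        with pytest.raises(ValueError, match="seed"):
            fit_hierarchical_mratio(cells, "pre", iterations=200, burnin=50)

    def test_missing_difficulty_cell_names_participant(self):
        cells = toy_cells(np.random.default_rng(0))
        with pytest.raises(ValueError, match="bet_0"):
            fit_hierarchical_mratio(cells[1:], "pre", iterations=200, burnin=50, seed=1)

    def test_single_group_rejected(self):
        cells = [c for c in toy_cells(np.random.default_rng(0)) if c.instruction == "bet"]
        with pytest.raises(ValueError, match="instruction group"):
            fit_hierarchical_mratio(cells, "pre", iterations=200, burnin=50, seed=1)

    def test_same_seed_gives_bit_identical_draws(self):
        cells = toy_cells(np.random.default_rng(1))
        kw = dict(phase="pre", chains=2, iterations=300, burnin=100, seed=99)
        s1 = fit_hierarchical_mratio(cells, **kw)
        s2 = fit_hierarchical_mratio(cells, **kw)
        for name in s1.draws:
            assert np.array_equal(s1.draws[name], s2.draws[name])

    def test_prior_predictive_without_data(self):
        """Zero-count cells leave the effect posteriors at their priors."""
        empty = RatingCounts(np.zeros((2, 2, 2), int))
        cells = toy_cells(np.random.default_rng(2), duplicate=empty)
        samples = fit_hierarchical_mratio(
            cells, "pre", chains=3, iterations=3000, burnin=500, seed=5)
        assert np.mean(samples.pooled("mu")) == pytest.approx(0.5, abs=0.25)
        for name in ("beta_instruction", "beta_difficulty", "beta_interaction"):
            assert np.mean(samples.pooled(name)) == pytest.approx(0.0, abs=0.25)

    def test_duplicated_participants_collapse_between_variance(self):
        rng = np.random.default_rng(3)
        shared = RatingCounts(rng.integers(3, 15, size=(2, 2, 2)))
        cells = toy_cells(rng, n_per_group=10, duplicate=shared)
        samples = fit_hierarchical_mratio(
            cells, "pre", chains=2, iterations=800, burnin=300, seed=6)
        assert np.median(samples.pooled("sigma_participant")) < 0.3


class TestLabelSwap:
    def test_swapping_instruction_flips_the_effect_sign(self, small_cohort):
        _, trials, _ = small_cohort
        cells = cells_from_trials(trials, "pre")
        swap = {"bet": "confidence", "confidence": "bet"}
        swapped = [
            CellAssignment(c.participant_id, swap[c.instruction], c.difficulty,
                           c.counts, c.d_prime, c.criterion)
            for c in cells
        ]
        kw = dict(phase="pre", chains=2, iterations=1200, burnin=400)
        m1 = np.median(fit_hierarchical_mratio(cells, seed=21, **kw)
                       .pooled("beta_instruction"))
        m2 = np.median(fit_hierarchical_mratio(swapped, seed=21, **kw)
                       .pooled("beta_instruction"))
        assert m1 == pytest.approx(-m2, abs=0.2)
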