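"""Serial-passage simulator: ground truth, dynamics, competition."""

import numpy as np
import pandas as pd
import pytest

from pancsel import SelectionSimParams
from pancsel.sim_selection import (
    default_ground_truth,
    run_selection,
    simulate_competition,
)


class TestGroundTruth:
    def test_wildtype_anchored_at_rho_wt(self, design):
        truth = default_ground_truth(design, seed=0)
        assert truth.rho(design.wildtype_protein) == truth.rho_wt
        assert truth.total_penalty(design.wildtype_protein) == 0.0

    def test_stop_variants_effectively_lethal(self, design):
        truth = default_ground_truth(design, seed=0)
        for variant in ("**A", "D*A", "DR*", "***"):
            assert truth.rho(variant) <= 1e-4 * truth.rho_wt
            # even under strong chaperonin buffering stops stay lethal
            assert truth.rho(variant, groels_buffer=0.5) <= 1e-4 * truth.rho_wt

    def test_buffer_halves_log_deficits(self, design):
        """With buffer 0.5 every variant's log10 deficit is exactly half
        the unbuffered deficit, recomputed directly from the penalty table."""
        truth = default_ground_truth(design, seed=3)
        rng = np.random.default_rng(0)
        variants = ["DRA", "MLL", "PTQ", "W*A"] + [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY*"), 3)) for _ in range(50)
        ]
        for v in variants:
            full = np.log10(truth.rho_wt) - np.log10(truth.rho(v, 1.0))
            half = np.log10(truth.rho_wt) - np.log10(truth.rho(v, 0.5))
            assert half == pytest.approx(full / 2, abs=1e-9)

    def test_buffering_never_hurts(self, design):
        truth = default_ground_truth(design, seed=4)
        rho_minus = truth.rho_map(1.0)
        rho_plus = truth.rho_map(0.5)
        assert all(rho_plus[v] >= rho_minus[v] for v in rho_minus)

    def test_deterministic_given_seed(self, design):
        a = default_ground_truth(design, seed=7).penalties
        b = default_ground_truth(design, seed=7).penalties
        pd.testing.assert_frame_equal(a, b)


def _two_variant_params(design, rho_ratio, wt_fraction, **kw):
    wt = design.wildtype_protein
    return SelectionSimParams(
        design=design,
        propagation_factor={wt: rho_ratio, "ARA": 1.0},
        input_abundance={wt: wt_fraction, "ARA": 1.0 - wt_fraction},
        **kw,
    )


class TestRunSelection:
    def test_frequencies_are_simplex_valued(self, small_library_sim):
        for pool in small_library_sim["pools"]:
            freqs = pool.frequencies
            assert (freqs >= 0).all()
            assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_seed_identical_counts(self, design):
        truth = default_ground_truth(design, seed=5)
        variants = sorted(truth.rho_map(1.0))[:100]
        kw = dict(
            design=design,
            propagation_factor={v: truth.rho(v) for v in variants},
            input_abundance={v: 1.0 for v in variants},
            read_depth=50_000,
            seed=42,
        )
        _, t1, e1 = run_selection(SelectionSimParams(**kw))
        _, t2, e2 = run_selection(SelectionSimParams(**kw))
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(e1, e2)

    def test_neutral_pool_has_no_systematic_drift(self, design):
        """With all rho equal, mean per-variant frequency drift from the
        input over replicate seeds stays within 3 standard errors."""
        variants = ["AAA", "CCC", "DDD", "EEE", "FFF"]
        drifts = []
        for seed in range(200):
            params = SelectionSimParams(
                design=design,
                propagation_factor={v: 1.0 for v in variants},
                input_abundance={v: 1.0 for v in variants},
                bottleneck=2000,
                read_depth=10,
                seed=seed,
            )
            pools, _, _ = run_selection(params)
            drifts.append(pools[-1].frequencies["AAA"] - pools[0].frequencies["AAA"])
        drifts = np.asarray(drifts)
        se = drifts.std(ddof=1) / np.sqrt(len(drifts))
        assert abs(drifts.mean()) < 3 * se

    @pytest.mark.parametrize("ratio,passages", [(10.0, 3), (2.0, 5), (1000.0, 2)])
    def test_deterministic_limit_odds_closed_form(self, design, ratio, passages):
        """Without bottleneck noise, two-variant odds multiply by the rho
        ratio each passage: odds_p = odds_0 * ratio**p."""
        params = _two_variant_params(
            design, ratio, 0.25, n_passages=passages, bottleneck=None, seed=0
        )
        pools, _, _ = run_selection(params)
        wt = design.wildtype_protein
        odds0 = 0.25 / 0.75
        for p, pool in enumerate(pools):
            odds = pool.frequencies[wt] / pool.frequencies["ARA"]
            assert odds == pytest.approx(odds0 * ratio**p, rel=1e-9)

    def test_raising_rho_never_lowers_final_frequency(self, design):
        """Monotonicity in the deterministic limit."""
        finals = []
        for rho_wt in (1.0, 2.0, 5.0, 50.0):
            params = _two_variant_params(design, rho_wt, 0.1, bottleneck=None, seed=0)
            pools, _, _ = run_selection(params)
            finals.append(pools[-1].frequencies[design.wildtype_protein])
        assert all(b >= a for a, b in zip(finals, finals[1:]))

    def test_groels_buffering_raises_enriched_count(self, design):
        """With buffer < 1, at least as many variants end above their
        input frequency (deterministic limit, same penalty draw)."""
        truth = default_ground_truth(design, seed=9)
        variants = sorted(truth.rho_map(1.0))[:300]
        abundance = {v: 1.0 for v in variants}
        counts = {}
        for buf in (1.0, 0.5):
            params = SelectionSimParams(
                design=design,
                propagation_factor={v: truth.rho(v) for v in variants},
                input_abundance=abundance,
                groels_buffer=buf,
                bottleneck=None,
                seed=0,
            )
            pools, _, _ = run_selection(params)
            gained = pools[-1].frequencies > pools[0].frequencies
            counts[buf] = int(gained.sum())
        assert counts[0.5] >= counts[1.0]

    def test_degenerate_pool_raises(self, design):
        with pytest.raises(ValueError):
            SelectionSimParams(
                design=design,
                propagation_factor={"AAA": 1.0},
                input_abundance={"AAA": 0.0},
            )

    def test_hitchhiker_rescues_deleterious_carrier(self, design):
        """A second-site hitchhiker mutation inflates the apparent
        enrichment of an otherwise-deleterious variant: with a nonzero
        acquisition rate and a large boost, the deleterious variant's
        final frequency exceeds its hitchhiker-free expectation."""
        kw = dict(
            design=design,
            propagation_factor={"DRA": 100.0, "MLL": 1.0},
            input_abundance={"DRA": 0.001, "MLL": 0.999},
            bottleneck=100_000,
            read_depth=10_000,
            n_passages=3,
        )
        with_hh = []
        without = []
        for seed in range(20):
            pools, _, _ = run_selection(
                SelectionSimParams(
                    **kw, hitchhiker_rate=3e-5, hitchhiker_boost=1000.0, seed=seed
                )
            )
            with_hh.append(pools[-1].frequencies["MLL"])
            pools, _, _ = run_selection(SelectionSimParams(**kw, seed=seed))
            without.append(pools[-1].frequencies["MLL"])
        assert np.mean(with_hh) > 10 * np.mean(without)


class TestCompetition:
    def test_takeover_after_exactly_crossing_odds(self, design):
        """1:1000 seeding with a tenfold advantage: odds reach 1 only after
        passage 3 (10**3 = 1000), so the first wild-type majority call is
        at passage 4 in the deterministic limit."""
        result = simulate_competition(
            1 / 1001, 10.0, design=design, n_passages=5, bottleneck=None
        )
        assert result.first_wt_majority == 4
        assert result.majority_calls[:4] == [result.mutant_label] * 4

    def test_even_start_no_advantage_no_majority_change(self, design):
        result = simulate_competition(0.5, 1.0, design=design, bottleneck=None)
        wt = design.wildtype_protein
        for pool in result.pools:
            assert pool.frequencies[wt] == pytest.approx(0.5, abs=1e-12)

    def test_thousandfold_advantage_takes_over_within_three_passages(self, design):
        """Monte Carlo over seeds: a 1:1000 wild-type spike-in with a
        1000-fold propagation advantage becomes the majority by passage 3
        in >= 95% of stochastic runs (1e5-phage bottleneck)."""
        wins = 0
        for seed in range(100):
            result = simulate_competition(
                1 / 1001, 1000.0, design=design, n_passages=3, bottleneck=100_000, seed=seed
            )
            first = result.first_wt_majority
            if first is not None and first <= 3:
                wins += 1
        assert wins >= 95

    def test_input_validation(self, design):
        with pytest.raises(ValueError):
            simulate_competition(0.0, 10.0, design=design)
        with pytest.raises(ValueError):
            simulate_competition(0.5, -1.0, design=design)


class TestTiters:
    def test_titer_tracks_pool_mean_propagation(self, design):
        """Deterministic two-variant run: the passage titer relative to the
        bottleneck equals the pool-mean rho (fold propagation)."""
        params = _two_variant_params(design, 1000.0, 0.5, bottleneck=None, seed=0)
        pools, _, _ = run_selection(params)
        # passage 1 pool-mean rho from the input composition
        expected = 0.5 * 1000.0 + 0.5 * 1.0
        assert pools[1].titer == pytest.approx(expected, rel=1e-12)
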