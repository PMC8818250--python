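"""LGR statistics: per-colony ratios, replicate tests, FDR, Z-scores, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from platescreen import (
    NormalizationOptions,
    bh_adjust,
    calculate_lgrs,
    call_hits,
    colony_lgr,
    combine_two_controls,
    neg_log,
    replicate_p_value,
    simulate_screen,
    z_scores,
)
from platescreen.screen_stats import PairingError
from tests.conftest import make_noiseless_config


class TestColonyLGR:
    def test_equal_sizes_give_zero(self):
        assert colony_lgr(100.0, 100.0) == 0.0

    def test_e_fold_defect_gives_unit_lgr(self):
        assert colony_lgr(np.e * 42.0, 42.0) == pytest.approx(1.0)

    def test_moderate_defect_value(self):
        # ln(100 / 67.032) computed independently on a calculator
        assert colony_lgr(100.0, 67.032) == pytest.approx(0.4000, abs=1e-4)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            colony_lgr(0.0, 1.0)

    @given(
        st.floats(min_value=1e-2, max_value=1e3),
        st.floats(min_value=1e-2, max_value=1e3),
    )
    def test_antisymmetry(self, a, b):
        assert colony_lgr(a, b) == pytest.approx(-colony_lgr(b, a), abs=1e-12)


class TestReplicateTest:
    def test_equal_means_give_p_one(self):
        assert replicate_p_value([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_constant_identical_samples_give_p_one(self):
        assert replicate_p_value([1, 1, 1, 1], [1, 1, 1, 1]) == 1.0

    def test_pooled_t_matches_hand_formula(self):
        # means 5 vs 2.5; s1^2 = 20/3, s2^2 = 5/3; s_p^2 = 25/6;
        # t = 2.5 / sqrt((25/6)(1/4 + 1/4)) = sqrt(3); df = 6
        a, b = [2, 4, 6, 8], [1, 2, 3, 4]
        t_hand = np.sqrt(3.0)
        p_hand = 2 * sps.t.sf(t_hand, 6)
        p = replicate_p_value(a, b)
        assert p == pytest.approx(p_hand, rel=1e-12)
        assert 0 < p < 1

    def test_agrees_with_scipy_ttest_ind(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(1.0, 0.2, 4)
            b = rng.normal(0.8, 0.2, 4)
            expected = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert replicate_p_value(a, b) == pytest.approx(expected, rel=1e-12)

    def test_single_replicate_is_missing(self):
        assert np.isnan(replicate_p_value([1.0], [2.0]))

    def test_zero_variance_unequal_means_is_missing(self):
        assert np.isnan(replicate_p_value([1, 1, 1], [2, 2, 2]))

    def test_empty_lists_are_missing(self):
        assert np.isnan(replicate_p_value([], []))


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force(p, m=None):
        """O(m^2) step-up straight from the definition."""
        p = np.asarray(p, float)
        m = m or p.size
        q = np.empty_like(p)
        order = np.argsort(p, kind="mergesort")
        for rank_i, i in enumerate(order, start=1):
            q[i] = min(
                min(p[j] * m / (rank_j + 1)
                    for rank_j, j in enumerate(order) if rank_j + 1 >= rank_i),
                1.0,
            )
        return q

    def test_textbook_uniform_ladder(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), 1.0)

    def test_matches_brute_force_on_many_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            p = rng.uniform(1e-8, 1.0, rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), self.brute_force(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-8, 1, 100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_domain_violation_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestTransforms:
    def test_neg_log_of_q05_is_the_volcano_guide(self):
        assert neg_log(0.05) == pytest.approx(2.9957, abs=1e-4)

    def test_neg_log_identities(self):
        assert neg_log(1.0) == 0.0
        assert neg_log(np.exp(-3.0)) == pytest.approx(3.0)

    def test_neg_log_domain(self):
        with pytest.raises(ValueError):
            neg_log(0.0)

    def test_z_scores_standardize(self):
        rng = np.random.default_rng(0)
        z = z_scores(rng.normal(0.3, 0.2, 500))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_z_of_mean_plus_196_sd(self):
        x = np.array([0.0, 1.0, -1.0, 2.0, -2.0])
        mu, sd = x.mean(), x.std(ddof=1)
        z = z_scores(np.append(x, mu + 1.96 * sd))
        # appending shifts the sample moments; check against recomputed ones
        assert z[-1] == pytest.approx(
            (mu + 1.96 * sd - np.append(x, mu + 1.96 * sd).mean())
            / np.append(x, mu + 1.96 * sd).std(ddof=1)
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            z_scores([0.5, 0.5, 0.5])


class TestCalculateLGRs:
    def test_noiseless_null_screen_is_all_zero(self, fmt96):
        sim = simulate_screen(make_noiseless_config(fmt96, n_plates=2))
        _, mean = calculate_lgrs(sim.experiment, sim.controls[0], sim.key)
        np.testing.assert_allclose(mean["mean_LGR"], 0.0, atol=1e-12)
        assert np.isfinite(mean["zscore"]).all()

    @pytest.mark.parametrize("smooth", [False, True])
    @pytest.mark.parametrize("mode,plate_sigma", [("plate_median", 0.2), ("none", 0.0)])
    def test_noiseless_planted_effect_recovered_exactly(self, fmt96, smooth, mode,
                                                        plate_sigma):
        # mode "none" skips plate correction, so plate effects must be absent
        sim = simulate_screen(
            make_noiseless_config(
                fmt96, planted={"HIT1": 0.8}, plate_effect_sigma=plate_sigma
            )
        )
        opts = NormalizationOptions(mode=mode, smooth=smooth)
        _, mean = calculate_lgrs(sim.experiment, sim.controls[0], sim.key, opts)
        hit = mean.set_index("ID").loc["HIT1", "mean_LGR"]
        assert hit == pytest.approx(0.8, abs=1e-9)

    def test_noiseless_recovery_with_control_normalization(self, fmt96):
        controls = tuple((1, 1, c) for c in range(1, 5))
        sim = simulate_screen(
            make_noiseless_config(
                fmt96, planted={"HIT1": 0.5}, control_positions=controls
            )
        )
        opts = NormalizationOptions(mode="control_median")
        _, mean = calculate_lgrs(sim.experiment, sim.controls[0], sim.key, opts)
        assert mean.set_index("ID").loc["HIT1", "mean_LGR"] == pytest.approx(0.5, abs=1e-9)

    def test_swapping_conditions_negates_mean_lgrs(self, small_noisy_screen):
        sim = small_noisy_screen
        rep_f, fwd = calculate_lgrs(sim.experiment, sim.controls[0], sim.key)
        _, rev = calculate_lgrs(sim.controls[0], sim.experiment, sim.key)
        # the control-dead rule is one-directional, so compare only strains
        # with no excluded replicate in the forward direction
        dead = set(
            map(tuple, rep_f.loc[rep_f["excluded"], ["Plate", "ID"]].to_numpy())
        )
        merged = fwd.merge(rev, on=["Plate", "ID"], suffixes=("_f", "_r"))
        clean = merged[
            ~merged[["Plate", "ID"]].apply(tuple, axis=1).isin(dead)
        ].dropna(subset=["mean_LGR_f", "mean_LGR_r"])
        assert len(clean) > 0
        np.testing.assert_allclose(
            clean["mean_LGR_f"], -clean["mean_LGR_r"], atol=1e-12
        )

    def test_one_mean_row_per_keyed_strain_per_plate(self, small_noisy_screen):
        sim = small_noisy_screen
        _, mean = calculate_lgrs(sim.experiment, sim.controls[0], sim.key)
        expected = len(
            {(p, sid) for (p, _, _), sid in sim.key.entries.items()}
        )
        assert len(mean) == expected

    def test_control_dead_positions_reported_but_not_aggregated(self, fmt96):
        sim = simulate_screen(
            make_noiseless_config(fmt96, pinning_failure_rate=0.05, seed=5)
        )
        rep, mean = calculate_lgrs(sim.experiment, sim.controls[0], sim.key)
        failed = {(p, r, c) for cond, p, r, c in sim.truth.failed_positions}
        assert failed, "expected some pinning failures at 5% rate"
        flagged = rep.loc[rep["excluded"], ["Plate", "Row", "Column"]]
        assert failed == set(map(tuple, flagged.to_numpy()))
        # excluded replicates are still present in the replicates table
        assert len(rep) == len(sim.key.entries)
        # strains keep their unaffected replicates in the mean
        ok = mean.loc[~mean["excluded"], "mean_LGR"]
        np.testing.assert_allclose(ok, 0.0, atol=1e-9)

    def test_plate_count_mismatch_raises(self, fmt96):
        sim = simulate_screen(make_noiseless_config(fmt96, n_plates=2))
        with pytest.raises(PairingError):
            calculate_lgrs(sim.experiment, sim.controls[0][:1], sim.key)

    def test_deterministic_given_inputs(self, small_noisy_screen):
        sim = small_noisy_screen
        opts = NormalizationOptions(smooth=True)
        a = calculate_lgrs(sim.experiment, sim.controls[0], sim.key, opts)
        b = calculate_lgrs(sim.experiment, sim.controls[0], sim.key, opts)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestCombineTwoControls:
    def test_avg_and_max_definitions(self, small_noisy_results):
        _, mean1, _, mean2 = small_noisy_results
        merged = combine_two_controls(mean1, mean2).set_index(["Plate", "ID"])
        m1 = mean1.set_index(["Plate", "ID"])
        m2 = mean2.set_index(["Plate", "ID"])
        key = merged.dropna(subset=["avg_LGR"]).index[0]
        assert merged.loc[key, "avg_LGR"] == pytest.approx(
            (m1.loc[key, "mean_LGR"] + m2.loc[key, "mean_LGR"]) / 2
        )
        both_q = merged.dropna(subset=["max_q"])
        np.testing.assert_allclose(
            both_q["max_q"],
            np.maximum(m1.loc[both_q.index, "q_value"], m2.loc[both_q.index, "q_value"]),
        )

    def test_max_q_dominates_each_control(self, small_noisy_results):
        _, mean1, _, mean2 = small_noisy_results
        merged = combine_two_controls(mean1, mean2).set_index(["Plate", "ID"])
        q1 = mean1.set_index(["Plate", "ID"])["q_value"]
        ok = merged["max_q"].notna()
        assert (merged.loc[ok, "max_q"] >= q1[merged.index[ok]] - 1e-15).all()

    def test_symmetric_up_to_labels(self, small_noisy_results):
        _, mean1, _, mean2 = small_noisy_results
        ab = combine_two_controls(mean1, mean2)
        ba = combine_two_controls(mean2, mean1)
        np.testing.assert_allclose(ab["avg_LGR"], ba["avg_LGR"], atol=1e-12)
        np.testing.assert_allclose(ab["max_q"], ba["max_q"], atol=1e-12)
        np.testing.assert_allclose(ab["mean_LGR_c1"], ba["mean_LGR_c2"], atol=1e-12)

    def test_merged_z_recomputed_from_avg(self, small_noisy_results):
        _, mean1, _, mean2 = small_noisy_results
        merged = combine_two_controls(mean1, mean2)
        avg = merged["avg_LGR"].dropna()
        z = merged["zscore_merged"].dropna()
        np.testing.assert_allclose(
            z, (avg - avg.mean()) / avg.std(ddof=1), atol=1e-12
        )

    def test_strain_missing_on_one_side_propagates_missing(self, small_noisy_results):
        _, mean1, _, mean2 = small_noisy_results
        truncated = mean2.iloc[5:]
        merged = combine_two_controls(mean1, truncated).set_index(["Plate", "ID"])
        dropped = mean2.iloc[:5].set_index(["Plate", "ID"]).index
        assert merged.loc[dropped, "avg_LGR"].isna().all()


class TestHitCalling:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {"ID": list("abcd"), "avg_LGR": [0.40, 0.39, 0.80, np.nan],
             "zscore_merged": [2.0, 1.0, 4.0, np.nan]}
        )

    def test_lgr_threshold_is_inclusive(self):
        hits = call_hits(self._table(), "lgr_threshold", 0.4)
        assert list(hits["is_hit"]) == [True, False, True, False]

    def test_zscore_rule(self):
        hits = call_hits(self._table(), "zscore_threshold", 1.96)
        assert list(hits["is_hit"]) == [True, False, True, False]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            call_hits(self._table(), "fold_change", 2.0)
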