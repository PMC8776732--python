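"""Donor selection score, pairwise linear models and gap filling."""

import numpy as np
import pandas as pd
import pytest
from oracles import brute_donor_choice, brute_ols, brute_pair_stats, brute_rank

from soilgaps import (
    ConfigurationError,
    EligibilityError,
    ImputeConfig,
    SensorMeta,
    fit_donor_model,
    impute_table,
    pair_statistics,
    rank_donors,
)
from soilgaps.simulate import SimConfig, simulate_dataset

from conftest import random_network


def _grid(n):
    g = pd.date_range("2010-01-01", periods=n, freq="120min")
    g.name = "timestamp"
    return g


class TestPairStatistics:
    def test_identical_series_same_microsite_scores_maximum(self):
        vals = [0.1, 0.2, 0.15, 0.3]
        table = pd.DataFrame({"Stipa_1": vals, "Stipa_2": vals}, index=_grid(4))
        meta = [SensorMeta("Stipa_1", "Stipa", 1), SensorMeta("Stipa_2", "Stipa", 2)]
        ps = pair_statistics(table, meta, "Stipa_1", "Stipa_2")
        assert ps.pct_valid_common == 100.0
        assert ps.r_squared == pytest.approx(1.0)
        assert ps.score == pytest.approx(300.0)

    def test_score_is_overlap_plus_r2_plus_bonus(self):
        # 4 of 10 timestamps in common, perfectly correlated, cross-microsite:
        # S = 40 + 100*1 + 0 = 140
        x = [0.1, 0.2, 0.3, 0.4] + [np.nan] * 6
        y = [0.2, 0.4, 0.6, 0.8, 0.5, 0.5] + [np.nan] * 4
        table = pd.DataFrame({"Stipa_1": x, "BSCl_1": y}, index=_grid(10))
        meta = [SensorMeta("Stipa_1", "Stipa", 1), SensorMeta("BSCl_1", "BSCl", 1)]
        ps = pair_statistics(table, meta, "Stipa_1", "BSCl_1")
        assert ps.n_common == 4
        assert ps.pct_valid_common == pytest.approx(40.0)
        assert not ps.same_microsite
        assert ps.score == pytest.approx(140.0)

    def test_identity_pair_rejected(self, toy_table, toy_meta):
        with pytest.raises(EligibilityError):
            pair_statistics(toy_table, toy_meta, "Stipa_1", "Stipa_1")

    def test_degenerate_overlap_marked_ineligible(self):
        table = pd.DataFrame(
            {"Stipa_1": [0.2, 0.2, 0.2], "Stipa_2": [0.1, 0.2, 0.3]}, index=_grid(3)
        )
        meta = [SensorMeta("Stipa_1", "Stipa", 1), SensorMeta("Stipa_2", "Stipa", 2)]
        ps = pair_statistics(table, meta, "Stipa_1", "Stipa_2")
        assert not ps.eligible
        assert ps.r == 0.0 and ps.r_squared == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        table, meta, values, microsites = random_network(rng)
        n_ts = len(table)
        for donor in table.columns:
            for target in table.columns:
                if donor == target:
                    continue
                ps = pair_statistics(table, meta, donor, target)
                ref = brute_pair_stats(values, microsites, donor, target, n_ts)
                assert ps.n_common == ref["n_common"]
                assert ps.pct_valid_common == pytest.approx(ref["pct_valid_common"])
                assert ps.r == pytest.approx(ref["r"], abs=1e-9)
                assert ps.score == pytest.approx(ref["score"], abs=1e-9)
                assert ps.same_microsite == ref["same_microsite"]
                assert ps.eligible == ref["eligible"]

    @pytest.mark.parametrize("seed", range(5))
    def test_score_decomposition(self, seed):
        rng = np.random.default_rng(100 + seed)
        table, meta, _, _ = random_network(rng)
        for donor in table.columns:
            for target in table.columns:
                if donor == target:
                    continue
                ps = pair_statistics(table, meta, donor, target)
                resid = ps.score - 100.0 * ps.same_microsite - 100.0 * ps.r_squared
                assert resid == pytest.approx(ps.pct_valid_common, abs=1e-9)
                assert 0.0 <= ps.score <= 300.0


class TestRankDonors:
    def test_higher_score_wins(self):
        base = np.linspace(0.1, 0.3, 20)
        table = pd.DataFrame(
            {
                "Stipa_1": np.where(np.arange(20) < 10, base, np.nan),  # target
                "Stipa_2": base,          # same site, full overlap
                "BSCl_1": base * 0.5,     # cross site, full overlap
            },
            index=_grid(20),
        )
        meta = [
            SensorMeta("Stipa_1", "Stipa", 1),
            SensorMeta("Stipa_2", "Stipa", 2),
            SensorMeta("BSCl_1", "BSCl", 1),
        ]
        ranked = rank_donors(table, meta, "Stipa_1", min_overlap=5)
        assert [p.donor_id for p in ranked] == ["Stipa_2", "BSCl_1"]

    def test_tie_broken_by_overlap_then_id(self):
        # both donors correlate perfectly and share the microsite bonus;
        # donor A overlaps 80% of the grid, donor B only 60%
        n = 10
        base = np.linspace(0.1, 0.3, n)
        a = base.copy()
        a[8:] = np.nan
        b = base.copy()
        b[6:] = np.nan
        table = pd.DataFrame(
            {"BSCm_1": base, "BSCl_1": a, "BSCl_2": b}, index=_grid(n)
        )
        meta = [
            SensorMeta("BSCm_1", "BSCm", 1),
            SensorMeta("BSCl_1", "BSCl", 1),
            SensorMeta("BSCl_2", "BSCl", 2),
        ]
        ranked = rank_donors(table, meta, "BSCm_1", min_overlap=2)
        assert ranked[0].donor_id == "BSCl_1"  # 80 + 100 > 60 + 100

        # exact score tie (same overlap, both perfect): lexicographic id
        table["BSCl_2"] = a
        ranked = rank_donors(table, meta, "BSCm_1", min_overlap=2)
        assert ranked[0].score == pytest.approx(ranked[1].score)
        assert [p.donor_id for p in ranked[:2]] == ["BSCl_1", "BSCl_2"]

    @pytest.mark.parametrize("seed", range(5))
    def test_full_ranking_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        table, meta, values, microsites = random_network(rng)
        for target in table.columns:
            ranked = rank_donors(table, meta, target, min_overlap=5)
            ref = brute_rank(values, microsites, target, len(table), min_overlap=5)
            assert [p.donor_id for p in ranked] == [d for d, _ in ref]

    def test_insufficient_overlap_excluded(self):
        table = pd.DataFrame(
            {"Stipa_1": [0.1, np.nan, np.nan], "Stipa_2": [0.1, 0.2, 0.3]},
            index=_grid(3),
        )
        meta = [SensorMeta("Stipa_1", "Stipa", 1), SensorMeta("Stipa_2", "Stipa", 2)]
        assert rank_donors(table, meta, "Stipa_1", min_overlap=2) == []


class TestFitDonorModel:
    def test_exact_line(self):
        table = pd.DataFrame(
            {"Stipa_1": [0.1, 0.2, 0.3], "Stipa_2": [0.2, 0.4, 0.6]}, index=_grid(3)
        )
        fit = fit_donor_model(table, "Stipa_1", "Stipa_2", min_overlap=3)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.predict(0.1) == pytest.approx(0.2)

    def test_matches_normal_equations_oracle(self):
        x = [0.1, 0.2, 0.3, 0.4]
        y = [0.11, 0.19, 0.32, 0.38]
        table = pd.DataFrame({"Stipa_1": x, "Stipa_2": y}, index=_grid(4))
        fit = fit_donor_model(table, "Stipa_1", "Stipa_2", min_overlap=4)
        intercept, slope = brute_ols(x, y)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.slope == pytest.approx(slope, abs=1e-12)

    def test_constant_donor_raises(self):
        table = pd.DataFrame(
            {"Stipa_1": [0.2, 0.2, 0.2], "Stipa_2": [0.1, 0.2, 0.3]}, index=_grid(3)
        )
        with pytest.raises(EligibilityError, match="constant"):
            fit_donor_model(table, "Stipa_1", "Stipa_2", min_overlap=3)

    def test_insufficient_overlap_raises(self, toy_table):
        with pytest.raises(EligibilityError, match="common cases"):
            fit_donor_model(toy_table, "Stipa_1", "Stipa_2", min_overlap=10**6)


class TestImputeTable:
    def test_single_gap_filled_from_exact_relation(self):
        x = [0.1, 0.2, 0.3, 0.1]
        y = [0.2, 0.4, 0.6, np.nan]
        table = pd.DataFrame({"Stipa_1": x, "Stipa_2": y}, index=_grid(4))
        meta = [SensorMeta("Stipa_1", "Stipa", 1), SensorMeta("Stipa_2", "Stipa", 2)]
        filled, quality, report = impute_table(table, meta, ImputeConfig(min_overlap=3))
        assert filled["Stipa_2"].iloc[3] == pytest.approx(0.2)
        assert quality["Stipa_2"].iloc[3] == pytest.approx(1.0)
        assert report.n_filled == 1
        assert len(report.gap_log) == 1
        assert report.gap_log.iloc[0]["donor_id"] == "Stipa_1"

    def test_cell_with_no_donor_stays_missing(self):
        table = pd.DataFrame(
            {"Stipa_1": [0.1, 0.2, 0.3, np.nan], "Stipa_2": [0.2, 0.4, 0.6, np.nan]},
            index=_grid(4),
        )
        meta = [SensorMeta("Stipa_1", "Stipa", 1), SensorMeta("Stipa_2", "Stipa", 2)]
        filled, quality, report = impute_table(table, meta, ImputeConfig(min_overlap=3))
        assert np.isnan(filled.iloc[3]).all()
        assert np.isnan(quality.iloc[3]).all()
        assert report.n_missing_after == 2

    def test_no_missing_is_identity_with_unit_quality(self, toy_table, toy_meta):
        full = toy_table.fillna(0.2)
        filled, quality, report = impute_table(full, toy_meta, ImputeConfig(min_overlap=5))
        pd.testing.assert_frame_equal(filled, full)
        assert (quality.to_numpy() == 1.0).all()
        assert report.n_missing_before == report.n_filled == report.n_missing_after == 0

    def test_min_overlap_below_two_rejected(self, toy_table, toy_meta):
        with pytest.raises(ConfigurationError):
            impute_table(toy_table, toy_meta, ImputeConfig(min_overlap=1))

    def test_predictions_clipped_into_unit_interval(self):
        x = [0.1, 0.2, 0.3, 0.9]
        y = [0.0, 0.3, 0.6, np.nan]  # slope 3: donor 0.9 predicts 2.4
        table = pd.DataFrame({"BSCl_1": x, "BSCl_2": y}, index=_grid(4))
        meta = [SensorMeta("BSCl_1", "BSCl", 1), SensorMeta("BSCl_2", "BSCl", 2)]
        filled, _, _ = impute_table(table, meta, ImputeConfig(min_overlap=3))
        assert filled["BSCl_2"].iloc[3] == 1.0
        filled, _, _ = impute_table(table, meta, ImputeConfig(min_overlap=3, clip=False))
        assert filled["BSCl_2"].iloc[3] == pytest.approx(2.4)

    @pytest.mark.parametrize("seed", range(4))
    def test_invariants_on_random_networks(self, seed):
        rng = np.random.default_rng(300 + seed)
        table, meta, _, _ = random_network(rng)
        filled, quality, report = impute_table(table, meta, ImputeConfig(min_overlap=5))
        obs = table.notna().to_numpy()
        # observed cells bit-identical, quality 1 exactly there
        assert np.array_equal(filled.to_numpy()[obs], table.to_numpy()[obs])
        assert np.all(quality.to_numpy()[obs] == 1.0)
        # monotone missingness
        assert not (table.notna() & filled.isna()).any().any()
        # three-way quality semantics
        f = filled.to_numpy()
        q = quality.to_numpy()
        imp = ~obs & ~np.isnan(f)
        assert np.all((q[imp] > 0) & (q[imp] <= 1))
        assert np.all(np.isnan(q[np.isnan(f)]))
        assert report.n_filled + report.n_missing_after == report.n_missing_before
        assert len(report.gap_log) == report.n_filled

    @pytest.mark.parametrize("seed", range(4))
    def test_donor_choice_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(400 + seed)
        table, meta, values, microsites = random_network(rng)
        _, _, report = impute_table(table, meta, ImputeConfig(min_overlap=5))
        chosen = {
            (row.timestamp, row.target_id): row.donor_id
            for row in report.gap_log.itertuples()
        }
        n_ts = len(table)
        for ti, t in enumerate(table.index):
            for target in table.columns:
                if values[target][ti] is not None:
                    continue
                ref = brute_donor_choice(values, microsites, target, ti, n_ts, 5)
                assert chosen.get((t, target)) == ref

    def test_zero_noise_collinear_replicates_recover_exactly(self):
        cfg = SimConfig(
            start="2018-01-01 00:00",
            end="2018-12-31 23:59",
            cadence_switch="2018-07-01 00:00",
            noise_sd=0.0,
            anomaly_prob=0.0,
            outage_rate_per_year=0.0,
            seed=1,
        )
        sim = simulate_dataset(cfg)
        table = sim.observed.copy()
        # disjoint per-replicate gaps: a same-microsite donor is always observed
        n = len(table)
        for j, col in enumerate(table.columns):
            lo = (j % 3) * n // 6
            table.iloc[lo : lo + n // 6, j] = np.nan
        filled, _, report = impute_table(table, sim.meta, ImputeConfig(min_overlap=10))
        assert report.n_missing_after == 0
        err = (filled - sim.truth).abs().to_numpy()
        assert np.nanmax(err) < 1e-9

    def test_error_decreases_with_sensor_noise(self):
        maes = []
        for noise in (0.02, 0.005, 0.0):
            cfg = SimConfig(
                start="2018-01-01 00:00",
                end="2018-12-31 23:59",
                cadence_switch="2018-07-01 00:00",
                noise_sd=noise,
                anomaly_prob=0.0,
                seed=7,
            )
            sim = simulate_dataset(cfg)
            filled, _, _ = impute_table(
                sim.observed, sim.meta, ImputeConfig(min_overlap=20)
            )
            imp = sim.observed.isna() & filled.notna()
            maes.append(float((filled - sim.truth)[imp].abs().stack().mean()))
        assert maes[0] > maes[1] > maes[2]

    def test_iterative_mode_fills_at_least_as_much(self):
        rng = np.random.default_rng(9)
        table, meta, _, _ = random_network(rng, n_sensors=5, n_timestamps=150,
                                           p_missing=0.6)
        _, _, single = impute_table(table, meta, ImputeConfig(min_overlap=5))
        _, _, iterative = impute_table(
            table, meta, ImputeConfig(min_overlap=5, iterative=True)
        )
        assert iterative.n_filled >= single.n_filled
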