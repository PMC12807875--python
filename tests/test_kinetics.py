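import math

import numpy as np
import pandas as pd
import pytest

from xiescape.errors import InsufficientDataError
from xiescape.kinetics import (DecaySingleFit, ExponentialDecayModel,
                               fit_decay, fit_trajectories, half_life,
                               neighbor_similarity_test, select_model)

T_GRID = np.array([0.0, 3.0, 7.0, 14.0, 21.0])


def _curve(a, k, b, t=T_GRID):
    return a * np.exp(-k * t) + b


class TestHalfLife:
    def test_ln2_decay_gives_one_day(self):
        assert half_life(math.log(2)) == 1.0

    def test_slow_decay(self):
        assert half_life(0.1) == pytest.approx(6.9315, abs=1e-4)

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestFitDecay:
    def test_noiseless_recovery(self):
        k_true = math.log(2) / 3
        fit = fit_decay(T_GRID, _curve(0.4, k_true, 0.1), model="offset")
        assert fit.a == pytest.approx(0.4, abs=1e-4)
        assert fit.k == pytest.approx(k_true, abs=1e-4)
        assert fit.b == pytest.approx(0.1, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-8)

    def test_constant_series_is_unreliable(self):
        fit = fit_decay(T_GRID, np.full_like(T_GRID, 0.3), model="offset")
        assert not fit.converged
        row = select_model(fit, fit_decay(T_GRID, np.full_like(T_GRID, 0.3),
                                          model="no_offset"))
        assert row["selected_model"] == "unreliable"

    def test_too_few_timepoints(self):
        with pytest.raises(InsufficientDataError):
            fit_decay([0, 3], [0.4, 0.2])

    def test_noisy_recovery_of_k(self):
        rng = np.random.default_rng(0)
        k_true, depth = 0.3, 200
        t = np.repeat(T_GRID, 3)
        errors = []
        for _ in range(20):
            p = _curve(0.35, k_true, 0.05, t)
            obs = rng.binomial(depth, p) / depth
            row = ExponentialDecayModel(t, obs).fit()
            if row["selected_model"] != "unreliable":
                errors.append(abs(row["k"] - k_true) / k_true)
        assert np.median(errors) < 0.15

    def test_rss_nesting(self):
        rng = np.random.default_rng(1)
        t = np.repeat(T_GRID, 3)
        for _ in range(10):
            obs = np.clip(_curve(rng.uniform(0.2, 0.5), rng.uniform(0.1, 0.8),
                                 rng.uniform(0, 0.2), t)
                          + rng.normal(0, 0.03, len(t)), 0, 1)
            model = ExponentialDecayModel(t, obs)
            assert model.fit_offset().rss <= model.fit_no_offset().rss + 1e-10

    def test_time_unit_coherence(self):
        rng = np.random.default_rng(2)
        t = np.repeat(T_GRID, 3)
        obs = np.clip(_curve(0.4, 0.3, 0.1, t) + rng.normal(0, 0.02, len(t)),
                      0, 1)
        row = ExponentialDecayModel(t, obs).fit()
        scaled = ExponentialDecayModel(2 * t, obs).fit()
        assert scaled["k"] == pytest.approx(row["k"] / 2, rel=1e-3)
        assert scaled["selected_model"] == row["selected_model"]
        assert scaled["r2_offset"] == pytest.approx(row["r2_offset"], abs=1e-6)
        assert scaled["b"] == pytest.approx(row["b"], abs=1e-4)

    def test_grid_search_cannot_improve_fit(self):
        rng = np.random.default_rng(3)
        obs = np.clip(_curve(0.4, 0.25, 0.1) + rng.normal(0, 0.02, len(T_GRID)),
                      0, 1)
        fit = fit_decay(T_GRID, obs, model="offset")
        a_grid = np.linspace(-1, 1, 81)
        k_grid = np.linspace(1e-4, 2.0, 81)
        b_grid = np.linspace(0, 0.5, 41)
        pred = (a_grid[:, None, None, None]
                * np.exp(-k_grid[None, :, None, None] * T_GRID[None, None, None, :])
                + b_grid[None, None, :, None])
        rss = ((pred - obs[None, None, None, :]) ** 2).sum(axis=-1)
        assert fit.rss <= rss.min() + 1e-8


class TestSelectModel:
    def _fit(self, rss, offset, r2=0.9, b=0.0):
        return DecaySingleFit(a=0.4, k=0.3, b=b, rss=rss, r_squared=r2,
                              n_obs=15, offset=offset, converged=True)

    def test_tie_goes_to_no_offset(self):
        row = select_model(self._fit(0.01, True), self._fit(0.01, False))
        assert row["selected_model"] == "no_offset"
        assert not row["residual_escape"]

    def test_lower_bic_wins(self):
        row = select_model(self._fit(0.001, True, b=0.2), self._fit(0.1, False))
        assert row["selected_model"] == "offset"
        assert row["residual_escape"]
        assert row["residual_escape_b"]  # b = 0.2 > 0.1

    def test_both_poor_fits_unreliable(self):
        row = select_model(self._fit(0.5, True, r2=0.1),
                           self._fit(0.5, False, r2=0.05))
        assert row["selected_model"] == "unreliable"
        assert np.isnan(row["half_life_days"])

    def test_half_life_consistent_with_selected_k(self):
        row = select_model(self._fit(0.001, True, b=0.2), self._fit(0.1, False))
        assert row["half_life_days"] == pytest.approx(math.log(2) / row["k"])

    def test_bic_selection_rates_under_known_truth(self):
        rng = np.random.default_rng(4)
        t = np.repeat(T_GRID, 3)

        def selection_rate(b, target):
            hits = total = 0
            for _ in range(40):
                amp, k = rng.uniform(0.15, 0.4), rng.uniform(0.1, 0.6)
                obs = rng.binomial(200, np.clip(_curve(amp, k, b, t), 0, 1)) / 200
                row = ExponentialDecayModel(t, obs).fit()
                if row["selected_model"] != "unreliable":
                    total += 1
                    hits += row["selected_model"] == target
            return hits / total

        assert selection_rate(0.0, "no_offset") >= 0.9
        assert selection_rate(0.3, "offset") >= 0.9


class TestFitTrajectories:
    def test_washout_and_auxin_samples_excluded(self, sim):
        from xiescape.ratios import compute_allelic_ratios

        table = compute_allelic_ratios(sim.counts, sim.sheet)
        gene = sim.truth[sim.truth.category == "facultative"].gene_id.iloc[0]
        results = fit_trajectories(table, sim.sheet, genes=[gene])
        n_dox_samples = int((sim.sheet.washout_days == 0).sum())
        assert results.table.n_obs.iloc[0] <= n_dox_samples

    def test_summary_reports_counts(self, pipeline_out):
        from xiescape.kinetics import DecayResults

        text = DecayResults(pipeline_out["kinetics"]).summary()
        assert "genes fitted" in text and "residual escape" in text


class TestNeighborSimilarity:
    def _fits(self, half_lives):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(half_lives))],
            "selected_model": "no_offset",
            "half_life_days": half_lives,
        })

    def _annotation(self, starts):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(starts))],
            "chromosome": "X", "start": starts,
            "end": np.asarray(starts) + 1000, "strand": "+",
        })

    def test_equal_half_lives_hit_p_floor(self):
        fits = self._fits([2.0] * 6)
        ann = self._annotation([0, 50_000, 90_000, 500_000, 540_000, 580_000])
        out = neighbor_similarity_test(fits, ann, n_permutations=99, seed=1)
        assert out.observed_statistic == 0.0
        assert out.p_value == pytest.approx(1 / 100)

    def test_clustered_half_lives_significant(self):
        rng = np.random.default_rng(5)
        starts, half_lives = [], []
        position = 0
        for cluster in range(8):
            base = rng.uniform(1, 20)
            for _ in range(4):
                starts.append(position)
                half_lives.append(base * rng.uniform(0.95, 1.05))
                position += 30_000
            position += 500_000
        out = neighbor_similarity_test(self._fits(half_lives),
                                       self._annotation(starts),
                                       n_permutations=999, seed=2)
        assert out.p_value < 0.05

    def test_seeded_runs_are_identical(self):
        rng = np.random.default_rng(6)
        fits = self._fits(list(rng.uniform(1, 10, 8)))
        ann = self._annotation(list(range(0, 8 * 60_000, 60_000)))
        a = neighbor_similarity_test(fits, ann, n_permutations=200, seed=3)
        b = neighbor_similarity_test(fits, ann, n_permutations=200, seed=3)
        assert a.p_value == b.p_value

    def test_missing_seed_rejected(self):
        with pytest.raises(ValueError):
            neighbor_similarity_test(self._fits([1, 2]),
                                     self._annotation([0, 1000]), seed=None)

    def test_unidentifiable_half_lives_excluded(self):
        # one extrapolated half-life (beyond the time course) would dominate
        # the mean |difference|; max_half_life drops it from the statistic
        fits = self._fits([2.0, 2.1, 500.0, 8.0, 8.2, 7.9])
        ann = self._annotation([0, 40_000, 80_000, 900_000, 940_000, 980_000])
        capped = neighbor_similarity_test(fits, ann, n_permutations=99,
                                          seed=5, max_half_life=21.0)
        uncapped = neighbor_similarity_test(fits, ann, n_permutations=99,
                                            seed=5)
        assert capped.observed_statistic < uncapped.observed_statistic
        assert capped.n_pairs < uncapped.n_pairs

    def test_no_neighbors_not_applicable(self):
        fits = self._fits([1.0, 2.0])
        ann = self._annotation([0, 10_000_000])
        out = neighbor_similarity_test(fits, ann, n_permutations=99, seed=4)
        assert not out.applicable
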