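import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirdecay import decay_model as dm
from mirdecay.io_formats import ExpressionMatrix

from conftest import exponential_rows, make_design, make_matrix


def geomean(v):
    return float(np.exp(np.mean(np.log(v))))


class TestSelectReferences:
    def test_constant_beats_decaying(self):
        rows = exponential_rows({
            "flat": (100.0, 0.0, 100.0, 0.0),
            "halving": (100.0, math.log(2) / 2, 100.0, math.log(2) / 2),
        })
        m = make_matrix(rows)
        assert dm.select_references(m, ["flat", "halving"], 1) == ["flat"]

    def test_k_equals_all_returns_sorted(self):
        rows = exponential_rows({c: (10.0, 0.01, 10.0, 0.01)
                                 for c in "edcba"})
        m = make_matrix(rows)
        assert dm.select_references(m, list("edcba"), 5) == list("abcde")

    def test_hand_computed_cv_ordering(self):
        # 5 candidates over 8 samples (1 rep per time); CVs computed by hand
        samples = make_design(replicates=1)
        rows = {
            "c1": [10, 10, 10, 10, 10, 10, 10, 10],     # CV 0
            "c2": [10, 12, 10, 12, 10, 12, 10, 12],     # sd 1.069, CV .0972
            "c3": [5, 15, 5, 15, 5, 15, 5, 15],         # CV .535
            "c4": [10, 10, 10, 10, 20, 20, 20, 20],     # CV .3563
            "c5": [9, 11, 9, 11, 9, 11, 9, 11],         # CV .1069
        }
        m = make_matrix(rows, samples)
        assert dm.select_references(m, list(rows), 2) == ["c1", "c2"]
        assert dm.select_references(m, list(rows), 4) == ["c1", "c2", "c5", "c4"]

    def test_k_too_large_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            dm.select_references(toy_matrix, ["refA"], 2)


class TestNormalizeSamples:
    def test_rescaled_column_restored(self, toy_matrix):
        refs = ["refA", "refB"]
        baseline = dm.normalize_samples(toy_matrix, refs)
        scaled = toy_matrix.copy()
        col = scaled.sample_ids(genotype="WT", time_h=4.0)[0]
        scaled.values[col] *= 2.0
        renorm = dm.normalize_samples(scaled, refs)
        pd.testing.assert_frame_equal(renorm.values, baseline.values)

    def test_idempotent(self, toy_matrix):
        refs = ["refA", "refB"]
        once = dm.normalize_samples(toy_matrix, refs)
        twice = dm.normalize_samples(once, refs)
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_reference_geomean_equal_within_genotype(self, rng):
        rows = exponential_rows({
            "tx1": (50.0, 0.2, 55.0, 0.18),
            "refA": (100.0, 0.0, 100.0, 0.0),
            "refB": (300.0, 0.0, 300.0, 0.0),
        })
        m = make_matrix(rows)
        # arbitrary per-sample distortions
        for col in m.values.columns:
            m.values[col] *= rng.uniform(0.5, 2.0)
        norm = dm.normalize_samples(m, ["refA", "refB"])
        for g in ("WT", "KO"):
            gms = [geomean(norm.values.loc[["refA", "refB"], c])
                   for c in norm.sample_ids(genotype=g)]
            assert np.allclose(gms, gms[0], rtol=1e-9)

    def test_two_reference_factors_hand_computed(self):
        # 1 replicate, 2 time points, WT only values chosen for hand math
        samples = make_design(times=(0.0, 2.0), replicates=1)
        rows = {
            "tx": [8.0, 8.0, 8.0, 8.0],
            "r1": [4.0, 8.0, 4.0, 4.0],
            "r2": [9.0, 2.0, 9.0, 9.0],
        }
        m = make_matrix(rows, samples)
        norm = dm.normalize_samples(m, ["r1", "r2"])
        # WT t0: geomean(4,9)=6 -> anchor 6, factor 1; WT t2: geomean(8,2)=4,
        # factor 4/6 -> tx value 8/(2/3) = 12
        wt_t2 = norm.sample_ids(genotype="WT", time_h=2.0)[0]
        assert norm.values.loc["tx", wt_t2] == pytest.approx(12.0)
        wt_t0 = norm.sample_ids(genotype="WT", time_h=0.0)[0]
        assert norm.values.loc["tx", wt_t0] == pytest.approx(8.0)

    def test_cross_genotype_ratio_invariant_to_scale_factors(self, rng):
        # the WT-vs-KO equilibrium ratio must survive arbitrary per-sample
        # library scale factors: the references share one anchor
        rows = exponential_rows({
            "tx1": (50.0, 0.2, 55.0, 0.18),
            "refA": (100.0, 0.0, 100.0, 0.0),
            "refB": (300.0, 0.0, 300.0, 0.0),
        })
        m = make_matrix(rows)
        clean = dm.normalize_samples(m, ["refA", "refB"])
        distorted = m.copy()
        for col in distorted.values.columns:
            distorted.values[col] *= rng.uniform(0.5, 2.0)
        norm = dm.normalize_samples(distorted, ["refA", "refB"])
        for t in (0.0, 2.0):
            wt = norm.sample_ids(genotype="WT", time_h=t)[0]
            ko = norm.sample_ids(genotype="KO", time_h=t)[0]
            want = (clean.values.loc["tx1", ko] / clean.values.loc["tx1", wt])
            got = norm.values.loc["tx1", ko] / norm.values.loc["tx1", wt]
            assert got == pytest.approx(want, rel=1e-9)

    def test_nonpositive_reference_rejected(self, toy_matrix):
        m = toy_matrix.copy()
        m.values.loc["refA", m.values.columns[0]] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            dm.normalize_samples(m, ["refA", "refB"])


class TestFitDecay:
    def test_exact_exponential_recovered(self):
        m = make_matrix(exponential_rows({"tx": (10.0, 0.1, 10.0, 0.1)}))
        fit = dm.fit_decay(m, "tx", "WT")
        assert fit.D == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log(10.0), abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 8

    def test_constant_series_gives_zero_rate(self):
        m = make_matrix(exponential_rows({"tx": (7.0, 0.0, 7.0, 0.0)}))
        fit = dm.fit_decay(m, "tx", "KO")
        assert fit.D == pytest.approx(0.0, abs=1e-14)
        assert fit.half_life_h == math.inf
        assert fit.r2 == 1.0  # flat line fits a constant exactly

    def test_matches_closed_form_ols_on_noisy_points(self, rng):
        samples = make_design()
        t = np.array([s.time_h for s in samples if s.genotype == "WT"])
        y = -0.15 * t + 2.0 + rng.normal(0, 0.2, size=t.size)
        vals = np.concatenate([np.exp(y), np.ones(8)])
        m = make_matrix({"tx": vals}, samples)
        fit = dm.fit_decay(m, "tx", "WT")
        tbar, ybar = t.mean(), y.mean()
        slope = ((t - tbar) * (y - ybar)).sum() / ((t - tbar) ** 2).sum()
        assert fit.D == pytest.approx(-slope, abs=1e-12)

    def test_nonpositive_value_instructs_to_filter(self):
        samples = make_design()
        vals = [1.0] * 16
        vals[3] = 0.0
        m = make_matrix({"tx": vals}, samples)
        with pytest.raises(ValueError, match="filter"):
            dm.fit_decay(m, "tx", "WT")

    def test_consistency_half_life_field(self, toy_matrix):
        for g in ("WT", "KO"):
            fit = dm.fit_decay(toy_matrix, "txB", g)
            assert fit.half_life_h == dm.half_life(fit.D)

    def test_scale_invariance_of_rates(self, toy_matrix, rng):
        refs = ["refA", "refB"]
        base = {g: dm.fit_decay(dm.normalize_samples(toy_matrix, refs),
                                "txA", g).D for g in ("WT", "KO")}
        scaled = toy_matrix.copy()
        for col in scaled.values.columns:
            scaled.values[col] *= rng.uniform(0.25, 4.0)
        renorm = dm.normalize_samples(scaled, refs)
        for g in ("WT", "KO"):
            assert dm.fit_decay(renorm, "txA", g).D == \
                pytest.approx(base[g], abs=1e-9)


class TestHalfLife:
    def test_log2_rate_gives_one_hour(self):
        assert dm.half_life(math.log(2)) == pytest.approx(1.0, abs=1e-12)

    def test_fifteen_hour_boundary_rate(self):
        assert dm.half_life(0.046210) == pytest.approx(15.0, abs=1e-3)

    @pytest.mark.parametrize("d", [0.0, -0.01])
    def test_non_decaying_is_infinite(self, d):
        assert dm.half_life(d) == math.inf


class TestApplyFilters:
    def make_five(self):
        # txLow fails FPKM (4.9 at the last WT sample); txSlow fails the
        # 16 h half-life; the other three pass
        rows = exponential_rows({
            "txA": (50.0, 0.2, 50.0, 0.2),
            "txB": (80.0, 0.1, 80.0, 0.1),
            "txC": (60.0, 0.3, 60.0, 0.3),
            "txSlow": (50.0, math.log(2) / 16, 50.0, math.log(2) / 16),
            "txLow": (4.9 * math.exp(0.2 * 8), 0.2, 50.0, 0.2),
        })
        return make_matrix(rows)

    def test_hand_enumerated_toy_keeps_three_of_five(self):
        m = self.make_five()
        fits = dm.fit_all(m, "WT")
        assert dm.apply_filters(m, fits) == {"txA", "txB", "txC"}

    def test_all_pass_when_unfiltered(self):
        m = self.make_five()
        fits = dm.fit_all(m, "KO")  # txLow has healthy KO expression
        kept = dm.apply_filters(m, fits, min_fpkm=0.0, max_halflife_h=1e9)
        assert kept == set(m.transcript_ids)

    def test_boundaries_inclusive(self):
        # FPKM exactly 5 at the worst sample and half-life exactly 15 h
        d15 = math.log(2) / 15.0
        rows = exponential_rows({
            "edge": (5.0 * math.exp(d15 * 8), d15, 5.0 * math.exp(d15 * 8), d15),
        })
        m = make_matrix(rows)
        fits = dm.fit_all(m, "WT")
        assert dm.apply_filters(m, fits) == {"edge"}


class TestMode1D:
    def test_degenerate_sample(self):
        assert dm.mode_1d([0.12, 0.12, 0.12]) == 0.12

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            dm.mode_1d([0.12])

    def test_symmetric_unimodal_center(self, rng):
        draws = rng.normal(0.12, 0.03, size=10_000)
        assert dm.mode_1d(draws) == pytest.approx(0.12, abs=0.005)

    def test_mixture_prefers_heavier_cluster(self, rng):
        draws = np.concatenate([
            rng.normal(0.1, 0.01, size=8000),
            rng.normal(0.3, 0.01, size=2000),
        ])
        assert dm.mode_1d(draws) == pytest.approx(0.1, abs=0.01)

    def test_matches_brute_force_grid_oracle(self, rng):
        from scipy.stats import gaussian_kde
        for _ in range(5):
            v = rng.gamma(4.0, 0.04, size=500)
            kde = gaussian_kde(v, bw_method="silverman")
            grid = np.linspace(v.min(), v.max(), 512)
            dens = [kde([g])[0] for g in grid[::8]]
            coarse_best = grid[::8][int(np.argmax(dens))]
            step = grid[1] - grid[0]
            assert abs(dm.mode_1d(v) - coarse_best) <= 8 * step


class TestNormalizeByMode:
    def _fits(self, values, genotype):
        return {f"t{i}": dm.DecayFit(f"t{i}", genotype, v, 0.0,
                                     dm.half_life(v), 8, 1.0)
                for i, v in enumerate(values)}

    def test_division_arithmetic(self):
        wt = self._fits([0.12] * 50 + [0.24], "WT")
        ko = self._fits([0.14] * 50 + [0.28], "KO")
        table = dm.normalize_by_mode({"WT": wt, "KO": ko})
        # mode sits at the dense cluster; every entry is D / genotype mode
        assert table.mode_wt == pytest.approx(0.12, abs=0.005)
        assert table.mode_ko == pytest.approx(0.14, abs=0.005)
        assert np.allclose(table.table["D_wt_norm"],
                           table.table["D_wt"] / table.mode_wt)
        assert np.allclose(table.table["D_ko_norm"],
                           table.table["D_ko"] / table.mode_ko)

    def test_genotypes_normalized_independently(self, rng):
        wt_vals = rng.gamma(5.0, 0.03, size=400)
        ko_vals = wt_vals * 0.8
        table = dm.normalize_by_mode({"WT": self._fits(wt_vals, "WT"),
                                      "KO": self._fits(ko_vals, "KO")})
        ratio = table.table["D_wt_norm"] / table.table["D_ko_norm"]
        # per-genotype mode division cancels the uniform 0.8 shift
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_mode_of_normalized_values_is_one(self, rng):
        vals = rng.gamma(5.0, 0.03, size=2000)
        table = dm.normalize_by_mode({"WT": self._fits(vals, "WT"),
                                      "KO": self._fits(vals, "KO")})
        renorm_mode = dm.mode_1d(table.table["D_wt_norm"].to_numpy())
        # KDE-grid tolerance: one grid step of the normalized sample
        span = (table.table["D_wt_norm"].max()
                - table.table["D_wt_norm"].min())
        assert abs(renorm_mode - 1.0) <= span / 511 + 0.02


class TestEquilibrium:
    def test_mean_of_t0_replicates(self):
        samples = make_design(times=(0.0, 2.0), replicates=2)
        rows = {"tx": [10.0, 12.0, 1.0, 1.0, 20.0, 24.0, 1.0, 1.0]}
        m = make_matrix(rows, samples)
        (rec,) = dm.equilibrium_expression(m)
        assert rec.X_wt == pytest.approx(11.0)
        assert rec.X_ko == pytest.approx(22.0)

    def test_single_replicate_is_identity(self):
        samples = make_design(times=(0.0, 2.0), replicates=1)
        m = make_matrix({"tx": [10.0, 1.0, 30.0, 1.0]}, samples)
        (rec,) = dm.equilibrium_expression(m)
        assert (rec.X_wt, rec.X_ko) == (10.0, 30.0)

    def test_missing_t0_rejected(self):
        samples = make_design(times=(2.0, 4.0), replicates=1)
        with pytest.raises(ValueError):
            samples = [s for s in samples]
            m = make_matrix({"tx": [1.0] * 4}, samples)
            dm.equilibrium_expression(m)


class TestImpliedDegradationRatio:
    def test_worked_example_bias(self):
        # equilibrium says +10%; synthesis doubles -> true increase 120%
        assert dm.implied_degradation_ratio(1.1, 2.0) == pytest.approx(2.2)

    def test_no_coupling_reduces_to_equilibrium(self):
        assert dm.implied_degradation_ratio(1.1, 1.0) == pytest.approx(1.1)

    def test_identity(self):
        assert dm.implied_degradation_ratio(1.0, 1.0) == 1.0

    @pytest.mark.parametrize("args", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(ValueError):
            dm.implied_degradation_ratio(*args)


@given(st.floats(0.01, 100), st.floats(0.01, 100))
def test_percent_change_complement_identity(a, b):
    from mirdecay.group_compare import percent_change
    u = percent_change(a, b)
    v = percent_change(b, a)
    assert (1 + u) * (1 + v) == pytest.approx(1.0, rel=1e-9)
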