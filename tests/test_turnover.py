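"""Unit and property tests for the dSILAC turnover estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import lysokit as lk
from lysokit.errors import InsufficientDataError, InsufficientOverlapError, ValidationError
from lysokit.turnover import CENSOR_MISSING, CENSOR_NONE, CENSOR_TOO_FAST, CENSOR_TOO_SLOW


class TestLabelRatio:
    @pytest.mark.parametrize("H,L,psi,theta", [
        (100.0, 100.0, 1.0, 0.5),
        (300.0, 100.0, 3.0, 0.75),
        (0.0, 100.0, 0.0, 0.0),
    ])
    def test_ratio_arithmetic(self, H, L, psi, theta):
        r = lk.label_ratio(L, H)
        assert r.psi == pytest.approx(psi)
        assert r.heavy_fraction == pytest.approx(theta)
        assert r.censored == CENSOR_NONE

    def test_no_light_is_censored_too_fast(self):
        r = lk.label_ratio(0.0, 50.0)
        assert r.censored == CENSOR_TOO_FAST and math.isinf(r.psi)

    def test_both_zero_is_missing(self):
        assert lk.label_ratio(0.0, 0.0).censored == CENSOR_MISSING

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            lk.label_ratio(-1.0, 5.0)

    def test_psi_theta_identity(self):
        r = lk.label_ratio(40.0, 160.0)
        assert r.psi == pytest.approx(r.heavy_fraction / (1 - r.heavy_fraction))


class TestSingleTimepoint:
    @pytest.mark.parametrize("psi,ts_h,expected_days", [
        (1.0, 96.0, 4.0),                        # ln2/ln2
        (3.0, 96.0, 2.0),                        # ln4 = 2 ln2
        (math.sqrt(2) - 1, 96.0, 8.0),           # ln(sqrt 2) = ln2/2
    ])
    def test_closed_form_anchor_points(self, psi, ts_h, expected_days):
        est = lk.single_timepoint_half_life(psi, ts_h)
        assert est.half_life_days == pytest.approx(expected_days, rel=1e-12)

    def test_matches_numeric_root_finder(self):
        # independent oracle: solve exp(k t_s) - 1 = psi for k
        psi, ts_h = math.e - 1, 144.0
        ts_d = ts_h / 24.0
        k = optimize.brentq(lambda kk: math.exp(kk * ts_d) - 1 - psi, 1e-6, 10)
        est = lk.single_timepoint_half_life(psi, ts_h)
        assert est.half_life_days == pytest.approx(math.log(2) / k, rel=1e-9)
        assert est.half_life_days == pytest.approx(6 * math.log(2), rel=1e-12)

    def test_psi_zero_censored_too_slow(self):
        est = lk.single_timepoint_half_life(0.0, 96.0)
        assert math.isinf(est.half_life_days) and est.censored == CENSOR_TOO_SLOW

    def test_fast_censoring_outside_dynamic_range(self):
        psi = 2 ** 30.0 - 1  # implies t_half = ts/30 < ts/20
        assert lk.single_timepoint_half_life(psi, 96.0).censored == CENSOR_TOO_FAST

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            lk.single_timepoint_half_life(-0.5, 96.0)
        with pytest.raises(ValidationError):
            lk.single_timepoint_half_life(1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(ts=st.floats(1.0, 1000.0))
    def test_identity_at_psi_one(self, ts):
        # psi = 1 means exactly one half-life has elapsed
        est = lk.single_timepoint_half_life(1.0, ts)
        assert est.half_life_days * 24.0 == pytest.approx(ts, rel=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(T=st.floats(0.3, 40.0), ts_d=st.floats(0.5, 10.0))
    def test_noiseless_consistency(self, T, ts_d):
        psi = 2.0 ** (ts_d / T) - 1.0
        est = lk.single_timepoint_half_life(psi, ts_d * 24.0, fast_censor_factor=1e9)
        assert est.half_life_days == pytest.approx(T, rel=1e-12)
        assert est.half_life_days * est.rate_k_per_day == pytest.approx(math.log(2))

    def test_strictly_decreasing_in_psi(self):
        psis = np.linspace(0.01, 20, 200)
        hl = [lk.single_timepoint_half_life(p, 96.0, fast_censor_factor=1e9).half_life_days
              for p in psis]
        assert all(a > b for a, b in zip(hl, hl[1:]))


class TestDecayFit:
    def test_noiseless_self_consistency(self):
        k = math.log(2) / 4.0
        t_h = np.array([24.0, 48.0, 96.0, 144.0])
        f = np.exp(-k * t_h / 24.0)
        est = lk.fit_first_order_decay(t_h, f)
        assert est.half_life_days == pytest.approx(4.0, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.n_points == 4

    def test_matches_grid_search_oracle(self):
        # independent oracle: dense grid over k minimizing the SSE
        k_true = math.log(2) / 1.5
        t_h = np.array([24.0, 48.0, 96.0, 144.0])
        f = np.exp(-k_true * t_h / 24.0)
        grid = np.linspace(0.01, 2.0, 200001)
        sse = ((f[None, :] - np.exp(-grid[:, None] * t_h / 24.0)) ** 2).sum(axis=1)
        k_grid = grid[np.argmin(sse)]
        est = lk.fit_first_order_decay(t_h, f)
        assert est.rate_k_per_day == pytest.approx(k_grid, rel=1e-4)
        assert est.half_life_days == pytest.approx(1.5, rel=1e-9)

    def test_no_decay_censored_too_slow(self):
        est = lk.fit_first_order_decay([24.0, 48.0, 96.0], [1.0, 1.0, 1.0])
        assert est.censored == CENSOR_TOO_SLOW and math.isinf(est.half_life_days)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            lk.fit_first_order_decay([24.0, 48.0], [0.9, 0.8])

    def test_noisy_fit_r_squared_below_one(self):
        rng = np.random.default_rng(1)
        k = math.log(2) / 3.0
        t_h = np.array([24.0, 48.0, 96.0, 144.0])
        f = np.exp(-k * t_h / 24.0) * rng.lognormal(0, 0.1, 4)
        est = lk.fit_first_order_decay(t_h, f)
        assert 0.5 < est.r_squared < 1.0


class TestProteinAggregation:
    def _pep(self, hl, censored=CENSOR_NONE):
        from lysokit.turnover import HalfLifeEstimate
        return HalfLifeEstimate("PEP", "peptide", "single_timepoint", hl,
                                math.log(2) / hl if math.isfinite(hl) and hl > 0 else 0.0,
                                censored=censored)

    def test_mean_of_peptides(self):
        est = lk.peptide_to_protein([self._pep(2.0), self._pep(4.0), self._pep(6.0)], "P1")
        assert est.half_life_days == pytest.approx(4.0)
        assert est.n_points == 3 and est.level == "protein"

    def test_single_peptide_identity(self):
        est = lk.peptide_to_protein([self._pep(3.7)], "P1")
        assert est.half_life_days == pytest.approx(3.7) and est.n_points == 1

    def test_censored_peptides_excluded(self):
        est = lk.peptide_to_protein(
            [self._pep(2.0), self._pep(4.0), self._pep(float("inf"), CENSOR_TOO_SLOW)], "P1")
        assert est.half_life_days == pytest.approx(3.0) and est.n_points == 2

    def test_all_censored_gives_missing(self):
        assert lk.peptide_to_protein([self._pep(float("inf"), CENSOR_TOO_SLOW)], "P1") is None

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.5, 30.0), min_size=1, max_size=8))
    def test_permutation_invariant_and_equals_mean(self, hls):
        a = lk.peptide_to_protein([self._pep(h) for h in hls], "P")
        b = lk.peptide_to_protein([self._pep(h) for h in reversed(hls)], "P")
        assert a.half_life_days == pytest.approx(b.half_life_days)
        assert a.half_life_days == pytest.approx(float(np.mean(hls)))


class TestPipeline:
    def test_noiseless_recovery_through_model(self, noiseless_dsilac):
        table, truth = noiseless_dsilac
        res = lk.HalfLifeModel(table).fit()
        recovered = res.protein_half_lives("WT")
        for pid, est in recovered.items():
            assert est == pytest.approx(truth.true_half_lives["WT"][pid], rel=1e-9)

    def test_multi_timepoint_matches_closed_form_noiseless(self, noiseless_dsilac):
        table, truth = noiseless_dsilac
        res = lk.HalfLifeModel(table).fit("multi_timepoint")
        assert (res.peptide_estimates["r_squared"].dropna() > 1 - 1e-9).all()
        recovered = res.protein_half_lives("WT")
        for pid, est in recovered.items():
            assert est == pytest.approx(truth.true_half_lives["WT"][pid], rel=1e-9)

    def test_missed_cleavage_peptides_excluded_by_default(self):
        design = lk.DSilacDesign(n_proteins=10, peptides_per_protein=4,
                                 n_replicates=1, noise_cv=0.0,
                                 missed_cleavage_fraction=0.5)
        table, _ = lk.generate_dsilac(design, seed=3)
        model = lk.HalfLifeModel(table)
        assert (model.data["missed_cleavages"] == 0).all()
        model_all = lk.HalfLifeModel(table, exclude_missed_cleavages=False)
        assert len(model_all.data) > len(model.data)

    def test_no_recycling_correction_code_path(self):
        # the estimator is the pure closed form: no recycling parameter exists
        import inspect
        from lysokit import turnover
        sig = inspect.signature(lk.single_timepoint_half_life)
        assert not any("recycl" in p.lower() for p in sig.parameters)
        assert not any("recycl" in name.lower() for name in dir(turnover))


class TestCompareEstimators:
    def test_noiseless_agreement_is_exact(self, noiseless_dsilac):
        table, _ = noiseless_dsilac
        model = lk.HalfLifeModel(table)
        multi = model.fit("multi_timepoint").protein_half_lives("WT")
        single = model.fit("single_timepoint").protein_half_lives("WT")
        cmp_ = lk.compare_estimators(multi, single)
        assert cmp_.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert cmp_.slope == pytest.approx(1.0, abs=1e-6)

    def test_noisy_agreement_stays_strong(self, noisy_dsilac):
        table, _ = noisy_dsilac
        model = lk.HalfLifeModel(table)
        multi = model.fit("multi_timepoint").protein_half_lives("WT")
        single = model.fit("single_timepoint").protein_half_lives("WT")
        assert lk.compare_estimators(multi, single).pearson_r > 0.95

    def test_disjoint_sets_raise(self):
        import pandas as pd
        a = pd.Series([1.0] * 12, index=[f"A{i}" for i in range(12)])
        b = pd.Series([1.0] * 12, index=[f"B{i}" for i in range(12)])
        with pytest.raises(InsufficientOverlapError):
            lk.compare_estimators(a, b)
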