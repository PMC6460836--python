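"""chrY- and size-based fetal-fraction estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ffenrich import (ChrYCalibration, SizeFFModel, apply_read_filters,
                      estimate_ff_size, ff_from_chry, size_ratios,
                      train_size_ff_model)
from ffenrich.fetal_fraction import estimate_ff_size_from_records

from conftest import make_sample


class TestChrY:
    cal = ChrYCalibration(b_f=0.0002, y_m=0.01)

    def test_baseline_maps_to_zero(self):
        assert ff_from_chry(0.0002, self.cal) == 0.0

    def test_pure_male_maps_to_one(self):
        assert ff_from_chry(0.01, self.cal) == 1.0

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            ChrYCalibration(b_f=0.01, y_m=0.005)

    def test_recovers_truth_on_male_cohort(self, genome, chry_calibration):
        """Mean chrY estimate over 25 male samples at ff=0.12 within 3 SE."""
        ests = []
        for i in range(25):
            rec, _ = make_sample(genome, 0.12, n=150_000, seed=4000 + i)
            filt, _ = apply_read_filters(rec)
            ests.append(ff_from_chry(filt, chry_calibration))
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.12) < 3 * se + 1e-3


class TestSizeRatios:
    def test_all_in_region_a(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=1_000, seed=0)
        rec = rec.assign(length=np.full(len(rec), 135, dtype=np.int16))
        r_a, r_b = size_ratios(rec)
        assert (r_a, r_b) == (1.0, 0.0)

    def test_half_open_region_bounds(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=4, seed=1)
        rec = rec.assign(length=np.array([130, 140, 155, 175], dtype=np.int16))
        r_a, r_b = size_ratios(rec)
        assert r_a == 0.25 and r_b == 0.25

    def test_empty_table_rejected(self, toy_genome):
        rec, _ = make_sample(toy_genome, 0.1, n=10, seed=2)
        with pytest.raises(ValueError):
            size_ratios(rec.iloc[:0])

    def test_region_shares_move_with_ff(self, genome):
        """Higher fetal fraction gives larger region-A and smaller region-B
        shares, pairwise across seeds."""
        for seed in range(5):
            lo, _ = make_sample(genome, 0.05, n=120_000, seed=100 + seed)
            hi, _ = make_sample(genome, 0.25, n=120_000, seed=100 + seed)
            ra_lo, rb_lo = size_ratios(lo)
            ra_hi, rb_hi = size_ratios(hi)
            assert ra_hi > ra_lo and rb_hi < rb_lo


class TestPdiffRule:
    def linear_model(self):
        x = np.linspace(0.0, 1.0, 11)
        return SizeFFModel(xa=x, ya=x, xb=x, yb=x)

    def test_identical_features(self):
        est = estimate_ff_size(self.linear_model(), 0.10, 0.10)
        assert est.p_diff == 0.0 and est.p == pytest.approx(0.10)
        assert est.predictable

    def test_boundary_point_four_is_still_predictable(self):
        est = estimate_ff_size(self.linear_model(), 0.15, 0.10)
        assert est.p_diff == pytest.approx(0.4)
        assert est.predictable and est.p == pytest.approx(0.125)

    def test_two_thirds_discrepancy_is_unpredictable(self):
        est = estimate_ff_size(self.linear_model(), 0.20, 0.10)
        assert est.p_diff == pytest.approx(2 / 3)
        assert not est.predictable and est.p is None

    def test_reversed_discrepancy_also_flagged(self):
        est = estimate_ff_size(self.linear_model(), 0.10, 0.20)
        assert not est.predictable

    def test_zero_features_guarded(self):
        est = estimate_ff_size(self.linear_model(), 0.0, 0.0)
        assert not est.predictable and est.p is None

    @given(st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    def test_pdiff_antisymmetric(self, a, b):
        m = self.linear_model()
        fwd = estimate_ff_size(m, a, b)
        rev = estimate_ff_size(m, b, a)
        assert fwd.p_diff == pytest.approx(-rev.p_diff)
        assert fwd.predictable == rev.predictable


class TestSizeModel:
    def test_noiseless_linear_training_reproduced(self):
        ra = np.linspace(0.05, 0.20, 40)
        rb = np.linspace(0.30, 0.15, 40)
        ff = np.linspace(0.03, 0.30, 40)
        model = train_size_ff_model(
            [((a, b), f) for a, b, f in zip(ra, rb, ff)])
        for a, f in zip(ra[5:-5], ff[5:-5]):
            assert model.predict_a(a) == pytest.approx(f, abs=0.01 * 0.3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train_size_ff_model([((0.1, 0.2), 0.1)] * 10)

    def test_json_roundtrip(self, tmp_path):
        x = np.linspace(0.0, 1.0, 5)
        model = SizeFFModel(xa=x, ya=x**2, xb=x, yb=1 - x)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = SizeFFModel.from_json(path)
        np.testing.assert_allclose(loaded.ya, model.ya)
        assert loaded.region_a == model.region_a

    def test_end_to_end_parameter_recovery(self, genome, chry_calibration):
        """Train on 60 chrY-labelled male samples, predict 20 held-out
        samples: mean absolute error below 0.03 and chrY/size estimates
        agree within 0.05 for 95% of samples."""
        rng = np.random.default_rng(7)
        train = []
        for i in range(60):
            ff = float(rng.uniform(0.03, 0.30))
            rec, _ = make_sample(genome, ff, n=150_000, seed=5000 + i)
            filt, _ = apply_read_filters(rec)
            label = ff_from_chry(filt, chry_calibration)
            train.append((filt, label))
        model = train_size_ff_model(train)

        errors, gaps = [], []
        for i in range(20):
            ff = float(rng.uniform(0.05, 0.28))
            rec, _ = make_sample(genome, ff, n=150_000, seed=6000 + i)
            filt, _ = apply_read_filters(rec)
            est = estimate_ff_size_from_records(model, filt)
            assert est.predictable
            errors.append(abs(est.p - ff))
            gaps.append(abs(est.p - ff_from_chry(filt, chry_calibration)))
        assert np.mean(errors) < 0.03
        assert np.mean(np.array(gaps) < 0.05) >= 0.95

    def test_pdiff_99th_percentile_below_ceiling(self, genome, chry_calibration):
        """On a normal cohort the empirical 99th percentile of |P_diff| stays
        below the 0.40 unpredictability ceiling."""
        rng = np.random.default_rng(9)
        train = []
        for i in range(40):
            ff = float(rng.uniform(0.03, 0.30))
            rec, _ = make_sample(genome, ff, n=120_000, seed=7000 + i)
            filt, _ = apply_read_filters(rec)
            train.append((filt, ff_from_chry(filt, chry_calibration)))
        model = train_size_ff_model(train)
        pdiffs = []
        for i in range(100):
            ff = float(np.clip(rng.normal(0.13, 0.045), 0.03, 0.30))
            rec, _ = make_sample(genome, ff, n=120_000, seed=8000 + i)
            filt, _ = apply_read_filters(rec)
            est = estimate_ff_size_from_records(model, filt)
            pdiffs.append(abs(est.p_diff))
        assert np.quantile(pdiffs, 0.99) < 0.40
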