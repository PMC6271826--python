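import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanpls import (
    build_report,
    convert_basis,
    fit_pls,
    loo_cross_validate,
    predict,
    r_squared,
    rmse,
)
from ramanpls.metrics import ErrorReport

from conftest import exact_rank_instance


def naive_rmse(y, y_hat):
    total = 0.0
    for a, b in zip(y, y_hat):
        total += (a - b) ** 2
    return math.sqrt(total / len(y))


class TestRmse:
    def test_identity_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0

    def test_hand_computed_case(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(math.sqrt(12.5), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_elementwise_loop(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=50)
        y_hat = rng.normal(size=50)
        assert rmse(y, y_hat) == pytest.approx(naive_rmse(y, y_hat), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse([], [])


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 5.0, 9.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_gives_zero(self):
        y = np.array([2.0, 4.0, 6.0, 8.0])
        assert r_squared(y, np.full(4, 5.0)) == pytest.approx(0.0, abs=1e-14)

    def test_four_point_hand_computation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        y_hat = np.array([1.1, 1.9, 3.2, 3.8])
        ss_res = 0.01 + 0.01 + 0.04 + 0.04
        ss_tot = 2.25 + 0.25 + 0.25 + 2.25
        assert r_squared(y, y_hat) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.full(3, 2.0), np.array([1.0, 2.0, 3.0]))


class TestConvertBasis:
    @pytest.mark.parametrize(
        "cbz_err, tablet_err",
        [(9.49, 1.58), (6.27, 1.04), (1.34, 0.22)],
    )
    def test_reported_bracket_values(self, cbz_err, tablet_err):
        """CBZ-basis validation errors x 50/300 reproduce the tablet-basis values."""
        assert round(convert_basis(cbz_err, 50.0 / 300.0), 2) == pytest.approx(
            tablet_err, abs=0.01
        )

    def test_zero_error_stays_zero(self):
        assert convert_basis(0.0, 0.5) == 0.0

    def test_linearity(self):
        assert convert_basis(7.0, 0.2) == pytest.approx(
            7.0 * convert_basis(1.0, 0.2), abs=1e-14
        )

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            convert_basis(5.0, 0.0)
        with pytest.raises(ValueError):
            convert_basis(5.0, 1.5)


def naive_loo(X, Y, candidates):
    """Straightforward per-candidate refit loop (the reference driver)."""
    import warnings

    n = X.shape[0]
    out = np.empty((len(candidates), n, Y.shape[1]))
    for j, k in enumerate(candidates):
        for i in range(n):
            keep = np.arange(n) != i
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_pls(X[keep], Y[keep], n_lv=min(k, m_cap(X[keep])))
            out[j, i] = predict(m, X[i])
    return np.sqrt(np.mean((out - Y[None]) ** 2, axis=1)).mean(axis=1)


def m_cap(X):
    return min(X.shape[0] - 1, X.shape[1])


class TestLooCrossValidate:
    def test_noiseless_exact_rank_instance_has_tiny_rmsecv(self, rng):
        X, Y = exact_rank_instance(rng, n=10, p=8, r=3)
        cv, _ = loo_cross_validate(X, Y, [3])
        assert cv.rmsecv_mean[0] < 1e-6

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(9, 6))
        Y = rng.normal(size=(9, 3)) + X[:, :2] @ rng.normal(size=(2, 3))
        candidates = [1, 2, 3, 4]
        cv, _ = loo_cross_validate(X, Y, candidates)
        assert np.allclose(cv.rmsecv_mean, naive_loo(X, Y, candidates), atol=1e-10)

    def test_minimal_three_sample_case(self, rng):
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(3, 2))
        cv, preds = loo_cross_validate(X, Y, [1])
        assert preds.shape == (1, 3, 2)

    def test_fewer_than_three_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            loo_cross_validate(rng.normal(size=(2, 4)), rng.normal(size=(2, 2)), [1])

    def test_calibration_optimism_holds_across_seeds(self):
        """RMSEC <= RMSECV in at least 95% of 100 seeded noisy instances."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 6))
            B = rng.normal(size=(6, 2))
            Y = X @ B + rng.normal(scale=0.5, size=(10, 2))
            n_lv = 2
            model = fit_pls(X, Y, n_lv=n_lv)
            rmsec = rmse(Y.ravel(), predict(model, X).ravel())
            cv, _ = loo_cross_validate(X, Y, [n_lv])
            rmsecv = float(cv.rmsecv_mean[0])
            hits += rmsec <= rmsecv
        assert hits >= 95


class TestBuildReport:
    @pytest.fixture
    def perfect_report(self, design):
        Y = design.responses()
        cal = {s.sample_id: Y[i] for i, s in enumerate(design) if s.role == "calibration"}
        val = {s.sample_id: Y[i] for i, s in enumerate(design) if s.role == "validation"}
        return build_report(design, cal, val)

    def test_perfect_predictions_give_zero_errors(self, perfect_report):
        assert (perfect_report.table[["rmsec", "rmsev"]] < 1e-12).all().all()
        assert (perfect_report.table["r2"] > 0.999999).all()

    def test_tablet_basis_is_cbz_basis_scaled(self, design):
        Y = design.responses()
        rng = np.random.default_rng(0)
        cal = {
            s.sample_id: Y[i] + rng.normal(scale=2.0, size=3)
            for i, s in enumerate(design) if s.role == "calibration"
        }
        val = {
            s.sample_id: Y[i] + rng.normal(scale=2.0, size=3)
            for i, s in enumerate(design) if s.role == "validation"
        }
        rep = build_report(design, cal, val)
        frac = rep.cbz_tablet_fraction
        assert frac == pytest.approx(50.0 / 300.0, abs=2e-3)  # actual, near nominal
        for m in ("rmsec", "rmsev"):
            assert np.allclose(
                rep.table[m + "_tablet"], rep.table[m] * frac, atol=1e-12
            )

    def test_missing_sample_predictions_rejected(self, design):
        Y = design.responses()
        cal = {s.sample_id: Y[i] for i, s in enumerate(design) if s.role == "calibration"}
        with pytest.raises(ValueError, match="missing"):
            build_report(design, cal, {})

    def test_csv_round_trip(self, perfect_report, tmp_path):
        path = tmp_path / "report.csv"
        perfect_report.to_csv(path)
        again = ErrorReport.from_csv(path)
        assert np.allclose(
            again.table.to_numpy(), perfect_report.table.to_numpy(), equal_nan=True
        )
        assert list(again.table.columns) == list(perfect_report.table.columns)

    def test_formatted_table_mentions_all_polymorphs(self, perfect_report):
        text = perfect_report.formatted()
        for name in ("CBZ_I", "CBZ_III", "CBZ_DH"):
            assert name in text
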