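"""LOD/LOQ estimation: detection-curve and CV-curve fits, model selection."""

import numpy as np
import pandas as pd
import pytest

from ednaquant import (
    LoqEstimator,
    SimulationConfig,
    assess_sensitivity,
    estimate_lod,
    estimate_loq,
    fit_standard_curve,
    mean_lod,
    poisson_theoretical_lod,
    simulate_dilution_series,
    summarize_cv,
    summarize_detections,
)
from ednaquant.records import SensitivityError

from conftest import make_standards


def detection_frame(copies, efficiency=1.0, n=10000):
    """Deterministic binomial summaries at the Poisson detection curve."""
    copies = np.asarray(copies, dtype=float)
    p = 1.0 - np.exp(-efficiency * copies)
    return pd.DataFrame(
        {
            "copies": copies,
            "n_replicates": n,
            "n_detected": np.round(n * p).astype(int),
        }
    )


class TestSummaries:
    def test_detection_counts(self):
        df = make_standards(-3.4, 38.0, np.concatenate([np.full(10, 100.0), np.full(10, 1.0)]))
        df.loc[df.index[-4:], "cq"] = np.nan  # 4 non-detects at 1 copy
        out = summarize_detections(df)
        assert out.shape[0] == 2
        low = out[out["copies"] == 1.0].iloc[0]
        assert (low["n_replicates"], low["n_detected"]) == (10, 6)
        high = out[out["copies"] == 100.0].iloc[0]
        assert (high["n_replicates"], high["n_detected"]) == (10, 10)

    def test_empty_errors(self):
        with pytest.raises(SensitivityError):
            summarize_detections(make_standards(-3.4, 38.0, np.array([])))

    def test_cv_requires_two_detected(self):
        df = make_standards(-3.4, 38.0, np.array([10.0, 10.0, 100.0]))
        df.loc[df.index[1], "cq"] = np.nan
        curve_df = make_standards(-3.4, 38.0, 10.0 ** np.arange(0, 5))
        curve = fit_standard_curve(curve_df)
        out = summarize_cv(df, curve)
        assert out["copies"].tolist() == []  # singleton groups dropped


class TestLod:
    def test_pure_poisson_gives_three_copies(self):
        lod, model, censored = estimate_lod(detection_frame([0.5, 1, 2, 3, 4, 5, 6, 8, 10]))
        assert model == "poisson_cloglog"
        assert not censored
        assert lod == pytest.approx(poisson_theoretical_lod(), abs=0.05)

    def test_half_efficiency_doubles_lod(self):
        lod, _, _ = estimate_lod(detection_frame([1, 2, 4, 6, 8, 12, 16, 20], efficiency=0.5))
        assert lod == pytest.approx(-np.log(0.05) / 0.5, abs=0.1)

    def test_complete_detection_is_censored(self):
        det = pd.DataFrame({"copies": [1.0, 10.0, 100.0], "n_replicates": 10, "n_detected": 10})
        lod, _, censored = estimate_lod(det)
        assert censored and lod == 1.0

    def test_no_detection_errors(self):
        det = pd.DataFrame({"copies": [1.0, 10.0], "n_replicates": 10, "n_detected": 0})
        with pytest.raises(SensitivityError):
            estimate_lod(det)

    def test_lod_monotone_in_chemistry_efficiency(self):
        copies = [1, 2, 4, 6, 8, 12, 16, 24, 32]
        lods = [
            estimate_lod(detection_frame(copies, efficiency=e))[0]
            for e in (0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(lods) < 0)

    def test_simulated_recovery_at_1000_reps(self):
        cfg = SimulationConfig(
            seed=2024,
            standards=tuple((float(q), 1000) for q in (1, 2, 3, 4, 5, 6, 8, 10)),
        )
        plate = simulate_dilution_series(cfg)
        lod, _, _ = estimate_lod(summarize_detections(plate))
        assert lod == pytest.approx(poisson_theoretical_lod(), abs=0.5)


class TestLoq:
    def test_exponential_decay_crossing(self):
        q = np.array([1, 5, 10, 20, 40, 80, 160], dtype=float)
        est = LoqEstimator().fit(q, 0.9 * np.exp(-0.03 * q))
        assert est.model_ == "exponential_decay"
        assert not est.censored_
        assert est.loq_ == pytest.approx(np.log(0.9 / 0.35) / 0.03, rel=1e-4)

    def test_linear_crossing(self):
        q = np.array([1.0, 10.0, 100.0])
        est = LoqEstimator().fit(q, 0.95 - 0.4 * np.log10(q))
        assert est.model_ == "linear"
        assert est.loq_ == pytest.approx(10**1.5, rel=1e-6)

    def test_polynomial_recovery(self):
        q = 10.0 ** np.arange(0, 5)
        cv = 0.1 * (np.log10(q) - 3) ** 2 + 0.2
        est = LoqEstimator().fit(q, cv)
        assert est.model_ == "polynomial2"
        assert est.loq_ == pytest.approx(10 ** (3 - np.sqrt(1.5)), rel=1e-6)

    def test_all_below_threshold_censored_at_lowest(self):
        q = np.array([1.0, 10.0, 100.0, 1000.0])
        est = LoqEstimator().fit(q, np.full(4, 0.1))
        assert est.censored_ and est.loq_ == 1.0

    def test_never_crossing_censored_at_highest(self):
        q = np.array([1.0, 10.0, 100.0])
        est = LoqEstimator().fit(q, np.array([0.9, 0.85, 0.8]))
        assert est.censored_ and est.loq_ == 100.0
        assert est.warnings_

    def test_from_standards(self):
        rng = np.random.default_rng(5)
        q = np.repeat(10.0 ** np.arange(0, 6), 10)
        df = make_standards(-3.4149, 37.5, q, cq_jitter=rng.normal(0, 0.3, q.size))
        curve = fit_standard_curve(df)
        loq, model, censored = estimate_loq(df, curve)
        assert model in ("exponential_decay", "linear", "polynomial2")
        assert loq > 0

    def test_singleton_replicates_error(self):
        df = make_standards(-3.4, 38.0, 10.0 ** np.arange(0, 4))  # one well per level
        curve = fit_standard_curve(df)
        with pytest.raises(SensitivityError):
            estimate_loq(df, curve)


class TestAssessment:
    def test_lod_never_exceeds_reported_loq(self, dilution_plate):
        curve = fit_standard_curve(dilution_plate)
        res = assess_sensitivity(dilution_plate, curve)
        assert res.lod_copies <= res.loq_copies
        assert res.lod_model in ("poisson_cloglog", "logistic_log10")
        assert res.loq_model in ("exponential_decay", "linear", "polynomial2")

    def test_mean_lod_reporting(self):
        # mean of four per-assay LODs typical of a validated panel; the
        # decimal mean 6.895 ties exactly at two-decimal precision
        assert mean_lod([4.11, 8.44, 4.65, 10.38]) == pytest.approx(6.89, abs=0.00500001)
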