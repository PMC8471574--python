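"""Detection gating, unit conversion, transformation and aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from ednaquant import (
    VolumeConfig,
    classify_detection,
    copies_per_liter,
    fold_change,
    log_transform,
    site_detection,
    summarize_survey,
)
from ednaquant.records import PipelineConfigError


class TestGating:
    def test_zero_is_negative(self):
        assert classify_detection(0.0, 4.11, 30.0) == "negative"

    @pytest.mark.parametrize(
        "copies, expected",
        [(3.0, "negative"), (4.11, "negative"), (15.0, "detected_below_loq"),
         (30.0, "quantifiable"), (45.0, "quantifiable")],
    )
    def test_band_classification(self, copies, expected):
        assert classify_detection(copies, 4.11, 30.0) == expected

    def test_partition_is_exhaustive_and_exclusive(self):
        grid = np.linspace(0, 100, 1001)
        status = classify_detection(grid, 4.11, 30.0)
        assert set(status) == {"negative", "detected_below_loq", "quantifiable"}
        # monotone non-decreasing status rank along increasing copies
        rank = {"negative": 0, "detected_below_loq": 1, "quantifiable": 2}
        ranks = np.array([rank[s] for s in status])
        assert np.all(np.diff(ranks) >= 0)

    def test_lod_above_loq_rejected(self):
        with pytest.raises(PipelineConfigError):
            classify_detection(10.0, 50.0, 30.0)


class TestSiteDetection:
    @pytest.mark.parametrize(
        "statuses, expected",
        [
            (["negative", "negative", "quantifiable"], True),
            (["negative", "negative", "negative"], False),
            (["detected_below_loq", "negative", "negative"], True),
        ],
    )
    def test_one_replicate_rule(self, statuses, expected):
        assert site_detection(statuses) is expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            site_detection([])


class TestUnits:
    def test_zero(self):
        assert copies_per_liter(0.0) == 0.0

    def test_default_factor_is_50(self):
        assert copies_per_liter(100.0) == pytest.approx(5000.0)

    def test_filtration_volume_inverse(self):
        v2 = VolumeConfig(filtration_volume=1.0)
        assert copies_per_liter(100.0, v2) == pytest.approx(2500.0)

    def test_linearity(self):
        a, b = 123.4, 567.8
        assert copies_per_liter(a + b) == pytest.approx(
            copies_per_liter(a) + copies_per_liter(b)
        )

    def test_invalid_volumes_rejected(self):
        with pytest.raises(PipelineConfigError):
            VolumeConfig(template_volume=-1)
        with pytest.raises(PipelineConfigError):
            VolumeConfig(template_volume=60.0)  # exceeds elution


class TestTransform:
    @pytest.mark.parametrize(
        "x, expected", [(0.0, 0.0), (99.0, 2.0), (1.09e6, 6.0374)]
    )
    def test_log10_plus_one(self, x, expected):
        assert log_transform(x) == pytest.approx(expected, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(-1.0)


class TestFoldChange:
    def test_equal_means(self):
        assert fold_change(5.0, 5.0) == 1.0

    def test_seasonal_ratio_from_printed_means(self):
        assert fold_change(1.09e6, 1.71e4) == pytest.approx(63.74, abs=0.01)

    def test_species_ratio_from_printed_means(self):
        assert fold_change(1.71e4, 1.96e3) == pytest.approx(8.72, abs=0.01)

    def test_zero_denominator_censored(self):
        assert math.isnan(fold_change(1.0, 0.0))


def quantified_frame(rows):
    return pd.DataFrame(
        rows, columns=["assay", "site", "season", "status", "copies_per_liter"]
    )


class TestSummaries:
    def one_site(self):
        return quantified_frame(
            [
                ("A", "s1", "spawning", "negative", 0.0),
                ("A", "s1", "spawning", "quantifiable", 6000.0),
                ("A", "s1", "spawning", "quantifiable", 8000.0),
            ]
        )

    def test_zero_fill_mean(self):
        out = summarize_survey(self.one_site(), ("assay", "site", "season"))
        row = out.iloc[0]
        assert row["detected"]
        assert row["mean_copies_per_liter"] == pytest.approx(14000 / 3, rel=1e-9)
        assert row["n_quantifiable"] == 2

    def test_omit_mean(self):
        out = summarize_survey(
            self.one_site(), ("assay", "site", "season"), negative_fill="omit"
        )
        assert out.iloc[0]["mean_copies_per_liter"] == pytest.approx(7000.0)

    def test_below_loq_counts_as_detection_not_in_mean(self):
        df = quantified_frame(
            [
                ("A", "s1", "spawning", "detected_below_loq", 100.0),
                ("A", "s1", "spawning", "negative", 0.0),
            ]
        )
        row = summarize_survey(df, ("assay", "site", "season")).iloc[0]
        assert row["detected"]
        assert row["mean_copies_per_liter"] == 0.0  # only the negative fills in

    def test_all_negative(self):
        df = quantified_frame(
            [("A", "s1", "spawning", "negative", 0.0)] * 3
        )
        row = summarize_survey(df, ("assay", "site", "season")).iloc[0]
        assert not row["detected"]
        assert row["mean_copies_per_liter"] == 0.0

    def test_unknown_group_key(self):
        with pytest.raises(KeyError):
            summarize_survey(self.one_site(), ("assay", "nonexistent"))
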