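"""Abundance tables, exposure encoding and Pearson correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from coleach import (
    AbundanceTable,
    ExposureVector,
    correlate_genera,
    encode_exposure,
    pearson_r,
    reference_schedule,
    run_schedule,
)


def textbook_pearson(x, y):
    """Independent product-moment oracle: the raw-sums formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = math.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * math.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    return num / den


def make_table(rows):
    return AbundanceTable(pd.DataFrame(rows))


BASE_ROWS = [
    {"sample_id": "a", "day": 11, "reactor": "experimental", "pcb_gL": 5.0,
     "Ferroplasma": 10.0, "Leptospirillum": 40.0},
    {"sample_id": "b", "day": 22, "reactor": "experimental", "pcb_gL": 11.9,
     "Ferroplasma": 8.0, "Leptospirillum": 55.0},
    {"sample_id": "c", "day": 34, "reactor": "experimental", "pcb_gL": 35.5,
     "Ferroplasma": 1.0, "Leptospirillum": 70.0},
]


class TestPearson:
    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_zero_covariance(self):
        assert pearson_r([0, 1, 2], [0, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        """Dual-route check against the raw-sums product-moment formula."""
        x, y = [5.0, 12.5, 37.5], [10.0, 8.0, 1.0]
        assert pearson_r(x, y) == pytest.approx(textbook_pearson(x, y), abs=1e-12)
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.uniform(0, 40, 8)
            y = rng.uniform(0, 100, 8)
            assert pearson_r(x, y) == pytest.approx(textbook_pearson(x, y), abs=1e-12)

    def test_invariances(self):
        x, y = [1.0, 4.0, 2.0, 8.0], [3.0, 1.0, 5.0, 2.0]
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r)
        assert pearson_r(10 * np.asarray(x) + 3, y) == pytest.approx(r)
        assert -1 <= r <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [2, 3, 4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pearson_r([1, 2, 3], [1, 2])


class TestCorrelateGenera:
    def test_perfect_linear_responder(self):
        rows = [dict(r) for r in BASE_ROWS]
        for row in rows:
            row["GenusA"] = 40.0 - row["pcb_gL"]
        table = make_table(rows)
        exposure = ExposureVector(table.data["pcb_gL"].to_numpy(), "concentration")
        corr = correlate_genera(table, exposure)
        assert corr.loc["GenusA", "r"] == pytest.approx(-1.0)

    def test_all_zero_genus_flagged_undefined(self):
        rows = [dict(r, Absent=0.0) for r in BASE_ROWS]
        table = make_table(rows)
        exposure = ExposureVector(table.data["pcb_gL"].to_numpy(), "concentration")
        corr = correlate_genera(table, exposure)
        assert not corr.loc["Absent", "defined"]
        assert math.isnan(corr.loc["Absent", "r"])

    def test_agrees_with_columnwise_pearson(self):
        table = make_table(BASE_ROWS)
        exposure = ExposureVector(table.data["pcb_gL"].to_numpy(), "concentration")
        corr = correlate_genera(table, exposure)
        for genus in table.genera:
            assert corr.loc[genus, "r"] == pytest.approx(
                pearson_r(exposure.values, table.abundance(genus))
            )


class TestEncodeExposure:
    @pytest.fixture
    def dilution(self):
        return run_schedule(5.0, reference_schedule())

    def test_control_samples_all_zero(self, dilution):
        rows = [dict(r, reactor="control") for r in BASE_ROWS]
        exposure = encode_exposure(make_table(rows), dilution)
        np.testing.assert_array_equal(exposure.values, 0.0)

    def test_lookup_matches_dilution_table(self, dilution):
        exposure = encode_exposure(make_table(BASE_ROWS), dilution)
        np.testing.assert_allclose(exposure.values, [5.0, 11.9, 35.5], atol=0.06)

    def test_presence_mode(self, dilution):
        exposure = encode_exposure(make_table(BASE_ROWS), dilution, mode="presence")
        np.testing.assert_array_equal(exposure.values, 1.0)

    def test_uncovered_day_rejected(self, dilution):
        rows = [dict(BASE_ROWS[0], day=-2)] + BASE_ROWS[1:]
        with pytest.raises(KeyError):
            encode_exposure(make_table(rows), dilution)


class TestTableValidation:
    def test_abundance_above_100_rejected(self):
        rows = [dict(BASE_ROWS[0], Ferroplasma=130.0)] + BASE_ROWS[1:]
        with pytest.raises(ValueError, match="out of"):
            make_table(rows)

    def test_oversumming_sample_rejected(self):
        rows = [dict(BASE_ROWS[0], Leptospirillum=95.0)] + BASE_ROWS[1:]
        with pytest.raises(ValueError, match="sum"):
            make_table(rows)

    def test_partial_table_without_other_accepted(self):
        table = make_table(BASE_ROWS)  # sums ~50-71%
        assert table.n_samples == 3

    def test_other_column_must_complete_to_100(self):
        rows = [dict(r, Other=10.0) for r in BASE_ROWS]
        with pytest.raises(ValueError, match="Other"):
            make_table(rows)
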