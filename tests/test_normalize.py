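import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import quantile_oracle
from kinomescreen import (
    compute_mi,
    filter_inconsistent,
    filter_low_dapi,
    normalize_channel,
    preprocess_screen,
    robust_zscore,
    summarize_gene,
)
from kinomescreen.exceptions import DegenerateScreenError, ValidationError


def _records(intensities=None, dapi=None, ph3=None):
    n = len(intensities) if intensities is not None else len(dapi)
    return pd.DataFrame(
        {
            "plate_id": ["P1"] * n,
            "well_id": [f"W{i}" for i in range(n)],
            "image_index": [1] * n,
            "dapi_count": dapi if dapi is not None else [100] * n,
            "dapi_intensity": intensities if intensities is not None else [1000.0] * n,
            "ph3_count": ph3 if ph3 is not None else [5] * n,
        }
    )


class TestLowDapiFilter:
    def test_first_percentile_of_1_to_100_removes_lowest(self):
        kept, removed, cutoff = filter_low_dapi(_records(list(range(1, 101))), 0.01)
        assert list(removed["dapi_intensity"]) == [1.0]
        assert cutoff == pytest.approx(quantile_oracle(range(1, 101), 0.01))

    def test_all_tied_intensities_remove_nothing(self):
        kept, removed, _ = filter_low_dapi(_records([7.0] * 50), 0.01)
        assert len(removed) == 0 and len(kept) == 50

    def test_two_records_at_median_percentile(self):
        kept, removed, _ = filter_low_dapi(_records([5.0, 500.0]), 0.5)
        assert list(removed["dapi_intensity"]) == [5.0]

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            filter_low_dapi(_records([]).iloc[0:0], 0.01)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(1.0, 1e6), min_size=2, max_size=200),
        st.floats(0.005, 0.2),
    )
    def test_conservation_and_oracle_cutoff(self, intensities, percentile):
        recs = _records(intensities)
        kept, removed, cutoff = filter_low_dapi(recs, percentile)
        assert len(kept) + len(removed) == len(recs)
        if len(removed):
            assert cutoff == pytest.approx(quantile_oracle(intensities, percentile))
            assert removed["dapi_intensity"].max() <= cutoff
            assert kept["dapi_intensity"].min() > cutoff
            # refiltering the kept records at the same cutoff removes nothing
            assert (kept["dapi_intensity"] > cutoff).all()


class TestInconsistentFilter:
    @pytest.mark.parametrize(
        "dapi,ph3,kept_expected",
        [(100, 5, True), (100, 101, False), (100, 100, True)],
    )
    def test_strict_inequality_rule(self, dapi, ph3, kept_expected):
        kept, removed = filter_inconsistent(_records(dapi=[dapi], ph3=[ph3]))
        assert (len(kept) == 1) is kept_expected
        assert len(kept) + len(removed) == 1

    def test_idempotent(self, joined_records):
        kept, _ = filter_inconsistent(joined_records)
        again, removed = filter_inconsistent(kept)
        assert len(removed) == 0 and len(again) == len(kept)


class TestNormalizeChannel:
    def test_single_plate_is_identity(self, rng):
        values = rng.uniform(10, 100, 30)
        out = normalize_channel(values, np.array(["P1"] * 30))
        np.testing.assert_allclose(out, values)

    def test_worked_example(self):
        # out = raw / plate median * overall median, checked on plate A's 50
        values = np.array([50.0, 100.0, 150.0, 200.0, 200.0, 260.0])
        plates = np.array(["A", "A", "A", "B", "B", "B"])
        out = normalize_channel(values, plates)
        overall = np.median(values)
        assert out[0] == pytest.approx(50.0 / 100.0 * overall)

    def test_plate_medians_equalized(self):
        values = np.array([8.0, 10.0, 12.0, 16.0, 20.0, 24.0])
        plates = np.array(["A", "A", "A", "B", "B", "B"])
        out = normalize_channel(values, plates)
        overall = np.median(values)
        for p in ("A", "B"):
            assert np.median(out[plates == p]) == pytest.approx(overall, rel=1e-12)

    def test_zero_median_plate_flagged_not_crashed(self):
        values = np.array([0.0, 0.0, 10.0, 20.0])
        plates = np.array(["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="plate 'A'"):
            out = normalize_channel(values, plates)
        assert np.isnan(out[:2]).all() and np.isfinite(out[2:]).all()

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.integers(2, 8),
        st.integers(3, 20),
        st.integers(0, 10_000),
    )
    def test_invariant_every_plate_median_equals_overall(self, n_plates, per_plate, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(5, 0.5, n_plates * per_plate)
        plates = np.repeat([f"P{i}" for i in range(n_plates)], per_plate)
        out = normalize_channel(values, plates)
        overall = np.median(values)
        for p in np.unique(plates):
            assert abs(np.median(out[plates == p]) - overall) <= 1e-9 * abs(overall)


class TestMitoticIndex:
    def test_direct_ratio(self):
        assert compute_mi(240, 12) == pytest.approx(0.05)

    def test_zero_numerator_uses_pseudocount(self):
        assert compute_mi(200, 0, pseudocount=0.5) == pytest.approx(0.0025)

    def test_zero_dapi_flagged_undefined(self):
        assert np.isnan(compute_mi(0, 5))

    def test_vectorized_matches_scalar(self):
        out = compute_mi(np.array([240, 200, 0]), np.array([12, 0, 5]))
        assert out[0] == pytest.approx(0.05)
        assert out[1] == pytest.approx(0.0025)
        assert np.isnan(out[2])


class TestSummarize:
    @pytest.mark.parametrize(
        "values,expected,n",
        [([0.04, 0.05, 0.06], 0.05, 3), ([0.02], 0.02, 1), ([np.nan, 0.03], 0.03, 1)],
    )
    def test_median_summary(self, values, expected, n):
        mi, n_used = summarize_gene(values)
        assert mi == pytest.approx(expected) and n_used == n

    def test_no_surviving_values_reports_na(self):
        mi, n_used = summarize_gene([np.nan, np.nan])
        assert np.isnan(mi) and n_used == 0

    def test_mean_option(self):
        assert summarize_gene([0.0, 0.1], "mean")[0] == pytest.approx(0.05)


class TestRobustZscore:
    def test_all_equal_is_degenerate(self):
        with pytest.raises(DegenerateScreenError):
            robust_zscore([3.0, 3.0, 3.0, 3.0])

    def test_mostly_tied_values_are_degenerate_too(self):
        # median 0 and median absolute deviation 0: thresholds undefined
        with pytest.raises(DegenerateScreenError):
            robust_zscore([0.0, 0.0, 0.0, 1.4826])

    def test_antisymmetry(self):
        z = robust_zscore([-2.0, 0.0, 2.0])
        assert z[1] == 0.0
        assert z[0] == pytest.approx(-z[2])

    def test_matches_direct_formula(self, rng):
        x = rng.normal(0, 1, 101)
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        np.testing.assert_allclose(robust_zscore(x), (x - med) / mad)

    def test_too_few_finite_values(self):
        with pytest.raises(ValidationError):
            robust_zscore([1.0, 2.0, np.nan])


class TestPreprocessScreen:
    def test_gene_table_covers_all_genes(self, joined_records, tiny_config):
        screen = preprocess_screen(joined_records)
        assert len(screen.genes) == tiny_config.n_genes
        assert screen.genes["mi"].gt(0).all()

    def test_filter_conservation_reported(self, joined_records):
        screen = preprocess_screen(joined_records)
        rep = screen.report
        assert rep.n_input == len(joined_records)
        assert (
            len(screen.records)
            == rep.n_input - rep.n_low_dapi_removed - rep.n_inconsistent_removed
        )

    def test_filtered_records_never_contribute(self, joined_records):
        """An absurd inconsistent record must be removed before MI, leaving
        the gene summary untouched."""
        base = preprocess_screen(joined_records)
        gene = base.genes.iloc[0]["gene_symbol"]
        well = joined_records.loc[joined_records["gene_symbol"] == gene].iloc[0]
        poisoned = pd.concat(
            [
                joined_records,
                pd.DataFrame([{**well.to_dict(), "image_index": 99, "ph3_count": 10_000}]),
            ],
            ignore_index=True,
        )
        screen = preprocess_screen(poisoned)
        assert screen.report.n_inconsistent_removed >= 1
        assert screen.genes.set_index("gene_symbol").loc[gene, "mi"] == pytest.approx(
            base.genes.set_index("gene_symbol").loc[gene, "mi"]
        )

    def test_zscores_centered_on_screen(self, joined_records):
        screen = preprocess_screen(joined_records)
        assert np.median(screen.genes["zscore"].dropna()) == pytest.approx(0.0, abs=1e-12)
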