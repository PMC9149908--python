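import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lopitmap.overlay import (
    bin_values,
    compare_tallies,
    map_to_reference,
    mapped_fraction,
    tally_compartments,
)
from lopitmap.reference_map import COMPARTMENTS, load_reference_map


def quantile_log10_bins_oracle(values, n_bins):
    """Hand-rolled sort-based quantile binning (lower order statistics)."""
    logs = sorted(math.log10(v) for v in values)
    n = len(logs)
    edges = [logs[math.floor((k / n_bins) * (n - 1))] for k in range(1, n_bins)]
    return [1 + sum(1 for e in edges if e < math.log10(v)) for v in values]


class TestBinValues:
    def test_one_to_hundred_endpoints(self):
        values = np.arange(1, 101, dtype=float)
        bins = bin_values(values, n_bins=5, scheme="quantile-log10")
        assert bins[0] == 1
        assert bins[-1] == 5
        assert list(bins) == quantile_log10_bins_oracle(values, 5)

    def test_all_equal_collapse_to_bin_one(self):
        bins = bin_values([7.0] * 10, n_bins=5)
        assert set(bins) == {1}

    def test_empty_input_gives_empty_output(self):
        assert bin_values([], n_bins=3).size == 0

    def test_invalid_n_bins(self):
        with pytest.raises(ValueError):
            bin_values([1.0], n_bins=0)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            bin_values([1.0, 0.0])

    @pytest.mark.parametrize("scheme", ["quantile-log10", "equal-width-log10"])
    def test_monotone_on_random_values(self, scheme):
        rng = np.random.default_rng(11)
        values = 10.0 ** rng.normal(6, 1, size=1000)
        bins = bin_values(values, n_bins=5, scheme=scheme)
        order = np.argsort(values)
        assert np.all(np.diff(bins[order]) >= 0)
        assert bins.min() >= 1 and bins.max() <= 5

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e12,
                           allow_nan=False, allow_infinity=False),
                 min_size=1, max_size=200),
        st.integers(min_value=1, max_value=8),
    )
    def test_bins_bounded_and_monotone(self, values, n_bins):
        bins = bin_values(values, n_bins=n_bins)
        assert bins.min() >= 1 and bins.max() <= n_bins
        arr = np.asarray(values)
        order = np.argsort(arr, kind="stable")
        sorted_bins = bins[order]
        assert np.all(np.diff(sorted_bins) >= 0)


class TestMapToReference:
    def test_partition_and_percent(self, small_map_file, small_quant_file):
        from lopitmap.quant_io import load_quant_table

        refmap = load_reference_map(small_map_file)
        quant = load_quant_table(small_quant_file)
        result, stats = map_to_reference(quant, refmap, value_fraction="W-1")
        # 4 detected in W-1, 3 of them (A1, A2, A3) have map entries
        assert result.n_mapped == 3
        assert result.unmapped == ["B9"]
        assert stats.table.loc["W-1", "percent_mapped"] == pytest.approx(75.0)
        # partition invariant
        assert result.n_input == 4

    def test_detection_is_per_fraction(self, small_map_file, small_quant_file):
        from lopitmap.quant_io import load_quant_table

        refmap = load_reference_map(small_map_file)
        quant = load_quant_table(small_quant_file)
        _, stats = map_to_reference(quant, refmap)
        # A2 has a blank Elute cell: 3 detected there, 2 mapped
        assert stats.table.loc["Elute", "total_ids"] == 3
        assert stats.table.loc["Elute", "mapped"] == 2

    def test_full_coverage_gives_100_percent(self, small_map_file):
        refmap = load_reference_map(small_map_file)
        result, stats = map_to_reference({"A1", "A2", "A3"}, refmap)
        assert stats.table.loc["set", "percent_mapped"] == pytest.approx(100.0)
        assert result.unmapped == []

    def test_empty_detected_set_warns_and_reports_zero(self, small_map_file):
        refmap = load_reference_map(small_map_file)
        with pytest.warns(UserWarning, match="no detected"):
            _, stats = map_to_reference(set(), refmap)
        assert stats.table.loc["set", "percent_mapped"] == 0.0

    def test_percent_recomputes_from_counts(self, refmap, bioid_data):
        quant, _ = bioid_data
        _, stats = map_to_reference(quant, refmap)
        for _, row in stats.table.iterrows():
            assert row["percent_mapped"] == pytest.approx(
                100.0 * row["mapped"] / row["total_ids"], abs=0.1
            )


class TestTally:
    def test_hand_counted_fixture(self, tmp_path):
        path = tmp_path / "m.tsv"
        rows = [f"C{i}\t0\t{i}\tcytosol" for i in range(3)]
        rows += [f"N{i}\t1\t{i}\tnucleus" for i in range(2)]
        path.write_text("accession\tx\ty\tcompartment\n" + "\n".join(rows) + "\n")
        refmap = load_reference_map(path)
        overlay, _ = map_to_reference(set(refmap.accessions), refmap)
        tally = tally_compartments(overlay)
        assert tally["cytosol"] == 3
        assert tally["nucleus"] == 2
        assert tally.drop(["cytosol", "nucleus"]).sum() == 0
        assert list(tally.index) == list(COMPARTMENTS)

    def test_empty_overlay_all_zero(self, small_map_file):
        refmap = load_reference_map(small_map_file)
        overlay, _ = map_to_reference({"ZZZ"}, refmap)
        assert tally_compartments(overlay).sum() == 0

    def test_tally_conserves_mapped_count(self, refmap, synth_cfg):
        rng = np.random.default_rng(3)
        for _ in range(5):
            picked = rng.choice(refmap.accessions, size=200, replace=False)
            extra = [f"NOPE{i}" for i in range(rng.integers(0, 50))]
            overlay, _ = map_to_reference(set(picked) | set(extra), refmap)
            tally = tally_compartments(overlay)
            assert tally.sum() == overlay.n_mapped
            assert overlay.n_input == len(set(picked)) + len(extra)


class TestMappedFraction:
    def test_integer_display_convention(self):
        assert round(mapped_fraction(1243, 908)) == 73
        assert round(mapped_fraction(6491, 2553)) == 39
        assert round(mapped_fraction(561, 272)) == 48

    def test_zero_mapped(self):
        assert mapped_fraction(10, 0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mapped_fraction(0, 0)
        with pytest.raises(ValueError):
            mapped_fraction(5, 6)


class TestCompareTallies:
    def _tally(self, **counts):
        t = pd.Series(0, index=pd.Index(COMPARTMENTS, name="compartment"))
        for k, v in counts.items():
            t[k.replace("_", " ")] = v
        return t

    def test_signed_difference(self):
        a = self._tally(**{"plasma membrane": 30})
        b = self._tally(**{"plasma membrane": 57})
        diff, summary = compare_tallies(a, b)
        assert diff["plasma membrane"] == -27
        assert "27 fewer proteins in plasma membrane" in summary

    def test_identical_tallies(self):
        a = self._tally(cytosol=5)
        diff, summary = compare_tallies(a, a.copy())
        assert (diff == 0).all()
        assert "no per-compartment differences" in summary

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = pd.Series(rng.integers(0, 100, len(COMPARTMENTS)), index=list(COMPARTMENTS))
        b = pd.Series(rng.integers(0, 100, len(COMPARTMENTS)), index=list(COMPARTMENTS))
        assert (compare_tallies(a, b)[0] == -compare_tallies(b, a)[0]).all()
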