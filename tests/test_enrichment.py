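import numpy as np
import pandas as pd
import pytest

from lopitmap.enrichment import (
    CARBOXYLASE_CONTROLS,
    apply_cutoff,
    carboxylase_benchmark,
    compute_fold_change,
    suggest_cutoff,
)
from lopitmap.quant_io import QuantTable


def make_quant(rows, fractions=("W-2", "Elute")):
    frame = pd.DataFrame(
        {f: [r[i] for r in rows.values()] for i, f in enumerate(fractions)},
        index=pd.Index(rows.keys(), name="accession"),
        dtype=float,
    )
    return QuantTable(frame)


def brute_force_pass(fc_table, cutoff, include_numerator_only):
    passing = []
    for acc, row in fc_table.iterrows():
        if row["status"] == "both" and row["ratio"] >= cutoff:
            passing.append(acc)
        elif row["status"] == "numerator_only" and include_numerator_only:
            passing.append(acc)
    return set(passing)


class TestComputeFoldChange:
    def test_simple_ratio(self):
        quant = make_quant({"A1": (2.0, 6.0)})
        fc = compute_fold_change(quant, "Elute", "W-2")
        assert fc.table.loc["A1", "ratio"] == pytest.approx(3.0)
        assert fc.table.loc["A1", "status"] == "both"

    def test_presence_statuses(self):
        quant = make_quant(
            {"A1": (2.0, 6.0), "A2": (np.nan, 5.0), "A3": (4.0, np.nan),
             "A4": (np.nan, np.nan)}
        )
        fc = compute_fold_change(quant, "Elute", "W-2")
        assert fc.table.loc["A2", "status"] == "numerator_only"
        assert np.isnan(fc.table.loc["A2", "ratio"])
        assert fc.table.loc["A3", "status"] == "denominator_only"
        assert fc.table.loc["A4", "status"] == "neither"

    def test_identity_ratio_for_same_fraction(self):
        quant = make_quant({"A1": (2.0, 6.0), "A2": (5.0, np.nan)})
        fc = compute_fold_change(quant, "W-2", "W-2")
        both = fc.of_status("both")
        assert (both["ratio"] == 1.0).all()

    def test_unknown_fraction_is_an_error(self):
        quant = make_quant({"A1": (2.0, 6.0)})
        with pytest.raises(KeyError):
            compute_fold_change(quant, "Elute", "W-9")

    def test_swapping_fractions_inverts_ratios_and_statuses(self, bioid_data):
        quant, _ = bioid_data
        fwd = compute_fold_change(quant, "PCFT Elute", "PCFT W-2").table
        rev = compute_fold_change(quant, "PCFT W-2", "PCFT Elute").table
        both = fwd["status"] == "both"
        np.testing.assert_allclose(
            fwd.loc[both, "ratio"], 1.0 / rev.loc[both, "ratio"]
        )
        assert (
            rev.loc[fwd["status"] == "numerator_only", "status"]
            == "denominator_only"
        ).all()

    def test_abundance_floor_turns_singletons_into_ratios(self):
        quant = make_quant({"A2": (np.nan, 5.0)})
        fc = compute_fold_change(quant, "Elute", "W-2", abundance_floor=1.0)
        assert fc.table.loc["A2", "status"] == "both"
        assert fc.table.loc["A2", "ratio"] == pytest.approx(5.0)


class TestCarboxylaseBenchmark:
    def test_per_protein_ratios_and_range(self):
        elute = [4.2, 20.0, 60.0, 137.6]
        w2 = [2.0, 2.0, 2.0, 2.0]
        rows = {acc: (w, e) for acc, w, e in zip(CARBOXYLASE_CONTROLS, w2, elute)}
        bench = carboxylase_benchmark(make_quant(rows), "Elute", "W-2")
        assert bench.per_protein_ratio["P11498"] == pytest.approx(2.1)
        assert bench.min_ratio == pytest.approx(2.1)
        assert bench.max_ratio == pytest.approx(68.8)
        assert bench.total_ratio == pytest.approx(sum(elute) / sum(w2))

    def test_missing_control_excluded(self, caplog):
        rows = {
            "P11498": (2.0, 4.2),
            "P05165": (np.nan, 20.0),
            "Q96RQ3": (2.0, 60.0),
            "Q13085": (2.0, 137.6),
        }
        bench = carboxylase_benchmark(make_quant(rows), "Elute", "W-2")
        assert "P05165" in bench.missing
        assert "P05165" not in bench.per_protein_ratio
        assert bench.min_ratio == pytest.approx(2.1)

    def test_all_equal_abundances_give_unit_ratios(self):
        rows = {acc: (5.0, 5.0) for acc in CARBOXYLASE_CONTROLS}
        bench = carboxylase_benchmark(make_quant(rows), "Elute", "W-2")
        assert bench.min_ratio == bench.max_ratio == bench.total_ratio == 1.0

    def test_no_control_in_both_fractions_is_an_error(self):
        rows = {acc: (np.nan, 5.0) for acc in CARBOXYLASE_CONTROLS}
        with pytest.raises(ValueError, match="benchmark undefined"):
            carboxylase_benchmark(make_quant(rows), "Elute", "W-2")


class TestApplyCutoff:
    def test_inclusive_boundary(self):
        quant = make_quant(
            {f"A{i}": (1.0, r) for i, r in enumerate([1.0, 2.0, 3.0, 4.0])}
        )
        fc = compute_fold_change(quant, "Elute", "W-2")
        passing, n = apply_cutoff(fc, 3.0)
        assert n == 2  # 3.0 passes: "at least" threefold
        assert set(passing.index) == {"A2", "A3"}

    def test_cutoff_zero_passes_all_both_status(self):
        quant = make_quant({"A1": (1.0, 0.5), "A2": (np.nan, 5.0)})
        fc = compute_fold_change(quant, "Elute", "W-2")
        _, n = apply_cutoff(fc, 0.0, include_numerator_only=False)
        assert n == 1

    def test_empty_input(self):
        quant = make_quant({"A1": (np.nan, np.nan)})
        fc = compute_fold_change(quant, "Elute", "W-2")
        _, n = apply_cutoff(fc, 3.0, include_numerator_only=False)
        assert n == 0

    def test_numerator_only_flagged_and_included_by_default(self):
        quant = make_quant({"A1": (np.nan, 5.0)})
        fc = compute_fold_change(quant, "Elute", "W-2")
        passing, n = apply_cutoff(fc, 3.0)
        assert n == 1
        assert passing.loc["A1", "status"] == "numerator_only"

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(1, 500))
            w2 = np.where(rng.random(n) < 0.8, 10.0 ** rng.normal(6, 1, n), np.nan)
            el = np.where(rng.random(n) < 0.8, 10.0 ** rng.normal(6, 1, n), np.nan)
            frame = pd.DataFrame({"W-2": w2, "Elute": el},
                                 index=[f"P{i}" for i in range(n)])
            frame = frame[frame.notna().any(axis=1)]
            if frame.empty:
                continue
            quant = QuantTable(frame)
            fc = compute_fold_change(quant, "Elute", "W-2")
            cutoff = float(rng.uniform(0, 10))
            include = bool(rng.integers(0, 2))
            passing, count = apply_cutoff(fc, cutoff, include_numerator_only=include)
            expected = brute_force_pass(fc.table, cutoff, include)
            assert set(passing.index) == expected
            assert count == len(expected)

    def test_monotone_in_cutoff(self, bioid_data):
        quant, _ = bioid_data
        fc = compute_fold_change(quant, "PCFT Elute", "PCFT W-2")
        counts = [apply_cutoff(fc, c)[1] for c in (0, 1, 2, 3, 5, 10, 100)]
        assert counts == sorted(counts, reverse=True)


class TestSuggestCutoff:
    def _bench(self, ratios):
        rows = {acc: (2.0, 2.0 * r) for acc, r in zip(CARBOXYLASE_CONTROLS, ratios)}
        return carboxylase_benchmark(make_quant(rows), "Elute", "W-2")

    def test_policies(self):
        bench = self._bench([2.1, 10.0, 30.0, 68.8])
        assert suggest_cutoff(bench, "min_control") == pytest.approx(2.1)
        assert suggest_cutoff(bench, "total") == pytest.approx(bench.total_ratio)
        assert suggest_cutoff(bench, "fixed", fixed_value=3) == 3.0

    def test_single_control_minimum(self):
        rows = {"P11498": (2.0, 13.4)}
        bench = carboxylase_benchmark(make_quant(rows), "Elute", "W-2",
                                      control_accessions=["P11498"])
        assert suggest_cutoff(bench, "min_control") == pytest.approx(6.7)

    def test_unknown_policy(self):
        bench = self._bench([1, 1, 1, 1])
        with pytest.raises(ValueError):
            suggest_cutoff(bench, "median")
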