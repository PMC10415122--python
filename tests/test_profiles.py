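"""Weighted profile statistics, washout arithmetic and dose bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from asokd import (correlogram, diff_from_overall, dose_molecule_count,
                   washout_recovery, weighted_pearson, weighted_sd)

finite_floats = st.floats(-100, 100, allow_nan=False)


class TestWeightedPearson:
    def test_equal_weights_reduce_to_plain_pearson(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho, p = weighted_pearson(x, y, np.full(12, 3.0))
        ref = stats.pearsonr(x, y)
        np.testing.assert_allclose(rho, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-9)

    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        rho, p = weighted_pearson(x, 2 * x + 1, [0.5, 4.0, 1.0, 2.0])
        assert rho == 1.0 and p == 0.0

    def test_matches_weighted_moment_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        w = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        rho, _ = weighted_pearson(x, y, w)
        wn = w / w.sum()
        mx, my = wn @ x, wn @ y
        cov = wn @ ((x - mx) * (y - my))
        expected = cov / np.sqrt((wn @ (x - mx) ** 2) * (wn @ (y - my) ** 2))
        np.testing.assert_allclose(rho, expected, rtol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(0.1, 10), b=finite_floats, c=st.floats(0.1, 10),
           d=finite_floats)
    def test_affine_invariance_and_bounds(self, a, b, c, d):
        x = np.array([1.0, 3.0, 2.0, 7.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0, 3.0])
        w = np.array([1.0, 2.0, 3.0, 1.0, 0.5])
        rho, _ = weighted_pearson(x, y, w)
        rho2, _ = weighted_pearson(a * x + b, c * y + d, w)
        assert abs(rho) <= 1.0
        np.testing.assert_allclose(rho, rho2, atol=1e-9)

    def test_integer_weights_match_expanded_sample(self):
        x = np.array([1.0, 5.0, 3.0])
        y = np.array([2.0, 4.0, 9.0])
        w = np.array([2, 3, 1])
        rho, _ = weighted_pearson(x, y, w)
        xe = np.repeat(x, w)
        ye = np.repeat(y, w)
        np.testing.assert_allclose(rho, stats.pearsonr(xe, ye).statistic, rtol=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError):
            weighted_pearson([1.0, 2.0], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            weighted_pearson([1, 2, 3], [1, 2, 3], [0, 0, 0])


class TestWeightedSd:
    def test_equal_weights_reduce_to_sample_sd(self, rng):
        x = rng.normal(size=9)
        np.testing.assert_allclose(weighted_sd(x, np.full(9, 2.0)),
                                   np.std(x, ddof=1), rtol=1e-12)

    def test_constant_vector_gives_zero(self):
        assert weighted_sd([4.0, 4.0, 4.0], [1, 5, 2]) == 0.0

    @pytest.mark.parametrize("w", [[1, 2, 3], [2, 2, 4], [5, 1, 1]])
    def test_integer_frequency_weights_match_expanded_sample(self, w):
        x = np.array([1.0, 6.0, 3.5])
        expanded = np.repeat(x, w)
        np.testing.assert_allclose(weighted_sd(x, w, frequency=True),
                                   np.std(expanded, ddof=1), rtol=1e-12)

    def test_unit_weights_identical_under_both_conventions(self):
        x = np.array([2.0, 7.0, 4.0, 4.5])
        w = np.ones(4)
        assert weighted_sd(x, w) == weighted_sd(x, w, frequency=True)


class TestDiffFromOverall:
    def test_simple_subtraction(self):
        d = diff_from_overall(pd.Series({"astro": 40.0}), 45.0)
        assert d["astro"] == -5.0

    def test_single_cell_type_is_zero(self):
        d = diff_from_overall(pd.Series({"only": 52.0}), 52.0)
        assert d["only"] == 0.0

    def test_cell_weighted_mean_difference_near_zero(self):
        """With a pooled (all-cells) overall residual and cell types of equal
        basal expression, the cell-count-weighted mean of the per-type
        differences is approximately zero (the pooled overall weights each
        cell type by its share of target expression, which then coincides
        with its cell-count share)."""
        from asokd import (CellTypeSpec, KnockdownModel, SimConfig,
                           aggregate_counts, simulate_experiment)

        cfg = SimConfig(
            cell_types=[CellTypeSpec("exc", 0.5, 300.0),
                        CellTypeSpec("inh", 0.3, 300.0),
                        CellTypeSpec("glia", 0.2, 300.0)],
            residual={"exc": 0.3, "inh": 0.5, "glia": 0.7},
            n_animals_per_arm=3, n_cells_per_animal=1500, seed=8,
        )
        counts, meta = simulate_experiment(cfg)
        agg = aggregate_counts(counts, meta)
        res = KnockdownModel(agg).fit()
        est = res.estimates.set_index("cell_type")
        allagg = (agg.assign(cell_type="all")
                  .groupby(["animal", "cell_type", "arm"], as_index=False)
                  .agg(target_umi=("target_umi", "sum"),
                       total_umi=("total_umi", "sum"), n_cells=("n_cells", "sum")))
        overall = KnockdownModel(allagg).fit().estimates["residual_mean"].iloc[0]
        # pooled-rate overall agrees with the all-cells GLM estimate
        trt = allagg[allagg["arm"] == "treated"]
        veh = allagg[allagg["arm"] == "vehicle"]
        pooled = ((trt["target_umi"].sum() / trt["total_umi"].sum())
                  / (veh["target_umi"].sum() / veh["total_umi"].sum()))
        np.testing.assert_allclose(overall, pooled, atol=5e-4)
        diffs = diff_from_overall(est["residual_mean"] * 100, overall * 100)
        w = est["n_cells_treated"]
        assert abs(np.average(diffs, weights=w)) < 2.0  # percentage points


class TestWashout:
    def test_printed_recoveries(self):
        # overall residual rising 47% -> 91% is a 44-point recovery;
        # 31% -> 65% is a 34-point recovery
        rec = washout_recovery({"overall": 47.0}, {"overall": 91.0})
        assert rec["recovery"].iloc[0] == pytest.approx(44.0)
        rec = washout_recovery({"overall": 31.0}, {"overall": 65.0})
        assert rec["recovery"].iloc[0] == pytest.approx(34.0)

    def test_identity_and_antisymmetry(self):
        a = {"exc": 30.0, "inh": 42.0}
        b = {"exc": 59.0, "inh": 71.0}
        fwd = washout_recovery(a, b).set_index("cell_type")["recovery"]
        rev = washout_recovery(b, a).set_index("cell_type")["recovery"]
        np.testing.assert_allclose(fwd, -rev)
        same = washout_recovery(a, a)
        assert (same["recovery"] == 0).all()

    def test_inner_join_warns_on_drops(self):
        with pytest.warns(UserWarning, match="micro"):
            rec = washout_recovery({"exc": 30.0, "micro": 20.0}, {"exc": 60.0})
        assert list(rec["cell_type"]) == ["exc"]

    def test_no_shared_cell_types_rejected(self):
        with pytest.raises(ValueError):
            washout_recovery({"a": 1.0}, {"b": 2.0})


class TestDoseArithmetic:
    def test_dose_molecule_scale(self):
        # 50 ug of a 7 kDa oligo is ~4e15 molecules; >1e7 per brain cell
        d = dose_molecule_count(50e-6, 7000.0, 1e8)
        assert d.molecules_total_1sf == 4e15
        assert d.molecules_per_cell > 1e7

    def test_round_trip_mass_molecules(self):
        from asokd.profiles import AVOGADRO

        d = dose_molecule_count(50e-6, 7000.0, 1e8)
        np.testing.assert_allclose(d.molecules_total * 7000.0 / AVOGADRO, 50e-6,
                                   rtol=1e-12)

    def test_productive_fraction(self):
        d = dose_molecule_count(50e-6, 7000.0, 1e8, productive_fraction=0.01)
        np.testing.assert_allclose(d.productive_per_cell,
                                   d.molecules_per_cell * 0.01, rtol=1e-12)
        assert dose_molecule_count(50e-6, 7000.0, 1e8,
                                   productive_fraction=0.0).productive_per_cell == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dose_molecule_count(50e-6, 0.0, 1e8)
        with pytest.raises(ValueError):
            dose_molecule_count(-1.0, 7000.0, 1e8)


class TestCorrelogram:
    def test_pairwise_structure_and_weight_combination(self):
        idx = ["exc", "inh", "astro", "oligo"]
        profiles = {
            "mouse": pd.Series([30.0, 40.0, 55.0, 60.0], index=idx),
            "nhp": pd.Series([35.0, 38.0, 60.0, 52.0], index=idx),
            "washout": pd.Series([59.0, 60.0, 75.0, 80.0], index=idx),
        }
        weights = {k: pd.Series([4000.0, 1500.0, 800.0, 600.0], index=idx)
                   for k in profiles}
        out = correlogram(profiles, weights)
        assert len(out) == 3  # all unordered pairs
        assert set(out.columns) == {"dataset_a", "dataset_b", "rho", "p", "n_celltypes"}
        row = out[(out["dataset_a"] == "mouse") & (out["dataset_b"] == "nhp")].iloc[0]
        rho, p = weighted_pearson(profiles["mouse"], profiles["nhp"],
                                  weights["mouse"] + weights["nhp"])
        np.testing.assert_allclose(row["rho"], rho)
        assert row["n_celltypes"] == 4
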