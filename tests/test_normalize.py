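"""Control-gene log ratios, probe/replicate collapses, median polish."""

import numpy as np
import pandas as pd
import pytest

import raslscreen as rs
from raslscreen.design import ValidationError, WellRecord
from raslscreen.normalize import (
    NormalizedMatrix,
    collapse_probes,
    collapse_replicates,
    drop_sex_markers,
    log_ratio_normalize,
    median_center,
    median_polish,
    median_polish_decompose,
)


CONTROL_PROBES = ["Ascl3_p1", "Psmd4_p1", "Sdha_p1", "Tbp_p1"]


def _counts(rows, wells, probes):
    return rs.CountMatrix(pd.DataFrame(rows, index=wells, columns=probes))


class TestLogRatioNormalize:
    def test_powers_of_two_closed_form(self, tiny_panel):
        # counts + 1 = 2, 8, 4, 16 -> geometric mean 2^2.5 ->
        # control log2 ratios -1.5, 0.5, -0.5, 1.5 with mean exactly 0
        cm = _counts([[1, 7, 3, 15]], ["w1"], CONTROL_PROBES)
        norm = log_ratio_normalize(cm, tiny_panel)
        np.testing.assert_allclose(
            norm.values["w1"].to_numpy(), [-1.5, 0.5, -0.5, 1.5], atol=1e-12
        )
        assert abs(norm.values["w1"].mean()) < 1e-12

    def test_uniform_counts_give_zero(self, tiny_panel):
        cm = _counts([[9] * 5], ["w1"], CONTROL_PROBES + ["GeneA_p1"])
        norm = log_ratio_normalize(cm, tiny_panel)
        np.testing.assert_allclose(norm.values.to_numpy(), 0.0, atol=1e-12)

    def test_matches_per_cell_oracle(self, tiny_panel):
        rng = np.random.default_rng(8)
        probes = CONTROL_PROBES + ["GeneA_p1", "GeneA_p2", "GeneB_p1"]
        counts = rng.poisson(300, size=(6, len(probes)))
        cm = _counts(counts, [f"w{i}" for i in range(6)], probes)
        norm = log_ratio_normalize(cm, tiny_panel)
        for i, w in enumerate(cm.wells):
            gm = np.exp(np.mean(np.log(counts[i, :4] + 1.0)))
            for j, p in enumerate(probes):
                expected = np.log2((counts[i, j] + 1.0) / gm)
                assert norm.values.loc[p, w] == pytest.approx(expected, abs=1e-12)

    def test_control_column_mean_exactly_zero(self, tiny_panel):
        rng = np.random.default_rng(9)
        probes = CONTROL_PROBES + ["GeneA_p1"]
        cm = _counts(rng.poisson(100, size=(20, 5)), [f"w{i}" for i in range(20)], probes)
        norm = log_ratio_normalize(cm, tiny_panel)
        control_mean = norm.values.loc[CONTROL_PROBES].mean(axis=0)
        np.testing.assert_allclose(control_mean.to_numpy(), 0.0, atol=1e-12)

    def test_missing_control_gene_is_hard_error(self, tiny_panel):
        cm = _counts([[5, 5, 5]], ["w1"], CONTROL_PROBES[:3])
        with pytest.raises(ValidationError, match="Tbp"):
            log_ratio_normalize(cm, tiny_panel)

    def test_scale_equivariance(self, tiny_panel):
        """Scaling every count in a well leaves its log ratios unchanged:
        the control geometric mean absorbs library size (pseudocount 0 on
        strictly positive counts for exactness)."""
        probes = CONTROL_PROBES + ["GeneA_p1"]
        base = np.array([[10, 20, 40, 80, 160]])
        n1 = log_ratio_normalize(_counts(base, ["w"], probes), tiny_panel, pseudocount=0)
        n2 = log_ratio_normalize(_counts(base * 7, ["w"], probes), tiny_panel, pseudocount=0)
        np.testing.assert_allclose(n1.values.to_numpy(), n2.values.to_numpy(), atol=1e-12)


class TestCollapseProbes:
    def test_odd_count_median(self, tiny_panel):
        values = pd.DataFrame(
            {"w1": [1.0, 2.0, 9.0]}, index=["GeneA_p1", "GeneA_p2", "GeneA_p3"]
        )
        out = collapse_probes(NormalizedMatrix(values, stage="probe"), tiny_panel)
        assert out.values.loc["GeneA", "w1"] == 2.0

    def test_single_probe_gene_passthrough(self, tiny_panel):
        values = pd.DataFrame({"w1": [0.7]}, index=["GeneB_p1"])
        out = collapse_probes(NormalizedMatrix(values, stage="probe"), tiny_panel)
        assert out.values.loc["GeneB", "w1"] == 0.7

    def test_matches_groupby_median_oracle(self, panel):
        rng = np.random.default_rng(10)
        probes = panel.probe_ids[:40]
        values = pd.DataFrame(
            rng.normal(size=(40, 5)), index=probes,
            columns=[f"w{i}" for i in range(5)],
        )
        out = collapse_probes(NormalizedMatrix(values, stage="probe"), panel)
        gene_of = panel.probe_to_gene()
        for g in out.values.index:
            members = [p for p in probes if gene_of[p] == g]
            np.testing.assert_allclose(
                out.values.loc[g].to_numpy(),
                values.loc[members].median(axis=0).to_numpy(),
            )


def _polish_oracle(arr, tol, max_iter):
    """Independent sweep-by-sweep median polish (naive loops)."""
    resid = arr.astype(float).copy()
    nr, nc = resid.shape
    row = [0.0] * nr
    col = [0.0] * nc
    overall = 0.0
    for _ in range(max_iter):
        prev = resid.copy()
        for i in range(nr):
            m = float(np.median(resid[i, :]))
            resid[i, :] -= m
            row[i] += m
        m = float(np.median(row))
        overall += m
        row = [r - m for r in row]
        for j in range(nc):
            m = float(np.median(resid[:, j]))
            resid[:, j] -= m
            col[j] += m
        m = float(np.median(col))
        overall += m
        col = [c - m for c in col]
        if np.max(np.abs(resid - prev)) < tol:
            break
    return overall, np.array(row), np.array(col), resid


class TestMedianPolish:
    def test_additive_matrix_has_zero_residuals(self):
        table = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"])
        res = median_polish_decompose(table)
        np.testing.assert_allclose(res.residuals.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.col_effects.to_numpy(), [-0.5, 0.5])
        assert res.n_iter <= 2

    def test_constant_matrix(self):
        # a single repeated value is pure overall effect: zero residuals,
        # output constant per gene (here identically zero)
        table = pd.DataFrame(np.full((3, 4), 2.5), index=list("abc"))
        res = median_polish_decompose(table)
        assert res.overall == pytest.approx(2.5)
        np.testing.assert_allclose(res.residuals.to_numpy(), 0.0, atol=1e-12)
        out = median_polish(NormalizedMatrix(table, stage="well"))
        assert np.ptp(out.values.to_numpy(), axis=1).max() == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(5, 7))
        table = pd.DataFrame(arr)
        res = median_polish_decompose(table, tol=1e-9, max_iter=100)
        overall, row, col, resid = _polish_oracle(arr, 1e-9, 100)
        assert res.overall == pytest.approx(overall, abs=1e-12)
        np.testing.assert_allclose(res.row_effects.to_numpy(), row, atol=1e-12)
        np.testing.assert_allclose(res.col_effects.to_numpy(), col, atol=1e-12)
        np.testing.assert_allclose(res.residuals.to_numpy(), resid, atol=1e-12)

    def test_residual_medians_near_zero(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(rng.normal(size=(8, 9)))
        res = median_polish_decompose(table, tol=1e-8, max_iter=200)
        assert np.abs(np.median(res.residuals.to_numpy(), axis=1)).max() < 1e-6
        assert np.abs(np.median(res.residuals.to_numpy(), axis=0)).max() < 1e-6

    def test_output_keeps_row_effects(self):
        table = pd.DataFrame([[1.0, 2.0], [5.0, 6.0]], index=["g1", "g2"])
        out = median_polish(NormalizedMatrix(table, stage="well"))
        # additive: residual zero, row effects +-2 around overall 3.5
        np.testing.assert_allclose(out.values.loc["g2"] - out.values.loc["g1"], 4.0)

    def test_non_finite_input_rejected(self):
        table = pd.DataFrame([[1.0, np.nan], [3.0, 4.0]], index=["g1", "g2"])
        with pytest.raises(ValidationError, match="g1"):
            median_polish_decompose(table)


class TestCollapseReplicates:
    def _design(self):
        wells = [
            WellRecord("P1", "A", i + 1, "chemX", 1.0, "M", i + 1, f"F{i}", f"R{i}")
            for i in range(3)
        ]
        return rs.PlateDesign(wells)

    def test_triplicate_median(self):
        design = self._design()
        values = pd.DataFrame(
            [[0.1, 0.5, 0.9]], index=["GeneA"],
            columns=[w.well_id for w in design.wells],
        )
        out = collapse_replicates(NormalizedMatrix(values, stage="well"), design)
        assert out.values.loc["GeneA", "chemX@1@M"] == 0.5

    def test_single_survivor_passthrough(self):
        design = self._design()
        values = pd.DataFrame(
            [[0.3]], index=["GeneA"], columns=[design.wells[0].well_id]
        )
        out = collapse_replicates(NormalizedMatrix(values, stage="well"), design)
        assert out.values.loc["GeneA", "chemX@1@M"] == 0.3

    def test_orphan_columns_rejected(self):
        design = self._design()
        values = pd.DataFrame([[0.3]], index=["GeneA"], columns=["nowhere:Z9"])
        with pytest.raises(ValidationError, match="nowhere:Z9"):
            collapse_replicates(NormalizedMatrix(values, stage="well"), design)


class TestMedianCenter:
    def test_simple_row(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = median_center(NormalizedMatrix(values, stage="condition"))
        np.testing.assert_allclose(out.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(4, 7)))
        once = median_center(NormalizedMatrix(values, stage="condition"))
        twice = median_center(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_row_medians_zero(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(6, 9)))
        out = median_center(NormalizedMatrix(values, stage="condition"))
        np.testing.assert_allclose(
            out.values.median(axis=1).to_numpy(), 0.0, atol=1e-12
        )

    def test_sex_markers_removed_first(self):
        values = pd.DataFrame(
            np.ones((3, 2)), index=["Xist", "Ddx3y", "GeneA"], columns=["a", "b"]
        )
        out = drop_sex_markers(NormalizedMatrix(values, stage="condition"))
        assert out.values.index.tolist() == ["GeneA"]


def test_zero_effect_screen_is_flat(panel):
    """End to end on a null screen: condition-level values show no treatment
    structure (mean |centered value| stays below a small seeded bound)."""
    design = rs.make_design(
        ["chemX", "chemY"], n_replicates=3, sexes=("M", "F"),
        concentrations=(1.0, 10.0), plate_size=96, vehicle_per_plate=8, seed=21,
    )
    from raslscreen.simulate import EffectProfile, SimulationConfig

    profiles = {c: EffectProfile(c) for c in ("chemX", "chemY", "VEHICLE")}
    counts, _ = rs.simulate_counts(
        design, panel, profiles,
        SimulationConfig(seed=21, well_failure_prob=0, probe_failure_prob=0),
    )
    filtered, _ = rs.run_qc(counts, panel)
    stages = rs.normalize_pipeline(filtered, panel, design)
    assert np.abs(stages["centered"].values.to_numpy()).mean() < 0.2
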