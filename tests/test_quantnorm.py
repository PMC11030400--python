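"""Normalization ladder arithmetic, CV computation, and the LOESS curve."""

import numpy as np
import pandas as pd
import pytest

from qcsentinel.errors import InsufficientDataError, ValidationError
from qcsentinel.ingest import RunType
from qcsentinel.quantnorm import (
    AnalyteKind,
    CvScope,
    CVTable,
    Level,
    QuantMatrix,
    assess_levels,
    batch_adjust,
    build_matrix,
    compute_cv,
    cv_abundance_curve,
    log2_median_normalize,
    rollup_proteins,
)
from qcsentinel.simulate import BatchEffectOnly, SimulationConfig, simulate_experiment, vignette_presets

from conftest import make_runlog, make_table


def qmatrix(values, batches, level=Level.L2_NORMALIZED):
    runs = [f"r{i}" for i in range(values.shape[1])]
    return QuantMatrix(
        pd.DataFrame(values, index=[f"a{i}" for i in range(values.shape[0])], columns=runs),
        level,
        pd.Series(batches, index=runs),
    )


class TestBuildMatrix:
    def test_toy_two_by_two(self):
        runlog = make_runlog([("q1", "EXTERNAL_QC_INTERBATCH", "B01"), ("q2", "EXTERNAL_QC_INTERBATCH", "B01")])
        table = make_table(
            [
                {"run_id": r, "analyte_id": a, "transition_area": v, "analyte_class": "ENDOGENOUS"}
                for r, a, v in [("q1", "A/2", 10.0), ("q1", "B/2", 20.0), ("q2", "A/2", 11.0), ("q2", "B/2", 21.0)]
            ],
            runlog,
        )
        m = build_matrix(table, runlog)
        assert m.values.shape == (2, 2)
        assert m.level is Level.L1_RAW
        assert m.values.loc["B/2", "q2"] == 21.0

    def test_absent_and_zero_become_missing(self):
        runlog = make_runlog([("q1", "EXTERNAL_QC_INTERBATCH", "B01"), ("q2", "EXTERNAL_QC_INTERBATCH", "B01")])
        table = make_table(
            [
                {"run_id": "q1", "analyte_id": "A/2", "transition_area": 10.0, "analyte_class": "ENDOGENOUS"},
                {"run_id": "q1", "analyte_id": "B/2", "transition_area": 0.0, "analyte_class": "ENDOGENOUS"},
                {"run_id": "q2", "analyte_id": "A/2", "transition_area": 11.0, "analyte_class": "ENDOGENOUS"},
            ],
            runlog,
        )
        m = build_matrix(table, runlog)
        assert np.isnan(m.values.loc["B/2", "q1"])
        assert np.isnan(m.values.loc["B/2", "q2"])

    def test_empty_selection_raises(self):
        runlog = make_runlog([("s1", "SAMPLE", "B01")])
        table = make_table([{"run_id": "s1", "analyte_id": "A/2"}], runlog)
        with pytest.raises(InsufficientDataError):
            build_matrix(table, runlog, {RunType.EXTERNAL_QC_INTERBATCH})


class TestLog2MedianNormalize:
    def test_doubled_run_columns_become_identical(self):
        rng = np.random.default_rng(0)
        a = np.exp2(rng.normal(18, 1, size=(20, 1)))
        m = qmatrix(np.hstack([a, 2 * a]), ["B1", "B1"], Level.L1_RAW)
        out = log2_median_normalize(m, min_obs=5)
        np.testing.assert_allclose(out.values.iloc[:, 0], out.values.iloc[:, 1], atol=1e-12)

    def test_run_medians_equal_grand_median(self):
        rng = np.random.default_rng(1)
        m = qmatrix(np.exp2(rng.normal(18, 1, size=(50, 12))), ["B1"] * 12, Level.L1_RAW)
        out = log2_median_normalize(m, min_obs=10)
        med = out.values.median(axis=0)
        assert np.ptp(med.to_numpy()) < 1e-9

    def test_centering_is_idempotent(self):
        rng = np.random.default_rng(2)
        m = qmatrix(np.exp2(rng.normal(18, 1, size=(30, 6))), ["B1"] * 6, Level.L1_RAW)
        once = log2_median_normalize(m, min_obs=5)
        again = QuantMatrix(np.exp2(once.values), Level.L1_RAW, once.batch_of)
        twice = log2_median_normalize(again, min_obs=5)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_sparse_run_listed_in_error(self):
        v = np.exp2(np.random.default_rng(3).normal(18, 1, size=(12, 3)))
        v[2:, 1] = np.nan
        m = qmatrix(v, ["B1"] * 3, Level.L1_RAW)
        with pytest.raises(InsufficientDataError, match="r1"):
            log2_median_normalize(m, min_obs=10)


class TestBatchAdjust:
    def test_identical_batches_unchanged(self):
        rng = np.random.default_rng(4)
        block = rng.normal(18, 1, size=(10, 3))
        m = qmatrix(np.hstack([block, block]), ["B1"] * 3 + ["B2"] * 3)
        out = batch_adjust(m)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)

    def test_pure_offset_removed_exactly(self):
        rng = np.random.default_rng(5)
        block = rng.normal(18, 1, size=(10, 4))
        m = qmatrix(np.hstack([block, block + 1.0]), ["B1"] * 4 + ["B2"] * 4)
        out = batch_adjust(m)
        np.testing.assert_allclose(out.values.iloc[:, :4], out.values.iloc[:, 4:], atol=1e-12)
        # per-analyte batch means coincide; grand means preserved
        bm = out.values.T.groupby(out.batch_of).mean().T
        np.testing.assert_allclose(bm["B1"], bm["B2"], atol=1e-9)
        np.testing.assert_allclose(out.values.mean(axis=1), m.values.mean(axis=1), atol=1e-9)

    def test_within_batch_variance_preserved(self):
        rng = np.random.default_rng(6)
        m = qmatrix(rng.normal(18, 1, size=(15, 8)), ["B1"] * 4 + ["B2"] * 4)
        out = batch_adjust(m)
        for b in ("B1", "B2"):
            cols = m.batch_of[m.batch_of == b].index
            np.testing.assert_allclose(
                out.values[cols].std(axis=1, ddof=1), m.values[cols].std(axis=1, ddof=1), atol=1e-12
            )

    def test_single_batch_is_warned_noop(self):
        m = qmatrix(np.random.default_rng(7).normal(18, 1, size=(5, 4)), ["B1"] * 4)
        with pytest.warns(UserWarning, match="single batch"):
            out = batch_adjust(m)
        np.testing.assert_allclose(out.values, m.values)
        assert out.level is Level.L3_BATCH_ADJUSTED

    def test_offset_recovery_against_identifiable_truth(self):
        """Injected per-analyte batch offsets are recovered with RMSE < 0.07.

        Offsets are identifiable only up to a per-analyte location, so the
        estimates are compared to the per-analyte-centered injected offsets.
        Conditions: 12 QC runs/batch, within-batch SD 0.2 log2, offsets
        N(0, 0.5^2).
        """
        rng = np.random.default_rng(8)
        n_analytes, n_batches, per_batch = 40, 6, 12
        offsets = rng.normal(0, 0.5, size=(n_analytes, n_batches))
        means = rng.normal(18, 1, size=n_analytes)
        cols, batches = [], []
        for b in range(n_batches):
            for _ in range(per_batch):
                cols.append(means + offsets[:, b] + rng.normal(0, 0.2, n_analytes))
                batches.append(f"B{b}")
        m = qmatrix(np.column_stack(cols), batches)
        out = batch_adjust(m)
        est = (m.values - out.values).T.groupby(m.batch_of).mean().T  # analyte × batch
        truth = offsets - offsets.mean(axis=1, keepdims=True)
        rmse = float(np.sqrt(np.mean((est.to_numpy() - truth) ** 2)))
        assert rmse < 0.07

    def test_sparse_analytes_passed_through(self):
        rng = np.random.default_rng(9)
        v = rng.normal(18, 1, size=(4, 6))
        v[0, 3:] = np.nan  # analyte a0 has no observations in batch B2
        m = qmatrix(v, ["B1"] * 3 + ["B2"] * 3)
        out = batch_adjust(m, min_per_batch=2)
        np.testing.assert_allclose(out.values.iloc[0, :3], m.values.iloc[0, :3], atol=1e-12)
        assert any("skipped" in p for p in out.provenance)


class TestRollup:
    def test_single_peptide_protein_equals_peptide(self):
        m = qmatrix(np.arange(8.0).reshape(2, 4) + 10, ["B1"] * 4)
        out = rollup_proteins(m, {"a0": "P1", "a1": "P2"})
        np.testing.assert_allclose(out.values.loc["P1"], m.values.loc["a0"])
        assert out.analyte_kind is AnalyteKind.PROTEIN

    def test_log2_mean_rollup(self):
        m = qmatrix(np.array([[10.0, 10.0], [12.0, 12.0]]), ["B1"] * 2)
        out = rollup_proteins(m, {"a0": "P", "a1": "P"})
        np.testing.assert_allclose(out.values.loc["P"], [11.0, 11.0])

    def test_level1_rollup_sums_linear_areas(self):
        m = qmatrix(np.array([[100.0, 110.0], [50.0, 60.0]]), ["B1"] * 2, Level.L1_RAW)
        out = rollup_proteins(m, {"a0": "P", "a1": "P"})
        np.testing.assert_allclose(out.values.loc["P"], [150.0, 170.0])
        assert out.level is Level.L1_RAW

    def test_protein_cv_not_worse_than_worst_peptide(self):
        """Averaging 3 peptides: protein CV ≤ max peptide CV in ≥95% of seeds."""
        wins = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            v = rng.normal(18, 0.15, size=(3, 10))
            m = qmatrix(v, ["B1"] * 10)
            prot = rollup_proteins(m, {f"a{i}": "P" for i in range(3)})
            cv_pep = compute_cv(m, scope=CvScope.INTER_BATCH).data["cv_percent"]
            cv_prot = compute_cv(prot, scope=CvScope.INTER_BATCH).data["cv_percent"].iloc[0]
            wins += cv_prot <= cv_pep.max()
        assert wins / n_seeds >= 0.95

    def test_empty_mapping_rejected(self):
        m = qmatrix(np.ones((2, 2)), ["B1"] * 2)
        with pytest.raises(ValidationError):
            rollup_proteins(m, {})


class TestComputeCv:
    def test_constant_analyte_cv_zero(self):
        m = qmatrix(np.full((1, 5), 123.0), ["B1"] * 5, Level.L1_RAW)
        cvt = compute_cv(m, scope=CvScope.INTER_BATCH, min_obs=3)
        assert cvt.data["cv_percent"].iloc[0] == 0.0

    def test_hand_computed_ten_percent(self):
        m = qmatrix(np.array([[90.0, 100.0, 110.0]]), ["B1"] * 3, Level.L1_RAW)
        cvt = compute_cv(m, scope=CvScope.INTER_BATCH, min_obs=3)
        assert cvt.data["cv_percent"].iloc[0] == pytest.approx(10.0, abs=1e-12)
        assert cvt.median_cv_eta == pytest.approx(10.0, abs=1e-12)

    def test_log2_matrix_back_transformed(self):
        m = qmatrix(np.log2([[90.0, 100.0, 110.0]]), ["B1"] * 3, Level.L2_NORMALIZED)
        cvt = compute_cv(m, scope=CvScope.INTER_BATCH, min_obs=3)
        assert cvt.data["cv_percent"].iloc[0] == pytest.approx(10.0, rel=1e-9)

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        v = np.exp2(rng.normal(18, 0.3, size=(8, 6)))
        a = compute_cv(qmatrix(v, ["B1"] * 6, Level.L1_RAW), scope=CvScope.INTER_BATCH)
        b = compute_cv(qmatrix(7.3 * v, ["B1"] * 6, Level.L1_RAW), scope=CvScope.INTER_BATCH)
        np.testing.assert_allclose(a.data["cv_percent"], b.data["cv_percent"], rtol=1e-9)

    def test_intra_batch_scope_one_cv_per_batch(self):
        rng = np.random.default_rng(11)
        n_batches = 8
        v = np.exp2(rng.normal(18, 0.3, size=(5, n_batches * 3)))
        batches = [f"B{i // 3}" for i in range(n_batches * 3)]
        cvt = compute_cv(qmatrix(v, batches, Level.L1_RAW), scope=CvScope.INTRA_BATCH)
        per_analyte = cvt.data.groupby("analyte_id").size()
        assert (per_analyte == n_batches).all()

    def test_subset_too_small_raises(self):
        m = qmatrix(np.ones((2, 4)), ["B1"] * 4, Level.L1_RAW)
        with pytest.raises(InsufficientDataError):
            compute_cv(m, runs=["r0"], scope=CvScope.INTER_BATCH)


def cvtable_from(x, y):
    return CVTable(
        pd.DataFrame(
            {
                "analyte_id": [f"a{i}" for i in range(len(x))],
                "scope": CvScope.INTER_BATCH.value,
                "batch_id": pd.NA,
                "cv_percent": y,
                "log2_median_abundance": x,
                "n_obs": 10,
            }
        ),
        CvScope.INTER_BATCH,
        float(np.median(y)),
        3,
    )


class TestCvAbundanceCurve:
    def test_constant_cv_gives_flat_curve(self):
        x = np.linspace(12, 24, 40)
        curve = cv_abundance_curve(cvtable_from(x, np.full(40, 12.0)))
        np.testing.assert_allclose(curve["cv_percent_smoothed"], 12.0, atol=1e-6)

    def test_linear_relationship_reproduced(self):
        x = np.linspace(12, 24, 60)
        y = 40.0 - 1.5 * x
        curve = cv_abundance_curve(cvtable_from(x, y))
        interior = curve.iloc[5:-5]
        np.testing.assert_allclose(
            interior["cv_percent_smoothed"],
            40.0 - 1.5 * interior["log2_median_abundance"],
            atol=1e-6,
        )

    def test_heteroscedastic_noise_gives_nonincreasing_curve(self):
        """Additive + multiplicative noise: CV falls with abundance."""
        rng = np.random.default_rng(12)
        n = 150
        log2_mean = rng.uniform(12, 22, n)
        mu = np.exp2(log2_mean)
        n_rep = 12
        obs = mu[:, None] * np.exp2(rng.normal(0, 0.1, (n, n_rep))) + rng.normal(
            0, 2 ** 13, (n, n_rep)
        )
        obs = np.clip(obs, 1.0, None)
        cv = 100 * obs.std(axis=1, ddof=1) / obs.mean(axis=1)
        curve = cv_abundance_curve(cvtable_from(log2_mean, cv), span=0.6)
        interior = curve["cv_percent_smoothed"].iloc[5:95].to_numpy()
        assert np.all(np.diff(interior) <= 1e-6)

    def test_too_few_analytes_suggests_scatter(self):
        with pytest.raises(InsufficientDataError, match="scatter"):
            cv_abundance_curve(cvtable_from(np.arange(5.0), np.arange(5.0)))


class TestAssessLevels:
    def test_identical_matrices_zero_deltas(self):
        rng = np.random.default_rng(13)
        v = rng.normal(18, 0.4, size=(12, 6))
        m1 = qmatrix(np.exp2(v), ["B1"] * 3 + ["B2"] * 3, Level.L1_RAW)
        m2 = qmatrix(v, ["B1"] * 3 + ["B2"] * 3, Level.L2_NORMALIZED)
        m3 = qmatrix(v, ["B1"] * 3 + ["B2"] * 3, Level.L3_BATCH_ADJUSTED)
        comp = assess_levels(
            m1, m2, m3, {CvScope.INTER_BATCH: list(m1.values.columns)}, min_obs=3
        )
        g = comp.etas.set_index("level")["median_cv_eta"]
        assert g["L2_NORMALIZED"] == pytest.approx(g["L3_BATCH_ADJUSTED"], rel=1e-9)
        l2_l3 = comp.deltas[comp.deltas["transition"] == "L2_NORMALIZED->L3_BATCH_ADJUSTED"]
        assert l2_l3["delta_eta"].abs().max() < 1e-9

    def test_ladder_reduces_interbatch_eta_on_simulated_batches(self):
        """L3 ≤ L2 ≤ L1 for inter-batch η in ≥95% of seeds."""
        ok = 0
        n_seeds = 60
        for seed in range(n_seeds):
            table, rl = simulate_experiment(vignette_presets("vignette6", seed=seed))
            ib = rl.run_ids({RunType.EXTERNAL_QC_INTERBATCH})
            l1 = build_matrix(table, rl, {RunType.EXTERNAL_QC_INTERBATCH})
            l2 = log2_median_normalize(l1)
            l3 = batch_adjust(l2)
            etas = [
                compute_cv(m, ib, CvScope.INTER_BATCH).median_cv_eta for m in (l1, l2, l3)
            ]
            ok += etas[2] <= etas[1] <= etas[0]
        assert ok / n_seeds >= 0.95

    def test_mismatched_shapes_rejected(self):
        m1 = qmatrix(np.ones((3, 4)), ["B1"] * 4, Level.L1_RAW)
        m2 = qmatrix(np.ones((2, 4)), ["B1"] * 4, Level.L2_NORMALIZED)
        m3 = qmatrix(np.ones((3, 4)), ["B1"] * 4, Level.L3_BATCH_ADJUSTED)
        with pytest.raises(ValidationError):
            assess_levels(m1, m2, m3, {CvScope.INTER_BATCH: ["r0", "r1"]})
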