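"""QC/normalization chain: background, filters, quantile norm, ComBat."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import mircortex as mc
from mircortex.containers import PipelineOrderError

from conftest import random_matrix


class TestBackground:
    def test_subtraction_and_missingness(self):
        m = random_matrix(1, 2, 0, state="raw")
        m.values.iloc[0] = [100.0, 20.0]
        bg = pd.Series({"f0": 30.0})
        out = mc.adjust_background(m, bg)
        assert out.values.iloc[0, 0] == 70.0
        assert np.isnan(out.values.iloc[0, 1])
        assert out.state == "background_adjusted"

    def test_elementwise_oracle(self):
        m = random_matrix(50, 20, 1, state="raw")
        rng = np.random.default_rng(2)
        bg = pd.Series(rng.uniform(0, 80, 50), index=m.feature_ids)
        out = mc.adjust_background(m, bg)
        for i in range(50):
            for j in range(20):
                v, b = m.values.iat[i, j], bg.iloc[i]
                expect = v - b if v > b else np.nan
                got = out.values.iat[i, j]
                assert (np.isnan(got) and np.isnan(expect)) or got == expect

    def test_errors(self):
        m = random_matrix(3, 3, 0, state="raw")
        with pytest.raises(ValueError, match="negative"):
            mc.adjust_background(m, pd.Series(-1.0, index=m.feature_ids))
        with pytest.raises(ValueError, match="background missing"):
            mc.adjust_background(m, pd.Series({"f0": 1.0}))
        done = random_matrix(3, 3, 0, state="filtered")
        with pytest.raises(PipelineOrderError):
            mc.adjust_background(done, pd.Series(1.0, index=done.feature_ids))


class TestCallRate:
    def test_boundary_rates(self):
        # 50 samples; feature present in 48 (96%) kept, in 47 (94%) removed
        m = random_matrix(2, 50, 3, state="background_adjusted")
        m.values.iloc[0, :2] = np.nan
        m.values.iloc[1, :3] = np.nan
        out, report = mc.filter_by_call_rate(m, 0.95, 0.95)
        assert list(out.feature_ids) == ["f0"]
        assert report.steps[0].removed == ["f1"]

    def test_features_filtered_before_samples(self):
        # a sample missing only within a dropped feature keeps a clean rate
        m = random_matrix(10, 10, 4, state="background_adjusted")
        m.values.iloc[0, :] = np.nan          # feature f0: fully missing
        m.values.iloc[1:, 0] = np.nan         # sample s0: missing elsewhere
        out, _ = mc.filter_by_call_rate(m, 0.5, 0.5)
        assert "f0" not in out.feature_ids
        assert "s0" not in out.sample_ids

    def test_brute_force_recount(self):
        m = random_matrix(100, 50, 5, missing_frac=0.08,
                          state="background_adjusted")
        out, report = mc.filter_by_call_rate(m, 0.95, 0.95)
        keep_f = [f for f in m.feature_ids
                  if m.values.loc[f].notna().mean() >= 0.95]
        assert list(out.feature_ids) == keep_f
        sub = m.values.loc[keep_f]
        keep_s = [s for s in m.sample_ids if sub[s].notna().mean() >= 0.95]
        assert list(out.sample_ids) == keep_s
        for step in report.steps:
            assert step.n_before - step.n_after == len(step.removed)

    def test_invalid_rate_rejected(self):
        m = random_matrix(3, 3, 0, state="background_adjusted")
        with pytest.raises(ValueError):
            mc.filter_by_call_rate(m, 0.0, 0.95)

    def test_idempotent(self):
        m = random_matrix(30, 20, 6, missing_frac=0.1,
                          state="background_adjusted")
        once, _ = mc.filter_by_call_rate(m)
        again_in = once.evolve(state="background_adjusted")
        twice, _ = mc.filter_by_call_rate(again_in)
        assert once.values.equals(twice.values)


class TestLowExpression:
    def test_boundary_inclusive_at_half(self):
        m = random_matrix(2, 10, 7, state="filtered", low=20, high=40)
        m.values.iloc[0, :5] = 10.0    # exactly 50% below 15 -> removed
        m.values.iloc[1, :4] = 10.0    # 40% below -> retained
        out, report = mc.filter_low_expression(m, 15.0, 0.5)
        assert list(out.feature_ids) == ["f1"]

    def test_missing_counts_as_below(self):
        m = random_matrix(1, 10, 8, state="filtered", low=20, high=40)
        m.values.iloc[0, :3] = np.nan
        m.values.iloc[0, 3:5] = 5.0    # 3 missing + 2 low = 50% -> removed
        out, _ = mc.filter_low_expression(m, 15.0, 0.5)
        assert out.n_features == 0

    def test_brute_force_oracle(self):
        m = random_matrix(80, 30, 9, missing_frac=0.1, state="filtered",
                          low=0, high=60)
        out, _ = mc.filter_low_expression(m, 15.0, 0.5)
        expect = []
        for f in m.feature_ids:
            row = m.values.loc[f]
            n_below = sum(1 for v in row if np.isnan(v) or v < 15.0)
            if n_below / len(row) < 0.5:
                expect.append(f)
        assert list(out.feature_ids) == expect


class TestLincrnaFilter:
    def test_strict_boundary(self):
        m = random_matrix(2, 10, 10, state="raw", feature_class="lincrna")
        m.values.iloc[0] = 4.9
        m.values.iloc[1] = 5.0
        out, _ = mc.filter_lincrna(m, 5.0)
        assert list(out.feature_ids) == ["f1"]

    def test_brute_force_and_reconciliation(self):
        m = random_matrix(40, 15, 11, state="raw", feature_class="lincrna",
                          low=0, high=12)
        out, report = mc.filter_lincrna(m, 5.0)
        expect = [f for f in m.feature_ids if m.values.loc[f].mean() >= 5.0]
        assert list(out.feature_ids) == expect
        step = report.steps[0]
        assert step.n_before == 40 and step.n_after == len(expect)

    def test_wrong_class_rejected(self):
        m = random_matrix(3, 3, 0, state="raw")
        with pytest.raises(ValueError):
            mc.filter_lincrna(m)


class TestQuantileNormalize:
    def test_hand_computed_rank_mean(self):
        m = mc.ExpressionMatrix(pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
            index=list("abc")), state="filtered")
        out = mc.quantile_normalize(m, log2=False)
        assert np.allclose(out.values["s1"], [2.5, 3.5, 4.5])
        assert np.allclose(out.values["s2"], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 7.0, 5.0])
        m = mc.ExpressionMatrix(pd.DataFrame(
            {"s1": col, "s2": col, "s3": col}, index=list("abcd")),
            state="filtered")
        out = mc.quantile_normalize(m, log2=False)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_sorted_columns_identical_and_ranks_preserved(self):
        m = random_matrix(60, 12, 13)
        out = mc.quantile_normalize(m, log2=True)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            assert np.allclose(np.sort(arr[:, j]), ref)
            orig = np.log2(m.values.to_numpy()[:, j] + 1.0)
            assert (np.argsort(orig, kind="mergesort")
                    == np.argsort(arr[:, j], kind="mergesort")).all()

    def test_ties_share_mean_order_statistic(self):
        m = mc.ExpressionMatrix(pd.DataFrame(
            {"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]},
            index=list("abc")), state="filtered")
        out = mc.quantile_normalize(m, log2=False)
        # target = [1.5, 2.5, 5.5]; tie in s1 rows a,b -> mean(1.5, 2.5)
        assert np.allclose(out.values["s1"], [2.0, 2.0, 5.5])

    def test_idempotent_fixed_point(self):
        m = random_matrix(40, 8, 14)
        once = mc.quantile_normalize(m, log2=False)
        twice = mc.quantile_normalize(once.evolve(state="filtered"),
                                      log2=False)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_single_sample_rejected(self):
        m = random_matrix(5, 1, 0)
        with pytest.raises(ValueError):
            mc.quantile_normalize(m)


def _batch_matrix(seed, n_feat=100, n_samp=200, shift=3.0, effect=None):
    """Two equal batches with a pure log-scale mean shift on batch B;
    optionally a planted binary-outcome effect orthogonal to batch."""
    rng = np.random.default_rng(seed)
    base = rng.normal(8.0, 1.0, size=(n_feat, n_samp))
    batch = np.array(["A"] * (n_samp // 2) + ["B"] * (n_samp - n_samp // 2))
    base[:, batch == "B"] += shift
    outcome = np.tile([0, 1], n_samp // 2)   # alternating: orthogonal to batch
    if effect is not None:
        base[0] += effect * outcome
    cols = [f"s{j}" for j in range(n_samp)]
    m = mc.ExpressionMatrix(pd.DataFrame(base, columns=cols,
                                         index=[f"f{i}" for i in range(n_feat)]),
                            batch=pd.Series(batch, index=cols),
                            state="normalized")
    return m, pd.Series(batch, index=cols), outcome


class TestCombat:
    def test_removes_pure_mean_shift(self):
        """A planted +3 log-scale shift collapses to ~0: the systematic
        (across-feature) batch difference vanishes and per-feature residuals
        shrink to sampling-noise scale."""
        m, batch, _ = _batch_matrix(20)
        out = mc.combat_adjust(m)
        v = out.values.to_numpy()
        delta = (v[:, (batch == "A").to_numpy()].mean(axis=1)
                 - v[:, (batch == "B").to_numpy()].mean(axis=1))
        assert abs(delta.mean()) < 0.05          # systematic shift removed
        assert np.abs(delta).mean() < 0.15       # per-feature residual noise
        assert np.abs(delta).max() < 0.6         # nothing close to the planted 3

    def test_preserves_orthogonal_outcome_effect(self):
        m, _, outcome = _batch_matrix(21, effect=1.0)
        before = mc.fit_association(m.values.iloc[0].to_numpy(), outcome)
        out = mc.combat_adjust(m)
        after = mc.fit_association(out.values.iloc[0].to_numpy(), outcome)
        assert after.beta == pytest.approx(before.beta, rel=0.05)

    def test_single_batch_rejected(self):
        m = random_matrix(10, 10, 22, state="normalized")
        with pytest.raises(ValueError, match="at least 2 batches"):
            mc.combat_adjust(m, pd.Series("A", index=m.sample_ids))

    def test_tiny_batch_rejected(self):
        m = random_matrix(10, 10, 23, state="normalized")
        labels = pd.Series(["A"] * 9 + ["B"], index=m.sample_ids)
        with pytest.raises(ValueError, match="<2 samples"):
            mc.combat_adjust(m, labels)

    def test_confounded_covariate_rejected(self):
        m, batch, _ = _batch_matrix(24, n_feat=5, n_samp=20)
        confounded = pd.DataFrame(
            {"x": (batch == "B").astype(float).to_numpy()},
            index=m.sample_ids)
        with pytest.raises(ValueError, match="singular"):
            mc.combat_adjust(m, covariates=confounded)

    def test_matches_bioconductor_sva_on_fixture(self, tmp_path):
        """Cross-check the EB adjustment against the reference R
        implementation on a small two-batch fixture."""
        m, batch, _ = _batch_matrix(25, n_feat=30, n_samp=24, shift=2.0)
        ours = mc.combat_adjust(m)
        csv = tmp_path / "x.csv"
        m.values.to_csv(csv)
        script = tmp_path / "combat.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.csv("{csv}", row.names = 1))
            batch <- c(rep("A", 12), rep("B", 12))
            out <- ComBat(dat = x, batch = batch)
            write.csv(out, "{tmp_path / 'out.csv'}")
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert np.allclose(ours.values.to_numpy(), ref.to_numpy(), atol=1e-6)


class TestFullChain:
    def test_report_reconciles_with_dimensions(self, planted_run):
        report = planted_run["report"]
        raw = planted_run["raw"]
        n = raw.n_features
        for step in report.steps:
            if step.axis == "feature":
                assert step.n_before == n
                n = step.n_after
        assert planted_run["processed"].n_features == n

    def test_batch_removal_preserves_downstream_associations(self):
        """Associations after ComBat on batched data match associations on
        batch-free data from the same seed (no batch-outcome confounding)."""
        cohort = mc.generate_cohort(300, 31)
        truth = mc.GroundTruth(seed=31)
        truth.effects["miR-synth-0001"] = ("ad", -0.08)
        raw_b, bg = mc.generate_mirna_counts(
            cohort, truth, 40, 31, mc.MirnaParams(batch_sd=0.6))
        raw_f, bg_f = mc.generate_mirna_counts(
            cohort, mc.GroundTruth(seed=31, effects=dict(truth.effects)),
            40, 31, mc.MirnaParams(batch_sd=0.0))
        proc_b, _ = mc.preprocess_mirna(raw_b, bg)
        proc_f, _ = mc.preprocess_mirna(raw_f, bg_f, run_combat=False)
        rb = mc.associate_all(proc_b, cohort, outcomes=("ad",)).set_index(
            "feature_id")
        rf = mc.associate_all(proc_f, cohort, outcomes=("ad",)).set_index(
            "feature_id")
        z = rb.loc["miR-synth-0001", "z"], rf.loc["miR-synth-0001", "z"]
        assert z[0] == pytest.approx(z[1], rel=0.15)
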