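"""Moderated t-test, hyperparameter estimation, thresholds and RPKM."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from splicesig.diffsplice import (DifferentialExpression, DifferentialSplicing,
                                  EBayesFit, call_differential_events,
                                  call_differential_genes, compute_rpkm,
                                  event_type_breakdown, fit_ebayes,
                                  moderated_t_test)


def psi_frame(a_rows, b_rows, ids=None):
    """Build events x samples frame: a_rows/b_rows are lists of group vectors."""
    data = np.hstack([np.atleast_2d(a_rows), np.atleast_2d(b_rows)])
    na = np.atleast_2d(a_rows).shape[1]
    nb = np.atleast_2d(b_rows).shape[1]
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    idx = ids or [f"e{i}" for i in range(data.shape[0])]
    return pd.DataFrame(data, index=idx, columns=cols)


def two_group_design(na, nb):
    return {f"a{i}": "A" for i in range(na)} | {f"b{i}": "B" for i in range(nb)}


class TestFitEbayes:
    def test_equal_variances_give_infinite_prior_df(self):
        fit = fit_ebayes([0.5] * 10, [4] * 10)
        assert math.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(0.5, rel=1e-6)

    def test_two_event_case_matches_independent_moment_solver(self):
        variances, d_g = np.array([1.0, 4.0]), np.array([4.0, 4.0])
        fit = fit_ebayes(variances, d_g)
        assert 0 < fit.d0 < math.inf
        assert 1.0 <= fit.s0_sq <= 4.0
        # independent check: the moment equations the estimate must satisfy
        e = np.log(variances) - special.digamma(2.0) + np.log(2.0)
        target_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, 2.0))
        resid = float(special.polygamma(1, fit.d0 / 2.0)) - target_var
        assert abs(resid) < 1e-6
        expected_s0 = math.exp(float(np.mean(e))
                               + float(special.digamma(fit.d0 / 2.0))
                               - math.log(fit.d0 / 2.0))
        assert fit.s0_sq == pytest.approx(expected_s0, rel=1e-8)

    def test_hyperparameter_recovery_from_known_hierarchy(self):
        rng = np.random.default_rng(2024)
        d0_true, s0_true, d_g = 4.0, 0.02, 4
        n_events = 5000
        s2 = s0_true * d0_true / rng.chisquare(d0_true, n_events)
        s2 = s2 * rng.chisquare(d_g, n_events) / d_g
        fit = fit_ebayes(s2, np.full(n_events, d_g))
        assert abs(fit.d0 - d0_true) / d0_true < 0.25

    def test_degenerate_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            fit_ebayes([0.0, 0.0, 0.0], [4, 4, 4])

    def test_moderated_variance_identity(self):
        fit = fit_ebayes([0.1, 1.0, 10.0, 0.5, 25.0], [3, 3, 3, 3, 3])
        assert math.isfinite(fit.d0)
        expected = (fit.d0 * fit.s0_sq + fit.d_g * fit.s_g_sq) / (fit.d0 + fit.d_g)
        np.testing.assert_allclose(fit.s_tilde_sq, expected)


class TestModeratedT:
    A = np.array([0.1, 0.2, 0.15])
    B = np.array([0.6, 0.7, 0.65])

    def d0_zero_fit(self):
        return EBayesFit(d0=0.0, s0_sq=1.0, s_g_sq=np.array([1.0]),
                         d_g=np.array([4.0]))

    def test_identical_groups_give_zero_delta_unit_p(self):
        fit = self.d0_zero_fit()
        delta, t, p = moderated_t_test(self.A, self.A, fit)
        assert delta == 0.0 and t == 0.0 and p == pytest.approx(1.0)

    def test_d0_zero_equals_classical_pooled_t(self):
        delta, t, p = moderated_t_test(self.A, self.B, self.d0_zero_fit())
        ref = stats.ttest_ind(self.A, self.B, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert delta == pytest.approx(self.A.mean() - self.B.mean())

    def test_d0_infinite_is_fixed_variance_z(self):
        fit = EBayesFit(d0=math.inf, s0_sq=0.0025, s_g_sq=np.array([1.0]),
                        d_g=np.array([4.0]))
        delta, t, p = moderated_t_test(self.A, self.B, fit)
        se = math.sqrt(0.0025 * (2 / 3))
        assert t == pytest.approx(delta / se)
        assert p == pytest.approx(2 * stats.norm.sf(abs(t)))

    def test_antisymmetry_under_group_swap(self):
        fit = self.d0_zero_fit()
        d1, t1, p1 = moderated_t_test(self.A, self.B, fit)
        d2, t2, p2 = moderated_t_test(self.B, self.A, fit)
        assert d1 == -d2 and t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_untestable_small_group_flagged_not_raised(self):
        fit = self.d0_zero_fit()
        delta, t, p = moderated_t_test(np.array([0.5]), self.B, fit)
        assert math.isnan(delta) and math.isnan(t) and math.isnan(p)

    def test_type_one_error_near_nominal_under_null(self):
        rng = np.random.default_rng(7)
        n_events, n = 10_000, 5
        vals = rng.beta(2, 2, size=(n_events, 2 * n))
        frame = psi_frame(vals[:, :n], vals[:, n:])
        res = DifferentialSplicing(frame, two_group_design(n, n)).fit(
            alpha=0.01, dpsi_min=0.0)
        rate = float((res.table["p"] <= 0.01).mean())
        assert 0.005 <= rate <= 0.02

    def test_matches_bioconductor_limma(self, tmp_path):
        """Dual-route check against the reference eBayes implementation."""
        rng = np.random.default_rng(42)
        n_ev, n = 200, 3
        true_var = 0.04 * 4 / rng.chisquare(4, n_ev)
        data = np.hstack([
            rng.normal(0.5, np.sqrt(true_var)[:, None], (n_ev, n)),
            rng.normal(0.55, np.sqrt(true_var)[:, None], (n_ev, n))])
        frame = psi_frame(data[:, :n], data[:, n:])
        csv = tmp_path / "x.csv"
        frame.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.csv(args[1]))
            design <- cbind(Intercept=1, GroupA=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,'GroupA'], d0=fit$df.prior, s02=fit$s2.prior)
            write.csv(out, args[2], row.names=FALSE)
        """))
        out = tmp_path / "limma.csv"
        subprocess.run(["Rscript", str(script), str(csv), str(out)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out)
        res = DifferentialSplicing(frame, two_group_design(n, n)).fit(
            alpha=0.01, dpsi_min=0.0)
        assert res.ebayes.d0 == pytest.approx(float(ref["d0"][0]), rel=1e-4)
        assert res.ebayes.s0_sq == pytest.approx(float(ref["s02"][0]), rel=1e-4)
        np.testing.assert_allclose(res.table["t_mod"].to_numpy(),
                                   ref["t"].to_numpy(), rtol=1e-6)


class TestSignificanceRule:
    def test_delta_psi_threshold_is_strict(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1e-4, size=(2, 6))
        a = np.array([[0.50] * 3, [0.50] * 3]) + noise[:, :3]
        b = np.vstack([a[0, :3] - 0.1, a[1, :3] - 0.25])
        frame = psi_frame(a, b)
        frame.iloc[0, :3] = [0.6, 0.6, 0.6]
        frame.iloc[0, 3:] = [0.5, 0.5, 0.5]  # delta exactly 0.10
        res = DifferentialSplicing(frame, two_group_design(3, 3)).fit()
        assert res.table.loc["e0", "delta_psi"] == pytest.approx(0.10)
        assert res.table.loc["e0", "p"] < 1e-6
        assert not res.table.loc["e0", "significant"]
        assert res.table.loc["e1", "significant"]

    def test_p_threshold_is_inclusive(self):
        frame = psi_frame([[0.6, 0.6, 0.6]], [[0.45, 0.45, 0.45]])
        model = DifferentialSplicing(frame, two_group_design(3, 3))
        res = model.fit(alpha=1.0, dpsi_min=0.1)
        p_exact = float(res.table["p"].iloc[0])
        res2 = model.fit(alpha=p_exact, dpsi_min=0.1)
        assert bool(res2.table["significant"].iloc[0])

    def test_cluster_collapse_keeps_largest_effect(self, cassette_events):
        ids = [e.event_id for e in cassette_events[:2]]
        frame = psi_frame([[0.9, 0.88, 0.92], [0.8, 0.78, 0.82]],
                          [[0.5, 0.52, 0.48], [0.6, 0.62, 0.58]], ids=ids)
        res = DifferentialSplicing(frame, two_group_design(3, 3),
                                   events=cassette_events).fit()
        assert res.table["significant"].sum() == 2
        assert len(res.unique_table) == 1  # one shared cluster
        assert abs(res.unique_table["delta_psi"].iloc[0]) == pytest.approx(0.4, abs=0.05)
        assert res.unique_table.index[0] == ids[0]

    def test_collapse_invariant_to_row_order(self, cassette_events):
        ids = [e.event_id for e in cassette_events[:2]]
        frame = psi_frame([[0.9, 0.88, 0.92], [0.8, 0.78, 0.82]],
                          [[0.5, 0.52, 0.48], [0.6, 0.62, 0.58]], ids=ids)
        res1 = DifferentialSplicing(frame, two_group_design(3, 3),
                                    events=cassette_events).fit()
        res2 = DifferentialSplicing(frame.iloc[::-1], two_group_design(3, 3),
                                    events=cassette_events).fit()
        pd.testing.assert_frame_equal(res1.unique_table, res2.unique_table)

    def test_design_with_three_groups_rejected(self):
        frame = psi_frame([[0.5, 0.5, 0.5]], [[0.5, 0.5, 0.5]])
        design = {"a0": "A", "a1": "B", "a2": "C", "b0": "A", "b1": "B", "b2": "C"}
        with pytest.raises(ValueError, match="two groups"):
            DifferentialSplicing(frame, design)

    def test_signature_carries_directions(self):
        frame = psi_frame([[0.9, 0.9, 0.88], [0.2, 0.22, 0.2]],
                          [[0.5, 0.52, 0.5], [0.6, 0.58, 0.6]])
        res = DifferentialSplicing(frame, two_group_design(3, 3)).fit()
        assert res.signature.directions == {"e0": 1, "e1": -1}


class TestBreakdown:
    def test_counts_by_type_and_direction(self, cassette_events):
        cas = next(e for e in cassette_events if e.event_type == "cassette-exon")
        irs = [e for e in cassette_events if e.event_type == "intron-retention"]
        table = pd.DataFrame({
            "direction": [1, -1, -1, -1],
            "cluster_id": ["c1", "c2", "c3", "c4"],
        }, index=pd.Index([cas.event_id] + [e.event_id for e in irs[:3]],
                          name="event_id"))
        counts = event_type_breakdown(table, cassette_events)
        assert counts.loc["cassette-exon", "inclusion"] == 1
        assert counts.loc["intron-retention", "exclusion"] == 3
        assert counts.to_numpy().sum() == 4

    def test_empty_signature_all_zero(self, cassette_events):
        table = pd.DataFrame({"direction": [], "cluster_id": []},
                             index=pd.Index([], name="event_id"))
        counts = event_type_breakdown(table, cassette_events)
        assert counts.to_numpy().sum() == 0

    def test_unknown_event_rejected(self, cassette_events):
        table = pd.DataFrame({"direction": [1], "cluster_id": ["c"]},
                             index=pd.Index(["nope"], name="event_id"))
        with pytest.raises(ValueError, match="unknown event_id"):
            event_type_breakdown(table, cassette_events)


class TestExpression:
    def test_rpkm_closed_form(self):
        assert compute_rpkm(1000, 1000, 10**6) == pytest.approx(1000.0)
        assert compute_rpkm(0, 1000, 10**6) == 0.0

    def test_rpkm_halves_when_library_doubles(self):
        r1 = compute_rpkm(777, 2345, 5_000_000)
        r2 = compute_rpkm(777, 2345, 10_000_000)
        assert r2 == pytest.approx(r1 / 2)

    def test_rpkm_rejects_zero_library(self):
        with pytest.raises(ValueError):
            compute_rpkm(10, 1000, 0)

    def test_fold_threshold_inclusive(self):
        # geometric-mean fold of exactly 1.5 with tiny within-group noise;
        # pseudocount 0 keeps the fold change exact
        frame = pd.DataFrame(
            [[150.0, 150.0 * 1.001, 150.0 / 1.001,
              100.0, 100.0 * 1.001, 100.0 / 1.001]],
            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        model = DifferentialExpression(frame, {"a0": "A", "a1": "A", "a2": "A",
                                               "b0": "B", "b1": "B", "b2": "B"},
                                       pseudocount=0.0)
        res = model.fit(alpha=0.01, min_fold=1.5)
        fold = float(res.table["fold_change"].iloc[0])
        assert fold == pytest.approx(1.5, rel=1e-6)
        assert res.table["p"].iloc[0] < 1e-4
        # the >= threshold is inclusive: a gene sitting exactly at the cutoff
        # is called significant
        res_at = model.fit(alpha=0.01, min_fold=fold)
        assert bool(res_at.table["significant"].iloc[0])

    def test_identical_groups_yield_no_calls(self):
        rpkm = pd.DataFrame(np.tile([10.0, 20.0, 5.0], (4, 2)).reshape(4, 6) + 0.0,
                            columns=[f"a{i}" for i in range(3)]
                            + [f"b{i}" for i in range(3)])
        rpkm.iloc[:, 3:] = rpkm.iloc[:, :3].to_numpy()
        res = call_differential_genes(rpkm, two_group_design(3, 3))
        assert res.table["significant"].sum() == 0

    def test_planted_two_fold_genes_recovered(self):
        rng = np.random.default_rng(11)
        n_genes, n_diff, n = 300, 50, 3
        base = rng.uniform(5, 50, n_genes)
        a = base[:, None] * rng.lognormal(0, 0.05, (n_genes, n))
        b = base[:, None] * rng.lognormal(0, 0.05, (n_genes, n))
        a[:n_diff] *= 2.0
        rpkm = pd.DataFrame(np.hstack([a, b]),
                            columns=[f"a{i}" for i in range(n)]
                            + [f"b{i}" for i in range(n)])
        res = call_differential_genes(rpkm, two_group_design(n, n))
        called = res.table["significant"].to_numpy()
        sensitivity = called[:n_diff].mean()
        assert sensitivity >= 0.9

    def test_negative_rpkm_rejected(self):
        frame = pd.DataFrame([[-1.0, 1, 1, 1, 1, 1]],
                             columns=[f"a{i}" for i in range(3)]
                             + [f"b{i}" for i in range(3)])
        with pytest.raises(ValueError, match="non-negative"):
            DifferentialExpression(frame, two_group_design(3, 3))
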