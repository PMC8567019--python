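import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from methcd8 import (
    AnalysisConfig,
    MethylationMatrix,
    ModerationPrior,
    ValidationError,
    benjamini_hochberg,
    call_dmps,
    classical_t_test,
    fit_moderation_prior,
    moderated_t_test,
)
from methcd8.dmp import full_statistics_table, trigamma_inverse
from methcd8.preprocess import matrix_to_m, m_to_beta

from conftest import random_matrix


def _m(n_probes, n_a, n_b, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    frame = pd.DataFrame(rng.normal(0, sd, size=(n_probes, n_a + n_b)),
                         index=[f"cg{i}" for i in range(n_probes)], columns=cols)
    return frame, cols[:n_a], cols[n_a:]


class TestTrigammaInverse:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-5, max_value=1e6))
    def test_round_trip(self, x):
        y = trigamma_inverse(x)
        assert special.polygamma(1, y) == pytest.approx(x, rel=1e-8)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            trigamma_inverse(0.0)


class TestModerationPrior:
    def test_identical_variances_give_degenerate_prior(self):
        prior = fit_moderation_prior(np.full(100, 2.0), df=10)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.0)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            fit_moderation_prior(np.zeros(10), df=5)

    def test_parameter_recovery_from_hierarchical_model(self):
        # sigma2 ~ s02 * d0 / chi2_{d0};  s2 | sigma2 ~ sigma2 * chi2_d / d
        rng = np.random.default_rng(42)
        d0, s0_sq, d = 4.0, 1.0, 17
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, size=10_000)
        s_sq = sigma_sq * rng.chisquare(d, size=10_000) / d
        prior = fit_moderation_prior(s_sq, df=d)
        assert 3.0 <= prior.d0 <= 5.0
        assert 0.9 <= prior.s0_sq <= 1.1


class TestModeratedT:
    def test_zero_prior_df_reproduces_classical_t(self):
        m, a, b = _m(50, 6, 6, seed=1)
        mod = moderated_t_test(m, a, b, prior=ModerationPrior(d0=0.0, s0_sq=1.0))
        cls = classical_t_test(m, a, b)
        np.testing.assert_allclose(mod.t_mod, cls.t_mod, atol=1e-10)
        np.testing.assert_allclose(mod.p, cls.p, atol=1e-10)
        # and the classical statistic agrees with scipy
        t_ref, p_ref = stats.ttest_ind(m[b], m[a], axis=1)
        np.testing.assert_allclose(cls.t_mod, t_ref, atol=1e-10)
        np.testing.assert_allclose(cls.p, p_ref, atol=1e-10)

    def test_infinite_prior_df_gives_pooled_variance_z(self):
        m, a, b = _m(40, 5, 5, seed=2)
        res = moderated_t_test(m, a, b, prior=ModerationPrior(d0=np.inf, s0_sq=2.0))
        effect = m[b].mean(axis=1) - m[a].mean(axis=1)
        expected = effect / (np.sqrt(2.0) * np.sqrt(1 / 5 + 1 / 5))
        np.testing.assert_allclose(res.t_mod, expected, atol=1e-10)
        np.testing.assert_allclose(res.p, 2 * stats.norm.sf(np.abs(expected)),
                                   atol=1e-12)

    def test_equal_group_means_give_zero_t_unit_p(self):
        m, a, b = _m(10, 4, 4, seed=3)
        m.iloc[0] = [1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0]
        res = moderated_t_test(m, a, b)
        assert res.t_mod[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p[0] == pytest.approx(1.0)

    def test_sample_order_permutation_invariance(self):
        m, a, b = _m(30, 6, 5, seed=4)
        rng = np.random.default_rng(0)
        res1 = moderated_t_test(m, a, b)
        res2 = moderated_t_test(m, list(rng.permutation(a)), list(rng.permutation(b)))
        np.testing.assert_allclose(res1.t_mod, res2.t_mod, atol=1e-12)

    def test_paired_mode_matches_one_sample_t_on_differences(self):
        m, a, b = _m(40, 6, 6, seed=5)
        res = classical_t_test(m, a, b, paired=True)
        t_ref, p_ref = stats.ttest_rel(m[b], m[a], axis=1)
        np.testing.assert_allclose(res.t_mod, t_ref, atol=1e-10)
        np.testing.assert_allclose(res.p, p_ref, atol=1e-10)

    def test_small_groups_rejected(self):
        m, a, b = _m(5, 1, 4)
        with pytest.raises(ValidationError):
            moderated_t_test(m, a, b)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        hits, total = 0, 0
        for _ in range(40):
            m, a, b = _m(2000, 9, 10, seed=rng.integers(2**31))
            res = moderated_t_test(m, a, b)
            hits += (res.p < 0.05).sum()
            total += res.p.size
        assert 0.04 <= hits / total <= 0.06


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_ties_get_equal_fdr(self):
        fdr = benjamini_hochberg([0.01, 0.01, 0.5])
        assert fdr[0] == fdr[1]

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_fdr_dominates_p_and_bounded(self, ps):
        fdr = benjamini_hochberg(ps)
        assert (fdr >= np.asarray(ps) - 1e-12).all()
        assert (fdr <= 1).all()


class TestCallDmps:
    def _setup(self, seed=0):
        matrix = random_matrix(60, 12, seed=seed)
        a = matrix.sample_ids[:6]
        b = matrix.sample_ids[6:]
        res = moderated_t_test(matrix_to_m(matrix), a, b)
        return matrix, a, b, res

    def test_threshold_rule_and_direction(self):
        # strong planted hypermethylation passes; sub-threshold effect fails
        rng = np.random.default_rng(1)
        beta = pd.DataFrame(rng.uniform(0.48, 0.52, size=(50, 12)),
                            index=[f"cg{i}" for i in range(50)],
                            columns=[f"s{j}" for j in range(12)])
        a, b = list(beta.columns[:6]), list(beta.columns[6:])
        beta.loc["cg0", b] += 0.30    # |delta beta| ~ 0.30 -> retained, hyper
        beta.loc["cg1", b] += 0.04    # significant but below the 0.1 effect floor
        beta.loc["cg1", a] -= 0.04
        matrix = MethylationMatrix(beta.clip(0, 1))
        res = moderated_t_test(matrix_to_m(matrix), a, b)
        table = full_statistics_table(res, matrix, a, b)
        assert table.loc["cg1", "fdr"] < 0.05          # significant ...
        assert abs(table.loc["cg1", "delta_beta"]) < 0.1   # ... but small effect
        dmps = call_dmps(res, matrix, a, b, AnalysisConfig())
        ids = {d.probe_id: d for d in dmps}
        assert "cg0" in ids and ids["cg0"].direction == "hyper"
        assert ids["cg0"].fdr < 0.05 and ids["cg0"].delta_beta > 0.1
        assert "cg1" not in ids

    def test_output_sorted_by_fdr(self):
        matrix, a, b, res = self._setup(3)
        dmps = call_dmps(res, matrix, a, b,
                         AnalysisConfig(fdr_threshold=0.999999, min_delta_beta=0.01))
        fdrs = [d.fdr for d in dmps]
        assert fdrs == sorted(fdrs)

    def test_effect_size_on_beta_statistics_on_m(self):
        """delta_beta comes from the beta matrix even though the test ran on
        M values (where the group difference ranks differently)."""
        beta = pd.DataFrame({
            "a0": [0.50, 0.010], "a1": [0.52, 0.012],
            "b0": [0.70, 0.060], "b1": [0.68, 0.058],
        }, index=["mid", "low"])
        matrix = MethylationMatrix(beta)
        a, b = ["a0", "a1"], ["b0", "b1"]
        res = moderated_t_test(matrix_to_m(matrix), a, b)
        table = full_statistics_table(res, matrix, a, b)
        # beta-scale effect is larger for "mid"; M-scale effect larger for "low"
        assert abs(table.loc["mid", "delta_beta"]) > abs(table.loc["low", "delta_beta"])
        assert abs(res.t_mod[res.probe_ids.index("low")]) > \
            abs(res.t_mod[res.probe_ids.index("mid")])
        np.testing.assert_allclose(
            table["delta_beta"],
            beta[b].mean(axis=1) - beta[a].mean(axis=1), atol=1e-12)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(fdr_threshold=1.5)


class TestAgainstLimma:
    """Independent oracle: limma's lmFit/eBayes on the same matrix."""

    def test_moderated_statistics_match(self, tmp_path):
        m, a, b = _m(120, 6, 6, seed=13, sd=0.4)
        m.iloc[:10, 6:] += 1.0
        ours = moderated_t_test(m, a, b)

        data_path = tmp_path / "m.csv"
        out_path = tmp_path / "limma.csv"
        m.to_csv(data_path)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            dat <- as.matrix(read.csv("{data_path}", row.names=1))
            group <- factor(c(rep("a", 6), rep("b", 6)), levels=c("a","b"))
            design <- model.matrix(~group)
            fit <- eBayes(lmFit(dat, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.csv(out, "{out_path}")
        """))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True, text=True)
        ref = pd.read_csv(out_path, index_col=0)
        assert ours.prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert ours.prior.s0_sq == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(ours.t_mod, ref["t"], rtol=1e-8)
        np.testing.assert_allclose(ours.p, ref["p"], rtol=1e-8)
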