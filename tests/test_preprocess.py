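import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methcd8 import (
    AnalysisConfig,
    Manifest,
    MethylationMatrix,
    ProbeAnnotation,
    ValidationError,
    beta_to_m,
    combat_correct,
    filter_probes,
    m_to_beta,
    normalize_probe_types,
)


def _manifest(ids, probe_type="II"):
    return Manifest([
        ProbeAnnotation(probe_id=p, chrom="chr1", pos=100 * (i + 1),
                        probe_type=probe_type)
        for i, p in enumerate(ids)
    ])


class TestFilterProbes:
    def _matrix(self, ids, detection=None):
        beta = pd.DataFrame(0.5, index=ids, columns=["s1", "s2"])
        dp = None
        if detection is not None:
            dp = pd.DataFrame(detection, index=ids, columns=["s1", "s2"])
        return MethylationMatrix(beta, dp)

    def test_detection_failure_in_one_sample_removes_probe(self):
        ids = ["cg1", "cg2"]
        det = [[0.001, 0.02], [0.001, 0.001]]   # cg1 fails the 0.01 cutoff once
        m = self._matrix(ids, det)
        out, rep = filter_probes(m, _manifest(ids), AnalysisConfig())
        assert out.probe_ids == ["cg2"]
        assert rep.n_removed_detection == 1

    def test_no_exclusions_is_identity(self):
        ids = [f"cg{i}" for i in range(5)]
        m = self._matrix(ids, [[0.0, 0.0]] * 5)
        out, rep = filter_probes(m, _manifest(ids), AnalysisConfig())
        assert out.probe_ids == ids
        assert rep.n_retained == 5

    def test_hand_counted_toy(self):
        # 10 probes: 2 SNP, 1 cross-reactive, 1 failing detection -> 6 retained
        ids = [f"cg{i}" for i in range(9)] + ["ch.9"]
        det = [[0.0, 0.0]] * 10
        det[0] = [0.5, 0.0]
        m = self._matrix(ids, det)
        out, rep = filter_probes(m, _manifest(ids), AnalysisConfig(),
                                 snp_list=["cg1", "cg2"],
                                 crossreactive_list=["cg3"])
        assert rep.n_removed_detection == 1
        assert rep.n_removed_snp == 2
        assert rep.n_removed_crossreactive == 1
        assert rep.n_removed_noncpg == 1
        assert rep.n_retained == 5
        assert out.probe_ids == ["cg4", "cg5", "cg6", "cg7", "cg8"]

    def test_precedence_counts_probe_once(self):
        # a probe that both fails detection and is a SNP counts as detection
        ids = ["cg1", "cg2"]
        det = [[0.5, 0.0], [0.0, 0.0]]
        m = self._matrix(ids, det)
        _, rep = filter_probes(m, _manifest(ids), AnalysisConfig(),
                               snp_list=["cg1"])
        assert rep.n_removed_detection == 1 and rep.n_removed_snp == 0
        assert rep.n_input - rep.n_retained == 1

    def test_absent_exclusion_id_ignored(self, caplog):
        ids = ["cg1"]
        m = self._matrix(ids)
        with caplog.at_level("WARNING"):
            out, _ = filter_probes(m, _manifest(ids), AnalysisConfig(),
                                   snp_list=["cg_missing"])
        assert out.probe_ids == ["cg1"]
        assert "cg_missing" in caplog.text


class TestBetaMTransform:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_reference_points(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trip_on_clipped_domain(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-10)

    def test_strictly_monotone(self):
        b = np.linspace(0, 1, 1001)
        m = beta_to_m(b)
        assert (np.diff(m[1:-1]) > 0).all()

    def test_extremes_are_clipped_finite(self):
        assert np.isfinite(beta_to_m(0.0)) and np.isfinite(beta_to_m(1.0))
        assert abs(beta_to_m(1.0)) < 20.5


class TestProbeTypeNormalization:
    def _mixed(self, x1, x2):
        ids = [f"cgI{i}" for i in range(len(x1))] + [f"cgII{i}" for i in range(len(x2))]
        man = Manifest(
            [ProbeAnnotation(probe_id=f"cgI{i}", chrom="chr1", pos=i + 1,
                             probe_type="I") for i in range(len(x1))]
            + [ProbeAnnotation(probe_id=f"cgII{i}", chrom="chr1",
                               pos=1000 + i, probe_type="II") for i in range(len(x2))])
        beta = pd.DataFrame({"s1": np.concatenate([x1, x2])}, index=ids)
        return MethylationMatrix(beta), man

    def test_identical_distributions_fixed_point(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.95, size=40)
        m, man = self._mixed(x, x.copy())
        out = normalize_probe_types(m, man)
        np.testing.assert_allclose(out.beta.to_numpy(), m.beta.to_numpy(), atol=1e-9)

    def test_shifted_type_two_moves_closer(self):
        rng = np.random.default_rng(1)
        x1 = rng.beta(2, 2, size=300)
        x2 = np.clip(m_to_beta(beta_to_m(rng.beta(2, 2, size=300)) + 1.0), 0, 1)
        m, man = self._mixed(x1, x2)
        out = normalize_probe_types(m, man)
        y2 = out.beta.to_numpy()[300:, 0]
        before = stats.ks_2samp(x1, x2).statistic
        after = stats.ks_2samp(x1, y2).statistic
        assert after < before

    def test_mapping_is_monotone(self):
        rng = np.random.default_rng(2)
        x1 = rng.uniform(0, 1, 50)
        x2 = rng.uniform(0, 1, 80)
        m, man = self._mixed(x1, x2)
        out = normalize_probe_types(m, man)
        y2 = out.beta.to_numpy()[50:, 0]
        order = np.argsort(x2)
        assert (np.diff(y2[order]) >= 0).all()

    def test_too_few_probes_of_one_type_rejected(self):
        m, man = self._mixed(np.full(3, 0.5), np.linspace(0.1, 0.9, 30))
        with pytest.raises(ValidationError, match="normalization"):
            normalize_probe_types(m, man)


def _m_matrix(n_probes, n_samples, seed=0, noise_sd=0.3):
    """M-value-like matrix: probe-specific levels plus array-scale noise."""
    rng = np.random.default_rng(seed)
    level = rng.normal(0, 3, size=(n_probes, 1))
    return pd.DataFrame(level + rng.normal(0, noise_sd, size=(n_probes, n_samples)),
                        index=[f"cg{i}" for i in range(n_probes)],
                        columns=[f"s{j}" for j in range(n_samples)]), rng


class TestCombat:
    def test_single_batch_is_identity(self):
        m, _ = _m_matrix(100, 8)
        out = combat_correct(m, ["b1"] * 8)
        pd.testing.assert_frame_equal(out, m)

    def test_planted_shift_removed(self):
        m, rng = _m_matrix(2000, 40, seed=3)
        batch = ["A"] * 20 + ["B"] * 20
        m.iloc[:, 20:] += 1.0
        out = combat_correct(m, batch)
        gap = (out.iloc[:, 20:].mean(axis=1) - out.iloc[:, :20].mean(axis=1)).abs()
        assert gap.median() < 0.05

    def test_group_effect_preserved_in_balanced_design(self):
        m, rng = _m_matrix(2000, 40, seed=4)
        batch = (["A"] * 10 + ["B"] * 10) * 2
        group = ["g1"] * 20 + ["g2"] * 20
        truth_probes = np.arange(100)
        m.iloc[truth_probes, 20:] += 1.0                       # group effect
        m.iloc[:, [b == "B" for b in batch]] += 0.8            # batch effect
        out = combat_correct(m, batch, group)
        est = (out.iloc[truth_probes, 20:].mean(axis=1)
               - out.iloc[truth_probes, :20].mean(axis=1))
        assert abs(est.median() - 1.0) < 0.1

    def test_near_idempotent_on_balanced_design(self):
        # EB shrinkage leaves a noise-scale residual, so a second pass is
        # only approximately a no-op; the residual shrinks with each pass
        m, _ = _m_matrix(1000, 24, seed=5)
        batch = ["A"] * 12 + ["B"] * 12
        m.iloc[:, 12:] += 0.7
        once = combat_correct(m, batch)
        twice = combat_correct(once, batch)
        first_change = np.median((once - m).abs().to_numpy())
        second_change = np.median((twice - once).abs().to_numpy())
        assert second_change < 0.02
        assert second_change < first_change / 5

    def test_singleton_batch_rejected(self):
        m, _ = _m_matrix(50, 5)
        with pytest.raises(ValidationError, match="single sample"):
            combat_correct(m, ["A", "A", "A", "A", "B"])

    def test_confounded_batch_group_rejected(self):
        m, _ = _m_matrix(50, 8)
        batch = ["A"] * 4 + ["B"] * 4
        group = ["g1"] * 4 + ["g2"] * 4
        with pytest.raises(ValidationError, match="confounded"):
            combat_correct(m, batch, group)

    def test_shape_and_labels_unchanged(self):
        m, _ = _m_matrix(60, 12, seed=7)
        out = combat_correct(m, ["A"] * 6 + ["B"] * 6)
        assert out.shape == m.shape
        assert list(out.index) == list(m.index)
        assert list(out.columns) == list(m.columns)


class TestCombatAgainstSva:
    """Independent oracle: Bioconductor sva::ComBat on a small matrix."""

    def test_matches_reference_implementation(self, tmp_path):
        m, _ = _m_matrix(80, 12, seed=11)
        batch = ["A"] * 6 + ["B"] * 6
        group = ["g1", "g1", "g1", "g2", "g2", "g2"] * 2
        m.iloc[:, 6:] += 0.9
        m.iloc[:20, [3, 4, 5, 9, 10, 11]] += 1.2
        ours = combat_correct(m, batch, group)

        data_path = tmp_path / "m.csv"
        out_path = tmp_path / "combat.csv"
        m.to_csv(data_path)
        script = tmp_path / "combat.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(sva))
            dat <- as.matrix(read.csv("{data_path}", row.names=1))
            batch <- c(rep("A", 6), rep("B", 6))
            group <- factor(rep(c("g1","g1","g1","g2","g2","g2"), 2))
            mod <- model.matrix(~group)
            out <- ComBat(dat=dat, batch=batch, mod=mod, par.prior=TRUE)
            write.csv(out, "{out_path}")
        """))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True, text=True)
        theirs = pd.read_csv(out_path, index_col=0)
        np.testing.assert_allclose(ours.to_numpy(), theirs.to_numpy(),
                                   rtol=1e-4, atol=1e-4)
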