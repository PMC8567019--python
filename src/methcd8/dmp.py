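"""Probe-wise differential methylation with empirical-Bayes moderated t-tests.

Per-probe residual variances s2 with d residual degrees of freedom are
shrunk toward a prior (d0, s02) fitted across probes by matching the
moments of log s2 to a scaled-F model (digamma/trigamma inversion):

    s2_tilde = (d0*s02 + d*s2) / (d0 + d)
    t_mod    = (mean_b - mean_a) / (s_tilde * sqrt(1/n_a + 1/n_b))

with p-values from a t distribution on d0 + d degrees of freedom.  Tests
run on M values; effect sizes (delta-beta) are computed on beta values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import AnalysisConfig, DMPRecord, MethylationMatrix, ValidationError
from .preprocess import matrix_to_m


@dataclass(frozen=True)
class ModerationPrior:
    """Prior on probe variances: d0 degrees of freedom (may be inf) and
    prior variance s0_sq.

    Fitted priors always have d0 > 0; d0 = 0 is accepted only as the
    explicit "no moderation" limit, under which the moderated statistic
    degenerates to the classical t.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValidationError("d0 must be non-negative")
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq must be positive")


def trigamma_inverse(x: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is positive, decreasing and convex on (0, inf), so the
    iteration below (on the reciprocal scale) converges monotonically.
    """
    if x <= 0:
        raise ValidationError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_moderation_prior(s_sq: np.ndarray, df: float) -> ModerationPrior:
    """Fit (d0, s02) from per-probe sample variances with df residual df.

    When the variances are numerically identical the data carry no
    dispersion information: the prior is degenerate (d0 = inf) with
    s02 equal to the common variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.size < 2:
        raise ValidationError("need >= 2 probes to fit the variance prior")
    if (s_sq < 0).any():
        raise ValidationError("variances must be non-negative")
    if np.all(s_sq <= 0):
        raise ValidationError("all residual variances are zero; degenerate data")
    mean = s_sq.mean()
    if s_sq.var() <= 1e-12 * max(mean**2, 1e-300):
        return ModerationPrior(d0=np.inf, s0_sq=float(mean))

    # moment matching on z = log s2 (zero variances excluded from the fit)
    positive = s_sq[s_sq > 0]
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationPrior(d0=float(d0), s0_sq=float(s0_sq))


@dataclass
class ModeratedTResult:
    """Per-probe moderated test statistics for one contrast."""

    probe_ids: list[str]
    t_mod: np.ndarray
    df_total: np.ndarray
    p: np.ndarray
    s_sq: np.ndarray
    s_sq_shrunk: np.ndarray
    prior: ModerationPrior
    paired: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_mod": self.t_mod, "df_total": self.df_total, "p": self.p,
            "s_sq": self.s_sq, "s_sq_shrunk": self.s_sq_shrunk,
        }, index=pd.Index(self.probe_ids, name="probe_id"))


def _shrink_and_test(effect: np.ndarray, s_sq: np.ndarray, df: float,
                     stderr_unit: float,
                     prior: Optional[ModerationPrior]) -> tuple:
    if prior is None:
        prior = fit_moderation_prior(s_sq, df)
    if np.isinf(prior.d0):
        s_sq_shrunk = np.full_like(s_sq, prior.s0_sq)
        df_total = np.full_like(s_sq, np.inf)
    else:
        s_sq_shrunk = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = np.full_like(s_sq, prior.d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s_sq_shrunk) * stderr_unit)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isinf(df_total),
                 2.0 * stats.norm.sf(np.abs(t)),
                 2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return t, df_total, p, s_sq_shrunk, prior


def moderated_t_test(
    m_values: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    paired: bool = False,
    prior: Optional[ModerationPrior] = None,
) -> ModeratedTResult:
    """Moderated t-test of group b vs group a on an M-value matrix.

    Unpaired: two-sample pooled-variance design.  Paired: samples_a[i] and
    samples_b[i] belong to the same subject and the one-sample analogue runs
    on within-subject differences (b - a).

    ``prior`` overrides the fitted prior; passing ``ModerationPrior`` with
    d0 -> 0 is not allowed by its invariant, use ``classical_t_test`` for
    the unmoderated statistic.
    """
    a = m_values[list(samples_a)].to_numpy(dtype=float)
    b = m_values[list(samples_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if paired:
        if n_a != n_b:
            raise ValidationError("paired test requires equal-length sample lists")
        if n_a < 2:
            raise ValidationError("paired test requires >= 2 pairs")
        d = b - a
        effect = d.mean(axis=1)
        s_sq = d.var(axis=1, ddof=1)
        df = float(n_a - 1)
        stderr_unit = 1.0 / np.sqrt(n_a)
    else:
        if n_a < 2 or n_b < 2:
            raise ValidationError("each group needs >= 2 samples")
        effect = b.mean(axis=1) - a.mean(axis=1)
        df = float(n_a + n_b - 2)
        s_sq = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / df
        stderr_unit = np.sqrt(1.0 / n_a + 1.0 / n_b)

    t, df_total, p, s_sq_shrunk, prior = _shrink_and_test(
        effect, s_sq, df, stderr_unit, prior)
    return ModeratedTResult(
        probe_ids=list(m_values.index), t_mod=t, df_total=df_total, p=p,
        s_sq=s_sq, s_sq_shrunk=s_sq_shrunk, prior=prior, paired=paired,
    )


def classical_t_test(m_values: pd.DataFrame, samples_a: Sequence[str],
                     samples_b: Sequence[str], paired: bool = False) -> ModeratedTResult:
    """The d0 -> 0 limit of the moderated test: the classical (pooled or
    paired) t statistic.  No shrinkage: s2_tilde = s2 and df = residual df."""
    a = m_values[list(samples_a)].to_numpy(dtype=float)
    b = m_values[list(samples_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if paired:
        if n_a != n_b or n_a < 2:
            raise ValidationError("paired test requires >= 2 equal-length pairs")
        d = b - a
        effect, s_sq = d.mean(axis=1), d.var(axis=1, ddof=1)
        df, stderr_unit = float(n_a - 1), 1.0 / np.sqrt(n_a)
    else:
        if n_a < 2 or n_b < 2:
            raise ValidationError("each group needs >= 2 samples")
        effect = b.mean(axis=1) - a.mean(axis=1)
        df = float(n_a + n_b - 2)
        s_sq = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / df
        stderr_unit = np.sqrt(1.0 / n_a + 1.0 / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s_sq) * stderr_unit)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.nextafter(0, 1), 1.0)
    return ModeratedTResult(
        probe_ids=list(m_values.index), t_mod=t, df_total=np.full_like(t, df), p=p,
        s_sq=s_sq, s_sq_shrunk=s_sq, prior=ModerationPrior(d0=np.inf, s0_sq=1.0),
        paired=paired,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH-adjusted p-values (monotone in p rank, each <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    stats_result: ModeratedTResult,
    matrix: MethylationMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    config: AnalysisConfig | None = None,
) -> list[DMPRecord]:
    """Retain probes with FDR < threshold and |delta-beta| > the minimum
    effect; direction is 'hyper' when group b is more methylated.

    Returns records sorted by FDR ascending (ties by p then probe id).
    """
    config = config or AnalysisConfig()
    beta = matrix.beta.loc[stats_result.probe_ids]
    mean_a = beta[list(samples_a)].mean(axis=1).to_numpy()
    mean_b = beta[list(samples_b)].mean(axis=1).to_numpy()
    delta = mean_b - mean_a
    fdr = benjamini_hochberg(stats_result.p)

    records = []
    for i, probe_id in enumerate(stats_result.probe_ids):
        if fdr[i] < config.fdr_threshold and abs(delta[i]) > config.min_delta_beta:
            records.append(DMPRecord(
                probe_id=probe_id,
                mean_beta_a=float(mean_a[i]), mean_beta_b=float(mean_b[i]),
                delta_beta=float(delta[i]),
                t_mod=float(stats_result.t_mod[i]),
                df_total=float(stats_result.df_total[i]),
                p=float(stats_result.p[i]), fdr=float(fdr[i]),
                direction="hyper" if delta[i] > 0 else "hypo",
            ))
    records.sort(key=lambda r: (r.fdr, r.p, r.probe_id))
    return records


def full_statistics_table(
    stats_result: ModeratedTResult,
    matrix: MethylationMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
) -> pd.DataFrame:
    """All-probe statistics (p, fdr, delta_beta, t) for downstream DMR
    calling, regardless of significance."""
    beta = matrix.beta.loc[stats_result.probe_ids]
    mean_a = beta[list(samples_a)].mean(axis=1).to_numpy()
    mean_b = beta[list(samples_b)].mean(axis=1).to_numpy()
    return pd.DataFrame({
        "t_mod": stats_result.t_mod,
        "df_total": stats_result.df_total,
        "p": stats_result.p,
        "fdr": benjamini_hochberg(stats_result.p),
        "mean_beta_a": mean_a,
        "mean_beta_b": mean_b,
        "delta_beta": mean_b - mean_a,
    }, index=pd.Index(stats_result.probe_ids, name="probe_id"))


def dmp_contrast(
    matrix: MethylationMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    paired: bool = False,
    config: AnalysisConfig | None = None,
) -> tuple[list[DMPRecord], pd.DataFrame]:
    """Convenience: M-transform, moderated test, DMP calls and the
    full-statistics table for one contrast (a vs b)."""
    m = matrix_to_m(matrix)
    res = moderated_t_test(m, samples_a, samples_b, paired=paired)
    dmps = call_dmps(res, matrix, samples_a, samples_b, config)
    table = full_statistics_table(res, matrix, samples_a, samples_b)
    return dmps, table
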