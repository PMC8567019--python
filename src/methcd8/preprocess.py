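"""Probe filtering, beta/M transforms, probe-type normalization and
empirical-Bayes (ComBat-style) batch correction.

Filtering removes, in this fixed order, probes that (i) fail the detection
p-value cutoff in any sample, (ii) overlap known SNPs, (iii) are not in CpG
context, and (iv) are cross-reactive; a probe matching several rules is
counted under the first.  Statistics downstream run on M values
(M = log2(beta/(1-beta))), which are close to homoscedastic, while effect
sizes are reported on the beta scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Manifest, MethylationMatrix, ValidationError, AnalysisConfig

logger = logging.getLogger(__name__)

#: beta values are clipped into [EPS, 1-EPS] before the logit; |M| <= ~19.9
M_CLIP_EPS = 1e-6


@dataclass
class FilterReport:
    """Bookkeeping of the probe-QC step; counts reconcile exactly."""

    n_input: int
    n_removed_detection: int
    n_removed_snp: int
    n_removed_noncpg: int
    n_removed_crossreactive: int
    n_retained: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = (self.n_removed_detection + self.n_removed_snp
                   + self.n_removed_noncpg + self.n_removed_crossreactive)
        if self.n_input - removed != self.n_retained:
            raise ValidationError("FilterReport counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_detection": self.n_removed_detection,
            "n_removed_snp": self.n_removed_snp,
            "n_removed_noncpg": self.n_removed_noncpg,
            "n_removed_crossreactive": self.n_removed_crossreactive,
            "n_retained": self.n_retained,
            "removed_ids": self.removed_ids,
        }


def filter_probes(
    matrix: MethylationMatrix,
    manifest: Manifest,
    config: AnalysisConfig | None = None,
    snp_list: Sequence[str] = (),
    crossreactive_list: Sequence[str] = (),
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the four QC exclusion rules; row order of survivors is kept.

    A probe is "not in CpG context" when its manifest id does not start with
    "cg" (array convention: ch./rs. probes are non-CpG controls).
    """
    config = config or AnalysisConfig()
    present = set(matrix.probe_ids)
    for name, ids in (("snp", snp_list), ("cross-reactive", crossreactive_list)):
        for probe_id in ids:
            if probe_id not in present:
                logger.warning("%s exclusion id %s absent from matrix; ignored", name, probe_id)

    snp = set(snp_list) & present
    xreact = set(crossreactive_list) & present

    failing_detection: set[str] = set()
    if matrix.detection_p is not None:
        fails = (matrix.detection_p.to_numpy() > config.detection_p_cutoff).any(axis=1)
        failing_detection = set(np.asarray(matrix.probe_ids)[fails])

    removed: dict[str, list[str]] = {
        "detection": [], "snp": [], "noncpg": [], "crossreactive": [],
    }
    keep: list[str] = []
    for probe_id in matrix.probe_ids:
        if probe_id in failing_detection:
            removed["detection"].append(probe_id)
        elif probe_id in snp:
            removed["snp"].append(probe_id)
        elif probe_id in manifest and not probe_id.startswith("cg"):
            removed["noncpg"].append(probe_id)
        elif probe_id in xreact:
            removed["crossreactive"].append(probe_id)
        else:
            keep.append(probe_id)

    report = FilterReport(
        n_input=len(matrix.probe_ids),
        n_removed_detection=len(removed["detection"]),
        n_removed_snp=len(removed["snp"]),
        n_removed_noncpg=len(removed["noncpg"]),
        n_removed_crossreactive=len(removed["crossreactive"]),
        n_retained=len(keep),
        removed_ids=removed,
    )
    return matrix.subset_probes(keep), report


# ---------------------------------------------------------------------------
# beta <-> M

def beta_to_m(beta, eps: float = M_CLIP_EPS):
    """M = log2(beta / (1 - beta)), with beta clipped into [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1), computed overflow-safely."""
    m = np.asarray(m, dtype=float)
    return np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (1.0 + np.exp2(m)))


def matrix_to_m(matrix: MethylationMatrix) -> pd.DataFrame:
    return pd.DataFrame(beta_to_m(matrix.beta.to_numpy()),
                        index=matrix.beta.index, columns=matrix.beta.columns)


# ---------------------------------------------------------------------------
# probe-type normalization

def normalize_probe_types(matrix: MethylationMatrix, manifest: Manifest,
                          min_probes: int = 10) -> MethylationMatrix:
    """Map, within each sample, type II beta quantiles onto the type I
    empirical quantile function; type I values pass through unchanged.

    The two Infinium chemistries produce systematically different beta
    distributions (type II compressed toward 0.5); this monotone quantile
    map aligns them without moving type I values.
    """
    types = np.array([
        manifest[p].probe_type if p in manifest else "II" for p in matrix.probe_ids
    ])
    is_one = types == "I"
    is_two = ~is_one
    n1, n2 = int(is_one.sum()), int(is_two.sum())
    if n1 < min_probes or n2 < min_probes:
        raise ValidationError(
            f"probe-type normalization needs >= {min_probes} probes of each "
            f"type (got I: {n1}, II: {n2})"
        )
    beta = matrix.beta.to_numpy().copy()
    for j in range(beta.shape[1]):
        x = beta[is_two, j]
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(n2)
        ranks[order] = np.arange(n2)
        _, inv = np.unique(x, return_inverse=True)
        # average rank per distinct value so equal inputs get equal outputs
        avg = np.bincount(inv, weights=ranks) / np.bincount(inv)
        q = avg[inv] / (n2 - 1)
        # evaluate the type I empirical quantile function at the type II ranks
        beta[is_two, j] = np.quantile(beta[is_one, j], np.clip(q, 0.0, 1.0))
    beta = np.clip(beta, 0.0, 1.0)
    out = pd.DataFrame(beta, index=matrix.beta.index, columns=matrix.beta.columns)
    return MethylationMatrix(out, matrix.detection_p)


# ---------------------------------------------------------------------------
# ComBat batch correction

@dataclass
class BatchModel:
    """Fitted location/scale batch model: per-(batch, probe) shifts gamma*
    and scales delta*^2 after empirical-Bayes shrinkage, plus the
    hyperparameters of their priors."""

    batches: list[str]
    gamma_star: np.ndarray    # n_batch x n_probe
    delta_star_sq: np.ndarray
    gamma_bar: np.ndarray     # per batch: prior mean of gamma
    tau_sq: np.ndarray        # per batch: prior variance of gamma
    a_prior: np.ndarray       # per batch: inverse-gamma shape for delta^2
    b_prior: np.ndarray       # per batch: inverse-gamma scale

    def __post_init__(self) -> None:
        if (self.delta_star_sq <= 0).any():
            raise ValidationError("BatchModel delta* must be positive")


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_correct(
    m_values: pd.DataFrame,
    batch: Sequence[str],
    group: Optional[Sequence[str]] = None,
    return_model: bool = False,
    tol: float = 1e-4,
    max_iter: int = 100,
):
    """Parametric empirical-Bayes location/scale batch adjustment of a
    probes x samples M-value matrix.

    Per probe the data are standardized preserving the group-mean structure,
    per-batch location (gamma) and scale (delta^2) are estimated and shrunk
    toward normal / inverse-gamma priors whose hyperparameters are fitted by
    moments across probes, then the adjusted data are back-transformed.
    A single-batch input is returned unchanged.
    """
    batch = np.asarray(list(batch))
    if len(batch) != m_values.shape[1]:
        raise ValidationError("batch labels must match the number of samples")
    levels = list(dict.fromkeys(batch))
    if len(levels) == 1:
        result = m_values.copy()
        return (result, None) if return_model else result
    sizes = {b: int((batch == b).sum()) for b in levels}
    for b, n in sizes.items():
        if n < 2:
            raise ValidationError(f"batch {b!r} has a single sample; cannot estimate scale")

    X = m_values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    batch_design = np.column_stack([(batch == b).astype(float) for b in levels])

    cov = np.empty((n_samples, 0))
    if group is not None:
        group = np.asarray(list(group))
        g_levels = list(dict.fromkeys(group))
        # reference coding; intercept is absorbed by the batch indicators
        cov = np.column_stack([(group == g).astype(float) for g in g_levels[1:]]) \
            if len(g_levels) > 1 else cov
        design = np.hstack([batch_design, cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(
                "batch is confounded with the group covariate: batches "
                f"{levels} cannot be separated from groups {g_levels}"
            )
    design = np.hstack([batch_design, cov])

    # grand (batch-weighted) means and covariate effects, probe-wise OLS
    B_hat, *_ = np.linalg.lstsq(design, X.T, rcond=None)       # n_params x n_probes
    n_per_batch = np.array([sizes[b] for b in levels], dtype=float)
    grand_mean = (n_per_batch / n_samples) @ B_hat[: len(levels)]   # n_probes
    resid = X - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)                        # n denominator, as pooled
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] + (cov @ B_hat[len(levels):]).T \
        if cov.shape[1] else np.repeat(grand_mean[:, None], n_samples, axis=1)
    s_data = (X - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((len(levels), n_probes))
    delta_hat = np.empty((len(levels), n_probes))
    for i, b in enumerate(levels):
        cols = batch == b
        gamma_hat[i] = s_data[:, cols].mean(axis=1)
        delta_hat[i] = s_data[:, cols].var(axis=1, ddof=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(delta_hat[i]) for i in range(len(levels))])
    b_prior = np.array([_bprior(delta_hat[i]) for i in range(len(levels))])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, b in enumerate(levels):
        cols = batch == b
        n_b = float(sizes[b])
        g_old, d_old = gamma_hat[i].copy(), delta_hat[i].copy()
        for _ in range(max_iter):
            g_new = (tau_sq[i] * n_b * gamma_hat[i] + d_old * gamma_bar[i]) / (
                tau_sq[i] * n_b + d_old)
            sum_sq = ((s_data[:, cols] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum_sq + b_prior[i]) / (n_b / 2.0 + a_prior[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star[i], delta_star[i] = g_old, np.maximum(d_old, 1e-12)

    adjusted = s_data.copy()
    for i, b in enumerate(levels):
        cols = batch == b
        adjusted[:, cols] = (s_data[:, cols] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i])[:, None]
    corrected = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    result = pd.DataFrame(corrected, index=m_values.index, columns=m_values.columns)
    if not np.isfinite(corrected).all():
        raise ValidationError("batch correction produced non-finite values")

    if return_model:
        model = BatchModel(
            batches=levels, gamma_star=gamma_star, delta_star_sq=delta_star,
            gamma_bar=gamma_bar, tau_sq=tau_sq, a_prior=a_prior, b_prior=b_prior,
        )
        return result, model
    return result
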