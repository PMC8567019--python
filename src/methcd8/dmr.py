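"""Differentially methylated regions from probe-level statistics.

Candidate CpGs (probe FDR below threshold, confirmed by a Gaussian-kernel
smooth of the squared t statistic along the chromosome) are merged when
consecutive candidates lie within the kernel bandwidth of each other.
Regions passing a minimum CpG count and a minimum mean |delta-beta| are
reported with three combined statistics: Stouffer's combined p, Fisher's
combined p, and the harmonic mean of member FDRs (HMFDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DMRRecord, Manifest, ValidationError


@dataclass
class DMRParams:
    """Tuning parameters of region extraction.

    lambda_bp is the kernel bandwidth (bp); the kernel standard deviation
    is lambda_bp / scaling_C.  Merging joins consecutive candidate CpGs
    whose gap is at most lambda_bp.
    """

    lambda_bp: float = 1000.0
    scaling_C: float = 2.0
    min_cpgs: int = 5
    fdr_threshold: float = 0.05
    min_mean_abs_delta_beta: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_bp <= 0 or self.scaling_C <= 0:
            raise ValidationError("lambda_bp and scaling_C must be positive")
        if self.min_cpgs < 2:
            raise ValidationError("min_cpgs must be >= 2")


def smooth_statistics(values: np.ndarray, positions: np.ndarray,
                      lambda_bp: float = 1000.0, scaling_C: float = 2.0) -> np.ndarray:
    """Gaussian-kernel smooth of per-probe values along one chromosome.

    Weights are normalized per probe, so every output is a convex
    combination of inputs; the kernel is truncated at 4 standard
    deviations for speed.  Positions must be sorted ascending.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.shape != positions.shape:
        raise ValidationError("values and positions must have equal length")
    if np.any(np.diff(positions) < 0):
        raise ValidationError("positions must be sorted ascending within a chromosome")
    n = values.size
    if n <= 1:
        return values.copy()
    sd = lambda_bp / scaling_C
    window = 4.0 * sd
    lo = np.searchsorted(positions, positions - window, side="left")
    hi = np.searchsorted(positions, positions + window, side="right")
    out = np.empty(n)
    for i in range(n):
        d = positions[lo[i]:hi[i]] - positions[i]
        w = np.exp(-0.5 * (d / sd) ** 2)
        out[i] = np.dot(w, values[lo[i]:hi[i]]) / w.sum()
    return out


def combine_pvalues(p: np.ndarray, fdr: np.ndarray) -> tuple[float, float, float]:
    """Region-level combined statistics from member-probe p-values/FDRs.

    Stouffer: z_bar = sum(Phi^-1(1-p_i)) / sqrt(k), combined p = 1-Phi(z_bar).
    Fisher:   X = -2*sum(ln p_i) ~ chi2 on 2k df.
    HMFDR:    k / sum(1/fdr_i)  (harmonic mean of the FDRs).
    """
    p = np.asarray(p, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if p.size < 1:
        raise ValidationError("combine_pvalues needs k >= 1 probes")
    if (p <= 0).any():
        warnings.warn("p-value of 0 clipped to 1e-300 before combining")
        p = np.maximum(p, 1e-300)
    if (p > 1).any() or (fdr <= 0).any() or (fdr > 1).any():
        raise ValidationError("p-values and FDRs must lie in (0,1]")
    k = p.size
    z = stats.norm.isf(p)                       # Phi^-1(1 - p)
    stouffer = float(stats.norm.sf(z.sum() / np.sqrt(k)))
    fisher_x = -2.0 * np.log(p).sum()
    fisher = float(stats.chi2.sf(fisher_x, 2 * k))
    hmfdr = float(k / np.sum(1.0 / fdr))
    stouffer = min(max(stouffer, np.nextafter(0, 1)), 1.0)
    fisher = min(max(fisher, np.nextafter(0, 1)), 1.0)
    return stouffer, fisher, hmfdr


def call_dmrs(stats_table: pd.DataFrame, manifest: Manifest,
              params: DMRParams | None = None) -> list[DMRRecord]:
    """Extract DMRs from a full-probe statistics table.

    ``stats_table`` must be indexed by probe_id with columns p, fdr and
    delta_beta (as produced by ``dmp.full_statistics_table``).  Candidates
    are probes with fdr < threshold whose smoothed t^2 exceeds the
    chromosome-wide median of the smoothed field; consecutive candidates
    with inter-probe gaps <= lambda_bp merge into one region.  Records are
    sorted by Fisher combined p.
    """
    params = params or DMRParams()
    if stats_table.empty:
        return []
    for col in ("p", "fdr", "delta_beta"):
        if col not in stats_table.columns:
            raise ValidationError(f"stats table missing column {col!r}")

    # positions of scored probes, grouped by chromosome, sorted
    rows = []
    for probe_id in stats_table.index:
        if probe_id not in manifest:
            raise ValidationError(f"probe {probe_id!r} missing from manifest")
        ann = manifest[probe_id]
        rows.append((probe_id, ann.chrom, ann.pos))
    locs = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]).set_index("probe_id")

    records: list[DMRRecord] = []
    for chrom, chrom_locs in locs.groupby("chrom", sort=True):
        chrom_locs = chrom_locs.sort_values("pos")
        ids = chrom_locs.index.to_numpy()
        pos = chrom_locs["pos"].to_numpy(dtype=float)
        sub = stats_table.loc[ids]
        t_sq = sub["t_mod"].to_numpy() ** 2 if "t_mod" in sub.columns else \
            stats.norm.isf(np.maximum(sub["p"].to_numpy(), 1e-300) / 2.0) ** 2
        smooth = smooth_statistics(t_sq, pos, params.lambda_bp, params.scaling_C)
        elevated = smooth >= np.median(smooth)
        candidate = (sub["fdr"].to_numpy() < params.fdr_threshold) & elevated

        idx = np.flatnonzero(candidate)
        if idx.size == 0:
            continue
        # split runs of candidates at gaps > lambda_bp
        breaks = np.flatnonzero(np.diff(pos[idx]) > params.lambda_bp)
        for run in np.split(idx, breaks + 1):
            if run.size < params.min_cpgs:
                continue
            member_ids = ids[run]
            delta = sub.loc[member_ids, "delta_beta"].to_numpy()
            meandiff = float(delta.mean())
            if abs(meandiff) < params.min_mean_abs_delta_beta:
                continue
            stouffer, fisher, hmfdr = combine_pvalues(
                sub.loc[member_ids, "p"].to_numpy(),
                sub.loc[member_ids, "fdr"].to_numpy())
            maxdiff = float(delta[np.argmax(np.abs(delta))])
            genes: set[str] = set()
            for probe_id in member_ids:
                genes.update(manifest[probe_id].genes)
            records.append(DMRRecord(
                chrom=chrom, start=int(pos[run[0]]), end=int(pos[run[-1]]),
                n_cpgs=int(run.size), stouffer=stouffer, hmfdr=hmfdr, fisher=fisher,
                maxdiff=maxdiff, meandiff=meandiff, genes=tuple(sorted(genes)),
                probe_ids=tuple(member_ids),
            ))
    records.sort(key=lambda r: (r.fisher, r.chrom, r.start))
    return records


def call_dmrs_multi(stats_table: pd.DataFrame, manifest: Manifest,
                    min_cpgs_set=(5, 10, 20),
                    params: DMRParams | None = None) -> dict[int, list[DMRRecord]]:
    """Region sets at several minimum CpG counts (nested by construction:
    raising min_cpgs can only drop regions)."""
    base = params or DMRParams()
    out: dict[int, list[DMRRecord]] = {}
    for k in sorted(min_cpgs_set):
        p = DMRParams(lambda_bp=base.lambda_bp, scaling_C=base.scaling_C,
                      min_cpgs=int(k), fdr_threshold=base.fdr_threshold,
                      min_mean_abs_delta_beta=base.min_mean_abs_delta_beta)
        out[int(k)] = call_dmrs(stats_table, manifest, p)
    return out
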