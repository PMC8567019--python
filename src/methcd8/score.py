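"""Pathway-restricted methylation disease-activity score.

DMPs annotated to a supplied pathway gene set (e.g. TNF-alpha / IL-17
signaling) are screened for strong Pearson correlation between beta value
and the PASI skin score across patient samples (|r| above a threshold,
default 0.8).  Each surviving probe is z-standardized against the healthy
controls, SV = (beta - mean_HC) / SD_HC, and the SVs are summed to a
per-sample score, whose correlation with PASI is then reported.

Because selection correlates probes with the same PASI values the score is
later evaluated against, results carry an explicit leakage flag; a
held-out variant (select on before-treatment samples only, evaluate on
the rest) is available through ``selection_timepoint``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DMPRecord, Manifest, MethylationMatrix, SampleSheet, ScoreModel, ValidationError,
)

logger = logging.getLogger(__name__)


def select_activity_dmps(
    dmps: Sequence[DMPRecord],
    pathway_genes: set[str],
    matrix: MethylationMatrix,
    manifest: Manifest,
    pasi: pd.Series,
    r_threshold: float = 0.8,
) -> pd.Series:
    """Pathway-restricted, PASI-correlated candidate probes.

    ``pasi`` maps patient sample ids to PASI values (samples without PASI
    must not appear).  Returns a Series probe_id -> selection r for probes
    whose |r| exceeds the threshold; empty (with a warning) when the
    pathway restriction leaves no candidates.
    """
    pasi = pasi.dropna()
    if len(pasi) < 3:
        raise ValidationError("need >= 3 patient samples with PASI for selection")
    candidates = []
    for dmp in dmps:
        ann = manifest[dmp.probe_id]
        if set(ann.genes) & pathway_genes:
            candidates.append(dmp.probe_id)
    if not candidates:
        warnings.warn("no DMPs map to the pathway gene set; score undefined")
        return pd.Series(dtype=float, name="r_sel")
    beta = matrix.beta.loc[candidates, pasi.index].to_numpy()
    y = pasi.to_numpy(dtype=float)
    yc = y - y.mean()
    xc = beta - beta.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = pd.Series(r, index=candidates, name="r_sel")
    return r[r.abs() > r_threshold]


def fit_score_model(
    matrix: MethylationMatrix,
    hc_samples: Sequence[str],
    selected: pd.Series,
    r_threshold: float = 0.8,
) -> ScoreModel:
    """Healthy-control reference (mean, SD with n-1 denominator, on the
    beta scale) for each selected probe; zero-SD probes are dropped."""
    if len(hc_samples) < 2:
        raise ValidationError("need >= 2 healthy-control samples")
    probes = list(selected.index)
    missing = [p for p in probes if p not in matrix.beta.index]
    if missing:
        raise ValidationError(f"selected probes absent from matrix: {missing[:5]}")
    hc = matrix.beta.loc[probes, list(hc_samples)]
    mean = hc.mean(axis=1).to_numpy()
    sd = hc.std(axis=1, ddof=1).to_numpy()
    keep = sd > 0
    for probe_id in np.asarray(probes)[~keep]:
        logger.warning("probe %s constant across HC; dropped from score", probe_id)
    return ScoreModel(
        probe_ids=list(np.asarray(probes)[keep]),
        mean_hc=mean[keep], sd_hc=sd[keep],
        r_sel=selected.to_numpy()[keep], r_threshold=r_threshold,
    )


def compute_scores(matrix: MethylationMatrix, model: ScoreModel) -> pd.Series:
    """Per-sample score: sum over selected probes of
    SV = (beta - mean_HC) / SD_HC."""
    missing = [p for p in model.probe_ids if p not in matrix.beta.index]
    if missing:
        raise ValidationError(f"score model probe missing from matrix: {missing[0]!r}")
    beta = matrix.beta.loc[model.probe_ids].to_numpy()
    sv = (beta - model.mean_hc[:, None]) / model.sd_hc[:, None]
    return pd.Series(sv.sum(axis=0), index=matrix.sample_ids, name="score")


def correlate_score_activity(scores: pd.Series, pasi: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation (r, two-sided p, n) between scores and PASI over
    the samples present in both; samples without PASI are excluded."""
    joined = pd.concat([scores.rename("score"), pasi.rename("pasi")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ValidationError("need >= 3 paired observations for a correlation")
    if joined["score"].std() == 0 or joined["pasi"].std() == 0:
        raise ValidationError("zero variance; correlation undefined")
    r, p = stats.pearsonr(joined["score"], joined["pasi"])
    return float(r), float(p), n


@dataclass
class ScoreResult:
    """Scores plus the score-PASI correlation and provenance flags."""

    model: ScoreModel
    scores: pd.Series
    r: float
    p: float
    n: int
    selection_sample_ids: list[str]
    evaluation_sample_ids: list[str]
    selection_overlaps_evaluation: bool = field(default=True)

    def summary(self) -> dict:
        return {
            "n_selected_probes": len(self.model.probe_ids),
            "r": self.r, "p": self.p, "n": self.n,
            "selection_overlaps_evaluation": self.selection_overlaps_evaluation,
        }


def run_activity_score(
    dmps: Sequence[DMPRecord],
    pathway_genes: set[str],
    matrix: MethylationMatrix,
    manifest: Manifest,
    sheet: SampleSheet,
    r_threshold: float = 0.8,
    selection_timepoint: Optional[str] = None,
) -> ScoreResult:
    """Full score chain: pathway restriction -> |r| filter -> HC
    standardization -> summed scores -> PASI correlation.

    ``selection_timepoint='before'`` restricts the selection correlation to
    before-treatment samples (held-out variant); the default uses every
    patient sample with a PASI value, and the result flags the resulting
    selection/evaluation overlap rather than hiding it.
    """
    patients = sheet.patient_samples_with_pasi(selection_timepoint)
    sel_pasi = patients.set_index("sample_id")["pasi"]
    selected = select_activity_dmps(dmps, pathway_genes, matrix, manifest,
                                    sel_pasi, r_threshold)
    if selected.empty:
        raise ValidationError("no probes passed the pathway + |r| selection")
    model = fit_score_model(matrix, sheet.samples_in_group("HC"), selected, r_threshold)
    scores = compute_scores(matrix, model)
    eval_pasi = sheet.patient_samples_with_pasi().set_index("sample_id")["pasi"]
    r, p, n = correlate_score_activity(scores, eval_pasi)
    overlap = bool(set(sel_pasi.index) & set(eval_pasi.index))
    return ScoreResult(
        model=model, scores=scores, r=r, p=p, n=n,
        selection_sample_ids=list(sel_pasi.index),
        evaluation_sample_ids=list(eval_pasi.index),
        selection_overlaps_evaluation=overlap,
    )
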