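"""Synthetic EPIC-like cohorts with known ground truth.

The generator emulates the structure of a small case/control methylation
study: three groups (healthy controls, skin psoriasis, psoriatic
arthritis), a subset of patients sampled before and after cytokine-blocker
treatment, planted differentially methylated probes and regions, additive
batch effects, and a set of "activity" CpGs whose methylation tracks a
latent skin-disease activity from which the PASI score is produced.

Generative model (per probe g, sample i, on the M scale):

    M_gi = logit2(beta_g) + group effect + batch offset + activity term
           + Normal(0, noise_sd_m)

with beta back-transformed and clipped into [0, 1].  Group and region
effects are specified as beta-scale differences and converted to M-scale
shifts at the probe's baseline, so beta stays bounded without ad-hoc
truncation.  PASI is an affine function of each patient's realized mean
beta over the activity CpGs with a negative coefficient, so hypomethylation
tracks higher disease activity; after-treatment samples have the activity
attenuated, so their scores recover toward the healthy-control level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Manifest, MethylationMatrix, ProbeAnnotation, SampleSheet, ValidationError,
)
from .preprocess import beta_to_m, m_to_beta

CONTRASTS = ("HC_vs_Pso", "HC_vs_PsA", "Pso_vs_PsA")


@dataclass
class CohortDesign:
    """Study-design knobs of the generator.

    Defaults mirror a small three-group cohort: 9 controls, 10 skin
    psoriasis and 7 psoriatic arthritis patients, with 5 treated subjects
    (4 Pso, 1 PsA) sampled before and after therapy; 1% of probes carry a
    planted group effect of |delta-beta| = 0.2, plus contiguous DMR blocks
    and 10 activity CpGs whose methylation falls with disease activity.
    """

    n_hc: int = 9
    n_pso: int = 10
    n_psa: int = 7
    n_paired_treated: int = 5
    n_probes: int = 5000
    chrom_layout: Optional[list[tuple[str, int, int]]] = None  # (chrom, n, mean bp spacing)
    frac_dmp: float = 0.01
    delta_beta_effect: float = 0.2
    dmr_blocks: Optional[list[tuple[str, int, int, float]]] = None  # (chrom, start idx, n, dbeta)
    n_batches: int = 2
    batch_shift_sd: float = 0.3          # M scale
    n_activity_cpgs: int = 10
    activity_slope: float = -0.015       # beta change per unit activity (PASI-like)
    treatment_attenuation: float = 0.15  # residual activity fraction after therapy
    pasi_noise_sd: float = 1.0
    noise_sd_m: float = 0.3
    n_noncpg_probes: int = 5
    n_snp_probes: int = 10
    n_crossreactive_probes: int = 10
    n_detection_fail: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValidationError("n_probes must be positive")
        if not 0 <= self.frac_dmp <= 1:
            raise ValidationError("frac_dmp must lie in [0,1]")
        if self.chrom_layout is None:
            half = self.n_probes // 2
            self.chrom_layout = [("chr1", half, 500), ("chr2", self.n_probes - half, 500)]
        self.chrom_layout = [(str(c), int(n), int(s)) for c, n, s in self.chrom_layout]
        if sum(n for _, n, _ in self.chrom_layout) != self.n_probes:
            raise ValidationError("chrom_layout probe counts must sum to n_probes")
        if self.dmr_blocks is None:
            # three 6-CpG blocks on the first chromosome, well separated
            self.dmr_blocks = []
            first_chrom, first_n, _ = self.chrom_layout[0]
            if self.delta_beta_effect != 0 and first_n >= 120:
                for frac in (0.1, 0.45, 0.8):
                    start = int(frac * first_n)
                    self.dmr_blocks.append(
                        (first_chrom, start, 6, self.delta_beta_effect))
        if sum(b[2] for b in self.dmr_blocks) > self.n_probes:
            raise ValidationError("DMR blocks exceed the number of probes")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        if "chrom_layout" in d and d["chrom_layout"] is not None:
            d["chrom_layout"] = [tuple(x) for x in d["chrom_layout"]]
        if "dmr_blocks" in d and d["dmr_blocks"] is not None:
            d["dmr_blocks"] = [tuple(x) for x in d["dmr_blocks"]]
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted effects, for parameter-recovery tests."""

    dmp_probe_ids: dict[str, list[str]]
    dmr_intervals: dict[str, list[tuple[str, int, int]]]
    dmr_probe_ids: dict[str, list[str]]
    batch_offsets: pd.DataFrame          # probes x batches, M scale
    activity_probe_ids: list[str]
    activity_genes: list[str]
    latent_activity: pd.Series           # per sample
    pasi: pd.Series                      # realized PASI per sample (NaN for HC)
    snp_probe_ids: list[str] = field(default_factory=list)
    crossreactive_probe_ids: list[str] = field(default_factory=list)
    detection_fail_probe_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "dmp_probe_ids": self.dmp_probe_ids,
            "dmr_intervals": {k: [list(iv) for iv in v]
                              for k, v in self.dmr_intervals.items()},
            "dmr_probe_ids": self.dmr_probe_ids,
            "batch_offsets": {
                "index": list(self.batch_offsets.index),
                "columns": list(self.batch_offsets.columns),
                "values": self.batch_offsets.to_numpy().tolist(),
            },
            "activity_probe_ids": self.activity_probe_ids,
            "activity_genes": self.activity_genes,
            "latent_activity": self.latent_activity.to_dict(),
            "pasi": {k: (None if pd.isna(v) else v) for k, v in self.pasi.items()},
            "snp_probe_ids": self.snp_probe_ids,
            "crossreactive_probe_ids": self.crossreactive_probe_ids,
            "detection_fail_probe_ids": self.detection_fail_probe_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        bo = d["batch_offsets"]
        return cls(
            dmp_probe_ids=d["dmp_probe_ids"],
            dmr_intervals={k: [tuple(iv) for iv in v]
                           for k, v in d["dmr_intervals"].items()},
            dmr_probe_ids=d["dmr_probe_ids"],
            batch_offsets=pd.DataFrame(bo["values"], index=bo["index"],
                                       columns=bo["columns"]),
            activity_probe_ids=d["activity_probe_ids"],
            activity_genes=d["activity_genes"],
            latent_activity=pd.Series(d["latent_activity"]),
            pasi=pd.Series({k: (np.nan if v is None else v)
                            for k, v in d["pasi"].items()}, dtype=float),
            snp_probe_ids=d["snp_probe_ids"],
            crossreactive_probe_ids=d["crossreactive_probe_ids"],
            detection_fail_probe_ids=d["detection_fail_probe_ids"],
        )


# ---------------------------------------------------------------------------
# manifest

def generate_manifest(design: CohortDesign) -> Manifest:
    """Probes sorted by position per chromosome, with gene/region labels
    spread roughly a third each over promoters, gene bodies and intergenic
    space, and island contexts assigned per probe cluster."""
    if not design.chrom_layout:
        raise ValidationError("chrom_layout must be nonempty")
    rng = np.random.default_rng([design.seed, 101])
    noncpg = set(rng.choice(design.n_probes, size=min(design.n_noncpg_probes,
                                                      design.n_probes), replace=False))
    probes: list[ProbeAnnotation] = []
    gene_counter = 0
    global_idx = 0
    for chrom, n, spacing in design.chrom_layout:
        pos = np.cumsum(rng.integers(max(2, spacing // 2), spacing * 2, size=n)) + 1000
        i = 0
        while i < n:
            run = int(rng.integers(4, 9))
            run = min(run, n - i)
            is_gene = rng.random() < 2.0 / 3.0
            context = rng.choice(["Island", "Shore", "Shelf", "OpenSea"],
                                 p=[0.20, 0.18, 0.10, 0.52])
            if is_gene:
                gene_counter += 1
                gene = f"G{gene_counter:05d}"
                labels = _gene_run_labels(run, rng)
            else:
                gene, labels = None, ["IGR"] * run
            for j in range(run):
                pid = (f"cg{global_idx:06d}" if global_idx not in noncpg
                       else f"ch.{global_idx:06d}")
                probe_type = "I" if rng.random() < 0.15 else "II"
                if gene is None:
                    genes, regions = (), ()
                else:
                    genes, regions = (gene,), (labels[j],)
                probes.append(ProbeAnnotation(
                    probe_id=pid, chrom=chrom, pos=int(pos[i + j]), strand="*",
                    probe_type=probe_type, genes=genes, gene_regions=regions,
                    island_context=str(context),
                ))
                global_idx += 1
            i += run
    return Manifest(probes, assembly="synthetic")


def _gene_run_labels(run: int, rng: np.random.Generator) -> list[str]:
    """Region labels along one gene's probe run: promoter labels first,
    a 3'UTR (or occasionally ExonBnd) last, Body in between."""
    labels = []
    promoter = ["TSS1500", "TSS200", "5UTR"]
    n_prom = min(run, int(rng.integers(1, 4)))
    labels.extend(promoter[:n_prom])
    while len(labels) < run - 1:
        labels.append("ExonBnd" if rng.random() < 0.05 else "Body")
    if len(labels) < run:
        labels.append("3UTR" if rng.random() < 0.6 else "Body")
    return labels[:run]


# ---------------------------------------------------------------------------
# cohort

def _sample_sheet(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_paired_pso = min(design.n_paired_treated, design.n_pso, 4) \
        if design.n_psa > 0 else min(design.n_paired_treated, design.n_pso)
    n_paired_psa = min(design.n_paired_treated - n_paired_pso, design.n_psa)

    for i in range(design.n_hc):
        rows.append(dict(sample_id=f"HC_{i+1}", subject_id=f"HC_{i+1}", group="HC",
                         timepoint="none", treatment="none"))
    for i in range(design.n_pso):
        subj = f"Pso_{i+1}"
        if i < n_paired_pso:
            trt = "antiTNF" if i % 2 == 0 else "antiIL17"
            rows.append(dict(sample_id=f"{subj}_before", subject_id=subj, group="Pso",
                             timepoint="before", treatment="none"))
            rows.append(dict(sample_id=f"{subj}_after", subject_id=subj, group="Pso",
                             timepoint="after", treatment=trt))
        else:
            rows.append(dict(sample_id=subj, subject_id=subj, group="Pso",
                             timepoint="none", treatment="none"))
    for i in range(design.n_psa):
        subj = f"PsA_{i+1}"
        if i < n_paired_psa:
            rows.append(dict(sample_id=f"{subj}_before", subject_id=subj, group="PsA",
                             timepoint="before", treatment="none"))
            rows.append(dict(sample_id=f"{subj}_after", subject_id=subj, group="PsA",
                             timepoint="after", treatment="antiTNF"))
        else:
            rows.append(dict(sample_id=subj, subject_id=subj, group="PsA",
                             timepoint="none", treatment="none"))
    frame = pd.DataFrame(rows)
    subjects = frame["subject_id"].unique()
    subj_sex = {s: str(rng.choice(["M", "F"])) for s in subjects}
    subj_age = {s: int(rng.integers(20, 70)) for s in subjects}
    frame["sex"] = frame["subject_id"].map(subj_sex)
    frame["age"] = frame["subject_id"].map(subj_age)
    frame["pasi"] = np.nan
    frame["batch"] = [f"batch_{(i % design.n_batches) + 1}" for i in range(len(frame))]
    return frame


def _m_shift_for_delta(beta0: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """M-scale shift realizing a target beta-scale difference at baseline
    beta0; targets outside [0.02, 0.98] are clipped with a warning."""
    target = np.asarray(beta0) + np.asarray(delta)
    clipped = np.clip(target, 0.02, 0.98)
    if np.any(np.abs(clipped - target) > 1e-12):
        warnings.warn("planted effect pushed beta outside [0.02, 0.98]; clipped")
    return beta_to_m(clipped) - beta_to_m(np.asarray(beta0))


def _effect_sign(beta0: float, rng: np.random.Generator) -> float:
    if beta0 > 0.75:
        return -1.0
    if beta0 < 0.25:
        return 1.0
    return float(rng.choice([-1.0, 1.0]))


def generate_cohort(
    design: CohortDesign, manifest: Manifest,
) -> tuple[MethylationMatrix, SampleSheet, SyntheticTruth]:
    """Simulate the beta matrix, sample sheet and ground truth."""
    rng = np.random.default_rng([design.seed, 202])
    sheet_frame = _sample_sheet(design, rng)
    sample_ids = list(sheet_frame["sample_id"])
    n_samples = len(sample_ids)
    probe_ids = manifest.probe_ids
    n_probes = len(probe_ids)
    index = pd.Index(probe_ids, name="probe_id")
    pos_of = {p.probe_id: p.pos for p in manifest}

    # trimodal baseline betas (low / intermediate / high methylation)
    component = rng.choice(3, size=n_probes, p=[0.35, 0.25, 0.40])
    baseline = np.empty(n_probes)
    baseline[component == 0] = rng.beta(2, 18, size=(component == 0).sum())
    baseline[component == 1] = rng.beta(12, 12, size=(component == 1).sum())
    baseline[component == 2] = rng.beta(18, 2, size=(component == 2).sum())
    baseline = np.clip(baseline, 0.02, 0.98)

    # --- choose planted probe sets (disjoint) --------------------------------
    blocks_by_contrast: dict[str, list[tuple[str, int, int]]] = {c: [] for c in CONTRASTS}
    dmr_probe_ids: dict[str, list[str]] = {c: [] for c in CONTRASTS}
    chrom_index: dict[str, list[str]] = {}
    for p in manifest:
        chrom_index.setdefault(p.chrom, []).append(p.probe_id)

    reserved: set[str] = set()
    dmr_members: list[tuple[list[str], float]] = []
    for chrom, start_idx, n_cpgs, dbeta in design.dmr_blocks:
        ids = chrom_index.get(chrom, [])
        if start_idx + n_cpgs > len(ids):
            raise ValidationError(f"DMR block exceeds probes on {chrom}")
        members = ids[start_idx:start_idx + n_cpgs]
        dmr_members.append((members, dbeta))
        reserved.update(members)
        interval = (chrom, pos_of[members[0]], pos_of[members[-1]])
        # blocks are planted in the Pso group: visible vs HC and vs PsA
        for contrast in ("HC_vs_Pso", "Pso_vs_PsA"):
            blocks_by_contrast[contrast].append(interval)
            dmr_probe_ids[contrast].extend(members)

    eligible = [p for p in probe_ids if p not in reserved and p.startswith("cg")]
    genic = [p for p in eligible if manifest[p].genes]
    activity_ids = [str(p) for p in rng.choice(
        genic, size=min(design.n_activity_cpgs, len(genic)),
        replace=False)] if design.n_activity_cpgs else []
    reserved.update(activity_ids)

    eligible = [p for p in eligible if p not in reserved]
    n_dmp = int(round(design.frac_dmp * n_probes))
    dmp_ids = [str(p) for p in rng.choice(eligible, size=min(n_dmp, len(eligible)),
                                          replace=False)]
    if design.n_psa == 0:
        pso_dmps, psa_dmps = dmp_ids, []
    elif design.n_pso == 0:
        pso_dmps, psa_dmps = [], dmp_ids
    else:
        half = len(dmp_ids) // 2
        pso_dmps, psa_dmps = dmp_ids[:half], dmp_ids[half:]
    dmp_by_contrast = {
        "HC_vs_Pso": sorted(pso_dmps),
        "HC_vs_PsA": sorted(psa_dmps),
        "Pso_vs_PsA": sorted(set(pso_dmps) | set(psa_dmps)),
    }

    # --- assemble M matrix ---------------------------------------------------
    loc = {p: i for i, p in enumerate(probe_ids)}

    # regions are direction-coherent: one sign per block, mid-range baselines
    # so the full effect fits inside [0, 1]
    block_signs: list[float] = []
    for members, dbeta in dmr_members:
        sign = -1.0 if dbeta < 0 else float(rng.choice([-1.0, 1.0]))
        block_signs.append(sign)
        block_base = float(rng.uniform(0.35, 0.6))
        for pid in members:
            baseline[loc[pid]] = float(np.clip(
                block_base + rng.normal(0.0, 0.03), 0.05, 0.95))

    M = beta_to_m(baseline)[:, None] + rng.normal(
        0.0, design.noise_sd_m, size=(n_probes, n_samples))

    group = sheet_frame["group"].to_numpy()
    is_pso = group == "Pso"
    is_psa = group == "PsA"
    for ids, affected in ((pso_dmps, is_pso), (psa_dmps, is_psa)):
        for pid in ids:
            g = loc[pid]
            sign = _effect_sign(baseline[g], rng)
            shift = _m_shift_for_delta(baseline[g], sign * design.delta_beta_effect)
            M[g, affected] += shift
    for (members, dbeta), sign in zip(dmr_members, block_signs):
        for pid in members:
            g = loc[pid]
            shift = _m_shift_for_delta(baseline[g], sign * abs(dbeta))
            M[g, is_pso] += shift

    # batch offsets
    batches = sheet_frame["batch"].to_numpy()
    batch_levels = list(dict.fromkeys(batches))
    offsets = pd.DataFrame(
        rng.normal(0.0, design.batch_shift_sd, size=(n_probes, len(batch_levels))),
        index=index, columns=batch_levels)
    if len(batch_levels) > 1:
        for b in batch_levels:
            M[:, batches == b] += offsets[b].to_numpy()[:, None]
    else:
        offsets.iloc[:, :] = 0.0

    # activity: latent disease activity drives hypomethylation at activity CpGs
    timepoint = sheet_frame["timepoint"].to_numpy()
    is_patient = group != "HC"
    latent = np.zeros(n_samples)
    subj_latent: dict[str, float] = {}
    for i, row in sheet_frame.iterrows():
        if row["group"] == "HC":
            continue
        base_l = subj_latent.setdefault(row["subject_id"], float(rng.uniform(8.0, 25.0)))
        latent[i] = base_l * (design.treatment_attenuation
                              if row["timepoint"] == "after" else 1.0)
    for pid in activity_ids:
        g = loc[pid]
        deltas = design.activity_slope * latent[is_patient]
        M[g, is_patient] += _m_shift_for_delta(
            np.full(is_patient.sum(), baseline[g]), deltas)

    beta = np.clip(m_to_beta(M), 0.0, 1.0)

    # realized PASI from mean beta over activity CpGs (negative coefficient:
    # hypomethylated activity CpGs <-> higher PASI)
    pasi = np.full(n_samples, np.nan)
    if activity_ids and design.activity_slope != 0:
        act_rows = [loc[p] for p in activity_ids]
        mean_beta_act = beta[act_rows].mean(axis=0)
        ref = float(baseline[act_rows].mean())
        raw = (mean_beta_act - ref) / design.activity_slope \
            + rng.normal(0.0, design.pasi_noise_sd, size=n_samples)
        pasi[is_patient] = np.maximum(0.0, raw[is_patient])
    else:
        pasi[is_patient] = np.maximum(
            0.0, latent[is_patient] + rng.normal(0.0, design.pasi_noise_sd,
                                                 size=int(is_patient.sum())))
    sheet_frame["pasi"] = pasi

    # detection p-values: near zero everywhere, a few planted failures
    detection = pd.DataFrame(
        rng.uniform(0.0, 1e-4, size=(n_probes, n_samples)),
        index=index, columns=sample_ids)
    cg_ids = [p for p in probe_ids if p not in reserved and p.startswith("cg")
              and p not in set(dmp_ids)]
    fail_ids = [str(p) for p in rng.choice(
        cg_ids, size=min(design.n_detection_fail, len(cg_ids)), replace=False)]
    for pid in fail_ids:
        col = int(rng.integers(n_samples))
        detection.loc[pid, sample_ids[col]] = float(rng.uniform(0.02, 0.9))
    remaining = [p for p in cg_ids if p not in set(fail_ids)]
    snp_ids = [str(p) for p in rng.choice(
        remaining, size=min(design.n_snp_probes, len(remaining)), replace=False)]
    remaining = [p for p in remaining if p not in set(snp_ids)]
    xreact_ids = [str(p) for p in rng.choice(
        remaining, size=min(design.n_crossreactive_probes, len(remaining)),
        replace=False)]

    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=index, columns=sample_ids), detection)
    sheet = SampleSheet(sheet_frame)
    activity_genes = sorted({g for p in activity_ids for g in manifest[p].genes})
    truth = SyntheticTruth(
        dmp_probe_ids=dmp_by_contrast,
        dmr_intervals=blocks_by_contrast,
        dmr_probe_ids={k: sorted(v) for k, v in dmr_probe_ids.items()},
        batch_offsets=offsets,
        activity_probe_ids=sorted(activity_ids),
        activity_genes=activity_genes,
        latent_activity=pd.Series(latent, index=sample_ids),
        pasi=pd.Series(pasi, index=sample_ids),
        snp_probe_ids=sorted(snp_ids),
        crossreactive_probe_ids=sorted(xreact_ids),
        detection_fail_probe_ids=sorted(fail_ids),
    )
    return matrix, sheet, truth


def generate_pathway_sets(
    manifest: Manifest,
    n_terms: int,
    include_activity_set: bool = False,
    activity_genes: Sequence[str] = (),
    seed: int = 0,
    set_size: tuple[int, int] = (5, 40),
) -> dict[str, set[str]]:
    """Random gene-set collection over the manifest's genes; with
    ``include_activity_set`` one extra set holds exactly the genes hosting
    the activity CpGs (an emulated cytokine-signaling pathway)."""
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    genes = sorted(manifest.genes())
    if not genes:
        raise ValidationError("manifest carries no gene labels")
    rng = np.random.default_rng([seed, 303])
    sets: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(set_size[0], min(set_size[1], len(genes)) + 1))
        sets[f"PW{t+1:04d}"] = set(rng.choice(genes, size=size, replace=False))
    if include_activity_set:
        if not activity_genes:
            raise ValidationError("include_activity_set requires activity_genes")
        sets["ACTIVITY_PATHWAY"] = set(activity_genes)
    return sets
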