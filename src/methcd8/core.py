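"""Shared data model for array methylation analysis.

The central objects are a probe-by-sample matrix of beta values (fraction
methylated, in [0, 1]), a probe manifest carrying genomic coordinates and
gene/CpG-island annotation, and a sample sheet describing the cohort
(group, treatment timepoint, batch, demographics, PASI skin score).

Coordinates are 1-based inclusive throughout (Illumina manifest convention);
BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

GENE_REGION_LABELS = ("TSS1500", "TSS200", "5UTR", "Body", "3UTR", "ExonBnd", "IGR")
PROMOTER_REGIONS = ("TSS1500", "TSS200", "5UTR")
ISLAND_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")
GROUPS = ("HC", "Pso", "PsA")
TIMEPOINTS = ("none", "before", "after")
TREATMENTS = ("none", "antiTNF", "antiIL17")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """Annotation of a single array probe.

    ``genes`` and ``gene_regions`` are parallel: probe i of a gene carries
    the gene-region label (TSS1500/TSS200/5UTR/Body/3UTR/ExonBnd) of its
    position relative to that gene.  Intergenic probes (label IGR) carry an
    empty gene list.
    """

    probe_id: str
    chrom: str
    pos: int
    strand: str = "*"
    probe_type: str = "II"
    genes: tuple[str, ...] = ()
    gene_regions: tuple[str, ...] = ()
    island_context: str = "OpenSea"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id}: pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-", "*"):
            raise ValidationError(f"probe {self.probe_id}: bad strand {self.strand!r}")
        if self.probe_type not in ("I", "II"):
            raise ValidationError(f"probe {self.probe_id}: probe_type must be I or II")
        if len(self.genes) != len(self.gene_regions):
            raise ValidationError(
                f"probe {self.probe_id}: genes and gene_regions differ in length"
            )
        for region in self.gene_regions:
            if region not in GENE_REGION_LABELS:
                raise ValidationError(
                    f"probe {self.probe_id}: unknown gene region label {region!r}"
                )
            if region == "IGR":
                raise ValidationError(
                    f"probe {self.probe_id}: IGR probes carry an empty gene list"
                )
        if self.island_context not in ISLAND_CONTEXTS:
            raise ValidationError(
                f"probe {self.probe_id}: unknown island context {self.island_context!r}"
            )

    @property
    def is_intergenic(self) -> bool:
        return len(self.genes) == 0


class Manifest:
    """Ordered, uniquely keyed collection of :class:`ProbeAnnotation`."""

    def __init__(self, probes: Sequence[ProbeAnnotation], assembly: str = "unknown"):
        self.probes: list[ProbeAnnotation] = list(probes)
        self.assembly = assembly
        self.by_id: dict[str, ProbeAnnotation] = {}
        for p in self.probes:
            if p.probe_id in self.by_id:
                raise ValidationError(f"duplicate probe_id in manifest: {p.probe_id}")
            self.by_id[p.probe_id] = p

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[ProbeAnnotation]:
        return iter(self.probes)

    def __getitem__(self, probe_id: str) -> ProbeAnnotation:
        return self.by_id[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.by_id

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def genes(self) -> set[str]:
        """All gene symbols annotated anywhere on the manifest."""
        out: set[str] = set()
        for p in self.probes:
            out.update(p.genes)
        return out

    def subset(self, probe_ids: Sequence[str]) -> "Manifest":
        keep = set(probe_ids)
        return Manifest([p for p in self.probes if p.probe_id in keep], self.assembly)


class MethylationMatrix:
    """Probes x samples beta-value matrix with optional detection p-values."""

    def __init__(self, beta: pd.DataFrame, detection_p: Optional[pd.DataFrame] = None):
        if beta.index.has_duplicates:
            dup = beta.index[beta.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if beta.columns.has_duplicates:
            dup = beta.columns[beta.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        values = beta.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("beta matrix contains non-numeric values")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing beta value at probe {beta.index[r]!r}, sample {beta.columns[c]!r}"
            )
        if (values < 0).any() or (values > 1).any():
            r, c = np.argwhere((values < 0) | (values > 1))[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {beta.index[r]!r}, "
                f"sample {beta.columns[c]!r}: {values[r, c]}"
            )
        if detection_p is not None:
            if detection_p.shape != beta.shape:
                raise ValidationError("detection_p shape differs from beta shape")
            detection_p = detection_p.reindex(index=beta.index, columns=beta.columns)
            dv = detection_p.to_numpy()
            if np.isnan(dv).any() or (dv < 0).any() or (dv > 1).any():
                raise ValidationError("detection_p values must lie in [0,1]")
        self.beta = beta.astype(float)
        self.detection_p = detection_p

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        dp = self.detection_p.loc[probe_ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta.loc[probe_ids], dp)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        dp = self.detection_p[sample_ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta[list(sample_ids)], dp)


SAMPLE_SHEET_COLUMNS = [
    "sample_id", "subject_id", "group", "timepoint", "treatment",
    "sex", "age", "pasi", "batch",
]


class SampleSheet:
    """Cohort description: one row per array sample.

    Healthy controls carry timepoint "none" and no PASI; before/after pairs
    of a treated patient share a subject_id.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        frame = frame[SAMPLE_SHEET_COLUMNS].copy()
        frame["pasi"] = pd.to_numeric(frame["pasi"], errors="coerce")
        frame["age"] = pd.to_numeric(frame["age"], errors="raise")
        if frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        for col, allowed in (
            ("group", GROUPS), ("timepoint", TIMEPOINTS), ("treatment", TREATMENTS)
        ):
            bad = set(frame[col]) - set(allowed)
            if bad:
                raise ValidationError(f"sample sheet: invalid {col} values {sorted(bad)}")
        hc = frame[frame["group"] == "HC"]
        if (hc["timepoint"] != "none").any():
            raise ValidationError("HC samples must have timepoint 'none'")
        if hc["pasi"].notna().any():
            raise ValidationError("HC samples must not carry a PASI score")
        if (frame.loc[frame["pasi"].notna(), "pasi"] < 0).any():
            raise ValidationError("PASI must be non-negative")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def patient_samples_with_pasi(self, timepoint: Optional[str] = None) -> pd.DataFrame:
        f = self.frame[self.frame["pasi"].notna()]
        if timepoint is not None:
            f = f[f["timepoint"] == timepoint]
        return f

    def paired_subjects(self) -> list[str]:
        """Subjects with both a before and an after treatment sample."""
        f = self.frame
        before = set(f.loc[f["timepoint"] == "before", "subject_id"])
        after = set(f.loc[f["timepoint"] == "after", "subject_id"])
        return sorted(before & after)

    def batches(self) -> pd.Series:
        return self.frame.set_index("sample_id")["batch"]


@dataclass
class AnalysisConfig:
    """Thresholds and tuning parameters of the pipeline."""

    fdr_threshold: float = 0.05
    min_delta_beta: float = 0.1
    dmr_min_cpgs: tuple[int, ...] = (5, 10, 20)
    dmr_lambda: float = 1000.0
    dmr_scaling_C: float = 2.0
    detection_p_cutoff: float = 0.01
    score_r_threshold: float = 0.8
    enrichment_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "detection_p_cutoff", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0,1), got {v}")
        if not 0 < self.min_delta_beta < 1:
            raise ValidationError("min_delta_beta must lie in (0,1)")
        if not 0 < self.score_r_threshold < 1:
            raise ValidationError("score_r_threshold must lie in (0,1)")
        self.dmr_min_cpgs = tuple(int(k) for k in self.dmr_min_cpgs)
        if any(k < 2 for k in self.dmr_min_cpgs):
            raise ValidationError("dmr_min_cpgs entries must be >= 2")
        if self.dmr_lambda <= 0 or self.dmr_scaling_C <= 0:
            raise ValidationError("dmr_lambda and dmr_scaling_C must be positive")


@dataclass(frozen=True)
class DMPRecord:
    """Per-probe differential methylation call between two groups (a vs b)."""

    probe_id: str
    mean_beta_a: float
    mean_beta_b: float
    delta_beta: float          # mean_beta_b - mean_beta_a
    t_mod: float
    df_total: float
    p: float
    fdr: float
    direction: str             # 'hyper' if group b more methylated, else 'hypo'


@dataclass(frozen=True)
class DMRRecord:
    """A differentially methylated region: a run of significant CpGs."""

    chrom: str
    start: int                 # 1-based inclusive
    end: int
    n_cpgs: int
    stouffer: float
    hmfdr: float
    fisher: float
    maxdiff: float             # signed delta-beta of the largest-|delta-beta| probe
    meandiff: float
    genes: tuple[str, ...]
    probe_ids: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"DMR end < start ({self.chrom}:{self.start}-{self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScoreModel:
    """Healthy-control reference defining the methylation activity score.

    Each selected probe j contributes SV_ij = (beta_ij - mean_HC_j) / SD_HC_j
    to sample i's score.
    """

    probe_ids: list[str]
    mean_hc: np.ndarray
    sd_hc: np.ndarray
    r_sel: np.ndarray
    r_threshold: float

    def __post_init__(self) -> None:
        self.mean_hc = np.asarray(self.mean_hc, dtype=float)
        self.sd_hc = np.asarray(self.sd_hc, dtype=float)
        self.r_sel = np.asarray(self.r_sel, dtype=float)
        n = len(self.probe_ids)
        if not (len(self.mean_hc) == len(self.sd_hc) == len(self.r_sel) == n):
            raise ValidationError("ScoreModel arrays must match probe_ids length")
        if (self.sd_hc <= 0).any():
            raise ValidationError("ScoreModel SD_HC must be positive")
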