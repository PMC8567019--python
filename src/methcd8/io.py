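"""Readers and writers for the delimited-text formats of the pipeline.

CSV vs TSV is autodetected from the file extension (.csv -> comma,
anything else -> tab).  All round trips are lossless: exact for text,
within formatting precision for reals (17 significant digits are written).
"""

from __future__ import annotations

import math
import os
from dataclasses import asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DMPRecord,
    DMRRecord,
    Manifest,
    MethylationMatrix,
    ProbeAnnotation,
    SampleSheet,
    SAMPLE_SHEET_COLUMNS,
    ValidationError,
)

_FLOAT_FMT = "%.17g"


def _sep(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


class ParseError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


# ---------------------------------------------------------------------------
# beta matrices

def read_beta_matrix(path: str, detection_p_path: Optional[str] = None) -> MethylationMatrix:
    """Read a probes x samples beta matrix (header = sample ids, first
    column = probe ids).  Values must parse as reals in [0, 1]."""
    frame = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: malformed numeric cell at probe {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r}: {frame.iat[r, c]!r}"
        )
    detection = None
    if detection_p_path is not None:
        detection = pd.read_csv(detection_p_path, sep=_sep(detection_p_path), index_col=0)
    return MethylationMatrix(numeric, detection)


def write_beta_matrix(matrix: MethylationMatrix, path: str) -> None:
    matrix.beta.to_csv(path, sep=_sep(path), float_format=_FLOAT_FMT, index_label="probe_id")


def write_detection_p(matrix: MethylationMatrix, path: str) -> None:
    if matrix.detection_p is None:
        raise ValidationError("matrix carries no detection p-values")
    matrix.detection_p.to_csv(path, sep=_sep(path), float_format=_FLOAT_FMT,
                              index_label="probe_id")


# ---------------------------------------------------------------------------
# manifests

_MANIFEST_COLUMNS = [
    "probe_id", "chrom", "pos", "strand", "probe_type",
    "genes", "gene_regions", "island_context",
]


def read_manifest(path: str, assembly: str = "unknown") -> Manifest:
    frame = pd.read_csv(path, sep=_sep(path), dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    probes = []
    for row in frame.itertuples(index=False):
        try:
            pos = int(row.pos)
        except ValueError:
            raise ParseError(f"{path}: non-integer position {row.pos!r} for {row.probe_id}")
        genes = tuple(g for g in str(row.genes).split(";") if g)
        regions = tuple(r for r in str(row.gene_regions).split(";") if r and r != "IGR")
        probes.append(ProbeAnnotation(
            probe_id=row.probe_id, chrom=row.chrom, pos=pos, strand=row.strand or "*",
            probe_type=row.probe_type, genes=genes, gene_regions=regions,
            island_context=row.island_context,
        ))
    return Manifest(probes, assembly=assembly)


def write_manifest(manifest: Manifest, path: str) -> None:
    rows = []
    for p in manifest:
        rows.append({
            "probe_id": p.probe_id, "chrom": p.chrom, "pos": p.pos, "strand": p.strand,
            "probe_type": p.probe_type, "genes": ";".join(p.genes),
            "gene_regions": ";".join(p.gene_regions), "island_context": p.island_context,
        })
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# sample sheets and exclusion lists

def read_sample_sheet(path: str) -> SampleSheet:
    frame = pd.read_csv(path, sep=_sep(path), dtype=str)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    sheet.frame.to_csv(path, sep=_sep(path), index=False, float_format="%.10g")


def read_exclusion_list(path: str) -> list[str]:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_exclusion_list(ids: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for probe_id in ids:
            fh.write(f"{probe_id}\n")


# ---------------------------------------------------------------------------
# result tables

def write_dmp_table(dmps: Sequence[DMPRecord], path: str) -> None:
    frame = pd.DataFrame([asdict(d) for d in dmps], columns=[
        "probe_id", "mean_beta_a", "mean_beta_b", "delta_beta",
        "t_mod", "df_total", "p", "fdr", "direction",
    ])
    frame.to_csv(path, sep=_sep(path), index=False, float_format=_FLOAT_FMT)


def read_dmp_table(path: str) -> list[DMPRecord]:
    frame = pd.read_csv(path, sep=_sep(path))
    return [DMPRecord(**row) for row in frame.to_dict(orient="records")]


def write_dmr_table(dmrs: Sequence[DMRRecord], path: str) -> None:
    rows = []
    for d in dmrs:
        rows.append({
            "chrom": d.chrom, "start": d.start, "end": d.end, "width": d.width,
            "strand": "*", "n_cpgs": d.n_cpgs, "stouffer": d.stouffer,
            "hmfdr": d.hmfdr, "fisher": d.fisher, "maxdiff": d.maxdiff,
            "meandiff": d.meandiff, "genes": ";".join(d.genes),
            "probe_ids": ";".join(d.probe_ids),
        })
    cols = ["chrom", "start", "end", "width", "strand", "n_cpgs", "stouffer",
            "hmfdr", "fisher", "maxdiff", "meandiff", "genes", "probe_ids"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep(path), index=False,
                                            float_format=_FLOAT_FMT)


def read_dmr_table(path: str) -> list[DMRRecord]:
    frame = pd.read_csv(path, sep=_sep(path)).fillna("")
    out = []
    for row in frame.to_dict(orient="records"):
        out.append(DMRRecord(
            chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
            n_cpgs=int(row["n_cpgs"]), stouffer=float(row["stouffer"]),
            hmfdr=float(row["hmfdr"]), fisher=float(row["fisher"]),
            maxdiff=float(row["maxdiff"]), meandiff=float(row["meandiff"]),
            genes=tuple(g for g in str(row["genes"]).split(";") if g),
            probe_ids=tuple(p for p in str(row.get("probe_ids", "")).split(";") if p),
        ))
    return out


def export_dmrs_bed(dmrs: Sequence[DMRRecord], path: str) -> None:
    """Write DMRs as BED6 (0-based half-open).

    The score column is -10*log10(Fisher combined p), capped at 1000; the
    name column joins overlapping genes with ';' ('.' when intergenic).
    """
    with open(path, "w") as fh:
        fh.write("# BED6 export: chrom start end genes score strand\n")
        for d in dmrs:
            if d.fisher <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * math.log10(d.fisher))))
            name = ";".join(d.genes) if d.genes else "."
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{name}\t{score}\t*\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT format: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for term in sets:
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def file_digest(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
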