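"""Functional genomic distribution of DMPs, set overlaps, and
hypergeometric over-representation analysis.

Gene-region classification of a probe uses the precedence
promoter (TSS1500/TSS200/5UTR) > 3'UTR > ExonBnd > Body > IGR, so each
probe contributes exactly once to the distribution table and the
percentages on each axis sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DMPRecord, Manifest, PROMOTER_REGIONS, ValidationError

REGION_CLASSES = ("promoter", "3UTR", "ExonBnd", "Body", "IGR")
ISLAND_CLASSES = ("Island", "Shore", "Shelf", "OpenSea")


def classify_gene_region(ann) -> str:
    """Single-label gene-region class of a probe (precedence above)."""
    regions = set(ann.gene_regions)
    if regions & set(PROMOTER_REGIONS):
        return "promoter"
    if "3UTR" in regions:
        return "3UTR"
    if "ExonBnd" in regions:
        return "ExonBnd"
    if "Body" in regions:
        return "Body"
    return "IGR"


def genes_with_promoter_dmp(dmps: Sequence[DMPRecord], manifest: Manifest,
                            include_body: bool = False) -> set[str]:
    """Genes carrying at least one DMP in their promoter (TSS1500, TSS200,
    5'UTR); with ``include_body`` also gene-body DMPs qualify."""
    qualifying = set(PROMOTER_REGIONS) | ({"Body"} if include_body else set())
    out: set[str] = set()
    for dmp in dmps:
        ann = manifest[dmp.probe_id]
        for gene, region in zip(ann.genes, ann.gene_regions):
            if region in qualifying:
                out.add(gene)
    return out


def distribution_table(dmps: Sequence[DMPRecord], manifest: Manifest) -> pd.DataFrame:
    """Percentages of DMPs per gene-region class and per CpG-island class,
    split by all / hypermethylated / hypomethylated.

    Returns a frame indexed by (axis, class) with columns all/hyper/hypo;
    percentages within one (axis, split) sum to 100 whenever the split is
    non-empty.
    """
    if not dmps:
        raise ValidationError("distribution_table needs at least one DMP")
    rows = []
    for dmp in dmps:
        if dmp.probe_id not in manifest:
            raise ValidationError(f"unknown probe id {dmp.probe_id!r}")
        ann = manifest[dmp.probe_id]
        rows.append((classify_gene_region(ann), ann.island_context, dmp.direction))
    frame = pd.DataFrame(rows, columns=["region", "island", "direction"])

    out = {}
    for split in ("all", "hyper", "hypo"):
        sub = frame if split == "all" else frame[frame["direction"] == split]
        n = len(sub)
        col = {}
        for cls in REGION_CLASSES:
            col[("gene_region", cls)] = 100.0 * (sub["region"] == cls).sum() / n if n else np.nan
        for cls in ISLAND_CLASSES:
            col[("island", cls)] = 100.0 * (sub["island"] == cls).sum() / n if n else np.nan
        out[split] = col
    table = pd.DataFrame(out)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["axis", "class"])
    return table


def overlap_sets(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive-region counts of the inclusion-exclusion lattice.

    For every non-empty combination of set names, the count of elements
    belonging to exactly those sets (Venn-diagram regions); region counts
    sum back to the size of each input set.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("overlap_sets needs >= 2 sets")
    universe = set().union(*sets.values())
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            counts[frozenset(combo)] = len(inside)
    return counts


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term of an over-representation test.

    k of the n query genes fall in the term (which has K members among the
    N universe genes); p is the hypergeometric upper tail P(X >= k).
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_bonferroni: float
    significant: bool


def hypergeometric_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, set],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of each gene set in the query, against the
    supplied universe, with Bonferroni correction over the tested terms.

    Terms are intersected with the universe before testing; the query must
    be a subset of the universe.  Records are sorted by p ascending.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    query = set(query)
    if not query <= universe:
        raise ValidationError(
            f"query genes outside the universe: {sorted(query - universe)[:5]}")
    n, N = len(query), len(universe)
    n_terms = len(gene_sets)
    records = []
    for term, members in gene_sets.items():
        term_genes = set(members) & universe
        K = len(term_genes)
        k = len(query & term_genes)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        p_bonf = min(1.0, p * n_terms)
        records.append(EnrichmentRecord(
            term_id=term, term_name=term, k=k, K=K, n=n, N=N,
            p=p, p_bonferroni=p_bonf, significant=p_bonf < alpha,
        ))
    records.sort(key=lambda r: (r.p, r.term_id))
    return records


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p": r.p, "p_bonferroni": r.p_bonferroni, "significant": r.significant,
    } for r in records])
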