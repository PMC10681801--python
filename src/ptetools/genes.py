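"""Target-gene assignment and transcription-group summaries.

Each PTE is assigned one likely target gene from the nearest transcription
start sites (TSS) to its left and right, using H3K27me3 status around the
TSS to arbitrate:

* if the closer TSS is H3K27me3-enriched, its gene is the target
  (``closer_tss_k27``);
* if only the farther TSS is enriched, that gene is the target
  (``farther_tss_k27``);
* if neither is enriched, the closer gene is the target
  (``no_k27_closest``).

A TSS counts as H3K27me3-enriched when a window around it (default
+-1 kb, promoter scale) overlaps a significant H3K27me3 region.  Genes are
also binned into transcription groups G1-G4 (quartiles of RNA counts over
the full gene universe, G1 lowest; ties share the lower group).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneRecord, GenomicInterval

__all__ = [
    "TargetAssignment",
    "assign_target",
    "assign_targets",
    "gene_pte_summary",
    "transcription_groups",
    "cross_cellline_overlap",
]


@dataclass(frozen=True)
class TargetAssignment:
    pte_id: str
    chrom: str
    position: int
    gene_id: str | None
    distance: int | None  # peak position to TSS, bp
    category: str  # closer_tss_k27 | farther_tss_k27 | no_k27_closest | unassigned


def _tss_enriched(
    chrom: str,
    tss: int,
    k27_regions: Sequence[GenomicInterval],
    window: int,
) -> bool:
    probe = GenomicInterval(chrom, max(0, tss - window), tss + window)
    return any(probe.overlaps(r) for r in k27_regions if r.chrom == chrom)


def assign_target(
    chrom: str,
    position: int,
    genes: Sequence[GeneRecord],
    k27_regions: Sequence[GenomicInterval],
    tss_window: int = 1_000,
    pte_id: str = "",
) -> TargetAssignment:
    """Assign the likely target gene of one PTE position.

    Finds the nearest TSS at or left of the position and the nearest TSS to
    its right, checks their H3K27me3 status, and applies the decision rule
    described in the module docstring.  With no TSS on the chromosome the
    PTE is reported unassigned.
    """
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        return TargetAssignment(pte_id, chrom, position, None, None, "unassigned")
    left = [g for g in on_chrom if g.tss <= position]
    right = [g for g in on_chrom if g.tss > position]
    cand: list[GeneRecord] = []
    if left:
        cand.append(max(left, key=lambda g: g.tss))
    if right:
        cand.append(min(right, key=lambda g: g.tss))
    cand.sort(key=lambda g: abs(g.tss - position))
    closer = cand[0]
    farther = cand[1] if len(cand) > 1 else None
    closer_k27 = _tss_enriched(chrom, closer.tss, k27_regions, tss_window)
    if closer_k27:
        chosen, cat = closer, "closer_tss_k27"
    elif farther is not None and _tss_enriched(
        chrom, farther.tss, k27_regions, tss_window
    ):
        chosen, cat = farther, "farther_tss_k27"
    else:
        chosen, cat = closer, "no_k27_closest"
    return TargetAssignment(
        pte_id, chrom, position, chosen.gene_id, abs(chosen.tss - position), cat
    )


def assign_targets(
    peaks: pd.DataFrame,
    genes: Sequence[GeneRecord],
    k27_regions: Sequence[GenomicInterval],
    tss_window: int = 1_000,
) -> pd.DataFrame:
    """Vector version of :func:`assign_target` over a consensus-peak table.

    Every input peak appears in the output exactly once, assigned or
    explicitly ``unassigned`` (conservation of inputs).
    """
    rows = []
    for i, r in enumerate(peaks.itertuples()):
        a = assign_target(
            r.chrom, int(r.position), genes, k27_regions, tss_window,
            pte_id=f"pte{i:04d}",
        )
        rows.append(
            (a.pte_id, a.chrom, a.position, a.gene_id, a.distance, a.category)
        )
    return pd.DataFrame(
        rows,
        columns=["pte_id", "chrom", "position", "gene_id", "distance", "category"],
    )


def gene_pte_summary(assignments: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-gene PTE counts and cohort summaries.

    Returns a per-gene table (PTE count, min distance, categories) and a
    dictionary of cohort statistics: number of target genes, fraction of
    genes with more than one PTE, and quartiles of the per-gene minimum
    PTE-TSS distance.
    """
    assigned = assignments.dropna(subset=["gene_id"])
    if assigned.empty:
        return (
            pd.DataFrame(
                columns=["gene_id", "n_ptes", "min_distance", "categories"]
            ),
            {"n_target_genes": 0, "fraction_multi_pte": float("nan")},
        )
    per_gene = (
        assigned.groupby("gene_id")
        .agg(
            n_ptes=("pte_id", "size"),
            min_distance=("distance", "min"),
            categories=("category", lambda c: ",".join(sorted(set(c)))),
        )
        .reset_index()
    )
    stats = {
        "n_target_genes": int(len(per_gene)),
        "fraction_multi_pte": float((per_gene["n_ptes"] > 1).mean()),
        "median_min_distance": float(per_gene["min_distance"].median()),
        "distance_q1": float(per_gene["min_distance"].quantile(0.25)),
        "distance_q3": float(per_gene["min_distance"].quantile(0.75)),
    }
    return per_gene, stats


def transcription_groups(counts: pd.DataFrame) -> pd.DataFrame:
    """Quartile transcription groups G1-G4 over the full gene universe.

    ``counts`` needs columns ``gene_id`` and ``count``.  Genes are ranked by
    count; rank quartiles map to G1 (lowest) through G4 (highest) with
    sizes balanced within one.  Tied counts share the group of their lowest
    member, so an all-zero universe is entirely G1.
    """
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    n = len(counts)
    out = counts.copy()
    c = out["count"].to_numpy()
    order = np.argsort(c, kind="stable")
    ordinal = np.empty(n, dtype=int)
    ordinal[order] = np.arange(n)
    # min-rank for ties: every member of a tie takes the smallest ordinal
    first_of_value = pd.Series(ordinal).groupby(c).transform("min").to_numpy()
    out["group"] = [f"G{r * 4 // n + 1}" for r in first_of_value]
    return out


def cross_cellline_overlap(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    groups_a: pd.DataFrame | None = None,
    groups_b: pd.DataFrame | None = None,
) -> tuple[float, pd.DataFrame | None]:
    """Overlap of PTE target-gene sets between two cell lines.

    The overlap fraction is |A ∩ B| divided by the size of the *smaller*
    set — the convention answers "what fraction of the smaller cohort is
    recovered in the other".  When per-gene transcription groups are given
    for both lines, a G-group transition table (Sankey-style counts) over
    the common genes is returned as well.
    """
    set_a, set_b = set(genes_a), set(genes_b)
    if not set_a or not set_b:
        return 0.0, None
    common = set_a & set_b
    fraction = len(common) / min(len(set_a), len(set_b))
    table = None
    if groups_a is not None and groups_b is not None:
        ga = groups_a.set_index("gene_id")["group"]
        gb = groups_b.set_index("gene_id")["group"]
        rows = [(ga[g], gb[g]) for g in sorted(common) if g in ga and g in gb]
        if rows:
            df = pd.DataFrame(rows, columns=["group_a", "group_b"])
            table = (
                df.groupby(["group_a", "group_b"]).size().unstack(fill_value=0)
            )
    return fraction, table
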