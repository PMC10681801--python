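"""Bound-region scoring, replicate concordance and standalone PRC2 regions.

A significantly enriched region (e.g. broad-caller output) is scored by its
*summit window*: the fixed-width (default 1000 bp) sub-window with the
largest signal sum; that sum is the region's binding score.  Regions are
kept only when the summit window is also significantly enriched in the
other replicate.  "Standalone" PRC2 regions are SUZ12 regions that overlap
an H3K27me3 region (catalytically active PRC2) but lie farther than a
configured distance from any significant MEL18 region — 100 kb for the
strict definition, 10 kb for the permissive one; the distance is a
parameter of the same operation.

A simplified significance caller (Poisson test of window sums against the
input track, Benjamini-Hochberg corrected) is included as a stand-in so the
pipeline is self-contained; it is deliberately minimal plumbing, not a
re-implementation of a production broad-peak caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import CoverageTrack, GenomicInterval

__all__ = [
    "RegionParams",
    "BoundRegion",
    "summit_score",
    "concordant_regions",
    "group_regions",
    "standalone_prc2_regions",
    "call_enriched_regions",
]


@dataclass(frozen=True)
class RegionParams:
    summit_window_bp: int = 1_000
    group_gap_bp: int = 100_000
    standalone_distance_bp: int = 100_000
    min_region_len: int = 1_000

    def __post_init__(self) -> None:
        for name in (
            "summit_window_bp",
            "group_gap_bp",
            "standalone_distance_bp",
            "min_region_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BoundRegion:
    """An enriched interval with its summit window and binding score(s)."""

    interval: GenomicInterval
    summit_window: GenomicInterval
    binding_score: float
    replicate_id: str | None = None
    score_rep1: float | None = None
    score_rep2: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def summit_score(
    region: GenomicInterval,
    track: CoverageTrack,
    params: RegionParams = RegionParams(),
    replicate_id: str | None = None,
) -> BoundRegion:
    """Maximal-sum window of width ``summit_window_bp`` inside the region.

    Ties are broken by the leftmost window.  Regions shorter than the window
    use the whole region as their summit window.
    """
    values = track.values(region)
    w = min(params.summit_window_bp, len(values))
    if w < 1:
        raise ValueError("region must span at least 1 bp")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    sums = csum[w:] - csum[:-w]
    best = int(np.argmax(sums))  # argmax returns the first (leftmost) maximum
    window = GenomicInterval(region.chrom, region.start + best, region.start + best + w)
    return BoundRegion(region, window, float(sums[best]), replicate_id)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or touching intervals merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def concordant_regions(
    regions_rep1: Sequence[GenomicInterval],
    regions_rep2: Sequence[GenomicInterval],
    track_rep1: CoverageTrack,
    track_rep2: CoverageTrack,
    params: RegionParams = RegionParams(),
) -> list[BoundRegion]:
    """Regions whose summit window is significantly enriched in both replicates.

    A replicate-1 region is kept iff its summit window (found on the
    replicate-1 track) overlaps a significant replicate-2 region, and
    symmetrically.  The kept intervals from both replicates are merged into
    one region set; each merged region is re-summited on the replicate-mean
    track and scored on each replicate over that summit window.
    """
    kept: list[GenomicInterval] = []
    for regions, track, others in (
        (regions_rep1, track_rep1, regions_rep2),
        (regions_rep2, track_rep2, regions_rep1),
    ):
        for region in regions:
            br = summit_score(region, track, params)
            if any(br.summit_window.overlaps(o) for o in others):
                kept.append(region)
    merged = merge_intervals(kept)
    mean_track = track_rep1.mean_with(track_rep2)
    out = []
    for region in merged:
        br = summit_score(region, mean_track, params)
        w = br.summit_window
        s1 = float(np.sum(track_rep1.values(w)))
        s2 = float(np.sum(track_rep2.values(w)))
        out.append(
            BoundRegion(region, w, (s1 + s2) / 2.0, "merged", s1, s2)
        )
    return out


def group_regions(
    regions: Sequence[BoundRegion | GenomicInterval],
    params: RegionParams = RegionParams(),
) -> list[list[BoundRegion | GenomicInterval]]:
    """Single-linkage chaining: regions closer than ``group_gap_bp`` join a
    group; groups never span chromosomes.  Input must be position-sorted."""
    groups: list[list] = []
    prev: GenomicInterval | None = None
    for r in regions:
        iv = r.interval if isinstance(r, BoundRegion) else r
        if (
            prev is not None
            and iv.chrom == prev.chrom
            and iv.start - prev.end <= params.group_gap_bp
        ):
            groups[-1].append(r)
            if iv.end > prev.end:
                prev = GenomicInterval(iv.chrom, prev.start, iv.end)
        else:
            groups.append([r])
            prev = iv
    return groups


def standalone_prc2_regions(
    suz12_regions: Sequence[GenomicInterval],
    k27_regions: Sequence[GenomicInterval],
    mel18_regions: Sequence[GenomicInterval],
    params: RegionParams = RegionParams(),
    distance_bp: int | None = None,
) -> list[GenomicInterval]:
    """SUZ12 regions bound by catalytically active PRC2 and MEL18-free.

    A SUZ12 region qualifies when it overlaps at least one H3K27me3 region
    and its nearest significant MEL18 region is farther than ``distance_bp``
    (edge-to-edge; overlap counts as distance 0).  Use 100 kb (default) for
    the strict standalone definition and 10 kb for the permissive census.
    """
    if distance_bp is None:
        distance_bp = params.standalone_distance_bp
    out = []
    for s in suz12_regions:
        if not any(s.overlaps(k) for k in k27_regions if k.chrom == s.chrom):
            continue
        dmin = min(
            (s.distance(m) for m in mel18_regions if m.chrom == s.chrom),
            default=None,
        )
        if dmin is None or dmin > distance_bp:
            out.append(s)
    return out


def call_enriched_regions(
    track: CoverageTrack,
    input_track: CoverageTrack,
    bin_size: int = 200,
    q_threshold: float = 0.05,
    merge_gap: int = 400,
    min_length: int = 1_000,
    pseudocount: float = 0.25,
) -> list[GenomicInterval]:
    """Simplified significant-region caller (stand-in plumbing).

    Tiles the genome in ``bin_size`` windows, tests each window's signal sum
    against a Poisson expectation from the input track (floored at the
    genome-wide mean), corrects with Benjamini-Hochberg, merges significant
    bins closer than ``merge_gap`` and keeps merged regions of at least
    ``min_length`` bp.  This is deliberately minimal — it exists so the
    pipeline runs end-to-end without an external broad-peak caller, and it
    makes no attempt to model read shifting or local-background hierarchies.
    """
    bins: list[tuple[str, int, float, float]] = []
    for chrom in track.chroms():
        sig = track[chrom]
        inp = input_track[chrom]
        n = (len(sig) // bin_size) * bin_size
        if n == 0:
            continue
        s = sig[:n].reshape(-1, bin_size).sum(axis=1)
        b = inp[:n].reshape(-1, bin_size).sum(axis=1)
        # put signal and input on a common depth scale
        scale = sig.sum() / max(inp.sum(), 1e-12)
        lam = np.maximum(b * scale, np.mean(s)) + pseudocount
        for i in range(len(s)):
            bins.append((chrom, i * bin_size, s[i], lam[i]))
    if not bins:
        return []
    obs = np.array([b[2] for b in bins])
    lam = np.array([b[3] for b in bins])
    pvals = stats.poisson.sf(np.round(obs), lam)
    qvals = _bh_adjust(pvals)
    sig_bins = [
        GenomicInterval(bins[i][0], bins[i][1], bins[i][1] + bin_size)
        for i in np.flatnonzero(qvals < q_threshold)
    ]
    # merge nearby significant bins
    merged: list[GenomicInterval] = []
    for iv in sorted(sig_bins):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= merge_gap
        ):
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return [iv for iv in merged if len(iv) >= min_length]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
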