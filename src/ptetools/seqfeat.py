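"""DNA sequence-feature and signal-aggregation statistics around peaks.

Everything here operates on fixed-width windows centred on peak positions:

* di-nucleotide difference maps (peak set minus control set, 100-bp sliding
  windows over 10-kb fragments);
* oriented homopolymer tract profiles — sequences are flipped so the target
  gene always lies to the right of the peak before counting poly(dA)5 /
  poly(dT)5 (or ATATA/TATAT control) tracts per window;
* CpG counts per sliding window;
* motif-centrality profiles — the best PWM match per sequence (either
  strand, log-odds over a background, above a score threshold) is binned by
  its position, normalized, aggregated per peak-score quartile and smoothed
  with a rolling mean;
* generic coverage metaprofiles over region centres.

Sliding statistics use step 1 throughout.  Overlapping homopolymer matches
are counted (an A6 run contains two A5 tracts) — the more sensitive of the
two conventions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CoverageTrack, GenomicInterval
from .simulate import encode, revcomp_codes

__all__ = [
    "PWM",
    "PositionProfile",
    "DinucMap",
    "dinucleotide_map",
    "polytract_profile",
    "polytract_window_counts",
    "cpg_window_track",
    "motif_centrality",
    "metaprofile",
    "extract_centered_sequences",
    "sample_control_windows",
]

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@dataclass
class PositionProfile:
    """A per-offset statistic over aligned (and possibly oriented) windows."""

    offsets: np.ndarray  # bp relative to the window/peak centre
    values: np.ndarray
    n_regions: int
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "n": self.n_regions}
        )


@dataclass
class DinucMap:
    """16 x offsets matrix of windowed frequency differences."""

    offsets: np.ndarray
    diff: np.ndarray  # (16, n_windows): peak-set mean minus control mean
    n_regions: int
    n_controls: int

    def row(self, dinuc: str) -> np.ndarray:
        return self.diff[DINUCLEOTIDES.index(dinuc)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.diff.T, columns=DINUCLEOTIDES)
        df.insert(0, "offset", self.offsets)
        return df


# ---------------------------------------------------------------------------
# position weight matrices


@dataclass(frozen=True)
class PWM:
    """Probability matrix (length x ACGT) with background and threshold.

    Scores are log2 odds against the background; the default threshold of
    5.0 follows the convention of centrality scanners.  ``from_consensus``
    builds a sharp matrix (0.96 on the consensus base) from a plain string.
    """

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float = 5.0
    name: str = "motif"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("matrix must be (length >= 4) x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_consensus(
        cls, consensus: str, match_prob: float = 0.96, **kwargs
    ) -> "PWM":
        codes = encode(consensus)
        if (codes > 3).any():
            raise ValueError("consensus must be an ACGT string")
        m = np.full((len(codes), 4), (1 - match_prob) / 3.0)
        m[np.arange(len(codes)), codes] = match_prob
        return cls(m, name=consensus, **kwargs)

    def swap_positions(self, i: int, j: int) -> "PWM":
        """Control PWM with two matrix rows exchanged (column-swap control:
        e.g. swapping the C and G positions scrambles the core while leaving
        the rest of the matrix intact)."""
        m = self.matrix.copy()
        m[[i, j]] = m[[j, i]]
        return PWM(m, self.background, self.threshold, self.name + "_swapped")

    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, 1e-4)
        return np.log2(p / self.background[None, :])

    def scan(self, codes: np.ndarray) -> np.ndarray:
        """Plus-strand log-odds score at every start position.

        Positions whose window contains an N score -inf.
        """
        lom = self.log_odds()
        m, L = len(self), len(codes)
        if m > L:
            return np.empty(0)
        n_pos = L - m + 1
        scores = np.zeros(n_pos)
        bad = np.zeros(n_pos, dtype=bool)
        for j in range(m):
            col = codes[j : j + n_pos]
            ok = col < 4
            bad |= ~ok
            scores += np.where(ok, lom[j, np.minimum(col, 3)], 0.0)
        scores[bad] = -np.inf
        return scores

    def best_match(self, codes: np.ndarray) -> tuple[int, float, str] | None:
        """Best-scoring match on either strand, above the threshold.

        Returns ``(start, score, strand)`` or None.  Ties prefer the plus
        strand, then the leftmost position.  The minus-strand scan scores
        the reverse complement of the motif against the plus-strand
        sequence, so ``start`` is always a plus-strand coordinate.
        """
        fwd = self.scan(codes)
        if len(fwd) == 0:
            return None
        rc = PWM(self.matrix[::-1, ::-1], self.background, self.threshold)
        rev = rc.scan(codes)
        best_f, best_r = np.max(fwd), np.max(rev)
        if max(best_f, best_r) < self.threshold:
            return None
        if best_f >= best_r:
            return int(np.argmax(fwd)), float(best_f), "+"
        return int(np.argmax(rev)), float(best_r), "-"

    # MEME minimal motif format -------------------------------------------
    def to_meme(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write(
                "Background letter frequencies\n"
                + " ".join(
                    f"{b} {f:.4f}" for b, f in zip("ACGT", self.background)
                )
                + "\n\n"
            )
            fh.write(f"MOTIF {self.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(self)}\n"
            )
            for row in self.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_meme(cls, path: str | Path, **kwargs) -> "PWM":
        lines = Path(path).read_text().splitlines()
        name, rows, bg = "motif", [], np.full(4, 0.25)
        it = iter(enumerate(lines))
        for i, line in it:
            s = line.strip()
            if s.startswith("Background letter frequencies"):
                parts = lines[i + 1].split()
                bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            elif s.startswith("MOTIF"):
                name = s.split()[1]
            elif s.startswith("letter-probability matrix"):
                w = int(s.split("w=")[1].split()[0])
                for j in range(w):
                    rows.append([float(v) for v in lines[i + 1 + j].split()])
                break
        if not rows:
            raise ValueError(f"{path}: no letter-probability matrix found")
        return cls(np.array(rows), background=bg, name=name, **kwargs)


# ---------------------------------------------------------------------------
# windowed counting helpers


def _window_sums(x: np.ndarray, window: int) -> np.ndarray:
    """Sums of ``x`` over sliding windows of ``window`` entries, step 1."""
    csum = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    return csum[window:] - csum[:-window]


def _center_offsets(seq_len: int, window: int, per: str = "window") -> np.ndarray:
    """Offsets of sliding-window centres relative to the sequence centre."""
    n = seq_len - window + 1 if per == "window" else seq_len
    start = np.arange(n)
    return start + window // 2 - seq_len // 2 if per == "window" else start - seq_len // 2


# ---------------------------------------------------------------------------
# di-nucleotide maps


def _dinuc_window_freqs(seq: str, window: int) -> np.ndarray:
    """(16, n_windows) frequencies; N-containing di-nucleotides excluded
    from the denominator; all-N windows are NaN."""
    codes = encode(seq)
    a, b = codes[:-1], codes[1:]
    valid = (a < 4) & (b < 4)
    ids = np.where(valid, 4 * np.minimum(a, 3) + np.minimum(b, 3), 0)
    L = len(codes)
    w = window - 1  # di-nucleotide positions per window
    n_win = L - window + 1
    denom = _window_sums(valid.astype(float), w)[:n_win]
    freqs = np.empty((16, n_win))
    for d in range(16):
        ind = (valid & (ids == d)).astype(float)
        freqs[d] = _window_sums(ind, w)[:n_win]
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, freqs / np.maximum(denom, 1.0), np.nan)
    return freqs


def dinucleotide_map(
    sequences: Sequence[str],
    control_sequences: Sequence[str],
    window: int = 100,
) -> DinucMap:
    """Windowed di-nucleotide frequency difference, peak set minus controls.

    All sequences must share one length; frequencies are averaged over each
    set per window (NaN windows, i.e. all-N, are excluded from the mean)
    and the control mean subtracted.  Before subtraction the 16 frequencies
    in every window sum to 1.
    """
    lengths = {len(s) for s in sequences} | {len(s) for s in control_sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
    (L,) = lengths
    if window > L:
        raise ValueError("window exceeds sequence length")

    def set_mean(seqs: Sequence[str]) -> np.ndarray:
        acc = np.zeros((16, L - window + 1))
        cnt = np.zeros(L - window + 1)
        for s in seqs:
            f = _dinuc_window_freqs(s, window)
            good = ~np.isnan(f[0])
            acc[:, good] += f[:, good]
            cnt[good] += 1
        with np.errstate(invalid="ignore"):
            return acc / np.maximum(cnt, 1)

    diff = set_mean(sequences) - set_mean(control_sequences)
    offsets = _center_offsets(L, window)
    return DinucMap(offsets, diff, len(sequences), len(control_sequences))


# ---------------------------------------------------------------------------
# homopolymer tract profiles


def _tract_starts(codes: np.ndarray, tract_codes: np.ndarray) -> np.ndarray:
    """Boolean indicator of (overlapping) tract matches per start position."""
    k, L = len(tract_codes), len(codes)
    if k > L:
        return np.zeros(0, dtype=bool)
    hit = np.ones(L - k + 1, dtype=bool)
    for j, c in enumerate(tract_codes):
        hit &= codes[j : j + L - k + 1] == c
    return hit


def polytract_window_counts(
    sequences: Sequence[str],
    gene_sides: Sequence[str] | None,
    tract: str,
    window: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence windowed tract counts on gene-oriented sequences.

    ``gene_sides[i]`` is 'R' (target gene right of the peak: sequence used
    as is) or 'L' (gene left: reverse complement used, so all genes end up
    to the right).  ``None`` skips orientation (control sequences).
    Returns ``(offsets, counts)`` with ``counts`` of shape
    (n_sequences, n_windows); counts are of tract *start* positions inside
    each window, overlapping occurrences included.
    """
    if gene_sides is not None and len(gene_sides) != len(sequences):
        raise ValueError("need one gene side per sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    (L,) = lengths
    tract_codes = encode(tract)
    k = len(tract_codes)
    if window < k:
        raise ValueError("window must be at least the tract length")
    n_win = L - window + 1
    counts = np.zeros((len(sequences), n_win))
    for i, s in enumerate(sequences):
        codes = encode(s)
        if gene_sides is not None:
            side = gene_sides[i]
            if side not in ("L", "R"):
                raise ValueError(f"unknown gene side {side!r}")
            if side == "L":
                codes = revcomp_codes(codes)
        hits = _tract_starts(codes, tract_codes).astype(float)
        # a tract counts towards a window only when fully contained in it
        counts[i] = _window_sums(hits, window - k + 1)[:n_win]
    offsets = _center_offsets(L, window)
    return offsets, counts


def polytract_profile(
    sequences: Sequence[str],
    gene_sides: Sequence[str] | None,
    tract: str,
    window: int = 100,
    control_sequences: Sequence[str] | None = None,
) -> tuple[PositionProfile, PositionProfile | None]:
    """Mean oriented tract frequency per window, plus an optional control
    profile from unoriented control sequences."""
    offsets, counts = polytract_window_counts(sequences, gene_sides, tract, window)
    profile = PositionProfile(offsets, counts.mean(axis=0), len(sequences), tract)
    control = None
    if control_sequences is not None:
        c_off, c_counts = polytract_window_counts(
            control_sequences, None, tract, window
        )
        control = PositionProfile(
            c_off, c_counts.mean(axis=0), len(control_sequences), tract + "_control"
        )
    return profile, control


# ---------------------------------------------------------------------------
# CpG windows


def cpg_window_track(sequence: str, window: int = 100) -> PositionProfile:
    """Count of CG di-nucleotides per sliding window along one sequence.

    Offsets are window *start* positions (0-based) along the sequence.
    """
    codes = encode(sequence)
    cg = ((codes[:-1] == 1) & (codes[1:] == 2)).astype(float)
    n_win = len(codes) - window + 1
    # only CG pairs fully inside the window count: window-1 start positions
    values = _window_sums(cg, window - 1)[:n_win]
    return PositionProfile(np.arange(n_win), values, 1, "CpG")


# ---------------------------------------------------------------------------
# motif centrality


def motif_centrality(
    sequences: Sequence[str],
    pwm: PWM,
    quartiles: Sequence[str],
    rolling: int = 500,
    normalize: str = "per_quartile",
) -> dict[str, PositionProfile]:
    """Per-quartile profile of best-match motif positions around peaks.

    For every sequence the single best PWM match (either strand, above the
    score threshold) contributes one count at its match-centre offset.
    Counts are normalized to the total number of matches (per quartile by
    default so the quartile curves are directly comparable; ``'global'``
    divides every quartile by the overall match count), aggregated per
    quartile, and smoothed with a centred rolling mean of ``rolling``
    positions.  Quartiles without any match yield a flat zero profile.
    """
    if len(quartiles) != len(sequences):
        raise ValueError("need one quartile label per sequence")
    if normalize not in ("per_quartile", "global"):
        raise ValueError("normalize must be 'per_quartile' or 'global'")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    (L,) = lengths
    if len(pwm) >= L:
        raise ValueError("PWM must be shorter than the sequences")
    labels = sorted(set(quartiles))
    raw = {q: np.zeros(L) for q in labels}
    n_seq = {q: 0 for q in labels}
    total_matches = 0
    for s, q in zip(sequences, quartiles):
        n_seq[q] += 1
        hit = pwm.best_match(encode(s))
        if hit is None:
            continue
        start, _, _ = hit
        center = start + len(pwm) // 2
        raw[q][center] += 1.0
        total_matches += 1
    out: dict[str, PositionProfile] = {}
    offsets = np.arange(L) - L // 2
    for q in labels:
        denom = raw[q].sum() if normalize == "per_quartile" else total_matches
        vals = raw[q] / denom if denom > 0 else raw[q]
        smoothed = (
            pd.Series(vals).rolling(rolling, center=True, min_periods=1).mean().to_numpy()
        )
        out[q] = PositionProfile(offsets, smoothed, n_seq[q], f"{pwm.name}:{q}")
        out[q].raw = vals  # unsmoothed, for normalization checks
    return out


# ---------------------------------------------------------------------------
# metaprofiles


def metaprofile(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    half_width: int,
    strand_aware: bool = False,
) -> PositionProfile:
    """Mean signal at each offset in [-half_width, +half_width) over region
    centres.  Regions whose window leaves the chromosome are excluded (their
    number is reported via ``n_regions``: only included regions count).
    With ``strand_aware`` minus-strand windows are flipped."""
    acc = np.zeros(2 * half_width)
    n = 0
    for r in regions:
        c = r.center
        lo, hi = c - half_width, c + half_width
        arr = track[r.chrom]
        if lo < 0 or hi > len(arr):
            continue
        win = arr[lo:hi]
        if strand_aware and r.strand == "-":
            win = win[::-1]
        acc += win
        n += 1
    values = acc / n if n else acc
    return PositionProfile(np.arange(-half_width, half_width), values, n, "metaprofile")


# ---------------------------------------------------------------------------
# sequence extraction and control sampling


def extract_centered_sequences(
    genome: dict[str, str],
    centers: Sequence[tuple[str, int]],
    half_width: int,
) -> tuple[list[str], list[int]]:
    """Fixed-width sequences centred on (chrom, position) points.

    Returns the sequences plus the indices of centres kept (windows falling
    off a chromosome end are dropped).
    """
    seqs, kept = [], []
    for i, (chrom, pos) in enumerate(centers):
        seq = genome[chrom]
        lo, hi = pos - half_width, pos + half_width
        if lo < 0 or hi > len(seq):
            continue
        seqs.append(seq[lo:hi])
        kept.append(i)
    return seqs, kept


def sample_control_windows(
    chrom_sizes: dict[str, int],
    n: int,
    width: int,
    exclude: Sequence[GenomicInterval] = (),
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Seeded uniform sampling of non-overlapping control windows.

    Windows overlapping ``exclude`` (e.g. peak-centred fragments) or a
    previously drawn window are rejected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    chroms = sorted(c for c, size in chrom_sizes.items() if size >= width)
    if not chroms:
        raise ValueError("no chromosome can hold a window of that width")
    weights = np.array([chrom_sizes[c] - width + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could only place {len(out)}/{n} control windows"
            )
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, chrom_sizes[chrom] - width + 1))
        cand = GenomicInterval(chrom, start, start + width)
        if any(cand.overlaps(e) for e in exclude):
            continue
        if any(cand.overlaps(o) for o in out):
            continue
        out.append(cand)
    out.sort()
    return out
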