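"""Synthetic genomes and ChIP-seq coverage with planted PRC1 tethering elements.

The generator emulates the signal structure the analysis assumes, so every
downstream stage can be exercised against a known ground truth:

* **PTE loci** — a ~1 kb core whose sequence is enriched in AA/TT
  di-nucleotides (first-order Markov boost), carrying one embedded instance
  of a short consensus motif near its centre and poly(dA)5 tracts biased to
  the strand pointing at the designated target gene; the core is flanked on
  both sides by CpG-rich (island-like) segments.
* **PRC2-only loci** — CpG-rich segments with no motif and no PRC1 signal.
* **Coverage tracks** — sharp Gaussian peaks for PRC1 subunits (MEL18-like)
  centred on the planted loci with independent per-replicate position
  jitter; broad flat-topped domains offset towards the flanking CpG islands
  for SUZ12; still broader domains for H3K27me3; pure noise for input.
  Per-base counts are drawn Poisson or gamma-Poisson (negative binomial)
  and depth-normalized so that each track sums to 1e9 (the RPKM of a 1-bp
  bin, i.e. sum x (1/10^3)/10^6 = 1).
* **RNA counts** — long-tailed (log-normal), with a configurable fraction of
  PTE target genes drawn from the low tail.

A single global seed fans out to per-track seeds keyed by (assay, replicate)
so adding a track never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CoverageTrack, GeneRecord, GenomicInterval

__all__ = [
    "SyntheticGenomeSpec",
    "TrackSpec",
    "PTELocus",
    "GroundTruth",
    "generate_genome",
    "generate_tracks",
    "generate_counts",
    "default_track_specs",
    "SimulatedTracks",
]

_CODE = {b: i for i, b in enumerate("ACGT")}
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space

# stable assay codes for counter-based seed fan-out
ASSAYS = ("MEL18", "BMI1", "RING2", "SUZ12", "H3K27me3", "INPUT", "MNASE")
_ASSAY_CODE = {a: i for i, a in enumerate(ASSAYS)}


class ConfigurationError(ValueError):
    """Planted loci cannot be laid out with the requested geometry."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Geometry and sequence composition of the synthetic genome.

    The default scale (4 chromosomes x 2 Mb, 60 genes, 24 PTE and 12
    PRC2-only loci) is large enough for quartile statistics yet runs in
    well under a minute.
    """

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 60
    n_pte_loci: int = 24
    n_prc2_only_loci: int = 12
    background_gc: float = 0.41
    cpg_island_gc: float = 0.65
    pte_core_aa_tt_boost: float = 0.15
    polyA_strand_bias: float = 0.85
    motif_consensus: str = "AAACGAAA"
    motif_placement_sd: float = 100.0
    seed: int = 0
    # locus geometry (bp)
    core_half_width: int = 500
    island_width: int = 2_000
    n_polya_tracts: int = 12
    target_gene_distance: tuple[int, int] = (500, 7_000)
    amplitude_range: tuple[float, float] = (1_000.0, 4_000.0)
    edge_margin: int = 50_000

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_genes": self.n_genes,
            "core_half_width": self.core_half_width,
            "island_width": self.island_width,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_pte_loci < 0 or self.n_prc2_only_loci < 0:
            raise ValueError("locus counts must be non-negative")
        for name in (
            "background_gc",
            "cpg_island_gc",
            "pte_core_aa_tt_boost",
            "polyA_strand_bias",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.motif_consensus) - set("ACGT"):
            raise ValueError("motif_consensus must be an ACGT string")
        if self.n_genes < self.n_pte_loci:
            raise ValueError("need at least one gene per PTE locus")

    @property
    def fragment_half_width(self) -> int:
        return self.core_half_width + self.island_width


@dataclass(frozen=True)
class TrackSpec:
    """Shape and noise parameters for one simulated assay."""

    assay: str
    peak_amplitude_range: tuple[float, float] = (1_000.0, 4_000.0)
    peak_width_sd: float = 250.0
    domain_width: int = 2_000
    replicate_position_jitter_sd: float = 120.0
    noise_model: str = "negative_binomial"
    nb_dispersion: float = 0.3
    baseline: float = 3.0
    seed: int | None = None  # None: derived from the global seed

    def validate(self) -> None:
        if self.assay not in _ASSAY_CODE:
            raise ValueError(f"unknown assay {self.assay!r}; one of {ASSAYS}")
        if self.replicate_position_jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if any(a < 0 for a in self.peak_amplitude_range):
            raise ValueError("amplitudes must be >= 0")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass(frozen=True)
class PTELocus:
    chrom: str
    position: int
    amplitude: float  # relative planted strength, units of the MEL18 range
    target_gene_id: str
    gene_side: str  # 'L' or 'R': side of the peak the target TSS lies on


@dataclass
class GroundTruth:
    pte_loci: list[PTELocus]
    prc2_only_regions: list[GenomicInterval]
    genes: list[GeneRecord]
    spec: SyntheticGenomeSpec

    @property
    def pte_positions(self) -> list[tuple[str, int, float, str]]:
        return [
            (p.chrom, p.position, p.amplitude, p.target_gene_id)
            for p in self.pte_loci
        ]

    def subset_loci(self, keep: Sequence[int]) -> "GroundTruth":
        """Ground truth restricted to a subset of PTE loci (e.g. a second
        cell line in which only part of the elements is occupied)."""
        keep = sorted(keep)
        return GroundTruth(
            pte_loci=[self.pte_loci[i] for i in keep],
            prc2_only_regions=list(self.prc2_only_regions),
            genes=list(self.genes),
            spec=self.spec,
        )

    def pte_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.chrom, p.position, p.amplitude, p.target_gene_id, p.gene_side)
                for p in self.pte_loci
            ],
            columns=["chrom", "position", "amplitude", "target_gene_id", "gene_side"],
        )


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _iid_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _markov_core(
    rng: np.random.Generator, n: int, gc: float, aa_tt_boost: float
) -> np.ndarray:
    """First-order Markov sequence with elevated A->A and T->T transitions.

    Base composition stays near the background; only the AA/TT di-nucleotide
    frequency is boosted, mirroring cores that are poly(dA:dT)-rich without
    being grossly AT-rich overall.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = np.tile(p, (4, 1))
    for b in (0, 3):  # A, T
        row = p.copy()
        boost = min(aa_tt_boost, 1.0 - row[b])
        row *= (1.0 - row[b] - boost) / (1.0 - row[b])
        row[b] = p[b] + boost
        trans[b] = row
    cum = np.cumsum(trans, axis=1)
    u = rng.random(n)
    seq = np.empty(n, dtype=np.uint8)
    seq[0] = rng.choice(4, p=p)
    for i in range(1, n):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i])
    return seq


def encode(seq: str) -> np.ndarray:
    """ACGTN string -> uint8 codes (N mapped to 4)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.uint8)
    for b, c in _CODE.items():
        out[arr == ord(b)] = c
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def _locus_slots(spec: SyntheticGenomeSpec, rng: np.random.Generator):
    """Deterministic locus layout: evenly spaced slots per chromosome with
    bounded jitter, so planted loci can never overlap."""
    n_total = spec.n_pte_loci + spec.n_prc2_only_loci
    per_chrom = [
        n_total // spec.n_chromosomes
        + (1 if c < n_total % spec.n_chromosomes else 0)
        for c in range(spec.n_chromosomes)
    ]
    margin = min(spec.edge_margin, spec.chrom_length // 10)
    usable = spec.chrom_length - 2 * margin
    # loci must keep their fragments apart and their target genes closest
    min_separation = 2 * spec.fragment_half_width + spec.target_gene_distance[1]
    slots: list[tuple[str, int]] = []
    for c, k in enumerate(per_chrom):
        if k == 0:
            continue
        spacing = usable / k
        if 0.6 * spacing < min_separation:
            raise ConfigurationError(
                f"cannot place {k} loci on a {spec.chrom_length} bp chromosome "
                "without overlap; reduce locus count or enlarge chromosomes"
            )
        for i in range(k):
            center = margin + (i + 0.5) * spacing
            center += rng.uniform(-spacing / 5, spacing / 5)
            slots.append((f"chr{c + 1}", int(center)))
    # deterministically interleave PTE and PRC2-only assignments
    kinds = np.array(["PTE"] * spec.n_pte_loci + ["PRC2"] * spec.n_prc2_only_loci)
    rng.shuffle(kinds)
    return slots, kinds


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], GroundTruth]:
    """Build the synthetic genome sequence and its ground truth.

    Deterministic given ``spec.seed``.  Raises :class:`ConfigurationError`
    when the requested loci cannot be placed without overlap.
    """
    spec.validate()
    rng = _rng(spec.seed, 0)
    chroms = {
        f"chr{c + 1}": _iid_sequence(rng, spec.chrom_length, spec.background_gc)
        for c in range(spec.n_chromosomes)
    }
    slots, kinds = _locus_slots(spec, rng)

    pte_loci: list[PTELocus] = []
    prc2_regions: list[GenomicInterval] = []
    genes: list[GeneRecord] = []
    gene_counter = 0
    lo, hi = spec.amplitude_range

    for (chrom, pos), kind in zip(slots, kinds):
        if kind == "PRC2":
            w = spec.island_width
            chroms[chrom][pos - w // 2 : pos + w - w // 2] = _iid_sequence(
                rng, w, spec.cpg_island_gc
            )
            prc2_regions.append(GenomicInterval(chrom, pos - w // 2, pos + w - w // 2))
            continue
        # --- PTE locus: build the gene-to-the-right oriented fragment ---
        chw, iw = spec.core_half_width, spec.island_width
        left_island = _iid_sequence(rng, iw, spec.cpg_island_gc)
        core = _markov_core(rng, 2 * chw, spec.background_gc, spec.pte_core_aa_tt_boost)
        right_island = _iid_sequence(rng, iw, spec.cpg_island_gc)
        frag = np.concatenate([left_island, core, right_island])
        center = iw + chw  # fragment index of the peak position
        # oriented poly(dA)5 tracts in the core and gene-proximal flank
        tract_lo, tract_hi = -chw, min(chw + 3 * chw, iw + chw) - 5
        for _ in range(spec.n_polya_tracts):
            off = int(rng.integers(tract_lo, tract_hi))
            tract = 0 if rng.random() < spec.polyA_strand_bias else 3  # A or T
            frag[center + off : center + off + 5] = tract
        # one motif instance near the core centre, random strand
        motif = encode(spec.motif_consensus)
        m_off = int(np.clip(rng.normal(0, spec.motif_placement_sd), -chw + 4, chw - 4))
        m_start = center + m_off - len(motif) // 2
        inst = motif if rng.random() < 0.5 else revcomp_codes(motif)
        frag[m_start : m_start + len(motif)] = inst
        # target gene: TSS on a random side, 0.5-7 kb from the peak
        side = "R" if rng.random() < 0.5 else "L"
        dist = int(rng.integers(*spec.target_gene_distance))
        gene_id = f"gene{gene_counter:04d}"
        gene_counter += 1
        tss = pos + dist if side == "R" else pos - dist
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(gene_id, chrom, tss, strand, 0.0))
        # write fragment into the genome, reverse-complemented when the
        # gene lies to the left (the oriented sense then reads rightwards
        # along the minus strand)
        if side == "L":
            frag = revcomp_codes(frag)
        start = pos - spec.fragment_half_width
        chroms[chrom][start : start + len(frag)] = frag
        pte_loci.append(PTELocus(chrom, pos, float(rng.uniform(lo, hi)), gene_id, side))

    # background (non-target) genes midway between locus slots
    n_bg = spec.n_genes - spec.n_pte_loci
    bg_positions = _background_gene_positions(spec, slots, n_bg)
    for chrom, tss in bg_positions:
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"gene{gene_counter:04d}", chrom, tss, strand, 0.0))
        gene_counter += 1

    sequences = {c: decode(arr) for c, arr in chroms.items()}
    truth = GroundTruth(pte_loci, prc2_regions, genes, spec)
    return sequences, truth


def _background_gene_positions(spec, slots, n_bg):
    """Spread non-target genes evenly, midway between locus slots."""
    out = []
    if n_bg <= 0:
        return out
    per_chrom = [
        n_bg // spec.n_chromosomes + (1 if c < n_bg % spec.n_chromosomes else 0)
        for c in range(spec.n_chromosomes)
    ]
    locus_pos = {}
    for chrom, pos in slots:
        locus_pos.setdefault(chrom, []).append(pos)
    margin = spec.edge_margin // 2
    for c, k in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        taken = np.array(sorted(locus_pos.get(chrom, [])), dtype=float)
        usable = spec.chrom_length - 2 * margin
        placed = 0
        i = 0
        while placed < k:
            cand = margin + ((i + 0.5) / k) * usable + (i % 3) * 937
            i += 1
            if taken.size and np.min(np.abs(taken - cand)) < 25_000:
                continue
            out.append((chrom, int(cand)))
            placed += 1
            if i > 20 * k:  # pragma: no cover - geometry guard
                raise ConfigurationError("cannot place background genes")
    return out


# ---------------------------------------------------------------------------
# coverage tracks


@dataclass
class SimulatedTracks:
    """Replicated coverage plus truth-derived enriched-region calls."""

    tracks: dict[str, list[CoverageTrack]]  # assay -> [replicate tracks]
    regions: dict[str, list[list[GenomicInterval]]]  # assay -> [replicate BEDs]
    jittered_centers: dict[str, list[np.ndarray]]  # assay -> per-replicate centres


def default_track_specs() -> list[TrackSpec]:
    return [
        TrackSpec("MEL18"),
        TrackSpec("SUZ12", peak_amplitude_range=(400.0, 1_600.0)),
        TrackSpec("H3K27me3", peak_amplitude_range=(200.0, 800.0)),
        TrackSpec("INPUT", peak_amplitude_range=(0.0, 0.0)),
    ]


def _flat_top(positions: np.ndarray, center: float, width: float,
              edge: float = 300.0) -> np.ndarray:
    """Flat-topped kernel: 1 within +-width/2 of center, sigmoid shoulders."""
    d = np.abs(positions - center) - width / 2.0
    return 1.0 / (1.0 + np.exp(np.clip(d / (edge / 4.0), -50, 50)))


def _mean_signal(
    assay: str,
    spec: TrackSpec,
    gspec: SyntheticGenomeSpec,
    truth: GroundTruth,
    chrom: str,
    length: int,
    centers: np.ndarray,
) -> np.ndarray:
    """Noise-free expected depth for one chromosome of one replicate."""
    mu = np.full(length, spec.baseline)
    lo, hi = spec.peak_amplitude_range
    a_lo, a_hi = gspec.amplitude_range
    span = (a_hi - a_lo) if a_hi > a_lo else 1.0
    loci = [p for p in truth.pte_loci if p.chrom == chrom]
    idx = [i for i, p in enumerate(truth.pte_loci) if p.chrom == chrom]
    pos = np.arange(length, dtype=float)

    def height(amp: float) -> float:
        return lo + (amp - a_lo) / span * (hi - lo)

    if assay in ("MEL18", "BMI1", "RING2"):
        for p, i in zip(loci, idx):
            c = centers[i]
            sd = spec.peak_width_sd
            w = int(6 * sd)
            s, e = max(0, int(c) - w), min(length, int(c) + w)
            mu[s:e] += height(p.amplitude) * np.exp(
                -0.5 * ((pos[s:e] - c) / sd) ** 2
            )
    elif assay == "SUZ12":
        # two flat-topped kernels offset towards the flanking CpG islands
        off = gspec.core_half_width + gspec.island_width // 2
        for p, i in zip(loci, idx):
            c = centers[i]
            h = 0.5 * height(p.amplitude)
            s, e = max(0, int(c) - 4 * off), min(length, int(c) + 4 * off)
            seg = pos[s:e]
            mu[s:e] += h * (
                _flat_top(seg, c - off, gspec.island_width)
                + _flat_top(seg, c + off, gspec.island_width)
            )
        for r in truth.prc2_only_regions:
            if r.chrom != chrom:
                continue
            s, e = max(0, r.start - 3_000), min(length, r.end + 3_000)
            mu[s:e] += 0.5 * (lo + hi) * _flat_top(pos[s:e], r.center, gspec.island_width
            )
    elif assay == "H3K27me3":
        half = 8_000.0
        for p, i in zip(loci, idx):
            c = centers[i]
            s, e = max(0, int(c) - 12_000), min(length, int(c) + 12_000)
            mu[s:e] += height(p.amplitude) * _flat_top(pos[s:e], c, 2 * half, edge=2_000.0
            )
        for r in truth.prc2_only_regions:
            if r.chrom != chrom:
                continue
            s, e = max(0, r.start - 12_000), min(length, r.end + 12_000)
            mu[s:e] += 0.5 * (lo + hi) * _flat_top(pos[s:e], r.center, 2 * half, edge=2_000.0
            )
    elif assay == "MNASE":
        for p, i in zip(loci, idx):
            c = centers[i]
            s, e = max(0, int(c) - 2_000), min(length, int(c) + 2_000)
            mu[s:e] += height(p.amplitude) * 0.1 * _flat_top(pos[s:e], c, 2 * gspec.core_half_width
            )
    elif assay == "INPUT":
        pass
    return mu


def _truth_regions(
    assay: str, gspec: SyntheticGenomeSpec, truth: GroundTruth,
    centers: np.ndarray, chrom_sizes: dict[str, int],
) -> list[GenomicInterval]:
    """Significant-region stand-in derived from the planted truth, expanded to
    a minimum length of 1000 bp (mirrors broad-caller output)."""
    halves = {
        "MEL18": 1_500, "BMI1": 1_500, "RING2": 1_500,
        "SUZ12": gspec.fragment_half_width,
        "H3K27me3": 8_000, "MNASE": 1_000,
    }
    out: list[GenomicInterval] = []
    if assay == "INPUT":
        return out
    half = halves[assay]
    for i, p in enumerate(truth.pte_loci):
        c = int(centers[i])
        s = max(0, c - half)
        e = min(chrom_sizes[p.chrom], c + half)
        if e - s >= 1_000:
            out.append(GenomicInterval(p.chrom, s, e))
    if assay in ("SUZ12", "H3K27me3"):
        dom = 2_000 if assay == "SUZ12" else 8_000
        for r in truth.prc2_only_regions:
            s = max(0, r.center - dom)
            e = min(chrom_sizes[r.chrom], r.center + dom)
            out.append(GenomicInterval(r.chrom, s, e))
    out.sort()
    return out


def generate_tracks(
    genome: dict[str, str] | dict[str, int],
    truth: GroundTruth,
    specs: Sequence[TrackSpec] | None = None,
    n_replicates: int = 2,
    seed: int | None = None,
) -> SimulatedTracks:
    """Simulate replicated, depth-normalized coverage for each assay.

    ``genome`` may be sequences or a plain ``chrom -> length`` mapping; only
    lengths are used.  Peak positions are jittered independently per
    replicate; per-base counts get Poisson or negative-binomial noise; each
    track is normalized so its genome-wide sum is 1e9 (RPKM-like units).
    """
    if n_replicates < 2:
        raise ValueError("pairing requires at least two replicates")
    specs = list(specs) if specs is not None else default_track_specs()
    for s in specs:
        s.validate()
    if seed is None:
        seed = truth.spec.seed
    chrom_sizes = {
        c: (len(v) if isinstance(v, str) else int(v)) for c, v in genome.items()
    }
    gspec = truth.spec
    tracks: dict[str, list[CoverageTrack]] = {}
    regions: dict[str, list[list[GenomicInterval]]] = {}
    centers_by_assay: dict[str, list[np.ndarray]] = {}
    true_pos = np.array([p.position for p in truth.pte_loci], dtype=float)

    for spec in specs:
        code = _ASSAY_CODE[spec.assay]
        tracks[spec.assay] = []
        regions[spec.assay] = []
        centers_by_assay[spec.assay] = []
        for rep in range(n_replicates):
            if spec.seed is not None:
                rng = _rng(spec.seed, rep)
            else:
                rng = _rng(seed, 1, code, rep)
            centers = true_pos + rng.normal(
                0.0, spec.replicate_position_jitter_sd, size=true_pos.shape
            )
            data: dict[str, np.ndarray] = {}
            for chrom, length in chrom_sizes.items():
                mu = _mean_signal(
                    spec.assay, spec, gspec, truth, chrom, length, centers
                )
                if spec.noise_model == "poisson":
                    counts = rng.poisson(mu).astype(float)
                else:  # gamma-Poisson mixture: var = mu + d*mu^2
                    shape = 1.0 / spec.nb_dispersion
                    lam = rng.gamma(shape, mu * spec.nb_dispersion)
                    counts = rng.poisson(lam).astype(float)
                data[chrom] = counts
            total = sum(a.sum() for a in data.values())
            scale = 1e9 / total if total > 0 else 0.0
            track = CoverageTrack({c: a * scale for c, a in data.items()})
            tracks[spec.assay].append(track)
            regions[spec.assay].append(
                _truth_regions(spec.assay, gspec, truth, centers, chrom_sizes)
            )
            centers_by_assay[spec.assay].append(centers)
    return SimulatedTracks(tracks, regions, centers_by_assay)


# ---------------------------------------------------------------------------
# RNA counts


def generate_counts(
    truth: GroundTruth,
    seed: int | None = None,
    fraction_low: float = 0.82,
    active_targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-tailed gene counts; PTE targets preferentially from the low tail.

    ``fraction_low`` is the probability that a PTE target gene is drawn from
    the weakly-expressed tail (the default reflects Polycomb targets being
    mostly silent).  ``active_targets`` restricts which genes count as PTE
    targets (default: all planted targets).  Returns a gene table with
    columns gene_id, chrom, tss, strand, count.
    """
    if not truth.genes:
        raise ValueError("gene table is empty")
    if seed is None:
        seed = truth.spec.seed
    rng = _rng(seed, 2)
    targets = (
        set(active_targets)
        if active_targets is not None
        else {p.target_gene_id for p in truth.pte_loci}
    )
    rows = []
    for g in truth.genes:
        if g.gene_id in targets and rng.random() < fraction_low:
            count = float(np.round(rng.lognormal(0.5, 0.8)))
        else:
            count = float(np.round(rng.lognormal(4.0, 1.6)))
        rows.append((g.gene_id, g.chrom, g.tss, g.strand, count))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "count"])
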