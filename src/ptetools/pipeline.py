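"""Pipeline orchestration: staged runs over a fixture directory.

Stages (``simulate``, ``regions``, ``peaks``, ``screen``, ``assign``,
``seqfeat``, ``all``) share a single declarative configuration and one
global seed; every stage writes its tables plus a machine-readable
manifest (parameters, input hashes, seed), so a rerun with the same config
is bit-identical apart from manifest timestamps.

The simulate stage builds two "cell lines" from one synthetic genome: line
A with every planted PTE occupied and line B with a configurable subset —
giving the screen its second-line scores and the gene-assignment stage a
cross-line overlap to measure.  Coverage tracks are *not* written to disk
by default (a noisy 8-Mb 1-bp track run-length-encodes to hundreds of MB);
because track simulation is a pure function of (truth, seed), later stages
regenerate them in memory instead.  Set ``write_tracks: true`` to emit
bedGraphs anyway.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import genes as genes_mod
from . import io, regions as regions_mod, screen as screen_mod, seqfeat, simulate
from .peaks import FilterParams, SmoothParams, peaks_to_frame, refine_peaks
from .regions import RegionParams, concordant_regions
from .screen import ScreenParams, ccnd2_like_screen, high_confidence_ptes

logger = logging.getLogger("ptetools")

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_regions",
    "run_peaks",
    "run_screen",
    "run_assign",
    "run_seqfeat",
    "run_all",
]

PEAK_ASSAYS = ("MEL18",)
REGION_ASSAYS = ("MEL18", "SUZ12", "H3K27me3")
LINE_B_ASSAYS = ("MEL18", "SUZ12")


@dataclass
class PipelineConfig:
    outdir: str = "ptetools_run"
    seed: int = 1
    genome: dict = field(default_factory=dict)  # SyntheticGenomeSpec overrides
    line_b_fraction: float = 0.6  # fraction of PTE loci occupied in line B
    fraction_low: float = 0.82  # PTE targets drawn from the low RNA tail
    write_tracks: bool = False
    summit_window_bp: int = 1_000
    group_gap_bp: int = 100_000
    standalone_distance_bp: int = 100_000
    span: float = 0.10
    degree: int = 2
    peak_fraction_grid: tuple = (0.50, 0.55, 0.60)
    valley_depth_grid: tuple = (0.30, 0.35)
    match_radius_bp: int = 50
    hc_max_accuracy: float = 300.0
    hc_quartiles: tuple = ("Q4", "Q3")
    screen_mel18_fraction: float = 0.5
    screen_second_fraction: float = 0.5
    tss_window: int = 1_000
    dinuc_half_width: int = 5_000
    motif_half_width: int = 2_500
    rolling: int = 500
    n_controls: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    # parameter objects ----------------------------------------------------
    def genome_spec(self) -> simulate.SyntheticGenomeSpec:
        return simulate.SyntheticGenomeSpec(seed=self.seed, **self.genome)

    def region_params(self) -> RegionParams:
        return RegionParams(
            summit_window_bp=self.summit_window_bp,
            group_gap_bp=self.group_gap_bp,
            standalone_distance_bp=self.standalone_distance_bp,
        )

    def smooth_params(self) -> SmoothParams:
        return SmoothParams(span=self.span, degree=self.degree)

    def filter_params(self) -> FilterParams:
        return FilterParams(
            tuple(self.peak_fraction_grid),
            tuple(self.valley_depth_grid),
            self.match_radius_bp,
        )

    def validate(self) -> None:
        self.genome_spec().validate()
        self.region_params()
        self.smooth_params()
        self.filter_params()
        if not (0 < self.line_b_fraction <= 1):
            raise ValueError("line_b_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
        "outputs": [str(p) for p in sorted(outputs)],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"required input {path} is missing — run the producing stage first"
        )
    return path


# ---------------------------------------------------------------------------
# shared state reconstruction


def _line_b_indices(cfg: PipelineConfig, n_loci: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    k = max(1, int(round(cfg.line_b_fraction * n_loci)))
    return sorted(rng.choice(n_loci, size=k, replace=False).tolist())


def _simulate_state(cfg: PipelineConfig) -> dict:
    """Deterministically rebuild genome, truth and tracks from the config."""
    spec = cfg.genome_spec()
    genome, truth = simulate.generate_genome(spec)
    truth_b = truth.subset_loci(_line_b_indices(cfg, len(truth.pte_loci)))
    specs_a = simulate.default_track_specs()
    specs_b = [s for s in specs_a if s.assay in LINE_B_ASSAYS]
    sim_a = simulate.generate_tracks(genome, truth, specs_a, seed=cfg.seed)
    sim_b = simulate.generate_tracks(genome, truth_b, specs_b, seed=cfg.seed + 1)
    return {
        "spec": spec,
        "genome": genome,
        "truth": truth,
        "truth_b": truth_b,
        "sim": {"a": sim_a, "b": sim_b},
    }


# ---------------------------------------------------------------------------
# stages


def run_simulate(cfg: PipelineConfig, state: dict | None = None) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = state or _simulate_state(cfg)
    genome, truth, truth_b = state["genome"], state["truth"], state["truth_b"]
    outputs = []

    fasta = outdir / "genome.fa"
    io.write_fasta(genome, fasta)
    outputs.append(fasta)
    pte_tsv = outdir / "truth_ptes.tsv"
    truth.pte_table().to_csv(pte_tsv, sep="\t", index=False)
    outputs.append(pte_tsv)
    prc2_bed = outdir / "truth_prc2_only.bed"
    io.write_regions(truth.prc2_only_regions, prc2_bed)
    outputs.append(prc2_bed)
    genes_tsv = outdir / "genes.tsv"
    io.write_gene_table(truth.genes, genes_tsv)
    outputs.append(genes_tsv)

    for line, tr in (("a", truth), ("b", truth_b)):
        counts = simulate.generate_counts(
            tr, seed=cfg.seed + (0 if line == "a" else 1),
            fraction_low=cfg.fraction_low,
        )
        p = outdir / f"counts_{line}.tsv"
        counts.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    for line, sim in state["sim"].items():
        for assay, reps in sim.regions.items():
            for r, regs in enumerate(reps, start=1):
                p = outdir / f"regions_{assay}_{line}_rep{r}.bed"
                io.write_regions(regs, p)
                outputs.append(p)
        if cfg.write_tracks:
            for assay, reps in sim.tracks.items():
                for r, track in enumerate(reps, start=1):
                    p = outdir / f"track_{assay}_{line}_rep{r}.bedgraph"
                    io.write_bedgraph(track, p)
                    outputs.append(p)

    _write_manifest(outdir, "simulate", cfg, [], outputs)
    logger.info(
        "simulate: %d PTE loci (line A), %d (line B), %d PRC2-only, %d genes",
        len(truth.pte_loci), len(truth_b.pte_loci),
        len(truth.prc2_only_regions), len(truth.genes),
    )
    return state


def run_regions(cfg: PipelineConfig, state: dict | None = None) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    state = state or _simulate_state(cfg)
    params = cfg.region_params()
    inputs, outputs = [], []
    state["concordant"] = {}
    for line, sim in state["sim"].items():
        state["concordant"][line] = {}
        for assay in sim.tracks:
            if assay == "INPUT":
                continue
            bed1 = _require(outdir / f"regions_{assay}_{line}_rep1.bed")
            bed2 = _require(outdir / f"regions_{assay}_{line}_rep2.bed")
            inputs += [bed1, bed2]
            regs1, regs2 = io.read_regions(bed1), io.read_regions(bed2)
            t1, t2 = sim.tracks[assay][0], sim.tracks[assay][1]
            conc = concordant_regions(regs1, regs2, t1, t2, params)
            state["concordant"][line][assay] = conc
            df = pd.DataFrame(
                [
                    (
                        b.interval.chrom, b.interval.start, b.interval.end,
                        b.summit_window.start, b.summit_window.end,
                        b.score_rep1, b.score_rep2, b.binding_score,
                    )
                    for b in conc
                ],
                columns=[
                    "chrom", "start", "end", "summit_start", "summit_end",
                    "score_rep1", "score_rep2", "score_mean",
                ],
            )
            p = outdir / f"concordant_{assay}_{line}.tsv"
            df.to_csv(p, sep="\t", index=False)
            outputs.append(p)
            logger.info(
                "regions[%s/%s]: %d + %d replicate regions -> %d concordant",
                line, assay, len(regs1), len(regs2), len(conc),
            )
    # standalone PRC2 regions (line A)
    conc_a = state["concordant"]["a"]
    standalone = regions_mod.standalone_prc2_regions(
        [b.interval for b in conc_a["SUZ12"]],
        [b.interval for b in conc_a["H3K27me3"]],
        [b.interval for b in conc_a["MEL18"]],
        params,
    )
    p = outdir / "standalone_prc2_a.bed"
    io.write_regions(standalone, p)
    outputs.append(p)
    _write_manifest(outdir, "regions", cfg, inputs, outputs)
    return state


def _load_concordant(outdir: Path, assay: str, line: str) -> list:
    p = _require(outdir / f"concordant_{assay}_{line}.tsv")
    df = pd.read_csv(p, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            regions_mod.BoundRegion(
                io.GenomicInterval(r.chrom, int(r.start), int(r.end)),
                io.GenomicInterval(r.chrom, int(r.summit_start), int(r.summit_end)),
                float(r.score_mean), "merged", float(r.score_rep1), float(r.score_rep2),
            )
        )
    return out


def run_peaks(cfg: PipelineConfig, state: dict | None = None) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    state = state or _simulate_state(cfg)
    state.setdefault("peaks", {})
    outputs, inputs = [], []
    for line, sim in state["sim"].items():
        conc = (
            state.get("concordant", {}).get(line, {}).get("MEL18")
            or _load_concordant(outdir, "MEL18", line)
        )
        inputs.append(outdir / f"concordant_MEL18_{line}.tsv")
        t1, t2 = sim.tracks["MEL18"][0], sim.tracks["MEL18"][1]
        peaks, log = refine_peaks(
            conc, t1, t2, cfg.region_params(), cfg.smooth_params(),
            cfg.filter_params(),
        )
        df = peaks_to_frame(peaks)
        p = outdir / f"peaks_{line}.tsv"
        df.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        state["peaks"][line] = df
        logger.info("peaks[%s]: %s", line, log)
    _write_manifest(
        outdir, "peaks", cfg, [p for p in inputs if p.exists()], outputs
    )
    return state


def run_screen(cfg: PipelineConfig, state: dict | None = None) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    state = state or _simulate_state(cfg)
    conc = (
        state.get("concordant", {}).get("a", {}).get("MEL18")
        or _load_concordant(outdir, "MEL18", "a")
    )
    sims = state["sim"]

    def window_score(track, w):
        return float(np.sum(track.values(w)))

    rows = []
    for b in conc:
        w = b.summit_window
        rows.append(
            {
                "chrom": w.chrom,
                "summit_start": w.start,
                "summit_end": w.end,
                "mel18": np.mean(
                    [window_score(t, w) for t in sims["a"].tracks["MEL18"]]
                ),
                "suz12": np.mean(
                    [window_score(t, w) for t in sims["a"].tracks["SUZ12"]]
                ),
                "mel18_second": np.mean(
                    [window_score(t, w) for t in sims["b"].tracks["MEL18"]]
                ),
                "suz12_second": np.mean(
                    [window_score(t, w) for t in sims["b"].tracks["SUZ12"]]
                ),
            }
        )
    scores = pd.DataFrame(rows)
    ref = scores.loc[scores["mel18"].idxmax()]
    params = ScreenParams.from_reference(
        ref["mel18"], ref["suz12"], ref["mel18_second"], ref["suz12_second"],
        mel18_fraction=cfg.screen_mel18_fraction,
        second_fraction=cfg.screen_second_fraction,
        hc_quartiles=tuple(cfg.hc_quartiles),
        hc_max_accuracy=cfg.hc_max_accuracy,
    )
    screened = ccnd2_like_screen(scores, params)
    p = outdir / "screen_a.tsv"
    screened.to_csv(p, sep="\t", index=False)
    state["screen"] = screened
    logger.info(
        "screen: %d/%d regions pass all three criteria",
        int(screened["pass_screen"].sum()), len(screened),
    )
    _write_manifest(outdir, "screen", cfg, [], [p])
    return state


def run_assign(cfg: PipelineConfig, state: dict | None = None) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    state = state or _simulate_state(cfg)
    genes_tsv = _require(outdir / "genes.tsv")
    inputs, outputs = [genes_tsv], []
    state.setdefault("assign", {})
    overlap_sets, overlap_groups = {}, {}
    for line in state["sim"]:
        peaks_p = _require(outdir / f"peaks_{line}.tsv")
        inputs.append(peaks_p)
        peaks = state.get("peaks", {}).get(line)
        if peaks is None:
            peaks = pd.read_csv(peaks_p, sep="\t")
        params = ScreenParams(
            hc_quartiles=tuple(cfg.hc_quartiles),
            hc_max_accuracy=cfg.hc_max_accuracy,
        )
        hc = high_confidence_ptes(peaks, params)
        hc_only = hc[hc["high_confidence"]].reset_index(drop=True)
        counts_p = _require(outdir / f"counts_{line}.tsv")
        inputs.append(counts_p)
        counts = pd.read_csv(counts_p, sep="\t")
        gene_records = [
            io.GeneRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand),
                          float(r.count))
            for r in counts.itertuples()
        ]
        k27 = (
            state.get("concordant", {}).get(line, {}).get("H3K27me3")
            if line in state.get("concordant", {})
            else None
        )
        if k27 is not None:
            k27_iv = [b.interval for b in k27]
        else:
            # line B has no H3K27me3 assay; fall back to line A's regions
            src = "a" if line == "b" else line
            try:
                k27_iv = [b.interval for b in _load_concordant(outdir, "H3K27me3", src)]
            except FileNotFoundError:
                k27_iv = []
        assignments = genes_mod.assign_targets(
            hc_only, gene_records, k27_iv, cfg.tss_window
        )
        per_gene, cohort = genes_mod.gene_pte_summary(assignments)
        groups = genes_mod.transcription_groups(counts)
        for df, name in (
            (hc, f"peaks_hc_{line}"),
            (assignments, f"assignments_{line}"),
            (per_gene, f"gene_summary_{line}"),
            (groups, f"transcription_groups_{line}"),
        ):
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        state["assign"][line] = {
            "assignments": assignments,
            "per_gene": per_gene,
            "cohort": cohort,
            "groups": groups,
        }
        overlap_sets[line] = set(assignments["gene_id"].dropna())
        overlap_groups[line] = groups
        logger.info(
            "assign[%s]: %d high-confidence PTEs -> %d target genes",
            line, len(hc_only), cohort["n_target_genes"],
        )
    if len(overlap_sets) == 2:
        frac, table = genes_mod.cross_cellline_overlap(
            sorted(overlap_sets["a"]), sorted(overlap_sets["b"]),
            overlap_groups["a"], overlap_groups["b"],
        )
        state["assign"]["overlap_fraction"] = frac
        if table is not None:
            p = outdir / "group_transitions.tsv"
            table.to_csv(p, sep="\t")
            outputs.append(p)
    _write_manifest(outdir, "assign", cfg, inputs, outputs)
    return state


def run_seqfeat(cfg: PipelineConfig, state: dict | None = None) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    state = state or _simulate_state(cfg)
    genome = state["genome"]
    spec = state["spec"]
    peaks_p = _require(outdir / "peaks_a.tsv")
    peaks = state.get("peaks", {}).get("a")
    if peaks is None:
        peaks = pd.read_csv(peaks_p, sep="\t")
    outputs = []
    hw = cfg.dinuc_half_width
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    q4 = peaks[peaks["quartile"] == "Q4"]
    centers = list(zip(q4["chrom"], q4["position"].astype(int)))
    q4_seqs, _ = seqfeat.extract_centered_sequences(genome, centers, hw)
    exclude = [
        io.GenomicInterval(c, max(0, p - hw), p + hw)
        for c, p in zip(peaks["chrom"], peaks["position"].astype(int))
    ]
    # cap the control count so rejection sampling cannot saturate a small genome
    capacity = int(0.3 * sum(chrom_sizes.values()) / (2 * hw))
    controls = seqfeat.sample_control_windows(
        chrom_sizes, min(cfg.n_controls, capacity), 2 * hw, exclude, seed=cfg.seed
    )
    control_seqs = [genome[c.chrom][c.start : c.end] for c in controls]
    dmap = seqfeat.dinucleotide_map(q4_seqs, control_seqs)
    p = outdir / "dinucleotide_map.tsv"
    dmap.to_frame().to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # oriented homopolymer profiles need the gene side per peak
    assign_p = _require(outdir / "assignments_a.tsv")
    assignments = pd.read_csv(assign_p, sep="\t")
    counts = pd.read_csv(_require(outdir / "counts_a.tsv"), sep="\t")
    tss = counts.set_index("gene_id")["tss"]
    merged = assignments.dropna(subset=["gene_id"])
    sides = ["R" if tss[g] >= p_ else "L" for g, p_ in
             zip(merged["gene_id"], merged["position"])]
    pk_centers = list(zip(merged["chrom"], merged["position"].astype(int)))
    or_seqs, kept = seqfeat.extract_centered_sequences(genome, pk_centers, hw)
    kept_sides = [sides[i] for i in kept]
    for tract in ("AAAAA", "TTTTT", "ATATA", "TATAT"):
        prof, ctrl = seqfeat.polytract_profile(
            or_seqs, kept_sides, tract, control_sequences=control_seqs
        )
        df = prof.to_frame()
        df["control"] = ctrl.values
        p = outdir / f"polytract_{tract}.tsv"
        df.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    # motif centrality per quartile on 5-kb fragments
    mhw = cfg.motif_half_width
    m_centers = list(zip(peaks["chrom"], peaks["position"].astype(int)))
    m_seqs, m_kept = seqfeat.extract_centered_sequences(genome, m_centers, mhw)
    quartiles = peaks["quartile"].iloc[m_kept].tolist()
    pwm = seqfeat.PWM.from_consensus(spec.motif_consensus)
    pwm.to_meme(outdir / "motif.meme")
    outputs.append(outdir / "motif.meme")
    profiles = seqfeat.motif_centrality(m_seqs, pwm, quartiles, cfg.rolling)
    for q, prof in profiles.items():
        p = outdir / f"motif_centrality_{q}.tsv"
        prof.to_frame().to_csv(p, sep="\t", index=False)
        outputs.append(p)

    # CpG window profile and SUZ12 metaprofile around line-A peaks
    if len(q4_seqs) > 0:
        cpg = seqfeat.cpg_window_track(q4_seqs[0])
        p = outdir / "cpg_example.tsv"
        cpg.to_frame().to_csv(p, sep="\t", index=False)
        outputs.append(p)
    suz_mean = state["sim"]["a"].tracks["SUZ12"][0].mean_with(
        state["sim"]["a"].tracks["SUZ12"][1]
    )
    meta_regions = [
        io.GenomicInterval(c, max(0, pos - 1), pos + 1)
        for c, pos in zip(peaks["chrom"], peaks["position"].astype(int))
    ]
    meta = seqfeat.metaprofile(suz_mean, meta_regions, hw)
    p = outdir / "suz12_metaprofile.tsv"
    meta.to_frame().to_csv(p, sep="\t", index=False)
    outputs.append(p)

    state["seqfeat"] = {"dinuc": dmap, "motif": profiles, "metaprofile": meta}
    _write_manifest(outdir, "seqfeat", cfg, [peaks_p, assign_p], outputs)
    return state


def run_all(cfg: PipelineConfig) -> dict:
    """Chain every stage and write a summary report of planted-vs-recovered
    counts (the numbers a user checks first on a fixture run)."""
    cfg.validate()
    state = _simulate_state(cfg)
    run_simulate(cfg, state)
    run_regions(cfg, state)
    run_peaks(cfg, state)
    run_screen(cfg, state)
    run_assign(cfg, state)
    run_seqfeat(cfg, state)

    truth = state["truth"]
    peaks_a = state["peaks"]["a"]
    planted = truth.pte_table()
    matched = 0
    errors = []
    for r in planted.itertuples():
        on_chrom = peaks_a[peaks_a["chrom"] == r.chrom]
        if on_chrom.empty:
            continue
        d = (on_chrom["position"] - r.position).abs().min()
        if d <= 500:
            matched += 1
            errors.append(float(d))
    assignments = state["assign"]["a"]["assignments"]
    truth_map = {p.target_gene_id for p in truth.pte_loci}
    correct = 0
    pos_to_target = {}
    for p_ in truth.pte_loci:
        pos_to_target[(p_.chrom, p_.position)] = p_.target_gene_id
    for r in assignments.itertuples():
        best = min(
            (
                (abs(r.position - pos), tgt)
                for (c, pos), tgt in pos_to_target.items()
                if c == r.chrom
            ),
            default=None,
        )
        if best and best[0] <= 500 and best[1] == r.gene_id:
            correct += 1
    report = {
        "n_planted_ptes": len(truth.pte_loci),
        "n_consensus_peaks_a": int(len(peaks_a)),
        "n_recovered_within_500bp": matched,
        "median_position_error_bp": float(np.median(errors)) if errors else None,
        "n_high_confidence_a": int(
            state["assign"]["a"]["assignments"].shape[0]
        ),
        "n_screen_pass": int(state["screen"]["pass_screen"].sum()),
        "n_target_genes_a": state["assign"]["a"]["cohort"]["n_target_genes"],
        "assignment_correct": correct,
        "cross_line_overlap_fraction": state["assign"].get("overlap_fraction"),
    }
    (Path(cfg.outdir) / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("report: %s", report)
    state["report"] = report
    return state
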