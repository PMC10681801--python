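"""DNA sequence signatures around planted PTEs.

Computes the di-nucleotide difference map (AA/TT-rich core, CpG-rich
flanks), the oriented poly(dA)5 / poly(dT)5 asymmetry, and the centrality
of the embedded consensus motif versus a column-swapped control PWM.
"""

import numpy as np

import ptetools as pt
from ptetools import seqfeat
from ptetools.io import GenomicInterval

spec = pt.SyntheticGenomeSpec(seed=1)  # default 4 x 2 Mb study, 24 PTEs
genome, truth = pt.generate_genome(spec)
centers = [(p.chrom, p.position) for p in truth.pte_loci]
sides = [p.gene_side for p in truth.pte_loci]
seqs, _ = seqfeat.extract_centered_sequences(genome, centers, 5_000)

sizes = {c: len(s) for c, s in genome.items()}
exclude = [GenomicInterval(c, p - 5_000, p + 5_000) for c, p in centers]
ctrl_iv = seqfeat.sample_control_windows(sizes, 60, 10_000, exclude, seed=1)
controls = [genome[iv.chrom][iv.start:iv.end] for iv in ctrl_iv]

dmap = seqfeat.dinucleotide_map(seqs, controls)
core = np.abs(dmap.offsets) <= 400
flank = (np.abs(dmap.offsets) > 800) & (np.abs(dmap.offsets) <= 2_300)
print("di-nucleotide frequency difference (peaks minus genomic controls):")
print(f"  AA in core   {dmap.row('AA')[core].mean():+.4f}")
print(f"  TT in core   {dmap.row('TT')[core].mean():+.4f}")
print(f"  CG in core   {dmap.row('CG')[core].mean():+.4f}")
print(f"  CG in flanks {dmap.row('CG')[flank].mean():+.4f}")

offs, a5 = seqfeat.polytract_window_counts(seqs, sides, "AAAAA")
_, t5 = seqfeat.polytract_window_counts(seqs, sides, "TTTTT")
right = (offs >= 0) & (offs <= 2_000)
wins = int((a5[:, right].mean(axis=1) > t5[:, right].mean(axis=1)).sum())
print(f"\noriented poly(dA)5 > poly(dT)5 on the gene-proximal flank: "
      f"{wins}/{len(seqs)} peaks")

pwm = seqfeat.PWM.from_consensus(spec.motif_consensus)
m_seqs, kept = seqfeat.extract_centered_sequences(genome, centers, 2_500)
prof = seqfeat.motif_centrality(m_seqs, pwm, ["Q4"] * len(m_seqs))["Q4"]
swapped = seqfeat.motif_centrality(
    m_seqs, pwm.swap_positions(3, 4), ["Q4"] * len(m_seqs)
)["Q4"]
off = prof.offsets


def central(p):
    return p.values[np.abs(off) <= 250].mean() / p.values.mean()


print(f"\nmotif centrality: best-match density peaks at offset "
      f"{off[int(np.argmax(prof.values))]} bp")
print(f"central enrichment  true PWM {central(prof):.2f}  "
      f"column-swapped control {central(swapped):.2f}")
# A central enrichment well above 1 means best matches concentrate under the
# peak summits; the swapped control shows how much of that is sequence
# composition rather than the motif itself.
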