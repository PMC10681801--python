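"""Build a small synthetic ChIP-seq study with planted PRC1 tethering elements.

Generates a 2 x 500 kb genome carrying 4 PTE loci and 2 PRC2-only loci,
simulates replicated MEL18/SUZ12/H3K27me3/input coverage, and prints the
ground truth that later stages try to recover.
"""

import ptetools as pt

spec = pt.SyntheticGenomeSpec(
    n_chromosomes=2, chrom_length=500_000, n_genes=8,
    n_pte_loci=4, n_prc2_only_loci=2, seed=42,
)
genome, truth = pt.generate_genome(spec)
sim = pt.generate_tracks(genome, truth, seed=42)

print("Planted PTE loci (position, relative amplitude, designated target):")
print(truth.pte_table().to_string(index=False))
print(f"\nPRC2-only loci: {len(truth.prc2_only_regions)}")
for assay, reps in sim.tracks.items():
    print(f"{assay}: {len(reps)} replicate tracks, each summing to {reps[0].total():.3g}")

# Each track is depth-normalized (sums to 1e9, RPKM-like units); the MEL18
# peaks sit exactly at the planted positions up to the per-replicate jitter,
# which is what the downstream pairing step estimates as 'accuracy'.
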