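"""Shared fixtures: synthetic genomes, tracks and small random generators."""

from __future__ import annotations

import numpy as np
import pytest

import ptetools as pt
from ptetools.simulate import TrackSpec


@pytest.fixture(scope="session")
def default_fixture():
    """The default-scale synthetic study: 4 x 2 Mb, 24 PTEs, 12 PRC2-only
    loci, 60 genes, replicate tracks at seed 1.  Built once per session."""
    spec = pt.SyntheticGenomeSpec(seed=1)
    genome, truth = pt.generate_genome(spec)
    sim = pt.generate_tracks(genome, truth, seed=1)
    return {"spec": spec, "genome": genome, "truth": truth, "sim": sim}


@pytest.fixture(scope="session")
def refined_peaks(default_fixture):
    """Consensus peaks from the full refinement on the default fixture."""
    sim = default_fixture["sim"]
    m1, m2 = sim.tracks["MEL18"]
    conc = pt.concordant_regions(
        sim.regions["MEL18"][0], sim.regions["MEL18"][1], m1, m2
    )
    peaks, log = pt.refine_peaks(conc, m1, m2)
    from ptetools.peaks import peaks_to_frame

    return {"concordant": conc, "peaks": peaks_to_frame(peaks), "log": log}


@pytest.fixture(scope="session")
def small_fixture():
    """A fast 2 x 400 kb genome with 4 PTEs and 2 PRC2-only loci."""
    spec = pt.SyntheticGenomeSpec(
        n_chromosomes=2,
        chrom_length=400_000,
        n_genes=10,
        n_pte_loci=4,
        n_prc2_only_loci=2,
        seed=11,
    )
    genome, truth = pt.generate_genome(spec)
    sim = pt.generate_tracks(genome, truth, seed=11)
    return {"spec": spec, "genome": genome, "truth": truth, "sim": sim}


@pytest.fixture(scope="session")
def many_peak_fixture():
    """>=50 planted PTEs (for pairing-distance statistics); MEL18 only."""
    spec = pt.SyntheticGenomeSpec(
        n_chromosomes=4,
        chrom_length=2_000_000,
        n_genes=56,
        n_pte_loci=56,
        n_prc2_only_loci=0,
        seed=5,
    )
    genome, truth = pt.generate_genome(spec)
    sim = pt.generate_tracks(
        genome, truth, specs=[TrackSpec("MEL18")], seed=5
    )
    return {"spec": spec, "genome": genome, "truth": truth, "sim": sim}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
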