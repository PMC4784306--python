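"""Shared fixtures: small genomes, reference frequencies, simulated cohorts."""
import numpy as np
import pytest

from mosaictrace import simulate, vcfio

# Published scenario values used as generative truth throughout the suite:
# founding African population, 11.9 % European pulse 13 generations ago;
# three-way composition 79.1/9.3/11.6 % (AFR/EUR/NAT).
PULSE_T = 13
PULSE_EUR = 0.119
Q_TOC1 = {"AFR": 0.791, "EUR": 0.093, "NAT": 0.116}


@pytest.fixture(scope="session")
def gmap22():
    return vcfio.GeneticMap.uniform(n_chrom=22, morgans=1.5)


@pytest.fixture(scope="session")
def gmap4():
    return vcfio.GeneticMap.uniform(n_chrom=4, morgans=1.0)


@pytest.fixture(scope="session")
def two_way_paths(gmap22):
    """Forward-simulated two-way cohort at the published pulse parameters."""
    history = simulate.PulseHistory(
        "AFR", (simulate.Pulse(PULSE_T, "EUR", PULSE_EUR),))
    return simulate.simulate_admixed_forward(
        history, gmap22, pop_size=500, n_out=84, seed=20_240_101)


@pytest.fixture(scope="session")
def three_way_paths(gmap22):
    """Three-way cohort: EUR pulse at 13, NAT pulse at 10 generations."""
    history = simulate.PulseHistory(
        "AFR", (simulate.Pulse(13, "EUR", 0.119), simulate.Pulse(10, "NAT", 0.12)))
    return simulate.simulate_admixed_forward(
        history, gmap22, pop_size=500, n_out=84, seed=20_240_202)


@pytest.fixture(scope="session")
def ref_freqs4(gmap4):
    """Three-population Balding-Nichols frequencies on the small genome."""
    return simulate.sample_ref_freqs(
        3000, ["AFR", "EUR", "NAT"], 0.15, seed=11, genetic_map=gmap4)


def make_table(chrom, pos, haps, samples, ref="A", alt="G", aa=None, pops=None):
    """Hand-build a VariantTable from python lists."""
    n = len(pos)
    haps = np.asarray(haps, dtype=np.int8)
    return vcfio.VariantTable(
        np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64),
        np.full(n, ref, dtype=object) if isinstance(ref, str) else np.asarray(ref, dtype=object),
        np.full(n, alt, dtype=object) if isinstance(alt, str) else np.asarray(alt, dtype=object),
        np.full(n, "", dtype=object) if aa is None else np.asarray(aa, dtype=object),
        haps, list(samples), pops or {},
    )
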