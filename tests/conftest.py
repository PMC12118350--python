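"""Shared fixtures: hand-built graphs and session-scoped simulations.

The heavy coalescent simulations (25-Mb stepping-stone replicates, the
pulse-recovery and null-calibration replicate sets) are session fixtures so
that unit tests and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from admixscreen.ags import AdmixtureGraph, Pulse, simulate_ags_genotypes
from admixscreen.dataset import SNPDataset
from admixscreen.fstats import compute_f2_blocks
from admixscreen.landscape import build_hex_landscape
from admixscreen.qpadm import fit_qpadm, qpwave_test
from admixscreen.ssl import sample_gene_flows, simulate_ssl


# ---------------------------------------------------------------------------
# hand-built graphs
# ---------------------------------------------------------------------------

def pulse_recovery_graph() -> AdmixtureGraph:
    """Two deeply diverged source clades, a 30/70 pulse into the target,
    rights differentially related to the two sides."""
    parents = {
        "anc": "top", "O2": "top", "O": "anc", "M": "anc",
        "M1": "M", "M2": "M", "R1": "M1", "X1": "M1", "R2": "M2", "X2": "M2",
        "A": "X1", "S1": "X1", "B": "X2", "S2": "X2",
        "T": "S1", "S1b": "S1", "S2b": "S2",
    }
    origin = {
        "top": 3400.0, "anc": 3200.0, "O2": 3200.0, "O": 3000.0, "M": 3000.0,
        "M1": 2800.0, "M2": 2800.0, "R1": 1600.0, "X1": 1600.0,
        "R2": 1600.0, "X2": 1600.0, "A": 1400.0, "S1": 1400.0,
        "B": 1400.0, "S2": 1400.0, "T": 1000.0, "S1b": 1000.0, "S2b": 1000.0,
    }
    sample = {g: 0.0 for g in ("A", "B", "T", "S1b", "S2b", "O", "O2", "R1", "R2")}
    return AdmixtureGraph(
        leaves=sorted(sample),
        parents=parents,
        origin_time=origin,
        ne={n: 2000 for n in origin},
        sample_time=sample,
        pulses=[Pulse(900.0, "T", "S2b", 0.7)],
        max_depth=3400.0,
    )


def cladal_null_graph() -> AdmixtureGraph:
    """Two groups split 5 generations ago (effectively one panmictic
    population) plus a nested chain of outgroups."""
    parents = {
        "P": "c1", "R1": "c1", "c1": "c2", "R2": "c2", "c2": "c3",
        "R3": "c3", "c3": "c4", "R4": "c4", "L1": "P", "L2": "P",
    }
    origin = {
        "c4": 1800.0, "c3": 1600.0, "R4": 1600.0, "c2": 1400.0, "R3": 1400.0,
        "c1": 1200.0, "R2": 1200.0, "P": 1000.0, "R1": 1000.0,
        "L1": 5.0, "L2": 5.0,
    }
    sample = {g: 0.0 for g in ("L1", "L2", "R1", "R2", "R3", "R4")}
    return AdmixtureGraph(
        leaves=sorted(sample),
        parents=parents,
        origin_time=origin,
        ne={n: 2000 for n in origin},
        sample_time=sample,
        pulses=[],
        max_depth=2000.0,
    )


def toy_dataset(genotypes, groups, ploidy="diploid", chrom=None, pos=None):
    """Small in-memory dataset from an explicit genotype matrix."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = geno.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.ones(n_sites, dtype=int),
            "pos": pos if pos is not None else np.arange(1, n_sites + 1),
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n_ind)],
            "group": groups,
            "date": 0.0,
        }
    )
    return SNPDataset(geno, sites, individuals, ploidy)


# ---------------------------------------------------------------------------
# session-scoped simulations
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def landscape():
    return build_hex_landscape(64)


@pytest.fixture(scope="session")
def sparse_ssl_dataset(landscape):
    """One 25-Mb replicate of the sparsest landscape, present slice only."""
    flows = sample_gene_flows(landscape, "1e-5_1e-4", seed=11)
    return simulate_ssl(landscape, flows, genome_len=25e6, seed=11, sample_times=(0,))


@pytest.fixture(scope="session")
def dense_ssl_dataset(landscape):
    """One 25-Mb replicate of the densest landscape, all three slices."""
    flows = sample_gene_flows(landscape, "1e-3_1e-2", seed=11)
    return simulate_ssl(landscape, flows, genome_len=25e6, seed=11)


@pytest.fixture(scope="session")
def recovery_fits():
    """qpAdm fits of the 30/70 pulse model over 20 simulation replicates."""
    graph = pulse_recovery_graph()
    fits = []
    for rep in range(20):
        data = simulate_ags_genotypes(
            graph, n_chrom=2, chrom_len=10_000_000, seed=100 + rep,
            samples_per_leaf=5,
        )
        blocks = compute_f2_blocks(data, blgsize=500_000)
        fits.append(
            fit_qpadm("T", ("S1b", "S2b"), ("O", "O2", "R1", "R2"), blocks)
        )
    return fits


@pytest.fixture(scope="session")
def null_qpwave_pvalues():
    """qpWave rank-0 P-values for a cladal left pair, 100 replicates of 20
    unlinked 1-Mb chromosomes (one jackknife block each)."""
    graph = cladal_null_graph()
    pvals = []
    for rep in range(100):
        data = simulate_ags_genotypes(
            graph, n_chrom=20, chrom_len=1_000_000, seed=300 + rep,
            samples_per_leaf=3,
        )
        blocks = compute_f2_blocks(data, blgsize=1_000_000)
        res = qpwave_test(("L1", "L2"), ("R1", "R2", "R3", "R4"), 0, blocks)
        pvals.append(res.p_value)
    return np.array(pvals)
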