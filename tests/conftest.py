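import numpy as np
import pandas as pd
import pytest

import admixkit as ak


def make_snp_table(n, chrom="1", spacing=10_000):
    pos = np.arange(spacing, spacing * (n + 1), spacing)
    return pd.DataFrame({
        "snp_id": [f"s{chrom}_{p}" for p in pos],
        "chromosome": chrom,
        "genetic_pos": pos * 1e-8,
        "physical_pos": pos,
        "allele_ref": "A",
        "allele_alt": "G",
    })


def random_matrix(rng, n_samples=6, n_snps=40, missing_rate=0.1,
                  n_chromosomes=2):
    """A random valid GenotypeMatrix split over chromosomes."""
    per = n_snps // n_chromosomes
    snps = pd.concat([make_snp_table(per, chrom=str(c + 1))
                      for c in range(n_chromosomes)], ignore_index=True)
    geno = rng.integers(0, 3, size=(n_samples, len(snps))).astype(np.int8)
    if missing_rate:
        geno[rng.random(geno.shape) < missing_rate] = ak.MISSING
    samples = pd.DataFrame({
        "sample_id": [f"ind{i}" for i in range(n_samples)],
        "population": ["P1" if i < n_samples // 2 else "P2"
                       for i in range(n_samples)],
        "sex": 0,
    })
    return ak.GenotypeMatrix(geno, samples, snps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_pop_freqs():
    """True frequencies for two populations drifted F=0.05 off one root."""
    cfg = ak.DriftTreeConfig(
        branches={"root": (None, 0.0), "A": ("root", 0.05),
                  "B": ("root", 0.05)},
        layout=ak.ChromosomeLayout(n_chromosomes=4, snps_per_chromosome=500),
        seed=11)
    return cfg, ak.simulate_frequencies(cfg)


@pytest.fixture
def clade_tree():
    """North/south clades with per-clade relatives and outgroups; the
    structured setting qpWave/qpAdm need for identifiability."""
    branches = {"root": (None, 0.0), "ANC": ("root", 0.02),
                "NORTH": ("ANC", 0.03), "SOUTH": ("ANC", 0.03),
                "N": ("NORTH", 0.05), "S": ("SOUTH", 0.05)}
    for i in range(4):
        branches[f"NR{i}"] = ("NORTH", 0.05)
        branches[f"SR{i}"] = ("SOUTH", 0.05)
        branches[f"O{i}"] = ("root", 0.1)
    right = ([f"NR{i}" for i in range(4)] + [f"SR{i}" for i in range(4)]
             + [f"O{i}" for i in range(4)])
    return branches, right
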