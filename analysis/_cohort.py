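"""Shared synthetic study cohort for the numbered analysis scripts.

The cohort emulates the assumed structure of a Tai-Kadai-style study
design: northern and southern population clades diverged under drift from a
common ancestor, per-clade reference populations, distant outgroups, an
admixed target of minor-northern / major-southern ancestry (both a
frequency-mixing version for f-statistics/qpAdm and a mosaic version for
LD dating), inbred individuals carrying long homozygous tracts, close
relatives, and one locus under target-branch selection.
"""

from pathlib import Path

import numpy as np

import admixkit as ak

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 20240901
ALPHA_SOUTH = 0.88
ADMIXTURE_GENERATIONS = 20
SWEEP_DELTA = 0.4

RIGHT_POPS = ([f"NR{i}" for i in range(4)] + [f"SR{i}" for i in range(4)]
              + [f"O{i}" for i in range(4)])


def drift_config(seed=SEED):
    branches = {"root": (None, 0.0), "ANC": ("root", 0.02),
                "NORTH": ("ANC", 0.03), "SOUTH": ("ANC", 0.03),
                "N": ("NORTH", 0.05), "S": ("SOUTH", 0.05)}
    for i in range(4):
        branches[f"NR{i}"] = ("NORTH", 0.05)
        branches[f"SR{i}"] = ("SOUTH", 0.05)
        branches[f"O{i}"] = ("root", 0.1)
    layout = ak.ChromosomeLayout(n_chromosomes=10, snps_per_chromosome=3000,
                                 bp_spacing=30_000)
    return ak.DriftTreeConfig(branches=branches, layout=layout, seed=seed)


def build_cohort(seed=SEED):
    """Simulate the full cohort; returns (config, truth freqs, genotypes,
    truth manifest)."""
    cfg = drift_config(seed)
    fr = ak.simulate_frequencies(cfg)
    g = ak.simulate_genotypes(fr, 25, seed=seed + 1,
                              populations=["N", "S"] + RIGHT_POPS)
    target = ak.simulate_admixed_population(
        fr, ak.AdmixtureEventConfig("Bouyei_like", ("N", "S"),
                                    (1 - ALPHA_SOUTH, ALPHA_SOUTH)),
        30, seed=seed + 2)
    g = ak.stack_samples(g, target)
    anchored = np.flatnonzero((fr["root"] > 0.25) & (fr["root"] < 0.35))
    sweep_snp = fr.snps["snp_id"].iloc[int(anchored[len(anchored) // 2])]
    features = [
        ak.PlantedFeature("selected_locus",
                          {"target": "Bouyei_like", "snp_id": sweep_snp,
                           "delta": SWEEP_DELTA}),
        ak.PlantedFeature("roh_segment",
                          {"sample_id": "Bouyei_like_0", "chromosome": "1",
                           "start_bp": 10_000_000, "end_bp": 14_500_000}),
        ak.PlantedFeature("relative_pair",
                          {"sample_a": "Bouyei_like_1",
                           "sample_b": "Bouyei_like_2",
                           "relationship": "duplicate"}),
        ak.PlantedFeature("relative_pair",
                          {"sample_a": "Bouyei_like_3",
                           "sample_b": "Bouyei_like_4",
                           "relationship": "parent_offspring"}),
    ]
    g, manifest = ak.plant_features(g, features, fr, seed=seed + 3)
    return cfg, fr, g, manifest


def build_mosaic_target(fr, seed=SEED):
    """Mosaic-chromosome version of the admixed target, for LD dating."""
    ev = ak.AdmixtureEventConfig("Bouyei_like", ("N", "S"),
                                 (1 - ALPHA_SOUTH, ALPHA_SOUTH),
                                 generations_ago=ADMIXTURE_GENERATIONS)
    return ak.simulate_admixed_mosaics(fr, ev, 30, seed=seed + 4)
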