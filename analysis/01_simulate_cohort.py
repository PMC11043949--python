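#!/usr/bin/env python
"""Simulate the study cohort and write it to disk.

Builds the synthetic north/south cohort with its admixed target and planted
ground truth (selective sweep, ROH tract, duplicate and parent-offspring
pairs), writes the genotypes in EIGENSTRAT format under scratch/ (they are
large and regenerable), the truth manifest and a gene annotation under
results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import admixkit as ak
from _cohort import RESULTS, SCRATCH, SEED, build_cohort, drift_config


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cfg, fr, g, manifest = build_cohort()
    ak.write_genotypes(g, SCRATCH / "cohort", "eigenstrat")
    (RESULTS / "truth_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    ak.write_fixture_annotation(cfg.layout, 50, RESULTS / "genes.bed")
    counts = g.samples.population.value_counts()
    print(f"cohort: {g.n_samples} samples, {g.n_snps} SNPs, "
          f"{len(counts)} populations (seed {SEED})")
    print(f"planted: sweep at {manifest['selected_loci'][0]['snp_id']} "
          f"(delta={manifest['selected_loci'][0]['delta']}), "
          f"{len(manifest['roh_segments'])} ROH tract, "
          f"{len(manifest['relative_pairs'])} relative pairs")
    print(f"wrote {SCRATCH / 'cohort'}.geno/.snp/.ind and "
          f"{RESULTS / 'truth_manifest.json'}")


if __name__ == "__main__":
    main()
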