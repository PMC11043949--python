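#!/usr/bin/env python
"""Population structure and per-genome QC of the cohort.

Reads the simulated cohort, then: KING-robust kinship with relatedness
flagging (recovers the planted duplicate and parent-offspring pairs), a
missingness + LD-pruning QC pass, PCA with the admixed target projected
onto the reference axes, the pairwise Hudson FST matrix of the main
populations, ROH calling (recovers the planted tract), and IBD segment
binning on a simulated segment-length table.  Tables land in results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

import admixkit as ak
from _cohort import RESULTS, SCRATCH, SEED


def main():
    g = ak.read_genotypes(SCRATCH / "cohort", "eigenstrat")
    print(f"loaded cohort: {g.n_samples} samples x {g.n_snps} SNPs")

    kinship = ak.king_kinship(g)
    close = kinship[kinship.kinship >= 0.0884].sort_values(
        "kinship", ascending=False)
    close.to_csv(RESULTS / "kinship_flagged.tsv", sep="\t", index=False)
    removed = ak.flag_related(kinship)
    print(f"kinship: {len(close)} pairs at 2nd degree or closer; "
          f"removing {removed} keeps the rest unrelated")

    keep = [s for s in g.samples.sample_id if s not in removed]
    g = g.take_samples(g.sample_index(keep))
    g = ak.filter_missingness(g, 0.05, 0.05)

    segs = ak.call_roh(g)
    roh = pd.DataFrame([vars(s) | {"length_bp": s.length_bp} for s in segs])
    roh.to_csv(RESULTS / "roh_segments.tsv", sep="\t", index=False)
    print(f"ROH: {len(segs)} segment(s) called; longest "
          f"{max((s.length_bp for s in segs), default=0) / 1e6:.1f} Mb "
          f"in {segs[0].sample_id if segs else 'n/a'}")

    pops = ["N", "S", "NR0", "SR0", "O0", "Bouyei_like"]
    af = ak.allele_frequencies(g)
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            v = ak.pairwise_fst(af, a, b).estimate
            fst.loc[a, b] = fst.loc[b, a] = v
    fst.round(5).to_csv(RESULTS / "fst_matrix.tsv", sep="\t")
    print("pairwise Hudson FST written; Bouyei_like is closest to "
          f"{fst.loc['Bouyei_like'].drop('Bouyei_like').idxmin()}")

    pruned = ak.ld_prune(g, 200, 25, 0.4)
    ref_ids = [s for s in pruned.samples.sample_id
               if not s.startswith("Bouyei_like")]
    proj_ids = [s for s in pruned.samples.sample_id
                if s.startswith("Bouyei_like")]
    pca = ak.pca_project(pruned, ref_ids, proj_ids, k=4)
    pca.coordinates.round(4).to_csv(RESULTS / "pca_coordinates.tsv",
                                    sep="\t", index=False)
    print(f"PCA: top-4 PCs explain {100 * pca.explained_variance.sum():.1f}% "
          "of reference variance; projected target coordinates written")

    # IBD binning on a simulated segment-length table (segment *detection*
    # is outside this package's scope)
    rng = np.random.default_rng(SEED + 9)
    pairs = rng.choice(proj_ids, size=(60, 2))
    ibd = pd.DataFrame({"sample_a": pairs[:, 0], "sample_b": pairs[:, 1],
                        "length_cm": rng.exponential(2.5, 60)})
    binned = ak.classify_ibd_segments(ibd, drop_shortest=True)
    counts = ak.ibd_bin_counts(binned)
    counts.to_csv(RESULTS / "ibd_bin_counts.tsv", sep="\t", index=False)
    print("IBD bins (shortest class dropped):",
          dict(zip(counts["bin"], counts["n_segments"])))


if __name__ == "__main__":
    main()
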