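#!/usr/bin/env python
"""Admixture signals and proportions via f-statistics and qpWave/qpAdm.

Runs admixture-f3 on the target (expects a strongly negative Z), f4
symmetry tests against the two source clades, the outgroup-f3 shared-drift
matrix with its neighbor-joining phylogeny, pairwise qpWave homogeneity
labels, and the two-way qpAdm model of the target (truth: 12% northern /
88% southern).  Outputs: TSV tables, a Newick tree, and a qpAdm JSON.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

import admixkit as ak
from _cohort import ALPHA_SOUTH, RESULTS, RIGHT_POPS, SCRATCH


def main():
    g = ak.read_genotypes(SCRATCH / "cohort", "eigenstrat")
    af = ak.allele_frequencies(g)
    target = "Bouyei_like"

    rows = []
    mixed = ak.f3(af, target, "N", "S")
    rows.append(("f3", f"{target};N,S", mixed.estimate,
                 mixed.jackknife.standard_error, mixed.z_score,
                 mixed.n_snps_used,
                 ak.classify_admixture_f3(mixed)))
    for a, b in (("N", "S"), ("NR0", "SR0")):
        r = ak.f4(af, target, "O0", a, b)
        rows.append(("f4", f"{target},O0;{a},{b}", r.estimate,
                     r.jackknife.standard_error, r.z_score, r.n_snps_used,
                     ""))
    fdf = pd.DataFrame(rows, columns=["statistic", "populations", "estimate",
                                      "se", "z", "n_snps", "classification"])
    fdf.to_csv(RESULTS / "f_statistics.tsv", sep="\t", index=False)
    print(f"admixture-f3({target}; N, S): {mixed.estimate:.5f} "
          f"(Z = {mixed.z_score:.1f}) -> {ak.classify_admixture_f3(mixed)}")

    pops = ["N", "S", "NR0", "NR1", "SR0", "SR1", target]
    tree = ak.outgroup_f3_nj_tree(af, pops, "O0")
    (RESULTS / "outgroup_f3_nj.nwk").write_text(tree.newick + "\n")
    print(f"outgroup-f3 NJ tree over {len(pops)} populations written "
          f"({'has' if tree.has_negative_branches else 'no'} negative "
          "branches)")

    labels = {}
    for pair in (("N", "S"), ("NR0", "NR1"), ("SR0", "SR1")):
        res = ak.qpwave_rank_test(af, list(pair),
                                  [p for p in RIGHT_POPS if p not in pair])
        labels["-".join(pair)] = (ak.pairwise_qpwave_labels(res),
                                  res.p_rank[0])
    qw = pd.DataFrame([(k, v[0], v[1]) for k, v in labels.items()],
                      columns=["pair", "label", "p_rank0"])
    qw.to_csv(RESULTS / "pairwise_qpwave.tsv", sep="\t", index=False)
    print("pairwise qpWave:", {k: v[0] for k, v in labels.items()})

    model = ak.qpadm(af, target, ["N", "S"], RIGHT_POPS)
    report = {"target": target, "sources": model.sources,
              "weights": model.weights.tolist(),
              "weight_se": model.weight_se.tolist(),
              "p_rank": {str(k): v for k, v in model.p_rank.items()},
              "feasible": model.feasible,
              "truth_southern": ALPHA_SOUTH,
              "n_snps": model.n_snps_used}
    (RESULTS / "qpadm_model.json").write_text(
        json.dumps(report, indent=2) + "\n")
    print(f"qpAdm: southern ancestry {model.weights[1]:.3f} "
          f"+/- {model.weight_se[1]:.3f} (truth {ALPHA_SOUTH})")


if __name__ == "__main__":
    main()
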