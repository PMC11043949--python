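"""f-statistics, NJ trees, and qpWave/qpAdm admixture modelling."""

import numpy as np
import pandas as pd
import pytest

import admixkit as ak
from admixkit.stats import AlleleFrequencyTable
from conftest import make_snp_table


def infinite_table(p_by_pop, n_snps=None):
    pops = list(p_by_pop)
    alt = np.vstack([np.atleast_1d(np.asarray(p_by_pop[p], float))
                     for p in pops])
    snps = make_snp_table(alt.shape[1])
    return AlleleFrequencyTable(pops, alt, np.full_like(alt, np.inf), snps)


@pytest.fixture(scope="module")
def drift_table():
    """Sampled frequencies for populations on a small drift tree."""
    cfg = ak.DriftTreeConfig(
        branches={"r": (None, 0.0), "A": ("r", 0.05), "B": ("r", 0.05),
                  "C": ("r", 0.05), "D": ("r", 0.05), "X": ("r", 0.05),
                  "O": ("r", 0.2)},
        layout=ak.ChromosomeLayout(4, 1500), seed=61)
    fr = ak.simulate_frequencies(cfg)
    g = ak.simulate_genotypes(fr, 25, seed=62,
                              populations=list("ABCDXO"))
    return ak.allele_frequencies(g)


# -- f2 / f3 / f4 -----------------------------------------------------------

def test_f2_infinite_sample_hand_value():
    af = infinite_table({"A": [0.8] * 2, "B": [0.2] * 2})
    res = ak.f2(af, "A", "B", blocks=np.array([0, 1]))
    assert res.estimate == pytest.approx(0.36, abs=1e-12)


def test_f2_between_halves_of_one_population_is_null():
    """Self comparison: two disjoint sample sets of the same population have
    true f2 = 0 and the corrected estimator sees that (|Z| < 3).  (Feeding
    the *identical* sample set into both slots is not a valid null: the
    sampling correction is then subtracted twice from an exact zero.)"""
    hits = 0
    for seed in range(10):
        cfg = ak.DriftTreeConfig(
            branches={"r": (None, 0.0), "A": ("r", 0.05)},
            layout=ak.ChromosomeLayout(4, 1500), seed=66 + seed)
        fr = ak.simulate_frequencies(cfg)
        g = ak.simulate_genotypes(fr, 40, seed=80 + seed, populations=["A"])
        ids = [f"A_{i}" for i in range(40)]
        grouping = ak.PopulationGrouping({"A1": ids[:20], "A2": ids[20:]})
        af = ak.allele_frequencies(g, grouping)
        hits += abs(ak.f2(af, "A1", "A2").z_score) < 3
    assert hits >= 9


def test_f2_symmetric(drift_table):
    ab = ak.f2(drift_table, "A", "B")
    ba = ak.f2(drift_table, "B", "A")
    assert ab.estimate == pytest.approx(ba.estimate, rel=1e-12)


def test_f3_degenerate_target_uncorrected_zero():
    rng = np.random.default_rng(0)
    p1 = rng.uniform(0.1, 0.9, 40)
    p2 = rng.uniform(0.1, 0.9, 40)
    af = infinite_table({"T": p1, "S1": p1, "S2": p2})
    res = ak.f3(af, "T", "S1", "S2", corrected=False,
                blocks=np.arange(40) // 10)
    assert res.estimate == pytest.approx(0.0, abs=1e-15)


def test_f3_rejects_target_among_sources(drift_table):
    with pytest.raises(ValueError):
        ak.f3(drift_table, "A", "A", "B")


def test_f4_hand_value_and_duplicate_column():
    af = infinite_table({"A": [0.8] * 2, "B": [0.2] * 2, "C": [0.9] * 2,
                         "D": [0.1] * 2})
    res = ak.f4(af, "A", "B", "C", "D", blocks=np.array([0, 1]))
    assert res.estimate == pytest.approx(0.48, abs=1e-12)
    null = ak.f4(af, "A", "B", "C", "C", blocks=np.array([0, 1]))
    assert null.estimate == 0.0


def test_f4_antisymmetry_and_linearity(drift_table):
    blocks = ak.assign_blocks(drift_table.snps)
    f = lambda *args: ak.f4(drift_table, *args, blocks=blocks).estimate
    assert f("A", "B", "C", "D") == pytest.approx(-f("B", "A", "C", "D"),
                                                  rel=1e-12)
    assert f("A", "B", "C", "D") == pytest.approx(-f("A", "B", "D", "C"),
                                                  rel=1e-12)
    # linearity through an intermediate population X
    assert f("A", "B", "C", "D") == pytest.approx(
        f("A", "X", "C", "D") + f("X", "B", "C", "D"), abs=1e-12)


def test_f2_equals_f4_of_pair_uncorrected(drift_table):
    blocks = ak.assign_blocks(drift_table.snps)
    f2u = ak.f2(drift_table, "A", "B", blocks=blocks, corrected=False)
    f4v = ak.f4(drift_table, "A", "B", "A", "B", blocks=blocks)
    assert f2u.estimate == pytest.approx(f4v.estimate, rel=1e-12)


def test_admixture_f3_detects_mixture_and_control():
    cfg = ak.DriftTreeConfig(
        branches={"r": (None, 0.0), "S1": ("r", 0.1), "S2": ("r", 0.1),
                  "T2": ("S1", 0.05)},
        layout=ak.ChromosomeLayout(4, 2500), seed=63)
    fr = ak.simulate_frequencies(cfg)
    g = ak.simulate_genotypes(fr, 25, seed=64, populations=["S1", "S2", "T2"])
    gt = ak.simulate_admixed_population(
        fr, ak.AdmixtureEventConfig("T", ("S1", "S2"), (0.5, 0.5)), 25,
        seed=65)
    af = ak.allele_frequencies(ak.stack_samples(g, gt))
    mixed = ak.f3(af, "T", "S1", "S2")
    assert mixed.estimate < 0 and mixed.z_score < -3
    assert ak.classify_admixture_f3(mixed) == "admixture_signal"
    control = ak.f3(af, "T2", "S1", "S2")
    assert control.estimate > 0
    assert ak.classify_admixture_f3(control) == "no_signal"
    # the relaxed threshold only widens the signal class
    borderline = ak.fstats.FStatResult(
        "f3", ("T", "S1", "S2"),
        ak.BlockJackknifeEstimate("f3", -0.001, np.zeros(2), np.ones(2),
                                  0.0004, 100))
    assert ak.classify_admixture_f3(borderline) == "no_signal"       # Z=-2.5
    assert ak.classify_admixture_f3(borderline,
                                    relaxed=True) == "admixture_signal"


# -- outgroup f3 + NJ -------------------------------------------------------

def test_outgroup_f3_matrix_symmetric(drift_table):
    m = ak.outgroup_f3_matrix(drift_table, ["A", "B", "C"], "O")
    assert np.allclose(m, m.T)
    with pytest.raises(ValueError):
        ak.outgroup_f3_matrix(drift_table, ["A", "O"], "O")


def test_nj_three_taxon_closed_form():
    d = pd.DataFrame([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                     index=list("ABC"), columns=list("ABC"), dtype=float)
    tree = ak.nj_tree(d)
    assert tree.newick == "(A:0.5,B:1.5,C:2.5);"
    assert not tree.has_negative_branches


def test_nj_recovers_additive_tree_topology():
    """NJ on additive distances from a known 6-leaf tree, cross-checked with
    an independent NJ implementation (scikit-bio)."""
    import dendropy
    import skbio
    true = "((P1:1,P2:1):1,((P3:1,P4:1):1,(P5:1,P6:1):1):1);"
    tns = dendropy.TaxonNamespace()
    t_true = dendropy.Tree.get(data=true, schema="newick",
                               taxon_namespace=tns)
    pdm = t_true.phylogenetic_distance_matrix()
    labels = [f"P{i}" for i in range(1, 7)]
    taxa = {t.label: t for t in tns}
    d = pd.DataFrame(
        [[pdm.distance(taxa[a], taxa[b]) for b in labels] for a in labels],
        index=labels, columns=labels, dtype=float)
    ours = ak.nj_tree(d)
    t_ours = dendropy.Tree.get(data=ours.newick, schema="newick",
                               taxon_namespace=tns)
    t_ours.encode_bipartitions()
    t_true.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(
        t_ours, t_true) == 0
    # independent oracle agrees on the topology
    sk = skbio.tree.nj(skbio.DistanceMatrix(d.to_numpy(), ids=labels))
    t_sk = dendropy.Tree.get(data=str(sk), schema="newick",
                             taxon_namespace=tns)
    t_sk.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(
        t_ours, t_sk) == 0


def test_nj_flags_negative_branches():
    d = pd.DataFrame([[0, 1, 10, 10], [1, 0, 1, 1], [10, 1, 0, 1],
                      [10, 1, 1, 0]],
                     index=list("ABCD"), columns=list("ABCD"), dtype=float)
    tree = ak.nj_tree(d)  # wildly non-additive distances
    assert tree.has_negative_branches


# -- qpWave / qpAdm ---------------------------------------------------------

@pytest.fixture(scope="module")
def clade_data(request):
    branches = {"root": (None, 0.0), "ANC": ("root", 0.02),
                "NORTH": ("ANC", 0.03), "SOUTH": ("ANC", 0.03),
                "N": ("NORTH", 0.05), "S": ("SOUTH", 0.05)}
    for i in range(4):
        branches[f"NR{i}"] = ("NORTH", 0.05)
        branches[f"SR{i}"] = ("SOUTH", 0.05)
        branches[f"O{i}"] = ("root", 0.1)
    right = ([f"NR{i}" for i in range(4)] + [f"SR{i}" for i in range(4)]
             + [f"O{i}" for i in range(4)])
    cfg = ak.DriftTreeConfig(branches=branches,
                             layout=ak.ChromosomeLayout(8, 2500), seed=71)
    fr = ak.simulate_frequencies(cfg)
    g = ak.simulate_genotypes(fr, 20, seed=72, populations=["N", "S"] + right)
    gt = ak.simulate_admixed_population(
        fr, ak.AdmixtureEventConfig("T", ("N", "S"), (0.7, 0.3)), 20, seed=73)
    return ak.stack_samples(g, gt), right


def test_qpwave_accepts_homogeneous_rejects_heterogeneous(clade_data):
    g, right = clade_data
    ids = [f"N_{i}" for i in range(20)]
    grouping = ak.PopulationGrouping({
        "NA": ids[:10], "NB": ids[10:],
        "S": [f"S_{i}" for i in range(20)],
        **{p: [f"{p}_{i}" for i in range(20)] for p in right}})
    af = ak.allele_frequencies(g, grouping)
    homog = ak.qpwave_rank_test(af, ["NA", "NB"], right)
    assert list(homog.p_rank) == [0]          # |left| = 2: only rank 0
    assert homog.p_rank[0] > 0.01
    assert ak.pairwise_qpwave_labels(homog) in ("+", "++")
    hetero = ak.qpwave_rank_test(af, ["NA", "S"], right)
    assert hetero.p_rank[0] < 0.01
    assert ak.pairwise_qpwave_labels(hetero) == "-"


def test_qpwave_argument_validation(clade_data):
    g, right = clade_data
    af = ak.allele_frequencies(g)
    with pytest.raises(ValueError, match="disjoint"):
        ak.qpwave_rank_test(af, ["N", right[0]], right)
    with pytest.raises(ValueError, match="at least 2"):
        ak.qpwave_rank_test(af, ["N"], right)


def test_qpadm_recovers_two_way_weights(clade_data):
    g, right = clade_data
    af = ak.allele_frequencies(g)
    model = ak.qpadm(af, "T", ["N", "S"], right)
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-8)
    assert model.weights[0] == pytest.approx(0.7, abs=0.05)
    assert abs(model.weights[0] - 0.7) < 2 * model.weight_se[0] + 0.05
    assert model.feasible and not model.degenerate


def test_qpadm_degenerate_target_equals_source(clade_data):
    g, right = clade_data
    ids = [f"N_{i}" for i in range(20)]
    grouping = ak.PopulationGrouping({
        "Ncore": ids[:10], "Nclone": ids[10:],
        "S": [f"S_{i}" for i in range(20)],
        **{p: [f"{p}_{i}" for i in range(20)] for p in right}})
    af = ak.allele_frequencies(g, grouping)
    model = ak.qpadm(af, "Nclone", ["Ncore", "S"], right)
    assert model.weights[0] == pytest.approx(1.0, abs=2 * model.weight_se[0]
                                             + 0.02)
    assert model.weights[1] == pytest.approx(0.0, abs=2 * model.weight_se[1]
                                             + 0.02)


def test_qpadm_weights_sum_to_one_three_way(clade_data):
    g, right = clade_data
    af = ak.allele_frequencies(g)
    model = ak.qpadm(af, "T", ["N", "S", right[-1]], right[:-1])
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-8)
    assert len(model.p_rank) == 3  # ranks 0..2 tested for 3 sources


def test_qpadm_argument_validation(clade_data):
    g, right = clade_data
    af = ak.allele_frequencies(g)
    with pytest.raises(ValueError, match="target"):
        ak.qpadm(af, "N", ["N", "S"], right)
    with pytest.raises(ValueError, match="right"):
        ak.qpadm(af, "T", ["N", "S"], right[:2])
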