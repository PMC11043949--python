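"""Allele frequencies, FST estimators, kinship, ROH, IBD bins, PCA, LD."""

import numpy as np
import pandas as pd
import pytest

import admixkit as ak
from admixkit.stats import AlleleFrequencyTable
from conftest import make_snp_table, random_matrix


def freq_table(p_by_pop, n_chrom=10.0):
    pops = list(p_by_pop)
    alt = np.vstack([np.atleast_1d(np.asarray(p_by_pop[p], float))
                     for p in pops])
    snps = make_snp_table(alt.shape[1])
    return AlleleFrequencyTable(pops, alt, np.full_like(alt, n_chrom), snps)


# -- allele frequencies -----------------------------------------------------

def test_allele_frequency_counting():
    snps = make_snp_table(2)
    samples = pd.DataFrame({"sample_id": ["a", "b", "c"],
                            "population": "P", "sex": 0})
    geno = np.array([[2, 0], [2, 1], [2, 2]], dtype=np.int8)
    g = ak.GenotypeMatrix(geno, samples, snps)
    af = ak.allele_frequencies(g)
    assert af.freq("P")[0] == 1.0 and af.n("P")[0] == 6
    assert af.freq("P")[1] == 0.5 and af.n("P")[1] == 6
    g.genotypes[0, 1] = ak.MISSING
    af2 = ak.allele_frequencies(g)
    assert af2.n("P")[1] == 4  # one missing sample removes 2 chromosomes


def test_empty_population_rejected(rng):
    g = random_matrix(rng)
    grouping = ak.PopulationGrouping({"P1": list(g.samples.sample_id),
                                      "Empty": []})
    with pytest.raises(ValueError, match="zero samples"):
        ak.allele_frequencies(g, grouping)


# -- FST --------------------------------------------------------------------

def test_hudson_single_snp_hand_value():
    af = freq_table({"P1": [0.4], "P2": [0.9]})
    # single SNP cannot be jackknifed; check the components directly
    num, den = ak.stats._hudson_components(
        np.array([0.4]), np.array([0.9]), np.array([10.0]), np.array([10.0]))
    assert num[0] == pytest.approx(0.213333, abs=1e-6)
    assert den[0] == pytest.approx(0.58, abs=1e-12)
    assert num[0] / den[0] == pytest.approx(0.367816, abs=1e-6)


def test_hudson_two_snp_ratio_of_averages():
    af = freq_table({"P1": [0.4, 0.5], "P2": [0.9, 0.5]})
    res = ak.pairwise_fst(af, "P1", "P2", blocks=np.array([0, 1]))
    assert res.estimate == pytest.approx(0.146091, abs=1e-6)
    assert res.per_snp_num[1] == pytest.approx(-0.055556, abs=1e-6)


def test_identical_frequencies_give_null_fst():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.1, 0.9, 2000)
    af = AlleleFrequencyTable(
        ["P1", "P2"], np.vstack([p, p]), np.full((2, 2000), np.inf),
        make_snp_table(2000))
    res = ak.pairwise_fst(af, "P1", "P2",
                          blocks=ak.assign_blocks(af.snps, mode="count",
                                                  n_blocks=20))
    assert res.estimate == pytest.approx(0.0, abs=1e-12)


def test_hudson_symmetry_and_allele_relabelling(two_pop_freqs):
    _, fr = two_pop_freqs
    g = ak.simulate_genotypes(fr, 30, seed=2, populations=["A", "B"])
    af = ak.allele_frequencies(g)
    ab = ak.pairwise_fst(af, "A", "B")
    ba = ak.pairwise_fst(af, "B", "A")
    assert ab.estimate == pytest.approx(ba.estimate, rel=1e-12)
    flipped = AlleleFrequencyTable(af.populations, 1.0 - af.alt_freq,
                                   af.n_chrom, af.snps)
    fl = ak.pairwise_fst(flipped, "A", "B")
    assert fl.estimate == pytest.approx(ab.estimate, rel=1e-12)
    assert fl.jackknife.standard_error == pytest.approx(
        ab.jackknife.standard_error, rel=1e-12)


def test_weir_cockerham_tracks_hudson_on_drifted_data(two_pop_freqs):
    _, fr = two_pop_freqs
    g = ak.simulate_genotypes(fr, 50, seed=4, populations=["A", "B"])
    af = ak.allele_frequencies(g)
    hudson = ak.pairwise_fst(af, "A", "B").estimate
    wc = ak.pairwise_fst(af, "A", "B", estimator="weir_cockerham").estimate
    assert wc == pytest.approx(hudson, abs=0.02)
    assert wc > 0


def test_fst_excludes_underobserved_snps():
    af = freq_table({"P1": [0.2, 0.4, 0.6], "P2": [0.3, 0.5, 0.7]})
    af.n_chrom[1, 1] = 0
    af.alt_freq[1, 1] = np.nan
    res = ak.pairwise_fst(af, "P1", "P2", blocks=np.array([0, 1, 2]))
    assert res.jackknife.n_snps_used == 2
    assert not res.valid[1]


# -- kinship ----------------------------------------------------------------

@pytest.fixture(scope="module")
def kin_matrix():
    cfg = ak.DriftTreeConfig(
        branches={"r": (None, 0.0), "A": ("r", 0.1), "B": ("r", 0.1)},
        layout=ak.ChromosomeLayout(4, 1500), seed=21)
    fr = ak.simulate_frequencies(cfg)
    g = ak.simulate_genotypes(fr, 4, seed=22, populations=["A", "B"])
    feats = [ak.PlantedFeature("relative_pair",
                               {"sample_a": "A_0", "sample_b": "A_1",
                                "relationship": "duplicate"}),
             ak.PlantedFeature("relative_pair",
                               {"sample_a": "A_2", "sample_b": "A_3",
                                "relationship": "parent_offspring"})]
    g2, _ = ak.plant_features(g, feats, fr, seed=23)
    return ak.king_kinship(g2)


def pair(table, a, b):
    row = table[((table.sample_a == a) & (table.sample_b == b))
                | ((table.sample_a == b) & (table.sample_b == a))]
    return float(row.kinship.iloc[0]), row.degree.iloc[0]


def test_duplicate_pair_is_half(kin_matrix):
    phi, degree = pair(kin_matrix, "A_0", "A_1")
    assert phi == pytest.approx(0.5, abs=0.02)
    assert degree == "duplicate_mz"


def test_parent_offspring_first_degree(kin_matrix):
    phi, degree = pair(kin_matrix, "A_2", "A_3")
    assert 0.177 <= phi < 0.354
    assert degree == "first_degree"


def test_cross_population_pairs_unrelated(kin_matrix):
    for a in ("A_0", "A_2"):
        for b in ("B_0", "B_1"):
            phi, degree = pair(kin_matrix, a, b)
            assert phi < 0.0884
            assert degree == "unrelated"


def test_flag_related_breaks_all_pairs(kin_matrix):
    removed = ak.flag_related(kin_matrix)
    keep = set(kin_matrix.sample_a) | set(kin_matrix.sample_b)
    keep -= set(removed)
    rest = kin_matrix[kin_matrix.sample_a.isin(keep)
                      & kin_matrix.sample_b.isin(keep)]
    assert (rest.kinship < 0.0884).all()
    assert len(removed) == 2  # one from each planted pair suffices


def test_no_overlap_pair_is_undefined():
    snps = make_snp_table(4)
    samples = pd.DataFrame({"sample_id": ["a", "b"], "population": "P",
                            "sex": 0})
    geno = np.array([[1, 1, ak.MISSING, ak.MISSING],
                     [ak.MISSING, ak.MISSING, 1, 1]], dtype=np.int8)
    table = ak.king_kinship(ak.GenotypeMatrix(geno, samples, snps))
    assert table.degree.iloc[0] == "undefined"


# -- ROH --------------------------------------------------------------------

def het_background_matrix(n_snps=600, n_chrom=2):
    snps = pd.concat([make_snp_table(n_snps // n_chrom, chrom=str(c + 1))
                      for c in range(n_chrom)], ignore_index=True)
    samples = pd.DataFrame({"sample_id": ["s0"], "population": "P", "sex": 0})
    geno = np.ones((1, len(snps)), dtype=np.int8)  # fully heterozygous
    return ak.GenotypeMatrix(geno, samples, snps)


def test_planted_tract_recovered_exactly():
    g = het_background_matrix()
    # SNPs every 10 kb; make indices 50..199 homozygous on chromosome 1
    g.genotypes[0, 50:200] = 2
    segs = ak.call_roh(g)
    assert len(segs) == 1
    seg = segs[0]
    assert (seg.chromosome, seg.n_snps) == ("1", 150)
    assert seg.start_bp == int(g.snps.physical_pos.iloc[50])
    assert seg.end_bp == int(g.snps.physical_pos.iloc[199])
    assert seg.length_bp >= 100_000


def test_49_snp_tract_not_called():
    g = het_background_matrix()
    g.genotypes[0, 50:99] = 0
    assert ak.call_roh(g) == []


def test_fully_heterozygous_sample_yields_nothing():
    assert ak.call_roh(het_background_matrix()) == []


def test_large_gap_splits_runs():
    g = het_background_matrix(n_snps=600, n_chrom=1)
    g.genotypes[0, 100:300] = 2
    snps = g.snps.copy()
    # open a 2 Mb physical gap in the middle of the tract
    snps.loc[200:, "physical_pos"] = snps.loc[200:, "physical_pos"] + 2_000_000
    snps.loc[200:, "snp_id"] = snps.loc[200:, "snp_id"] + "_b"
    g = ak.GenotypeMatrix(g.genotypes, g.samples, snps)
    segs = ak.call_roh(g, max_gap_bp=1_000_000)
    assert len(segs) == 2
    assert {s.n_snps for s in segs} == {100}


def test_short_span_tract_rejected_by_length():
    g = het_background_matrix()
    g.genotypes[0, 50:110] = 2  # 60 SNPs but only ~0.59 Mb... span ok; shrink
    segs = ak.call_roh(g, min_length_bp=1_000_000)
    assert segs == []


def test_roh_tolerates_sparse_hets_within_allowance():
    g = het_background_matrix()
    g.genotypes[0, 50:250] = 0
    g.genotypes[0, 150] = 1  # a single embedded het within the allowance
    segs = ak.call_roh(g, het_allowance=1)
    assert len(segs) == 1 and segs[0].n_snps == 200


def test_roh_segments_never_overlap_and_respect_minima(rng):
    cfg = ak.DriftTreeConfig(
        branches={"r": (None, 0.0), "P": ("r", 0.3)},
        layout=ak.ChromosomeLayout(2, 1000), seed=31)
    fr = ak.simulate_frequencies(cfg)
    g = ak.simulate_genotypes(fr, 10, missing_rate=0.02, seed=32,
                              populations=["P"])
    segs = ak.call_roh(g)
    by_key = {}
    for s in segs:
        assert s.n_snps >= 50 and s.length_bp >= 100_000
        by_key.setdefault((s.sample_id, s.chromosome), []).append(s)
    for group in by_key.values():
        group.sort(key=lambda s: s.start_bp)
        for prev, nxt in zip(group, group[1:]):
            assert prev.end_bp < nxt.start_bp


# -- IBD binning ------------------------------------------------------------

def test_ibd_binning_and_dropping():
    df = pd.DataFrame({"sample_a": "x", "sample_b": "y",
                       "length_cm": [0.5, 0.7, 2.0, 3.2, 7.0, 1.0, 5.0]})
    out = ak.classify_ibd_segments(df)
    assert list(out["bin"]) == ["<1", "<1", "1-5", "1-5", ">5", "1-5", "1-5"]
    dropped = ak.classify_ibd_segments(df, drop_shortest=True)
    assert len(dropped) == 5 and "<1" not in set(dropped["bin"])
    counts = ak.ibd_bin_counts(out)
    assert dict(zip(counts["bin"], counts["n_segments"])) == {
        "<1": 2, "1-5": 4, ">5": 1}


def test_negative_ibd_length_rejected():
    df = pd.DataFrame({"sample_a": ["x"], "sample_b": ["y"],
                       "length_cm": [-1.0]})
    with pytest.raises(ValueError, match="negative"):
        ak.classify_ibd_segments(df)


# -- PCA --------------------------------------------------------------------

@pytest.fixture(scope="module")
def pca_setup():
    cfg = ak.DriftTreeConfig(
        branches={"r": (None, 0.0), "A": ("r", 0.1), "B": ("r", 0.1)},
        layout=ak.ChromosomeLayout(4, 1500), seed=41)
    fr = ak.simulate_frequencies(cfg)
    return ak.simulate_genotypes(fr, 25, seed=42, populations=["A", "B"])


def test_self_projection_reproduces_coordinates(pca_setup):
    g = pca_setup
    ref = list(g.samples.sample_id)
    res = ak.pca_project(g, ref, [ref[0], ref[30]], k=3)
    co = res.coordinates
    for sid in (ref[0], ref[30]):
        r = co[(co.sample_id == sid) & (co.role == "reference")]
        p = co[(co.sample_id == sid) & (co.role == "projected")]
        for pc in ("PC1", "PC2", "PC3"):
            assert float(p[pc].iloc[0]) == pytest.approx(
                float(r[pc].iloc[0]), abs=1e-8)


def test_pc1_separates_populations(pca_setup):
    g = pca_setup
    ids = list(g.samples.sample_id)
    res = ak.pca_project(g, ids, [], k=2)
    co = res.coordinates
    pops = co.sample_id.str[0]
    a, b = co[pops == "A"].PC1, co[pops == "B"].PC1
    within = max(a.std(), b.std())
    assert abs(a.mean() - b.mean()) > 5 * within


def test_explained_variance_well_formed(pca_setup):
    res = ak.pca_project(pca_setup, list(pca_setup.samples.sample_id), [], k=4)
    ev = res.explained_variance
    assert ev.sum() <= 1.0 + 1e-12
    assert np.all(np.diff(ev) <= 1e-12)


def test_k_exceeding_rank_rejected(pca_setup):
    with pytest.raises(ValueError):
        ak.pca_project(pca_setup, list(pca_setup.samples.sample_id)[:3], [],
                       k=5)


# -- pairwise r2 ------------------------------------------------------------

def test_duplicated_snp_column_r2_one(rng):
    g = random_matrix(rng, n_samples=20, missing_rate=0.0)
    g.genotypes[:, 1] = g.genotypes[:, 0]
    r2 = ak.pairwise_r2(g, np.array([0, 1, 2]))
    assert r2[0, 1] == pytest.approx(1.0, abs=1e-12)
    finite = np.isfinite(r2)
    assert np.allclose(r2[finite], r2.T[finite])
    assert (r2[finite] >= -1e-12).all() and (r2[finite] <= 1 + 1e-9).all()


def test_monomorphic_snp_flagged_undefined(rng):
    g = random_matrix(rng, n_samples=20, missing_rate=0.0)
    g.genotypes[:, 2] = 1
    r2 = ak.pairwise_r2(g, np.array([0, 1, 2]))
    assert np.isnan(r2[2]).all() and np.isnan(r2[:, 2]).all()


def test_null_ld_mean_near_one_over_n():
    n = 40
    freqs = ak.SimulatedFrequencies(
        make_snp_table(200), {"P": np.full(200, 0.5)})
    g = ak.simulate_genotypes(freqs, {"P": n}, seed=51)
    r2 = ak.pairwise_r2(g, np.arange(200), population="P")
    off = r2[np.triu_indices(200, k=1)]
    assert np.nanmean(off) == pytest.approx(1 / n, rel=0.25)
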