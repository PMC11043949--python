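"""Allele-frequency and per-genome statistics.

Covers the pre-admixture-modelling toolbox: per-population allele
frequencies, Hudson and Weir–Cockerham FST with block-jackknife errors,
KING-robust kinship with relatedness QC, a runs-of-homozygosity caller,
IBD segment length binning, PCA with least-squares projection of extra
samples, and pairwise genotype LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationGrouping
from .jackknife import BlockJackknifeEstimate, assign_blocks, ratio_jackknife


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-population alternate-allele frequencies with chromosome counts.

    ``alt_freq`` and ``n_chrom`` are (n_populations x n_snps) arrays; a
    frequency is NaN wherever the population has zero observed chromosomes.
    ``n_chrom`` may be ``inf`` for true (simulated) frequencies, in which
    case all finite-sample corrections vanish.
    """

    populations: list[str]
    alt_freq: np.ndarray
    n_chrom: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self._index = {p: i for i, p in enumerate(self.populations)}

    def freq(self, pop: str) -> np.ndarray:
        return self.alt_freq[self._index[pop]]

    def n(self, pop: str) -> np.ndarray:
        return self.n_chrom[self._index[pop]]

    @property
    def n_snps(self) -> int:
        return self.alt_freq.shape[1]

    @classmethod
    def from_true_frequencies(cls, freqs) -> "AlleleFrequencyTable":
        """Wrap a SimulatedFrequencies object as an infinite-sample table."""
        pops = list(freqs.freqs)
        alt = np.vstack([freqs[p] for p in pops])
        return cls(pops, alt, np.full_like(alt, np.inf), freqs.snps)


def allele_frequencies(g: GenotypeMatrix,
                       grouping: PopulationGrouping | None = None
                       ) -> AlleleFrequencyTable:
    """Observed alternate-allele frequency and chromosome count per
    population per SNP.  Defaults to the matrix's own population labels."""
    if grouping is None:
        grouping = PopulationGrouping.from_matrix(g)
    grouping.validate_against(g)
    pops = list(grouping.groups)
    alt = np.empty((len(pops), g.n_snps))
    n_chrom = np.empty((len(pops), g.n_snps))
    for i, pop in enumerate(pops):
        members = grouping.groups[pop]
        if not members:
            raise ValueError(f"population {pop!r} has zero samples")
        geno = g.genotypes[g.sample_index(members)]
        observed = geno != MISSING
        n_chrom[i] = 2.0 * observed.sum(axis=0)
        counts = np.where(observed, geno, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt[i] = np.where(n_chrom[i] > 0, counts / n_chrom[i], np.nan)
    return AlleleFrequencyTable(pops, alt, n_chrom, g.snps)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Genome-wide FST (ratio of averages) with per-SNP components."""

    estimator: str
    pop_a: str
    pop_b: str
    per_snp_num: np.ndarray
    per_snp_den: np.ndarray
    valid: np.ndarray
    jackknife: BlockJackknifeEstimate

    @property
    def estimate(self) -> float:
        return self.jackknife.estimate

    def per_snp_fst(self) -> np.ndarray:
        """N/D per SNP; NaN where excluded or D = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.per_snp_num / self.per_snp_den
        return np.where(self.valid & (self.per_snp_den != 0), f, np.nan)


def _hudson_components(p1, p2, n1, n2):
    with np.errstate(invalid="ignore", divide="ignore"):
        corr1 = np.where(np.isinf(n1), 0.0, p1 * (1 - p1) / (n1 - 1))
        corr2 = np.where(np.isinf(n2), 0.0, p2 * (1 - p2) / (n2 - 1))
    num = (p1 - p2) ** 2 - corr1 - corr2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _weir_cockerham_components(p1, p2, n1, n2):
    # Two-population variance components from allele frequencies and
    # chromosome counts; the heterozygosity term uses its HWE expectation
    # 2p(1-p) because the table carries no genotype-level het counts.
    r = 2.0
    n1d, n2d = n1 / 2.0, n2 / 2.0  # diploid sample sizes
    n_bar = (n1d + n2d) / r
    nc = (n1d + n2d - (n1d ** 2 + n2d ** 2) / (n1d + n2d)) / (r - 1)
    p_bar = (n1d * p1 + n2d * p2) / (n1d + n2d)
    s2 = (n1d * (p1 - p_bar) ** 2 + n2d * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1d * 2 * p1 * (1 - p1) + n2d * 2 * p2 * (1 - p2)) / (n1d + n2d)
    a = n_bar / nc * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                            - h_bar / 4) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                               - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, a + b + c


_FST_COMPONENTS = {"hudson": _hudson_components,
                   "weir_cockerham": _weir_cockerham_components}


def pairwise_fst(freqs: AlleleFrequencyTable, pop_a: str, pop_b: str,
                 estimator: str = "hudson",
                 blocks: np.ndarray | None = None) -> FstResult:
    """Genome-wide pairwise FST as a ratio of per-SNP averages.

    SNPs with fewer than 2 observed chromosomes in either population are
    excluded.  ``blocks`` defaults to contiguous 5 Mb physical blocks.
    """
    if estimator not in _FST_COMPONENTS:
        raise ValueError(f"unknown estimator {estimator!r}")
    p1, p2 = freqs.freq(pop_a), freqs.freq(pop_b)
    n1, n2 = freqs.n(pop_a), freqs.n(pop_b)
    valid = (np.isfinite(p1) & np.isfinite(p2) & (n1 >= 2) & (n2 >= 2))
    if not valid.any():
        raise ValueError("no SNPs usable in both populations")
    num, den = _FST_COMPONENTS[estimator](p1, p2, n1, n2)
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    jk = ratio_jackknife(num, den, blocks,
                         name=f"fst_{estimator}({pop_a},{pop_b})", valid=valid)
    return FstResult(estimator, pop_a, pop_b, num, den, valid, jk)


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

KINSHIP_CUTPOINTS = {  # lower bound of each degree label
    "duplicate_mz": 0.354,
    "first_degree": 0.177,
    "second_degree": 0.0884,
}


def _degree_label(phi: float) -> str:
    if not np.isfinite(phi):
        return "undefined"
    if phi >= KINSHIP_CUTPOINTS["duplicate_mz"]:
        return "duplicate_mz"
    if phi >= KINSHIP_CUTPOINTS["first_degree"]:
        return "first_degree"
    if phi >= KINSHIP_CUTPOINTS["second_degree"]:
        return "second_degree"
    return "unrelated"


def king_kinship(g: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust between-family kinship for every sample pair.

    phi = (N_hethet - 2 * N_opposing_hom) / (N_het_i + N_het_j), with all
    counts restricted to SNPs non-missing in both samples.  Pairs with no
    overlapping SNPs (or no heterozygous calls) get phi = NaN.
    """
    if g.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    geno = g.genotypes
    het = (geno == 1).astype(np.float64)
    hom0 = (geno == 0).astype(np.float64)
    hom2 = (geno == 2).astype(np.float64)
    valid = (geno != MISSING).astype(np.float64)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_in_pair = het @ valid.T  # het in row-sample over sites valid in col
    denom = het_in_pair + het_in_pair.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hethet - 2 * n_opp) / denom, np.nan)
    ids = g.samples["sample_id"].to_numpy()
    rows = []
    for i in range(g.n_samples):
        for j in range(i + 1, g.n_samples):
            rows.append((ids[i], ids[j], phi[i, j], _degree_label(phi[i, j])))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                       "kinship", "degree"])


def flag_related(kinship: pd.DataFrame,
                 threshold: float = KINSHIP_CUTPOINTS["second_degree"]
                 ) -> list[str]:
    """Greedy minimal removal so no remaining pair exceeds ``threshold``.

    Repeatedly drops the sample involved in the most over-threshold pairs
    (ties broken by sample id for determinism).
    """
    over = kinship[kinship["kinship"] >= threshold][["sample_a", "sample_b"]]
    pairs = [tuple(r) for r in over.itertuples(index=False)]
    removed: list[str] = []
    while pairs:
        counts: dict[str, int] = {}
        for a, b in pairs:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = max(sorted(counts), key=lambda s: counts[s])
        removed.append(worst)
        pairs = [(a, b) for a, b in pairs if worst not in (a, b)]
    return removed


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _scan_chromosome(statuses: np.ndarray, pos: np.ndarray, min_snps: int,
                     min_length_bp: int, max_gap_bp: int, het_allowance: int,
                     missing_allowance: int):
    """Yield (start_idx, end_idx) index pairs of accepted runs.

    statuses: 0 hom, 1 het, 2 missing.  A run grows while every trailing
    window of ``min_snps`` covered SNPs holds at most ``het_allowance``
    heterozygotes and ``missing_allowance`` missing calls; a physical gap
    above ``max_gap_bp`` closes the run.  Runs are trimmed to homozygous
    endpoints before the two minimum criteria are applied.
    """
    n = statuses.size
    runs = []
    start = 0
    k = 0
    window: list[int] = []  # indices of non-hom SNPs in the trailing window

    def close(end_idx: int) -> None:
        # trim to homozygous non-missing endpoints
        lo, hi = start, end_idx
        while lo <= hi and statuses[lo] != 0:
            lo += 1
        while hi >= lo and statuses[hi] != 0:
            hi -= 1
        if hi >= lo:
            n_in = hi - lo + 1
            if n_in >= min_snps and pos[hi] - pos[lo] >= min_length_bp:
                runs.append((lo, hi))

    while k < n:
        if k > start and pos[k] - pos[k - 1] > max_gap_bp:
            close(k - 1)
            start, window = k, []
        window = [i for i in window if i > k - min_snps]
        if statuses[k] != 0:
            window.append(k)
            hets = sum(1 for i in window if statuses[i] == 1)
            misses = len(window) - hets
            if hets > het_allowance or misses > missing_allowance:
                close(k - 1)
                # restart just past the earliest offending call so a long
                # tract interrupted by sparse hets is not lost
                start = window[0] + 1
                window = [i for i in window if i >= start]
        k += 1
    close(n - 1)
    return runs


def call_roh(g: GenotypeMatrix, min_snps: int = 50,
             min_length_bp: int = 100_000, max_gap_bp: int = 1_000_000,
             het_allowance: int = 1,
             missing_allowance: int = 5) -> list[ROHSegment]:
    """Call runs of homozygosity per sample per chromosome.

    A run must contain at least ``min_snps`` SNPs AND span at least
    ``min_length_bp``; a gap over ``max_gap_bp`` between consecutive SNPs
    splits runs into independent segments.
    """
    segments: list[ROHSegment] = []
    chrom_arr = g.snps["chromosome"].to_numpy()
    pos_arr = g.snps["physical_pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[cols]
        for row in range(g.n_samples):
            geno = g.genotypes[row, cols]
            statuses = np.where(geno == MISSING, 2,
                                np.where(geno == 1, 1, 0)).astype(np.int8)
            for lo, hi in _scan_chromosome(statuses, pos, min_snps,
                                           min_length_bp, max_gap_bp,
                                           het_allowance, missing_allowance):
                segments.append(ROHSegment(
                    sample_id=g.samples["sample_id"].iloc[row],
                    chromosome=str(chrom),
                    start_bp=int(pos[lo]), end_bp=int(pos[hi]),
                    n_snps=int(hi - lo + 1)))
    return segments


# ---------------------------------------------------------------------------
# IBD length binning
# ---------------------------------------------------------------------------

def classify_ibd_segments(segments: pd.DataFrame,
                          cut_points: tuple[float, float] = (1.0, 5.0),
                          drop_shortest: bool = False) -> pd.DataFrame:
    """Bin IBD segments into <1, 1-5 and >5 cM categories.

    ``segments`` needs columns (sample_a, sample_b, length_cm); boundary
    lengths (exactly 1 or 5 cM) fall in the middle bin.  With
    ``drop_shortest`` the sub-1 cM bin — the noisiest, oldest signal — is
    excluded from the returned table.
    """
    lo, hi = cut_points
    lengths = segments["length_cm"].to_numpy(dtype=float)
    if (lengths < 0).any():
        raise ValueError("negative IBD segment length")
    labels = np.where(lengths < lo, f"<{lo:g}",
                      np.where(lengths <= hi, f"{lo:g}-{hi:g}", f">{hi:g}"))
    out = segments.copy()
    out["bin"] = labels
    if drop_shortest:
        out = out[out["bin"] != f"<{lo:g}"].reset_index(drop=True)
    return out


def ibd_bin_counts(classified: pd.DataFrame,
                   by: list[str] | None = None) -> pd.DataFrame:
    """Counts per bin, optionally grouped (e.g. by population columns)."""
    keys = (by or []) + ["bin"]
    return (classified.groupby(keys, observed=True).size()
            .rename("n_segments").reset_index())


# ---------------------------------------------------------------------------
# PCA with projection
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # sample_id, role, PC1..PCk
    explained_variance: np.ndarray   # fraction of total variance per PC
    snp_loadings: np.ndarray
    snp_index: np.ndarray            # columns of g used (polymorphic in ref)


def pca_project(g: GenotypeMatrix, reference_samples: list[str],
                projected_samples: list[str], k: int = 2) -> PCAResult:
    """PCA on a reference set with least-squares projection of extra samples.

    Genotypes are centred at twice the reference allele frequency and scaled
    by ``1/sqrt(p(1-p))``; projected samples are regressed onto the SNP
    loadings over their non-missing SNPs (smartpca's ``lsqproject``).
    """
    if len(reference_samples) < k + 1:
        raise ValueError("need at least k+1 reference samples")
    ref_idx = g.sample_index(reference_samples)
    proj_idx = g.sample_index(projected_samples)
    ref = g.genotypes[ref_idx].astype(float)
    ref[g.genotypes[ref_idx] == MISSING] = np.nan
    p_hat = np.nanmean(ref, axis=0) / 2.0
    poly = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    cols = np.flatnonzero(poly)
    p_hat = p_hat[cols]
    scale = np.sqrt(p_hat * (1 - p_hat))

    def standardize(rows: np.ndarray) -> np.ndarray:
        x = g.genotypes[np.ix_(rows, cols)].astype(float)
        miss = g.genotypes[np.ix_(rows, cols)] == MISSING
        x = (x - 2 * p_hat) / scale
        x[miss] = np.nan
        return x

    x_ref = standardize(ref_idx)
    x_ref_filled = np.where(np.isnan(x_ref), 0.0, x_ref)
    u, s, vt = np.linalg.svd(x_ref_filled, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds reference rank {rank}")
    loadings = vt[:k].T                       # (snps x k)
    ref_coords = u[:, :k] * s[:k]
    total_var = float(np.sum(s ** 2))
    explained = s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)

    proj_coords = np.empty((len(proj_idx), k))
    x_proj = standardize(proj_idx)
    for r in range(x_proj.shape[0]):
        mask = np.isfinite(x_proj[r])
        coef, *_ = np.linalg.lstsq(loadings[mask], x_proj[r, mask], rcond=None)
        proj_coords[r] = coef

    ids = g.samples["sample_id"].to_numpy()
    frames = []
    for coords, rows, role in ((ref_coords, ref_idx, "reference"),
                               (proj_coords, proj_idx, "projected")):
        df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "sample_id", ids[rows])
        df.insert(1, "role", role)
        frames.append(df)
    return PCAResult(pd.concat(frames, ignore_index=True), explained,
                     loadings, cols)


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

def pairwise_r2(g: GenotypeMatrix, snp_indices: np.ndarray,
                population: str | None = None) -> np.ndarray:
    """Squared Pearson correlation of genotype dosages between SNPs.

    Computed over mutually non-missing samples per pair; monomorphic SNPs
    (within the chosen population) yield NaN rows/columns.
    """
    snp_indices = np.asarray(snp_indices)
    if population is None:
        rows = np.arange(g.n_samples)
    else:
        rows = np.flatnonzero(g.samples["population"] == population)
    x = g.genotypes[np.ix_(rows, snp_indices)].astype(float)
    x[g.genotypes[np.ix_(rows, snp_indices)] == MISSING] = np.nan
    xm = np.ma.masked_invalid(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.ma.corrcoef(xm, rowvar=False)
    r2 = np.asarray(r.filled(np.nan)) ** 2
    sd = np.nanstd(x, axis=0)
    degenerate = ~(sd > 0)
    r2[degenerate, :] = np.nan
    r2[:, degenerate] = np.nan
    return r2
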