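"""Population branch statistic (PBS) selection scanning.

For a target population A with ingroup B and outgroup C, each pairwise
per-SNP FST is transformed to a branch length ``T = -log(1 - FST)`` and the
target-branch length is

    PBS_A = (T_AB + T_AC - T_BC) / 2.

Large PBS marks allele-frequency change specific to A's branch since the
A-B split — a candidate signal of positive selection.  Candidates are the
SNPs strictly above an empirical percentile of the genome-wide PBS
distribution (default: the top 0.1%).  The module also annotates candidate
SNPs against BED gene intervals, intersects candidate gene sets across scan
configurations (the multi-ingroup Venn design), and produces regional-LD
and per-population frequency tables for follow-up of individual hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .stats import AlleleFrequencyTable, allele_frequencies, pairwise_fst, \
    pairwise_r2

_LOG_CLAMP = 1.0 - 1e-12


@dataclass
class ScanConfiguration:
    """One PBS scan: target A, ingroup B, outgroup C, and the candidate
    percentile (99.9 = top 0.1%)."""

    target: str
    ingroup: str
    outgroup: str
    percentile: float = 99.9
    label: str = ""

    def __post_init__(self) -> None:
        if len({self.target, self.ingroup, self.outgroup}) != 3:
            raise ValueError("target, ingroup and outgroup must be distinct")
        if not self.label:
            self.label = f"{self.target}-{self.ingroup}-{self.outgroup}"


def pbs_per_snp(fst_ab: np.ndarray, fst_ac: np.ndarray,
                fst_bc: np.ndarray) -> np.ndarray:
    """PBS from three aligned per-SNP FST series.

    Negative per-SNP FST values are clamped to 0 (and values at 1 pulled
    just inside) before the log transform, keeping every branch length
    finite and non-negative; PBS itself may still be negative.
    """
    series = [np.asarray(a, dtype=float) for a in (fst_ab, fst_ac, fst_bc)]
    if not (series[0].shape == series[1].shape == series[2].shape):
        raise ValueError("FST inputs must be aligned on the same SNP list")
    t = [-np.log1p(-np.clip(s, 0.0, _LOG_CLAMP)) for s in series]
    return (t[0] + t[1] - t[2]) / 2.0


def pbs_scan(g: GenotypeMatrix, cfg: ScanConfiguration,
             estimator: str = "hudson",
             freqs: AlleleFrequencyTable | None = None) -> pd.DataFrame:
    """Per-SNP PBS table for one configuration, sorted by PBS descending.

    Columns: chromosome, physical_pos, snp_id, fst_ab, fst_ac, fst_bc, pbs,
    rank, candidate.  The candidate flag is strict: PBS must exceed (not
    merely reach) the empirical percentile of all finite PBS values.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    for pop in (cfg.target, cfg.ingroup, cfg.outgroup):
        members = (freqs.n(pop) >= 2)
        if not members.any():
            raise ValueError(f"population {pop!r} below minimum size")
    res_ab = pairwise_fst(freqs, cfg.target, cfg.ingroup, estimator=estimator)
    res_ac = pairwise_fst(freqs, cfg.target, cfg.outgroup, estimator=estimator)
    res_bc = pairwise_fst(freqs, cfg.ingroup, cfg.outgroup,
                          estimator=estimator)
    fst_ab = res_ab.per_snp_fst()
    fst_ac = res_ac.per_snp_fst()
    fst_bc = res_bc.per_snp_fst()
    pbs = pbs_per_snp(fst_ab, fst_ac, fst_bc)
    table = pd.DataFrame({
        "chromosome": freqs.snps["chromosome"].to_numpy(),
        "physical_pos": freqs.snps["physical_pos"].to_numpy(),
        "snp_id": freqs.snps["snp_id"].to_numpy(),
        "fst_ab": fst_ab, "fst_ac": fst_ac, "fst_bc": fst_bc,
        "pbs": pbs,
    })
    table = table[np.isfinite(table["pbs"])].reset_index(drop=True)
    threshold = np.percentile(table["pbs"], cfg.percentile)
    table["candidate"] = table["pbs"] > threshold
    table = table.sort_values("pbs", ascending=False, kind="stable",
                              ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["threshold"] = float(threshold)
    table.attrs["label"] = cfg.label
    return table


@dataclass
class CandidateGeneSet:
    """Genes hit by candidate SNPs in one scan configuration."""

    label: str
    genes: set[str]
    top_snp: dict[str, tuple[str, float]] = field(default_factory=dict)
    n_candidate_snps_in_genes: int = 0


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED file of gene intervals (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     usecols=[0, 1, 2, 3],
                     names=["chromosome", "start", "end", "gene_id"],
                     dtype={"chromosome": str, "gene_id": str})
    if df[["start", "end"]].isna().any().any() or (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED interval")
    return df


def annotate_candidates(table: pd.DataFrame, genes: pd.DataFrame,
                        label: str | None = None) -> CandidateGeneSet:
    """Map candidate SNPs onto gene intervals.

    A SNP at 1-based position p hits [start, end) iff start <= p-1 < end on
    the same chromosome; the half-open end coordinate is excluded.
    """
    label = label or table.attrs.get("label", "scan")
    cands = table[table["candidate"]]
    hits: set[str] = set()
    top: dict[str, tuple[str, float]] = {}
    n_in_genes = 0
    by_chrom = {c: sub for c, sub in genes.groupby("chromosome")}
    for row in cands.itertuples(index=False):
        sub = by_chrom.get(str(row.chromosome))
        if sub is None:
            continue
        zero_based = row.physical_pos - 1
        inside = sub[(sub["start"] <= zero_based) & (zero_based < sub["end"])]
        if len(inside):
            n_in_genes += 1
        for gene in inside["gene_id"]:
            hits.add(gene)
            if gene not in top or row.pbs > top[gene][1]:
                top[gene] = (row.snp_id, float(row.pbs))
    return CandidateGeneSet(label, hits, top, n_in_genes)


def intersect_candidate_sets(sets: list[CandidateGeneSet]) -> dict:
    """Venn membership of candidate genes across scan configurations.

    Returns ``{"region_counts": {...}, "full_intersection": [...],
    "membership": DataFrame}``; Venn regions are keyed by the sorted
    '&'-joined labels of the configurations containing each gene.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 candidate sets to intersect")
    labels = [s.label for s in sets]
    all_genes = sorted(set().union(*(s.genes for s in sets)))
    membership = pd.DataFrame(
        {lab: [g in s.genes for g in all_genes]
         for lab, s in zip(labels, sets)}, index=all_genes)
    region_counts: dict[str, int] = {}
    for gene in all_genes:
        key = "&".join(lab for lab in labels if membership.loc[gene, lab])
        region_counts[key] = region_counts.get(key, 0) + 1
    full = [g for g in all_genes if membership.loc[g].all()]
    return {"region_counts": region_counts, "full_intersection": full,
            "membership": membership}


def regional_ld_table(g: GenotypeMatrix, population: str, index_snp: str,
                      window_bp: int = 200_000) -> pd.DataFrame:
    """r² of every SNP within a window against an index SNP.

    ``window_bp`` is the total span centred on the index SNP (±window/2).
    """
    where = np.flatnonzero(g.snps["snp_id"] == index_snp)
    if where.size == 0:
        raise KeyError(f"unknown SNP id {index_snp!r}")
    i0 = int(where[0])
    chrom = g.snps["chromosome"].iloc[i0]
    pos0 = int(g.snps["physical_pos"].iloc[i0])
    half = window_bp / 2.0
    sel = np.flatnonzero(
        (g.snps["chromosome"] == chrom)
        & (np.abs(g.snps["physical_pos"] - pos0) <= half))
    r2 = pairwise_r2(g, sel, population=population)
    local0 = int(np.flatnonzero(sel == i0)[0])
    if not np.isfinite(r2[local0]).any() and sel.size > 1:
        raise ValueError(f"index SNP {index_snp!r} monomorphic in "
                         f"{population!r}")
    out = pd.DataFrame({
        "snp_id": g.snps["snp_id"].to_numpy()[sel],
        "physical_pos": g.snps["physical_pos"].to_numpy()[sel],
        "distance_bp": g.snps["physical_pos"].to_numpy()[sel] - pos0,
        "r2": r2[local0],
    })
    out.loc[out["snp_id"] == index_snp, "r2"] = 1.0
    return out.sort_values("physical_pos", ignore_index=True)


def candidate_frequency_table(freqs: AlleleFrequencyTable,
                              snp_ids: list[str],
                              populations: list[str]) -> pd.DataFrame:
    """Tidy (snp, population, frequency, n_chrom) table for chosen SNPs.

    Frequencies are taken directly from the allele-frequency table — the
    same values every other estimator consumes.
    """
    lookup = pd.Index(freqs.snps["snp_id"])
    idx = lookup.get_indexer(snp_ids)
    if (idx < 0).any():
        unknown = [s for s, i in zip(snp_ids, idx) if i < 0]
        raise KeyError(f"unknown SNP ids: {unknown}")
    rows = []
    for snp, i in zip(snp_ids, idx):
        for pop in populations:
            rows.append({"snp_id": snp, "population": pop,
                         "frequency": float(freqs.freq(pop)[i]),
                         "n_chrom": float(freqs.n(pop)[i])})
    return pd.DataFrame(rows,
                        columns=["snp_id", "population", "frequency",
                                 "n_chrom"])
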