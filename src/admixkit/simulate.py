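"""Synthetic genotype data with known demographic truth.

Populations drift from a shared ancestor along the branches of a rooted
tree under the Balding–Nichols model: given a parental frequency ``p`` and a
branch drift intensity ``F``, the daughter frequency is Beta-distributed
with mean ``p`` and variance ``F * p * (1 - p)``.  This gives closed-form
expectations for downstream estimators — e.g. two leaves hanging off the
same node with drift ``F`` each have expected Hudson FST of
``1 - (1 - F)**2``.

Two admixture modes are provided:

* frequency mixing — the target's per-SNP frequency is the weighted average
  of its sources'.  Carries no LD; sufficient for f-statistics and qpAdm.
* mosaic chromosomes — each haploid chromosome copy is a mosaic of
  source-labelled segments with exponentially distributed genetic lengths
  (mean ``1/n`` Morgans for an admixture ``n`` generations ago).  Carries
  the decaying admixture LD that weighted-LD dating detects.

``plant_features`` injects loci under selection, runs of homozygosity and
close relatives, and records every planted truth in a JSON-serializable
manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

FREQ_CLAMP = 1e-6  # keep Beta parameters and Bernoulli draws non-degenerate


@dataclass
class ChromosomeLayout:
    """Evenly spaced SNPs on equally sized chromosomes.

    ``bp_spacing`` is the physical distance between adjacent SNPs and
    ``morgans_per_bp`` the (constant) recombination rate; the default is
    1 cM/Mb.  Chromosome genetic length is therefore
    ``snps_per_chromosome * bp_spacing * morgans_per_bp``.
    """

    n_chromosomes: int = 4
    snps_per_chromosome: int = 5000
    bp_spacing: int = 10_000
    morgans_per_bp: float = 1e-8

    @property
    def snp_count(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    def snp_table(self) -> pd.DataFrame:
        chroms, pos = [], []
        for c in range(1, self.n_chromosomes + 1):
            chroms.extend([str(c)] * self.snps_per_chromosome)
            pos.extend(range(self.bp_spacing,
                             self.bp_spacing * (self.snps_per_chromosome + 1),
                             self.bp_spacing))
        pos = np.asarray(pos, dtype=np.int64)
        return pd.DataFrame({
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chroms, pos)],
            "chromosome": chroms,
            "genetic_pos": pos * self.morgans_per_bp,
            "physical_pos": pos,
            "allele_ref": "A",
            "allele_alt": "G",
        })


@dataclass
class DriftTreeConfig:
    """A rooted population tree with per-branch Balding–Nichols drift.

    ``branches`` maps every node name to ``(parent_name, F)``; the root has
    parent ``None`` and its F is ignored.  Ancestral frequencies are drawn
    uniformly on ``[freq_low, freq_high]``.
    """

    branches: dict[str, tuple[str | None, float]]
    layout: ChromosomeLayout = dataclass_field(default_factory=ChromosomeLayout)
    freq_low: float = 0.05
    freq_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        roots = [n for n, (p, _) in self.branches.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        for name, (parent, f) in self.branches.items():
            if parent is not None and parent not in self.branches:
                raise ValueError(f"unknown parent {parent!r} of {name!r}")
            if not 0 <= f < 1:
                raise ValueError(f"branch F of {name!r} outside [0, 1)")

    @property
    def root(self) -> str:
        return next(n for n, (p, _) in self.branches.items() if p is None)

    def leaves(self) -> list[str]:
        parents = {p for p, _ in self.branches.values() if p is not None}
        return [n for n in self.branches if n not in parents]


@dataclass
class SimulatedFrequencies:
    """True per-population alternate-allele frequencies on a SNP panel."""

    snps: pd.DataFrame
    freqs: dict[str, np.ndarray]

    def __getitem__(self, pop: str) -> np.ndarray:
        return self.freqs[pop]

    def __contains__(self, pop: str) -> bool:
        return pop in self.freqs

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class AdmixtureEventConfig:
    """A 2- or 3-way admixture pulse forming ``target`` from ``sources``."""

    target: str
    sources: tuple[str, ...]
    weights: tuple[float, ...]
    generations_ago: int = 10

    def __post_init__(self) -> None:
        if len(self.sources) not in (2, 3):
            raise ValueError("2 or 3 admixture sources required")
        if len(self.weights) != len(self.sources):
            raise ValueError("one weight per source required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        if self.generations_ago < 1:
            raise ValueError("generations_ago must be >= 1")


@dataclass
class PlantedFeature:
    """A ground-truth feature injected into simulated genotypes.

    kind ``selected_locus``: params target (population), snp_id, delta.
    kind ``roh_segment``: params sample_id, chromosome, start_bp, end_bp.
    kind ``relative_pair``: params sample_a, sample_b,
    relationship in {duplicate, parent_offspring}.
    """

    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in ("selected_locus", "roh_segment", "relative_pair"):
            raise ValueError(f"unknown feature kind {self.kind!r}")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     f: float) -> np.ndarray:
    if f == 0:
        return p.copy()
    scale = (1.0 - f) / f
    child = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(child, FREQ_CLAMP, 1.0 - FREQ_CLAMP)


def simulate_frequencies(cfg: DriftTreeConfig) -> SimulatedFrequencies:
    """Draw true allele frequencies for every node of the drift tree.

    Deterministic under ``cfg.seed``; every node (internal and leaf) gets a
    frequency vector over the configured SNP panel.
    """
    rng = np.random.default_rng(cfg.seed)
    snps = cfg.layout.snp_table()
    n = cfg.layout.snp_count
    ancestral = rng.uniform(cfg.freq_low, cfg.freq_high, size=n)
    freqs: dict[str, np.ndarray] = {}

    def visit(node: str) -> None:
        parent, f = cfg.branches[node]
        base = ancestral if parent is None else freqs[parent]
        freqs[node] = base.copy() if parent is None else _balding_nichols(
            rng, base, f)
        for child, (par, _) in cfg.branches.items():
            if par == node:
                visit(child)

    visit(cfg.root)
    return SimulatedFrequencies(snps, freqs)


def expected_hudson_fst(cfg: DriftTreeConfig, pop_a: str, pop_b: str) -> float:
    """Closed-form expected Hudson FST between two tree populations.

    Drift composes serially along a path: a population whose path from the
    pair's most recent common ancestor crosses branches with intensities
    ``F_1..F_k`` has unshared drift ``v = 1 - prod(1 - F_i)``.  The Hudson
    ratio-of-averages estimator converges to the *mean* of the two
    populations' unshared drifts, ``(v_a + v_b) / 2``: shared drift above
    the MRCA cancels from numerator and denominator alike.
    """
    def path_to_root(node: str) -> list[str]:
        path = [node]
        while cfg.branches[path[-1]][0] is not None:
            path.append(cfg.branches[path[-1]][0])
        return path

    pa, pb = path_to_root(pop_a), path_to_root(pop_b)
    mrca = next(n for n in pa if n in set(pb))

    def unshared_drift(path: list[str]) -> float:
        keep = path[:path.index(mrca)]
        prod = 1.0
        for node in keep:
            prod *= 1.0 - cfg.branches[node][1]
        return 1.0 - prod

    return 0.5 * (unshared_drift(pa) + unshared_drift(pb))


def simulate_genotypes(freqs: SimulatedFrequencies,
                       samples_per_pop: dict[str, int] | int,
                       missing_rate: float = 0.0,
                       seed: int = 0,
                       populations: list[str] | None = None) -> GenotypeMatrix:
    """Binomial(2, p) genotypes per population with optional missingness."""
    rng = np.random.default_rng(seed)
    if populations is None:
        populations = (list(samples_per_pop)
                       if isinstance(samples_per_pop, dict)
                       else list(freqs.freqs))
    if isinstance(samples_per_pop, int):
        samples_per_pop = {p: samples_per_pop for p in populations}
    blocks, ids, pops = [], [], []
    for pop in populations:
        n = samples_per_pop[pop]
        p = np.clip(freqs[pop], 0.0, 1.0)
        geno = rng.binomial(2, p[None, :], size=(n, freqs.n_snps))
        blocks.append(geno.astype(np.int8))
        ids.extend(f"{pop}_{i}" for i in range(n))
        pops.extend([pop] * n)
    genotypes = np.vstack(blocks)
    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes[mask] = MISSING
    samples = pd.DataFrame({"sample_id": ids, "population": pops, "sex": 0})
    return GenotypeMatrix(genotypes, samples, freqs.snps)


def admixed_frequencies(freqs: SimulatedFrequencies,
                        event: AdmixtureEventConfig) -> np.ndarray:
    """The target's per-SNP frequency under frequency-mixing admixture."""
    out = np.zeros(freqs.n_snps)
    for src, w in zip(event.sources, event.weights):
        out += w * freqs[src]
    return out


def simulate_admixed_population(freqs: SimulatedFrequencies,
                                event: AdmixtureEventConfig,
                                n_samples: int,
                                seed: int = 0,
                                missing_rate: float = 0.0) -> GenotypeMatrix:
    """Frequency-mixing admixed target genotypes (no LD structure)."""
    mixed = SimulatedFrequencies(
        freqs.snps, {event.target: admixed_frequencies(freqs, event)})
    return simulate_genotypes(mixed, {event.target: n_samples},
                              missing_rate=missing_rate, seed=seed)


def simulate_admixed_mosaics(freqs: SimulatedFrequencies,
                             event: AdmixtureEventConfig,
                             n_samples: int,
                             seed: int = 0) -> GenotypeMatrix:
    """Mosaic-chromosome admixed target genotypes carrying admixture LD.

    Each haploid copy of each chromosome is partitioned into ancestry
    segments by a Poisson process of rate ``generations_ago`` per Morgan;
    each segment's ancestry is drawn independently with the admixture
    weights, and its alleles are Bernoulli draws from that source's
    frequencies.
    """
    rng = np.random.default_rng(seed)
    snps = freqs.snps
    if "genetic_pos" not in snps or snps["genetic_pos"].isna().any():
        raise ValueError("mosaic simulation requires a genetic map")
    n_gen = event.generations_ago
    weights = np.asarray(event.weights)
    src_freqs = np.vstack([np.clip(freqs[s], FREQ_CLAMP, 1 - FREQ_CLAMP)
                           for s in event.sources])
    genotypes = np.zeros((n_samples, len(snps)), dtype=np.int8)
    for chrom, sub in snps.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        gpos = sub["genetic_pos"].to_numpy()
        start, stop = gpos[0], gpos[-1]
        length = max(stop - start, 1e-9)
        for s in range(n_samples):
            for _copy in range(2):
                n_breaks = rng.poisson(n_gen * length)
                breaks = np.sort(rng.uniform(start, stop, size=n_breaks))
                seg_of_snp = np.searchsorted(breaks, gpos, side="right")
                anc = rng.choice(len(weights), size=n_breaks + 1, p=weights)
                p_here = src_freqs[anc[seg_of_snp], idx]
                genotypes[s, idx] += (rng.random(idx.size) < p_here)
    ids = [f"{event.target}_{i}" for i in range(n_samples)]
    samples = pd.DataFrame({"sample_id": ids,
                            "population": event.target, "sex": 0})
    return GenotypeMatrix(genotypes, samples, snps)


def stack_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Concatenate two sample sets that share an identical SNP panel."""
    if not a.snps["snp_id"].equals(b.snps["snp_id"]):
        raise ValueError("SNP panels differ; use merge_datasets instead")
    return GenotypeMatrix(np.vstack([a.genotypes, b.genotypes]),
                          pd.concat([a.samples, b.samples],
                                    ignore_index=True),
                          a.snps)


# ---------------------------------------------------------------------------
# planted features
# ---------------------------------------------------------------------------

def _plant_selected_locus(rng, g, freqs, params, manifest):
    pop, snp_id, delta = params["target"], params["snp_id"], params["delta"]
    col = int(np.flatnonzero(g.snps["snp_id"] == snp_id)[0])
    if pop in freqs:
        p_old = float(freqs[pop][col])
    else:  # e.g. an admixed target absent from the drift-tree truth table
        obs = g.genotypes[np.flatnonzero(g.samples["population"] == pop), col]
        obs = obs[obs != MISSING]
        p_old = float(obs.mean() / 2.0)
    p_new = p_old + delta
    if not 0.0 <= p_new <= 1.0:
        warnings.warn(f"selected-locus frequency {p_new:.3f} clamped to [0,1]")
        p_new = float(np.clip(p_new, 0.0, 1.0))
    rows = np.flatnonzero(g.samples["population"] == pop)
    g.genotypes[rows, col] = rng.binomial(2, p_new, size=rows.size)
    if pop in freqs:
        freqs.freqs[pop] = freqs[pop].copy()
        freqs.freqs[pop][col] = p_new
    manifest["selected_loci"].append({
        "population": pop, "snp_id": snp_id,
        "chromosome": str(g.snps["chromosome"].iloc[col]),
        "physical_pos": int(g.snps["physical_pos"].iloc[col]),
        "delta": delta, "freq_before": p_old, "freq_after": p_new})


def _plant_roh(rng, g, freqs, params, manifest):
    sample, chrom = params["sample_id"], str(params["chromosome"])
    start, end = int(params["start_bp"]), int(params["end_bp"])
    row = int(g.sample_index([sample])[0])
    pop = g.samples["population"].iloc[row]
    in_span = ((g.snps["chromosome"] == chrom)
               & (g.snps["physical_pos"] >= start)
               & (g.snps["physical_pos"] <= end)).to_numpy()
    cols = np.flatnonzero(in_span)
    for rec in manifest["roh_segments"]:
        if rec["sample_id"] == sample and rec["chromosome"] == chrom \
                and not (end < rec["start_bp"] or start > rec["end_bp"]):
            raise ValueError("overlapping planted ROH in one sample")
    p = np.clip(freqs[pop][cols] if pop in freqs else 0.5, 0.0, 1.0)
    hap = rng.random(cols.size) < p
    g.genotypes[row, cols] = 2 * hap.astype(np.int8)
    pos = g.snps["physical_pos"].to_numpy()[cols]
    manifest["roh_segments"].append({
        "sample_id": sample, "chromosome": chrom,
        "start_bp": int(pos[0]) if cols.size else start,
        "end_bp": int(pos[-1]) if cols.size else end,
        "n_snps": int(cols.size)})


def _plant_relative(rng, g, freqs, params, manifest):
    a, b = params["sample_a"], params["sample_b"]
    rel = params["relationship"]
    ia, ib = (int(i) for i in g.sample_index([a, b]))
    if rel == "duplicate":
        g.genotypes[ib] = g.genotypes[ia]
    elif rel == "parent_offspring":
        pop = g.samples["population"].iloc[ib]
        parent = g.genotypes[ia].astype(float)
        p_pop = np.clip(freqs[pop], 0.0, 1.0) if pop in freqs \
            else np.full(g.n_snps, 0.5)
        transmit_p = np.where(parent == MISSING, p_pop, parent / 2.0)
        from_parent = rng.random(g.n_snps) < transmit_p
        from_pop = rng.random(g.n_snps) < p_pop
        g.genotypes[ib] = (from_parent.astype(np.int8)
                           + from_pop.astype(np.int8))
    else:
        raise ValueError(f"unknown relationship {rel!r}")
    manifest["relative_pairs"].append(
        {"sample_a": a, "sample_b": b, "relationship": rel})


_PLANTERS = {"selected_locus": _plant_selected_locus,
             "roh_segment": _plant_roh,
             "relative_pair": _plant_relative}


def plant_features(g: GenotypeMatrix, features: list[PlantedFeature],
                   freqs: SimulatedFrequencies,
                   seed: int = 0) -> tuple[GenotypeMatrix, dict]:
    """Inject ground-truth features; returns (modified copy, truth manifest)."""
    rng = np.random.default_rng(seed)
    out = GenotypeMatrix(g.genotypes.copy(), g.samples.copy(), g.snps.copy())
    manifest: dict = {"selected_loci": [], "roh_segments": [],
                      "relative_pairs": []}
    for feat in features:
        _PLANTERS[feat.kind](rng, out, freqs, feat.params, manifest)
    return out, manifest


def write_fixture_annotation(layout: ChromosomeLayout, genes_per_chrom: int,
                             path) -> pd.DataFrame:
    """Tile non-overlapping gene intervals over each chromosome as a BED file.

    Genes occupy alternating slices of each chromosome (gene, gap, gene, ...)
    so that intervals never touch.  Returns the SNP-to-gene truth table with
    columns (gene_id, chromosome, start, end) in 0-based half-open BED
    coordinates.
    """
    path = Path(path)
    records = []
    chrom_len = layout.bp_spacing * (layout.snps_per_chromosome + 1)
    slice_len = chrom_len // max(2 * genes_per_chrom, 1)
    for c in range(1, layout.n_chromosomes + 1):
        for gi in range(genes_per_chrom):
            start = 2 * gi * slice_len
            end = start + slice_len
            records.append({"gene_id": f"gene{c}_{gi}", "chromosome": str(c),
                            "start": start, "end": end})
    truth = pd.DataFrame(records,
                         columns=["gene_id", "chromosome", "start", "end"])
    with open(path, "w") as fh:
        for rec in truth.itertuples(index=False):
            fh.write(f"{rec.chromosome}\t{rec.start}\t{rec.end}\t"
                     f"{rec.gene_id}\n")
    return truth
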