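"""Admixture dating from the decay of admixture linkage disequilibrium.

A single admixture pulse ``n`` generations ago leaves covariance between
ancestry (hence alleles) at pairs of loci that decays as ``exp(-n * d)``
with genetic distance ``d`` (Morgans).  The two-reference weighted-LD
statistic accumulates, for every SNP pair within a distance bin, the
product of the target's genotype covariance and the allele-frequency
contrasts of two reference populations at both SNPs; fitting
``a(d) = M * exp(-n * d) + c`` to the binned curve estimates the date ``n``
in generations, with leave-one-chromosome-out jackknife errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .genotypes import MISSING, GenotypeMatrix
from .stats import AlleleFrequencyTable

DEFAULT_MINDIS = 0.005   # Morgans; below this, background LD dominates
DEFAULT_MAXDIS = 0.5
DEFAULT_BIN_WIDTH = 0.001

_MULTISTART_RATES = (5.0, 20.0, 50.0, 100.0, 200.0)


@dataclass
class DecayCurve:
    """A binned weighted-LD decay curve, optionally with a fitted model."""

    bin_left: np.ndarray            # left bin edges, Morgans
    value: np.ndarray               # mean weighted-LD product per bin
    pair_count: np.ndarray
    per_chrom_sums: dict[str, np.ndarray] = field(default_factory=dict)
    per_chrom_counts: dict[str, np.ndarray] = field(default_factory=dict)
    amplitude: float | None = None  # M
    rate: float | None = None       # n, generations
    affine: float | None = None     # c
    converged: bool = False

    def populated(self) -> np.ndarray:
        return self.pair_count > 0

    def drop_chromosome(self, chrom: str) -> "DecayCurve":
        sums = sum(v for c, v in self.per_chrom_sums.items() if c != chrom)
        counts = sum(v for c, v in self.per_chrom_counts.items() if c != chrom)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(counts > 0, sums / counts, np.nan)
        return DecayCurve(self.bin_left, value, counts)


def weighted_ld_curve(g: GenotypeMatrix, freqs: AlleleFrequencyTable,
                      target: str, ref1: str, ref2: str,
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      mindis: float = DEFAULT_MINDIS,
                      maxdis: float = DEFAULT_MAXDIS) -> DecayCurve:
    """Accumulate the two-reference weighted-LD curve for ``target``.

    For every same-chromosome SNP pair (i, j) with genetic distance in
    ``[mindis, maxdis]``, the quantity
    ``cov_target(i, j) * (p1_i - p2_i) * (p1_j - p2_j)`` is averaged into
    the bin of the pair's distance.
    """
    if len({target, ref1, ref2}) != 3:
        raise ValueError("target and the two references must be distinct")
    gpos_all = g.snps["genetic_pos"].to_numpy(dtype=float)
    if np.isnan(gpos_all).any():
        raise ValueError("weighted LD requires a genetic map")
    edges = np.arange(mindis, maxdis + bin_width, bin_width)
    n_bins = edges.size - 1
    rows = np.flatnonzero(g.samples["population"] == target)
    if rows.size < 2:
        raise ValueError(f"target {target!r} needs >= 2 samples")
    w_all = freqs.freq(ref1) - freqs.freq(ref2)
    per_chrom_sums: dict[str, np.ndarray] = {}
    per_chrom_counts: dict[str, np.ndarray] = {}
    any_pairs = False
    for chrom, sub in g.snps.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        gpos = gpos_all[idx]
        x = g.genotypes[np.ix_(rows, idx)].astype(float)
        x[g.genotypes[np.ix_(rows, idx)] == MISSING] = np.nan
        mu = np.nanmean(x, axis=0)
        z = np.where(np.isnan(x), 0.0, x - mu)
        cov = z.T @ z / (rows.size - 1)
        w = w_all[idx]
        weight = np.outer(w, w)
        dist = np.abs(gpos[:, None] - gpos[None, :])
        iu = np.triu_indices(idx.size, k=1)
        d = dist[iu]
        keep = (d >= mindis) & (d <= maxdis) & np.isfinite(weight[iu]) \
            & np.isfinite(cov[iu])
        if not keep.any():
            per_chrom_sums[str(chrom)] = np.zeros(n_bins)
            per_chrom_counts[str(chrom)] = np.zeros(n_bins)
            continue
        any_pairs = True
        which = np.clip(((d[keep] - mindis) // bin_width).astype(int),
                        0, n_bins - 1)
        prod = (cov[iu][keep]) * (weight[iu][keep])
        per_chrom_sums[str(chrom)] = np.bincount(which, weights=prod,
                                                 minlength=n_bins)
        per_chrom_counts[str(chrom)] = np.bincount(
            which, minlength=n_bins).astype(float)
    if not any_pairs:
        raise ValueError("no SNP pairs beyond mindis; chromosomes too short")
    sums = sum(per_chrom_sums.values())
    counts = sum(per_chrom_counts.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(counts > 0, sums / counts, np.nan)
    return DecayCurve(edges[:-1], value, counts,
                      per_chrom_sums, per_chrom_counts)


def fit_decay(curve: DecayCurve) -> DecayCurve:
    """Weighted nonlinear fit of ``M * exp(-n*d) + c`` to a binned curve.

    Multi-start over decay rates {5, 20, 50, 100, 200} generations guards
    against local minima.  A flat or unfittable curve returns with
    ``converged=False`` rather than raising.
    """
    ok = curve.populated() & np.isfinite(curve.value)
    if ok.sum() < 5:
        raise ValueError("need at least 5 populated bins to fit")
    d = curve.bin_left[ok] + 0.0
    y = curve.value[ok]
    w = np.sqrt(curve.pair_count[ok])
    w = w / w.max()
    scale = np.abs(y).max()
    best = None
    if scale > 0 and np.ptp(y) > 0:
        for n0 in _MULTISTART_RATES:
            try:
                res = least_squares(
                    lambda th: w * (th[0] * np.exp(-th[1] * d) + th[2] - y),
                    x0=[y[0] - y[-1] if y[0] != y[-1] else scale, n0, y[-1]],
                    bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
                    max_nfev=2000)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    fitted = DecayCurve(curve.bin_left, curve.value, curve.pair_count,
                        curve.per_chrom_sums, curve.per_chrom_counts)
    if best is not None:
        fitted.amplitude, fitted.rate, fitted.affine = map(float, best.x)
        fitted.converged = True
    return fitted


@dataclass
class AdmixtureDate:
    """Jackknifed admixture date in generations before sampling."""

    generations: float
    se_generations: float
    amplitude: float
    z_amplitude: float
    per_chromosome: dict[str, float]
    converged: bool
    years_per_generation: float = 29.0

    @property
    def years_before_sampling(self) -> float:
        return self.generations * self.years_per_generation

    @property
    def se_years(self) -> float:
        return self.se_generations * self.years_per_generation


def jackknife_date(g: GenotypeMatrix, freqs: AlleleFrequencyTable,
                   target: str, ref1: str, ref2: str,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   mindis: float = DEFAULT_MINDIS,
                   maxdis: float = DEFAULT_MAXDIS,
                   years_per_generation: float = 29.0) -> AdmixtureDate:
    """Full weighted-LD dating with leave-one-chromosome-out errors.

    Refits the decay curve excluding each chromosome in turn; replicates
    that fail to converge are dropped (with a warning via the result's
    ``per_chromosome`` map).  Requires at least 3 chromosomes.
    """
    chroms = list(pd.unique(g.snps["chromosome"]).astype(str))
    if len(chroms) < 3:
        raise ValueError("leave-one-chromosome-out needs >= 3 chromosomes")
    curve = weighted_ld_curve(g, freqs, target, ref1, ref2,
                              bin_width=bin_width, mindis=mindis,
                              maxdis=maxdis)
    full = fit_decay(curve)
    per_chrom_n: dict[str, float] = {}
    per_chrom_m: dict[str, float] = {}
    for chrom in chroms:
        try:
            sub = fit_decay(curve.drop_chromosome(chrom))
        except ValueError:
            continue
        if sub.converged:
            per_chrom_n[chrom] = sub.rate
            per_chrom_m[chrom] = sub.amplitude

    def loo_se(loo_vals: list[float]) -> float:
        arr = np.asarray(loo_vals, dtype=float)
        b = arr.size
        if b < 2:
            return np.nan
        return float(np.sqrt((b - 1) / b * ((arr - arr.mean()) ** 2).sum()))

    se_n = loo_se(list(per_chrom_n.values()))
    se_m = loo_se(list(per_chrom_m.values()))
    amp = full.amplitude if full.converged else np.nan
    rate = full.rate if full.converged else np.nan
    z_amp = amp / se_m if (se_m and np.isfinite(se_m) and se_m > 0) else np.nan
    return AdmixtureDate(generations=rate, se_generations=se_n,
                         amplitude=amp, z_amplitude=z_amp,
                         per_chromosome=per_chrom_n,
                         converged=bool(full.converged),
                         years_per_generation=years_per_generation)
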