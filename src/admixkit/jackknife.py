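"""Block jackknife over contiguous genomic blocks.

All genome-wide statistics in this package are ratios of per-SNP sums,
``theta = sum(num) / sum(den)`` (f-statistics use ``den = 1`` per SNP).
Standard errors come from the weighted delete-one block jackknife of
Busing, Meijer & van der Leeden (1999), with block weights proportional to
the number of SNPs per block; linked SNPs within a block never contribute
independent information to the SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BlockJackknifeEstimate:
    """A genome-wide ratio statistic with its block-jackknife error."""

    name: str
    estimate: float
    loo_estimates: np.ndarray   # leave-one-block-out values, one per block
    block_weights: np.ndarray   # SNPs per block
    standard_error: float
    n_snps_used: int

    @property
    def z_score(self) -> float:
        if self.standard_error > 0:
            return self.estimate / self.standard_error
        return np.nan

    def __repr__(self) -> str:  # compact, admixtools-log style
        return (f"{self.name}: {self.estimate:.6g} "
                f"+/- {self.standard_error:.3g} (Z={self.z_score:.2f}, "
                f"nsnps={self.n_snps_used})")


def assign_blocks(snps: pd.DataFrame, mode: str = "bp",
                  block_size_bp: int = 5_000_000,
                  n_blocks: int | None = None) -> np.ndarray:
    """Assign every SNP to a contiguous block.

    mode ``"bp"``: contiguous physical spans of ``block_size_bp`` within each
    chromosome (the default for f-statistics and FST).
    mode ``"chromosome"``: one block per chromosome (leave-one-chromosome-out,
    used for admixture dating).
    mode ``"count"``: ``n_blocks`` blocks of (nearly) equal SNP counts,
    ignoring chromosome boundaries.
    """
    if mode == "count":
        if not n_blocks or n_blocks < 2:
            raise ValueError("mode='count' needs n_blocks >= 2")
        return (np.arange(len(snps)) * n_blocks // len(snps)).astype(int)
    ids = np.empty(len(snps), dtype=int)
    next_id = 0
    for _, sub in snps.groupby("chromosome", sort=False):
        if mode == "chromosome":
            ids[sub.index.to_numpy()] = next_id
            next_id += 1
        elif mode == "bp":
            local = (sub["physical_pos"].to_numpy()
                     - sub["physical_pos"].iloc[0]) // block_size_bp
            ids[sub.index.to_numpy()] = next_id + local
            next_id += int(local[-1]) + 1
        else:
            raise ValueError(f"unknown block mode {mode!r}")
    return ids


def ratio_jackknife(num: np.ndarray, den: np.ndarray, block_ids: np.ndarray,
                    name: str = "stat",
                    valid: np.ndarray | None = None) -> BlockJackknifeEstimate:
    """Jackknife a ratio-of-sums statistic over blocks.

    ``num``/``den`` are per-SNP contributions; SNPs where ``valid`` is False
    (or where num/den is non-finite) are excluded everywhere.  Blocks left
    empty after exclusion are dropped.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    ok = np.isfinite(num) & np.isfinite(den)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    if not ok.any():
        raise ValueError("no usable SNPs for jackknife")
    num, den, block_ids = num[ok], den[ok], np.asarray(block_ids)[ok]
    uniq, inv = np.unique(block_ids, return_inverse=True)
    n_blocks = uniq.size
    if n_blocks < 2:
        raise ValueError("need at least 2 non-empty blocks")
    num_b = np.bincount(inv, weights=num, minlength=n_blocks)
    den_b = np.bincount(inv, weights=den, minlength=n_blocks)
    m_b = np.bincount(inv, minlength=n_blocks).astype(float)
    tot_num, tot_den, n_tot = num_b.sum(), den_b.sum(), m_b.sum()
    theta = tot_num / tot_den
    loo = (tot_num - num_b) / (tot_den - den_b)
    # Busing et al. weighted delete-one jackknife
    h = n_tot / m_b
    theta_tilde = n_blocks * theta - np.sum((1.0 - m_b / n_tot) * loo)
    tau = h * theta - (h - 1.0) * loo
    var = np.sum((tau - theta_tilde) ** 2 / (h - 1.0)) / n_blocks
    return BlockJackknifeEstimate(
        name=name, estimate=float(theta), loo_estimates=loo,
        block_weights=m_b, standard_error=float(np.sqrt(max(var, 0.0))),
        n_snps_used=int(n_tot))


def jackknife_covariance(loo_matrix: np.ndarray) -> np.ndarray:
    """Delete-one jackknife covariance of a vector statistic.

    ``loo_matrix`` has one row per block (the leave-one-block-out estimate
    of the vector).  Returns the (dim x dim) covariance of the full-data
    estimate under equal block weights.
    """
    loo = np.asarray(loo_matrix, dtype=float)
    b = loo.shape[0]
    centered = loo - loo.mean(axis=0)
    return (b - 1.0) / b * (centered.T @ centered)
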