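"""f-statistics, the outgroup-f3 NJ tree, and qpWave/qpAdm admixture models.

All statistics are per-SNP moments of population allele frequencies,
averaged over the complete-case SNP set of their arguments and jackknifed
over contiguous genomic blocks:

* ``f2(A,B)``   = E[(pA - pB)^2], bias-corrected for finite samples;
* ``f3(T;A,B)`` = E[(pT - pA)(pT - pB)]; significantly negative values are
  possible only when T is admixed between populations related to A and B;
* ``f4(A,B;C,D)`` = E[(pA - pB)(pC - pD)], zero under treeness.

qpWave asks how many independent ancestry streams relate a "left" set of
populations to a "right" (outgroup) set, by testing the rank of the matrix
``X[i,j] = f4(l0, li; r0, rj)`` under its jackknife covariance.  qpAdm
models a target as a mixture of source populations: the target's vector of
f4-affinities to the right set must be the weight-combination of the
sources' vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .jackknife import (BlockJackknifeEstimate, assign_blocks,
                        jackknife_covariance, ratio_jackknife)
from .stats import AlleleFrequencyTable


@dataclass
class FStatResult:
    statistic: str
    populations: tuple[str, ...]
    jackknife: BlockJackknifeEstimate

    @property
    def estimate(self) -> float:
        return self.jackknife.estimate

    @property
    def z_score(self) -> float:
        return self.jackknife.z_score

    @property
    def n_snps_used(self) -> int:
        return self.jackknife.n_snps_used


def _valid_mask(freqs: AlleleFrequencyTable, pops) -> np.ndarray:
    m = np.ones(freqs.n_snps, dtype=bool)
    for p in pops:
        m &= np.isfinite(freqs.freq(p)) & (freqs.n(p) >= 2)
    return m


def _het_correction(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.isinf(n), 0.0, p * (1 - p) / (n - 1))


def _jackknife_stat(name, pops, per_snp, valid, freqs, blocks):
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    jk = ratio_jackknife(per_snp, np.ones_like(per_snp), blocks,
                         name=name, valid=valid)
    return FStatResult(name.split("(")[0], tuple(pops), jk)


def f2(freqs: AlleleFrequencyTable, a: str, b: str,
       blocks: np.ndarray | None = None, corrected: bool = True) -> FStatResult:
    """Unbiased f2 drift distance between two populations."""
    pa, pb = freqs.freq(a), freqs.freq(b)
    per_snp = (pa - pb) ** 2
    if corrected:
        per_snp = per_snp - _het_correction(pa, freqs.n(a)) \
            - _het_correction(pb, freqs.n(b))
    return _jackknife_stat(f"f2({a},{b})", (a, b), per_snp,
                           _valid_mask(freqs, (a, b)), freqs, blocks)


def f3(freqs: AlleleFrequencyTable, target: str, source1: str, source2: str,
       blocks: np.ndarray | None = None, corrected: bool = True) -> FStatResult:
    """f3(target; source1, source2), admixture or outgroup form.

    ``corrected`` subtracts the target's heterozygosity sampling term
    (required for the admixture test; irrelevant to within-outgroup
    comparisons, where it is a shared constant).
    """
    if target in (source1, source2):
        raise ValueError("target must differ from both sources")
    pt = freqs.freq(target)
    per_snp = (pt - freqs.freq(source1)) * (pt - freqs.freq(source2))
    if corrected:
        per_snp = per_snp - _het_correction(pt, freqs.n(target))
    return _jackknife_stat(f"f3({target};{source1},{source2})",
                           (target, source1, source2), per_snp,
                           _valid_mask(freqs, (target, source1, source2)),
                           freqs, blocks)


def classify_admixture_f3(result: FStatResult,
                          relaxed: bool = False) -> str:
    """Label an admixture-f3 result.

    ``"admixture_signal"`` when the estimate is negative with Z below -3
    (or -2 with ``relaxed``), else ``"no_signal"``.
    """
    z_cut = -2.0 if relaxed else -3.0
    if result.estimate < 0 and result.z_score < z_cut:
        return "admixture_signal"
    return "no_signal"


def f4(freqs: AlleleFrequencyTable, a: str, b: str, c: str, d: str,
       blocks: np.ndarray | None = None) -> FStatResult:
    """f4(A,B;C,D) = E[(pA-pB)(pC-pD)]; unbiased without correction."""
    per_snp = (freqs.freq(a) - freqs.freq(b)) * (freqs.freq(c) - freqs.freq(d))
    return _jackknife_stat(f"f4({a},{b};{c},{d})", (a, b, c, d), per_snp,
                           _valid_mask(freqs, (a, b, c, d)), freqs, blocks)


# ---------------------------------------------------------------------------
# outgroup-f3 matrix and neighbor joining
# ---------------------------------------------------------------------------

def outgroup_f3_matrix(freqs: AlleleFrequencyTable, populations: list[str],
                       outgroup: str,
                       blocks: np.ndarray | None = None) -> pd.DataFrame:
    """Symmetric matrix of shared drift M[i,j] = f3(outgroup; i, j).

    No heterozygosity correction on the outgroup by default: with a single
    fixed outgroup the correction is a constant shift that cancels in
    relative comparisons.
    """
    if outgroup in populations:
        raise ValueError("outgroup must not appear among the populations")
    k = len(populations)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            res = f3(freqs, outgroup, populations[i], populations[j],
                     blocks=blocks, corrected=False)
            m[i, j] = m[j, i] = res.estimate
    if not np.isfinite(m).all():
        raise ValueError("non-finite outgroup-f3 entries")
    return pd.DataFrame(m, index=populations, columns=populations)


@dataclass
class NJTree:
    """An unrooted binary tree from neighbor joining, as Newick text."""

    newick: str
    leaves: list[str]
    has_negative_branches: bool = False


def nj_tree(distances: pd.DataFrame) -> NJTree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Negative branch lengths (possible with non-additive distances such as
    1 - outgroup-f3) are retained and flagged, not clamped.
    """
    labels = list(distances.index)
    d = distances.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [lab for lab in labels]  # newick fragment per active node
    active = list(range(n))
    negative = False
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2 * (m - 2))
        lj = dij - li
        negative |= (li < 0) or (lj < 0)
        # distances from the new internal node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k_loc, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join the last three nodes on a central vertex
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    negative |= min(li, lj, lk) < 0
    newick = (f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},"
              f"{nodes[k]}:{lk:.10g});")
    return NJTree(newick=newick, leaves=labels,
                  has_negative_branches=bool(negative))


def outgroup_f3_nj_tree(freqs: AlleleFrequencyTable, populations: list[str],
                        outgroup: str,
                        blocks: np.ndarray | None = None) -> NJTree:
    """NJ phylogeny from D = 1 - f3(outgroup; i, j)."""
    m = outgroup_f3_matrix(freqs, populations, outgroup, blocks=blocks)
    d = 1.0 - m
    dv = d.to_numpy()
    np.fill_diagonal(dv, 0.0)
    return nj_tree(pd.DataFrame(dv, index=d.index, columns=d.columns))


# ---------------------------------------------------------------------------
# qpWave / qpAdm
# ---------------------------------------------------------------------------

def _per_block_means(per_snp: np.ndarray, valid: np.ndarray,
                     block_ids: np.ndarray):
    """Total and leave-one-block-out means for a stack of per-SNP series.

    ``per_snp`` is (n_stats x n_snps); returns (totals, loo) where ``loo``
    is (n_blocks x n_stats).
    """
    ok = valid & np.isfinite(per_snp).all(axis=0)
    vals = per_snp[:, ok]
    uniq, inv = np.unique(np.asarray(block_ids)[ok], return_inverse=True)
    n_blocks = uniq.size
    if n_blocks < 2:
        raise ValueError("need at least 2 non-empty blocks")
    sums = np.zeros((n_blocks, vals.shape[0]))
    np.add.at(sums, inv, vals.T)
    counts = np.bincount(inv, minlength=n_blocks).astype(float)
    tot_sum, tot_n = sums.sum(axis=0), counts.sum()
    totals = tot_sum / tot_n
    loo = (tot_sum[None, :] - sums) / (tot_n - counts)[:, None]
    return totals, loo


def _f4_stack(freqs, first, second, col_first, col_pops):
    """Per-SNP f4(first, second; col_first, c) series for each c."""
    base = freqs.freq(first) - freqs.freq(second)
    rows = [base * (freqs.freq(col_first) - freqs.freq(c)) for c in col_pops]
    return np.vstack(rows)


def _regularized_inverse(cov: np.ndarray, ridge_scale: float = 1e-12):
    dim = cov.shape[0]
    ridge = ridge_scale * np.trace(cov) / dim
    try:
        return np.linalg.inv(cov + ridge * np.eye(dim))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "jackknife covariance not invertible; use coarser blocks "
            "(fewer, larger) so there are more blocks than f4 cells"
        ) from exc


def _rank_fit_statistic(x: np.ndarray, cov_inv: np.ndarray, shape, r,
                        n_iter: int = 200, tol: float = 1e-12) -> float:
    """GLS residual of the best rank-r approximation of matrix vec ``x``."""
    nrow, ncol = shape
    if r == 0:
        return float(x @ cov_inv @ x)
    xm = x.reshape(nrow, ncol)
    u, s, vt = np.linalg.svd(xm, full_matrices=False)
    a = u[:, :r] * s[:r]
    b = vt[:r].T
    prev = np.inf
    for _ in range(n_iter):
        # solve for a given b: vec(ab') = (I_nrow kron b) vec(a')  -- build
        # the design explicitly; the problem sizes here are tiny.
        design_a = np.zeros((nrow * ncol, nrow * r))
        for i in range(nrow):
            design_a[i * ncol:(i + 1) * ncol, i * r:(i + 1) * r] = b
        g = design_a.T @ cov_inv
        a = np.linalg.solve(g @ design_a, g @ x).reshape(nrow, r)
        design_b = np.zeros((nrow * ncol, ncol * r))
        for i in range(nrow):
            for j in range(ncol):
                design_b[i * ncol + j, j * r:(j + 1) * r] = a[i]
        g = design_b.T @ cov_inv
        b = np.linalg.solve(g @ design_b, g @ x).reshape(ncol, r)
        resid = x - (a @ b.T).ravel()
        cost = float(resid @ cov_inv @ resid)
        if abs(prev - cost) < tol * (1 + abs(cost)):
            break
        prev = cost
    return cost


@dataclass
class QpWaveResult:
    left: list[str]
    right: list[str]
    p_rank: dict[int, float]
    statistics: dict[int, float]
    dof: dict[int, int]
    n_snps_used: int


def qpwave_rank_test(freqs: AlleleFrequencyTable, left: list[str],
                     right: list[str],
                     blocks: np.ndarray | None = None) -> QpWaveResult:
    """Test the rank of the left-right f4 matrix for r = 0..|left|-2.

    Small tail probabilities at rank r reject "at most r+1 ancestry
    streams"; a homogeneous left pair is accepted when p_rank0 > 0.01.
    """
    if len(left) < 2:
        raise ValueError("need at least 2 left populations")
    if len(right) < len(left):
        raise ValueError("need at least as many right as left populations")
    if set(left) & set(right):
        raise ValueError("left and right sets must be disjoint")
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    nrow, ncol = len(left) - 1, len(right) - 1
    per_snp = np.vstack([
        _f4_stack(freqs, left[0], li, right[0], right[1:]) for li in left[1:]])
    valid = _valid_mask(freqs, list(left) + list(right))
    totals, loo = _per_block_means(per_snp, valid, blocks)
    cov = jackknife_covariance(loo)
    cov_inv = _regularized_inverse(cov)
    p_rank, stats_, dof = {}, {}, {}
    for r in range(len(left) - 1):
        stat = _rank_fit_statistic(totals, cov_inv, (nrow, ncol), r)
        df = (nrow - r) * (ncol - r)
        stats_[r] = stat
        dof[r] = df
        p_rank[r] = float(sps.chi2.sf(stat, df)) if df > 0 else np.nan
    n_used = int((valid & np.isfinite(per_snp).all(axis=0)).sum())
    return QpWaveResult(list(left), list(right), p_rank, stats_, dof, n_used)


def pairwise_qpwave_labels(result: QpWaveResult) -> str:
    """The homogeneity annotation for one population pair: '++' when
    p_rank0 > 0.05, '+' when > 0.01, '-' otherwise."""
    p0 = result.p_rank[0]
    if p0 > 0.05:
        return "++"
    if p0 > 0.01:
        return "+"
    return "-"


@dataclass
class AdmixtureModel:
    target: str
    sources: list[str]
    right: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    p_rank: dict[int, float]
    feasible: bool
    degenerate: bool
    n_snps_used: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"source": self.sources, "weight": self.weights,
                             "se": self.weight_se})


def _solve_weights(y_t, y_s, cov_inv_builder):
    """GLS weights for y_t ~ sum_i alpha_i y_s[i] with sum(alpha) = 1.

    Eliminates the constraint through the last source; one feasible-GLS
    refinement re-estimates the residual covariance at the interim solution.
    """
    k = y_s.shape[0]
    w = y_t - y_s[-1]
    m = (y_s[:-1] - y_s[-1]).T  # (cells x k-1)
    if k == 1:
        return np.array([1.0]), False
    gamma, *_ = np.linalg.lstsq(m, w, rcond=None)
    degenerate = False
    for _ in range(2):
        cov_inv = cov_inv_builder(gamma)
        gram = m.T @ cov_inv @ m
        try:
            gamma = np.linalg.solve(gram, m.T @ cov_inv @ w)
        except np.linalg.LinAlgError:
            gamma = np.linalg.pinv(gram) @ (m.T @ cov_inv @ w)
            degenerate = True
    if np.linalg.matrix_rank(m, tol=1e-10 * max(1.0, np.abs(m).max())) \
            < k - 1:
        degenerate = True
    alpha = np.append(gamma, 1.0 - gamma.sum())
    return alpha, degenerate


def qpadm(freqs: AlleleFrequencyTable, target: str, sources: list[str],
          right: list[str],
          blocks: np.ndarray | None = None) -> AdmixtureModel:
    """Estimate admixture weights modelling ``target`` from ``sources``.

    The target's f4-affinity vector to the right set,
    ``y(pop)[j] = E[(p_pop - p_r0)(p_rj - p_r0)]``, must equal the
    weight-combination of the sources' vectors; the shared finite-sample
    bias from the r0 frequency cancels under the sum-to-one constraint.
    Weight standard errors re-run the entire fit leaving out each block.
    """
    if target in sources:
        raise ValueError("target must not be one of the sources")
    left = [target] + list(sources)
    if set(left) & set(right):
        raise ValueError("left and right sets must be disjoint")
    if len(right) < len(sources) + 1:
        raise ValueError("need at least |sources|+1 right populations")
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    per_snp = np.vstack([
        _f4_stack(freqs, pop, right[0], right[0], right[1:]) for pop in left])
    # sign: y[j] = (p_pop - p_r0)(p_r0 - p_rj) = -(above); constant across
    # pops, so either sign gives identical weights -- keep as computed.
    valid = _valid_mask(freqs, left + list(right))
    totals, loo = _per_block_means(per_snp, valid, blocks)
    ncells = len(right) - 1
    k = len(sources)

    def split(vec):
        mat = vec.reshape(len(left), ncells)
        return mat[0], mat[1:]

    def fit(vec, loo_mat):
        y_t, y_s = split(vec)

        def cov_inv_builder(gamma):
            resid_loo = []
            for row in loo_mat:
                yt_b, ys_b = split(row)
                w_b = yt_b - ys_b[-1]
                m_b = (ys_b[:-1] - ys_b[-1]).T
                resid_loo.append(w_b - m_b @ gamma)
            cov = jackknife_covariance(np.vstack(resid_loo))
            return _regularized_inverse(cov)

        return _solve_weights(y_t, y_s, cov_inv_builder)

    alpha, degenerate = fit(totals, loo)
    # whole-fit jackknife for the weight SEs
    n_blocks = loo.shape[0]
    alphas_b = np.empty((n_blocks, k))
    for b in range(n_blocks):
        keep = np.arange(n_blocks) != b
        alphas_b[b], _ = fit(loo[b], loo[keep])
    se = np.sqrt((n_blocks - 1) / n_blocks
                 * ((alphas_b - alphas_b.mean(axis=0)) ** 2).sum(axis=0))
    rank = qpwave_rank_test(freqs, left, right, blocks=blocks)
    feasible = bool(np.all(alpha >= 0) and np.all(alpha <= 1))
    return AdmixtureModel(target, list(sources), list(right), alpha, se,
                          rank.p_rank, feasible, degenerate, rank.n_snps_used)
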