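"""Genotype matrices and on-disk formats.

The central container is :class:`GenotypeMatrix`: a samples x SNPs table of
alternate-allele dosages (0, 1, 2, or missing) with sample and SNP metadata.
Two interchange formats are supported, PLINK binary (bed/bim/fam) and
EIGENSTRAT (geno/snp/ind), both read and written natively so that round
trips are bit-exact.

Conventions
-----------
* physical positions are 1-based (the native convention of both formats);
  BED gene annotations elsewhere in the package are 0-based half-open and
  converted at the boundary.
* genetic positions are stored in Morgans. When an input carries no genetic
  map, positions default to ``physical_pos * 1e-8`` (1 cM/Mb).
* the missing-genotype sentinel is ``MISSING`` (-1) in memory, ``9`` in
  EIGENSTRAT geno files and the ``01`` bit pair in PLINK bed files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

SNP_COLUMNS = ["snp_id", "chromosome", "genetic_pos", "physical_pos",
               "allele_ref", "allele_alt"]
SAMPLE_COLUMNS = ["sample_id", "population", "sex"]


class GenotypeFormatError(ValueError):
    """Raised when an on-disk genotype file violates its format contract."""


def _read_table(path: Path, names, dtype=None) -> pd.DataFrame:
    if path.stat().st_size == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in names})
    return pd.read_csv(path, sep=r"\s+", header=None, names=names, dtype=dtype)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a set of samples at a set of SNPs.

    Parameters
    ----------
    genotypes : ndarray of shape (n_samples, n_snps), integer
        Alternate-allele dosage per sample per SNP; values in
        ``{0, 1, 2, MISSING}``.
    samples : DataFrame with columns sample_id, population, sex
    snps : DataFrame with columns snp_id, chromosome, genetic_pos
        (Morgans), physical_pos (1-based bp), allele_ref, allele_alt,
        sorted by (chromosome, physical_pos).
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_samples, n_snps = self.genotypes.shape
        if len(self.samples) != n_samples:
            raise ValueError("sample table does not match genotype rows")
        if len(self.snps) != n_snps:
            raise ValueError("SNP table does not match genotype columns")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_ids")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,missing}")
        if (self.snps["allele_ref"] == self.snps["allele_alt"]).any():
            raise ValueError("allele_ref == allele_alt at some SNP")
        chrom = self.snps["chromosome"].to_numpy()
        pos = self.snps["physical_pos"].to_numpy()
        boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        if len(np.unique(chrom)) != len(boundaries) + 1 and n_snps > 0:
            raise ValueError("SNPs of one chromosome must be contiguous")
        within = np.ones(max(n_snps - 1, 0), dtype=bool)
        within[boundaries - 1] = False
        if np.any((np.diff(pos) < 0) & within):
            raise ValueError("SNPs not position-sorted within chromosome")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = pd.Index(self.samples["sample_id"])
        idx = lookup.get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"unknown sample ids: {missing}")
        return idx

    def take_samples(self, indices) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes[np.asarray(indices)],
                              self.samples.iloc[indices],
                              self.snps)

    def take_snps(self, indices) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes[:, np.asarray(indices)],
                              self.samples,
                              self.snps.iloc[indices])

    def populations(self) -> dict[str, list[str]]:
        return {p: list(sub["sample_id"])
                for p, sub in self.samples.groupby("population", sort=False)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (np.array_equal(self.genotypes, other.genotypes)
                and self.samples[SAMPLE_COLUMNS].equals(
                    other.samples[SAMPLE_COLUMNS])
                and self.snps[["snp_id", "chromosome", "physical_pos",
                               "allele_ref", "allele_alt"]].equals(
                    other.snps[["snp_id", "chromosome", "physical_pos",
                                "allele_ref", "allele_alt"]])
                and np.allclose(self.snps["genetic_pos"],
                                other.snps["genetic_pos"]))


@dataclass
class PopulationGrouping:
    """Maps population names to member sample ids, with a declared outgroup."""

    groups: dict[str, list[str]]
    outgroup: str | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pop, members in self.groups.items():
            for s in members:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {pop!r}")
                seen[s] = pop
        if self.outgroup is not None and self.outgroup not in self.groups:
            raise ValueError(f"outgroup {self.outgroup!r} not a population")

    @classmethod
    def from_matrix(cls, g: GenotypeMatrix,
                    outgroup: str | None = None) -> "PopulationGrouping":
        return cls(g.populations(), outgroup=outgroup)

    @classmethod
    def from_tsv(cls, path, outgroup: str | None = None) -> "PopulationGrouping":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["sample_id", "population"], dtype=str)
        groups: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            groups.setdefault(row["population"], []).append(row["sample_id"])
        return cls(groups, outgroup=outgroup)

    def validate_against(self, g: GenotypeMatrix) -> None:
        known = set(g.samples["sample_id"])
        for pop, members in self.groups.items():
            unknown = set(members) - known
            if unknown:
                raise ValueError(f"population {pop!r} references unknown "
                                 f"samples {sorted(unknown)}")


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

_SEX_TO_EIG = {1: "M", 2: "F", 0: "U"}
_EIG_TO_SEX = {"M": 1, "F": 2, "U": 0}


def _read_eigenstrat(prefix: Path) -> GenotypeMatrix:
    geno_path, snp_path, ind_path = (prefix.with_suffix(s)
                                     for s in (".geno", ".snp", ".ind"))
    for p in (geno_path, snp_path, ind_path):
        if not p.exists():
            raise FileNotFoundError(f"missing EIGENSTRAT component: {p}")
    ind = pd.read_csv(ind_path, sep=r"\s+", header=None,
                      names=["sample_id", "sex", "population"], dtype=str)
    snp = _read_table(snp_path,
                      names=["snp_id", "chromosome", "genetic_pos",
                             "physical_pos", "allele_ref", "allele_alt"],
                      dtype={"snp_id": str, "chromosome": str})
    n_samples, n_snps = len(ind), len(snp)
    geno = np.empty((n_snps, n_samples), dtype=np.int8)
    count = 0
    with open(geno_path, "rb") as fh:
        for raw in fh:
            line = raw.strip()
            if count >= n_snps:
                raise GenotypeFormatError("geno has more lines than .snp rows")
            if len(line) != n_samples:
                raise GenotypeFormatError(
                    f"geno line {count + 1} has {len(line)} characters, "
                    f"expected {n_samples}")
            row = np.frombuffer(line, dtype=np.uint8) - ord("0")
            if not np.isin(row, (0, 1, 2, 9)).all():
                raise GenotypeFormatError(
                    f"invalid geno character, line {count + 1}")
            geno[count] = row
            count += 1
    if count != n_snps:
        raise GenotypeFormatError("geno line count disagrees with .snp")
    geno[geno == 9] = MISSING
    samples = pd.DataFrame({
        "sample_id": ind["sample_id"],
        "population": ind["population"],
        "sex": ind["sex"].map(_EIG_TO_SEX).fillna(0).astype(int),
    })
    snp["physical_pos"] = snp["physical_pos"].astype(np.int64)
    snp["genetic_pos"] = snp["genetic_pos"].astype(float)
    return GenotypeMatrix(geno.T, samples, snp[SNP_COLUMNS])


def _write_eigenstrat(g: GenotypeMatrix, prefix: Path) -> None:
    geno = g.genotypes.T.copy()
    geno[geno == MISSING] = 9
    chars = (geno + ord("0")).astype(np.uint8)
    with open(prefix.with_suffix(".geno"), "wb") as fh:
        if g.n_snps:
            out = np.empty((g.n_snps, g.n_samples + 1), dtype=np.uint8)
            out[:, :-1] = chars
            out[:, -1] = ord("\n")
            fh.write(out.tobytes())
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for row in g.snps.itertuples(index=False):
            fh.write(f"{row.snp_id}\t{row.chromosome}\t"
                     f"{row.genetic_pos:.10g}\t{row.physical_pos}\t"
                     f"{row.allele_ref}\t{row.allele_alt}\n")
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for row in g.samples.itertuples(index=False):
            sex = _SEX_TO_EIG.get(int(row.sex) if pd.notna(row.sex) else 0, "U")
            fh.write(f"{row.sample_id}\t{sex}\t{row.population}\n")


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------
# bed is SNP-major: per SNP, ceil(n/4) bytes, two bits per sample, LSB first.
# Bit pairs: 00 = two copies of allele-1, 01 = missing, 10 = het,
# 11 = zero copies of allele-1.  We store allele-1 (bim column 5) as the
# alternate allele, so the dosage is the count of allele-1.

_CODE_FROM_DOSAGE = np.full(4, 0, dtype=np.uint8)
_CODE_FROM_DOSAGE[0] = 0b11
_CODE_FROM_DOSAGE[1] = 0b10
_CODE_FROM_DOSAGE[2] = 0b00
_DOSAGE_FROM_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bed_path, bim_path, fam_path = (prefix.with_suffix(s)
                                    for s in (".bed", ".bim", ".fam"))
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK component: {p}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "sample_id", "father", "mother",
                             "sex", "phenotype"], dtype=str)
    bim = _read_table(bim_path,
                      names=["chromosome", "snp_id", "genetic_pos",
                             "physical_pos", "allele_alt", "allele_ref"],
                      dtype={"chromosome": str, "snp_id": str})
    n_samples, n_snps = len(fam), len(bim)
    bytes_per_snp = (n_samples + 3) // 4
    raw = bed_path.read_bytes()
    if raw[:3] != PLINK_MAGIC:
        raise GenotypeFormatError(
            f"{bed_path} does not start with the PLINK magic bytes")
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != n_snps * bytes_per_snp:
        raise GenotypeFormatError(
            f"bed payload is {body.size} bytes, expected "
            f"{n_snps * bytes_per_snp}")
    body = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit codes, LSB-first within each byte
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    geno = _DOSAGE_FROM_CODE[codes[:, :n_samples]]
    samples = pd.DataFrame({
        "sample_id": fam["sample_id"],
        "population": fam["fid"],
        "sex": pd.to_numeric(fam["sex"], errors="coerce").fillna(0).astype(int),
    })
    snps = pd.DataFrame({
        "snp_id": bim["snp_id"],
        "chromosome": bim["chromosome"],
        "genetic_pos": bim["genetic_pos"].astype(float),
        "physical_pos": bim["physical_pos"].astype(np.int64),
        "allele_ref": bim["allele_ref"],
        "allele_alt": bim["allele_alt"],
    })
    return GenotypeMatrix(geno.T, samples, snps)


def _write_plink(g: GenotypeMatrix, prefix: Path) -> None:
    n_samples = g.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    geno = g.genotypes.T  # SNP-major
    codes = np.where(geno == MISSING, 0b01,
                     _CODE_FROM_DOSAGE[np.clip(geno, 0, 2)]).astype(np.uint8)
    padded = np.zeros((g.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    packed = np.zeros((g.n_snps, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in g.snps.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t"
                     f"{row.genetic_pos:.10g}\t{row.physical_pos}\t"
                     f"{row.allele_alt}\t{row.allele_ref}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for row in g.samples.itertuples(index=False):
            sex = int(row.sex) if pd.notna(row.sex) else 0
            fh.write(f"{row.population}\t{row.sample_id}\t0\t0\t{sex}\t-9\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_READERS = {"plink_bed": _read_plink, "eigenstrat": _read_eigenstrat}
_WRITERS = {"plink_bed": _write_plink, "eigenstrat": _write_eigenstrat}


def read_genotypes(path_prefix, format: str) -> GenotypeMatrix:
    """Read a genotype dataset given its file-system prefix.

    ``format`` is ``"plink_bed"`` (prefix.bed/.bim/.fam) or ``"eigenstrat"``
    (prefix.geno/.snp/.ind).
    """
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}")
    return _READERS[format](Path(path_prefix))


def write_genotypes(g: GenotypeMatrix, path_prefix, format: str) -> None:
    """Write ``g`` under ``path_prefix`` in the chosen format."""
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}")
    g.validate()
    Path(path_prefix).parent.mkdir(parents=True, exist_ok=True)
    _WRITERS[format](g, Path(path_prefix))


def merge_datasets(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two sample sets on the intersection of their SNPs.

    SNPs are matched by (chromosome, physical_pos).  If ``b``'s ref/alt
    alleles are swapped relative to ``a``'s, ``b``'s dosages are recoded
    ``g -> 2 - g``.  SNPs whose allele pairs are incompatible (including
    strand-ambiguous mismatches) are dropped and counted in the log.
    """
    shared_samples = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if shared_samples:
        raise ValueError(f"duplicate sample ids across inputs: "
                         f"{sorted(shared_samples)[:5]}")
    key_a = pd.MultiIndex.from_frame(a.snps[["chromosome", "physical_pos"]])
    key_b = pd.MultiIndex.from_frame(b.snps[["chromosome", "physical_pos"]])
    pos_in_b = key_b.get_indexer(key_a)
    matched = np.flatnonzero(pos_in_b >= 0)
    if matched.size == 0:
        raise ValueError("no shared SNP positions between the two datasets")
    ia, ib = matched, pos_in_b[matched]
    ref_a = a.snps["allele_ref"].to_numpy()[ia]
    alt_a = a.snps["allele_alt"].to_numpy()[ia]
    ref_b = b.snps["allele_ref"].to_numpy()[ib]
    alt_b = b.snps["allele_alt"].to_numpy()[ib]
    same = (ref_a == ref_b) & (alt_a == alt_b)
    flipped = (ref_a == alt_b) & (alt_a == ref_b)
    keep = same | flipped
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("merge: dropped %d SNPs with incompatible alleles",
                    n_dropped)
    ia, ib = ia[keep], ib[keep]
    flipped = flipped[keep]
    gb = b.genotypes[:, ib].copy()
    if flipped.any():
        col = gb[:, flipped]
        miss = col == MISSING
        col = 2 - col
        col[miss] = MISSING
        gb[:, flipped] = col
    genotypes = np.vstack([a.genotypes[:, ia], gb])
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    return GenotypeMatrix(genotypes, samples, a.snps.iloc[ia])


def filter_missingness(g: GenotypeMatrix, snp_max_missing: float = 0.05,
                       sample_max_missing: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs then samples whose missing fraction exceeds its threshold.

    The SNP pass runs first; sample missingness is then recomputed over the
    surviving SNPs.  Idempotent.
    """
    for frac in (snp_max_missing, sample_max_missing):
        if not 0 <= frac <= 1:
            raise ValueError("missingness thresholds must lie in [0, 1]")
    miss = g.genotypes == MISSING
    snp_keep = miss.mean(axis=0) <= snp_max_missing
    miss = miss[:, snp_keep]
    if miss.shape[1] == 0:
        sample_keep = np.ones(g.n_samples, dtype=bool)
    else:
        sample_keep = miss.mean(axis=1) <= sample_max_missing
    return GenotypeMatrix(g.genotypes[np.ix_(sample_keep, snp_keep)],
                          g.samples.loc[sample_keep],
                          g.snps.loc[snp_keep])


def _window_r2(geno: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation of genotype columns; missing entries are
    mean-imputed and monomorphic columns are treated as r² = 0."""
    x = geno.astype(float)
    x[geno == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    inds = np.where(np.isnan(x))
    x[inds] = mean[inds[1]]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    x[:, ok] /= sd[None, ok]
    x[:, ~ok] = 0.0
    r = (x.T @ x) / x.shape[0]
    r2 = r * r
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(g: GenotypeMatrix, window_snps: int = 200, step_snps: int = 25,
             r2_threshold: float = 0.4) -> GenotypeMatrix:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` SNPs, while any surviving pair has
    r² above the threshold, the member of the worst pair with the lower
    minor-allele frequency (tie-break: the later position) is removed; the
    window then slides by ``step_snps``.
    """
    if not window_snps > step_snps > 0:
        raise ValueError("require window_snps > step_snps > 0")
    n = g.n_snps
    keep = np.ones(n, dtype=bool)
    x = g.genotypes.astype(float)
    x[g.genotypes == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(x, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1 - freq)
    for start in range(0, max(n - step_snps, 1), step_snps):
        idx = np.flatnonzero(keep[start:start + window_snps]) + start
        if idx.size < 2:
            continue
        r2 = _window_r2(g.genotypes[:, idx])
        active = np.ones(idx.size, dtype=bool)
        while True:
            sub = r2[np.ix_(active, active)]
            if sub.size == 0 or sub.max() <= r2_threshold:
                break
            ai = np.flatnonzero(active)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            gi, gj = idx[ai[i]], idx[ai[j]]
            if maf[gi] < maf[gj]:
                drop = gi
            elif maf[gj] < maf[gi]:
                drop = gj
            else:
                drop = max(gi, gj)  # later position
            keep[drop] = False
            active[np.flatnonzero(idx == drop)[0]] = False
    return g.take_snps(np.flatnonzero(keep))
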