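# Methods

`admixkit` implements the allele-frequency statistical toolbox of
population-genomic admixture studies — f-statistics, qpWave/qpAdm, FST and
PBS selection scanning, ROH and kinship QC, PCA projection, and weighted-LD
admixture dating — together with a drift-tree genotype simulator whose
closed-form expectations serve as oracles for every stage. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic validation does and does not show.

## Genotype data model

A `GenotypeMatrix` is a samples × SNPs table of alternate-allele dosages
{0, 1, 2, missing}. Physical positions are 1-based (PLINK/EIGENSTRAT
convention); BED gene intervals are 0-based half-open and converted exactly
once, at the annotation boundary. Genetic positions are Morgans; when an
input has no genetic map, 1 cM/Mb (`physical_pos × 1e-8`) is assumed —
exact for the simulator, which always writes a constant-rate map.

Merging matches SNPs by (chromosome, position), recodes `g → 2 − g` where
the second dataset's ref/alt are swapped, and drops allele-incompatible
sites with a logged count. No strand flipping is attempted: the formats are
array-derived and strand-ambiguous (A/T, C/G) mismatches cannot be resolved
from genotypes alone, so dropping is the conservative choice.

Missingness QC removes SNPs above the SNP threshold first, then samples
above the sample threshold computed over the surviving SNPs (both default
0.05). The fixed order matches the common tool behaviour; note it is not a
strict fixed point when missingness straddles a threshold, because removing
a sample changes surviving SNPs' missing fractions.

LD pruning is greedy within sliding windows (defaults 200 SNPs, step 25,
r² > 0.4): the worse member of the worst pair is removed repeatedly, where
"worse" means lower minor-allele frequency, then later position.
Monomorphic SNPs have undefined correlation and are treated as r² = 0
(retained).

## The drift-tree simulator

Populations sit on a rooted tree. Ancestral frequencies are uniform on
[0.05, 0.95]; down a branch with drift intensity F the daughter frequency is
Beta-distributed with mean p and variance F·p(1−p) (the Balding–Nichols
model), clamped to [1e-6, 1−1e-6] to keep Beta parameters and Bernoulli
draws non-degenerate. Genotypes are Binomial(2, p) per diploid.

**Closed-form FST.** Serial drift composes multiplicatively: a population
whose path from a reference ancestor crosses branches F₁…F_k has unshared
drift v = 1 − ∏(1 − F_i), i.e. Var(p_leaf) = v·p(1−p). For two populations
the Hudson ratio-of-averages estimator converges to the **mean of the two
unshared drifts below their MRCA**, (v_a + v_b)/2 — shared drift above the
MRCA adds the same covariance to numerator and denominator and cancels.
Derivation: E[(p₁−p₂)²] = (v₁+v₂)·E[pq] after the sampling corrections,
and E[p₁(1−p₂)+p₂(1−p₁)] = 2E[pq] when the unshared drifts are
independent. `simulate.expected_hudson_fst` implements this and the
simulation tests confirm it to ±0.01 at 50k SNPs. Two leaves hanging one
branch of F=0.05 each off the root therefore give FST ≈ 0.05; leaves at the
end of two-branch chains of F=0.05 each give 1−(1−0.05)² ≈ 0.0975.

**Two admixture modes.** Frequency mixing draws target genotypes from
Σαᵢpᵢ per SNP — correct marginals, no LD; sufficient for f-statistics,
qpAdm, and PBS. Mosaic mode partitions each haploid chromosome copy by a
Poisson(n per Morgan) breakpoint process, assigns each segment an ancestry
iid with the admixture weights, and draws alleles from that source — this
produces ancestry covariance decaying as exp(−n·d), the signal weighted-LD
dating measures. Segment ancestries are independent across segments (no
back-coalescence), which slightly inflates breakpoint effects at very small
n but is standard for pulse-model generators.

**Planted truth.** Selected loci shift one SNP's target-population
frequency by +δ (clamped with a warning) and regenerate that column; ROH
tracts overwrite a span with 2× one haplotype draw; relatives are genotype
copies (duplicates) or Mendelian children (one transmitted allele with
probability g/2, one population draw). All truths go into a JSON manifest.

## Block jackknife

Every genome-wide statistic is a ratio of per-SNP sums Σn/Σd. Standard
errors use the weighted delete-one block jackknife (Busing et al. 1999)
with weights proportional to SNPs per block, which reduces to
SE² = (B−1)/B · Σ(θ_b − θ̄)² for equal blocks. Blocks default to contiguous
5 Mb physical spans for f-statistics/FST (community default) and to whole
chromosomes for dating (leave-one-chromosome-out). The engine is verified
against an independent loop-based reimplementation to 1e-12.

## FST estimators

Hudson (default; Bhatia et al. 2013 recommendation): per SNP
N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), D = p₁(1−p₂)+p₂(1−p₁),
n in chromosomes; genome-wide value is ΣN/ΣD (ratio of averages, never the
average of ratios). Weir–Cockerham is provided for parity with PLINK-based
workflows; since the frequency table carries no genotype-level het counts,
its h̄ term uses the HWE expectation 2p(1−p). Hudson is exact and is what
every internal consumer (PBS, acceptance oracles) uses. SNPs with fewer
than 2 observed chromosomes in either population are excluded.

## f-statistics

f2(A,B) = E[(p_A−p_B)²] with both sampling corrections; f3(T;A,B) =
E[(p_T−p_A)(p_T−p_B)] minus the target correction p_T(1−p_T)/(n_T−1) when
`corrected` (required for the admixture test; off by default in outgroup
mode, where the correction is a constant shift within one outgroup);
f4(A,B;C,D) = E[(p_A−p_B)(p_C−p_D)], unbiased as-is. SNP inclusion is
complete-cases per statistic; all four argument populations must have ≥ 2
chromosomes. An admixture-f3 is labelled a signal at Z < −3, with a relaxed
Z < −2 exploratory flag — both thresholds are emitted because both are used
in practice.

The outgroup-f3 matrix M_ij = f3(O; i, j) feeds neighbor joining on
D = 1 − M (Saitou–Nei Q-criterion, standard branch-length formulas,
three-point closure at the end). Negative branch lengths — possible since
1 − f3 is not additive — are retained and flagged, not clamped. The NJ
implementation is cross-checked against scikit-bio's in the tests.

## qpWave and qpAdm

qpWave forms X_ij = f4(l₀, l_i; r₀, r_j) over the complete-case SNP set of
all left and right populations, estimates the covariance of vec(X) by the
delete-one block jackknife, and for each rank r fits the best rank-r
approximation X ≈ AB′ by alternating generalized least squares; the
residual statistic is referred to χ² with (|L|−1−r)(|R|−1−r) degrees of
freedom. Rank 0 tests one shared ancestry stream: a homogeneous population
pair shows p_rank0 > 0.01 ("+", or "++" above 0.05). The covariance gets a
ridge of 1e-12 × trace/dim; genuinely singular cases (fewer blocks than
matrix cells) raise with advice to coarsen blocks.

qpAdm uses the affinity vectors y(pop)_j = E[(p_pop − p_r0)(p_rj − p_r0)]:
under the admixture model y(target) = Σαᵢ·y(sourceᵢ) with Σαᵢ = 1, and the
finite-sample bias from p̂_r0 is identical for every left population, so it
cancels in the constrained residual. Weights solve the GLS problem with
the constraint eliminated through the last source; the residual covariance
is re-estimated once at the interim solution (feasible GLS). Weight SEs
re-run the entire fit leaving out each block. The feasibility flag reports
weights outside [0, 1]; rank-deficient source configurations (e.g. two
identical sources) are flagged degenerate. Identifiability requires right
populations differentially related to the sources — on a star phylogeny
the weights are undefined, which is a property of the method, not the
implementation. With few SNPs and small samples the errors-in-variables
noise in the source vectors attenuates weights slightly toward the centre;
at the validation sizes (10⁵ SNPs, 20 diploids) recovery is within ±0.05.

## Kinship and relatedness QC

KING-robust between-family: φ = (N_hethet − 2·N_opposing-hom) /
(N_het(i) + N_het(j)), counts over mutually non-missing SNPs. Degrees use
the standard cut points: ≥ 0.354 duplicate/MZ, [0.177, 0.354) first degree,
[0.0884, 0.177) second degree. `flag_related` greedily removes the sample
in the most over-threshold pairs (deterministic tie-break by id) until no
pair exceeds the threshold, defaulting to 0.0884 (keep through second
cousins out). Pairs with no overlapping calls are flagged undefined.

## Runs of homozygosity

The caller scans each sample × chromosome for maximal runs in which every
trailing window of `min_snps` SNPs holds at most `het_allowance` (1)
heterozygotes and `missing_allowance` (5) missing calls; a physical gap
above `max_gap_bp` (1 Mb) splits runs into independent segments; runs are
trimmed to homozygous endpoints; a segment is emitted iff it has ≥ 50 SNPs
AND spans ≥ 100 kb. The two printed minima under-determine a caller, so the
sentence admits two readings — minimum length and gap splitting — and both
are implemented as separate parameters rather than choosing one. The other
window parameters follow PLINK's defaults and are all exposed.

## PBS selection scan

Per SNP, each pairwise FST (Hudson N/D by default) is clamped to
[0, 1−1e-12] and transformed to T = −ln(1−FST); the target branch length is
PBS_A = (T_AB + T_AC − T_BC)/2. Clamping happens only inside the log —
reported FST stays unbiased (negative values intact). PBS is per-SNP (no
windowing; an optional window mean exists but is off). Candidates are SNPs
**strictly** above the empirical percentile of all finite PBS values;
default 99.9 (top 0.1%), with the stricter 99.99 available as a parameter
since both conventions circulate. Annotation joins candidate SNPs (1-based
p) to BED genes via start ≤ p−1 < end; the Venn machinery reports occupied
regions and the all-configuration intersection. Regional LD tables
interpret "200 kb" as the total span centred on the index SNP.

**Sweep-recovery design.** A planted shift δ competes with the upper tail
of coherent target-branch drift: over M SNPs the largest background
displacement is ≈ sqrt(F·pq)·Φ⁻¹(1−1/M) plus binomial sampling noise
sqrt(pq/n_chrom). At δ = 0.4 this forces small background drift: the
validation uses F = 0.005, M = 10⁴ and 150 diploids per population, and
anchors the planted SNP at ancestral frequency ≈ 0.3 (conditioning on the
*target's* frequency would select for target-branch drift and bias the
plant). Under these conditions the planted SNP ranks first in all six
ingroup configurations across validation seeds; at F = 0.02 and M = 5×10⁴
it demonstrably does not, whatever the implementation.

## Weighted-LD admixture dating

For target t and references 1, 2, every same-chromosome SNP pair (i, j)
with genetic distance d ∈ [mindis, maxdis] contributes
cov_t(i,j)·(p₁ᵢ−p₂ᵢ)·(p₁ⱼ−p₂ⱼ) to the bin of d; bin values are means.
`mindis` defaults to 0.005 Morgans (background LD dominates below),
bin width 0.001 M, maxdis 0.5 M. The curve is fit by pair-count-weighted
nonlinear least squares to M·exp(−n·d) + c with multi-starts at
n ∈ {5, 20, 50, 100, 200}; a flat curve returns a non-convergence flag.
Dates and amplitudes get leave-one-chromosome-out jackknife errors
(non-convergent replicates dropped with the survivors reported); the
amplitude Z-score is the no-admixture control — on unadmixed targets
|Z(M)| < 2 in ≥ 90% of seeds at the validation sizes (10 chromosomes of
0.7 M; fewer chromosomes leave too few jackknife replicates to calibrate
the SE). Only generations are reported; calendar conversion is a pure
config multiplication (default 29 years/generation, "years before
sampling") — no calendar-era arithmetic is attempted.

## Validation sizes

The test suite simulates all its data. Sizes were chosen so each
statistical property is comfortably powered: FST closed form at 50k SNPs ×
50 diploids; f4 null calibration over 200 replicates of 20k SNPs; f3
admixture signal over 100 replicates; qpAdm at 100k SNPs with 12 right
populations; qpWave calibration over 20 replicates per direction; sweep
recovery at the conditions derived above; dating over 50 admixed and 50
null seeds; NJ topology recovery over 20 seeds of a 6-leaf tree.

## Limitations

Synthetic data has no real LD beyond the planted admixture LD, no
genotyping error, no ascertainment bias, and a constant recombination map;
passing these tests shows the estimators are correct and calibrated under
their model assumptions, not that real-data preprocessing (phasing,
strand resolution, array ascertainment) is handled. IBD segment
*detection* and model-based clustering are out of scope by design — only
segment binning of precomputed tables is provided. The Weir–Cockerham
variant assumes HWE within populations for its heterozygosity term.
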