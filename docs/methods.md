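# Methods

## Model

### Estimation step

For one gene with K isoforms in one sample, let l_k be the transcript
length of isoform k and r₁…r_N the aligned read pairs overlapping the
gene span. Each pair either matches isoform k — both mates map
contiguously onto the isoform's exon chain, every splice gap in the
alignment coinciding with an intron of the isoform — or it does not.
When it matches, the *implied fragment length* l_kⁿ is the inclusive
transcript-coordinate distance between the pair's outer ends; when it
does not, l_kⁿ = 0. Transcript offsets are computed genomic-forward:
fragment lengths are differences of offsets, so the computation is
strand-symmetric (verified on both strands in the tests).

With f(·) the sample-wide fragment length distribution, the per-read
terms are

    a_nk = f(l_kⁿ) / (l_k − l_kⁿ + 1),   0 if l_kⁿ = 0 or l_kⁿ > l_k,

i.e. the fragment length carries probability f(l) and the fragment is
placed uniformly over the l_k − l + 1 start positions on the isoform.
EM with the source isoform as latent variable maximises

    ℓ(p) = Σ_n log Σ_k p_k a_nk

over mixture weights p on the simplex (E-step responsibilities
w_nk ∝ p_k a_nk; M-step p_k ← mean_n w_nk). Usage is recovered by the
effective-length inversion

    θ̂_k ∝ p̂_k / Z_k,    Z_k = Σ_l f(l)·(l_k − l + 1)₊,

which undoes the bias by which longer isoforms attract more fragments.
Reads compatible with no isoform are dropped and tallied (no noise
class is modelled); so are structurally compatible pairs whose implied
lengths all fall outside f's truncated support, which carry zero
density. No junction-overhang restriction is imposed on spliced reads.
Duplicate pairs are retained unless the deduplication filter is
enabled.

f(·) is estimated per sample, pooled genome-wide, from pairs whose
compatible isoforms all imply the *same* fragment length (e.g. both
mates inside an exon shared by all isoforms, or single-isoform genes),
so the estimate is independent of the unknown usage. Support is
truncated at the 0.001/0.999 empirical quantiles (configurable), with
optional Gaussian kernel smoothing; below 1,000 usable fragments a
discretised normal fallback (default mean 250, sd 25) is used with a
warning. Per-gene f estimates were rejected as too unstable.

### Testing step

Usage compositions are compositional data; statistical work is done in
Aitchison geometry via the ilr transform z = V·clr(θ), with
clr(θ)ᵢ = ln θᵢ − mean_j ln θⱼ and V the (K−1)×K Helmert-type
orthonormal contrast matrix (row i contrasts the first i parts against
part i+1). The hierarchical sampling model treats each sample's
estimate as ilr(θ̂_ij) ~ N(ilr(θ_ij), Υ_ij) around a sample mean that
itself varies as ilr(θ_ij) ~ N(ilr(θ_i), Σ_i) about the group mean.
Assuming a common within-group Υ_i, all samples of group i share the
marginal covariance Σ_i + Υ_i, which differs between groups — the
multivariate Behrens–Fisher problem. Group means are reported as the
compositional (component-wise geometric) mean, the ilr-inverse of the
ilr average.

Before transforming: isoforms whose usage is numerically zero
(≤ 10⁻⁸; EM only reaches exact zero when an isoform has no compatible
reads) in *every* sample of *both* groups are removed and the rest
re-closed — if fewer than two isoforms survive the gene is untestable.
Remaining zeros are replaced by a small ε (default 10⁻⁴, user
adjustable; larger values such as 0.01 damp the influence of near-zero
usage on log-ratio distances) and the composition re-closed.

Three tests of H₀: equal group means on ℝ^(K−1):

* **KY** — T² = d′S̃⁻¹d with S̃ = S₁/J₀ + S₂/J₁; T²(ν−p+1)/(νp) is
  referred to F(p, ν−p+1) with the modified Nel–van der Merwe degrees
  of freedom ν = (p + p²) / Σᵢ [tr((S̃ᵢS̃⁻¹)²) + tr(S̃ᵢS̃⁻¹)²]/(Jᵢ−1).
  At p = 1 this is exactly Welch's t-test (ν reduces to
  Welch–Satterthwaite). Requires S̃ invertible, hence p < min(J₀, J₁);
  otherwise the result is flagged inapplicable.
* **CQ** — the sum of between-observation cross-products within and
  across groups, standardised by the leave-one/two-out trace
  estimators of tr(Σᵢ²) and tr(Σ₁Σ₂); upper-tail normal p-value. No
  covariance inversion, so valid when K−1 exceeds the group sizes.
* **SKK** — q = d′D̂⁻¹d with D̂ = diag(S̃), centred at its asymptotic
  null expectation p and scaled by √(2·tr(R̂²)·c_{p,n}) where
  R̂ = D̂^{−1/2}S̃D̂^{−1/2} and c_{p,n} = 1 + tr(R̂²)·p^{−3/2} is the
  small-sample correction; upper-tail normal p-value. At p = 1 the
  kernel q is the squared Welch t statistic. Because of the diagonal
  standardisation SKK — unlike KY and CQ — is *not* invariant to the
  ilr basis; the package fixes the Helmert basis and records it, and
  the basis dependence is asserted as documented behaviour in the
  tests. Zero-variance dimensions are dropped with a flag.

SKK is the default test; its and CQ's normal reference is
anti-conservative at small J (empirical size ≈ 0.09–0.10 at J = 5,
K−1 = 3 in the package's own null calibration), which motivates the
**permutation** option: group labels are permuted and the statistic
recomputed; with at most B distinct splits all are enumerated and
p = #{splits with statistic ≥ observed}/n_splits, otherwise B random
splits give p = (1 + #{≥ observed})/(1 + B). Ties count as ≥
(conservative). For an exchange-symmetric statistic the observed
split's complement always ties it, so the attainable minimum
exhaustive p at J₀ = J₁ = 5 is 2/252, and the exact size of the
α = 0.05 rule is 12/252 ≈ 0.048.

Across genes, p-values are adjusted by Bonferroni (FWER, default) or
Benjamini–Hochberg (FDR); the family is the set of testable genes in
the comparison, and untestable genes (NaN) are excluded from the
family size.

## Simulator

The generator runs the estimation model forward. Per-sample usage is
drawn on ilr coordinates from N(ilr(θ_group), Σ) — the same
logistic-normal hierarchy the tests assume — and mapped back to the
open simplex. Read-pair counts per gene are set by
N = round(coverage · Σ_k θ_k l_k / (2·read_len)), a definition chosen
here since "average coverage" has no canonical operational form.
Source isoforms are Categorical(p) with p_k ∝ θ_k Z_k; fragment
lengths are drawn from f conditioned on fitting the isoform; start
positions are uniform over valid placements; mate blocks are projected
across exon junctions into genomic intervals and can be emitted as
valid coordinate-sorted SAM/BAM with spliced (N) CIGARs, proper-pair
flags and no timestamps (byte-identical reruns under a fixed seed).
Reads are emitted pre-aligned and error-free: sequencing errors,
mapping ambiguity, positional/GC bias and noise reads are *not*
emulated, so passing calibration shows correctness of the statistical
machinery under the assumed generative model, not robustness to
alignment artefacts in real data.

Default study conditions: five samples per group, coverage grid
{10, 30, 50, 70, 90, 110} (single-level studies use 100), fragment
lengths discretised-normal (mean 200, sd 20 for the built-in toy genes,
whose isoforms are 400–1,300 nt; the estimation fallback default is
250/25, typical of real libraries), read length 50, between-sample
ilr standard deviation 0.15 (diagonal Σ). The group-level covariances
in published designs of this kind come from unpublished tissue data;
the simulator ships configurable diagonal covariances instead, so
calibration studies reproduce the *design*, not specific tabulated
values. The built-in toy gene set (K = 1, 2, 3, 5 with skipped exons,
alternate first/last exons, one minus-strand gene) keeps studies
CPU-cheap; study sizes in the test suite (200 round-trip replicates,
10,000 multivariate-normal null replicates, 1,000 permutation null
datasets) were chosen to make the Monte-Carlo standard errors small
relative to the asserted tolerances.

## Numerical choices and edge cases

* Coordinates are 0-based half-open internally; GTF I/O converts at
  the boundary. Genes spanning multiple chromosomes or strands are
  rejected as meaningless for this model. Each annotated gene is
  processed independently; a read pair may count toward every gene
  whose span contains it.
* EM starts at uniform p with one Dirichlet random restart by default
  (fixed seed), keeping the best likelihood; convergence is
  max|Δp| < 10⁻⁶ (the scale the updates live on) or 1,000 iterations,
  with non-convergence flagged rather than raised. Identical isoforms
  make p non-identifiable: the fixed point from the uniform start is
  reported and a `non_identifiable` flag set when term-matrix columns
  coincide.
* Genes with fewer than 10 usable pairs (configurable) are flagged
  `insufficient_reads` and excluded from testing by the pipeline;
  genes with usable reads in fewer than two samples of either group
  are reported untestable with a reason code.
* KY falls back to a flagged NaN result when S̃ is singular or has
  condition number above 10¹²; CQ returns a flagged p = 1 when its
  variance estimate is non-positive (degenerate constant data).
* Technical replicates are pooled at the read-pair level before
  estimation; read-name collisions are suffix-disambiguated.

## Limitations

Single-end reads, transcript assembly, expression-level testing,
bias correction and >2-group designs are out of scope. The exact
placement-probability and f-estimation conventions of other
implementations differ in unpublished details; the conventions above
are declared, self-consistent (simulate→estimate round-trips are part
of the acceptance suite) and recorded in output metadata, but p-values
from the basis-dependent SKK test are comparable only under the same
ilr basis.
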