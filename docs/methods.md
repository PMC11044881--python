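# Methods

## Model

Allele frequency at a locus is treated as a probability mass function on
the discrete space of all 4^l nucleotide sequences of length l, with
distance the number of substitutions (Hamming distance). The estimator is a
discrete KDE: each of the n sampled sequences contributes 1/n of mass
spread by the kernel

    Q_P(x) = (1 − 3P)^(l−x) · P^x,

the probability that one *specific* sequence at distance x arises from the
kernel center under the Jukes–Cantor substitution model. `P` is the
per-base probability that one specific base has turned into one specific
other base; after g generations at per-base rate μ it equals
P(g, μ) = ¼ + (μ/3 − ¼)(1 − 4μ/3)^(g−1) ≡ ¼(1 − (1 − 4μ/3)^g), rising from
0 to the saturation value ¼. Neither g nor μ is needed at estimation time:
`P` is the single bandwidth parameter, selected directly.

Assumptions inherited from the kernel: equal-length, gap-free sequences
(indels are rejected — a single indel event touches many sites and cannot
be folded into a substitution distance), no mixed/ambiguity bases, and an
isotropic substitution process (all base exchanges equally likely).
Anisotropic kernels for general time-reversible models would make the
kernel value depend on the actual bases, which is incompatible with the
distance-space compression and is out of scope.

## Distance space

The full sequence space is materialized only for l ≤ 10 (4^10 coordinates,
a hard guard checked before any allocation). Otherwise the estimate lives
on the distance space: one coordinate per detected allele plus one per
realizable vector of distances from an undetected sequence to the detected
alleles. With the kernel truncated at mutation number m:

- sequences farther than m from every detected allele carry no mass and
  are not represented at all;
- distance entries above m in *undetected* coordinates are censored to
  `Inf` (serialized as the literal string "Inf");
- *detected* coordinates keep their full uncensored distance vectors —
  those distances are known exactly from the data (so `{AAA, AAT, GGG}` at
  m = 1 yields `(0,1,3), (1,0,3), (3,3,0)` plus four censored classes).

Coordinates are found constructively by enumerating all patterns of ≤ m
mutated positions around each detected allele (with incremental distance
updates and exact deduplication across anchors), or by brute enumeration of
4^l when that is cheaper; both routes produce identical coordinates and
multiplicities and are cross-checked against an independent enumeration
oracle in the test suite. Only realizable coordinates are stored: every
coordinate's multiplicity (the count of sequences realizing it) is a
positive integer, and the multiplicities of the untruncated space total
4^l. Feasibility shortcuts that admit coordinates satisfying the pairwise
sum bound d_i + d_j ≥ D_ij but violating the triangle bound
|d_i − d_j| ≤ D_ij would inflate the space with zero-multiplicity phantom
coordinates and are deliberately not used.

Coordinate order is deterministic: detected alleles first (input order),
then undetected coordinates lexicographically with `Inf` sorting last.

## Estimation and cross-validation

On either space, the per-sequence mass at a coordinate is
(1/n) Σᵢ cᵢ Q_P(dᵢ) over the detected alleles with counts cᵢ at distances
dᵢ ≤ m (censored entries contribute nothing); a coordinate's total mass is
that value times its multiplicity. With the default renormalization the
truncated kernel is rescaled to total 1 over its within-m shells, so every
sample contributes exactly 1/n and the estimate is a proper mass function
(total 1 within 1e−9 by construction; at P = 0 or m = 0 it equals counting
exactly). Without renormalization total mass falls below 1; both behaviors
are exposed because the truncation convention is genuinely open — the
renormalized default is this package's choice, made so that "frequencies
sum to one" survives truncation.

Bandwidth selection evaluates a deterministic grid (0 plus 64 log-spaced
points from 1e−8 to 0.2499) and optionally refines the optimum by bounded
golden-section search between the neighboring grid points (xatol 1e−7;
accepted only if it strictly improves the criterion; ties break toward
smaller P, i.e. less smoothing):

- **LSCV** minimizes Σ_c mult(c) f̂(c)² − (2/n) Σᵢ f̂₋ᵢ(aᵢ), the discrete
  integrated-squared-error criterion. Multiplicity weighting makes the
  distance-space value identical to the sequence-space value
  (oracle-verified), which is why it is the adopted form.
- **LCV** maximizes Σᵢ log f̂₋ᵢ(aᵢ). Leave-one-out removes one
  *individual*, not one allele type (denominator n − 1). If any held-out
  allele has zero leave-one-out mass the criterion is −∞; candidates at −∞
  are excluded, and if every candidate is −∞ the selection falls back to
  P = 0 with a flag — the estimate then equals plain counting. This
  degeneracy is real, not an implementation artifact: any sample containing
  a singleton allele farther than m from every other sampled allele drives
  LCV to −∞ at every bandwidth.

The discrete CV forms above are the standard derivative-free analogues;
plug-in selectors require Taylor expansions that the sequence space does
not support.

## Approximate nucleotide diversity

π = Σᵢ Σⱼ pᵢ pⱼ dᵢⱼ/l cannot be computed exactly on the distance space
because distances between undetected coordinates are not recorded. The
approximation keeps detected–detected terms (exact distances), adds
detected–undetected terms, and drops undetected–undetected terms; since
every dropped term is non-negative, π̃ never exceeds the full-space value
on the same estimate — the source of its systematic negative bias. For a
coordinate whose entry for allele B is censored, its sequences sit at a
known distance x from the nearest finite-entry anchor allele A (ties break
toward the lexicographically smallest allele) and farther than m from B;
the term uses the mean of the exact conditional distance distribution,
computed by convolution over the d differing and l − d agreeing positions
of A and B (a change at an agreeing position shifts the distance to B by
+1 with 3 variants; at a differing position by −1 with 1 variant or 0 with
2). With a debug flag (and member tracking enabled) the
undetected–undetected terms are restored from the actual member sequences,
which reproduces the exact sequence-space π to 1e−10 in tests. Expected
heterozygosity and Watterson's θ are excluded: they need per-site
frequencies the distance space does not retain.

The concordance rate 1 − Σ|f − f̂| is evaluated on the estimate's
coordinate system: population alleles are mapped onto coordinates (several
may share one; their frequencies add) and alleles outside the truncated
space contribute their whole frequency as discrepancy. It is 1 iff the
distributions coincide and can reach −1 for disjoint supports.

## Numerical choices

Kernel masses are computed in log space — (l−x)·log1p(−3P) + x·log P, with
the truncated normalizer via log-sum-exp — and exponentiated once at the
boundary; the point-mass limits P = 0 and m = 0 are handled exactly rather
than by underflow. Subsequent accumulation (mass sums, CV criteria) uses
linear double-precision dot products: all summands are non-negative, so no
cancellation occurs and the dynamic range (≥ P^m with P ≥ 1e−8, m ≤ 2 in
practice) is far from underflow. Degenerate inputs are rejected early with
typed errors (gap, alphabet, length, empty input, capacity, configuration
mismatches).

## Synthetic populations

The generator emulates the evaluation setup: a single-deme Kingman
coalescent for N lineages (exponential waiting times with rate C(k,2),
scaled by 2N generations per coalescent unit, so a pair coalesces after 2N
generations in expectation — the sampled lineages *are* the population by
default, with the timescale exposed separately for sensitivity checks),
finite-sites Jukes–Cantor mutations using the same closed-form chain as
the kernel (per branch of b generations each site changes with probability
3P(b, μ) in a single exact draw), and seeded subsampling without
replacement. Defaults follow the study conditions: population size 100,
mutation rates 0.01–0.1 per base per generation, sample sizes 20–100,
20 replicates; sequence length defaults to 200 to keep the full factorial
experiment tractable on one CPU (1,000 bp is supported).

What the generator does not emulate: recombination, demography, migration,
selection, rate heterogeneity across sites, and non-JC substitution
(GTR would require the anisotropic kernels excluded above). Passing tests
therefore certify the estimator's internal consistency and its behavior on
idealized neutral single-locus data, not performance on real loci.

A consequence of the study conditions worth stating plainly: at rate
0.01/bp/generation on a 2N-generation timescale, pairwise divergence
(≈ 4 substitutions per site) saturates the Jukes–Cantor chain, so
populations consist of a few recent clusters plus many mutually saturated
lineages. Samples then almost always contain isolated singletons, LCV is
−∞ at every bandwidth and falls back to counting (mirroring the real-data
observation that LCV selects near-zero bandwidths), while LSCV — whose
criterion rewards spreading mass — selects large bandwidths and collapses
the diversity estimate. The harness reports both, which is itself the
method's central negative result: smoothing does not help, and the m = 0
baseline is the most accurate in every cell.

## Experiment harness

One population is simulated per (mutation rate, replicate) and shared
across sample sizes, mutation numbers and CV methods (the resampling
design); all randomness flows from one root seed through documented
SeedSequence spawning, and two runs with the same seed produce
byte-identical reports. Per replicate the harness records the selected
bandwidth, fallback flag, π̃, the known population π, relative errors and
the concordance rate; per-cell aggregation divides the bias/accuracy sums
by the replicate count so values are comparable across designs. When
counting the fraction of negative-bias replicates, exact ties (LCV
fallback) are treated as zero bias — a dead zone of 1e−9 on the relative
error — so that ±1e−16 roundoff does not masquerade as signal.

## Limitations

- The distance space still grows quickly with the number of detected
  alleles and the mutation number; m = 2 at 1,000 bp with ~100 alleles is
  the practical ceiling on a workstation, and m ≥ 3 is typically
  unaffordable. Guards refuse, rather than attempt, oversized spaces.
- π̃'s negative bias grows with the mass placed on undetected alleles,
  i.e. exactly when the method smooths most.
- LCV degenerates to counting whenever any sampled singleton is isolated
  beyond m — increasingly likely at high divergence or small m.
- The model is single-locus and haploid-sample oriented; no linkage,
  phasing or diploid genotype handling.
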