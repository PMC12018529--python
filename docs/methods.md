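# Methods

## Model and assumptions

`seqepi` analyses two SIR epidemics run one after the other on the same
configuration-model network. The assumptions that make the analysis
exact in the large-population limit are:

- **Static configuration model.** Degrees are i.i.d. from a prescribed
  distribution D with finite second moment; half-edges are paired
  uniformly at random. Self-loops and parallel edges are removed — their
  number is bounded in expectation as n grows, so they do not affect
  asymptotics. Heavy-tailed degree laws with infinite variance (the pure
  power law) are outside the model's assumptions and are rejected.
- **Constant infectious periods.** Both epidemics scale time so each
  infectious period has length one. This makes per-edge transmission
  events independent, which is what turns the first epidemic into bond
  percolation (edge retention probability p = 1 − e^(−β)) and makes the
  outbreak probability and the attack rate coincide at 1 − q. Random
  infectious periods would require a four-type process and are not
  implemented.
- **Strict succession.** The first epidemic ends before the second
  starts; the only state it leaves behind is which vertices were
  infected.
- **Conditioning.** All second-epidemic quantities are conditional on
  the first epidemic being large (supercritical R0_1 > 1 and the seed's
  percolation cluster being the giant one).

## The three-type branching calculus

On the local tree around a uniform vertex, the first epidemic is
encoded by colouring edges "red" independently with probability p and
calling a vertex a prior case iff it lies on an infinite red path.
Types: 1 = prior case with an infinite red path *of descent*, 2 = prior
case without one, 3 = escapee; types 1 vs {2,3} are labels A/B. The
probability a non-root vertex has label B is q̃, the smallest root of
s = f_{D̃−1}(1−p+ps), solved by monotone fixed-point iteration from 0
(the map is a PGF composition, hence increasing and convex, so the
iteration converges to the smallest root; subcritical inputs return 1
silently so degenerate downstream cases remain well defined).

The label means use f_D'' at x* = 1−p+pq̃:

    mu_AA = (f''(1) − (1−p) f''(x*)) / mu_D
    mu_AB = (q̃/(1−q̃)) (f''(1) − f''(x*)) / mu_D
    mu_BA = ((1−p)(1−q̃)/q̃) f''(x*) / mu_D
    mu_BB = f''(x*) / mu_D

The q̃/(1−q̃) prefactor on mu_AB comes from the Bayes inversion in the
derivation of the conditional offspring law; it is validated
mechanically by the test that differentiates the offspring PGF bundle
numerically at (1,1,1) and compares entrywise with the mean matrix M,
and empirically by the reproduction of the published asymptotic table
to four decimals. At p = 1 exactly, label B has probability zero; mu_AB
and mu_BB vanish in the limit and the indeterminate mu_BA is set to 0
("sterile B" convention — harmless because B never occurs).

Forward process (outbreak probability): offspring PGFs are compositions
of the tree-offspring PGFs (built from f_D and f_{D̃−1}) with affine
per-child thinning maps in the contact probabilities π_ij. The
extinction vector ξ is the minimal fixed point in [0,1]³, found by
iterating from the origin. The major-outbreak probability is
1 − w1 f1(ξ) − w3 f3(ξ), with root-type weights (1−q, q) for a
uniformly chosen seed. A second seeding scheme weights the root by
susceptibility — the seed is drawn uniformly among those still
susceptible (polarized) or by an alpha_S-rejection loop (leaky), giving
type-3 weight q/(q+α(1−q)) resp. q/(q+α_S(1−q)); this is the scheme
under which the reference table values are reproduced, and it is
undefined (an error) for a general contact table.

Backward process (final size): the susceptibility set of a uniform
vertex is a branching process with the *transposed* contact table
(π̂_ij = π_ji), reusing the same tree-offspring PGFs. For polarized
immunity the backward process needs its own PGFs because a vertex can
be contacted by several children: a prior case is globally immune with
probability 1 − α, giving the mixture form 1 − α + α f(1−p′+p′s, …).
The mixture maps use the second-epidemic probability p′ throughout
(not the first-epidemic p — a plausible-looking alternative; the two
readings differ whenever p′ ≠ p, and with p′ = 0.3 against p = 0.15
the reference table values confirm p′). Final size: z = 1 − (1−q) ξ̌₁ − q ξ̌₃, with the four-way
joint classification (q ξ̌₃, (1−q) ξ̌₁, q(1−ξ̌₃), (1−q)(1−ξ̌₁)). Root
typing always uses the uniform weights (1−q, q): the size of a large
outbreak does not depend on how it was seeded.

## Critical immunity and herd immunity

alpha_c solves R0_2(α) = 1. Two routes are provided: the closed-form
quadratic for polarized immunity with p′ = p (roots computed in a
cancellation-safe form, smaller in-range root selected; a numerically
degenerate leading coefficient, |a| < 1e−12·|b|, falls back to the
linear root), and generic bisection of R0_2(α) − 1 on [0, 1] (200
iterations, tol 1e−10), which applies to both leaky and polarized
builders; the two agree to 1e−8 where both apply. When α_S α_I = α with
α_I > 0 the leaky and polarized mean matrices are similar via
diag(1, 1, 1/α_I), so their spectra — and hence alpha_c — coincide.

Under complete immunity (π_11 = π_01 = 0) the second epidemic is
single-type with R0_2 = π_00 f''(x*)/mu_D. The herd-immunity threshold
solves R0_2(p) = 1 for the first-epidemic p by outer bisection (tol
1e−10) with q̃(p) re-solved inside the objective (inner tol 1e−12); the
objective is monotone non-increasing in p. For Poisson-type families
(f_D' ∝ (f_D)^κ: Poisson κ = 1, Binomial(n) κ = (n−1)/n with constant
degree d the θ = 1 case, NegBin(r) κ = (r+1)/r) the closed form
q′ = (1/R0′)^{1/(2κ−1)} is exposed and checked against the numeric
solve; κ ≤ 1/2 is rejected. The overshoot comparison against the
homogeneous benchmark 1 − 1/R0′ reverses sign exactly at κ = 1.

## Numerical choices

- **PGF engine.** The four named families use closed-form PGFs; the
  power-law-with-cutoff family evaluates the polylogarithm Li_s(z) by
  direct series summation in blocks of 256 terms with a geometric tail
  bound (z = e^(−1/κ) < 1 always, so the series is eventually
  geometric; relative truncation 1e−16). Custom distributions are
  finite pmf vectors; a size-biased specification is inverted via
  p_k ∝ p̃_k/k. Degree sampling uses closed-form generators where numpy
  has them and inverse-CDF tables otherwise (tail truncated at 1e−15).
- **Fixed points.** All extinction vectors iterate from the origin with
  sup-norm tolerance 1e−12 and a 10^6 iteration cap; near criticality
  convergence is slow but monotone and safe. Because the stopping rule
  is on successive iterates, downstream closed-form comparisons use
  tolerances of 1e−8..1e−9 rather than 1e−12.
- **Spectral radius.** R0_2 is computed with the dense eigensolver and
  asserted to be attained by a numerically real eigenvalue
  (Perron–Frobenius for non-negative matrices).
- **Degenerate inputs.** The all-degree-2, p = 1 network (pure cycles)
  makes the fixed-point equation the identity and is rejected
  explicitly. Subcritical first epidemics return q̃ = q = 1 rather than
  erroring.

## Simulator

Each replicate regenerates the graph (i.i.d. degrees, uniform pairing,
odd leftover half-edge dropped, self-loops removed, parallel edges
merged — the imperfection count is recorded and is O(1) in n). The
first epidemic retains each edge with probability p1 and takes the
seed's connected component (scipy's connected components on the
retained subgraph). The second epidemic runs in discrete generations:
each ordered infectious→susceptible pair is resolved exactly once, with
probability π_{a(u),a(v)}; under polarized immunity the per-individual
coin is tossed before seeding so "uniform among susceptibles" is well
defined, and every attempt onto a non-immune target succeeds with
probability p′. The chosen seed is infected unconditionally and counts
toward the outbreak size. "Large" means size > cutoff with defaults
100/200/300 for n = 500/1000/≥5000. Estimators: p̂_maj = (# large
second among large first)/(# large first) with a binomial standard
error; ẑ_maj = mean infected fraction over the large second epidemics
with a sample standard error. Per-replicate RNG streams are spawned
from one master seed, so results are reproducible and replicates
independent.

**Problem sizes.** The test suite exercises the simulator at n = 2000
with 300 replicates for routine cross-validation and at n = 10000 with
1000 replicates for the headline comparison; the acceptance script uses
n = 10000 with 1000 replicates (standard error of ẑ ≈ 6e−4, comfortably
resolving the asymptotic value). The Monte-Carlo branching-process
oracle uses 10^5 runs per extinction probability with a survival
declaration at population 50 (misclassification probability below
ξ^50 ≈ 1e−37, negligible against sampling error).

## What the generator emulates — and what it does not

The study conditions are those of the published numerical
illustrations: four mean-10 degree families (constant 10, Poisson(10),
geometric(1/10), power law α_D = 1 with cutoff κ = 36.6472, variances
0/10/90/271.495), first-epidemic per-pair transmission 0.15,
second-epidemic baseline 0.3, polarized α = 1/2 and leaky
α_S = α_I = √1/2 (calibrated so both immunity models share R0_2).
The synthetic networks are pure configuration models: no clustering, no
degree assortativity, no households or spatial structure, and no
temporal overlap between the epidemics. Passing tests therefore show
correctness of the percolation/branching calculus and simulator under
those idealisations, not robustness of the predictions on real contact
networks, where clustering and assortativity are known to shift both
thresholds and final sizes.

## Known limitations

- Constant infectious periods only; i.i.d. random periods need a
  four-type process (not implemented).
- The final-size convergence for the second epidemic is supported by
  branching-process theory plus simulation agreement; a full
  finite-n convergence proof is beyond scope here as in the source
  theory.
- The configuration-model reconfiguration approximations from the
  earlier literature (two-type percolation on a rewired network) are
  deliberately not implemented; the package computes the asymptotically
  exact quantities they approximate.
- The simulator is a desk-scale tool (n up to ~10^5); it regenerates
  the graph per replicate by default, which dominates runtime.
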