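# Methods

## Problem and notation

Single-individual haplotyping (haplotype assembly) reconstructs the two
haplotypes of a diploid individual from aligned sequence fragments. Only
heterozygous sites are informative, and alleles are recoded per site to
{0, 1}, so the target is a phase vector `Φ = φ_1…φ_M` with
`φ_j ∈ Δ = {(0,1), (1,0)}`. A fragment is a sparse map from 1-based site
index to allele; it *spans* the sites it reports and *covers* cut `j` when
it spans sites on both sides of the boundary between `j−1` and `j`
(possibly non-consecutively). Because the two haplotypes have no intrinsic
identity, `Φ` and its site-wise complement are the same prediction, and
every comparison in the package is invariant under that switch. Fragments
spanning fewer than two sites carry no phase information and are dropped
at load (counted and logged).

## Mixture likelihood

Fragments are modelled as independent draws: fragment `f` picks a
haplotype `h` with probability `p_m(h) = ½` and emits, at each spanned
site, the allele that the (latent) phase places on `h`, corrupted by a
symmetric error channel with rate `α`:

    P(f | Θ) = Σ_h ½ Π_{j∈X(f)} Σ_ν θ_{jν} p_e(f_j | ν_h).

`α` is a fixed constant, default 0.1, never optimised: the heterozygous
sites alone are a poor source for estimating it, while read-level data at
large are a good one. The mixture weights are fixed at ½ (they converge
there anyway); the only free parameters are the phase probabilities
`θ_jν`, with `θ_j(0,1) + θ_j(1,0) = 1`. All likelihood arithmetic is in
natural logs (log-sum-exp), so every score the package reports —
connectivity, MC, chimerity — is in **nats**.

## Variational inference

The posterior over fragment origins `H`, per-fragment phase assignments
`Ψ` and parameters `Θ` is approximated by a factorised
`Q(H,Ψ)·Q(Θ)` with `Q(Θ)` a product of per-site Dirichlet distributions
`Dir(θ_j | λ_j)`. The resulting coordinate updates are the standard
mean-field/conjugate pair for this generative model:

* E step: `log β_ihjν = log p_e(f_ij|ν_h) + ψ(λ_jν) − ψ(Σ_ν' λ_jν')`;
  fragment responsibilities `q_ih ∝ ½ Π_j Σ_ν β_ihjν`; phase
  responsibilities `ρ_ihjν ∝ β_ihjν` (ψ = digamma).
* M step: `λ_jν = λ⁰_jν + Σ_i Σ_h q_ih ρ_ihjν` over fragments spanning `j`.

After an E step the evidence lower bound reduces to
`Σ_i log Z_i − Σ_j KL(Dir(λ_j) ‖ Dir(λ⁰_j))` with `Z_i` the per-fragment
normaliser; it is non-decreasing over iterations (asserted to 1e−8 in the
tests) and each full cycle adds exactly `Σ_i |X(f_i)|` units of Dirichlet
mass. Point estimates use the posterior mean
`θ̂_jν = λ_jν / Σ_ν' λ_jν'`.

Defaults: uniform prior `λ⁰ = 1` (least informative proper choice; the
posterior-mean confidence of a site spanned by `n` fragments is therefore
capped at `(1+n)/(2+n)`), convergence when the ELBO gain drops below
1e−6, at most 500 cycles, 3 jittered random restarts keeping the best
ELBO (the perfectly symmetric state is a saddle point, so the
initialisation adds `U(0, 0.1)` jitter per `(j, ν)` from the seeded RNG).

The production loop runs through a fused numba kernel (one pass computes
the E step, the conjugate update and the per-fragment normalisers); the
pure-numpy `e_step`/`m_step`/`elbo` functions are the reference
implementation and a unit test pins the two to ~1e−14 agreement.

## Twist-restart optimisation

Gradient-free coordinate ascent cannot repair a *switch error* — a suffix
fitted with exchanged haplotype labels — because every single-site change
lowers the objective. The optimiser therefore alternates VBEM with
*twists*: flip the Dirichlet hyperparameters `λ_jν → λ_jν̄` for all sites
at or beyond a candidate cut, re-run VBEM from the twisted state, and
keep the result only if the data log-likelihood at the posterior mean
improves by more than 1e−6. Candidate cuts are visited in ascending order
of connectivity (recomputed from the current posterior mean after every
accepted twist); cuts already tried since the last accepted twist are
skipped, cuts no fragment covers are never tried (a twist there provably
changes nothing), and the loop stops when no candidate improves or after
`max_twists = 100` re-runs. Accepted log-likelihoods are monotone
non-decreasing by construction. On simulated data the heuristic reaches —
and often exceeds — the likelihood of a run started from a truth-biased
initial state (`λ⁰ + 1` on the true phase), which the tests use as the
optimality reference.

## Connectivity and confident blocks

The connectivity of cut `j₀` is the marginal log-likelihood drop under a
twist of the *parameters* at `j₀`. By the switch symmetry of the model the
contribution of every fragment not covering `j₀` cancels, so

    connectivity(j₀) = Σ_{f ∈ F^c(j₀)} [log P(f|Θ) − log P(f|Θ')],

zero for uncovered cuts. The vectorised implementation computes, per
fragment, within-fragment prefix sums of the per-site, per-haplotype log
factors; a twist between two consecutive spanned positions then swaps the
haplotype role of the suffix in O(1), and the drops are scattered onto
the cut range between the two positions with a difference array. A unit
test checks the result against the full likelihood difference at every
cut.

`MC(j₁, j₂) = min_{j₁<j≤j₂} connectivity(j)` is the block confidence
score. Block extraction works per connected component of the co-spanning
graph (components may be non-contiguous in coordinates; the boundary
between consecutive member sites is scored by the minimum connectivity
over the raw cuts between them): maximal runs whose boundaries all clear
the threshold become blocks, runs of one site are discarded, and phases
are the per-site argmax of the posterior mean with exact ties broken to
(0, 1). Inside a block every site pair has MC at or above the threshold;
raising the threshold can only remove predicted pairs. The default
reporting threshold is 6.0 nats; the `curve` command sweeps thresholds.

## Chimerity

Pooled long-fragment protocols occasionally merge read clusters from the
two homologous chromosomes into one fragment. Against known haplotypes,
fragment `f` is scored by the log-likelihood gain of breaking it in two:

    chimerity(f) = max_{j,h} [log P₀(f_≤j|h) + log P₀(f_>j|h̄)] − max_h log P₀(f|h),

with `P₀(f|h) = (1−α₀)^{n(f,h)} α₀^{|X(f)|−n(f,h)}`, `n(f,h)` the number
of sites matching haplotype `h`, and `α₀ = 0.028` an empirical per-allele
error rate. The split index excludes the last spanned site so both parts
are non-empty — allowing the empty suffix would pin every fragment at
chimerity 0 and void the statistic. A fragment consistent with a single
haplotype scores `log(α₀/(1−α₀)) ≈ −3.55` regardless of length; a perfect
half-and-half chimera scores `≈ +3.55` per site of its shorter half, so
the removal threshold 10 corresponds to a three-site minimum half.
Detection requires a truth phase (trio-phased haplotypes in practice; the
simulator's truth here) — no reference-free mode is provided, and `α₀` is
a supplied constant, not estimated.

## Accuracy measures

A site pair `(j, j')` inside a predicted block is *consistent* when the
predicted joint phase equals the true joint phase or its global switch.
Precision is `CP/(CP+IP)` over all within-block pairs; it degrades
gracefully: a switch error mid-block destroys many pairs, one at the edge
few, and two adjacent switch errors (a single flipped site) leave the
flanks mutually consistent — exactly the behaviours that make the plain
switch-error rate misleading, though that rate is also reported. The
prediction space is the set of pairs within connected components (size
≥ 2) of the co-spanning graph; recall is predicted pairs over total
pairs. The no-assembly baseline phases each co-spanned pair by strict
majority vote of the fragments spanning both sites (relative phase =
allele equality); tied votes predict nothing, since a coin flip would add
pairs without information.

## Simulator

`simulate_dataset` draws `M` truth phases uniformly, replicates each
haplotype `c` times, cuts every copy into consecutive pieces with lengths
uniform on `[l₁, l₂]`, and flips each emitted allele independently with
probability `e`. Defaults `M = 1000, c = 5, l₁ = 3, l₂ = 7, e = 0.1`
emulate pooled-sequencing SNP fragments at site coverage `2c = 10`. Exact
division is impossible in general, so the final remainder of a copy may be
shorter than `l₁`; remainders of ≥ 2 sites are kept (preserving uniform
coverage), shorter ones dropped. `inject_chimeras` replaces a
Bernoulli-rate subset of fragments by resampling the suffix after a
uniformly chosen interior spanned site from the opposite haplotype (then
re-applying flips), returning ground-truth labels. Everything is
deterministic given the seed.

What the simulator does **not** emulate: realistic heterozygous-site
spacing and coverage heterogeneity, correlated (mapping-induced) errors,
per-base quality variation, pool barcoding, or multi-allelic/indel sites.
Passing tests on these data show the inference and scoring machinery is
correct under the model's own assumptions, not that real fosmid-pool data
meet those assumptions.

## Study protocols and problem sizes

The reproduction scripts use the protocol sizes of the original
experiments: the pairwise-accuracy study runs ten seeded repeats at
`M = 2000` (≈ 4000 fragments each); the condition grid runs
`c ∈ {3,5,10} × e ∈ {0.05,0.1,0.15,0.2} × [l₁,l₂] ∈ {[3,7],[5,10],[8,15]}`
at `M = 1000` with ten repeats per cell, and reports per cell the lowest
MC threshold whose ten-repeat average precision reaches 0.95 (threshold
grid 0–16 in 0.5-nat steps; a cell that never reaches 0.95 is reported
just beyond the top of the searched range). The test suite runs the same
grid with three repeats per cell.

## Known limitations

* Grid cells combining high error (`e ≥ 0.15`), low coverage and long
  fragments are hard for the *model*, not just the optimiser: with `α`
  held at 0.1 while the true flip rate is 0.2, long fragments make wrong
  phase configurations confidently likely, and even truth-seeded fits
  leave high-connectivity switch errors. In such regimes the minimal MC
  threshold for 0.95 precision can substantially exceed the default 6.0,
  and matching `α` to the true error rate only partly closes the gap.
* The twist budget (100 re-runs) can bind on large, noisy instances;
  precision at full recall then varies between ~0.5 (a residual
  mid-component switch error) and ~1 across seeds.
* Connectivity is evaluated at the posterior-mean `θ`, whose confidence
  ceiling under the uniform prior lowers connectivities slightly relative
  to a sharper point estimate; MC thresholds are calibrated to this
  choice.
* Chimerity requires externally supplied truth and binary biallelic
  sites; block coordinates are site indices, not genome coordinates.
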