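# Methods

## Setting and notation

A two-way admixed population (population A with genome-wide proportion λ,
population B with 1−λ; τ generations since admixture). For a pedigree of
n individuals typed at L ordered markers with genetic positions in cM,
X_{i,t} ∈ {0,1,2} is individual i's true diploid ancestry dosage at locus
t (the number of A alleles, A^{[1]}_{i,t} + A^{[2]}_{i,t}) and Y_{i,t}
the dosage called by upstream local-ancestry software run under an
unrelatedness assumption. Accuracy is measured by the dosage error rate
err = Σ_{i,t} |Y_{i,t} − X_{i,t}| / (nL).

## Observation model

Each called allele independently differs from the truth with probability
ε ("allelic error rate"), giving the 3×3 inference matrix

    P(Y|X=0) = ((1−ε)², 2ε(1−ε), ε²)
    P(Y|X=1) = (ε(1−ε), (1−ε)²+ε², ε(1−ε))
    P(Y|X=2) = mirror of X=0.

Under the Binomial(2, λ) marginal of X this implies
err = 2ε(1−ε) + 2ε²[λ²+(1−λ)²]. `expected_dosage_error` also exposes a
`"literal"` variant that carries the ε² term without the factor 2, as
the formula is often quoted; the two differ by at most ε² and the
flip-model form — verified against exact 9-cell enumeration and
error-injection Monte Carlo — is the package default.

## Transition model

Per haploid track, the ancestry state over a gap of d Morgans follows
P(l|k) = e^{−dτ}·1[l=k] + (1−e^{−dτ})·π_l with stationary weights
π = (1−λ, λ). (A common display of this kernel writes the diagonal and
off-diagonal entries both with λ and is then not row-stochastic for the
k=0 row; the conditional form used here restores normalization and is
standard in the ancestry-HMM literature.) The diploid dosage transition
is the projection of two independent haploid chains onto unordered allele
counts; it is row-stochastic and preserves the Binomial(2, λ) stationary
vector, both asserted to 1e−12 in the tests.

## Mendelian consistency

A configuration X_t is consistent when ordered allele pairs exist, one
per individual, such that each child's paternal allele lies in its
father's pair and its maternal allele in its mother's pair. For a trio
this yields the familiar 15-member feasible set.

Implementation note: when every dosage in a column is observed, each
parent's allele *multiset* is fixed by its dosage, so the per-(child,
parents) constraints share no latent variables; global consistency is
then exactly the conjunction of local 3-way table lookups, which makes
the locus scan vectorizable. Columns containing missing dosages fall back
to genotype elimination — constraint propagation over ordered-pair
bitmask sets with a backtracking search for residual ambiguity — with a
missing individual's alleles left unconstrained.

## Error detection

Three flag types, screened per chromosome:

1. **Mendelian**: the locus's configuration is inconsistent.
2. **Double crossover**: per individual, a maximal constant-dosage run
   bounded by two dosage changes whose flanking dosages are equal (a
   switch that reverts), with genetic span (first to last marker of the
   run) below the window (default 2 cM). At τ = 8 the probability of two
   or more genuine crossovers in 2 cM is 1 − e^{−x} − xe^{−x} at
   x = 0.16, ≈ 0.0115, so such runs are overwhelmingly call errors. The
   run must additionally span no more than either flanking run — i.e. be
   the *deviating* segment. Without this qualifier the long
   majority-state stretch between two isolated single-marker errors is
   itself a "return run" with equal flanks and would be flagged; at
   ε = 0.01 that flagged the bulk of a chromosome and made correction
   counterproductive.
3. **Low quality**: any call with upstream posterior confidence below the
   threshold (default 0.90) flags its locus.

## MAP correction

For a flagged locus t with trusted flanking configurations X_left and
X_right at distances d_left, d_right (Morgans):

    X̂_t = argmax_{X ∈ Ped} Π_i P(Y_{i,t}|X_i) · Π_i P(X_{right,i}|X_i) · Π_i P(X_i|X_{left,i})

computed in log space with probabilities floored at 1e−300 so that
inadmissible transitions remain comparable. At a chromosome boundary the
absent flank's factor is dropped. Candidates are the consistent
configurations within Hamming distance `max_diff` (default 2) of Y_t; if
none exist the radius is escalated once, after which the locus is left
unchanged and reported. Ties within 1e−12 resolve to the candidate
closest to Y_t, then lexicographically — deterministic output.

The sweep runs left to right; corrected loci are trusted as left-flank
context (consistent with the model's assumption that neighbours are
error-free), while the right flank is the nearest locus carrying no flag
— necessary when flagged loci are consecutive. A `block` mode treats
maximal runs of identical configurations as single loci with the
flanking blocks as neighbours, trading resolution for speed on long
ancestry blocks; `marker` mode is the default. One sweep is performed by
default (`sweeps` option available); ε is not re-estimated after
correction.

Restricting to Hamming distance 2 is justified by the binomial bound on
the number of members erring at one locus: at err ≈ 0.02 and n = 20 the
probability of three or more simultaneous errors is ≈ 1e−3 per locus,
and the brute-force equivalence test confirms the restricted argmax
matches the full-set argmax whenever the optimum is within radius 2.

## Estimating ε from Mendelian errors

The pedigree is divided greedily into non-overlapping nuclear families
(largest sibship first, then earliest generation; a parent consumed by an
earlier family leaves a one-parent family behind). For each family the
number of Mendelian-inconsistent family-loci is counted — a 0/1
indicator per locus, with loci missing any member call excluded — and
equated to its expectation under the assumption that at most one member
errs per locus: a member carries a single-allele error with weight
2ε(1−ε) and a double-allele error with weight ε². This yields a quadratic
in ε per family type:

* **Two parents, m children** — the implemented polynomial is *exact*
  for this mechanism (verified against full enumeration to 1e−12 across
  λ ∈ {0.5, 0.8}, ε ∈ {0.01, 0.05}, m ∈ {1, 2, 3}).
* **One parent, m children** — the implemented polynomial deviates from
  the exact mechanism by up to ≈ 5% relative at ε = 0.05 (≈ 1% at
  ε = 0.01); the package exposes `exact_mendelian_rate` (full
  enumeration) and `mendelian_rate_mc` (vectorized Monte Carlo) as
  independent oracles, and the acceptance checks report the deviation
  magnitudes rather than absorbing them.

Aggregating Σ_f L_f · rate_f(ε) = Σ_f observed_f gives a single quadratic
solved in closed form (with a bracketing fallback); the root in [0, 0.5)
is returned, the smaller when two qualify. λ defaults to the sample mean
dosage / 2. Because real data violate the one-error-per-locus assumption
with probability O(ε²), the estimator runs slightly low at larger ε —
recovery experiments at 50 two-parent families, L = 2000, λ = 0.8 stay
within −12%/+4% of injected ε ∈ {0.01, 0.02, 0.03}.

## Simulator

`simulate` generates data at the level the method consumes — ancestry
tracks, not genotypes (reference-haplotype genotype emission would add no
testable surface for this pipeline):

* **Founders**: first locus Bernoulli(λ); over each gap a recombination
  occurs with probability 1 − e^{−dτ} (τ = 8 by default), upon which the
  state is resampled Bernoulli(λ). This resample-on-recombination scheme
  allows invisible self-switches but has exactly the conditional-
  transition marginal law; the visible-switch-rate test pins this down.
* **Meioses**: each transmitted haplotype starts from a uniformly chosen
  parental haplotype and switches source with probability 1 − e^{−d}
  per gap (single-generation rate, τ = 1). A child with only one
  recorded parent draws its other haplotype from the population chain.
* **Errors**: every allele flips independently with probability ε; the
  observed matrix carries a constant 0.99 quality layer.

Default map: L markers uniformly spaced 0.03 cM apart, so L = 2000 spans
60 cM — a chromosome-22-like scale. Default conditions λ = 0.8, τ = 8,
ε = 0.01 reflect African-American admixture and the accuracy of good
upstream callers. One seeded numpy Generator is threaded through all
sampling in deterministic topological order.

The three representative pedigrees (n = 20, 10, 4; `demo_pedigree`) are
synthetic three-/two-generation structures of the kind found in
family-based admixture studies, constructed for this package.

### What the simulator does not emulate

Real upstream callers make *segmental* errors — whole intervals assigned
to the wrong ancestry, shifted switch points, errors correlated along
the chromosome and between the two haplotypes — whereas the injector
flips alleles independently per site. Passing tests therefore demonstrate
the machinery (detection, estimation, MAP selection) under the package's
own error model, not performance against any particular caller; in
particular the near-total error removal seen on simulated data
overstates what correlated real-world errors allow. Shifted switch
points are explicitly out of scope: a locus-by-locus corrector anchored
on neighbouring loci cannot repair an error that spans its anchors.

## Numerical and degenerate-input choices

* Distances are converted once to Morgans; co-located markers (d = 0)
  are legal and give identity transitions.
* Probability floors (1e−300) rather than −inf keep argmax total.
* ε = 0 is legal throughout (identity inference matrix); λ is clamped to
  (0, 1) when estimated from degenerate all-0/all-2 samples.
* Childless pedigrees yield no nuclear families and no estimate;
  all-zero Mendelian counts return ε̂ = 0 exactly.
* An observed Mendelian-error rate exceeding the model maximum on
  [0, 0.5) raises with both numbers in the message.

## Known limitations

* Single-locus correction conditioned on two flanking loci; no joint
  HMM/Viterbi pass over the chromosome, no phasing, no haplotype-level
  output.
* The one-parent Mendelian-rate polynomial's small systematic deviation
  (above) propagates into ε̂ when one-parent families dominate.
* Boundary loci are corrected from one flank only and fare worse; an
  error at the outermost marker of a chromosome that triggers no
  Mendelian flag is invisible.
* X chromosome, inbreeding loops and three-way admixture are out of
  scope.
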