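# Methods

## Model

The sample is modelled as a mixture of catalogued haplotypes with
latent fractions ψ on the simplex, each haplotype represented by its
binary variant fingerprint against a common reference. The central
assumption is that the catalogue captures **all** variation at the
locus: every fragment comes from one of the catalogued haplotypes (up
to mis-mapping). Under that assumption the allele frequency of variant
*j* is fully determined by ψ,

θ_j = Σ_i V[i,j] ψ_i / Σ_i Cov[i,j] ψ_i,

where V marks carriers and Cov marks haplotypes whose alignment spans
the variant locus. Cov is stored *inclusively* (a carrier always
counts as spanning); this is what keeps θ_j inside [0, 1] for every ψ —
with an exclusive coverage matrix the ratio could exceed 1 (two
spanning haplotypes, one carrier, ψ = (½, ½) must give θ = ½, which
requires the carrier in the denominator).

Fragment evidence enters exclusively through per-variant likelihood
curves θ ↦ log Pr(Z_vj | θ). Each fragment contributes a two-level
mixture marginalising two Bernoulli latent variables: correctly mapped
(probability π, the complement of the Phred-decoded MAPQ) and sampled
from the variant allele (probability θτ, with τ the probability that a
fragment from the variant copy covers the variant at all). A
mis-mapped fragment contributes the uninformative equal mixture
½(Pr(Z|alt) + Pr(Z|ref)), so it pulls toward no particular θ; this is a
deliberate simplification of full locus-swap modelling, which is out of
scope. Allele likelihoods per base are 1 − ε for a match and ε/3 for a
mismatch with ε = 10^(−Q/10), multiplied across MNV positions; indel
evidence uses CIGAR concordance at the locus (gap present vs absent,
error rate 0.01) with no realignment.

The posterior over an enumerated fraction universe is exact: log prior
plus joint log-likelihood per candidate, normalised by log-sum-exp.
The diploid universe enumerates all n(n+1)/2 unordered pairs
(fractions in {0, ½, 1}); the continuous universe is approximated by a
regular simplex grid with q points per axis, interpreted as a
rectangle-rule quadrature whose uniform cell volumes cancel in the
normalisation, so the reported values are normalised probabilities
(labelled densities for grids). Markov-chain approximations are
deliberately not used — for pruned catalogues the exact enumeration is
cheap and has no convergence questions.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| likelihood grid | 101 points (step 0.01) | support of the per-variant curve; matches the finest fraction universe used downstream; linear interpolation between points |
| π for MAPQ 255 | 0.99 | mapping probability when the aligner reports "unavailable" |
| likelihood floor | log 1e-10 | per-fragment allele log-likelihoods are floored to avoid −∞ propagation |
| τ | 1.0 | per-variant override intended for indels; SNV/MNV observations demonstrably cover their site |
| indel ε | 0.01 | error rate of the CIGAR-concordance indel model |
| LP threshold t | 0.01 | minimum LP fraction to keep a haplotype |
| LP extension m | 0 | maximum variant-set symmetric difference to re-admit a haplotype |
| call filter | ≤ 5 solutions, mass > 0.7 | maximum size and minimum cumulative mass of the rank-1 equal-probability group |
| tie tolerance | relative 1e-9 on log posteriors | "equal probability" for ranking and the call filter; exact float equality would be meaningless |
| grid budget | 2·10⁶ candidates | refuse continuous enumerations larger than this and advise stronger pruning |

## LP preselection

Exact enumeration over the full catalogue is infeasible (O(q^n)), so a
linear program discards haplotypes that cannot contribute: minimise
Σ_{j∈W} |Σ_i ψ_i V[i,j] − θ̂_j| subject to ψ on the simplex, where θ̂
are the grid-argmax (flat-prior MAP) frequency estimates and W is the
set of variants covered by *all* haplotypes — the restriction that
keeps the induced frequency linear in ψ (denominator 1). The
linearised program (one deviation variable per variant) is solved with
the HiGHS simplex method, which is deterministic; any optimal vertex is
accepted since retention uses a threshold, not a ranking. When W is
empty, pruning is skipped with a warning and the whole catalogue passes
through. The base set {ψ*_i ≥ t} is extended by haplotypes whose
fingerprint differs from a kept one by at most m variants (symmetric
difference over all columns), which at m = 0 re-admits exactly the
haplotypes with identical fingerprints; the extension is computed
relative to the thresholded base set. If no fraction reaches t, the
single largest-fraction haplotype is kept so the retained set is never
empty.

## Synthetic data and what passing tests show

The simulator generates the model's own generative story: a random
reference; variant sites ≥ 10 bp apart (SNVs by default, optional MNV
and indel quotas, indels stored left-aligned); distinct binary carrier
fingerprints per haplotype with every variant carried at least once;
and per-variant fragment counts Poisson around the target depth, each
fragment drawn from a spanning haplotype proportionally to ψ, its
allele call flipped with probability 10^(−Q/10) and mis-mapped (MAPQ 0,
uniform allele) with a configurable rate. Default study conditions for
the recovery experiments: 10 haplotypes, 6 variants, depth 30, Q30,
MAPQ 60, mis-mapping 0.01.

Recovery experiments draw the true diploid genotype among the
*identifiable* ones — pairs whose induced frequency signature is unique
in the catalogue. Two pairs whose fingerprint sums coincide induce
identical allele frequencies at every variant and generate identically
distributed fragments, so no method operating on the data can separate
them; with only 6 variants such collisions affect several percent of
uniform draws, and including them would measure the combinatorics of
random binary matrices rather than the method. The analogous condition
guards the LP retention experiment: a true haplotype is only required
to be retained when every zero-deviation mixture keeps mass ≥ t on it
(checked with an independent LP), because with more haplotypes than
variants the exact-fit polytope is generically non-trivial and some
valid optimal vertices exclude the truth.

What the simulator does *not* emulate — and passing tests therefore do
not establish: read-level sequences and alignment artefacts, reference
bias, indel realignment ambiguity, non-uniform error profiles,
coverage variation beyond Poisson, and catalogue incompleteness (a
sample haplotype missing from the catalogue violates the model's core
assumption and will be "explained" by the nearest catalogued
fingerprints).

## Numerical choices

- All probability arithmetic is in natural-log space; normalisation by
  `scipy.special.logsumexp`. Discrete posteriors sum to 1 within 1e-9.
- Likelihood curves are exact at grid points (vectorised log-add-exp
  over fragments); between points linear interpolation is used. For
  diploid universes with inclusive coverage every induced frequency is
  a multiple of ½, so posterior evaluation never interpolates.
- MAP frequency ties break toward the smaller θ (first grid argmax).
- Ranking ties (within relative 1e-9 on the log posterior) order
  lexicographically by haplotype name.
- Alignment scoring: match +1, mismatch −4, gap open −6, gap extend −1
  (a length-L gap scores −6 − (L−1)); N is treated as a mismatch
  against everything, and variants containing N are dropped with a
  warning. Terminal gap operations are trimmed — they reflect length
  differences between haplotype and reference window, not variants —
  and the aligned reference span defines Cov. Indels are left-anchored
  and left-aligned through repeats before the variant union is formed.
- Degenerate inputs: an empty observation set yields the constant-zero
  curve (posterior = prior); variants uncovered under a candidate
  (zero denominator) are skipped per candidate and counted; a
  single-haplotype catalogue always posts probability 1 on ψ = (1).

## Known limitations

- The mis-mapped background term is an equal allele mixture, not a
  model of where the fragment actually came from.
- The LP uses only variants covered by all haplotypes; catalogues with
  very heterogeneous coverage can leave W empty, in which case no
  pruning happens and large catalogues may be slow.
- Fragment extraction from BAM merges mates by query name and takes
  the less confident mate's mapping probability; chimeric pairs are
  not modelled.
- The continuous universe is a fixed regular grid; posterior mass
  between grid points is attributed to the nearest cells and very
  peaked posteriors need a fine q to be resolved.
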