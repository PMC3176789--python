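# Methods

## Biophysical site model and the synthetic generator

Binding specificity is modelled as an additive energy matrix: position j
of an L-long site contributes `epsilon(b, j) >= 0` kT for base b, with the
preferred base at exactly 0, so the consensus sequence has energy 0. The
probability that the factor occupies a site of energy E is the standard
two-state (Fermi–Dirac) expression `theta(E) = 1/(1 + exp(E - mu))`; at
the default chemical potential `mu = -0.5` the consensus is bound with
probability 0.38, low enough that relative occupancies are nearly
Boltzmann ratios. The generator enumerates the complete landscape of all
4^L sequences (4096 at L=6, 16 384 at L=7), converts energies to
occupancies, normalizes to a sampling distribution `pi`, and draws sites
i.i.d. with replacement from `pi` with a seeded `numpy` generator. Whether
to sample with or without replacement is a genuinely open choice; with
replacement is used because binding sites in a genome are not mutually
exclusive draws, and it keeps `pi` exactly the per-draw law.

Default study conditions: 500 sites per dataset, `mu = -0.5`, uniform
background. Every sample records its true energies, matrix, `mu` and seed,
and sample files regenerate byte-identically from the same configuration.

### The eight default true models

The shipped family mimics a dimeric repressor half-site. The 7-long
odd-symmetric models (`M7S-1/2`, consensus GTGGCAC; center position 4
unconstrained by the symmetry, preferring G narrowly over C, i.e. GTGSCAC
counting both strands) are constructed from three left-half columns plus a
center column, with the right half the complement-mirror of the left.
Swapping positions 5 and 6 produces the asymmetric twins (`M7A-1/2`,
consensus GTGGACC) with exactly the same parameter set; deleting the
center yields the 6-long even-symmetric (`M6S-1/2`, GTGCAC) and asymmetric
(`M6A-1/2`, GTGACC) models. The `-1`/`-2` variants permute the position-2
energies (affinity ranks T,G > C,A versus T,A > C,G) and use a less
discriminating center column in `-2`.

The numeric energies are the package's own calibration (0.04–3.3 kT).
They were chosen once so that the simulated study sits in a realistic and
interesting regime: true motif information ~2.9 bits; a control fit from
500 sites reaches landscape R² ≈ 0.94–0.99; a symmetric fit forced onto
asymmetric data collapses to R² ≈ 0.2–0.4; and the symmetric-vs-asymmetric
E-value race on symmetric data is close (tens of nats out of ~1000). Two
structural choices produce the collapse: the motif's specificity is
concentrated in the swapped column pair (positions 2 and 3), and those two
columns prefer conflicting bases, so complement-averaging them — which is
what the symmetry assumption does to an asymmetric motif — destroys most
of the discriminating signal. Weak flanking and center columns keep the
correctly-shared positions from propping up the wrong model's R².

## Motif estimation

With every input sequence being exactly one site, estimation reduces to
orientation assignment plus counting. `fixed` mode counts sites as given;
it is the control whose only error is finite-sample noise. `symmetric`
mode counts each site in both orientations: the count matrix equals its
own reverse complement exactly and the effective sample doubles to 2N.
`asymmetric` mode maximizes the information content
`I = sum_j sum_b f(b,j) log2(f(b,j)/p_b)` over the 2^N orientation
assignments: exhaustively for N ≤ 12, otherwise by coordinate ascent
(sweep sites in order, flip an orientation only if I strictly increases by
more than 1e-9; ties never flip) from 20 seeded restarts (first restart
all-forward, the rest random). The returned model is canonicalized to a
forward-orientation majority, breaking exact ties toward the
lexicographically smaller consensus, so results are platform-stable.
Restart count and iteration cap are configurable; non-convergence is
recorded in the model's provenance and has not been observed at the
default settings.

Information content uses base-2 logarithms, zero pseudocount and no
small-sample correction — at N = 500 the correction (~3L/2N ln 2 ≈ 0.03
bits) is negligible against sampling scatter (SD ≈ 0.14 bits).

## Significance and model selection

The null distribution of a single column's information for n background
letters is computed exactly (up to score binning) by dynamic programming
over the four bases with states (letters placed, score bin), entirely in
natural-log space; probabilities as small as e^-2000 are routine. Each
base's score contribution is rounded to the nearest bin (default width
0.005 bits) before accumulation; mass conservation is checked to 1e-9 and
halving the bin width moves a far-tail log p-value at n = 500, L = 7 by
~0.14%. The L-column p-value `ln P(I_total >= I_obs)` is the L-fold
log-space convolution of the column distribution.

E-values multiply the p-value by the number of candidate alignments the
search considered: 2^N for orientation-free discovery (each of N sites in
either orientation), 1 for the fixed and symmetric modes. Reports carry
`-ln(E-value)`, larger meaning more significant, and `select_model` keeps
the mode with the larger value.

The symmetric mode's null is *not* L independent columns. Symmetrizing
ties column j to column L+1-j: the statistic is
`2 * sum of floor(L/2) free-column informations` (each free column is the
sum of two independent N-letter draws, i.e. Multinomial(2N)), plus, for
odd L, a self-symmetrized center column whose information is
`1 - H2(W/N)` bits with `W = #A + #T ~ Binomial(N, p_A + p_T)`. Treating
the symmetric matrix as L independent columns of 2N letters roughly
doubles the apparent significance and would select "symmetric" for every
dataset, including strongly asymmetric ones; with the constrained null the
E-value ranking recovers the generating symmetry class in 40/40 validation
replicates while raw information content is wrong on every symmetric one.
The constrained null requires a complement-symmetric background
(p_A = p_T, p_C = p_G), which the uniform default satisfies. As a simpler
advisory output, `select_model` also reports each mode's free-parameter
count (3L versus 3·ceil(L/2)).

## Landscape evaluation

A discovered motif is converted to energies by inverting the low-occupancy
sampling relationship: `epsilon_hat(b,j) = ln(f_max(j) / f(b,j))` with a
0.5 pseudocount (so unseen bases get a large finite penalty), placing the
preferred base of each column at 0 — the same gauge as the true matrices.
For every one of the 4^L sequences the log total binding probability
`ln(theta(E_fwd) + theta(E_rev))` is computed under both the true and the
fitted matrix at the sampling `mu`, and accuracy is R², the squared
Pearson correlation of the two vectors. Summing the two strand occupancies
is the default; a `max` combine rule is available and typically lowers R²
by up to ~0.1. R² is invariant to affine transformations of either vector,
so residual gauge constants cancel.

## Numerical choices and degenerate inputs

- All probability arithmetic in the significance module is log-space
  (log-sum-exp); occupancies use `scipy.special.expit`, saturating cleanly
  to 0/1 at infinite energies.
- Landscape enumeration refuses widths above 12 (4^12 ≈ 1.7e7 records).
- The DP lattice is guarded at ~8e7 states; exceeding it raises with the
  advice to enlarge the bin width.
- `fit_energy_matrix` reconstructs a matrix from (site, energy) records by
  least squares; the additive model is identifiable only up to per-column
  constants, fixed by shifting every column's minimum to 0. Residuals
  beyond 1e-6 raise (non-additive input); base/position combinations never
  observed are returned as NaN and flagged, rather than guessed.
- A single site is a valid sample: discovery returns it forward with
  information 2L bits.
- Ties in the orientation search never flip; ties in consensus strings
  break toward A < C < G < T.

## What the simulations do and do not show

The generator draws fixed-length, perfectly aligned, independent sites
from the exact model family the estimators assume (additive energies,
independent positions). Real data adds alignment uncertainty, flanking
sequence, position interactions, chemical-potential mismatch and
measurement noise, none of which is modelled here. Passing results
therefore demonstrate the *logic* of symmetry-aware model selection — that
information content alone overfits orientation freedom and that the
alignment-count-corrected E-value compensates — not the field performance
of any particular motif finder. Exact published table values from the
study this package emulates depend on unpublished energy parameters; the
package reproduces the regime and every qualitative ranking, not those
numbers, and `scripts/acceptance.py` recomputes all reported quantities
from scratch at run time.

## Problem sizes

Default runs use 500 sites per dataset, landscapes of at most 16 384
sequences, and null distributions at n = 500 and n = 1000 letters (cached
per process); the full eight-model study completes in seconds and the
40-replicate validation in well under a minute on one CPU.
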