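# Methods

## Setting and model

A family of peptide-recognition domains (PRDs — PDZ, SH3, kinase and
similar modules) is given as a multiple sequence alignment `A` with `n`
rows and `m` columns, together with one aligned position weight matrix
(PWM) per domain: `W_ik(y)` is the probability of residue `y` at peptide
position `k` of domain `i`'s binding profile, with `w` positions shared by
all profiles. The premise is evolutionary covariation across the binding
interface: if a domain residue helps determine specificity, a change at
that alignment site tends to be accompanied by a compensating change in
the preferred peptide residue, so the alignment column and the PWM
position covary across the family.

With normalized per-sequence weights `a_i` the three relevant
distributions are

    p_j(x)     = sum_i a_i [A_ij = x]
    p_k(y)     = sum_i a_i W_ik(y)
    p_jk(x, y) = sum_i a_i [A_ij = x] W_ik(y)

Entropies use `H(p) = -sum p log_b p` with `0 log 0 = 0`. The default log
base is 20 so that a residue distribution's entropy lies in [0, 1]; the
base is configurable, and the package's regression tests pin the toy
worked example in base 2. Mutual information is
`MI(j,k) = H(A_j) + H(W_k) - H(A_j, W_k)`.

Raw MI is inflated at individually diverse sites (the toy example in the
test-suite makes this concrete: a perfectly covarying pair of two-state
sites has MI 1 bit while two unrelated four-residue sites reach 1.5 bits).
The ranking score is therefore the uncertainty coefficient. The symmetric
form `UC = 2 MI / (H(A_j) + H(W_k))` is the default; the asymmetric
variants `MI/H(A_j)` and `MI/H(W_k)` are selectable. UC is defined as 0
when its denominator vanishes, and is invariant under change of log base.

## Sequence weighting

Public domain families over-represent well-studied clades. Weights enter
every distribution above, so redundancy is corrected once, at the input:
the unit weight at the root of a guide tree is pushed down recursively,
each node splitting its share among child subtrees in proportion to the
subtree's total branch length (own edge plus descendants); when all child
lengths are zero the split falls back to leaf counts. Sequences inside
crowded shallow clades therefore share one allocation. When no tree is
supplied, a deterministic UPGMA guide tree is built from
`1 - fractional identity` distances (gaps count as mismatches, ids fed in
lexicographic order so ties are reproducible). The contract is
qualitative — crowded clades are down-weighted, a star tree with equal
branches reproduces uniform weights — and no numeric agreement with any
particular published weighting scheme is claimed. Duplicating a sequence
and its PWM while halving its weight leaves every score unchanged; this
invariance is tested.

## Site filtering

Only alignment sites that are gap-free and whose most frequent residue
holds at most half of the total sequence weight are scored. The boundary
is inclusive: a two-state site split exactly 50/50 is kept. Gapped or
conserved sites are reported with reasons rather than silently dropped.
The gap rule exists because the joint distribution above has no defined
gap category; the conservation rule removes sites that carry almost no
covariation information and would otherwise contribute noise.

## Significance

Two optional per-pair tests:

* **Chi-square approximation.** For base-2 MI, `2 n ln(2) MI` is
  asymptotically chi-square with `(|R_j|-1)(|R_k|-1)` degrees of freedom
  under independence, where the cardinalities count residues with nonzero
  marginal probability at each site (the effective contingency-table
  dimension). Pairs with a single-residue side are reported as NaN.
* **Permutation test.** The alignment column is shuffled across rows
  (weights stay attached to rows, profiles untouched), which breaks the
  pairing while preserving both marginal compositions;
  `p = (1 + #{MI* >= MI_obs}) / (1 + n_perm)`. Per-pair generator streams
  are derived from the top-level seed, so maps are reproducible and
  independent of evaluation order. At small `n` the weighted-MI null is
  discrete and the test is conservative (empirically ~0 rejections at
  nominal 0.05 under a true null with n = 30), which is acceptable for its
  screening role.

## Profile prediction

Given a query domain aligned to the training MSA, the baseline predictor
averages training PWMs weighted by whole-sequence identity (matches over
full alignment length `m`; gapped columns never match). The
covariation-weighted predictor replaces the global similarity with a
per-target-site similarity: for peptide position `k`, alignment columns
are weighted by `UC(A_j, W_k)` (0 at filtered sites, renormalized over
columns), so training domains that agree with the query at the columns
that covary with `k` dominate the average there. If all UC weights vanish
for some `k` the site falls back to the baseline predictor (logged).
Prediction error between two profiles is the root-mean-square difference
over all `w × 20` entries; its maximum, attained by disjoint delta
profiles, is `sqrt(2/20) ≈ 0.3162`.

Validation repeatedly holds out a random fraction of domains (at least
one; at least two must remain for training), recomputes the covariation
map from training rows only, predicts every held-out profile, and reports
the mean and standard deviation over per-repeat mean errors. Splits use
per-repeat child seeds of one top-level seed. Near-duplicate rows
(identity ≥ 0.9 by default, greedy scan in input order) should be
collapsed first so the same domain cannot appear on both sides of a
split. A regression-tree predictor is exposed as a named,
deliberately-unimplemented hook; weighted averaging outperformed such
models on this task and the hook only documents the interface.

## Structure-based evaluation

Covarying pairs are expected to be physically close in a co-crystal
structure of the bound complex. Three residue-pair metrics are computed
from heavy atoms only (crystal structures at typical resolution lack
hydrogens): Euclidean distance between heavy-atom centroids
("residue_center" — the pinned reading of a residue's center), CA–CA
distance (pairs missing a CA are marked missing, not fatal), and the
minimum interatomic distance minus both Bondi van der Waals radii (may be
negative; unknown elements fall back to 1.70 Å; the table is embedded and
dumpable via `sdrcov structeval --dump-radii`). Disordered atoms use the
highest-occupancy conformer, ties favouring altloc A. The Pearson
correlation between covariation score and distance is computed either
over all mapped pairs or after reducing to each domain site's top-scoring
peptide position (ties to the smaller position index); missing distances
are dropped and counted. Two-sided p-values use the Fisher transformation
`z = atanh(r)` with standard error `1/sqrt(n-3)`, requiring at least four
points.

## Synthetic data

The generator plants covarying pairs with controllable strength. For each
planted pair `(j, k)` every sequence receives a hidden state; states are
assigned in balanced shuffled blocks rather than i.i.d., so a two-state
site splits the family evenly — a clean clade split — and sits exactly on
the inclusive conservation boundary. (For odd `n` a two-state split is
necessarily uneven and the site can trip the filter; three-state pairs
are robust to this and to subsetting inside validation splits, and are
the recommended scheme for validation experiments.) The state fixes the
residue at MSA site `j`; the PWM column at `k` is
`coupling × keyed + (1 - coupling) × background`, where the keyed column
places `(sharpness + 1/20)/(sharpness + 1)` on a state-specific target
residue (delta at infinite sharpness, uniform at 0) and the background
column is shared across sequences.

Non-planted MSA columns draw i.i.d. from a small per-site repertoire —
default 4 residues, consensus probability 0.3 — because real alignment
columns tolerate a handful of residues; columns near-unique per sequence
would generate large finite-sample MI against any strongly varying PWM
column and are not representative. Non-planted PWM columns are Dirichlet
draws around a shared background, independent of the sequences, so they
carry no covariation signal. Optional duplication counts append exact
copies of chosen rows to emulate crowded clades. Everything is
deterministic given the spec and seed.

The toy structure places single-CA domain residues on a ring and
non-planted peptide residues on the ring's axis, so all non-planted
mapped pairs sit at essentially one "far" distance (at least the `far`
parameter; the radius is grown until this holds) while each planted
peptide residue sits `near` Å radially inside its partner. This keeps the
near/far contrast sharp instead of spreading background distances.

What the generator does *not* emulate: phylogenetic correlation along a
tree, indels (output is gap-free), realistic residue composition,
binding-energy physics, or indirect covariation through intermediate
sites. Passing tests therefore demonstrate correctness and power of the
machinery under idealized two-block covariation, not performance on real
domain families.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| log base | 20 | entropy in [0,1] for residue distributions |
| UC variant | symmetric | `2MI/(H_msa+H_pwm)` |
| conservation cutoff | 0.5, inclusive | max weighted residue share of a kept site |
| identity threshold | 0.9 | greedy near-duplicate removal |
| permutation count | 999 | per-pair permutation test |
| generator | n=30, m=10, w=5, coupling 0.9, sharpness 8, conservation 0.3, support 4 | modest domain family with one planted pair |
| toy structure | near 4 Å, far 15 Å | contact-like vs non-contact distances |

Problem sizes in the test suite (100–200 seeds/repeats, n = 24–30
sequences) were chosen as the smallest sets at which the stochastic
properties under test are stable.

## Numerical choices

MI values in `(-1e-9, 0)` from floating-point cancellation are clamped to
0; anything more negative raises an internal-consistency error. PWM input
columns whose sums deviate from 1 by at most 1e-3 are renormalized,
larger deviations rejected. Ranking ties break by ascending (site,
position). All site indices are 1-based at every interface.

## Known limitations

* Highly conserved specificity determinants are invisible by
  construction: a site filtered for conservation can never rank.
* Indirect covariation through intermediate residues is not corrected
  (no average-product correction or residue-group analysis).
* Tree weights follow the recursive-apportioning contract qualitatively;
  different reasonable weighting schemes will shift scores slightly.
* Results inherit alignment quality; gapped columns are excluded rather
  than modeled.
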