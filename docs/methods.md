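# Methods

## Model

The package estimates the stability change of a point mutation from the
sequence statistics of close backbone matches to the tertiary structural
motif (TERM) around the mutated site. The central assumption is that the
amino acids observed at the seed position of matching substructures,
drawn from unrelated proteins, are Boltzmann-like samples shaped by the
same energetics that govern the query site. Matches are modelled with a
softmax over the 20 amino acids: P_m(x) ∝ exp(−E_m(x))·P0(x), where
E_m(x) is a self energy parameter (sEP) plus one pair energy parameter
(pEP) per contacting position covered by the match, keyed by the amino
acid the match carries there, and P0 is the database-wide background
amino-acid distribution (+1 pseudocount per amino acid). ΔΔG(u→v) is the
energy difference of the two end states in the native sequence context;
positive values are destabilizing. The energy scale is statistical
(dimensionless); comparisons to experimental kcal/mol values go through
correlation and regression, not absolute units.

## Pipeline stages and defaults

- **Contact set.** Contact degree c(i, j) is the probability-weighted
  fraction of mutually accommodated rotamer pairs with heavy atoms
  within 3 Å, weights Pr(a)Pr(b)p(r_i)p(r_j); positions with
  c > 0.02 form the contact set C. Sequence neighbors (|i−j| < 2) are
  excluded: their side-chain proximity is dominated by covalent
  geometry. Both the numerator and denominator of the degree run over
  the clash-pruned rotamer sets. A provable short-circuit skips pairs
  whose CA–CA distance exceeds 2·(library reach) + 3 Å.
- **Rotamers.** A packaged idealized χ-rotamer library (χ1/χ2 over
  {−60°, 60°, 180°}, remaining torsions trans, uniform probabilities,
  1–9 rotamers per amino acid) built from internal coordinates in a
  canonical N–CA–C frame. This is a deliberate simplification of
  backbone-dependent statistical libraries: the occupancy metrics built
  on it need relative geometric accessibility, not rotamer
  thermodynamics. Any library in the same JSON schema can be swapped in.
  The backbone-clash cutoff is 2.5 Å (heavy atom), configurable. A side
  effect of the coarse library is that fully extended chains can show
  weak i±2 contacts that a finer library would suppress.
- **Freedom and the contact potential.** Freedom is the weighted
  fraction of all rotamers a position's backbone environment
  accommodates (1 = fully exposed). Database residues are binned into 70
  equal freedom bins to give propensities P(a|F) (+1 pseudocount;
  empty bins fall back to the background). Contacting pairs are split
  into five contact-degree bins ([0.02,0.05), [0.05,0.1), [0.1,0.2),
  [0.2,0.5), [0.5,1]) and the potential is Ĵ_ab = −ln(N_obs/N_exp) with
  +1 pseudocounts, where N_exp uses the freedom propensities of the two
  positions and halves same-amino-acid pairs so that the expectation
  summed over unordered pairs equals the contact count.
- **TERMs and search.** Flank ±2 residues per covered position
  (overlapping/adjacent intervals merge). Order-0 and order-1 sub-TERMs
  are always searched; an order-k sub-TERM requires all its order-(k−1)
  parents to exceed 100 raw matches. The search RMSD cutoff is
  base 0.5 Å + 0.3 Å per extra segment + 0.1·ln(n_residues) Å — a
  documented stand-in for an automatic complexity-dependent cutoff, all
  constants configurable. The search maps segments to contiguous,
  non-overlapping, order-free windows of one chain and prunes candidates
  with the lossless bound sqrt(Σ_k N_k r_k²/N) ≤ cutoff before the full
  Kabsch superposition; matches are capped at 20,000 after sorting by
  RMSD.
- **Filtering.** Homologs are removed by local-alignment identity
  (≥ 30% over ≥ 30 aligned residues, plus the query chain itself) — an
  alignment-identity stand-in for E-value-based homology detection that
  does not depend on database size or external binaries. Redundancy is
  removed by greedy centroid clustering of 31-residue seed-centered
  sequence windows at 40% ungapped identity, scanning in ascending-RMSD
  order so centroids are the best structural representatives (identity
  over the offsets both clipped windows share).
- **Fit.** Ensemble weight w_s = M_s/(M_s+1000). Regularization default
  λ = 1000 for the reference configuration; the standard model caps
  sub-TERM order at 2. Parameters start at their priors and are
  optimized by block-coordinate descent over 1+|C| groups (20 sEPs,
  then 400 pEPs per contact) using L-BFGS-B with analytic gradients
  within each group (the objective is smooth; a Nelder-Mead switch
  exists for cross-checking). Termination: objective improvement
  < 1e-5 between cycles, or all per-group parameter changes < 0.01 in
  l2 norm, or 100 cycles. The model is invariant to a constant shift of
  all sEPs; fitted sEPs are mean-centered purely to make reports
  deterministic.
- **Confidence.** Ubiquity ν is the larger, over the two end-state
  amino acids, of occurrence/20 for the sEP plus the mean pEP occurrence
  over contacts (pair term dropped when |C| = 0). It is monotone in
  occurrences; the package asserts the metric's computation and
  monotonicity, not any accuracy claim on real data.
- **Variants.** `conpot` pins all parameters at priors (no search);
  `noprior` zeroes the priors; `order0/1/2` cap the sub-TERM order;
  `full` removes the cap.

## Fitness-derived ΔΔG

Deep-mutational-scanning counts convert to fitness
W_i = (N_input/N_selected)·(N_wt,selected/N_wt,input) — implemented as
printed in the source derivation, with an `enrichment` switch for the
reciprocal convention since published transcriptions disagree; the two
orientations are reciprocal and neither is asserted as canonical. The
ΔΔG of mutation B against a marginally stable reference background A is
−ln[(W_B−W_AB)/W_AB] + ln[(1−W_A)/W_A], rejected when W_B ≤ W_AB, when
the double mutant's input count is below 90, or when W_B < 0.24 (checked
in that order); surviving per-reference estimates are averaged.

## Synthetic fixtures: what they emulate and what they do not

Fixture chains are ideal-geometry backbones (Engh/Huber-like bond
constants; helix (−60, −45), strand (−120, 120) with ~6° torsion noise)
with i.i.d. sequences; motif copies are planted by overwriting randomly
chosen windows with rigidly transformed, Gaussian-jittered copies of a
geometrically irregular template, and seed amino acids can be drawn from
a known Boltzmann model. This gives exact ground truth for search
(placement logs), for parameter recovery (generating energy parameters),
and for the fitness inversion (planted ΔΔG and filter violations). It
does **not** reproduce real-protein packing, loop geometry,
sequence-structure correlation outside the planted sites, database
redundancy structure, or evolutionary homology — so passing tests show
the machinery is correct and self-consistent, not that field accuracy on
experimental mutation sets is reproduced here (that requires curated
experimental structure and mutation databases outside this repository).

Study-condition scales used by the tests and the acceptance script,
chosen as the smallest sizes at which each property is
well-conditioned: search checks use 10–12 chains × 50 residues with 5–7
planted copies at 0.2–0.25 Å jitter; parameter recovery uses |C| = 2
with 500/2000/5000 matches per sub-TERM at λ = 1e-3; the end-to-end sign
test uses 40 planted copies with a −3 sEP preference and runs the
`noprior` model at λ = 1 — with tens (not thousands) of matches, λ must
be of the order of the expected occurrences for the data to speak, which
is the regularizer's intended semantics; the fitness inversion uses
depth 1e5–1e6 with W_B = 0.8 and W_A = 0.5.

## Numerical choices and edge cases

- Superposition is closed-form SVD (Kabsch) with the proper-rotation
  determinant correction; RMSD of degenerate (collinear) point sets is
  still defined by the formula.
- Ties: matches sort by (RMSD, source id, aligned positions); greedy
  outlier removal breaks ties by lowest index; altloc ties by letter
  order.
- Pseudocounts (+1) keep every propensity, potential cell, and
  background frequency finite.
- Empty ensembles fit to priors with a warning; a position with zero
  matches at every order falls back to the ConPot prediction with a
  flagged report.
- Residues missing any backbone atom are dropped at parse time (the
  search needs complete 4-atom windows).
- The Hill fit uses the reparameterized constrained form
  min(|a|,1)·x^|n|/(x^|n|+|K|^|n|), best of 100 seeded random restarts;
  exactly flat data short-circuits to a = y with a degenerate flag.
- Sign accuracy counts an exact zero as correct only against an exact
  zero (zeros are measure-zero on real data).

## Known limitations

- The rotamer library is backbone-independent and coarse; absolute
  contact-degree and freedom values differ from those computed with a
  statistical library, though their orderings are similar in the regimes
  the pipeline uses.
- The search assumes segments map to windows of a single chain;
  interface-spanning motifs are out of scope.
- The RMSD-cutoff formula's constants are stand-ins for an automatic
  complexity-based choice; they are exposed in configuration.
- The homology filter is identity-based, not statistical; an exclusion
  list can be supplied where a curated homology set exists.
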