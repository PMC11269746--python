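# Methods

This note documents the models, rules and numerical choices behind
`convloss`, and what the synthetic-data generators do and do not emulate.

## Mk model machinery (`convloss.mk`)

**Model.** A discrete character on a rooted tree with branch lengths in time
units evolves under a continuous-time Markov chain with rate matrix Q
(non-negative off-diagonals, zero row sums). For the binary gene
presence/absence case Q has two free parameters, the gain rate `q01` and
loss rate `q10`, and `P(t) = expm(Qt)` has the closed form
`P11(t) = pi1 + pi0·exp(−(q01+q10)t)` with `pi1 = q01/(q01+q10)`; the
k-state case uses `scipy.linalg.expm` per branch. The likelihood is
computed by Felsenstein pruning with per-node rescaling (log-scale
accumulator), vectorised across characters so a 128-tip × 1000-OG table is
one pass. Missing tip states enter as all-ones partial vectors; zero-length
branches are identity transitions; negative branch lengths are rejected.

**Root prior.** Stationary distribution of the rate model by default, with
`root_prior="flat"` or an explicit vector as alternatives. The stationary
choice matches the equilibrium treatment implicit in the Mk framework; both
options are exposed because neither is canonical.

**ML fitting.** Optimisation is on log-rates (box constraint rate ≥ 1e-10,
L-BFGS-B). Binary fits use two deterministic starts (unit rates and an
observed-frequency heuristic). Non-identifiable inputs (fewer than two
distinct observed states) sit on a likelihood ridge; the fitter returns the
canonical boundary MLE (unobserved transition at the floor) with
`identifiable=False` and a warning instead of letting the optimiser wander
the ridge. k-state fits free all k(k−1) off-diagonal rates and use
multi-start (uniform 1/k(k−1) — e.g. 1/42 for the 7-state repertoire model
— a turnover heuristic, and random starts) because these surfaces are
multimodal.

**MCMC.** Random-walk Metropolis on `(log q01, log q10)`, jointly proposed
with a normal step (sd 0.5), initialised at the ML estimate, with
independent exponential priors of mean 2× the ML estimate (floored at
1e-6). Defaults are 500 retained samples after a burn-in of 500 iterations
and thinning of 10. The kernel and priors are this package's documented
choice; calibration is demonstrated by recovery tests (posterior medians
within a factor of two of generating rates) rather than by matching any
specific external sampler. A chain that accepts nothing raises. The
`autocorrelation` diagnostic is the per-lag Pearson correlation of the
chain with its lagged copy (so an exactly alternating chain scores −1 at
lag 1).

**Reconstruction.** Joint reconstruction is dynamic programming over states
(max-product with back-pointers, log space); ties are broken toward the
lowest state index and flagged (detected at absolute log-probability
differences ≤ 1e-12). Marginal reconstruction is the standard up/down
message-passing pass; per-node posteriors are normalised and sum to 1
within 1e-9. Both are checked against exhaustive enumeration on small
trees in the test suite.

## Convergence analysis (`convloss.convergence`)

Scenario classification counts, per OG, the presence triplet at
(LCAfa, LCAa, LCAf) across replicates; the majority scenario's ties are
broken toward more presences (conservative against inferring loss) and
flagged. Loss-branch assignment admits only replicates whose node-state
sequence along a path has exactly one 1→0 transition and no 0→1; the
assigned branch is the plurality vote (ties toward the earlier branch,
flagged), with support = votes/qualifying replicates. OGs with no
qualifying replicate raise and are excluded downstream.

The loss-order similarity S counts unordered OG pairs whose rank signs
agree between lineages. Pairs tied on the same branch count as concordant
iff tied in both lineages (`ties="concordant"`, the default — treating
"same branch" as a genuine order statement); `ties="exclude"` drops pairs
tied in either lineage from the denominator. The permutation null shuffles
the OG → branch correspondence independently within each lineage,
preserving each lineage's multiset of branch labels and hence its tie
structure; p is the plain fraction of S′ ≥ S (can be 0) and an
add-one-smoothed value is also reported. Timing along a path is the 1-based
branch index, not cumulative branch length: branch indices are the natural
event-order scale when paths have different branch-length profiles.

**Identifiability of planted-order experiments.** Order recovery is only
well-posed when each lineage retains presence evidence *above* its loss
branch. If an OG is lost on the first branch of both paths (or with no
presence signal above the loss on either path), a single loss on the stem
explains the data at least as well, and reconstruction correctly prefers
it — the OG is then excluded by the single-loss rule rather than
mis-assigned. Recovery experiments therefore plant losses strictly below
the first branch of each path.

## Fragment rules (`convloss.adhe`)

The 800–1000 aa window for complete-gene candidates is inclusive on both
bounds; the >45% identity/coverage, >50% gap and >800 aa rules are strict,
mirroring wording that distinguishes ">" from ranges. The alignment center
of a row is the midpoint of its first and last non-gap columns (1-based,
halved and rounded down); the mean of all non-gap column indices is
available via `center_method="mean"`. Classification order: complete
(length and center window), then ALDH-only (center left of 400), then
ADH-only (center right of 900), else incomplete; it is total and
deterministic for every non-empty row. Coverage in hit records is target
coverage. The repertoire catalog is the fixed 7-state set
{none, 1_complete, 2_complete, 1_ALDH, 1_ADH, 1_incomplete,
complete_plus_ALDH}; combinations outside it map to "other" with a warning,
and explicit per-species overrides (e.g. tandem-fragment assembly artifacts
treated as one complete gene) are applied last. Outgroup-based paralog
exclusion reroots the gene tree on the outgroup leaf and keeps leaves under
the MRCA of the complete genes; since a leaf outgroup always separates
cleanly after rerooting, the detectable topology conflict is the outgroup
being listed among the complete genes.

## Substitution mapping (`convloss.substitutions`)

Ancestral amino acids use an equal-exchangeability (F81-style) model with
free stationary frequencies, `P_ij(t) = pi_j + exp(−mu t)(delta_ij − pi_j)`,
mu normalised so one unit of branch length is one expected substitution per
site; frequencies default to alignment counts with a pseudocount of 1.
Model selection is out of scope: the model is an explicit input and a
user-supplied rate matrix is accepted. Gaps are missing data, not a 21st
state. Residues are called where the posterior strictly exceeds 0.5 (at
most one residue can), else "uncertain"; branch-sites with an uncertain or
gapped endpoint emit no event and are tallied in diagnostics, never
imputed. One event per branch-site (presence/absence of change), not per
inferred multiple hit. A branch is a fragment branch iff all its descendant
tips are fragment tips — maximal monophyletic fragment clades including
their stem branches. Site enrichment = fragment events / total events,
reported for sites with ≥5 events; top-k ordering breaks ratio ties by
higher fragment count, then lower site index.

## Structure contacts (`convloss.contacts`)

"Within 5 Å" is inclusive (≤ 5.0); all atoms participate (hydrogens are
rarely present in crystal structures, so this matches an any-atom rule);
altloc policy keeps the first conformer (occupancy-max available); waters
are excluded by default. The toy-structure generator avoids the 5.0 Å
boundary by construction (planted contacts at 4.0 Å, everything else
beyond 6.0 Å).

## Statistics (`convloss.stats`)

Chi-square is the Pearson statistic without continuity correction
(correction available by flag); zero marginals are rejected. Mann–Whitney
uses exact enumeration for untied samples with n+m ≤ 12 and the
tie-corrected normal approximation otherwise; two-sided by default. The
phylogenetic ANOVA follows the simulation-null formulation: the observed
one-way ANOVA F is compared with F values from Brownian-motion simulations
on the tree with group labels fixed; the Brownian rate is estimated from
the data by independent contrasts (mean squared standardised contrast),
though F is scale-invariant so the p value does not depend on it. p is the
fraction of null F ≥ observed F; under a Brownian null the observed F is
exchangeable with the simulated ones, giving an exact type-I error of
(⌊α·n_sim⌋+1)/(n_sim+1) ≈ α (verified at 0.052 over 5000 replicates with
n_sim = 200).

## Synthetic data (`convloss.synthetic`)

What the generators emulate, and the defaults used in the verification
battery:

- **Trees.** `simulate_tree` grows a pure-birth (Yule) tree rescaled to
  depth 1.0 (ultrametric by construction, deterministically named).
  `simulate_two_clade_tree` builds the two-convergent-lineage geometry
  directly — a shared ancestor from which two chains of internal nodes
  (default 6 and 8 branches, each hanging a side tip so ancestral presence
  along the paths is identifiable) descend to two focal clades, plus an
  outgroup; node depths get a small seeded jitter. Random Yule trees cannot
  guarantee path lengths, so the scaffold is deterministic by design.
- **Gene content.** Binary OG histories are simulated forward under the
  same gain/loss model the inference assumes (background rates 0.3/0.3 in
  the recovery experiments; 0.2/2.0 where heavy loss is wanted). Planted
  convergent losses are deterministic overwrites of the background —
  present everywhere except at the loss branch's child and its descendants
  on each path — so the true orders are exactly recoverable and recovery
  tests are not blurred by simulation noise.
- **Repertoires.** k-state histories are exact jump-chain simulations of
  the supplied rate matrix.
- **Domain alignments.** Sequences evolve site-independently under a
  20-state Poisson process (base rate 0.5/unit by default; 0.3 in the
  enrichment experiments); designated interface sites run at a multiplier
  (10× in the recovery experiments) on fragment-clade branches, and
  fragment-clade tips have the entire C-terminal domain gapped. The
  enrichment recovery experiment uses two 16-tip fragment clades attached
  at 70% of tree depth: many moderately short fragment branches keep
  fast sites below saturation, which is what lets ancestral calls stay
  confident and all planted sites clear the ≥5-event floor.
- **Structures.** CA-only two-chain PDB fixtures with planted contacts at
  exactly 4.0 Å and all other inter-chain pairs >6.0 Å; placement is
  deterministic (the seed parameter is reserved).

Not emulated: real genome sequences, horizontal transfer, codon structure,
rate heterogeneity across sites or branches, alignment error, taxonomy.
Passing tests therefore demonstrate correctness and calibration of the
*methods* under their own model assumptions and the recovery of planted
signals — not robustness to model misspecification in real data.

## Problem sizes in tests and the acceptance script

Exactness checks run on 200 random 4–6-tip binary instances and 50 random
4-tip, 10-site amino-acid alignments (exhaustive enumeration is the
reference). Rate recovery uses 1000 OGs on a 128-tip tree. The end-to-end
branch-recovery experiment uses 20 planted OGs with 50 MCMC-replicated
joint reconstructions each on a ~20-tip two-clade scaffold. Null
calibrations use 1000 random-assignment datasets (200 permutations each)
and 500 Brownian null datasets (200 simulations each). The enrichment
experiment uses 20 seeds of a 150+100-column alignment on a ~40-tip
scaffold. These sizes were chosen so each check is statistically meaningful
while the whole battery completes in well under a minute.

## Known limitations

- The binary MCMC sampler targets the two-rate model only; k-state rate
  uncertainty is not sampled (ML only).
- Joint reconstruction is per-character; it is not vectorised across
  thousands of OGs the way the likelihood is (replicated reconstruction
  loops are the dominant cost of the end-to-end experiment).
- The phylogenetic ANOVA's contrasts estimator assumes a fully bifurcating
  tree; multifurcations are resolved by sequential pairing.
- The amino-acid model has no among-site rate variation, so strongly
  saturated sites lose events to uncertain calls; the enrichment statistics
  are ratios and remain informative, but absolute event counts at fast
  sites are underestimates.
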