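# Methods

## The Dollo stochastic character mapping

Each family is a binary character on a rooted timetree whose branch lengths
are absolute time (Myr). Node ages are reconstructed from branch lengths by
root-to-tip accumulation with the deepest tip anchored at 0 Ma, so the tree
need not be ultrametric and extinct or non-contemporaneous tips are
representable. An optional *root stem* (e.g. to a 720 Ma analysis horizon)
hosts the gain of families present on both sides of the root; a tree
without a stem raises an explicit error for such families rather than
silently placing the event at the root node.

Under the Dollo assumption a family is gained exactly once and can only be
lost afterwards. Two consequences drive the implementation:

1. **Placement is deterministic.** The gain branch is the terminal branch
   (singletons) or the branch subtending the least inclusive clade of
   presence tips. With presence fixed at the gain node and only 1→0
   transitions allowed, a node must be present iff any descendant tip is
   present, so the loss branches are exactly the stems of the maximal
   all-absent subtrees inside the gain clade. This is the unique
   minimum-loss irreversible history; general-purpose stochastic mapping
   of the loss process would sample the same branch set with probability
   one, so the implementation separates a deterministic placement stage
   from a stochastic timing stage. They are mathematically equivalent for
   counts, which is verified against exhaustive enumeration of irreversible
   histories on all small trees in the test suite.
2. **Only timings are stochastic.** Event times are uniform on their
   branch's age interval (zero-length branches yield the shared endpoint).
   A loss branch is always a strict descendant of its family's gain branch,
   so their age intervals are disjoint and the gain precedes every loss by
   construction — asserted, never rejection-sampled. A
   truncated-exponential loss-timing option (clock running tipward from
   the branch's older end at a user-supplied rate) is available and flagged
   in the output metadata; uniform is the default so losses are treated
   exactly like gains.

The mapping is replicated (default 1,000×). Replicate *r* draws from an
independent RNG stream spawned from the master seed
(`numpy.random.SeedSequence(seed).spawn`), so any single replicate is
reproducible in isolation and branch assignments (hence all counts) are
identical across replicates and seeds.

### Derived quantities

* **Per-branch rates** divide the (replicate-invariant) counts by branch
  duration; zero-length branches keep their counts and report `NaN` rates.
  Branches are classified as *gains-only* (changes but no losses), *≥75%
  gains*, and *loss-majority* (losses > gains).
* **Binned series** use half-open bins [older, younger) of width 10 Myr
  from 720 Ma, labelled by the older edge; an event exactly on an edge
  falls in the younger bin, and an event exactly at 0 Ma in the youngest
  bin. Per bin, the mean and the empirical 2.5%/97.5% quantiles across
  replicates form the 95% CI. Per replicate the bin counts sum exactly to
  the event totals.
* **Lineage summaries** sum events over all branches on the root→tip path
  (including the stem). The gain:loss ratio is gains/losses and the
  percentage loss is 100·losses/gains — the convention recoverable from
  published per-lineage tables; the alternative 100·losses/(gains+losses)
  is reported alongside as `pct_loss_of_changes`. Zero-loss lineages report
  `NaN` (rendered N/A).
* **Loss bounds**: per family minimum 0; maximum N − 2 for a
  least-inclusive clade of N > 2 tips (all losses terminal, two presences
  needed to define the clade), 0 for singletons and two-tip clades.
* **Rate-outlier flags** default to the 2.5–97.5 empirical percentiles of
  the per-branch gain-rate distribution. This is a documented stand-in: a
  principled significance test would need a null model of rate variation,
  which is beyond this package's scope. The rule in force is recorded in
  the output, and flagging is disabled (with a warning) below 5 branches.

## The maximum-likelihood two-state model

The cross-check model is a continuous-time Markov chain on
{absent, present} with generator Q = [[−g, g], [l, −l]], rates per Myr on
the supplied tree, a single (g, l) shared by all families, and the root
fixed to absence (a stationary-root mode exists for sensitivity analysis;
the root stem is not part of the likelihood). The log-likelihood is
computed by Felsenstein pruning over unique tip patterns with closed-form
2×2 transition probabilities. Because published software does not always
state its rate normalization, estimates are reported both per Myr and per
unit of total tree length.

Numerical choices: the likelihood magnitude (~10⁴) leaves finite-difference
gradients below the double-precision noise floor, so the optimizer is
bounded Nelder-Mead in log-rate space from five deterministic log-grid
starts (tolerance 1e-8 on the log-likelihood); standard errors come from a
finite-difference Hessian in log-rate space via the delta method. Ancestral
states are marginal presence probabilities from a standard up-down pass;
hard states use a 0.5 threshold with exactly 0.5 resolved to absence
(conservative against inferring presence). The likelihood-based event
mapping counts a gain on a branch whose parent hard state is 0 and child 1,
a loss for 1→0.

Two modelling caveats are intentional and documented rather than corrected:

* **No ascertainment-bias correction.** The observed matrix contains only
  families present somewhere; conditioning on observability is omitted to
  match the analysis stage this model reproduces, which biases the gain
  rate upward when gains are rare.
* **Identifiability.** When g·(typical branch length) ≫ 1 the chain is at
  stationarity at every tip and only the ratio g:l is identified; rate
  *magnitudes* then cannot be recovered from realistic family counts.
  Parameter-recovery tests therefore run in the identifiable loss ≫ gain
  regime (g = 0.002, l = 0.02 per Myr), which is also the regime the model
  is used for.

## Homoplasy

Per-family minimum changes (1 for any variable binary character) and actual
changes by a two-state Sankoff dynamic program on the fixed rooted tree —
identical to Fitch/Wagner parsimony for unordered binary characters, exact
for multifurcations, and invariant to root placement (asserted by test).
Constant families are excluded from both sums, following the conventional
treatment. The ensemble CI is Σmin/Σactual and is bounded by the extreme
per-family ratios.

Expected-CI reference curves are power laws CI = a·n^b with a common slope
b = −0.42 and intercepts calibrated so the categorical curve passes through
0.50 and the molecular curve through 0.64 at 35 taxa — the reference points
of the comparative surveys of homoplasy in categorical vs molecular
matrices. The coefficients are configuration, not estimates; every report
records the set in force, and a constant set (b = 0) passes through
unchanged for auditability.

## The synthetic-data generator

`simulate_matrix` realizes the process the mapping assumes: family origins
arrive as a Poisson process along branch time with intensity λ (families
per Myr of branch time; optionally a step function of age, and per-branch
burst multipliers), and each family, once gained, is lost independently on
each descendant lineage at rate μ, irreversibly. Families with no surviving
presence are kept in the ground truth but excluded from the emitted matrix,
so the ascertainment effect is measurable. Every run records the full event
log (gain and loss branches and times) and the final tip states.

Defaults (`study_scale_config`) emulate a curated metazoan-scale study:
λ is set so the expected number of simulated families is 1,139 over the
fixture tree's total branch time, and μ = 5e-4 per family per lineage-Myr,
calibrated so ~92% of simulated families are never lost (~0.13 losses per
family) on the fixture tree — the rare-loss regime of well-curated
repertoires.

What the generator does **not** emulate:

* **Loss-rate heterogeneity.** Real losses concentrate in a few families
  and a few simplified lineages; the homogeneous μ spreads them more
  evenly, so the simulated loss-count histogram has a thinner tail than
  real data and no single choice of μ can match both the zero-loss
  fraction and the losses-per-family of a heterogeneous data set.
  Gamma-distributed loss rates belong to the Bayesian analysis stage that
  is outside this package's scope.
* **Phylogenetic realism.** The committed fixture tree
  (`data/timetree35_synthetic.nwk`) is a seeded random 35-taxon timetree
  (root 693 Ma, stem to 720 Ma), synthetic by construction; it matches a
  real metazoan constraint timetree in scale (total branch time
  ~13,600 Myr, mean branch ~200 Myr) but not in topology or dates.
  Passing tests therefore demonstrate algorithmic correctness and
  statistical behaviour at realistic scale, not agreement with any
  empirical data set.

Parsimony is a lower bound on the true number of losses: a loss is hidden
when its sibling flank is also lost (the two merge into one inferred loss
on the parent) or when early losses shrink the observable clade. The test
suite identifies, from the truth alone, the families whose true history is
already minimal and asserts exact recovery for them and the lower-bound
property for all.

`inject_noise` corrupts a matrix the way poor annotation does: per-tip
false-negative masking (low-coverage genomes) and per-tip false-positive
singleton families (misannotation). Every corruption is listed in a
manifest that exactly explains the input/output difference. On noise-free,
loss-free simulations any inferred loss is attributable to masking, and
inferred losses are monotone in the false-negative rate; end-to-end, noise
inflates recent apparent loss and gain rates relative to the clean run,
reproducing the curated-vs-uncurated contrast in direction.

## Problem sizes

Default test and acceptance runs use the 35-taxon fixture tree with
~1,000–1,100 observable families, 40–1,000 mapping replicates and 2,000
families for ML recovery; exhaustive oracles run on all rooted binary trees
with ≤ 6 tips. These sizes were chosen to make every stage's statistical
checks informative while keeping a full run in seconds.

## Known limitations

* The Dollo mapping conditions on the observed matrix; it does not model
  unobservable (everywhere-lost) families, so inferred gain counts equal
  observed family counts by construction.
* Uniform event timing ignores any rate information within a branch; the
  truncated-exponential option is provided but shares the branch-level
  placement.
* The ML model fits a single (g, l) for all families; per-family or
  gamma-distributed rates are out of scope.
* Expected-CI curves are calibrated reference values, valid in the 4–60
  taxon range and approximate by nature.
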