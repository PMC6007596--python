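# dollomap

Birth and death of gene-family characters — such as animal microRNA
families — on a time-calibrated phylogeny.

Curated presence/absence matrices of miRNA families behave like almost-ideal
Dollo characters: a family arises once and, rarely, is lost, never to be
regained. `dollomap` implements the analysis pipeline built on that
assumption: it maps each family's single gain and its losses onto a fixed
timetree, samples event *times* stochastically to propagate timing
uncertainty into rates, and cross-checks the parsimony mapping with a
maximum-likelihood two-state Markov model and a consistency-index homoplasy
assessment. A synthetic-data generator with an annotation-noise injector
(false negatives from low-coverage genomes, false-positive singleton
annotations) makes every stage testable without any external data and lets
you reproduce the qualitative artefact that uncurated repertoires inflate
apparent recent gain and loss rates.

## The model

For a binary family *f* on a rooted timetree (branch lengths in Myr, node
ages in Ma):

* **Gain placement (Dollo).** The single gain sits on the terminal branch
  for a singleton family, otherwise on the branch subtending the least
  inclusive clade containing all presence tips. Under irreversibility the
  internal states are forced (a node is present iff any descendant tip is),
  so the loss branches — stems of the maximal all-absent subtrees inside
  the gain clade — and hence the loss *count* are deterministic; this is
  the unique minimum-loss irreversible history.
* **Stochastic timing.** Each event's time is drawn uniformly on its
  branch's age interval; the mapping is replicated (default 1,000×) to give
  means and empirical 95% CIs for per-10-Myr-bin gain/loss counts over a
  720 Ma horizon, per-branch rates (events/Myr), and cumulative root-to-tip
  lineage summaries (gains, losses, gain:loss ratio, percentage loss =
  100·losses/gains).
* **Loss bounds.** Per family, minimum losses = 0 and maximum = N − 2 where
  N is the tip count of the least-inclusive clade (0 for singletons and
  two-tip clades): all losses on terminal branches, with two presences
  needed to define the clade.
* **ML cross-check.** A two-state continuous-time Markov chain with
  generator Q = [[−g, g], [l, −l]] (rates per Myr), root fixed absent,
  shared (g, l) across families, fitted by Felsenstein pruning +
  multi-start direct search; marginal ancestral states and a
  likelihood-based event mapping provide the robustness check to the
  parsimony mapping.
* **Homoplasy.** Ensemble consistency index CI = Σ(min changes)/Σ(Fitch
  steps) on the fixed tree, with expected-CI reference curves by taxon
  count for categorical and molecular data.

## Worked example

```python
from dollomap import (DolloCharacterMapping, GainLossMarkovModel,
                      ensemble_ci, load_fixture_timetree,
                      simulate_matrix, study_scale_config)

tree = load_fixture_timetree()                       # synthetic 35-taxon, 720-Ma tree
matrix, truth = simulate_matrix(study_scale_config(tree, seed=7))
res = DolloCharacterMapping(matrix, tree).fit(n_reps=1000, seed=7)
print(res.summary())
```

```
Dollo stochastic character mapping
==================================================
families:            1025
taxa:                35
replicates:          1000
loss timing:         uniform
total gains:         1025
total losses:        93
families w/o loss:   980 (95.6%)
summed max losses:   525
loss-count histogram: 0:980, 1:25, 2:4, 3:8, 4:5, 5:2, 6:1
```

Every family contributes exactly one gain (1,025 gains for 1,025 observable
families); the deterministic Dollo placement infers 93 losses, 95.6% of
families are never lost, and the N−2 rule caps the total conceivable losses
at 525. `res.lineage_summaries()` gives the per-tip cumulative table
(e.g. a tip with 59 gains and 1 loss reports ratio 59.00 and percentage
loss 1.69), `res.rate_series()` the binned series with Monte-Carlo CIs, and
`res.branch_rates()` the per-branch classification (gains-only, ≥75% gains,
loss-majority).

```python
fit = GainLossMarkovModel(matrix, tree).fit()
print(fit.summary())
ci = ensemble_ci(matrix, tree)
print(f"ensemble CI: {ci.ci:.3f}")
```

```
2-state gain/loss Markov model (root fixed absent)
========================================================
families: 1025   taxa: 35   tree length: 13613.9 Myr
log-likelihood: -5219.389   converged: True   starts: 5   iterations: 424

                rate/Myr     std err   rate/tree
gain (0->1)      0.00009     0.00000       1.164
loss (1->0)      0.00052     0.00006       7.097

ensemble CI: 0.924
```

The fitted loss rate (0.00052/Myr) recovers the generator's true value
(0.0005/Myr), and the loss:gain ratio ≫ 1 shows the ML model does not
manufacture the rarity of loss — it estimates it. The ensemble CI of 0.92
is far above the ≈0.50 expected for a categorical data set of 35 taxa,
the signature of near-zero homoplasy.

The same workflow is scriptable:

```sh
dollomap simulate --seed 7 --outdir out
dollomap report --matrix out/matrix.csv --tree mytree.nwk --stem-age 720 \
    --n-reps 1000 --seed 7 --outdir out
```

## Layout

| module | contents |
|---|---|
| `dollomap.treeio` | `TimeTree`, `PresenceMatrix`, Newick/NEXUS/CSV/TSV readers, event-table I/O |
| `dollomap.dollo_scm` | gain/loss placement, timing, replication; `DolloCharacterMapping` model |
| `dollomap.rates` | per-branch rates, binned series + CIs, lineage summaries, histograms, outlier flags |
| `dollomap.mlmodel` | pruning likelihood, rate fitting, ancestral states; `GainLossMarkovModel` |
| `dollomap.homoplasy` | Fitch/Sankoff steps, ensemble CI, expected-CI curves |
| `dollomap.synthetic` | gain/loss simulator with ground truth, noise injector, fixture tree |
| `dollomap.cli` | `dollomap` command: simulate, inject-noise, map, rates, bounds, fit, ci, report |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
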