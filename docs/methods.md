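# Methods

## Model

The package treats marker discovery as a search over *candidate
subnetworks* of a PPIN, each scored by a coalition game. The biological
premise is the standard one for network-based biomarkers: genes driving
a phenotype tend to be both differentially expressed and densely
interconnected, so a good marker is a locally dense subgraph of
high-scoring genes.

### Expression scoring

For gene *i* with expression x_i1 … x_im over m labelled samples, a
Gaussian N(μ̂, σ̂) is fitted to each phenotype class by the sample mean
and unbiased (n−1) standard deviation; each class needs at least three
samples. The per-sample feature is the natural-log likelihood ratio
LLR_i(x_ij) = ln f_i1(x_ij) − ln f_i2(x_ij), and the gene's scalar score
t(i) is the Welch unequal-variance t-statistic of the LLR values, class
1 (case) minus class 2 (control).

Choices worth noting:

- **Gaussian class densities.** The density family is a modelling
  choice; Gaussian-on-normalized-expression is the convention of the
  log-likelihood scoring framework this follows. No kernel or empirical
  density estimation is offered.
- **σ floor, 1e−6.** A constant gene in one class would otherwise give
  infinite LLRs. The floor is far below any realistic expression
  standard deviation, so non-degenerate fits are untouched.
- **Log base is irrelevant downstream.** Changing the base rescales
  every LLR vector by one positive constant, and t-statistics are
  scale-invariant, so t(i) — and everything built from it (LS, payoffs,
  equilibria) — is unchanged. This is asserted numerically in the test
  suite (deviations < 1e−8). Natural log is declared only so reported
  raw LLR values are reproducible.
- **Degenerate t.** If both class LLR variances are below 1e−12 with
  equal means the t-score is 0; with unequal means a floored-variance
  Welch quotient keeps it finite. Every gene therefore has a finite
  score.
- The Welch statistic is computed by `scipy.stats.ttest_ind`
  (unequal-variance mode); the fallback path above only runs where scipy
  returns a non-finite value.

### The game

On a candidate subnetwork, each player (gene) picks join (1) or leave
(0); the seed always joins. With V_join the joined set, E_join its
induced edges and w(e) edge weights:

- local score LS(i) = Σ t(j) over i's *joined* neighbours, 0 for a
  leaving player;
- density DE = Σ_{E_join} w(e) / C(|V_join|, 2), shared by every player
  regardless of strategy, defined as 0 when |V_join| < 2;
- payoff PF(i) = α·t(i) + β·LS(i) + γ·DE − δ·(|V_join| − 1).

Defaults α = 1.24, β = 1, γ = 1, δ = 2 (dimensionless weights; δ is the
per-member cost that keeps coalitions small). The t-score term applies
under either strategy, so a leaver's payoff still moves with DE and the
membership cost — this matters for deviation checks.

LS sums over joined neighbours specifically (not all neighbours in the
candidate): the leave rule "a leaving gene has no neighbour in the
subnetwork" only makes sense if membership means joining, and a
state-dependent LS is what gives the game non-trivial structure.

### Candidate construction

Seeds are the genes with degree ≥ the working graph's mean degree,
visited in decreasing |t| (a `rank_signed` flag restores signed
ranking; |t| is the default so down-regulated discriminators rank
symmetrically). The candidate is the seed's distance-≤2 neighbourhood
with induced edges.

**Pruning.** Tier nodes are visited once in increasing in-candidate
degree (ties lexicographic); a node is removed iff removal *strictly*
increases the reference clustering coefficient (recomputed after each
accepted removal), otherwise it is restored. For the one-step tier the
reference is the seed's local clustering coefficient — fraction of
realized edges among its current neighbours, 0 when fewer than two
neighbours (so pruning to a single neighbour is never trivially
"optimal"). The one-step tier is never emptied; if every removal were
accepted the largest-|t| neighbour is retained, since the game needs at
least one sub-game.

For the two-step tier the same acceptance rule needs a reference, and
a non-neighbour's removal cannot change the seed's own clustering
coefficient. Three variants are provided (`two_step_rule`):

- `seed` (default): the rule applied literally. The seed's clustering
  coefficient never strictly increases when a two-step node is removed,
  so the pass removes only *orphans* — two-step nodes left without a
  retained one-step neighbour. Selectivity for the two-step tier then
  comes from the per-anchor cap and filter (below). This default was
  chosen after the alternatives proved far too aggressive on the
  synthetic benchmark: `anchor` routinely emptied the two-step tier
  entirely, destroying recall of planted modules.
- `anchor`: the rule is applied to the clustering coefficient of the
  node's one-step anchor (its lexicographically smallest retained
  one-step neighbour).
- `seed2`: the reference is the edge density of the seed's full
  second-order neighbourhood.

**Caps.** The one-step tier keeps at most `max_one_step` nodes (1–19);
the two-step cap is per anchor: each retained one-step neighbour
carries at most `max_two_step` of its adjacent two-step nodes into its
sub-game. Over-cap tiers are thinned by the `filter_method`: largest
|t| (default) or largest in-candidate degree, ties lexicographic.
Package defaults are 4 and 3, the configuration used in the upstream
tool's worked illustration.

### Solving and merging

One sub-game per retained one-step anchor: members are the seed, the
anchor and the anchor's assigned two-step nodes, with induced edges, so
a game with four one-step and twelve two-step neighbours (2¹⁶ states
undecomposed) collapses to four sub-games of 2⁴ states. Payoffs during
deviation checks are computed on the sub-game's induced graph — that is
precisely what bounds the state space. All 2^free states (seed pinned
to join) are enumerated in a fixed binary-counter order over
lexicographically sorted players; enumeration order never influences
selection. Sub-games above `max_subgame_players` (21) free players are
refused with advice to lower the caps; the solver is vectorized
(numpy), evaluating all states at once.

A state is a pure Nash equilibrium iff no free player can *strictly*
raise its own payoff by unilaterally flipping. Among equilibria the one
with the highest mean |t| over joined genes is selected; ties go to the
larger joined set, then the lexicographically smallest joined tuple. A
pure equilibrium is not guaranteed to exist; in that (empirically rare,
< 1% of random sub-games) case the max-total-payoff state is used and
the fallback is counted in the run summary, never silent.

Per-sub-game solutions merge by union: a two-step gene adjacent to
several anchors appears in each of their sub-games and joins the marker
iff it joins in at least one (join wins — every sub-game's positive
evidence is preserved). The merged marker need not be a global
equilibrium of the undecomposed game; on small instances where
sub-games are disjoint apart from the seed, the tests verify it matches
a full exhaustive search.

### Pipeline

Gene universe = intersection of network nodes and expression genes
(removed counts logged): intersection is the only choice that leaves
every player scoreable. Every eligible seed is processed (ranking is
global, then truncated to `n_results`); markers with identical joined
sets collapse to the higher-ranked seed's marker; final ranking is by
marker score (mean |t| of joined genes), descending, ties by seed name.
Identical inputs and configuration give byte-identical outputs — the
algorithm has no randomness.

## Synthetic benchmark

`gta.simulate` generates what the method assumes: an Erdős–Rényi
background graph (default 200 genes, edge probability 0.02) with a
planted module (default 10 genes) rewired to a higher edge probability
(0.6) and forced connected by a random spanning tree; expression is
Gaussian noise (sd 1) with the planted genes shifted by Δ = 2 in the
case class only (20 case / 20 control by default). A log-normal option
exponentiates the matrix to probe robustness to the Gaussian
assumption.

What it does *not* emulate: scale-free/modular topology of real
interactomes, correlated noise, batch effects, heavy-tailed expression,
partially perturbed modules. Passing recovery tests therefore shows the
machinery works under its own assumptions, not that markers from real
cohorts will reproduce.

**Recovery experiment.** On the default family, the recovery runs use
caps (6, 2) with the t-score filter and the default two-step rule —
the per-anchor cap of 2 is what filters background two-step nodes,
whose |t| ≈ 0.8 cannot compete with planted genes' |t| ≈ 6. These
option values were fixed by an initial calibration run on the family
and then frozen. Across disjoint 20-replicate families the fraction of
replicates whose top-ranked marker overlaps the planted module with
Jaccard ≥ 0.6 measured 0.75–1.0 (mean ≈ 0.9). Problem sizes throughout
the tests (200-gene graphs, ≤ 10 free players for oracle comparisons,
20 replicates) were chosen so the full suite runs in seconds at
desk scale.

## Known limitations

- **Selected-equilibrium size is not monotone in δ.** One might expect
  a higher membership cost never to produce a larger marker. False: the
  pure-equilibrium *set* is not monotone in δ — lowering δ can
  destabilize a large state (an outsider then strictly prefers joining)
  while a high-|t(seed)| seed-only equilibrium survives, and the
  mean-|t| selection then returns the smaller set. About 2% of random
  sub-games show such a reversal; the dedicated test documents concrete
  instances.
- Mean-|t| ranking structurally favours small, high-scoring marker
  cores over larger supersets; with aggressive pruning this can trade
  recall for precision.
- LCC-based pruning legitimately trims weakly attached members of a
  true module (a module at internal edge probability 0.6 has such
  members almost surely), bounding attainable recall below 100%.
- No overlap-aware seed skipping: near-duplicate (not identical)
  markers from neighbouring seeds are all reported.
- No mixed-strategy equilibria; exhaustive solving above the sub-game
  player cap is available only as a test oracle.
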