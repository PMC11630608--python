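# Methods

## Model

`qbbn` propagates qualitative change through a signed directed network.
State is the probability that each node increases, P(Xᵢ) ∈ [0.1, 0.9]; the
probability of decrease is never stored, it is the complement (P(Xᵢ) +
P(X_d) = 1).  Integer inputs v ∈ {−4..4} map to probabilities as
(5 + v)/10 — computed in that form so all nine table values are exact in
binary floating point — and outputs map back as 10 × (P − 0.5).

An edge holds P(child increases | parent increases) and is fixed for the
run.  The network definition gives only that one conditional; the model
closes the table with the complement rule P(Xᵢ|Y_d) = 1 − P(Xᵢ|Yᵢ).  This
choice makes the whole pipeline odd-symmetric about the neutral probability
(negating every prior negates every output), which is what an ordinal
reading of the −4..4 scale demands; the test suite asserts this antisymmetry
to 10⁻¹² on random networks.

Each iteration is synchronous: every node reads the previous iteration's
state, so results are independent of the order nodes appear in the CSV and
a signal travels exactly one edge per iteration.  A parent is *informative*
when its probability differs from 0.5 by more than 10⁻⁹; uninformative
parents are excluded and n in both posterior formulas counts informative
parents only.  Two candidate posteriors are computed (prior-bearing and
interactions-only mean); the one furthest from 0.5 wins.  Certainty
comparisons use a 10⁻¹² tolerance under which ties go to the prior-bearing
candidate — an exact-arithmetic tie such as 0.7 vs 0.3 is not a float tie,
and without the tolerance the tie-break rule would fire on noise.

Posteriors are clamped to [0.1, 0.9] after every update; the prior-bearing
formula can otherwise exceed the bound (0.9 prior with a 0.82 conditional
gives a raw 0.9288).  The absolute-value bars sometimes written around
(1 − P(Xᵢ)) are treated as typographic since P(Xᵢ) ≤ 1 always.

**Pinning (signal-loss prevention).**  Nodes with nonzero scenario priors
represent *known* changes.  After each update, if such a node's posterior is
nearer 0.5 than its initial prior probability, the prior is restored.  A
posterior that is *more* certain (in either direction) stands.  A practical
consequence users must know: a pinned node cannot reveal feedback onto
itself.  To study, say, how a ban on harvesting a species ultimately affects
that species, add an explicit policy node with the nonzero prior and an edge
into the harvest node, leaving the harvest node free to move.

**Defaults.**  4 iterations; this is also the propagation horizon, so nodes
further than 4 directed hops from every manipulated node report exactly 0.
The iteration count is exposed for deeper networks.

## Bootstrap intervals

Each replicate perturbs ⌈0.10·E⌉ distinct edges (chosen uniformly without
replacement) by Uniform(−0.1, +0.1) *on the probability scale*, clamped to
[0.1, 0.9], and re-runs the prediction.  Deltas may carry a weak edge across
0.5 (a sign flip); that is the literal reading of "up to ±0.1" and is
allowed.  Perturbation happens once per replicate, not once per iteration.
Per node, the 95% interval is nearest-rank after trimming: sort the B
replicate values, drop ⌊0.025·B⌋ from each tail, and take the extreme
survivors (with B = 1000 that is the 26th and 975th order statistics).  The
interval is the raw empirical spread of the replicate distribution, not a
point-centred offset — the alternative reading; near the ±4 clamp the
one-sided spread can therefore sit entirely on one side of the point
estimate.  The point estimate is always the unperturbed run, never a
bootstrap mean.  `boot_max = 1` (the default) skips bootstrapping entirely.

## Sensitivity ranking

The sensitivity analysis asks which edge values most influence chosen
outcome nodes (at most 3 recommended).  Each of boot_max (default 1000)
replicates perturbs 10% of edges *and* 10% of node priors (the prior rule
mirrors the edge rule: ⌈0.10·n⌉ nodes, Uniform(−0.1, +0.1), clamped).
Perturbed priors are noise, not known changes, so they are not pinned;
scenario-pinned nodes keep their (possibly jittered) starting values as the
pin.  The exact prior-perturbation scheme is an interpretation — users
comparing against other implementations should be aware of it.

Replicate impact is Σ |replicate change − baseline change| over the outcome
nodes (absolute values so increases and decreases both count).  Every edge
perturbed in a replicate whose impact reaches the top 25% scores one count;
ties at the cutoff all count.  Two degenerate regimes are worth knowing:
edges feeding a node saturated at the ±4 clamp can be invisible to
perturbation, and if more than 75% of replicates have exactly zero impact
the cutoff is zero and the tie rule floods the ranking — both are properties
of the counting rule, and both argue for driving the system with a scenario
that keeps the outcome nodes off the clamp.

## Stepwise dynamics (timeseries)

The timeseries mode deliberately omits the signal-loss machinery: each
timestep every node with informative parents takes the plain mean of its
conditionals.  Values therefore attenuate along paths and do **not** match
the headline predictor — the mode answers *when*, not *how much*.  Column 1
of the output is the scenario itself; timesteps are ordinal.

Press mode re-imposes the scenario: after each step a manipulated node is
restored to the more certain of (computed value, prior), so feedback can
reinforce but never erode it; nodes with no informative parents keep their
value.  Pulse mode applies the scenario at timestep 1 only, and a node whose
parents are all uninformative relaxes to neutral.  The relax-to-neutral rule
is the package's design choice: holding the last value would freeze the head
of a released chain at its peak forever, whereas relaxation lets the
disturbance travel as a peak and trough through the network, which is the
behaviour the pulse mode exists to show.

## Rendering

Flow frames shade nodes by the *ordinal rank* of their change at that
timestep — biggest increase black, smallest white, ties share a shade,
intermediate ranks linearly interpolated — never by the value itself.
Outgoing edges are drawn only for nodes with |change| above the threshold
(default 0.2 on the −4..4 scale).  Full-network diagrams colour negative
edges red and positive black, width proportional to |strength| times the
arrow scale (default 4), and fill nodes by their 1–4 class using the
Okabe–Ito colour-blind-safe palette (white, grey, orange, yellow).  Layouts:
grid (preserves input order), circle, sphere (Fibonacci sphere projection),
random and Fruchterman–Reingold, the latter two seeded.  Rendering is pure:
identical inputs give byte-identical SVG (fixed hash salt, no timestamps).
Files overwrite silently by default, matching common workflow expectations;
`--no-overwrite` refuses instead, because silent overwrite is a known
footgun.  Prediction panels fill column-major, scenario 2 below scenario 1,
up to 12 per figure.

## Input conventions

Matrix rows are parents, columns children.  Node names match exactly after
trimming outer whitespace — names may contain spaces, and no dot-for-space
substitution is performed.  A literal 0 cell is accepted as "no edge" with a
warning; decimals and out-of-range values fail with the offending cell
named; duplicate names, row/column set mismatches and non-blank diagonals
(self-edges: the update never reads them, so accepting them would mislead)
are errors.  Scenario files listing a node as 0 and scenario files omitting
a node mean the same thing (no known change); omissions warn.  Unknown
labels fail with a nearest-match suggestion.

## Synthetic data

The generator draws each ordered non-self pair as an edge with probability
`density` (default 0.3 — sparse, like real interaction webs), strength
uniform on the chosen set, and guarantees at least one edge; scenarios
manipulate a small number of nodes (default 1), as real interventions do.
Generated data have no community structure, no degree heterogeneity and no
correlation between sign and topology, so passing tests demonstrate the
correctness and invariances of the algorithms, not predictive skill on any
real ecosystem.  The bundled `web8` toy is explicitly synthetic: it copies
the structural motifs of coastal-management models (trophic chain,
reciprocal competition, policy and revenue nodes) with invented strengths.

## Problem sizes

The test suite's heavier checks use: 1000 random networks of 3–8 nodes for
the bounds property, 200 for antisymmetry, the exhaustive enumeration of all
2- and 3-node networks over strengths {−4, −2, 2, 4} with single ±4 priors
(93,850 predictions) against an independently written naive transcription of
the update rules, 10⁵ bootstrap deltas, and 500 sensitivity replicates.
These sizes give the properties enough room to fail while keeping the whole
suite to a few seconds.

## Known limitations

Outputs are ordinal: a change of 2.0 is not "twice" 1.0, and values cannot
be compared across differently parameterised models.  The propagation
horizon equals the iteration count, so distant nodes silently report 0
rather than "unknown".  Edge probabilities are symmetric by construction
(the complement rule); asymmetric responses to parent increase vs decrease
cannot be expressed.  The bootstrap perturbs edges only (the sensitivity
mode also perturbs priors); structural uncertainty — missing or spurious
edges — is not modelled.
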