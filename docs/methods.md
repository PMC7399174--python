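# Methods

## Scope and data flow

`synlogic` turns a signed, directed prior-knowledge network of cancer
signaling into cell-line-specific logical models and uses them to rank
drug pairs by predicted synergy.  The stages are: network parsing and
validation → generic rule generation → calibration to baseline activity
→ perturbation simulation and synergy calling → scoring against a
binarized dose-matrix screen → node-influence and network-feature
analysis.  Every stage consumes and produces plain-text formats
(3-column interaction TSV, profile TSV, panel TSV, long-format screen
CSV, rule files, YAML edit lists).

## Logical formalism

Nodes are Boolean except the two phenotype outputs (and any node
explicitly promoted, e.g. a multi-level transcription-factor family
node), which take levels 0..3.  A multi-valued node counts as *active*
in any Boolean context when its level is ≥ 1; this threshold semantics
is the simplest consistent choice and is applied uniformly.

Generic rules derive mechanically from the network: activators are
OR-ed, inhibitors are OR-ed, and the clauses combine with the link
operator AND NOT (inhibitor-dominant, the default) or OR NOT
(activation-favored, per-node override).  Nodes with only inhibitors
get `!(I_1 | ...)`; regulator-free input nodes get the identity rule, so
both of their values are admissible fixed points until baseline data
pins them.  Output nodes carry a counting rule,
`level = clip(#active positive regulators − #active negative
regulators, 0, max_level)`; a pure positive count is available as a
configuration (`output_rule_mode="positive"`) because the exact output
wiring convention is a modeling choice, not a property of the network.
Free-form expression rules (`&`, `|`, `!`, with brackets) cover curated
exceptions such as coincidence detection (`M = C1 & C2`).

## Fixed points and attractors

Fixed points are enumerated **exactly**: a feedback vertex set of the
regulatory dependency graph is chosen greedily (repeatedly removing the
highest-degree node of any cyclic strongly connected component), all
level combinations of that set are enumerated, the acyclic remainder is
filled in by propagation in topological order, and an assignment is kept
iff every enumerated node reproduces its value.  This is exact and
complete for any model; its cost is exponential only in the feedback
vertex set, which is small for signaling topologies.  Correctness is
pinned in the test suite against full 2^N enumeration on 200 random
models (most of 6–12 nodes, a minority of 13–15, chosen so the oracle
stays cheap).  States are reported in lexicographic order of the
sorted-node value tuple, making every downstream tie-break
deterministic.

Asynchronous dynamics use unitary updates (one node per step, levels
moving by ±1 toward the rule's target).  Attractors are the terminal
strongly connected components of the explicit transition graph;
singletons are the fixed points, larger components are complex
attractors.  State spaces above `max_states` (default 2^14) return an
explicit *undecided* result — never a truncated answer — which
propagates to an NA synergy call.

## Model reduction

Nodes outside the retained set are eliminated by substituting their
Boolean rule into all downstream rules.  Eliminating a node whose rule
does not involve itself preserves the solution set of the fixed-point
equation system exactly, so projections onto retained nodes are
unchanged (this is the package's contract, checked against brute-force
enumeration).  Elimination may make a remaining node self-regulated;
such nodes — and self-loop inputs and multi-valued counting nodes, whose
thresholds have no pure Boolean substitution form — are kept and
reported as irreducible.  Perturbation simulation falls back to
reduction (retaining drug targets, outputs and irreducible loops)
followed by asynchronous attractor analysis whenever clamping leaves no
fixed point.

## Calibration

Baseline activity profiles map nodes to 0/1/NA; a combined profile
overlays literature-curated values over omics-inferred ones, literature
taking priority on conflict.  Calibration searches for link-operator
flips (AND NOT → OR NOT) that bring a stable state into agreement with
the profile:

1. identity-rule input nodes with non-NA baseline values are pinned to
   those values (the topology cannot decide them);
2. round 1 proposes flips at should-be-active nodes whose inhibitors are
   active (per baseline, falling back to the current stable state where
   the baseline is NA);
3. round 2 proposes flips at the inactive negative regulators of
   should-be-inactive nodes, pushing the inhibitor toward activity;
4. a final pass proposes flips at any remaining should-be-active
   mismatch — without it, mismatches at nodes whose activators *and*
   inhibitors are silent (the case an OR NOT flip is designed to rescue)
   would be unreachable and the iterate-until-agreement loop could never
   terminate at full agreement.

Candidates are visited in sorted node order; a flip is accepted only if
it **strictly** increases the matched fraction (so agreement is monotone
and few changes are preferred over many); rounds repeat up to
`max_rounds` (default 10).  Non-convergence is reported explicitly with
the best model found.  When several stable states exist, the one
maximizing profile agreement is selected, ties broken lexicographically.
On synthetic models with planted flips, this recovers full agreement
using at most the planted flips across 100 seeds (an acceptance
property).

## Perturbation and synergy

A drug clamps all of its target nodes to 0 (full inhibition; no partial
dosing, no off-target effects).  Among multiple stable states under a
perturbation, the one at minimum Hamming distance from the calibrated
wild-type state is taken (perturbation continues the calibrated
condition); complex-attractor output levels are averaged over the
attractor's states (configurable to min/max for sensitivity analysis).
Viability is prosurvival minus antisurvival level; a pair is synergistic
iff its viability is strictly below both single-drug viabilities.  Any
undecided member makes the pair NA, and NA pairs are excluded from both
sides of the confusion counts.

## Screen scoring

The highest-single-agent excess of a combination cell at doses (a, b) is
`V_AB(a,b) − min(V_A(a), V_B(b))`; the observed call uses the mean over
all combination cells of the grid (averaging over a stated diagonal is a
configuration) with an inclusive cutoff of −0.11 by default (half/double
cutoffs are a parameter).  Metrics follow the standard definitions;
reports round percentages to one decimal and MCC/balanced accuracy to
two.  The random baseline draws the predicted number of pairs uniformly
without replacement (`numpy` hypergeometric sampling, seeded) and
reports mean counts and metrics; the closed form E[TP] = nK/N and its
standard error accompany every run.

## Influence analysis

Each Boolean non-output node is clamped at its wild-type stable-state
value (*fix*) and at the inverse (*invert*); all d single and d(d−1)/2
double perturbations are re-simulated per mutant (2 · n · (d + d(d−1)/2)
conditions in total) and changed synergy calls are recorded per pair,
classified into TP/TN/FP/FN gains and losses when observed calls are
supplied.  A mutant condition that ends in a complex or undecided
attractor counts as a complex-attractor occurrence — conservative toward
high influence.  High-influence = any changed call or any
complex-attractor occurrence; ranking is by total changed calls
(unweighted; the per-class counts are preserved for re-weighting), ties
by node identifier.  Output and multi-valued nodes are excluded from the
sweep because inversion `1 − value` is only well defined for Boolean
nodes.

Mechanism subgraphs for a predicted synergy collect the pair-specific
influential nodes (excluding complex-attractor inducers), induce the
subgraph, knock each furthest-downstream member in (clamp 1) and out
(clamp 0) under the double perturbation, add every node whose
stable-state activity changes, and finally prune non-output sinks in a
single pass.  Node roles distinguish influence-loss/-gain from
activity-altered membership.

## Network features

Features are computed on the directed graph ignoring edge signs:
out-degree; betweenness (fraction of directed shortest paths through the
node, endpoints excluded); closeness in the harmonic form (mean inverse
incoming distance, well defined on disconnected digraphs; the classic
form is a configuration); global efficiency E = mean over ordered pairs
of 1/d(i,j) with unreachable pairs contributing 0; and PCI(v) =
(E(G) − E(G∖v)) / E(G) via node removal, the remaining N−1 nodes forming
the denominator's pair universe.  Feature importance uses a
random-forest Gini importance averaged over seeded repeats, with an
optional balanced mode that subsamples the majority class per repeat.
Biological annotations (pathway memberships, oncogene/suppressor flags)
are accepted as pass-through columns, not computed.

## Synthetic data: what it emulates and what it does not

The bundle (`make_bundle`) plants every ground truth the pipeline needs:

* **Network** (default 28 nodes, 6 drugs): two always-active inputs
  drive six drug targets; targets 1–4 feed branch pairs converging on
  `C1 = B1 | B2` and `C2 = B3 | B4`, which a coincidence node
  `M = C1 & C2` integrates into the prosurvival count alongside two
  constitutive regulators.  Only the pairs (D1, D2) and (D3, D4) silence
  `M`, dropping viability 3 → 2 — an OR-redundancy motif mirroring how
  convergence nodes mediate synergy in curated models — so the planted
  synergy set is expressible in the planted model by construction and
  `M` is the strongest influence-sweep hit.  Drugs 5–6 hit redundantly
  bypassed nodes and can never act.  Filler nodes carry the planted
  link-operator flips (default 2); they feed only the antisurvival
  count's floor, so calibration must find them from the stable state
  alone while the synergy structure stays intact.
* **Profiles**: omics-like = truth with a configurable fraction of
  flipped and NA values; literature-like = exact truth on a small random
  subset (default 9 nodes, the scale of sparse curation).
* **Screen**: monotone single-agent dose-response over a 3-dose grid
  with per-drug offsets; combination cells sit at the best single agent
  plus a planted excess (default −0.2) for synergistic pairs, plus
  Gaussian noise.

Default scale keeps brute-force oracles feasible (2^N enumeration,
full transition graphs).  Deliberately *not* emulated: realistic
pharmacology of dose-response shapes, off-target drug profiles,
feedback-driven multistability in the bundle (the bundle network is
acyclic so the planted stable state is unique; cyclic networks are
exercised by the random generator instead), and any correlation
structure between omics noise and network position.  Passing tests
therefore demonstrate the machinery — exact dynamics, faithful scoring,
recoverable calibration — not biological fidelity of any particular
network.

## Numerical and design choices

* Determinism everywhere: sorted node order wherever a sequence matters,
  lexicographic state tie-breaks, seeded generators with the seed
  recorded in outputs.
* Dual (both-sign) regulations are stored as two parallel edges and
  surface in both the activator and inhibitor sets; the validator
  reports them.
* `remove_edge` on a free-expression rule substitutes the regulator by
  constant 0 (absent-inactive); structured rules drop the member
  directly.  `set_rule` re-synchronises the node's incoming edges with
  the polarities of the new expression.
* Degenerate inputs: empty networks parse to empty models; profiles with
  zero informative entries, single-class feature labels, fewer than 3
  correlation rows, oversized random-baseline draws and unknown
  node references all raise typed errors rather than degrade.
* Problem sizes in the shipped tests — 200 random models ≤ 15 nodes for
  fixed-point and reduction checks, 100 bundles for calibration
  recovery, 100 graphs ≤ 10 nodes for feature oracles, 100,000-rep
  Monte-Carlo baselines — were chosen so the whole suite runs in minutes
  on one CPU while every contract is still pinned by an independent
  oracle.

## Known limitations

* The greedy calibration is not guaranteed to find a *minimum* flip set
  on adversarial topologies; it guarantees monotone improvement and
  reports non-convergence.
* Asynchronous analysis enumerates the full state space of the reduced
  model; models whose reduction still exceeds the cap return NA calls.
* The influence sweep's cost grows as 2 · n · (d + d(d−1)/2) stable-state
  computations; at screening-panel scale this is minutes, not seconds.
* HSA is the only synergy reference model implemented (no Bliss, Loewe
  or ZIP), matching the screen-scoring convention the pipeline targets.
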