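# Methods

This note records the execution semantics, numerical choices, and design
decisions behind `biodomain`, at the level of detail a maintainer or a
modeller building on the package needs.

## The three modelling levels

A `DomainModel` aggregates (i) a research context — phenomena, expected
emergent behaviours, components, and polarized links (autoimmune /
regulatory / neutral) between them; (ii) a spatial compartment graph with
per-entity migration rules; (iii) perspectives, i.e. activity networks
each expanding one or more expected behaviours; and (iv) one state machine
per entity type. Assembly enforces referential integrity (every
cross-reference resolves, case-sensitively) and the scope discipline that
an out-of-scope phenomenon may be declared but never linked: declaring it
records its existence while asserting the model does not explain it.

All rates and durations live in one flat parameter table referenced by
name from guards and edges. This is deliberate: the biology source for
the case study publishes no numeric rates, and named parameters keep that
gap explicit, auditable, and overridable per run.

## Statechart execution

Time is discrete. A machine is a set of orthogonal regions; each region
holds a tree of states (atomic, composite with a declared initial, or
isolated) and exactly one active leaf. Guards combine three atom kinds:

* predicate atoms, valued by the per-step environment;
* `δ(p)`: one Bernoulli(p) draw **per occurrence per evaluation** —
  evaluation is eager (no short-circuit, no caching), so a guard that
  mentions the same δ parameter twice draws twice. Modellers should
  mention a δ atom once per guard unless they mean independent draws.
* `λ(t)`: true once the transition's source state has been continuously
  active for at least `t` steps. Dwell counters reset on every entry,
  including re-entry, so λ measures dwell time, not age.

One step evaluates, per region, the guards of transitions leaving the
active leaf or any active ancestor composite, against a start-of-step
snapshot of configuration and environment. At most one transition fires
per region; ties are broken uniformly at random from the run's seeded
generator. Firing runs exit actions innermost-first (leaving a composite
exits its active substate), the transition's actions, then entry actions
outermost-first, descending into composite initials, and zeroes the dwell
counters of entered states. Quiescent regions increment their dwell
counters. After all regions settle, the per-step emissions of every
active state are appended.

Partial orthogonality — one region's dynamics constraining another's — is
expressed exclusively through guard predicates naming other regions'
active states (`in_<state>`), never through shared states. Because all
guards read the start-of-step snapshot, a firing in one region can never
change guard outcomes in another within the same step.

Two consequences worth stating plainly. First, execution with all δ
parameters at zero is deterministic *provided* the machine never enables
two transitions from one state simultaneously; competing always-enabled
transitions are resolved by the seeded tie-break, which is a stochastic
element by design. Second, identical seeds and inputs give bit-identical
trajectories; the test suite asserts both properties.

## Token-flow execution

Perspectives execute under a multiset-of-tokens semantics. Each step: all
tokens age by one; a start-of-step snapshot of token positions is taken;
then, per node, tokens whose per-edge dwell (a parameter, default 1 step)
has elapsed traverse sequential edges. Multiple outgoing sequential edges
duplicate the token (an implicit fork — the concurrent reading of the
biology); fork nodes do the same explicitly; join nodes consume one token
per incoming branch and emit one; merge nodes pass tokens through; tokens
reaching end nodes are consumed; start nodes inject nothing after
initialization. Perspectives are typically cyclic and need no end nodes —
start nodes exist to make the network explorable, not to pump tokens.

The three extended relationships:

* **Propagating**: each token at the source spawns `Poisson(spawn_rate)`
  new tokens at the target, per step, judged on the snapshot; the source
  token is never moved or consumed by propagation, and spawning stops the
  step the source activity empties. Poisson was chosen because spawns may
  occur any number of times per step and the total over a holding period
  has a closed form (mean = rate × steps), giving an analytic test oracle.
* **Interrupting**: a sequential edge's traversal probability is
  multiplied by Π(1 − degree_i) over interrupters holding at least one
  token in the snapshot. Multiple interrupters compose multiplicatively
  (independent partial blockades, order-free). Degree 1 blocks fully;
  degree 0 is exactly a no-op.
* **Contributory**: a decision node routes each of its tokens along one
  branch sampled from weights — baseline 1 per branch, plus the signed
  shifts of every contributory source active in the snapshot, floored at
  0 and renormalized. Additive-then-floor is the simplest auditable
  functional form. The source is not consumed, so one active source
  influences arbitrarily many routings.

Swim lanes are compartment annotations checked by the consistency rules,
not execution constraints.

## Consistency rules

R1–R7 (see `biodomain.consistency.RULE_REGISTRY`) make cross-diagram
claims checkable. R3, the interesting one, is decided statically: a
binding predicate is declared structurally ({partner entity, partner
state}) rather than parsed from its name; the checker computes the
compartments where the guarded transition is satisfiable (location
predicates fixed per compartment; since the guard grammar has no
negation, the maximal assignment decides satisfiability exactly) and the
compartments the partner's location region can reach from its initial
state via location transitions and migration rules, and flags any gap.
This mirrors a static cross-reference argument and is conservative: no
simulation is consulted. Molecules are treated as confined to their
secretion compartment; diffusion between compartments is not modelled.
Violations are data (warnings); strict callers — the simulator by
default, the CLI's exit code — treat any violation as an error, because
deliberate abstraction can make a rule inapplicable and that judgement
belongs to the modeller.

## Population simulation

Agents step synchronously in seeded-shuffled order against start-of-step
snapshots. Interaction rules are sampled per eligible actor: one
uniformly random eligible co-located partner, then a Bernoulli draw at
the rule's rate — a well-mixed-within-compartment contact model, chosen
as the least-assumption option and surfaced as a config choice. Effects
assert predicates (which the recipient's own machine interprets), mark
kills (the `killed` predicate; the victim's machine decides what death
looks like), or spawn agents. An agent whose death state has been active
for one full step is removed; the one-step linger is what lets phagocytes
ingest apoptotic cells before they disappear.

Cytokines are per-compartment scalar fields, not individual agents: a
`secrete_<Molecule>` emission adds 1 to the local field, fields decay
geometrically per step, and machines perceive them through
`<Molecule>_present` predicates thresholded by a parameter. This is a
declared simplification of the per-molecule influence-machine view, kept
because population runs with molecule-as-agent granularity add cost
without changing any modelled decision. The molecule state machines
remain in the model as single-entity documentation and are checked by the
consistency rules.

Migration is driven by the migration rules: each agent attempts at most
one move per step with a per-type probability (`p_migrate_<Type>`,
falling back to `p_migrate`), choosing uniformly among rule-permitted
targets; the agent's location region is then re-pointed at the new
compartment leaf. Location-region *transitions* express the same
spatial claims inside the statechart view — they are exercised in
standalone machine execution and by rules R1–R3, and are masked during
population runs so that space is not double-stepped.

Accounting is exact: for every type at every step, initial + cumulative
births = alive + cumulative deaths, asserted over full runs in the tests.

## The EAE case study

Every fixture element carries a provenance entry: `quoted` (stated in the
source description's text), `figure-described` (content of one of its
figures), or `inferred` (a modelling completion where the source
reproduces a diagram only partially). The inferred count is
snapshot-tested so completions cannot grow silently. Notable choices:

* The autoimmune arm (inception and self-perpetuation of CNS
  inflammation) is packaged as a third perspective expanding the
  "immune system harms neurons" behaviour, following the narrative's
  four-phase decomposition; its node inventory is inferred.
* CD4Treg's role is abstracted to licensing: activated CD4Tregs license
  mature DCs, licensed DCs upregulate Qa-1:CDR1/2 presentation, and only
  Qa-1-presenting DCs prime CD8Tregs. The CD8Treg priming guard carries
  `in_Lymphoid`, which is exactly what rule R3 verifies against the DC's
  reachable compartments (DCs never enter the circulation).
* Effector CD8Tregs are excluded from CLN, Spleen and SLO by state
  conditions on every migration edge into a lymphoid compartment.
* Interaction rules travel in the run configuration (`SimConfig`) rather
  than the document aggregate, keeping the document format a pure
  description of the three diagram levels.

### Default parameters and study conditions

All numeric defaults are invented — the source publishes none — and were
calibrated once, qualitatively, so that the shipped configuration
reproduces the case study's defining emergent pattern (autoimmune
expansion followed by spontaneous recovery, and no recovery under the
killing knockout); they were then frozen. The shipped run uses 185 agents
(20 DC, 36 CD4Th1, 24 CD4Th2, 18 CD4Treg, 20 CD8Treg, 15 CNS macrophages,
40 neurons) over 250 steps, sizes chosen so a full two-arm, ten-seed
comparison runs in well under a minute on one core while leaving every
population large enough for its role to be visible above sampling noise.
The regulatory arm's rate-limiting parameters (licensing rate 0.15, Qa-1
upregulation δ = 0.06, CD8Treg priming/activation δ = 0.3, lymphoid entry
δ = 0.15) set the recovery delay: with them, CD4Th1 peaks near step 40–50
and collapses by about step 80. T-cell λ lifespans (500 steps) exceed the
run length so that, under the knockout, decline can only come from
killing — which is the point of the contrast. With the shipped rates the
neuron population is exhausted before regulation completes; recovery in
this model is recovery of the *immune* state, and neuron sparing would
require a slower macrophage arm than the frozen defaults provide.

What passing runs do and do not show: the simulation demonstrates that
the modelled interaction structure suffices for the qualitative
onset-then-recovery pattern and its knockout reversal under invented
rates. It makes no quantitative claim about real EAE kinetics, real
population sizes, or parameter values, and none of the shipped numbers
should be read as estimates of biological quantities.

## Numerical and engineering choices

* Randomness: a single `numpy` Generator per run seeds everything
  (tie-breaks, guard draws, interaction sampling, iteration shuffling);
  identical seeds give bit-identical trajectories, CSV and DOT output.
* Guard printing uses minimal parentheses but parenthesizes right-nested
  same-operator children, so parse → print → parse is a structural
  identity (the parser is left-associative).
* The document validator is a compact structural checker over a shipped
  JSON-Schema-like description, reporting JSON-pointer paths; YAML input
  is mapped 1:1 onto the same structure.
* DOT output is assembled deterministically; composite states and swim
  lanes become clusters, interrupt relationships are drawn through
  mid-edge anchor points, and the legend is embedded as comments.

## Known limitations

* No negation in the guard grammar: exclusions must be phrased as
  disjunctions of permitted states (as the effector-exclusion conditions
  are). This is also what makes R3's satisfiability check exact.
* UML event queues, history pseudostates, deferred events and
  do-activities are out of scope, as are expansion regions — compounding
  concurrency is expressed by propagating edges instead.
* Continuous quantities (expression levels, concentrations) are
  representable only as categorical states plus thresholded fields.
* Within-compartment space is not modelled; contact is well-mixed.
* The checker validates structure, not biology: it will happily pass a
  consistent model of wrong biology.
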