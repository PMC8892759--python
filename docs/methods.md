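# Methods

## The response-distribution network

`rmetnet` analyzes four-alternative forced-choice emotion-recognition data
(the Reading the Mind in the Eyes Test is the motivating instrument) by
looking at the *full distribution* of answers rather than only the correct
ones. For each group of participants a directed graph is built:

* **Target nodes** — one per item, standing for the item's photograph /
  correct answer. Item-scoped.
* **Source nodes** — the answer categories a participant can produce: the
  four candidate words plus the no-response (timeout) condition. Word
  nodes are shared across items (two items offering the distractor *sad*
  share one node); no-response nodes are item-scoped by default, with a
  `global` mode collapsing them into one node. The published counts for
  this family of networks cannot disambiguate the two conventions, so
  both are provided and neither is treated as canonical.
* **Edges** — one directed edge per observed (answer category → item
  target) pair, weighted by the number of participants who made that
  choice. Choosing the correct word also creates an edge (from the target
  word's source identity into the target node), which is what lets an
  item's in-degree reach 5. Only observed choices instantiate nodes and
  edges; there are no zero-weight edges.

Conservation holds exactly: total edge weight = participants × items.

## Indices

* **Item in-degree** — distinct in-edges to the item's target node, in
  [1, 5]. 1 means complete consensus; 5 means every answer category
  (including timeout) was observed. It equals the count of distinct answer
  categories in the raw records, which is how it is cross-checked in the
  tests.
* **Item density** — realized connections among the item's five candidate
  nodes over the 10 potential unordered pairs. Under the source-to-target
  topology the realized connections are exactly the in-edges, so item
  density = in-degree/10 and cannot exceed 0.5. The denominator of 10 is
  retained as the definitional convention rather than "corrected"; the cap
  is documented here instead.
* **Network density** — `e / (n·(n−1))`, the directed-graph convention
  (no self-pairs). This is the only convention under which published
  node/edge counts at this scale (e.g. 127 nodes / 170 edges → 0.011)
  reproduce their reported 3-decimal densities, which an acceptance test
  pins down. Reported values are rounded half-even to 3 decimals; full
  precision is kept internally.
* **Behavioral measures** — percent accuracy over all items (timeouts
  count as incorrect: a non-answer cannot be a correct response) and mean
  reaction time over responded trials only.

## Inference

Accuracy and RT are compared by one-way ANOVA (two groups, df `(1,
n₁+n₂−2)`); for two groups F = t² of the pooled t-test, asserted as a
property test. In-degree vectors (overall and per valence stratum) are
compared by the Student pooled-variance two-sample t-test: its df
`n₁+n₂−2` (84 for 43+43 items, 36/28/16 for the 19/15/9 valence strata)
is the structure this study design prints, which identifies the pooled
rather than Welch variant; `welch=True` is available. All tests are
two-sided. No multiple-testing correction is applied across the three
valence strata by default — the analysis mirrors the single-study
convention — and a Bonferroni option exists for users who want it.
Accuracy–trait associations use Pearson correlation (df `n−2`).

A deliberate caveat, surfaced rather than hidden: the item-level t-test
treats *items* as the units of inference, so it speaks to consistency of
choice patterns across this item set, not to participant-level sampling
variability. The type-I-error Monte-Carlo check below documents how the
test behaves under the generator's assumptions.

## Synthetic cohort generator

Because clinical RMET datasets are not openly deposited, the package
ships a generator whose defaults are the reference study shape: 2 groups
× 30 male-cohort-sized samples, 43 items, valence partition 19 negative /
15 neutral / 9 positive.

Choice model: per item and group, the target word gets probability
`target_prob` (defaults 0.68 group A, 0.74 group B, matching the two
groups' mean accuracies). The residual mass is spread over the three
distractors and no-response by one draw from a symmetric Dirichlet with
concentration `diversity`, optionally scaled per valence. Low
concentration piles the wrong-answer mass on a single alternative (a
consistent confusion); high concentration spreads it (diverse errors).
Participants are i.i.d. categorical draws. Defaults: diversity 1.0 for
group A with a ×2.5 multiplier on negative items (encoding the clinical
group's extra error diversity on negative words), 0.4 for group B. These
were chosen once as plausible values producing group-A mean in-degree
near 4 and group-B near 3 at n=30, and are not tuned per test.

Reaction times are log-normal: a participant-level latent mean drawn from
a log-normal matched to the group mean/SD (defaults 4006±438 ms group A,
3485±671 ms group B), then per-trial log-normal noise with
within-participant CV 0.2, truncated to the 8-second display window by
redraw. Timeout trials carry no RT.

Trait scores are linear in participant accuracy plus Gaussian noise
scaled so the Pearson correlation hits the configured target in
expectation (defaults −0.441 for AQ *patterns*, both groups; −0.427 for
ADI-R *socio-emotional reciprocity*, group A only, since the instrument
is administered to the clinical group). Score locations/scales (AQ ~6±2,
ADI-R ~14±5) are plausibility choices only; correlation is
scale-invariant.

All randomness flows from one `numpy.random.Generator` seeded from the
config; the same config is bit-identical on regeneration.

**What the generator does not emulate:** real item-specific difficulty
(an optional logit jitter exists, off by default), within-participant
dependence across items, speed–accuracy coupling, and any true
distribution of trait scores. Passing tests therefore validate the
*pipeline and its statistics under a known generative model*, not claims
about clinical populations.

## Recovery and calibration experiments

`recovery_experiment` symmetrizes both groups onto group A's parameters
and shifts group B's diversity by `delta_diversity`, so at delta 0 the
groups are exchangeable. Each replicate simulates a cohort, builds both
networks, and records mean in-degrees, densities, and the pooled t. At
study scale (30+30, 43 items, 200 replicates) a diversity gap of 2.0 is
recovered — higher-diversity group shows higher mean in-degree — in
≥95% of replicates, and at delta 0 the t-test's rejection rate sits
within Monte-Carlo error of the nominal 5%. The 200-replicate size keeps
the experiment to a few seconds while giving a binomial SE of ~1.5
percentage points on the rates.

## Numerical choices and degenerate inputs

* Word matching: exact equality after Unicode NFC normalization and
  whitespace trim; never fuzzy.
* No-response encoding on read: empty choice cell or literal `NR`, both
  normalized to one token; an RT on a timeout row (or a missing RT on a
  responded row) is an error, not a warning, because the display window
  defines the timeout.
* Reported densities: round-half-even via `decimal`, 3 digits.
* Zero pooled variance in the t-test: t = 0, p = 1 when means agree; a
  signed infinite-t sentinel with p = 0 when they differ.
* Constant input to Pearson correlation raises a dedicated degeneracy
  error (CLI exit code 3; validation errors exit 2).
* Dirichlet concentration 0 is taken as its limit: all residual mass on
  one uniformly chosen category.
* Valence strata with fewer than 2 items skip their t-test with a note in
  the report.
* Graph exports order nodes deterministically (item id, then word) so
  identical inputs produce identical files.

## Known limitations

* In-degree ignores edge weights, so one participant's stray choice
  raises an item's score as much as a group-wide systematic confusion
  would; weighted variants are out of scope here.
* Whole-network node/edge counts depend on the no-response convention
  (per-item vs global), so absolute counts are comparable only within one
  convention.
* Item density can never exceed 0.5 under this topology even at maximal
  diversity (see above).
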