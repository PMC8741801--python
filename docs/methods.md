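# Methods

`tigertask` simulates and analyzes the two-door "tiger" decision task in
its single-agent (TT) and dyadic interactive (ITT) forms, and implements
the computational models of optimal performance against which behavior in
this task family is judged.

## Task model

Two doors hide a tiger and a pot of gold. Each round an agent listens
(`L`, cost 1 point) for a growl that reports the tiger's side with
accuracy `p_growl` (default 0.70), or opens a door (`OL`/`OR`). Opening
ends the *tiger-trial*: payouts are delivered and tiger/gold are
re-randomized (0.5 per side). A session is 10 tiger-trials. In the ITT,
rounds begin with a prediction of the partner's action; every round also
emits a social signal — creak-left, creak-right, or silence — that reports
the partner's action class with accuracy `p_creak` (default 0.80), errors
split evenly over the two wrong signals (a maximum-entropy choice; the
confusion structure is configurable). A trial ends as soon as either agent
opens; the opener's partner receives its social signal but no growl on the
ending round. Both agents act simultaneously; the 5-second response window
and forced-listen default of the human task are not simulated (agents
always respond; the log schema carries a `forced` flag for imported data).

### Payout tables

Base single-agent values: listen −1; gold +20 and tiger −50 in the
*modified* variant; +10/−100 in the *original* variant. Dyadic tables
derive from the base values:

* **original** — each agent receives its own base payout plus (cooperative)
  or minus (competitive) half the other's base payout, in every cell (the
  half-share rule of this task family's original multiagent formulation).
* **modified** — the same half-share applies only when the other agent
  opened a *different* door; identical joint actions and a listening
  partner leave base payouts unchanged. This keeps all entries whole
  numbers and reproduces the reported anchor cells: a joint listen costs
  1 each, joint gold pays +20 each (the table maximum), joint tiger −50
  each (the minimum), and a competitive gold-vs-tiger round pays
  (+45, −60). The full modified matrices are not available as text, so the
  off-diagonal open-vs-listen cells are a reconstruction; this is the main
  structural uncertainty in the environment definition.

## Solo model: exact POMDP solution plus quantal response

The belief `b = P(tiger left)` evolves by Bayes' rule on growls and resets
to 0.5 after an opening. The infinite-horizon discounted problem
(`gamma = 0.95`; the task family's customary discount — results are
threshold-grained and insensitive to moderate changes) is solved by
alpha-vector value iteration. One sweep backs up listen vectors only for
observation-conditional maximizer pairs found on a dense belief grid
(4097 points) — exactly the useful vectors of the full cross-sum — and
prunes to the upper envelope with relative epsilon `1e-9`; this tames the
tiger problem's notorious crowd of near-duplicate vectors. Iteration stops
when successive value functions differ by less than `1e-6` (sup-norm). An
independent belief-grid value iteration and, for horizons ≤ 3, brute-force
expectimax enumeration serve as cross-checks (the latter to 1e-9, with
near-exact pruning, since small finite-horizon sets need no epsilon
control).

The solved policy is a symmetric belief-threshold rule: listen on an
interval around 0.5, open outward, ties breaking toward opening. At
`p_growl = 0.7` the induced net-evidence thresholds are d = 4 (original)
and d = 2 (modified); the deterministic mean listens/trial then follow the
exact two-sided first-passage law `E[T] = d/(2p−1) · (1−ρ^d)/(1+ρ^d)`
with `ρ = (1−p)/p` (≈ 9.35 and 3.45). Note the one-sided approximation
`d/(2p−1)` overstates these because wrong-side threshold crossings also
end trials.

The *behavioral* model is the solved policy filtered through a
quantal-response (softmax) function on the optimal action values,
`P(a|b) ∝ exp(λ·Q(b,a))`. The temperature is a package-level calibration
frozen at `λ_solo = 0.22`; with it the model averages ≈ 7.2 listens/trial
under the original payouts and ≈ 2.8 under the modified — both reported
model values — which a deterministic optimal policy cannot do at any
discount (it pins to the first-passage values of integer thresholds).

## Interactive model: Level-1 I-POMDP with a particle filter

A Level-1 agent augments the physical state with a model of its partner:
interactive states are pairs (tiger side, partner belief). The partner is
modeled as a Level-0 player. Two readings are implemented:

* `subintentional_fixed` (default): an *unintentional* player with a fixed
  uniform action distribution;
* `pomdp_noisy`: a solo noisy-rational POMDP agent (temperature
  `level0_lambda = 0.22`, the solo model's frozen value).

The default matters: with a mostly-rational Level-0 partner, competitive
listening is taxed (half the partner's likely gain is subtracted while one
listens) and competitive opening is subsidized by the +45 cell, so the
Level-1 agent *races* — listening less under competition, like human
participants but unlike the reported models. With the unintentional
reading, competitive listening collects half of a randomly erring
partner's losses while cooperative listening pays for them, and the
reported orderings (more listening under competition than cooperation,
and more at horizon 2 than horizon 1) emerge. The package therefore
defaults to the unintentional reading.

Beliefs over interactive states are tracked with an interactive particle
filter (1000 particles): each particle samples the partner's action from
its Level-0 model, is weighted by the likelihood of the observed creak
given that action, of the observed growl given the hypothesized tiger
side, and of the public trial-continuation event (a continuing round
proves nobody opened — omitting this factor is incorrect Bayes), then
propagates the partner's belief with a sampled growl and is systematically
resampled. Weight collapse triggers rejuvenation from the prior with a
warning.

Action values: horizon 1 is the expected immediate payoff marginalized
over particles and the partner's action distribution. Horizon 2 adds
`gamma` times the expected best next-round horizon-1 value, marginalized
exactly over the partner's action (any opening leads to the fresh-trial
continuation value) and over the agent's own observation branches; the
three creak signals share one posterior mid-trial (their likelihood under
a listening partner does not depend on the interactive state), so only the
two growl branches reweight particles, each split over the partner's
unobserved growl. Action selection is quantal response with
`λ_interactive = 2.0`, calibrated once against the reported
horizon-1 model means and frozen (the fit plateaus for λ ≥ 2).

Predictions (the ITT's prediction stage) are the modal action of the
marginal Level-0 distribution, ties resolving to listen.

### Replay scoring

Reported model listen counts come from replaying models against recorded
observation streams: the model chooses freely each round given the
recorded creaks and growls; if it opens while recorded rounds remain, its
listen count stands; when the recording ends first, the trial is completed
with observations sampled from the task's channels (growls from the
recorded tiger side; creaks for a still-listening partner), 30 times, and
averaged. Replay counts are therefore *untruncated* by the partner's
opening, unlike raw self-play counts. The package reproduces model-side
numbers through this replay pipeline, scoring the models against
synthetic-participant sessions (below), and also offers coupled dyad
self-play (`simulate_dyad`).

### Known limitation

With 70%-accurate growls, +20/−50 base open payouts and any half-share
reconstruction of the reported anchor cells, a two-step-lookahead agent
opens once net evidence reaches 2 — opening at belief 0.845 dominates
every two-step continuation, and even the infinite-horizon solo optimum
stops at d = 2. The horizon-2 model therefore averages ≈ 2.6–2.9
listens/trial (competitive) and ≈ 2.3–2.6 (cooperative), reproducing the
reported *orderings* but not the reported horizon-2 *magnitudes*
(5.98/3.91 listens; 3.25 evidence), which imply an effective net-evidence
threshold near 3. No setting of discount, temperature, or Level-0 kind in
this model family reaches those magnitudes; they presumably reflect
unstated semantics of the original C++ solver. The shortfall is reported
as-is by the acceptance suite rather than fitted away.

## Behavioral indices

All indices run identically on human-format logs, synthetic participants,
and models: listens per tiger-trial; evidence difference; correct-open
fraction; total score; and for dyads identical opens (same door on the
ending round), identical actions (per round), listen predictions,
prediction accuracy, logically consistent actions (own action equals the
action predicted for the partner — the identity reading, configurable in
principle but not parameterized here), and the correctly predicted subset
of consistent actions (undefined, NaN, when no round is consistent).
Fractions are reported in [0, 1].

**Evidence difference** defaults to the magnitude `|nGL − nGR|` at the
trial's end. The reported per-condition values exceed `(2p−1)·nListen`,
which Wald's identity makes impossible for the truth-signed mean of any
stopping rule on i.i.d. growls; the magnitude reading (equivalently,
evidence toward the opened door for evidence-driven agents) is attainable,
and matches the index's stated purpose of measuring an agent's realized
evidence threshold (a threshold-d agent scores exactly d on self-ended
trials). Truth-signed and chosen-door-signed modes are available.

## Synthetic participants

Human data for this task family are not publicly deposited, so the
analysis pipeline is exercised on populations of *net-evidence threshold
agents*: listen until `|nGL − nGR| ≥ d`, then open away from the believed
tiger, with a lapse probability of uniform random actions, a
prediction-fidelity parameter `copy_prob` (a mirror-self predictor states
its intended action with this probability and a decoy otherwise —
unpredictable play), a cooperative opening-round convention
`min_open_round` (hold open actions until a common round, which is what
synchronizes identical opens; with partners visible only through noisy
creaks and trials ending at the first open, threshold agents cannot
coordinate same-round opens any other way), and per-session drifts on
`d`, `copy_prob` and lapse that reproduce the direction of the reported
learning effects (identical opens rise under cooperation; correctly
predicted consistent actions fall under competition).

Population defaults were calibrated once against the reported participant
means and frozen: modified solo `d ∈ {2 (0.8), 3 (0.2)}` (evidence ≈ 2.05,
listens ≈ 3.8); original solo `{2: 0.4, 3: 0.6}` (≈ 2.49/5.1); modified
cooperative `{2: 0.4, 3: 0.6}` with `min_open_round = 5`, copy 0.98
(listens ≈ 5.3, evidence ≈ 2.4, consistency ≈ 0.98); modified competitive
`{2: 0.5, 3: 0.5}`, copy 0.95 with negative drift (listens ≈ 3.0,
evidence ≈ 1.5, consistency ≈ 0.88). What passing tests on these
populations show is that the *pipeline* recovers known generator structure
and the reported contrast directions — not that humans are threshold
agents; in particular the generator has no reaction times beyond an
optional log column, no forced responses, and no inter-individual
correlation beyond the threshold mixtures.

## Statistics

Welch's two-sample t-test (scipy's unequal-variance t with Satterthwaite
degrees of freedom) with a 95% CI for the mean difference and Cohen's d on
the pooled standard deviation; zero-variance inputs are flagged degenerate
rather than erroring. The Bonferroni gate is strict inequality at
`alpha/m` (default 0.05/8). The Fisher z comparison of two correlations
uses `z = (atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3))` with
significance beyond ±1.96 — the denominator is the standard form; the
literal reading of the printed formula, `1/N − 3`, would give negative
variances. Mixed-effects ANOVA and mixed-effects regression are
deliberately out of scope; `indices.reports_frame` exports the tidy
per-(agent, session) table such fits consume.

## Reproduction pipeline and problem sizes

`scripts/acceptance.py` recomputes the model-side quantities from scratch:
solo models simulated for 1000 tiger-trials per variant; interactive
models replayed with 1000 particles and 30 completions over 20 synthetic
dyads (one session of 10 trials each) per condition — sizes chosen to keep
Monte-Carlo standard errors of the reported means below ~0.05 listens
while completing in minutes on one CPU. The test suite uses smaller sizes
with correspondingly widened statistical tolerances (typically 3 standard
errors). All randomness flows from explicit seeds; identical seeds give
byte-identical outputs.
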