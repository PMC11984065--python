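# Methods

## The analysis problem

`protoconv` analyses dyadic vocal interaction between an infant and a
caregiver recorded in short (~5 min) semi-structured play sessions, across
a longitudinal design of four timepoints (T1–T4, roughly 4, 6, 9 and 12
months of age) and three play contexts (book-sharing, manipulative toys,
rattle-shaking). The raw material is utterance-level manual annotation in
Praat TextGrid files: one interval tier per speaker, each labelled interval
one utterance. The package derives per-session outcomes — vocalization
rates, conversational-turn rates in both directions, and mean signed turn
transition times — and models them longitudinally with marginal (GEE)
regression.

## Annotation model

An infant utterance is a vocalization on a single expiration cycle, coded
as protophone, syllable, protoword, laugh or cry. A caregiver utterance is
a vocal sound bounded by silent pauses longer than 200 ms, coded as speech,
vocalization, singing or laughter. The 200 ms inter-pausal rule is applied
computationally by `merge_close_sounds`: successive same-category sounds
with a pause of *at most* the threshold are fused (the rule splits only on
pauses strictly greater than 200 ms, so a pause of exactly 200 ms fuses);
fusion is transitive. Design choices where the coding convention is silent:

* **Fusion across categories** is off by default — category is an
  annotation-level judgement that automatic fusion must not erase. A
  `merge_across_categories` switch exposes the alternative.
* **Infant streams are not pause-merged by default**: the inter-pausal rule
  belongs to the caregiver coding scheme; infant utterances are delimited
  by expiration cycles. `merge_infant=True` applies the rule to infants for
  sensitivity analyses.
* **Coordinate convention**: times are seconds from session start;
  intervals are half-open `[onset, offset)`, so an onset equal to the
  previous offset is contiguity, not overlap.
* **Analysis set**: reflexive infant sounds (laugh, cry) and caregiver
  laughter are excluded before any outcome is computed; speech,
  vocalization and singing together form caregiver vocal production.
  Every exclusion is counted and logged — no silent data loss.
* **Annotation slips**: overlapping same-speaker intervals in an input file
  are a hard error by default; `repair="clip"` truncates the earlier
  interval at the later one's onset and logs the repair.

TextGrid reading accepts Praat's long and short text dialects in UTF-8 or
UTF-16 and rejects binary files with a clear message; writing emits
long-format UTF-8 with silence intervals tiling `[0, duration]` and 17
significant digits, so a write/read round trip reproduces boundaries to
better than 1e-9 s. Multi-line interval labels are not supported.

## Turn detection

For each initiator (Speaker 1) utterance `v`, the candidate responses are
the other speaker's utterances whose onset lies in
`(v.onset, v.offset + W]`, with window `W = 3 s` by default. The matched
response is the candidate minimizing `|onset − v.offset|`; the signed turn
transition time is `onset − v.offset` (negative = overlap, positive =
gap). Both directions are computed independently on each session.

Interpretation choices, each oracle-tested against an exhaustive
brute-force matcher:

* A response may begin *during* the initiator's utterance (an overlap) but
  never before the initiator's onset — the only reading consistent with a
  forward search that still admits negative transitions.
* An exact tie between an overlap and a gap of equal magnitude resolves to
  the gap; residual ties resolve to the earlier responder onset.
* By default one responder utterance may answer several initiator
  utterances (per-initiator nearest search). `unique_responses=True`
  switches to one-to-one assignment, greedy by ascending `|transition|`
  with earlier initiators winning ties.
* A `gaps_only` variant restricts candidates to onsets strictly after the
  initiator's offset; under independence its matched fraction follows the
  homogeneous-Poisson law `1 − exp(−λW)`, which the validation suite
  checks.

Zero-turn sessions yield a *missing* mean transition time, never an imputed
zero; the modelling stage drops such rows per outcome (available-case
analysis).

## Session metrics and the long table

Rates are event counts divided by the full task duration in minutes, taken
from the session manifest (an optional `effective_duration_s` column
overrides the denominator for sensitivity analyses). Mean utterance
durations are computed over the filtered analysis set. One row per dyad x
timepoint x task; duplicate keys are an error; missing sessions are simply
absent and reported as missing design cells.

## The dyad simulator

The study's recordings are not redistributable, so the package ships a
generative stand-in with the statistical structure the analysis assumes: a
marked Poisson process with a post-offset response kernel.

* Spontaneous onsets per speaker: homogeneous Poisson at a (task,
  timepoint)-dependent per-minute rate, multiplied by a dyad-level
  mean-one lognormal random effect (`dyad_sd = 0.2` on log rates) shared
  across the dyad's sessions.
* Responses: after each spontaneous utterance of one partner, the other
  responds with probability `p_response` at latency `|N(0.6 s, 0.4 s)|`;
  with probability `overlap_prob = 0.2` the response onset is placed
  inside the initiator's utterance (but after its onset), producing a
  negative transition. Responses do not themselves trigger responses.
* Durations: lognormal per speaker (infant median 0.6 s, log-SD 0.5;
  caregiver median 1.0 s, log-SD 0.6).
* Reflexive sounds (infant laugh/cry at 0.5/min, caregiver laughter at
  0.3/min) form separate streams, so the base rates describe the
  *post-filtering* analysis set.
* Collisions: a scheduled utterance overlapping an existing same-speaker
  utterance is dropped (later-scheduled loses). Drop counts are recorded
  in session metadata; at caregiver-typical densities (~12/min with ~1.2 s
  utterances) the thinning is material (~15–20%), and all rate-recovery
  comparisons account for it explicitly rather than pretending it away.
* Sessions are 300 s; whole sessions are masked missing independently with
  probability 0.3, matching the attrition level of a typical longitudinal
  infant cohort (roughly 70 of 104 dyads contributing per cell).

Default rate tables encode the qualitative pattern the inference stage is
expected to detect: caregiver rates are highest during book-sharing at
every timepoint (12–13.5/min versus 8–9/min); the infant's spontaneous
rate and the coupled response load (`p_response x caregiver rate`) are both
task-balanced at T1–T3, and book-sharing/rattle-shaking exceed
manipulative-toys play by ~2 utterances/min — about two session-level
standard deviations of the outcome — only at T4. One side effect of the
coupling is a small caregiver-rate interaction at T4 (infants vocalize
more there, so caregivers produce slightly more responses); it is an order
of magnitude smaller than the caregiver task main effect.

Randomness: one root seed; dyad effects, missingness masks and per-session
generators are derived deterministically from it, so identical seeds give
identical studies down to the TextGrid bytes.

What the simulator does **not** emulate: empirical latency distributions
(only boxplot summaries are published, so the Normal latency is a
placeholder), utterance content and prosody, coder disagreement, burstiness
beyond Poisson, and any dependence of response probability on utterance
duration or category. Passing tests therefore demonstrate that the
pipeline and inference behave correctly under a plausible generative
model, not that the published effect sizes are reproduced on real data —
the recordings behind the published numbers are embargoed, so those values
are not desk-reproducible.

## Marginal models

Each outcome is modelled as `outcome ~ task * timepoint` (treatment coding,
reference book-sharing/T1) by GEE with the dyad as cluster and sandwich
(robust) covariance, via statsmodels. Omnibus Wald chi-square tests of the
task (df 2), timepoint (df 3) and interaction (df 6) terms use the
quadratic form `b' V^{-1} b` on the robust covariance; post-hoc task
contrasts are differences of estimated marginal means per task x timepoint
cell with z-based p-values and a Bonferroni family of the 3 task pairs
within each timepoint (a global family of 12, and a marginal family
averaging over timepoints, are available).

Two covariance decisions were settled by simulation at study-realistic
sizes (60–80 dyads, 30% missingness):

* **Working correlation: independence by default.** GEE point estimates
  are consistent under any working structure, but *estimating* an
  exchangeable correlation at ~60 clusters adds enough noise to the
  sandwich that the 6-df interaction test rejects true nulls at ~0.09–0.10
  instead of 0.05. With independence the same test is calibrated
  (~0.05–0.07, matching an independent cluster-robust implementation in R
  exactly). Exchangeable and AR(1) remain one switch away.
* **Finite-sample scaling `G/(G−1)` of the sandwich** (G = clusters), the
  default convention of the standard cluster-robust implementations in R
  and Stata, is applied by default (`cluster_adjust=False` restores the
  raw sandwich, which is what the in-suite statsmodels oracle checks
  against). Bias-corrected small-sample estimators of the Mancl–DeRouen
  family are deliberately out of scope; residual small-sample liberality
  of the 6-df test at a few dozen clusters is a documented limitation.

A Gaussian identity link is the default for the per-minute rate outcomes;
a Poisson log link with a `log(duration/60)` exposure offset is available
for count outcomes. An ML linear mixed model (random dyad intercept) is
provided as an optional comparison output only, not a validated estimator.

Degenerate inputs: a constant outcome column is fitted by exact least
squares (the GEE scale estimate degenerates there); fewer than two
clusters, duplicate design rows, non-convergence and singular covariance
submatrices are explicit errors.

## Validation suite: problem sizes

The package validates itself end-to-end at the following sizes, chosen to
give tight Monte-Carlo error while keeping the full suite around a minute:

* turn matcher vs exhaustive oracle: 1000 random sessions (≤30 utterances
  per speaker, half on an exactly-representable 0.25 s grid to force
  floating-point ties), both directions, both reuse modes, exact equality;
* segmentation: boundary cases plus idempotence on 1000 random streams;
* chance-level baseline: 200 uncoupled sessions, infant onsets at 4/min,
  gap-only matched fraction within 3 Monte-Carlo SEs of `1 − exp(−0.2)`
  (≈ 0.181), restricted to initiators whose window fits in the session;
* rate recovery: 200 sessions at caregiver 12/min pushed through TextGrid
  write/read, filtering and summarization; extracted mean within 3 MC SEs
  of the nominal rate after the reported collision-drop correction, with
  scheduled onsets checked against the pure Poisson law;
* type-I error: 500 task-balanced (null) studies of 60 dyads; omnibus
  interaction rejection must lie in [0.03, 0.08] at alpha = 0.05
  (measured 0.078);
* power/specificity: 200 studies of 80 dyads with the default T4-only
  effect; the Bonferroni-adjusted book-vs-toys contrast must flag T4 in
  >80% of replicates (measured ~100%) and T1 in <10%.

The type-I and power loops use an array-level fast path that shares the
stream generator (and therefore produces bit-identical counts) with the
object-building simulator; a dedicated test pins that equivalence.

## Known limitations

* No small-sample bias correction of the sandwich beyond the `G/(G−1)`
  convention; inference below ~40 clusters should be treated cautiously.
* The `ar1` working correlation treats the four visits as equally spaced.
* The simulator's response kernel is first-order (responses do not chain),
  so very long alternating exchanges are rarer than in real dyads.
* TextGrid support covers interval and point tiers in the text dialects
  only; labels containing newlines are not handled.
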