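# Methods

This note documents the models in `caaprio`, the choices made where the
underlying framework leaves details open, and what the synthetic data can
and cannot show.

## AHP weight derivation (`caaprio.ahp`)

Judgments use the standard Saaty 1–9 ratio scale with reciprocals.
Validation enforces, rather than repairs, the structural invariants
(positivity, unit diagonal, reciprocity to relative tolerance 1e-9), since
a reciprocity violation signals a data-entry error that should surface, not
be averaged away.

Weights are the L1-normalised principal right eigenvector computed by power
iteration on the raw matrix: normalise every step, stop when successive
vectors differ by less than 1e-12 in the max norm, cap at 10,000
iterations. Perron–Frobenius guarantees a simple dominant eigenvalue with a
positive eigenvector for positive matrices, so convergence is assured and
the cap is a safety net. $\lambda_{\max}$ is read off as
$\sum_i (Aw)_i$ at the converged, unit-sum $w$. The test suite checks the
power-iteration route against a dense eigendecomposition (an independent
algorithm) to 1e-8 on a thousand random reciprocal matrices.

Consistency: $CI = (\lambda_{\max} - n)/(n-1)$, $CR = CI / RI(n)$ with
Saaty's random-index table $RI = \{3{:}\,0.58,\ 4{:}\,0.90,\ 5{:}\,1.12,\
6{:}\,1.24,\ 7{:}\,1.32,\ 8{:}\,1.41,\ 9{:}\,1.45,\ 10{:}\,1.49\}$;
$CR \equiv 0$ for $n \le 2$ (2×2 reciprocal matrices are always
consistent). Tiny negative round-off is clamped to zero so reports honour
$CI, CR \ge 0$. Acceptability threshold 0.10 (conventional).

Panel aggregation takes the element-wise geometric mean of the individual
matrices before deriving weights ("aggregation of individual judgments").
This is the only element-wise aggregation that maps reciprocal matrices to
a reciprocal matrix; aggregating per-expert priority vectors instead is a
defensible alternative, and for consistent-ish panels the two nearly
coincide. The aggregate matrix is rebuilt from its upper triangle so the
reciprocity invariant holds exactly despite log/exp round-off.

## Modified-Delphi arithmetic (`caaprio.delphi`)

Scores are 9-point Likert integers on two dimensions per factor:
importance and measurement capability. The decisive per-factor summary is
the **median** over experts (midpoint of the two central order statistics
for even panels); means are computed and carried in every decision record
for transparency but never decide.

Band rule, applied to the medians: any dimension below 4 eliminates the
factor (a factor that cannot be measured is useless no matter how
important, and vice versa); above 7 on **both** dimensions selects it;
everything else advances to another round. Medians exactly on a boundary
(4 or 7) advance — the bands are "below four" and "higher than seven", so
the boundary belongs to the middle.

Agreement for a factor is the fraction of experts whose score falls in the
same Likert band (1–3 / 4–7 / 8–9) as the factor's median; a half-integer
median is banded by the same rule (e.g. 3.5 → low, 7.5 → high). A round
terminates the Delphi when every non-eliminated factor reaches agreement ≥
0.80 on both dimensions (per-factor agreement is reported as the minimum
over the two dimensions). The ≥ convention means a panel at exactly 80%
counts as agreed. Factors retained by explicit researcher decision despite
their bands are supported as an `override_selected` set and are always
flagged in the output, never silent.

Not modelled: questionnaire administration, panel recruitment, and the
qualitative merging of factors between rounds — those are human processes.

## Scoring framework (`caaprio.scoring`)

The packaged default carries the seven consensus factors and weights
(0.22, 0.18, 0.15, 0.15, 0.12, 0.10, 0.08). Factor scores are integers
0–10; the published framework's contribution ranges start at 0 points,
which requires a 0 score, so 0–10 is the default and a 1–10 reading is
available by setting `score_min` in the config. With scale 10 and weights
summing to one the total lies in [0, 100] and the per-factor point ceilings
are (22, 18, 15, 15, 12, 10, 8).

Tier boundaries are inclusive-lower: exactly 80 points is tier 1, exactly
50 is tier 2. Wait targets are 4 and 8 weeks; the open-ended
"three to four months" third tier is rendered as 16 weeks (configurable).
Totals are kept at full precision internally — rounding happens only at
display/CSV time — and tier assignment uses the unrounded total.

Ranking is total points descending with a deterministic tie-break chain:
waiting-time factor score descending (longer waiters first), referral date
ascending, patient id ascending. The ranking is therefore a pure function
of the roster, invariant to input order.

Whether patients should be mechanically re-scored as they wait is not
settled by the framework's description; the scoring module takes scores as
given, and only the simulator (which must take a stance) re-scores the
waiting-time factor over time.

## Waiting-list simulator (`caaprio.simulate`)

Weekly time steps: arrivals join at the start of a week, the queue is
re-ranked, up to `capacity` patients are served that week (a patient served
in their arrival week has wait 0). Weeks give adequate resolution for wait
targets quoted in months while keeping runs cheap.

Synthetic stream: weekly arrival counts are Poisson; each patient draws a
latent severity $u \sim \mathrm{Beta}(a, b)$ and the six clinical/social
factor scores independently as $\mathrm{Binomial}(10, u)$, which induces
the positive inter-factor correlation of real referral mixes. The
waiting-time factor is scored mechanically as
$\min(10, \lfloor 10\,t/16 \rfloor)$ after $t$ weeks (saturation horizon 16
weeks, configurable) — the deployed framework treats it as
physician-assigned, but a simulator needs a rule.

Default scenario, chosen once: 0.9 arrivals/week against capacity 1
(utilization 0.9), 200 weeks, severity Beta(2, 2). A single-slot service at
0.9 utilization behaves like an M/D/1 queue and produces genuine multi-week
queues; the same utilization spread over a large weekly batch produces
almost no queueing and makes every policy look identical. Beta(2, 2)
spreads severity across the range, yielding roughly 4% tier-1, 40% tier-2,
56% tier-3 arrivals — a plausible elective triage pyramid in which urgent
patients exist but are rare.

Outcome metrics stratify patients by their tier **at arrival** (waiting-time
score 0), a property of the patient rather than of the queue policy, so
tiers are comparable across policies. Target attainment is computed over
"evaluable" patients — those whose tier target window closed before the
simulation horizon — and an unserved evaluable patient counts as a breach.
Policy comparisons run both disciplines on the identical stream (common
random numbers); mean-wait deltas carry simple percentile-bootstrap
intervals over served patients.

Known behaviour, reported not asserted: the framework policy can starve
low-severity patients — tier-3 waits grow relative to FIFO (the waiting-time
factor's 10-point ceiling bounds how much waiting alone can escalate
priority). No health outcomes, no-shows, or capacity variation are
modelled, and nothing is calibrated to any real service's data: passing
tests show the arithmetic and queue mechanics are right, not that a real
waiting list will reproduce the simulated effect sizes.

## Numerical and interface conventions

CSV artifacts are comma-separated UTF-8 with header rows, ISO-8601 dates,
decimal points; configs are JSON. All randomness flows from explicit seeds
(one `--seed` at the CLI), and identical inputs plus seed give
byte-identical output CSVs. Every CLI run writes a manifest with input
digests, config snapshot, seed and timestamp.

Problem sizes used by the test suite and reference-results script — a
7-factor matrix, 1,000 random matrices of orders 3–9, streams of ~10,000
patients for calibration checks, and 100 paired 200-week replicates — were
chosen as comfortable desk-scale sizes for a laptop-class machine.
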