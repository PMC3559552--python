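# Model and methods

`endoabm` simulates systemic inflammation after an intravenous endotoxin
(LPS) bolus as a multi-compartment lattice agent model: every molecule is an
agent performing a persistent random walk on a 2-D grid, and all chemistry is
rule-based and stochastic. The model couples three layers:

1. **Signalling** — LPS binds membrane TLR4 (forming the active complex
   LPSR), LPSR and imported pro-inflammatory cytokines activate the kinase
   IKK, activated IKK liberates NFκB from its inhibitory NFκB·IκB complex,
   and free NFκB re-complexes with IκB. Nuclear NFκB drives production of
   pro-inflammatory proxies and of its own inhibitor — the canonical
   two-feedback NFκB module.
2. **Transcriptional response proxies** — three aggregate species stand in
   for whole expression programs: P (pro-inflammatory cytokines), A
   (anti-inflammatory cytokines) and E (bio-energetic proteins). P and A of
   equal status annihilate on contact; production in the nucleus costs one E.
3. **Neuro-endocrine layer** — the brain compartment produces cortisol (F)
   and melatonin (M) with sine-ramped circadian windows (F: 3:00→9:00, M:
   22:00→2:00). Circulating hormones are imported into cells like cytokines;
   F binds its receptor GR into FR, which promotes A and IκB production and
   suppresses NFκB activity and GR synthesis; nuclear M promotes P.

## Geometry and populations

The plasma is an 80×50 unitless lattice containing an 11×11 brain region and
one lattice point per leukocyte (50 cells). Each cell owns a 40×30 lattice
with a centered 11×11 nucleus (≈10% of the cell area). Compartment
permissions are enforced every tick: LPS is plasma-only; LPSR, IKK, NFκB·IκB,
E and GR are cytoplasmic; NFκB, IκB and FR shuttle between cytoplasm and
nucleus; imported (active) P, A and M may enter the nucleus; F never does;
M and A never enter the brain.

Initial copy numbers follow a homeostatic occupancy argument: molecules fill
25% of the cell area (300 of 1200 sites), and copies are proportional to
molecular lifetime (twice the half-life), expressed as integer weights
relative to IκB — 1 (IκB), 5 (NFκB·IκB), 5 (IKK), 3 (P), 3 (A), 4 (E), 4
(TLR4), 4 (GR), summing to 29. Hence f = ⌊300/29⌋ = 10 copies of IκB and the
familiar 10/50/50/30/30/40/40/40 column, 290 molecules per cell. The plasma
P and A pools start at 10% of the summed cellular counts (150 each). Initial
molecule ages are drawn uniformly over one lifetime so the starting
population does not expire in a synchronized wave.

## Two clocks

Two tick-per-hour scales coexist. The **life-scale** S_l = f/R = 20 governs
production and degradation: default production adds one unit per species per
cell with probability R = 0.5 per tick, balancing degradation (removal after
`lifetime` idle life-hours, 20 ticks each). The **time-scale** T_sc maps
ticks to wall-clock hours for circadian windows, injections and reporting;
it is 50 ticks/hour after calibration against the in-vivo response timing.

Life processes are anchored to the *tick* clock. Raising the time-scale
therefore relabels ticks as hours — circadian windows stretch over more
ticks while cascade kinetics (movement-driven) compress in wall-clock hours —
without disturbing the tuned per-tick production/degradation balance. This is
what makes the homeostatic calibration independent of the later time-scale
search, and it is the mechanism of that search: at 20 ticks/hour the
pro-inflammatory response peaks too late in wall-clock hours; at 50 it falls
into the observed 2–6 h window.

## Movement, attraction, imports

Molecules wait w ~ U{0..2} ticks, then step once per tick through the Moore
neighbourhood along a heading kept for n ~ U{1..5} steps (both configurable;
the source distributions are not published). Interactive pairs within a
Chebyshev distance of θ = 3 steer toward each other (headings refreshed every
3 ticks, found by KD-tree nearest-partner queries), and circulating mediators
near a cell steer toward it. Non-LPS molecules arriving on a cell's lattice
point are imported with probability 0.30 (≈ the initial TLR4 membrane
coverage, 40/136), become *active*, and land uniformly on the cell grid —
nucleus-eligible actives may land directly in the nucleus. Imported
molecules never return to plasma; locally produced (inactive) P and A are
released to plasma when they reach the membrane. LPS import is
contact-mediated: each arrival probes one uniformly drawn membrane position
and binds iff a TLR4 occupies it, consuming the receptor and creating LPSR.
LPS is deliberately excluded from the capture steering — with chemotactic
capture ~70% of a bolus was imported, an order of magnitude above the
published effective concentration.

## Production, energy, degradation

Nucleus production draws fire **once per tick of residence**: each resident
producer rolls its Bernoulli parameters (NFκB: κp→P, κi→IκB; active P:
pt→TLR4; active A: ae→E; FR: fa→A, fi→IκB; active M: mp→P) every tick it
spends inside the nucleus region. Each success burns one bio-energetic
molecule of the cell, and successes are rationed by the available E. The
nucleus is therefore an energy-limited production budget for which resident
species compete — at night melatonin residents route the budget toward P, in
the morning FR routes it toward A and IκB while also silencing NFκB draws
(when FR outnumbers nuclear NFκB) and GR default production. This cadence is
the decisive interpretation choice of the build: with once-per-entry draws
the hormonal fluxes are ~1% of cytokine turnover and no circadian cytokine
phase can emerge; with per-tick draws the energy gate both prevents
divergence and creates the published phase structure. Brain draws (P entry:
pf→F; F entry: fm→M, blocked while brain P > 2× brain F) fire once per entry —
the brain has no energy gate, so per-tick draws there would let the morning
cortisol window flood melatonin production.

A molecule is removed after `2 × half-life` life-hours without any action
other than movement. Actions that reset the idle clock: creation, import
(the status flips to active), a state change (IKK activation), and a
successful production (for the producer). Translocation between compartments
is movement and does not reset the clock; catalysts (LPSR) are not reset by
the activations they cause. Activated IKK spends its charge on liberating
one NFκB and reverts to inactive — this keeps the resting NFκB pool small
(the component table lists no initial NFκB) while LPSR persistence sustains
re-activation during a challenge.

## Circadian driver

During each hormone's window a batch of c_fm = 3 units is added with
per-tick probability `(1 − 1/c_fm) · R · sin(π/2 · elapsed/window)`. At the
window peak the hormone's total production rate is then exactly c_fm times
its default rate, and because hormone lifetimes (0.8 wall-hours at
T_sc = 50) are much shorter than the windows, the peak *level* is ≈ c_fm
times the ambient level — the stated design criterion for the batch size.
Cortisol batches are placed in the brain region; melatonin is secreted
directly into plasma (it cannot reside in the brain).

## Homeostatic tuning

With circadian drivers and endotoxin off, the nine production probabilities
start at 70% and are adjusted daily: the hourly system-wide count of each
species is regressed on time (OLS), and a trend is significant when the 95%
slope CI excludes zero **and** the half-day mean shift exceeds 10% (and at
least 10 molecules — a relative criterion on a ~20-copy hormone pool is
sampling noise). The conjunction matters: on autocorrelated stochastic
counts the iid-OLS interval alone fires on most species most days and the
loop would never meet its stopping rule (no parameter change for three
consecutive days). Significant trends adjust the responsible parameters
(P←κp,mp; IκB←κi,fi; A←fa; E←ae; TLR4←pt; F←pf; M←fm) multiplicatively and
opposite to the trend, `p' = p(1 − Δ)` with Δ the relative half-day shift,
halved when two parameters share a species, clamped into (0.001, 1]. Two
relaxation days precede the first adjustment so the loop does not chase the
initial transient. Experiments default to the published adjusted
probabilities; a freshly tuned set can be passed instead.

## Experiments and statistics

Experiments start from a saved homeostatic snapshot (2 unstimulated
relaxation days, then 1 circadian day ending at midnight); replicate r runs
on seed `base_seed + r`, making every experiment a pure function of
(configuration, base seed). Default replicate count is 100, as in the
source study; tests and the acceptance script use 6–20 with correspondingly
wider stochastic allowances. Challenge response metrics (P peak time/height,
fitness minimum) are evaluated over a 12-hour post-injection window — and a
6-hour window for the time-of-day sweep — so that the next nocturnal
circadian rise is not misread as part of the response.

* **Variability-based fitness** F_var(t) = H_A(t)/H_P(t), the ratio of
  cross-cell Shannon entropies of anti- and pro-inflammatory counts after
  whole-number contraction by C = 5. The ratio is log-base invariant; hours
  with H_P = 0 carry the previous value forward. The anti-inflammatory arm
  sits in the numerator so that fitness falls when the pro-inflammatory arm
  spreads across cells after a bolus. Because the fitness has its own daily
  pattern, the post-challenge dip is read against a paired dose-0 control
  run with identical seeds.
* **Synchronization** — mean per-cell Pearson correlation against the
  population-mean trajectory over 3-hour windows; constant trajectories are
  excluded, and an all-constant window is flagged undefined. With hourly
  sampling each window holds 4 points, so single-window estimates are noisy
  and only replicate averages are interpreted.
* **Sensitivity** — each production parameter is perturbed ±75% (capped at
  1.0, with the realized relative change in the denominator), the system is
  re-run without endotoxin, and the coefficient is the percentage change of
  the fitness (Σ|ΔF_var|/ΣF_var) per unit relative parameter change.
* **Effective concentration** — 100 × (total cellular LPSR)/(50 × 1200), the
  percentage of the summed cell volume occupied by active complexes.

## What the simulations do and do not show

The model is a proxy-level abstraction: single species stand in for whole
cytokine programs, cells are identical point-targets with independent
internal grids, and there is no receptor trafficking, mRNA/protein
distinction or explicit HPA feedback loop. Passing tests show that the rule
system reproduces the *qualitative* physiology it encodes — circadian
hormone phases with ~3× peaks, a nocturnal pro-inflammatory phase, a 2–4 h
pro-inflammatory response to a 9 AM bolus with ~0.33% effective
concentration, transient energy suppression, morning-protected/midnight-
vulnerable dosing — not that it predicts quantitative human cytokine levels.

Known limitations found during validation:

* The homeostatic circadian amplitude of P (~10–15% of its mean) makes the
  clock-hour of its daily peak a noisy statistic below ~20 replicates; the
  peak sits on a nocturnal plateau (≈23:00–5:00) whose argmax wanders
  between adjacent hours.
* The energy budget caps *increases* of stimulated production but not
  decreases. Sensitivity coefficients therefore rank parameters whose
  reduction shrinks the pro-inflammatory arm (κp) above parameters whose
  effect requires pushing production further up (κi decrease acts through
  NFκB persistence, which the saturated budget mutes). The published
  ranking (κi-decrease and fa on top) is not reproduced — an expected
  consequence of the per-tick/energy-rationed production interpretation,
  recorded as a failing check rather than hidden.
* The time-of-day sweep shows a robust morning minimum of the
  pro-inflammatory peak; the night-time maximum is shallow (≈4-6% above the
  minimum) and its hour wanders between 18:00 and 3:00 — evening injections
  often edge out midnight, so the "largest response around midnight" claim
  is only partially reproduced (the corresponding check is left failing).

## Numerical choices

Simultaneous vectorized updates with uniformly random pair resolution
replace per-agent sequential scheduling; each molecule joins at most one
consuming event per tick. Pair matching at shared lattice points is exact;
steering uses nearest partners under the Chebyshev metric. Degenerate
inputs: zero-variance trend series are never significant; a zero original
fitness sum, misaligned panels and empty count vectors raise errors;
probabilities are clamped to (0.001, 1] during tuning. All randomness flows
from one `numpy` Generator per world, seeded explicitly; runs are
bit-reproducible.
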