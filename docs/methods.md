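# Methods

## Model structure and assumptions

The decision problem is second-line treatment of advanced/metastatic
esophageal cancer: pembrolizumab 200 mg q3w versus investigator's-choice
chemotherapy (paclitaxel, docetaxel or irinotecan), evaluated separately
for the trial's total population, the PD-L1 CPS ≥ 10 subgroup and the
squamous-cell-carcinoma subgroup.

A Markov cohort model with three mutually exclusive states —
progression-free survival (PFS), progressive disease (PD), death — is
run in 1-month cycles over a 5-year horizon (60 cycles; 5-year survival
in this population is a few percent, so longer horizons add little).
Assumptions:

- The cohort starts fully in PFS.
- Transition probabilities are constant over time (one monthly value per
  transition). No tunnel states, no time-on-state dependence.
- Death is absorbing; no separate background (other-cause) mortality is
  added — the calibrated transitions already absorb all-cause death as
  observed in the trial.
- Backward transitions (PD → PFS) are excluded.

## Rewards, discounting, half-cycle correction

Per-cycle rewards: PFS carries drug acquisition + tests/scans +
grade ≥ 3 adverse-event management; PD carries subsequent-line therapy;
QALYs accrue at annual utility / 12 per month alive (0.75 PFS, 0.67 PD).

Costs and QALYs are accumulated with a **trapezoid half-cycle
correction** — cycle *t* accrues over the average of the start- and
end-of-cycle occupancy — and discounted at the cycle start with monthly
rate `(1.03)^(1/12) − 1` (geometric compounding of the 3% annual rate).
Both choices were validated against the published per-state results
rather than assumed: with them, all twelve per-state/total cost cells
across the six subgroup–arm combinations reproduce within 0.15%, and all
QALY cells match at their printed 2-decimal precision; without the
half-cycle correction costs overshoot by ~10–13%. The simple monthly
rate 0.03/12 is selectable via `ModelConfig(discount_compounding=
"simple")`; it changes totals by < 0.05% here. One published cell — the
squamous-subgroup chemotherapy total cost — disagrees with the sum of
its own published components by ~$273; the engine reproduces the
components, and we treat the printed total as a transcription error.

Intermediate quantities are kept at full floating precision; rounding
(half-up, 2 decimals) happens only at the reporting boundary.

## Limits of reproduction: incremental QALYs and ICERs

The packaged transition probabilities are printed to 3 decimals. Per-arm
totals are insensitive to that rounding, but incremental QALYs are small
differences (0.09–0.23) of ~0.5 quantities, so third-decimal input
rounding shifts them by several percent, and the ICERs — which divide by
them — inherit the error: the recomputed ICERs are $160,703 (CPS ≥ 10),
$215,900 (total) and $169,817 (SCC) per QALY versus the published
$163,165 / $202,709 / $163,643. Back-solving the published incremental
cost over ICER gives incremental QALYs of 0.228 / 0.094 / 0.160 against
our 0.2318 / 0.0884 / 0.1528 — discrepancies in both directions, which is
what input rounding (not a convention mismatch) produces; no
half-cycle/discount/timing variant does better, and incremental costs
agree to ~0.15% throughout. The substantive conclusion — ICERs an order
of magnitude above the $11,105.8/QALY threshold — is unaffected. The
test suite pins the per-arm cells tightly and records the ICER gap
explicitly.

## Cost inputs

Per-month cost components are packaged as model inputs. Two derivation
helpers validate them rather than replace them:

- `monthly_drug_cost` converts vial prices and dosing schedules
  (whole-vial ceiling, no sharing; body surface area 1.72 m² for per-BSA
  dosing) to monthly costs under a **28-day month**: 200 mg q21d
  pembrolizumab from 100 mg vials at $2,763.80 gives
  2 × 2763.80 × 28/21 = $7,370.13/month, matching the packaged $7,370.14
  to the cent — the convention the packaged numbers imply. The packaged
  chemotherapy monthly cost blends the three regimens with unstated usage
  weights, so it is taken as given.
- `expected_ae_cost_per_month` reconstructs the adverse-event cost as
  Σ incidence × per-event cost over the trial's grade ≥ 3 events. Two
  events (diarrhea, alopecia) have reported incidences but no published
  unit cost, so the reconstruction ($10.40 and $130.23/month) undershoots
  the packaged $12.23 / $131.79, which remain authoritative.

All amounts are 2021 USD; the CNY exchange rate (6.4831) is metadata.

## Calibration

`calibrate_transitions` fits the five transition probabilities to
tabulated OS/PFS curves on an integer-month grid (≥ 3 points past
month 0; linear interpolation onto integer months is provided as an
opt-in helper for digitised curves). Three free parameters — PFS stay
probability *a*, the share *w* of PFS exits that progress rather than
die, PD stay probability *b* — are optimised on the logit scale so the
simplex constraints hold by construction, minimising the summed squared
error over both curves. The procedure is deterministic: a closed-form
initialiser for *a* (exp of the mean per-month log-PFS drop, exploiting
the model's triangular structure), a fixed coarse grid (step 0.05 per
parameter), then Nelder–Mead refinement (SSE tolerance 1e-10, ≤ 10,000
evaluations), ties broken by lowest SSE then lexicographic parameter
order. Best-so-far SSE is recorded per evaluation, giving a monotone
descent trajectory.

Degenerate inputs are flagged rather than fitted: a flat PFS curve
(no exits) or OS ≈ PFS everywhere (PD never meaningfully occupied)
returns `converged = False` with a diagnostic, because the PD-state
parameters are then unidentifiable. Since the original study's
digitised curve coordinates and objective are not published, the
calibrator is validated by round-trip recovery: noiseless
predict → calibrate recovers interior matrices to < 0.005 per parameter
with SSE < 1e-8.

## Synthetic patient-level data

`simulate_cohort` walks individual patients through the same monthly
chain, recording progression and death months on the integer-month grid
(the chain's native resolution — no continuous-time interpolation), with
optional single-cut administrative censoring; `km_estimate` applies the
product-limit estimator (lifelines) per endpoint. The generator's
defaults mirror the modelled trial setting: transition matrices from the
packaged subgroup configs, 60-month follow-up, no censoring unless
requested. It deliberately omits real-trial features — dropout,
treatment switching, interval-censored tumour assessments, subgroup
enrolment imbalance — so recovery tests demonstrate correctness of the
estimator/calibrator chain under the model's own assumptions, not
robustness to real-world messiness.

End-to-end check: 20,000 uncensored patients → Kaplan–Meier →
calibration recovers the generating matrix to < 0.01 per parameter.

## Sensitivity analysis

- **One-way (OWSA)**: each registered parameter (per-arm drug, test and
  AE costs; shared subsequent-therapy cost; both utilities; the discount
  rate — 10 in all) is set to baseline × (1 ± 0.20), others fixed; both
  arms re-run; rows ranked by ICER spread (ties keep registration order;
  zero-spread rows rank last). Utilities may cross during one-way
  variation (u_pfs × 0.8 < u_pd), so the u_pd ≤ u_pfs ordering is
  enforced on baseline sets only.
- **Probabilistic (PSA)**: 10,000 draws by default; costs ~ Gamma,
  utilities ~ Beta, matched by method of moments to mean = baseline and
  SD = 20% of baseline (the published analysis names the distribution
  families but not their variances; 20% mirrors the one-way range and is
  exposed as `se_fraction`). Transition probabilities stay fixed, as only
  costs and utilities were assigned distributions. One root seed;
  per-parameter child streams keyed by a stable hash of the parameter
  name, so adding a parameter leaves other draws unchanged. Because the
  matrices are fixed, each arm's discounted person-months are constants
  and per-draw outcomes are exact linear functions of the draws.
- **CEAC**: P(strategy cost-effective | λ) over λ = 0…250,000 in 2,500
  steps (always including 11,105.8); a draw counts for the intervention
  iff λ·ΔQ − ΔC > 0, ties to the comparator, so the two probabilities
  sum to 1. The published acceptability figures cannot be matched
  numerically (variances unreported); the qualitative behaviour —
  intervention probability ≈ 0 at the WTP threshold, crossing 0.5 only
  around $150–175k/QALY in the CPS ≥ 10 subgroup — reproduces.

## Problem sizes and determinism

Default analyses are small: a 60-cycle trace is a 61×3 array, PSA at
10,000 draws runs in well under a second, calibration needs a few
thousand objective evaluations, and the recovery studies use cohorts of
20,000–50,000 patients. Every stochastic entry point (`simulate_cohort`,
`run_psa`, the CLI `psa`/`simulate` commands) requires an explicit seed
and is bitwise reproducible given it.

## Known limitations

- Time-homogeneous transitions cannot express the late-crossing survival
  curves typical of immunotherapy; the calibrated constant probabilities
  are a deliberate simplification inherited from the modelled analysis.
- The SCC + CPS ≥ 10 combined subgroup is not modelled (its PFS curve
  was never published).
- Reproduction of published ICERs is bounded by the printed precision of
  the transition inputs (see above); per-arm quantities are the reliable
  regression surface.
- The PSA omits parameter correlation and transition-probability
  uncertainty (e.g. Dirichlet rows), and no EVPI is computed.
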