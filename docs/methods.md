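# Methods

## Model structure

The model is a decision tree linked to a state-transition (semi-Markov)
cohort model. One cohort member is a moderate-to-severe atopic-dermatitis
patient aged 38 at entry; the cohort is homogeneous (the 54% male share and
48/52 severe/moderate mix are carried as metadata only — mortality is
unisex and severity enters solely through the two per-cycle healthcare-cost
levels). Cycles are 4 months (1/3 year); the horizon is 63 years (189
cycles, to age 101). States:

- `initial` — the 16-week decision-tree phase, cycle 0 only;
- `response` — dupilumab maintenance (dupilumab arm) or supportive-care
  response (SC arm);
- `no_response` — supportive-care treatment; absorbing except death;
- `dead` — absorbing, zero cost and utility.

At the end of cycle 0, survivors split by the week-16 EASI-75 response
probability (0.477 dupilumab, 0.133 SC). Dupilumab responders exit to
`no_response` at the cycle-converted 6.3%/year discontinuation rate; SC
responders relapse at 0.367 per cycle (the table-of-record value; a 0.658
variant can be set in a config). Death competes multiplicatively
(independent risks) with these exits at the age-specific cycle probability.
Transitions occur at cycle end; costs and QALYs accrue on cycle-start
occupancy with **no half-cycle correction** — a stated convention, chosen
for determinism.

During cycle 0 the whole cohort accrues the no-response utility and
healthcare cost (response status is unknown until week 16); the dupilumab
arm accrues 26/3 + 1 drug units — the extra unit covers the 600 mg loading
dose (600 mg = 2 × 300 mg replacing the first regular dose) — and the
one-time injection-site-reaction cost (rate × per-episode cost).
Conjunctivitis costs recur every maintenance cycle as occupancy × rate ×
annual cost × cycle length, at on-treatment rates for dupilumab responders
and supportive-care rates otherwise.

The cohort recursion has a closed form (state occupancies are products of
per-cycle survival and persistence factors), and is implemented as
vectorised cumulative products; occupancy conservation and monotonicity of
the dead state are asserted on every run.

## Parameters

All costs are 2021 KRW. Headline inputs (see `parameters.base_case()` for
the full registry, including every PSA distribution):

| parameter | value | unit / note |
|---|---|---|
| week-16 response, dupilumab / SC | 0.477 / 0.133 | Beta(218,239) / Beta(61,399) |
| annual discontinuation | 0.063 | Beta(24,357), converted per cycle |
| SC relapse per cycle | 0.367 | Beta(40,69) |
| healthcare cost, no-response / response | 1,058,567 / 522,041 | KRW per cycle, Gamma |
| utilities dup no-resp / resp | 0.63 / 0.89 | Gamma(SE 0.015 / 0.024), truncated to [0,1] |
| utilities SC no-resp / resp | 0.61 / 0.86 | Gamma(SE 0.016 / 0.046) |
| unit price (300 mg) | 710,000 | KRW, fixed (decision variable) |
| doses per year | 26 | q2w; annual drug cost 18,460,000 KRW |
| discount rate | 0.045 | per year, costs and QALYs |

Adverse-event treatment costs use Gamma distributions with SE = 10% of the
mean. Utilities are sampled from the Gamma specifications as listed and
truncated to [0, 1] at sampling time. The unit price, dosing, discount rate
and time structure carry no distribution.

## Background mortality

The packaged life table is Gompertz–Makeham: annual death probability
`q(x) = 1 − exp(−(a + b·e^{c·x}))` with a = 1e-4, b = 1e-5, c = 0.10,
capped at 1 and forced to 1 at the terminal age 110. These constants give a
remaining life expectancy at age 38 of ≈ 48.5 years, in line with recent
Korean unisex life tables; the modal age at death is ≈ 92. What the
synthetic table does **not** emulate: infant/young-adult mortality
structure (irrelevant for a cohort starting at 38), sex-specific rates, and
year-over-year mortality improvement. Absolute lifetime outcomes (total
QALYs, ICER levels) therefore differ from what the authors' unpublished
national table would give, by a few percent; relative quantities — the
EPED-induced percentage ICER change, the value-based-price ratio,
acceptability *changes* — are essentially life-table-invariant, and tests
distinguish the two classes accordingly. A real table can be supplied as a
two-column CSV (`age,qx`, contiguous integer ages, terminal q = 1); annual
probabilities are looked up by the floor of the fractional age and
converted by `1 − (1 − q)^{1/3}` (constant hazard within the year of age).

## Economics

Discounting is discrete at each cycle's start time, `(1+r)^{−t/3}`.
Incremental quantities take dupilumab + SC as the intervention. Drug cost
is exactly `Σ_t units_t · price_t · disc_t`, which makes incremental cost
affine in the unit price; the value-based price at willingness-to-pay λ is
therefore closed-form, `P* = (λ·ΔQ − ΔC_nondrug)/U_eff` with
`U_eff = Σ_t units_t · m_t · disc_t` (m_t the policy multiplier), and a
bisection solver cross-checks it to 1 KRW. Two exact consequences are
tested: the pre/post-EPED drug-cost difference equals
`(1 − factor) · price · (discounted units after entry)`, and the
post/pre value-based-price ratio `U_pre/U_post` is identical across all
thresholds. A zero incremental QALY raises an explicit degenerate-
comparison error rather than returning an ICER; dominance-quadrant results
are flagged.

## EPED price schedules

The cut applies from the first cycle whose start time is ≥ the entry time
T\* (for T\* = 10.3 y and 4-month cycles, cycle 31); the straddling cycle
is not prorated — the rule keeps schedules piecewise-constant and tests
deterministic, and the choice shifts results by well under 1% of drug
cost. The chemical rule holds 0.70 for start times in [T\*, T\*+1) and
0.535 after; the first generic's own 59.5% year-one price is recorded but
never applied because patients are assumed not to switch products. No
price erosion beyond the mandated cut is modelled, and the comparator has
no drug price.

## Probabilistic sensitivity analysis

1000 draws by default. Both policy settings are evaluated on the same
sampled parameter set (common random numbers), matching a paired
cost-effectiveness scatter and guaranteeing, draw by draw, that the price
cut can only increase net monetary benefit — hence the post-EPED CEAC
dominates the pre-EPED CEAC pointwise. An unpaired variant is available
for comparison. The CEAC grid runs 0–100M KRW in 1M steps with the four
named thresholds (1-GDP 40,052,159; anticancer 45,320,000; rare-disease
38,400,000; general 17,170,000 KRW/QALY) inserted exactly. Sampling is
fully reproducible under a fixed seed. The test suite checks convergence
of the PSA means to the deterministic evaluation at 4,000 draws within
3 Monte Carlo standard errors (or 2% if larger) — a problem size chosen to
keep the default test run brief while leaving Monte Carlo error well below
the tolerance.

## One-way sensitivity analysis

Each distributed input moves to the 2.5th/97.5th percentile of its
distribution ("95% interval" — the inputs have no separately published
confidence intervals). The default outcome is the EPED-induced ICER change
(post − pre); a config switch targets the plain ICER. Utility percentiles
outside [0, 1] are clamped and flagged. Because the ICER change equals
−(drug-cost saving)/ΔQ, inputs that touch neither post-entry drug units
nor ΔQ — per-state healthcare costs, adverse-event rates and costs —
produce (near-)zero bars, while the state utilities dominate; the two
no-response utilities carry the most leverage. Bars are sorted by
descending width, ties broken alphabetically.

## Scenarios

The standard grid: entry at 5, 7 and 12 years; the chemical-type cut;
30- and 20-year horizons (hard truncation of the cycle loop, no terminal-
state valuation); a 3% discount rate; and the relaxed EASI-50 response
criterion. EASI-50 response probabilities must be supplied explicitly
(they come from trial data and have no defensible default); running that
scenario without them is an error, not a silent fallback.

## Known limitations

- The synthetic life table shifts absolute outcomes relative to any
  specific national table (see above); use `--lifetable` for calibrated
  absolute results.
- No treatment switching (to biosimilars or next-line therapy), no
  risk-sharing clawback, no indirect or emollient costs, no EVPI.
- The 4-month cycle is treated as exactly 1/3 year; week-16 quantities are
  mapped onto it without re-scaling.
- Cycle-0 accrual assigns the whole cohort the no-response profile; a
  mixture convention would raise the incremental QALY by ~0.03.
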