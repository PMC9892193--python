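# Methods

## The nitrogen balance as a biomass proxy

The method rests on one assumption: in the cathode compartment of a
continuously fed, reducing bioelectrochemical reactor, assimilation into
biomass is the only reaction involving elemental nitrogen. Nitrogen then
behaves as a conserved tracer, and the gap between nitrogen fed and nitrogen
leaving (dissolved in the filtrate plus carried by suspended cells) must be
nitrogen locked into biomass retained in the system — overwhelmingly the
biofilm on the electrode. A nitrogen balance is preferred over a carbon
balance because CO₂ inflow and outflow are enormous compared with carbon
accumulation in biomass, and the signal would drown in those terms.

Per sampling interval the retained amount is
Δn_N = F·(c_N,in − c_N-aq,out − c_N-pX,out)·Δt. We orient the balance so
that retention is positive and compute
n_X,T = n_X,0 + (Σ Δn_N)/ν_N,X. The same balance is sometimes written with
the opposite sign convention (biomass as minus the accumulated dissolved-N
change); the orientation used here makes the growth direction explicit and
is asserted by the conservation test (import = export + retention to
machine precision).

Negative increments are meaningful, not errors: when the outflow carries
more nitrogen than the feed supplies — observed late in long runs — the
balance attributes it to lysis of non-viable cells and EPS releasing soluble
nitrogen, and total biomass decreases.

## Parameters

| Parameter | Default | Units | Meaning / why this value |
|---|---|---|---|
| `v_tc` | 0.12 | L | catholyte volume of the bench-scale cell |
| `f_in` | 0.015 | L/d | 0.625 mL/h feed; HRT = 8 d |
| `c_n_in` | 7.478e-3 | mol-N/L | 0.4 g/L NH₄Cl; may be a step schedule for mid-run medium changes |
| `nu_nx` | 0.2 | mol-N/C-mol | N content of standard dry biomass CH₁.₈O₀.₅N₀.₂ |
| `mw_x` | 25.25 | g/C-mol | molar mass of that composition |
| `gamma_x` | 4.2 | e⁻/C-mol | degree of reduction of biomass with ammonium as N source |
| electrode | 7.35 / 7.35 / 1 | cm³ / cm² / cm | carbon-felt volume, projected area, thickness |
| `inoculum_g_per_l` | 0.46 | g/L | inoculated dry biomass; n_X,0 = 0.46·V/MW_X ≈ 2.19 mmol |

Electron counts per product mole follow 6n−4 for CnH2nO2 carboxylates
(acetate 8, butyrate 20, hexanoate 32); mass↔mole conversion uses free-acid
molar masses (60.05, 88.11, 116.16 g/mol). The Faraday constant is fixed at
96485 C/mol.

## Numerical choices

- **Increment rule.** Default is rectangular with end-of-interval
  concentrations: each measurement stands for the interval that produced it,
  with no look-ahead, matching integration over short sampling intervals. A
  trapezoidal option (`integration="trapz"`) averages both interval ends and
  is second-order accurate; on noiseless synthetic data it reduces the
  biomass error from ~1.6% to ~0.01% at 0.5-day sampling.
- **Dissolved-N holdup.** By default the change in dissolved nitrogen
  inventory (V_TC·Δc_N-aq) is neglected relative to retained nitrogen, the
  standard approximation for long runs. The `dissolved_holdup=True` option
  adds the correction; it matters most during rapid drawdown (mid-run errors
  up to ~50% without it on a 60-day synthetic run, <2% with it) and is used
  whenever the pipeline is validated against simulator ground truth.
- **Feed steps.** A piecewise-constant feed schedule is averaged exactly
  over any interval containing a step.
- **μ estimator.** Forward difference of n_X,T over each interval plus the
  planktonic washout term F·c_pX (biomass balance with no biomass in the
  feed), divided by midpoint biomass. The washout term can be switched off
  for a pure-accumulation estimate; with biofilm-dominated biomass the two
  differ by well under 1%. Optional centered rolling-mean smoothing is
  off by default.
- **Degenerate inputs.** Zero or negative midpoint biomass yields missing
  rates with a flag; transiently negative biofilm amounts (possible under
  noise) are reported as-is with a flag and excluded from the biofilm
  fraction, never silently clipped.
- **Calibration.** OLS with a free intercept; predictions are clamped at
  zero because the fitted intercept can be slightly negative. Several dated
  calibrations can be supplied; the nearest one fitted at or before the
  sample time applies, supporting re-calibration against OD drift.
- **FE accounting.** Net production counts outflow export plus catholyte
  accumulation. Biomass is included with γ_X = 4.2 e⁻/C-mol (configurable),
  and gross biomass formation (net change plus planktonic export) carries
  the electron count, consistent with how the simulator generates current.

## The synthetic reactor

The simulator exists to give every pipeline stage a known ground truth. It
is a well-mixed CSTR with an attached biofilm compartment:

- biofilm: dn_bX/dt = (μ_b − k_det − k_dec)·n_bX with
  μ_b = μ_max·c_N/(K_N+c_N)·(1 − n_bX/n_bX,max) — Monod limitation on
  nitrogen reproduces the near-depletion episode during fast colonization;
  the logistic space term reproduces the biomass plateau after the electrode
  is fully colonized;
- planktonic: gains detached cells, grows at μ_b, washes out at F/V;
- dissolved N: fed and washed by the flow, consumed by gross growth, and
  returned by decay (lysis) — so late in a run with active decay the
  reactor nitrogen can exceed the feed concentration;
- products: formed at prescribed biomass-specific rates q_p (C-mol basis,
  optionally delayed by a lag or gated on a precursor titer to mimic chain
  elongation thresholds), washed out at F/V;
- current: exactly the stoichiometric electron demand of product formation
  plus biomass growth, so Faradaic efficiency closes at 100% by
  construction and closure is a test, not a fit.

Default kinetics (μ_max = 0.15 d⁻¹, K_N = 0.5 mmol/L, n_bX,max = 20 mmol,
k_det = 0.001 d⁻¹, k_dec = 0, q_p totalling 0.2 mol-C·mol-X⁻¹·d⁻¹ across
acetate/butyrate/hexanoate) are chosen so the simulated run reproduces the
qualitative regimes reported for biofilm-based MES at these operating
conditions: μ rising to ~0.13 d⁻¹ after a short lag and falling below
0.01 d⁻¹ as space runs out, biomass plateauing in the tens of mmol, >99% of
biomass as biofilm once colonized, and steady titers of a few g/L. The
detachment rate is set low enough that suspended cells are ~1% of total
biomass at steady state, matching the biofilm-dominated partition the
method was designed for.

Observation noise is multiplicative Gaussian, truncated at zero, with a
mandatory seed; OD600 is generated by inverting the calibration line, so
calibration and simulation are exactly consistent. `observe()` re-samples
noisy measurement tables from one ODE solve, which keeps replicate studies
(e.g. 50 noise seeds) cheap.

What the simulator does **not** emulate: spatial structure of the biofilm
(porosity gradients, mass-transfer limitation), pH and charge transport,
community composition shifts, EPS nitrogen pools, precipitation of
N-containing salts, and parasitic currents (H₂ slip). Passing tests
therefore demonstrate that the estimation machinery is correct and
well-conditioned under the stated observation model — not that the method's
biological assumptions hold in any particular real reactor.

## Integration and solver settings

ODEs are integrated with LSODA at rtol 1e-9 / atol 1e-12, piecewise across
known discontinuities (lag end, feed steps). Ground truth is reported on a
0.01-day grid by default; the nitrogen-closure residual on that grid is
below 1e-6 of cumulative feed nitrogen (typically ~1e-8 relative). Test and
validation runs use a 60-day horizon at 0.1–0.5-day sampling (the long
steady-state check uses 120 days at a 0.05-day solver step), sizes at which
the full suite completes in well under a minute.

## Known limitations

- One calibration line is assumed valid across its window; OD-to-nitrogen
  drift within a window biases the (small) planktonic term.
- Nitrogen in EPS and in retained non-viable cells is counted as live
  biomass, so q-values and μ are lower bounds in mature biofilms.
- The method cannot distinguish biofilm loss from lysis-driven N release
  within one interval; both appear as negative growth.
- Rates are interval averages; features faster than the sampling interval
  (twice-weekly in practice) are invisible.
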