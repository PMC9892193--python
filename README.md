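# mesbalance

Operando quantification of biofilm and planktonic biomass in continuously
operated bioelectrochemical reactors, using only routine measurements: total
dissolved nitrogen (TN) in the filtrate, optical density (OD600) of the
broth, product concentrations, and cathodic current. From the biomass
trajectory the package derives the biomass-specific rates that let you judge
the microbial catalyst itself rather than the reactor around it.

## Who this is for

In microbial electrosynthesis (MES) and other biofilm-based microbial
electrochemical technologies, most of the catalyst lives as a biofilm inside
a 3D electrode where it cannot be weighed, counted, or imaged without
destroying the experiment. Performance is therefore usually reported per
electrode area or electrolyte volume — numbers that say little about how
active the microbes are. This package implements a non-destructive
nitrogen-balance method that partitions biomass between biofilm and
suspension at every sampling point of a continuous run, so that
biomass-specific production rates (q-values) and the specific growth rate
(μ) can be tracked over time.

## The method

Nitrogen is a strict tracer for biomass: in a reducing cathode compartment
assimilation into cells is the only relevant nitrogen reaction, so over a
sampling interval Δt the nitrogen retained in the compartment is

    Δn_N = F·(c_N-aq,in − c_N-aq,out − c_N-pX,out)·Δt

where F is the flow (L/d), c_N-aq,out the measured dissolved N in the 0.2 µm
filtrate, and c_N-pX,out the nitrogen carried by suspended cells, obtained
from a linear OD600 calibration (c_N-pX = a·OD + b). Summing increments and
dividing by the biomass nitrogen content ν_N,X (0.2 mol-N per C-mol for
standard biomass CH₁.₈O₀.₅N₀.₂) gives the total biomass amount

    n_X,T(t) = n_X,0 + Σ Δn_N / ν_N,X

Planktonic biomass follows directly from the calibration
(c_pX = c_N-pX/ν_N,X), and biofilm biomass is the remainder
n_bX = n_X,T − n_pX. Rates follow from the component mass balance
dn_i/dt = F·c_i,in − F·c_i,out + r_i·V_TC and the q-value definition
q_i = r_i·V_TC·C_i/n_X,T (C-mol basis; acetate 2, butyrate 4, hexanoate 6
carbons). Faradaic efficiency is the electron recovery
FE% = 100·F_const·(Σ n_i·e_i + n_X·γ_X)/Q_T with the trapezoidal charge
integral Q_T.

A built-in synthetic reactor (Monod growth on nitrogen, logistic space
limitation on the electrode, detachment, decay with nitrogen recycling,
product formation at prescribed q_p, and stoichiometrically exact current)
provides ground truth for validating every stage.

## Worked example

```python
from mesbalance import MESBalanceModel, ReactorConfig, SimulationParams, simulate

cfg = ReactorConfig()                      # 0.12 L, HRT 8 d, carbon-felt cathode
truth, samples = simulate(cfg, SimulationParams(seed=42, noise=0.03))
res = MESBalanceModel(samples, cfg).fit()
print(res.summary())
```

```
Nitrogen-balance biomass estimation
===================================================
Samples:   121    span: 0.0-60.0 d
Catholyte volume: 0.12 L   flow: 0.015 L/d   HRT: 8 d
nu_N,X: 0.2 mol-N/C-mol   MW_X: 25.25 g/C-mol
---------------------------------------------------
Final total biomass:       18.773 mmol
Final planktonic:          0.1689 mmol
Final biofilm:             18.604 mmol
Final biofilm fraction:     99.10 %
Biofilm packing:            2.531 mmol/cm^3 (19.5% of theoretical)
mu (peak / final):         0.1269 / 0.0080 1/d
q_p total (final):         0.2702 mol-C/C-mol/d
Faradaic efficiency:       100.53 %
===================================================
```

Reading the output: after 60 days of simulated colonization the electrode
holds ~18.6 mmol of biomass as biofilm (99% of the total — suspended cells
are a rounding error once the felt is colonized), the specific growth rate
peaked at 0.13 d⁻¹ during early colonization and has fallen to 0.008 d⁻¹ as
space runs out, the community produces 0.27 mol of product carbon per C-mol
of biomass per day, and essentially all cathodic charge is recovered in
products plus biomass.

The same pipeline runs from the shell on CSV inputs:

```
mesbalance simulate --scenario growth_plateau --seed 1 --outdir fixtures
mesbalance run fixtures/growth_plateau/measurements.csv \
    --config fixtures/growth_plateau/config.yaml \
    --calibration fixtures/growth_plateau/calibration.csv \
    --outdir results
```

## Layout

- `mesbalance.calibration` — OD600 → planktonic-nitrogen line (OLS, dated sets)
- `mesbalance.balance` — nitrogen-balance integration and biomass partition
- `mesbalance.rates` — volumetric rates, q-values, specific growth rate
- `mesbalance.electro_kpi` — charge, Faradaic efficiency, KPI normalizations
- `mesbalance.synthetic_reactor` — ODE reactor simulator and fixtures
- `mesbalance.model` — `MESBalanceModel` / `MESBalanceResults` front end
- `mesbalance.cli` — `mesbalance` command-line interface
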