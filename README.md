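# ambuecon

Willingness-to-pay survey analysis and break-even scenario modelling for
ambulance operations in low-resource settings.

Many low-resource countries have no prehospital emergency service, and a
donated ambulance fleet only survives if its running costs can be recovered
locally. `ambuecon` implements the economic analysis behind a sustainable
field-to-hospital transport service, built around a three-month pilot
operation in Kinshasa (DR Congo, 2013): stated willingness-to-pay (WTP)
elicited with the open-ended contingent valuation method from four
stakeholder groups (patients, policemen, hospital staff, ambulance
personnel), weighted-rank scoring of service-need areas, pay-service
preference cross-tabulation, and a linear annual cost–revenue model solved
for the break-even user charge under 24 operator/crew/payment scenarios.

## The model

With `x_i` daily operations of service type `i` per ambulance, `y_i` the
user charge per operation, and `z` ambulances, over a year of `D = 365`
days:

```
revenue     = D · z · Σ_i x_i y_i
expenditure = [ K/T + L + D · v · Σ_i x_i ] · z + C + e
```

where `K/T` is straight-line depreciation of the vehicle/equipment capital
(100,000 USD over 10 years), `L` the annual crew labor per ambulance
(salaried: 12 months × monthly salary × 3 shifts per slot; incentive crews
are paid per operation instead), `v = 5.26` USD the variable cost per
operation (fuel 1.58 + supplies/maintenance 3.68), `C` the dispatch
control-center labor (12 × 250 × 6 = 18,000 USD/yr, carried only by an
operator that runs its own center), and `e` a residual annual cost
(default 0). The break-even point (BEP) sets revenue = expenditure and is
solved in closed form for the field-to-hospital charge `y*`, pricing the
other services at the mean WTP of the operator's own constituency. A
negative `y*` means those services already yield net income.

The package ships the canonical 24 scenarios — independent operator
(salaried crews, own control center), hospital organization (physician
crews, salaried or incentive), police organization (EMT crews, no
physician, hence no home visits) — plus an incentive-rate inversion (the
per-operation pay rates 0.56/0.28/0.14 USD for physician/nurse/driver are
recovered from the published full-rate incentive charges by solving a
linear system) and a subsidy variant that re-solves a scenario with chosen
cost components externally funded.

A synthetic-data generator reproduces the survey's statistical structure
(zero-truncated normal WTP per group × service, sequential
without-replacement rank triples, per-group preference draws, a multinomial
dispatch log), so the whole pipeline is testable without field data.

## Worked example

```
$ ambuecon scenarios | head -4
   operator                                                 crew  scenario       service_type  daily_rate_pct  ops_per_day  charge        op_cost classification
independent  3-crew physician model (physician + nurse + driver)         1  field-to-hospital           100.0         12.0   22.27          22.27           cost
independent  3-crew physician model (physician + nurse + driver)         2  field-to-hospital            50.0          6.0  -32.15 32.15 (income)         income
independent  3-crew physician model (physician + nurse + driver)         2  hospital-to-hospital        25.0          3.0   66.61          66.61 charged at WTP
```

Scenario 1 (independent operator, salaried physician+nurse+driver crew,
12 field runs/day) must charge 22.27 USD per transport to break even:
per ambulance, 10,000 capital + 63,000 salaries + 1,500 control-center
share + 23,038.80 variable = 97,538.80 USD/yr over 4,380 annual runs.
Scenario 2 halves the field rate and sells interhospital transfers at
66.61 and home visits at 86.77 USD (the ambulance personnel's mean WTP);
those alone overshoot costs, so the field service could run free with a
32.15 USD surplus per run — the `(income)` marker.

```
$ ambuecon subsidy 16
scenario 16: charge -52.24 -> -67.33 with ['variable', 'vehicle_capital'] subsidized
```

The hospital-based 2-crew physician incentive model (scenario 16) already
yields 52.24 USD per field run; with vehicle and variable costs covered by
external aid, the surplus rises to 67.33 USD.

`ambuecon synth | needs | prefs | wtp | report` generate synthetic data and
replicate the survey-side tables; `ambuecon report` writes the full bundle
(CSV tables, pilot summary, JSON manifest of every parameter).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the scenario engine from scratch — enumerating the 24
configurations, deriving charges from the WTP means and incentive rates,
and solving each break-even — and writes the headline break-even charges
(scenarios 1, 7, 2, 10, 16, 22, 24) and the subsidized scenario-16 surplus
magnitude as JSON.

See `docs/methods.md` for modelling assumptions, derived constants, and
known limitations.
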