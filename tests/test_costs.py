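"""Cost-model tests: revenue/expenditure arithmetic, break-even solving,
feasible-region enumeration, parameter serialization."""

import dataclasses

import pytest

from ambuecon import (
    ChargeSchedule,
    ConfigError,
    CostParameters,
    FleetConfig,
    PaymentMode,
    Role,
    ServiceMix,
    ServiceType,
    annual_expenditure,
    annual_revenue,
    breakeven_charge,
    feasible_region,
)
from ambuecon.scenarios import crew_2_physician, crew_3_physician, crew_2_emt

FIELD = ServiceType.FIELD_TO_HOSPITAL
INTER = ServiceType.HOSPITAL_TO_HOSPITAL
HOME = ServiceType.HOME_VISIT


@pytest.fixture()
def fleet():
    return FleetConfig(n_ambulances=12, ops_capacity_per_ambulance_per_day=12)


def brute_force_revenue(mix, charges, fleet, params):
    """Day-by-day accumulation oracle, independent of the closed form."""
    total = 0.0
    for _day in range(params.days_per_year):
        for _amb in range(fleet.n_ambulances):
            for s in ServiceType:
                total += mix.get(s) * charges.get(s)
    return total


def brute_force_expenditure(crew, mix, fleet, params):
    """Component-by-component accumulation oracle for salaried crews."""
    total = params.error_cost_e
    if fleet.control_center_shared:
        for _month in range(12):
            total += (
                params.monthly_salary[Role.TELEPHONE_OPERATOR]
                * params.n_operators_control_center
            )
    for _amb in range(fleet.n_ambulances):
        total += params.vehicle_capital / params.depreciation_years
        for _month in range(12):
            for role, count in crew.slots:
                total += params.monthly_salary[role] * count * params.shifts_per_day
        for _day in range(params.days_per_year):
            total += params.variable_per_op * mix.total
    return total


def test_revenue_zero_mix_is_zero(fleet, params):
    mix = ServiceMix({s: 0.0 for s in ServiceType})
    assert annual_revenue(mix, ChargeSchedule({}), fleet, params) == 0.0


def test_revenue_worked_example(params):
    """One ambulance doing 3 interhospital + 3 home visits a day at the
    ambulance-personnel WTP means earns 167,951.10 USD/year."""
    fleet = FleetConfig(n_ambulances=1, ops_capacity_per_ambulance_per_day=12)
    mix = ServiceMix({INTER: 3, HOME: 3})
    charges = ChargeSchedule({INTER: 66.61, HOME: 86.77})
    assert annual_revenue(mix, charges, fleet, params) == pytest.approx(167951.10)


def test_revenue_linear_in_fleet_size(params):
    mix = ServiceMix({FIELD: 5})
    charges = ChargeSchedule({FIELD: 20.0})
    r1 = annual_revenue(mix, charges, FleetConfig(1, 12), params)
    r2 = annual_revenue(mix, charges, FleetConfig(2, 12), params)
    assert r2 == pytest.approx(2 * r1)


def test_revenue_and_expenditure_match_brute_force_oracle(rng):
    """Linearity in every x_i, y_i and z: 1,000 random parameter draws agree
    with a day-by-day / component-by-component accumulation oracle."""
    crew = crew_3_physician()
    for _ in range(1000):
        params = CostParameters(
            vehicle_capital=float(rng.uniform(0, 200_000)),
            depreciation_years=float(rng.uniform(1, 20)),
            fuel_per_op=float(rng.uniform(0, 5)),
            supplies_maintenance_per_op=float(rng.uniform(0, 5)),
            error_cost_e=float(rng.uniform(0, 1000)),
        )
        fleet = FleetConfig(
            n_ambulances=int(rng.integers(1, 6)),
            ops_capacity_per_ambulance_per_day=24,
            control_center_shared=bool(rng.integers(0, 2)),
        )
        mix = ServiceMix(
            {s: float(rng.uniform(0, 8)) for s in ServiceType}
        )
        charges = ChargeSchedule(
            {s: float(rng.uniform(0, 100)) for s in ServiceType}
        )
        assert annual_revenue(mix, charges, fleet, params) == pytest.approx(
            brute_force_revenue(mix, charges, fleet, params), rel=1e-9
        )
        assert annual_expenditure(crew, mix, fleet, params).total == pytest.approx(
            brute_force_expenditure(crew, mix, fleet, params), rel=1e-9
        )


def test_expenditure_itemization_full_rate(fleet, params):
    """Per-ambulance share at full rate: 10,000 capital + 63,000 salaried
    labor + 1,500 control-center share + 23,038.80 variable = 97,538.80."""
    mix = ServiceMix({FIELD: 12})
    breakdown = annual_expenditure(crew_3_physician(), mix, fleet, params)
    z = fleet.n_ambulances
    assert breakdown.capital / z == pytest.approx(10_000)
    assert breakdown.labor / z == pytest.approx(63_000)
    assert breakdown.control_center / z == pytest.approx(1_500)
    assert breakdown.variable / z == pytest.approx(23_038.80)
    assert breakdown.total / z == pytest.approx(97_538.80)


def test_expenditure_capital_only(params):
    fleet = FleetConfig(3, 12, control_center_shared=False)
    mix = ServiceMix({s: 0.0 for s in ServiceType})
    crew = crew_2_emt(PaymentMode.INCENTIVE_PER_OPERATION)  # no ops, no pay
    breakdown = annual_expenditure(crew, mix, fleet, params)
    assert breakdown.total == pytest.approx(3 * 10_000)


def test_nurse_salary_gap_between_crews(fleet, params):
    mix = ServiceMix({FIELD: 12})
    three = annual_expenditure(crew_3_physician(), mix, fleet, params).total
    two = annual_expenditure(crew_2_physician(), mix, fleet, params).total
    per_ambulance_gap = (three - two) / fleet.n_ambulances
    assert per_ambulance_gap == pytest.approx(12 * 500 * 3)  # one nurse slot


def test_breakeven_self_consistency(fleet, params):
    """Plugging the solved charge back in balances the books."""
    mix = ServiceMix({FIELD: 6, INTER: 3, HOME: 3})
    fixed = ChargeSchedule({INTER: 66.61, HOME: 86.77})
    y = breakeven_charge(FIELD, crew_3_physician(), mix, fixed, fleet, params)
    rev = annual_revenue(mix, fixed.with_charge(FIELD, y), fleet, params)
    exp = annual_expenditure(crew_3_physician(), mix, fleet, params).total
    assert abs(rev - exp) < 0.005 * params.days_per_year


def test_breakeven_fixed_point(fleet, params):
    """If existing charges exactly cover costs with the solved service at c,
    the solver returns c."""
    mix = ServiceMix({FIELD: 12})
    exp = annual_expenditure(crew_3_physician(), mix, fleet, params).total
    c = exp / (params.days_per_year * fleet.n_ambulances * 12)
    y = breakeven_charge(
        FIELD, crew_3_physician(), mix, ChargeSchedule({}), fleet, params
    )
    assert y == pytest.approx(c)


def test_breakeven_monotone_in_fixed_charge_and_volume(fleet, params):
    mix = ServiceMix({FIELD: 6, INTER: 3})
    crew = crew_3_physician()

    def solve(inter_charge, inter_ops):
        m = ServiceMix({FIELD: 6, INTER: inter_ops})
        return breakeven_charge(
            FIELD, crew, m, ChargeSchedule({INTER: inter_charge}), fleet, params
        )

    assert solve(80.0, 3) < solve(66.61, 3) < solve(50.0, 3)
    assert solve(66.61, 4) < solve(66.61, 3) < solve(66.61, 2)


def test_breakeven_zero_costs_zero_charge(fleet):
    params = CostParameters(
        vehicle_capital=0.0,
        monthly_salary={r: 0.0 for r in Role},
        fuel_per_op=0.0,
        supplies_maintenance_per_op=0.0,
        error_cost_e=0.0,
    )
    mix = ServiceMix({FIELD: 12})
    y = breakeven_charge(
        FIELD, crew_3_physician(), mix, ChargeSchedule({}), fleet, params
    )
    assert y == pytest.approx(0.0)


def test_breakeven_requires_positive_ops(fleet, params):
    mix = ServiceMix({FIELD: 0.0, INTER: 3})
    with pytest.raises(ConfigError, match="zero daily operations"):
        breakeven_charge(
            FIELD, crew_3_physician(), mix, ChargeSchedule({}), fleet, params
        )


def test_feasible_region_margin_below_variable_cost(fleet, params):
    """A charge under the 5.26 USD variable cost can never recover any
    positive fixed cost."""
    charges = ChargeSchedule({FIELD: 5.00})
    region = feasible_region(crew_3_physician(), charges, fleet, params)
    assert region == set()


def test_feasible_region_at_published_charge(fleet, params):
    """At the full-rate break-even charge, the fleet breaks even exactly
    from 12 operations/day upward."""
    charges = ChargeSchedule({FIELD: 22.27})
    region = feasible_region(crew_3_physician(), charges, fleet, params)
    assert region == set(range(12, 25))


def test_feasible_region_zero_fixed_costs(fleet):
    params = CostParameters(
        vehicle_capital=0.0,
        monthly_salary={r: 0.0 for r in Role},
        error_cost_e=0.0,
    )
    fleet = dataclasses.replace(fleet, control_center_shared=False)
    charges = ChargeSchedule({FIELD: 10.0})  # above 5.26 variable cost
    region = feasible_region(crew_3_physician(), charges, fleet, params)
    assert region == set(range(0, 25))


def test_cost_parameters_yaml_round_trip(tmp_path, params):
    path = tmp_path / "params.yaml"
    params.save(path)
    assert CostParameters.load(path) == params
    jpath = tmp_path / "params.json"
    params.save(jpath)
    assert CostParameters.load(jpath) == params


@pytest.mark.parametrize(
    "kwargs",
    [
        {"vehicle_capital": -1.0},
        {"depreciation_years": 0.5},
        {"fuel_per_op": -0.1},
        {"monthly_salary": {Role.PHYSICIAN: -5.0}},
    ],
)
def test_cost_parameters_invariants(kwargs):
    with pytest.raises(ConfigError):
        CostParameters(**kwargs)


def test_capacity_enforced(params):
    fleet = FleetConfig(1, 12)
    mix = ServiceMix({FIELD: 13})
    with pytest.raises(ConfigError, match="capacity"):
        annual_revenue(mix, ChargeSchedule({FIELD: 1.0}), fleet, params)
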