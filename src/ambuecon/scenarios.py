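"""The 24 canonical ambulance-operation scenarios and their break-even
solutions.

A scenario fixes: the principal operator (independent team, hospital, or
police organization), the crew composition and payment mode, and the daily
service mix on a 12-operations/day ambulance. The operator determines two
things — whether the fleet pays for its own dispatch control center (only
the independent team does) and which stakeholder group's mean
willingness-to-pay prices the non-solved services (the operator's own
constituency: ambulance personnel, hospital staff, or policemen). Each
scenario is then solved for the break-even field-to-hospital user charge;
a negative solution means the other charged services already produce net
income.

Canonical structure (full rate = 12 ops/day; mixed physician scenarios run
field at 50% with 25% interhospital + 25% home visits; mixed EMT scenarios
run field at 75% with 25% interhospital, since a crew without a physician
cannot provide home-visit care):

    independent (1-8):  3/2-crew physician and 3/2-crew EMT, salaried
    hospital (9-16):    3/2-crew physician, salaried and incentive
    police (17-24):     3/2-crew EMT, salaried and incentive
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import defaults
from .costs import (
    ChargeSchedule,
    CostParameters,
    CrewModel,
    DEFAULT_INCENTIVES,
    ExpenditureBreakdown,
    FleetConfig,
    IncentiveSchedule,
    ServiceMix,
    annual_expenditure,
    annual_revenue,
    breakeven_charge,
)
from .enums import Group, Operator, PaymentMode, Role, ServiceType
from .records import ConfigError, ValidationError

__all__ = [
    "CrewModel",
    "IncentiveSchedule",
    "Scenario",
    "ScenarioResult",
    "enumerate_scenarios",
    "solve_scenario",
    "solve_all",
    "derive_incentive_schedule",
    "apply_subsidy",
    "rank_scenarios",
    "WTP_SOURCE_BY_OPERATOR",
    "SUBSIDIZABLE_COMPONENTS",
]

#: Which stakeholder group's WTP means price an operator's non-solved services.
WTP_SOURCE_BY_OPERATOR: dict[Operator, Group] = {
    Operator.INDEPENDENT: Group.AMBULANCE_PERSONNEL,
    Operator.HOSPITAL: Group.HOSPITAL_STAFF,
    Operator.POLICE: Group.POLICEMEN,
}

SUBSIDIZABLE_COMPONENTS = frozenset(
    {"vehicle_capital", "variable", "labor", "control_center"}
)


def _crew(roles: tuple[Role, ...], mode: PaymentMode, label: str) -> CrewModel:
    slots: dict[Role, int] = {}
    for r in roles:
        slots[r] = slots.get(r, 0) + 1
    return CrewModel(slots=tuple(slots.items()), payment_mode=mode, label=label)


def crew_3_physician(mode: PaymentMode = PaymentMode.SALARIED) -> CrewModel:
    suffix = " incentive" if mode is PaymentMode.INCENTIVE_PER_OPERATION else ""
    return _crew(
        (Role.PHYSICIAN, Role.NURSE, Role.DRIVER),
        mode,
        f"3-crew physician{suffix} model (physician + nurse + driver)",
    )


def crew_2_physician(mode: PaymentMode = PaymentMode.SALARIED) -> CrewModel:
    suffix = " incentive" if mode is PaymentMode.INCENTIVE_PER_OPERATION else ""
    return _crew(
        (Role.PHYSICIAN, Role.DRIVER),
        mode,
        f"2-crew physician{suffix} model (physician + driver)",
    )


def crew_3_emt(mode: PaymentMode = PaymentMode.SALARIED) -> CrewModel:
    suffix = " incentive" if mode is PaymentMode.INCENTIVE_PER_OPERATION else ""
    return _crew(
        (Role.NURSE, Role.NURSE, Role.DRIVER),
        mode,
        f"3-crew EMT{suffix} model (nurse + nurse + driver)",
    )


def crew_2_emt(mode: PaymentMode = PaymentMode.SALARIED) -> CrewModel:
    suffix = " incentive" if mode is PaymentMode.INCENTIVE_PER_OPERATION else ""
    return _crew(
        (Role.NURSE, Role.DRIVER),
        mode,
        f"2-crew EMT{suffix} model (nurse + driver)",
    )


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One operational configuration to solve for its break-even field charge."""

    scenario_id: int | str
    operator: Operator
    crew: CrewModel
    mix: ServiceMix
    wtp_source: Group
    fleet: FleetConfig

    def validate(self) -> None:
        for service, ops in self.mix.daily_ops.items():
            if ops > 0 and not self.crew.can_serve(service):
                raise ValidationError(
                    f"scenario {self.scenario_id}: crew {self.crew.label!r} "
                    f"cannot provide {service.value}"
                )
        if self.operator is not Operator.INDEPENDENT and self.fleet.control_center_shared:
            raise ValidationError(
                f"scenario {self.scenario_id}: {self.operator.value} operators reuse "
                "existing dispatch infrastructure (control_center_shared must be false)"
            )


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    """Solved scenario: itemized expenditure, revenue of the priced services,
    and the signed break-even field-to-hospital charge."""

    scenario_id: int | str
    operator: Operator
    crew_label: str
    mix: ServiceMix
    expenditure: ExpenditureBreakdown
    revenue_charged_services: float
    breakeven_field_charge: float
    classification: str  # "income" if the charge is negative else "cost"

    @property
    def field_rate_pct(self) -> float:
        total = self.mix.total
        return 100.0 * self.mix.get(ServiceType.FIELD_TO_HOSPITAL) / total if total else 0.0


def _mix(fleet: FleetConfig, field: float, inter: float = 0.0, home: float = 0.0) -> ServiceMix:
    cap = fleet.ops_capacity_per_ambulance_per_day
    return ServiceMix(
        {
            ServiceType.FIELD_TO_HOSPITAL: cap * field,
            ServiceType.HOSPITAL_TO_HOSPITAL: cap * inter,
            ServiceType.HOME_VISIT: cap * home,
        }
    )


def enumerate_scenarios(
    params: CostParameters | None = None,
    n_ambulances: int = 12,
    capacity: float = 12.0,
) -> list[Scenario]:
    """Build the 24 canonical scenarios.

    Mix shapes are fixed: full-rate field-only, or mixed — 50/25/25 with home
    visits for physician crews, 75/25 without for EMT crews.
    """
    shared = FleetConfig(n_ambulances, capacity, control_center_shared=True)
    hosted = FleetConfig(n_ambulances, capacity, control_center_shared=False)

    spec: list[tuple[Operator, CrewModel, tuple[float, float, float], FleetConfig]] = []
    # Independent team: salaried crews only, own control center.
    for crew_fn in (crew_3_physician, crew_2_physician):
        spec.append((Operator.INDEPENDENT, crew_fn(), (1.0, 0.0, 0.0), shared))
        spec.append((Operator.INDEPENDENT, crew_fn(), (0.5, 0.25, 0.25), shared))
    for crew_fn in (crew_3_emt, crew_2_emt):
        spec.append((Operator.INDEPENDENT, crew_fn(), (1.0, 0.0, 0.0), shared))
        spec.append((Operator.INDEPENDENT, crew_fn(), (0.75, 0.25, 0.0), shared))
    # Hospital organization: physician crews, salaried then incentive.
    for mode in (PaymentMode.SALARIED, PaymentMode.INCENTIVE_PER_OPERATION):
        for crew_fn in (crew_3_physician, crew_2_physician):
            spec.append((Operator.HOSPITAL, crew_fn(mode), (1.0, 0.0, 0.0), hosted))
            spec.append((Operator.HOSPITAL, crew_fn(mode), (0.5, 0.25, 0.25), hosted))
    # Police organization: EMT crews, salaried then incentive.
    for mode in (PaymentMode.SALARIED, PaymentMode.INCENTIVE_PER_OPERATION):
        for crew_fn in (crew_3_emt, crew_2_emt):
            spec.append((Operator.POLICE, crew_fn(mode), (1.0, 0.0, 0.0), hosted))
            spec.append((Operator.POLICE, crew_fn(mode), (0.75, 0.25, 0.0), hosted))

    scenarios = []
    for sid, (operator, crew, shape, fleet) in enumerate(spec, start=1):
        s = Scenario(
            scenario_id=sid,
            operator=operator,
            crew=crew,
            mix=_mix(fleet, *shape),
            wtp_source=WTP_SOURCE_BY_OPERATOR[operator],
            fleet=fleet,
        )
        s.validate()
        scenarios.append(s)
    assert len(scenarios) == 24
    return scenarios


def _charges_from_wtp(s: Scenario) -> ChargeSchedule:
    means = defaults.WTP_MEANS[s.wtp_source]
    return ChargeSchedule(
        {
            service: means[service]
            for service in ServiceType
            if service is not ServiceType.FIELD_TO_HOSPITAL and s.mix.get(service) > 0
        }
    )


def solve_scenario(
    s: Scenario,
    params: CostParameters | None = None,
    incentives: IncentiveSchedule | None = None,
) -> ScenarioResult:
    """Solve one scenario for its break-even field-to-hospital charge.

    Non-solved services are priced at the wtp_source group's mean stated WTP.
    """
    if params is None:
        params = CostParameters()
    if incentives is None:
        incentives = DEFAULT_INCENTIVES
    s.validate()
    charges = _charges_from_wtp(s)
    expenditure = annual_expenditure(s.crew, s.mix, s.fleet, params, incentives)
    revenue_charged = annual_revenue(s.mix, charges, s.fleet, params)
    y_star = breakeven_charge(
        ServiceType.FIELD_TO_HOSPITAL,
        s.crew,
        s.mix,
        charges,
        s.fleet,
        params,
        incentives,
    )
    return ScenarioResult(
        scenario_id=s.scenario_id,
        operator=s.operator,
        crew_label=s.crew.label,
        mix=s.mix,
        expenditure=expenditure,
        revenue_charged_services=revenue_charged,
        breakeven_field_charge=y_star,
        classification="income" if y_star < 0 else "cost",
    )


def solve_all(
    params: CostParameters | None = None,
    incentives: IncentiveSchedule | None = None,
) -> list[ScenarioResult]:
    """Solve all 24 canonical scenarios in id order."""
    return [solve_scenario(s, params, incentives) for s in enumerate_scenarios(params)]


#: Published full-rate (100% field) break-even charges of the four incentive
#: crews, the inputs from which the per-operation pay rates are recovered.
PUBLISHED_INCENTIVE_FULL_RATE_CHARGES: dict[int, float] = {
    13: 8.52,  # physician + nurse + driver
    15: 8.24,  # physician + driver
    21: 8.24,  # nurse + nurse + driver
    23: 7.96,  # nurse + driver
}


def derive_incentive_schedule(
    rows: list[tuple[CrewModel, float]] | None = None,
    params: CostParameters | None = None,
    capacity: float = 12.0,
    round_to_cents: bool = True,
) -> IncentiveSchedule:
    """Recover per-operation incentive rates from full-rate break-even charges.

    At 100% field service with no control-center cost, each published charge
    obeys charge = capital/(D * capacity) + variable_per_op + sum of the
    crew's per-op rates, a linear system in the (physician, nurse, driver)
    rates. Printed charges carry cent precision, so the recovered rates are
    rounded to the cent by default; with four rows and three unknowns the
    system is solved by least squares and a residual above half a cent on
    any row raises.
    """
    if params is None:
        params = CostParameters()
    if rows is None:
        by_id = {
            13: crew_3_physician(PaymentMode.INCENTIVE_PER_OPERATION),
            15: crew_2_physician(PaymentMode.INCENTIVE_PER_OPERATION),
            21: crew_3_emt(PaymentMode.INCENTIVE_PER_OPERATION),
            23: crew_2_emt(PaymentMode.INCENTIVE_PER_OPERATION),
        }
        rows = [
            (by_id[i], charge)
            for i, charge in PUBLISHED_INCENTIVE_FULL_RATE_CHARGES.items()
        ]
    base = params.annual_capital_per_ambulance / (
        params.days_per_year * capacity
    ) + params.variable_per_op
    roles = [Role.PHYSICIAN, Role.NURSE, Role.DRIVER]
    a = np.zeros((len(rows), len(roles)))
    b = np.zeros(len(rows))
    for i, (crew, charge) in enumerate(rows):
        for role, count in crew.slots:
            if role not in roles:
                raise ConfigError(f"no incentive unknown for role {role.value}")
            a[i, roles.index(role)] = count
        b[i] = charge - base
    rates, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < len(roles):
        raise ConfigError("incentive system is singular: crews do not span all roles")
    residual = a @ rates - b
    if np.abs(residual).max() > 0.005:
        raise ConfigError(
            f"incentive rates inconsistent with the given charges "
            f"(max residual {np.abs(residual).max():.4f} USD)"
        )
    if round_to_cents:
        rates = np.round(rates + 1e-12, 2)
    return IncentiveSchedule(per_op_incentive=dict(zip(roles, rates)))


def apply_subsidy(
    s: Scenario,
    subsidized: set[str],
    params: CostParameters | None = None,
    incentives: IncentiveSchedule | None = None,
) -> ScenarioResult:
    """Re-solve a scenario with named cost components externally subsidized.

    Components (any subset of ``SUBSIDIZABLE_COMPONENTS``) are set to zero:
    ``vehicle_capital`` (depreciation), ``variable`` (fuel +
    supplies/maintenance), ``labor`` (crew salaries or incentive pay), and
    ``control_center`` (dispatch-center staffing).
    """
    if params is None:
        params = CostParameters()
    if incentives is None:
        incentives = DEFAULT_INCENTIVES
    unknown = set(subsidized) - SUBSIDIZABLE_COMPONENTS
    if unknown:
        raise ConfigError(f"unknown subsidy component(s): {sorted(unknown)}")
    if "vehicle_capital" in subsidized:
        params = dataclasses.replace(params, vehicle_capital=0.0)
    if "variable" in subsidized:
        params = dataclasses.replace(params, fuel_per_op=0.0, supplies_maintenance_per_op=0.0)
    if "labor" in subsidized:
        params = dataclasses.replace(
            params,
            monthly_salary={
                **params.monthly_salary,
                Role.PHYSICIAN: 0.0,
                Role.NURSE: 0.0,
                Role.DRIVER: 0.0,
            },
        )
        incentives = IncentiveSchedule(
            per_op_incentive={r: 0.0 for r in incentives.per_op_incentive}
        )
    if "control_center" in subsidized:
        s = dataclasses.replace(
            s, fleet=dataclasses.replace(s.fleet, control_center_shared=False)
        )
    return solve_scenario(s, params, incentives)


def rank_scenarios(
    results: list[ScenarioResult],
    operator: Operator | None = None,
) -> list[ScenarioResult]:
    """Sort results by ascending break-even field charge (cheapest for the
    user first); ties broken by scenario id. Optionally filter by operator."""
    if operator is not None:
        results = [r for r in results if r.operator is operator]
    if not results:
        raise ValidationError("no scenario results to rank")

    def key(r: ScenarioResult):
        # canonical integer ids sort before custom string tags
        sid = r.scenario_id
        tie = (0, sid, "") if isinstance(sid, int) else (1, 0, str(sid))
        return (r.breakeven_field_charge, *tie)

    return sorted(results, key=key)
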