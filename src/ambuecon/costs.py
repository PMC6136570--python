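"""Linear annual cost-revenue model for an ambulance fleet.

Notation (per day unless stated): x_i is the number of operations of service
type i per ambulance, y_i the user charge per operation of type i, z the
fleet size. Over a year of D days,

    revenue      = D * z * sum_i x_i * y_i
    expenditure  = [ K / T  +  L  +  D * v * sum_i x_i ] * z  +  C  +  e

with K the vehicle/facility/equipment capital, T the straight-line
depreciation period (years), L the annual crew labor per ambulance
(salaried: 12 months * monthly salary * shift multiplier per slot;
incentive: per-operation rates * annual operations), v the variable cost
per operation (fuel + supplies/maintenance), C the control-center labor
(12 * operator salary * number of operators, charged once per fleet when the
operator runs its own dispatch center), and e a residual annual error cost.

The break-even charge for one service is the y* at which revenue equals
expenditure, holding the other services' charges fixed; the model is linear
so y* has a closed form. A negative y* means the other charged services
already more than cover costs — the service yields net income even free.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .enums import PaymentMode, Role, ServiceType
from .records import ConfigError


@dataclasses.dataclass(frozen=True)
class CostParameters:
    """Monetary constants of the model (USD). Defaults are the pilot
    study's stated costs for Kinshasa."""

    vehicle_capital: float = 100_000.0  # ambulance + facilities + equipment
    depreciation_years: float = 10.0
    monthly_salary: dict[Role, float] = dataclasses.field(
        default_factory=lambda: {
            Role.PHYSICIAN: 1_000.0,
            Role.NURSE: 500.0,
            Role.DRIVER: 250.0,
            Role.TELEPHONE_OPERATOR: 250.0,
        }
    )
    shifts_per_day: int = 3
    fuel_per_op: float = 1.58
    supplies_maintenance_per_op: float = 3.68
    n_operators_control_center: int = 6  # 2 phone lines x 3 shifts
    days_per_year: int = 365
    error_cost_e: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "vehicle_capital",
            "fuel_per_op",
            "supplies_maintenance_per_op",
            "error_cost_e",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.depreciation_years < 1:
            raise ConfigError("depreciation_years must be >= 1")
        if any(v < 0 for v in self.monthly_salary.values()):
            raise ConfigError("monthly_salary values must be >= 0")

    @property
    def variable_per_op(self) -> float:
        return self.fuel_per_op + self.supplies_maintenance_per_op

    @property
    def annual_capital_per_ambulance(self) -> float:
        return self.vehicle_capital / self.depreciation_years

    @property
    def annual_control_center_cost(self) -> float:
        return (
            12
            * self.monthly_salary[Role.TELEPHONE_OPERATOR]
            * self.n_operators_control_center
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["monthly_salary"] = {r.value: v for r, v in self.monthly_salary.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CostParameters":
        d = dict(d)
        if "monthly_salary" in d:
            d["monthly_salary"] = {
                Role(k): float(v) for k, v in d["monthly_salary"].items()
            }
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "CostParameters":
        """Read parameters from a YAML or JSON file (YAML parses both)."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclasses.dataclass(frozen=True)
class CrewModel:
    """An ambulance crew: role slots, compensation mode, display label."""

    slots: tuple[tuple[Role, int], ...]
    payment_mode: PaymentMode = PaymentMode.SALARIED
    label: str = ""

    def __post_init__(self) -> None:
        if not self.slots:
            raise ConfigError("crew needs at least one slot")
        for role, count in self.slots:
            if role is Role.TELEPHONE_OPERATOR:
                raise ConfigError("telephone operators staff the control center, not a crew")
            if count < 1:
                raise ConfigError(f"slot count for {role.value} must be >= 1")

    @property
    def has_physician(self) -> bool:
        return any(role is Role.PHYSICIAN for role, _ in self.slots)

    def can_serve(self, service: ServiceType) -> bool:
        """Crews without a physician cannot provide home-visit medical care."""
        return self.has_physician or service is not ServiceType.HOME_VISIT

    def monthly_salary_total(self, params: CostParameters) -> float:
        return sum(
            params.monthly_salary[role] * count for role, count in self.slots
        )


@dataclasses.dataclass(frozen=True)
class IncentiveSchedule:
    """Per-operation pay rates for incentive (pay-for-performance) crews."""

    per_op_incentive: dict[Role, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_op_incentive.values()):
            raise ConfigError("incentive rates must be >= 0")

    def per_op_for_crew(self, crew: CrewModel) -> float:
        try:
            return sum(
                self.per_op_incentive[role] * count for role, count in crew.slots
            )
        except KeyError as exc:
            raise ConfigError(f"no incentive rate for role {exc.args[0]}") from exc


#: Per-operation incentive rates recovered from the published full-rate
#: incentive charges; proportional 4:2:1 to monthly salaries. Re-derivable
#: with scenarios.derive_incentive_schedule.
DEFAULT_INCENTIVES = IncentiveSchedule(
    per_op_incentive={Role.PHYSICIAN: 0.56, Role.NURSE: 0.28, Role.DRIVER: 0.14}
)


@dataclasses.dataclass(frozen=True)
class ServiceMix:
    """Daily operations per ambulance by service type."""

    daily_ops: dict[ServiceType, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.daily_ops.values()):
            raise ConfigError("daily operation counts must be >= 0")

    @property
    def total(self) -> float:
        return sum(self.daily_ops.values())

    def get(self, service: ServiceType) -> float:
        return self.daily_ops.get(service, 0.0)

    def scaled_to_total(self, total: float) -> "ServiceMix":
        """Same mix shape, rescaled so daily ops sum to ``total``."""
        if self.total == 0:
            raise ConfigError("cannot rescale an all-zero mix")
        f = total / self.total
        return ServiceMix({s: v * f for s, v in self.daily_ops.items()})


@dataclasses.dataclass(frozen=True)
class ChargeSchedule:
    """User charge (USD) per operation by service type."""

    charge: dict[ServiceType, float]

    def get(self, service: ServiceType) -> float:
        return self.charge.get(service, 0.0)

    def with_charge(self, service: ServiceType, amount: float) -> "ChargeSchedule":
        return ChargeSchedule({**self.charge, service: amount})


@dataclasses.dataclass(frozen=True)
class FleetConfig:
    """Fleet size and capacity. ``control_center_shared`` is true when the
    operator runs its own dispatch center (its labor is then added once per
    fleet); hospitals and police reuse existing dispatch infrastructure."""

    n_ambulances: int = 12
    ops_capacity_per_ambulance_per_day: float = 12.0
    control_center_shared: bool = True

    def __post_init__(self) -> None:
        if self.n_ambulances < 1 or self.n_ambulances != int(self.n_ambulances):
            raise ConfigError("n_ambulances must be a whole number >= 1")
        if self.ops_capacity_per_ambulance_per_day < 1:
            raise ConfigError("ops capacity must be >= 1")


@dataclasses.dataclass(frozen=True)
class ExpenditureBreakdown:
    """Itemized annual expenditure (USD/year, whole fleet)."""

    capital: float
    labor: float
    variable: float
    control_center: float
    error: float

    @property
    def total(self) -> float:
        return self.capital + self.labor + self.variable + self.control_center + self.error

    def to_dict(self) -> dict[str, float]:
        return {
            "capital": self.capital,
            "labor": self.labor,
            "variable": self.variable,
            "control_center": self.control_center,
            "error": self.error,
            "total": self.total,
        }


def _check_capacity(mix: ServiceMix, fleet: FleetConfig) -> None:
    if mix.total > fleet.ops_capacity_per_ambulance_per_day + 1e-9:
        raise ConfigError(
            f"daily mix total {mix.total} exceeds capacity "
            f"{fleet.ops_capacity_per_ambulance_per_day} per ambulance"
        )


def annual_revenue(
    mix: ServiceMix,
    charges: ChargeSchedule,
    fleet: FleetConfig,
    params: CostParameters,
) -> float:
    """Fleet revenue over one year: D * z * sum_i x_i * y_i."""
    _check_capacity(mix, fleet)
    per_day = sum(mix.get(s) * charges.get(s) for s in ServiceType)
    return params.days_per_year * fleet.n_ambulances * per_day


def annual_expenditure(
    crew: CrewModel,
    mix: ServiceMix,
    fleet: FleetConfig,
    params: CostParameters,
    incentives: IncentiveSchedule | None = None,
) -> ExpenditureBreakdown:
    """Fleet expenditure over one year, itemized.

    Salaried crews cost 12 * monthly salary * shift multiplier per slot per
    ambulance regardless of workload; incentive crews are paid per operation
    and carry no base salary.
    """
    _check_capacity(mix, fleet)
    z = fleet.n_ambulances
    capital = params.annual_capital_per_ambulance * z
    annual_ops_per_amb = params.days_per_year * mix.total
    if crew.payment_mode is PaymentMode.SALARIED:
        labor = 12 * crew.monthly_salary_total(params) * params.shifts_per_day * z
    else:
        if incentives is None:
            incentives = DEFAULT_INCENTIVES
        labor = incentives.per_op_for_crew(crew) * annual_ops_per_amb * z
    variable = params.variable_per_op * annual_ops_per_amb * z
    control = params.annual_control_center_cost if fleet.control_center_shared else 0.0
    return ExpenditureBreakdown(
        capital=capital,
        labor=labor,
        variable=variable,
        control_center=control,
        error=params.error_cost_e,
    )


def breakeven_charge(
    solve_for: ServiceType,
    crew: CrewModel,
    mix: ServiceMix,
    fixed_charges: ChargeSchedule,
    fleet: FleetConfig,
    params: CostParameters,
    incentives: IncentiveSchedule | None = None,
) -> float:
    """Charge y* on ``solve_for`` at which annual revenue equals expenditure.

    The other services' charges stay at ``fixed_charges``. Negative output
    means those services already cover all costs (net income). Exact closed
    form: y* = (E / (D z) - sum_{i != s} x_i y_i) / x_s.
    """
    x_s = mix.get(solve_for)
    if x_s <= 0:
        raise ConfigError(
            f"cannot solve break-even charge for {solve_for.value}: zero daily operations"
        )
    expenditure = annual_expenditure(crew, mix, fleet, params, incentives).total
    other_daily = sum(
        mix.get(s) * fixed_charges.get(s) for s in ServiceType if s is not solve_for
    )
    per_amb_per_day = expenditure / (params.days_per_year * fleet.n_ambulances)
    return (per_amb_per_day - other_daily) / x_s


def feasible_region(
    crew: CrewModel,
    charges: ChargeSchedule,
    fleet: FleetConfig,
    params: CostParameters,
    mix_shape: ServiceMix | None = None,
    incentives: IncentiveSchedule | None = None,
    max_total: int = 24,
) -> set[int]:
    """Integer daily totals sum(x_i) in [0, max_total] at which the fleet
    breaks even or better, allocating operations proportionally to
    ``mix_shape`` (default: all field-to-hospital).

    The sweep covers the model's stated global constraint (at most 24
    operations/day) even when that exceeds the fleet's nominal per-ambulance
    capacity, so the full break-even frontier is visible.
    """
    if mix_shape is None:
        mix_shape = ServiceMix({ServiceType.FIELD_TO_HOSPITAL: 1.0})
    sweep_fleet = dataclasses.replace(
        fleet,
        ops_capacity_per_ambulance_per_day=max(
            fleet.ops_capacity_per_ambulance_per_day, float(max_total)
        ),
    )
    feasible = set()
    for total in range(max_total + 1):
        mix = (
            ServiceMix({s: 0.0 for s in mix_shape.daily_ops})
            if total == 0
            else mix_shape.scaled_to_total(total)
        )
        rev = annual_revenue(mix, charges, sweep_fleet, params)
        exp = annual_expenditure(crew, mix, sweep_fleet, params, incentives).total
        if rev >= exp:
            feasible.add(total)
    return feasible
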