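"""Synthetic survey and dispatch-log generator.

Emulates the statistical structure of the pilot study so every downstream
stage is testable without field data: per-group open-ended WTP amounts drawn
from a zero-truncated normal, rank triples drawn sequentially by place
without replacement, pay-service preferences drawn per group (with the
observed non-response rates), and a multinomial dispatch log over the pilot
window.

The zero-truncation is this module's own assumption — the study reports only
that elicitation was open-ended. Rejection sampling at zero biases the
sample mean upward relative to the configured (pre-truncation) mean whenever
the sd is large relative to the mean; recovery checks must therefore
compare against :func:`truncated_normal_mean`, not the raw configured mean.
"""

from __future__ import annotations

import dataclasses
import datetime
import math

import numpy as np
from scipy import stats

from . import defaults
from .enums import Group, NeedArea, ReportCategory, ServiceType
from .records import ConfigError, DispatchRecord, SurveyResponse

_PROB_TOL = 1e-9


def truncated_normal_mean(mean: float, sd: float) -> float:
    """Mean of a normal(mean, sd) conditioned on being >= 0.

    Closed form: mu + sd * phi(a) / (1 - Phi(a)) with a = -mu/sd. This is the
    population mean the generator's rejection sampler targets.
    """
    if sd == 0:
        return mean
    a = -mean / sd
    return mean + sd * stats.norm.pdf(a) / stats.norm.sf(a)


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic world.

    ``rank_place_probs`` maps each rank place (1, 2, 3) to a probability
    vector over need areas; triples are drawn place by place without
    replacement, renormalizing after each draw. ``category_mix`` is a
    probability vector over the exclusive dispatch categories.
    ``extra_patients_rate`` is the Poisson rate of patients beyond the first
    per report (default matches the pilot's 212 patients on 162 reports).
    """

    group_sizes: dict[Group, int]
    wtp_params: dict[tuple[Group, ServiceType], tuple[float, float]]
    rank_place_probs: dict[int, dict[NeedArea, float]]
    preference_probs: dict[Group, dict[ServiceType, float]]
    preference_response_rate: dict[Group, float]
    pilot_days: int = defaults.PILOT_DAYS
    total_reports: int = defaults.PILOT_TOTAL_REPORTS
    category_mix: dict[ReportCategory, float] = dataclasses.field(
        default_factory=lambda: {
            c: n / defaults.PILOT_TOTAL_REPORTS
            for c, n in defaults.PILOT_CATEGORY_COUNTS.items()
        }
    )
    extra_patients_rate: float = (
        (defaults.PILOT_TOTAL_PATIENTS - defaults.PILOT_TOTAL_REPORTS)
        / defaults.PILOT_TOTAL_REPORTS
    )
    pilot_start: datetime.date = defaults.PILOT_START
    seed: int = defaults.DEFAULT_SEED

    @classmethod
    def default(cls, seed: int = defaults.DEFAULT_SEED) -> "GeneratorConfig":
        """Configuration reproducing the pilot study's published structure."""
        rank_place_probs: dict[int, dict[NeedArea, float]] = {}
        for place in (1, 2, 3):
            col = {a: defaults.RANK_FREQS[a][place - 1] for a in NeedArea}
            total = sum(col.values())
            rank_place_probs[place] = {a: n / total for a, n in col.items()}
        preference_probs = {}
        for g, counts in defaults.PREFERENCE_FREQS.items():
            total = sum(counts)
            preference_probs[g] = {
                s: c / total for s, c in zip(ServiceType, counts)
            }
        return cls(
            group_sizes=dict(defaults.GROUP_SIZES),
            wtp_params=dict(defaults.WTP_PARAMS),
            rank_place_probs=rank_place_probs,
            preference_probs=preference_probs,
            preference_response_rate=dict(defaults.PREFERENCE_RESPONSE_RATE),
            seed=seed,
        )

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ConfigError(f"group_sizes[{g.value}] must be >= 0, got {n}")
        for key, (mean, sd) in self.wtp_params.items():
            if sd < 0:
                raise ConfigError(f"wtp_params[{key}] sd must be >= 0, got {sd}")
        for place, vec in self.rank_place_probs.items():
            _check_prob_vector(f"rank_place_probs[{place}]", vec.values())
        for g, vec in self.preference_probs.items():
            _check_prob_vector(f"preference_probs[{g.value}]", vec.values())
        for g, r in self.preference_response_rate.items():
            if not 0 <= r <= 1:
                raise ConfigError(
                    f"preference_response_rate[{g.value}] must be in [0, 1], got {r}"
                )
        if self.total_reports < 0:
            raise ConfigError(f"total_reports must be >= 0, got {self.total_reports}")
        if self.pilot_days < 1:
            raise ConfigError(f"pilot_days must be >= 1, got {self.pilot_days}")
        if self.total_reports:
            _check_prob_vector("category_mix", self.category_mix.values())
        if self.extra_patients_rate < 0:
            raise ConfigError(
                f"extra_patients_rate must be >= 0, got {self.extra_patients_rate}"
            )


def _check_prob_vector(name: str, values) -> None:
    values = list(values)
    if any(v < 0 for v in values):
        raise ConfigError(f"{name}: negative probability")
    if not math.isclose(sum(values), 1.0, abs_tol=_PROB_TOL):
        raise ConfigError(f"{name}: probabilities sum to {sum(values)}, not 1")


def _draw_wtp(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Rejection-sample normal(mean, sd) until non-negative; cents precision."""
    if sd == 0:
        return round(max(mean, 0.0), 2)
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return round(x, 2)


def _draw_ranks(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[NeedArea, ...]:
    chosen: list[NeedArea] = []
    for place in (1, 2, 3):
        probs = {
            a: p
            for a, p in cfg.rank_place_probs[place].items()
            if a not in chosen
        }
        areas = list(probs)
        weights = np.array([probs[a] for a in areas], dtype=float)
        if weights.sum() <= 0:  # point-mass configs can exhaust the support
            weights = np.ones(len(areas))
        weights = weights / weights.sum()
        chosen.append(areas[rng.choice(len(areas), p=weights)])
    return tuple(chosen)


def generate_survey(config: GeneratorConfig) -> list[SurveyResponse]:
    """Draw one :class:`SurveyResponse` per configured respondent.

    Deterministic for a fixed (config, seed): identical inputs yield an
    identical response list.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    responses: list[SurveyResponse] = []
    i = 0
    for group in Group:
        for _ in range(config.group_sizes.get(group, 0)):
            i += 1
            ranks = _draw_ranks(rng, config)
            preferred: ServiceType | None = None
            if rng.random() < config.preference_response_rate.get(group, 1.0):
                vec = config.preference_probs[group]
                services = list(vec)
                weights = np.array([vec[s] for s in services])
                preferred = services[rng.choice(len(services), p=weights)]
            wtp = {
                service: _draw_wtp(rng, mean, sd)
                for (g, service), (mean, sd) in config.wtp_params.items()
                if g == group
            }
            responses.append(
                SurveyResponse(
                    respondent_id=f"R{i:04d}",
                    group=group,
                    ranks=ranks,
                    preferred_service=preferred,
                    wtp=wtp,
                )
            )
    return responses


def generate_dispatch_log(config: GeneratorConfig) -> list[DispatchRecord]:
    """Draw a dispatch log: reports multinomial over days, one category and
    >= 1 patient each."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    if config.total_reports == 0:
        return []
    day_counts = rng.multinomial(
        config.total_reports, np.ones(config.pilot_days) / config.pilot_days
    )
    categories = list(config.category_mix)
    cat_weights = np.array([config.category_mix[c] for c in categories])
    records: list[DispatchRecord] = []
    i = 0
    for day, count in enumerate(day_counts):
        date = config.pilot_start + datetime.timedelta(days=day)
        for _ in range(count):
            i += 1
            category = categories[rng.choice(len(categories), p=cat_weights)]
            n_patients = 1 + int(rng.poisson(config.extra_patients_rate))
            records.append(
                DispatchRecord(
                    report_id=f"D{i:04d}",
                    date=date,
                    category=category,
                    n_patients=n_patients,
                )
            )
    return records


def make_pilot_log() -> list[DispatchRecord]:
    """Deterministic dispatch log reproducing the pilot's published totals.

    162 reports over the 89-day window (2013-09-18..2013-12-15), exclusive
    category counts 121/34/7 (traffic transports / other transports /
    non-transports) and 212 patients in total. Synthetic reconstruction: the
    study prints only these margins, so dates, category order and the
    placement of multi-patient reports are an arbitrary deterministic
    round-robin, not field data.
    """
    categories = [
        c
        for c, n in defaults.PILOT_CATEGORY_COUNTS.items()
        for _ in range(n)
    ]
    extra = defaults.PILOT_TOTAL_PATIENTS - defaults.PILOT_TOTAL_REPORTS
    records = []
    for i, category in enumerate(categories):
        date = defaults.PILOT_START + datetime.timedelta(days=i % defaults.PILOT_DAYS)
        records.append(
            DispatchRecord(
                report_id=f"P{i + 1:04d}",
                date=date,
                category=category,
                n_patients=2 if i < extra else 1,
            )
        )
    return records
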