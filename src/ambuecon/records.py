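"""Row-level record types and validation errors."""

from __future__ import annotations

import dataclasses
import datetime

from .enums import Group, NeedArea, ReportCategory, ServiceType


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(ValueError):
    """A record violates an invariant; the message identifies the record."""


@dataclasses.dataclass(frozen=True)
class SurveyResponse:
    """One respondent: group, ranked need areas, pay-service preference, WTP.

    ``ranks`` lists up to three pairwise-distinct need areas in rank order
    (1st place first). ``preferred_service`` is None when the respondent
    skipped the pay-service item; ``wtp`` holds the stated amount in USD per
    service type, omitting services left unanswered.
    """

    respondent_id: str
    group: Group
    ranks: tuple[NeedArea, ...]
    preferred_service: ServiceType | None = None
    wtp: dict[ServiceType, float] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if len(set(self.ranks)) != len(self.ranks):
            raise ValidationError(
                f"respondent {self.respondent_id!r}: duplicate need area in ranks {self.ranks}"
            )
        if not 0 <= len(self.ranks) <= 3:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: expected at most 3 ranks, got {len(self.ranks)}"
            )
        for service, amount in self.wtp.items():
            if amount < 0:
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: negative WTP {amount} for {service.value}"
                )


@dataclasses.dataclass(frozen=True)
class DispatchRecord:
    """One telephonic report from the pilot dispatch log."""

    report_id: str
    date: datetime.date
    category: ReportCategory
    n_patients: int = 1

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError(
                f"report {self.report_id!r}: n_patients must be >= 1, got {self.n_patients}"
            )
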