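"""CSV dialects for survey responses and dispatch logs.

Column contracts:

survey:   respondent_id, group, rank1, rank2, rank3, preferred_service,
          wtp_field, wtp_interhospital, wtp_homevisit
dispatch: report_id, date (ISO-8601), category, n_patients

Empty cells encode missing preference / missing WTP / missing rank.
"""

from __future__ import annotations

import csv
import datetime
from pathlib import Path

from .enums import Group, NeedArea, ReportCategory, ServiceType
from .records import DispatchRecord, SurveyResponse, ValidationError

SURVEY_COLUMNS = [
    "respondent_id",
    "group",
    "rank1",
    "rank2",
    "rank3",
    "preferred_service",
    "wtp_field",
    "wtp_interhospital",
    "wtp_homevisit",
]
DISPATCH_COLUMNS = ["report_id", "date", "category", "n_patients"]

_WTP_COLS = {
    ServiceType.FIELD_TO_HOSPITAL: "wtp_field",
    ServiceType.HOSPITAL_TO_HOSPITAL: "wtp_interhospital",
    ServiceType.HOME_VISIT: "wtp_homevisit",
}


def write_survey_csv(responses: list[SurveyResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_COLUMNS)
        for r in responses:
            ranks = [a.value for a in r.ranks] + [""] * (3 - len(r.ranks))
            row = [r.respondent_id, r.group.value, *ranks]
            row.append(r.preferred_service.value if r.preferred_service else "")
            for service in ServiceType:
                amount = r.wtp.get(service)
                row.append("" if amount is None else f"{amount:.2f}")
            writer.writerow(row)


def read_survey_csv(path: str | Path) -> list[SurveyResponse]:
    responses: list[SurveyResponse] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(SURVEY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: missing survey columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ranks = tuple(
                    NeedArea(row[c]) for c in ("rank1", "rank2", "rank3") if row[c]
                )
                wtp = {
                    service: float(row[col])
                    for service, col in _WTP_COLS.items()
                    if row[col] != ""
                }
                response = SurveyResponse(
                    respondent_id=row["respondent_id"],
                    group=Group(row["group"]),
                    ranks=ranks,
                    preferred_service=(
                        ServiceType(row["preferred_service"])
                        if row["preferred_service"]
                        else None
                    ),
                    wtp=wtp,
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            response.validate()
            responses.append(response)
    return responses


def write_dispatch_csv(records: list[DispatchRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DISPATCH_COLUMNS)
        for r in records:
            writer.writerow(
                [r.report_id, r.date.isoformat(), r.category.value, r.n_patients]
            )


def read_dispatch_csv(path: str | Path) -> list[DispatchRecord]:
    records: list[DispatchRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(DISPATCH_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: missing dispatch columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                record = DispatchRecord(
                    report_id=row["report_id"],
                    date=datetime.date.fromisoformat(row["date"]),
                    category=ReportCategory(row["category"]),
                    n_patients=int(row["n_patients"]),
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            record.validate()
            records.append(record)
    return records
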