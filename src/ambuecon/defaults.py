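"""Published constants of the Kinshasa (DR Congo) pilot ambulance study.

Everything here is a printed survey or pilot statistic: group sizes,
per-group willingness-to-pay (WTP) means and standard deviations elicited
with the open-ended contingent valuation method, need-area rank
frequencies, pay-service preference frequencies, and the three-month
dispatch-log totals. These numbers parameterize the synthetic-data
generator and price the non-solved services in the scenario model.
"""

from __future__ import annotations

import datetime

from .enums import Group, NeedArea, ReportCategory, ServiceType

#: Respondents per stakeholder group.
GROUP_SIZES: dict[Group, int] = {
    Group.PATIENTS: 19,
    Group.POLICEMEN: 20,
    Group.HOSPITAL_STAFF: 63,
    Group.AMBULANCE_PERSONNEL: 31,
}

#: Open-ended WTP (mean USD, sd USD) per (group, service type).
WTP_PARAMS: dict[tuple[Group, ServiceType], tuple[float, float]] = {
    (Group.PATIENTS, ServiceType.FIELD_TO_HOSPITAL): (26.63, 20.13),
    (Group.POLICEMEN, ServiceType.FIELD_TO_HOSPITAL): (37.00, 33.73),
    (Group.HOSPITAL_STAFF, ServiceType.FIELD_TO_HOSPITAL): (60.40, 31.00),
    (Group.AMBULANCE_PERSONNEL, ServiceType.FIELD_TO_HOSPITAL): (54.50, 27.05),
    (Group.PATIENTS, ServiceType.HOSPITAL_TO_HOSPITAL): (31.53, 24.80),
    (Group.POLICEMEN, ServiceType.HOSPITAL_TO_HOSPITAL): (49.50, 25.64),
    (Group.HOSPITAL_STAFF, ServiceType.HOSPITAL_TO_HOSPITAL): (76.83, 23.27),
    (Group.AMBULANCE_PERSONNEL, ServiceType.HOSPITAL_TO_HOSPITAL): (66.61, 32.80),
    (Group.PATIENTS, ServiceType.HOME_VISIT): (5.32, 2.96),
    (Group.POLICEMEN, ServiceType.HOME_VISIT): (35.10, 32.95),
    (Group.HOSPITAL_STAFF, ServiceType.HOME_VISIT): (60.63, 12.30),
    (Group.AMBULANCE_PERSONNEL, ServiceType.HOME_VISIT): (86.77, 21.66),
}

#: Group WTP means by service, used to price the non-solved services of a
#: scenario (the operator's own constituency sets the charge).
WTP_MEANS: dict[Group, dict[ServiceType, float]] = {
    g: {s: WTP_PARAMS[(g, s)][0] for s in ServiceType} for g in Group
}

#: Need-area rank frequencies: area -> (1st-place, 2nd-place, 3rd-place) counts.
RANK_FREQS: dict[NeedArea, tuple[int, int, int]] = {
    NeedArea.TRAFFIC_COLLISIONS: (88, 15, 14),
    NeedArea.NONTRAFFIC_INJURIES: (23, 46, 30),
    NeedArea.EMERGENCY_DISEASE: (14, 49, 49),
    NeedArea.DRUG_INTOXICATION: (2, 5, 9),
    NeedArea.INTERHOSPITAL_TRANSPORT: (6, 18, 30),
    NeedArea.OTHER: (0, 0, 1),
}

#: Pay-service preference counts per group, ordered
#: (field_to_hospital, hospital_to_hospital, home_visit).
PREFERENCE_FREQS: dict[Group, tuple[int, int, int]] = {
    Group.PATIENTS: (3, 1, 12),
    Group.POLICEMEN: (8, 2, 10),
    Group.HOSPITAL_STAFF: (20, 19, 24),
    Group.AMBULANCE_PERSONNEL: (10, 12, 6),
}

#: Fraction of each group that stated any pay-service preference
#: (preference totals 127 of 133 respondents).
PREFERENCE_RESPONSE_RATE: dict[Group, float] = {
    g: sum(PREFERENCE_FREQS[g]) / GROUP_SIZES[g] for g in Group
}

# Pilot dispatch log: three months of field operations.
PILOT_START = datetime.date(2013, 9, 18)
PILOT_END = datetime.date(2013, 12, 15)
PILOT_DAYS = (PILOT_END - PILOT_START).days + 1  # inclusive span: 89 days
PILOT_TOTAL_REPORTS = 162
PILOT_TOTAL_PATIENTS = 212

#: Exclusive category counts; transports to hospital total 155 (121 of them
#: traffic collisions), the remaining 7 reports led to no transport.
PILOT_CATEGORY_COUNTS: dict[ReportCategory, int] = {
    ReportCategory.TRAFFIC_TRANSPORT: 121,
    ReportCategory.NONTRAFFIC_TRANSPORT: 34,
    ReportCategory.OTHER_NONTRANSPORT: 7,
}

#: Package-wide default random seed (pilot start date, YYYYMMDD).
DEFAULT_SEED = 20130918
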