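"""Controlled vocabularies shared across the package."""

from __future__ import annotations

import enum


class Group(str, enum.Enum):
    """Stakeholder group surveyed during the pilot service."""

    PATIENTS = "patients"
    POLICEMEN = "policemen"
    HOSPITAL_STAFF = "hospital_staff"
    AMBULANCE_PERSONNEL = "ambulance_personnel"


class ServiceType(str, enum.Enum):
    """The three chargeable ambulance service types."""

    FIELD_TO_HOSPITAL = "field_to_hospital"
    HOSPITAL_TO_HOSPITAL = "hospital_to_hospital"
    HOME_VISIT = "home_visit"


class NeedArea(str, enum.Enum):
    """Candidate areas of ambulance-service need ranked by respondents."""

    TRAFFIC_COLLISIONS = "traffic_collisions"
    NONTRAFFIC_INJURIES = "nontraffic_injuries"
    EMERGENCY_DISEASE = "emergency_disease"
    DRUG_INTOXICATION = "drug_intoxication"
    INTERHOSPITAL_TRANSPORT = "interhospital_transport"
    OTHER = "other"


class ReportCategory(str, enum.Enum):
    """Mutually exclusive dispatch-report categories.

    The pilot's headline figures overlap (most traffic-collision reports were
    also hospital transports), so the exclusive partition separates transports
    by cause; the overlapping margins are recomputed at summary time.
    """

    TRAFFIC_TRANSPORT = "traffic_transport"
    NONTRAFFIC_TRANSPORT = "nontraffic_transport"
    OTHER_NONTRANSPORT = "other_nontransport"


class Operator(str, enum.Enum):
    """Principal operator of the ambulance service."""

    INDEPENDENT = "independent"
    HOSPITAL = "hospital"
    POLICE = "police"


class Role(str, enum.Enum):
    """Payroll roles in the cost model."""

    PHYSICIAN = "physician"
    NURSE = "nurse"
    DRIVER = "driver"
    TELEPHONE_OPERATOR = "telephone_operator"


class PaymentMode(str, enum.Enum):
    """How an ambulance crew is compensated."""

    SALARIED = "salaried"
    INCENTIVE_PER_OPERATION = "incentive_per_operation"
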