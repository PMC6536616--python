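from datetime import date, timedelta

import pytest

from bmis_turnover import InvestigatorHistory, Location, SubmissionRecord


def make_record(
    last="SMITH",
    first="ANN",
    country="USA",
    when=date(2001, 1, 1),
    **passthrough,
):
    return SubmissionRecord(
        last_name=last,
        first_name=first,
        country_name=country,
        receipt_date=when,
        passthrough=passthrough,
    )


def make_history(newid, dates, location=Location.US, last="SMITH", first="ANN"):
    return InvestigatorHistory(
        newid=newid,
        last_name=last,
        first_name=first,
        submissions=tuple(sorted(dates)),
        location=location,
    )


@pytest.fixture
def hand_cohort():
    """Four investigators: one single-submission, three with gaps 5/50/5000 d."""
    base = date(2000, 6, 1)
    return [
        make_history(1, [base], last="A"),
        make_history(2, [base, base + timedelta(days=5)], last="B"),
        make_history(3, [base, base + timedelta(days=50)], last="C"),
        make_history(4, [base, base + timedelta(days=5000)], last="D",
                     location=Location.NON_US),
    ]
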