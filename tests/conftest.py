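import itertools

import pytest

from kneebench.registry import ConstructKey, ProcedureRecord, Registry

_COUNTER = itertools.count()

DEFAULT_KEY = ConstructKey("Acme", "cemented", "fixed", "CR")


def make_records(pairs, construct=DEFAULT_KEY):
    """Build ProcedureRecords from (time, status) pairs."""
    return [
        ProcedureRecord(
            procedure_id=f"p{next(_COUNTER):07d}",
            construct=construct,
            time_years=float(t),
            status=status,
        )
        for t, status in pairs
    ]


@pytest.fixture
def toy_records():
    """The 4-record worked example: F(3) = 0.625, Greenwood Var = 0.08203125."""
    return make_records(
        [(1, "revision"), (2, "censored"), (3, "revision"), (4, "censored")]
    )


@pytest.fixture
def small_registry():
    keys = [
        ConstructKey("Acme", "cemented", "fixed", "CR"),
        ConstructKey("Acme", "cemented", "fixed", "PS"),
        ConstructKey("Zenith", "uncemented", "mobile", "CR"),
    ]
    records = []
    for key in keys:
        records.extend(
            make_records([(2.0, "censored"), (5.0, "revision"), (8.0, "death")], key)
        )
    return Registry(records=records)
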