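import pytest

from ohfa.io import load_fixture
from ohfa.profiles import (
    Basis,
    Branching,
    ConditionVariable,
    FattyAcidDescriptor,
    Measurement,
    SampleProfile,
    ValueKind,
)


def oh(carbon, branching=Branching.NORMAL, unsat=0):
    """Shorthand for a 3-OH descriptor."""
    return FattyAcidDescriptor(carbon, branching, unsat, True)


def make_profile(values, *, basis=Basis.TOTAL_3OH_FAS, level=25.0, rep="r1",
                 strain="S", kind=ValueKind.RELATIVE_ABUNDANCE):
    """Profile from a descriptor -> abundance mapping (None = n.d.)."""
    p = SampleProfile(
        strain_id=strain,
        condition_variable=ConditionVariable.TEMPERATURE_C,
        condition_value=level,
        replicate_id=rep,
        basis=basis,
    )
    for desc, v in values.items():
        if v is None:
            p.add(Measurement(desc, None, kind, False))
        else:
            p.add(Measurement(desc, float(v), kind, True))
    return p


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5")


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6")


@pytest.fixture(scope="session")
def oh_tables(table4, table5, table6):
    return {"table4": table4, "table5": table5, "table6": table6}
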