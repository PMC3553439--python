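import pytest

from poptk import (
    BreastfeedingSchedule,
    ChildPhysiology,
    CompoundParams,
    DyadProfile,
    MaternalPhysiology,
)


@pytest.fixture
def pcb153():
    return CompoundParams("PCB-153", 14.4)


@pytest.fixture
def maternal():
    return MaternalPhysiology(age_at_delivery=25.0, prepregnancy_weight=60.2)


@pytest.fixture
def child():
    return ChildPhysiology(
        sex="female", birth_weight=3.4, weight_records=((0.5, 7.9), (1.0, 9.5))
    )


@pytest.fixture
def dyad(maternal, child):
    feeding = BreastfeedingSchedule(exclusive_duration=0.25, partial_duration=0.5)
    return DyadProfile(maternal=maternal, child=child, feeding=feeding)


@pytest.fixture
def dyad_no_bf(maternal, child):
    feeding = BreastfeedingSchedule(exclusive_duration=0.0)
    return DyadProfile(maternal=maternal, child=child, feeding=feeding)
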