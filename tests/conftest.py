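import numpy as np
import pytest

from segtrends.io_dataset import PERIODS, GroupedSample, SegmentRecord


def make_record(i=0, **kwargs):
    defaults = dict(
        species_id=f"sp{i:04d}",
        order_name="Phacopida",
        family_name="Phacopida_fam1",
        period="Cambrian",
        thorax=8,
        pygidium=9,
    )
    defaults.update(kwargs)
    return SegmentRecord(**defaults)


def grouped(variable="thorax", **groups):
    return GroupedSample(
        variable=variable,
        groups={k: np.asarray(v, dtype=float) for k, v in groups.items()},
    )


@pytest.fixture
def toy_records():
    """One record per period, thorax increasing with age rank."""
    return [
        make_record(i, period=p, thorax=5 + i, pygidium=3 + i)
        for i, p in enumerate(PERIODS)
    ]


@pytest.fixture
def shift_carrier_records():
    """Two periods, two orders; the 'Shifter' order carries the entire
    Cambrian->Ordovician median shift, 'Stable' is flat."""
    records = []
    i = 0
    for period, shifter_thorax in (("Cambrian", 5), ("Ordovician", 15)):
        for j in range(20):
            jitter = j % 3 - 1  # -1, 0, +1 spread keeps medians stable
            records.append(
                make_record(i, period=period, order_name="Shifter",
                            family_name="Shifter_fam1",
                            thorax=shifter_thorax + jitter, pygidium=4)
            )
            i += 1
            records.append(
                make_record(i, period=period, order_name="Stable",
                            family_name="Stable_fam1", thorax=10 + jitter, pygidium=4)
            )
            i += 1
    return records
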