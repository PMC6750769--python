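import datetime as dt

import numpy as np
import pytest

from cfdattain import CriterionSpec, MonitoringRecord


@pytest.fixture
def make_record():
    """Factory for monitoring records with sensible defaults."""

    def _make(
        do_value,
        weight=1.0,
        date=dt.date(2000, 7, 15),
        segment="SEG001",
        use="OW",
        station="ST1",
    ):
        return MonitoringRecord(
            station_or_cell_id=station,
            timestamp=date,
            segment_id=segment,
            designated_use=use,
            do_value=do_value,
            weight=weight,
        )

    return _make


@pytest.fixture
def ow_criterion():
    return CriterionSpec("OW", 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160914)
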